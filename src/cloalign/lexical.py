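"""Label/xref normalization and the shortest Levenshtein distance (SLD).

Cell-line names are compared after a conservative normalization: Unicode
compatibility folding, case folding, mapping typographic dash variants to the
ASCII hyphen, and whitespace collapsing. Punctuation is deliberately kept —
cell line "17/14" (ATCC HB-8153) is a different line from "171-4" (ATCC
HB-296), and stripping punctuation would conflate them.

The SLD between two records is the minimum Levenshtein distance over the
cross product of their normalized name sets (labels plus synonyms). Distances
are computed with edlib; unit edit costs throughout.
"""

from __future__ import annotations

import re
import unicodedata

import edlib

# every Unicode dash/hyphen variant collapses to ASCII "-"
_DASHES = "‐‑‒–—―−­⁃"
_DASH_TABLE = str.maketrans({c: "-" for c in _DASHES})
_WS_RE = re.compile(r"\s+")

_CVCL_RE = re.compile(r"^CVCL_[0-9A-Za-z]{4}$")
_XREF_SPLIT_RE = re.compile(r"^\s*([A-Za-z][A-Za-z0-9._-]*?)\s*[:\s]\s*(\S.*?)\s*$")


def normalize_label(raw: str) -> str:
    """Normalize a cell-line name for lexical comparison.

    Idempotent; empty input yields the empty string. Punctuation survives.
    """
    s = unicodedata.normalize("NFKC", raw)
    s = s.casefold()
    s = s.translate(_DASH_TABLE)
    s = _WS_RE.sub(" ", s).strip()
    return s


def normalize_xref(raw: str) -> str:
    """Canonicalize a database cross-reference to ``PREFIX:id`` form.

    Bare Cellosaurus accessions (``CVCL_xxxx``) get the CELLOSAURUS prefix;
    otherwise the resource prefix is upper-cased and the prefix/id separator
    becomes ":". A token with no recognizable separator is returned stripped.
    """
    s = raw.strip()
    if _CVCL_RE.match(s):
        return f"CELLOSAURUS:{s}"
    m = _XREF_SPLIT_RE.match(s)
    if m:
        return f"{m.group(1).upper()}:{m.group(2)}"
    return s


def levenshtein(a: str, b: str) -> int:
    """Plain Levenshtein distance with unit edit costs."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    try:
        d = edlib.align(a, b, task="distance")["editDistance"]
    except (ValueError, UnicodeError):  # edlib alphabets cap at 256 symbols
        d = _dp_levenshtein(a, b)
    return d


def _dp_levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def sld(names_a: set[str], names_b: set[str]) -> int:
    """Shortest Levenshtein distance over all pairs of (normalized) names.

    Zero iff the two name sets intersect. Both sets must be non-empty.
    """
    if not names_a or not names_b:
        raise ValueError("SLD requires two non-empty name sets")
    if names_a & names_b:
        return 0
    return min(levenshtein(a, b) for a in names_a for b in names_b)


def normalized_names(names: set[str]) -> set[str]:
    """Apply label normalization to a name set, dropping empty results."""
    return {n for n in (normalize_label(x) for x in names) if n}
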