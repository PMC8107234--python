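"""Thin wrappers over edlib returning match/column counts.

edlib computes unit-cost edit alignments; identity here is always
matches / alignment columns, read off the extended CIGAR, so the scoring
scheme only influences the alignment path, never the identity definition.
"""

from __future__ import annotations

import re

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def cigar_stats(cigar: str) -> tuple[int, int]:
    """Return (matches, columns) from an extended CIGAR string."""
    matches = 0
    columns = 0
    for count, op in _CIGAR_RE.findall(cigar):
        n = int(count)
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def global_identity(a: str, b: str) -> tuple[float, int]:
    """Needleman–Wunsch identity of two sequences: (fraction, columns)."""
    if not a or not b:
        raise ValueError("empty sequence")
    res = edlib.align(a, b, mode="NW", task="path")
    matches, columns = cigar_stats(res["cigar"])
    return matches / columns, columns


def infix_identity(query: str, window: str, max_dist: int = -1) -> tuple[float, int] | None:
    """Align query inside window (free end gaps in the window only).

    Returns (identity fraction, columns) or None when the alignment is
    rejected by ``max_dist``.
    """
    res = edlib.align(query, window, mode="HW", task="path", k=max_dist)
    if res["editDistance"] < 0 or res["cigar"] is None:
        return None
    matches, columns = cigar_stats(res["cigar"])
    return matches / columns, columns
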