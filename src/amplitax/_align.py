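"""Pairwise nucleotide identity, used everywhere identity appears.

Identity is defined once, consistently: matches / alignment columns of a
global alignment.  When the two sequences differ substantially in length
(a truncated read against a full-length seed) the shorter is aligned
end-gap-free within the longer, so missing tail sequence is not
penalised.  edlib provides the alignments.
"""

from __future__ import annotations

import re

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _cigar_columns(cigar: str) -> int:
    return sum(int(n) for n, _ in _CIGAR_RE.findall(cigar))


def identity(a: str, b: str) -> float:
    """Fraction of matching columns in the pairwise alignment of a and b."""
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    # infix mode leaves the longer sequence's overhang unpenalised
    mode = "HW" if len(query) < len(target) else "NW"
    res = edlib.align(query, target, mode=mode, task="path")
    cols = _cigar_columns(res["cigar"])
    if cols == 0:
        return 0.0
    return (cols - res["editDistance"]) / cols


def percent_identity(a: str, b: str) -> float:
    return 100.0 * identity(a, b)
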