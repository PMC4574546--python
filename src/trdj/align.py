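"""Global pairwise alignment and percent-identity utilities.

All alignment in the package goes through one scoring scheme so that
identity thresholds, numbering transfer and the progressive MSA are
mutually consistent: match +1, mismatch -1, gap open -4, gap extend -1,
with a deterministic choice among co-optimal alignments.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align

MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -4.0
GAP_EXTEND = -1.0


class AlignmentError(ValueError):
    """Raised for empty inputs or unalignable sequence pairs."""


@lru_cache(maxsize=4)
def _aligner(molecule: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def global_align(a: str, b: str, molecule: str = "dna") -> tuple[str, str, float]:
    """Globally align two sequences.

    Returns the two gapped strings plus the optimal score.  The first
    alignment reported by the underlying dynamic program is used, which
    is deterministic for fixed inputs.
    """
    if not a or not b:
        raise AlignmentError("cannot align empty sequence")
    aln = _aligner(molecule).align(a.upper(), b.upper())[0]
    ga, gb = str(aln[0]), str(aln[1])
    return ga, gb, aln.score


def _terminal_gap_mask(ga: str, gb: str) -> list[bool]:
    """True for columns inside a leading/trailing gap run of either row."""
    n = len(ga)
    mask = [False] * n
    for row in (ga, gb):
        i = 0
        while i < n and row[i] == "-":
            mask[i] = True
            i += 1
        i = n - 1
        while i >= 0 and row[i] == "-":
            mask[i] = True
            i -= 1
    return mask


def pairwise_identity(a: str, b: str, molecule: str = "dna") -> float:
    """Percent identity over a global alignment.

    The denominator counts every aligned column except those lying in a
    terminal-gap run of either sequence, so that comparing a complete
    gene against a 5'- or 3'-truncated one is not penalised for the
    missing ends.  Arguments are ordered canonically before aligning so
    that identity is exactly symmetric even when co-optimal alignments
    differ in gap placement.
    """
    if b.upper() < a.upper():
        a, b = b, a
    ga, gb, _ = global_align(a, b, molecule)
    mask = _terminal_gap_mask(ga, gb)
    matches = cols = 0
    for x, y, skip in zip(ga, gb, mask):
        if skip:
            continue
        cols += 1
        if x == y and x != "-":
            matches += 1
    if cols == 0:
        raise AlignmentError("no aligned columns outside terminal gaps")
    return 100.0 * matches / cols
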