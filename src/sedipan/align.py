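"""Global protein alignment with free terminal gaps (semi-global).

This provides the identity and coverage statistics that define protein
family membership. The identity convention is *global identity over the
shorter sequence*: ``identity_short = matches / len(shorter)``, matching
the convention of greedy identity/coverage clustering tools. Coverage of
each sequence is the fraction of it spanned by the aligned region
(first to last aligned residue, inclusive).

Default scoring is BLOSUM62 with affine gaps (open 11, extend 1) and free
end gaps. To make results symmetric under argument swap, the pair is
canonicalized before alignment (longer sequence first; ties broken
lexicographically), so ``global_align(a, b)`` and ``global_align(b, a)``
derive their statistics from the same traceback.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .formats import SequenceRecord

__all__ = ["AlignmentResult", "global_align", "make_aligner"]


@dataclass(frozen=True)
class AlignmentResult:
    """Statistics of one pairwise semi-global alignment.

    ``matches`` counts identical aligned residue pairs; ``aligned_columns``
    counts residue-residue columns (gap columns excluded); coverage values
    are fractions of each sequence inside the aligned span.
    """

    matches: int
    aligned_columns: int
    identity_short: float
    cov_long: float
    cov_short: float
    score: float


@lru_cache(maxsize=8)
def make_aligner(
    matrix_name: str = "BLOSUM62", gap_open: float = 11.0, gap_extend: float = 1.0
) -> Align.PairwiseAligner:
    """Build (and cache) the semi-global aligner used across the package."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.mode = "global"
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    # free terminal gaps on both sequences -> semi-global
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def _residues(x: SequenceRecord | str) -> str:
    return x.residues if isinstance(x, SequenceRecord) else x


def global_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal semi-global alignment of two protein sequences.

    Raises ``ValueError`` on empty input. Ties between equal-scoring
    alignments are resolved by the aligner's deterministic traceback on the
    canonicalized (longer-first) argument order.
    """
    sa, sb = _residues(a), _residues(b)
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    # canonical order: longer first, lexicographic tie-break => symmetry
    if (len(sb), sb) > (len(sa), sa):
        sa, sb = sb, sa
    long_seq, short_seq = sa, sb

    aligner = make_aligner(matrix_name, gap_open, gap_extend)
    alignment = aligner.align(long_seq, short_seq)[0]
    long_blocks, short_blocks = alignment.aligned

    matches = 0
    aligned_columns = 0
    for (ls, le), (ss, se) in zip(long_blocks, short_blocks):
        aligned_columns += int(le - ls)
        for x, y in zip(long_seq[ls:le], short_seq[ss:se]):
            if x == y:
                matches += 1

    if aligned_columns == 0:
        cov_long = cov_short = 0.0
    else:
        span_long = int(long_blocks[-1][1] - long_blocks[0][0])
        span_short = int(short_blocks[-1][1] - short_blocks[0][0])
        cov_long = span_long / len(long_seq)
        cov_short = span_short / len(short_seq)

    return AlignmentResult(
        matches=matches,
        aligned_columns=aligned_columns,
        identity_short=matches / len(short_seq),
        cov_long=cov_long,
        cov_short=cov_short,
        score=float(alignment.score),
    )
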