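"""Pairwise alignment kernels shared by the clustering and orthology stages.

Two kernels are exposed:

``pairwise_identity``
    Global (Needleman-Wunsch, affine gaps) nucleotide alignment scored
    match +1 / mismatch -2 / gap open -4 / gap extend -1.  Percent identity
    is the number of matched columns over all alignment columns excluding
    terminal-gap columns.  ``N`` never counts as a match.

``protein_similarity``
    Local (Smith-Waterman, affine gaps) amino-acid alignment under BLOSUM62
    with gap open -11 / gap extend -1.  Returns the raw score, percent
    identity over aligned columns, and query coverage.

Both are exact dynamic-programming alignments (Bio.Align.PairwiseAligner).
``identity_upper_bound`` provides a cheap edit-distance bound used to skip
alignments that provably cannot reach a clustering threshold.
"""

from __future__ import annotations

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

NT_MATCH = 1.0
NT_MISMATCH = -2.0
NT_GAP_OPEN = -4.0
NT_GAP_EXTEND = -1.0

PROT_GAP_OPEN = -11.0
PROT_GAP_EXTEND = -1.0

_NT_ALPHABET = "ACGTN"


def _nt_matrix() -> substitution_matrices.Array:
    m = substitution_matrices.Array(_NT_ALPHABET, dims=2)
    for x in _NT_ALPHABET:
        for y in _NT_ALPHABET:
            # N matches nothing, not even another N
            m[x, y] = NT_MATCH if (x == y and x != "N") else NT_MISMATCH
    return m


def nucleotide_aligner() -> Align.PairwiseAligner:
    """Global affine-gap nucleotide aligner with the module's scoring."""
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = _nt_matrix()
    al.open_gap_score = NT_GAP_OPEN
    al.extend_gap_score = NT_GAP_EXTEND
    return al


def protein_aligner() -> Align.PairwiseAligner:
    """Local BLOSUM62 aligner (gap open -11, extend -1)."""
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = PROT_GAP_OPEN
    al.extend_gap_score = PROT_GAP_EXTEND
    return al


_NT_ALIGNER = None
_PROT_ALIGNER = None


def _get_nt_aligner() -> Align.PairwiseAligner:
    global _NT_ALIGNER
    if _NT_ALIGNER is None:
        _NT_ALIGNER = nucleotide_aligner()
    return _NT_ALIGNER


def _get_prot_aligner() -> Align.PairwiseAligner:
    global _PROT_ALIGNER
    if _PROT_ALIGNER is None:
        _PROT_ALIGNER = protein_aligner()
    return _PROT_ALIGNER


def _trim_terminal_gaps(row_a: str, row_b: str) -> tuple[int, int]:
    """Return (start, stop) column bounds after removing terminal-gap runs."""
    n = len(row_a)
    lead = 0
    while lead < n and (row_a[lead] == "-" or row_b[lead] == "-"):
        lead += 1
    trail = n
    while trail > lead and (row_a[trail - 1] == "-" or row_b[trail - 1] == "-"):
        trail -= 1
    return lead, trail


def _validate_nt(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - set(_NT_ALPHABET)
    if bad:
        raise ValueError(f"{name}: non-ACGTN characters {sorted(bad)!r}")
    return seq


def alignment_identity(row_a: str, row_b: str) -> float:
    """Percent identity of a gapped alignment, terminal-gap columns excluded."""
    lead, trail = _trim_terminal_gaps(row_a, row_b)
    columns = trail - lead
    if columns == 0:
        return 0.0
    matches = 0
    for x, y in zip(row_a[lead:trail], row_b[lead:trail]):
        if x == y and x != "-" and x != "N":
            matches += 1
    return 100.0 * matches / columns


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment percent identity between two nucleotide sequences.

    Symmetric; ``N`` columns never count as matches; terminal-gap columns
    are excluded from the denominator.
    """
    seq_a = _validate_nt(seq_a, "seq_a")
    seq_b = _validate_nt(seq_b, "seq_b")
    if seq_a == seq_b and "N" not in seq_a:
        return 100.0
    # canonical argument order: co-optimal alignments may differ in match
    # count, so the pair is always aligned the same way round
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    aln = _get_nt_aligner().align(seq_a, seq_b)[0]
    return alignment_identity(str(aln[0]), str(aln[1]))


def identity_upper_bound(seq_a: str, seq_b: str) -> float:
    """Cheap upper bound on ``pairwise_identity`` from the unit-cost edit distance.

    Any alignment has at least ``D`` (the edit distance) non-match columns,
    so matches <= (|a| + |b| - D) / 2.  Dividing by the shortest sequence
    length (a lower bound on non-terminal columns for this scoring scheme)
    gives a conservative bound used for prescreening only.
    """
    la, lb = len(seq_a), len(seq_b)
    d = edlib.align(seq_a, seq_b, mode="NW", task="distance")["editDistance"]
    matches_ub = (la + lb - d) / 2.0
    return min(100.0, 100.0 * matches_ub / min(la, lb))


_AA_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")


def _sanitize_protein(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    seq = seq.upper().rstrip("*")
    if not seq:
        raise ValueError(f"{name}: sequence contains only stop characters")
    # anything outside the standard 20 letters is treated as X (mismatch-like)
    return "".join(c if c in _AA_STANDARD else "X" for c in seq)


def protein_alignment_stats(prot_a: str, prot_b: str) -> tuple[float, float, float, float]:
    """Local-alignment statistics for an amino-acid pair.

    Returns ``(score, identity_pct, coverage_a_pct, coverage_b_pct)`` where
    identity is over aligned columns (gaps included) and coverage is the
    fraction of each sequence's residues inside the aligned region.
    """
    a = _sanitize_protein(prot_a, "prot_a")
    b = _sanitize_protein(prot_b, "prot_b")
    aligner = _get_prot_aligner()
    alns = aligner.align(a, b)
    if len(alns) == 0 or alns.score <= 0:
        return 0.0, 0.0, 0.0, 0.0
    aln = alns[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    lead, trail = _trim_terminal_gaps(row_a, row_b)
    columns = trail - lead
    if columns == 0:
        return float(aln.score), 0.0, 0.0, 0.0
    seg_a = row_a[lead:trail]
    seg_b = row_b[lead:trail]
    matches = sum(1 for x, y in zip(seg_a, seg_b) if x == y and x != "-")
    res_a = columns - seg_a.count("-")
    res_b = columns - seg_b.count("-")
    identity = 100.0 * matches / columns
    return (
        float(aln.score),
        identity,
        100.0 * res_a / len(a),
        100.0 * res_b / len(b),
    )


def protein_similarity(prot_a: str, prot_b: str) -> tuple[float, float, float]:
    """(score, identity_pct, query_coverage_pct) for ``prot_a`` vs ``prot_b``."""
    score, identity, cov_a, _ = protein_alignment_stats(prot_a, prot_b)
    return score, identity, cov_a


def protein_self_score(prot: str) -> float:
    """BLOSUM62 score of a protein aligned to itself (no alignment needed)."""
    p = _sanitize_protein(prot, "prot")
    bl = substitution_matrices.load("BLOSUM62")
    return float(sum(bl[c, c] for c in p))
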