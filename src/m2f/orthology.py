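"""Reciprocal-best-hit orthology and the percent-shared-genes statistic.

Every protein is searched against the partner proteome under local BLOSUM62
alignment; a hit counts only when the raw score reaches ``score_floor`` and
the query coverage reaches ``coverage_floor``.  Reciprocal best hits form
the matched set.  Percent shared genes is

    100 * 2 * |matched pairs| / (n_genes_a + n_genes_b)

i.e. matched genes counted once per genome over the total genes in both
("dual" formula; a union-of-families variant is available).

Unmatched proteins can be validated by a translated search against the
partner's genome assembly (all six reading frames, bacterial code), the
in-package analogue of a tBLASTn check.  Significance there uses identity
and query coverage above 70% plus the raw-score floor; no e-value model is
used at this corpus scale.

For speed the all-vs-all search skips sequence pairs that share fewer
than four 6-mers (no plausible hit can pass the score and coverage floors
without them; short proteins are always aligned); identical sequences short-circuit to their self-score, which is the
maximum any local alignment can reach.  Set ``prefilter=False`` to force
full dynamic programming everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import protein_alignment_stats, protein_self_score
from .genomes import AnnotatedGenome, reverse_complement, translate_cds

SCORE_FLOOR = 50.0
COVERAGE_FLOOR = 50.0
VALIDATION_IDENTITY = 70.0
VALIDATION_COVERAGE = 70.0

_KMER_K = 6
_KMER_MIN_SHARED = 4
_KMER_MIN_LEN = 40  # prescreen only applies to proteins at least this long


@dataclass
class PairComparison:
    """Proteome comparison between two genomes."""

    genome_a: str
    genome_b: str
    n_genes_a: int
    n_genes_b: int
    matched_pairs: list[tuple[str, str]]
    unmatched_a: list[str]
    unmatched_b: list[str]
    percent_shared: float
    marker_bin: float | None = None


@dataclass
class ValidationResult:
    protein_id: str
    best_identity: float
    best_coverage: float
    best_score: float
    significant: bool


def _kmers(seq: str, k: int = _KMER_K) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def _hamming_identity(a: str, b: str) -> float:
    """Percent identical positions of two equal-length strings."""
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def percent_shared(n_a: int, n_b: int, matched: int, formula: str = "dual") -> float:
    if formula == "dual":
        return 100.0 * (2.0 * matched) / (n_a + n_b)
    if formula == "union":
        return 100.0 * matched / (n_a + n_b - matched)
    raise ValueError(f"unknown shared-gene formula {formula!r}")


def rbh_match(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    genome_a: str = "A",
    genome_b: str = "B",
    score_floor: float = SCORE_FLOOR,
    coverage_floor: float = COVERAGE_FLOOR,
    formula: str = "dual",
    prefilter: bool = True,
) -> PairComparison:
    """Reciprocal-best-hit ortholog matching between two proteomes."""
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")

    ids_a = sorted(proteome_a)
    ids_b = sorted(proteome_b)
    seq_a = {i: proteome_a[i].upper().rstrip("*") for i in ids_a}
    seq_b = {i: proteome_b[i].upper().rstrip("*") for i in ids_b}

    by_seq_b: dict[str, list[str]] = {}
    for j in ids_b:
        by_seq_b.setdefault(seq_b[j], []).append(j)
    kmers_a = {i: _kmers(seq_a[i]) for i in ids_a} if prefilter else {}
    kmers_b = {j: _kmers(seq_b[j]) for j in ids_b} if prefilter else {}

    # hits[(i, j)] = (score, cov_a, cov_b); computed once per unordered pair
    hits: dict[tuple[str, str], tuple[float, float, float]] = {}
    for i in ids_a:
        sa = seq_a[i]
        identical = by_seq_b.get(sa, [])
        for j in identical:
            hits[(i, j)] = (protein_self_score(sa), 100.0, 100.0)
        for j in ids_b:
            if (i, j) in hits:
                continue
            sb = seq_b[j]
            if (
                prefilter
                and len(sa) >= _KMER_MIN_LEN
                and len(sb) >= _KMER_MIN_LEN
                and len(kmers_a[i] & kmers_b[j]) < _KMER_MIN_SHARED
                # short highly diverged homologs can lack shared 6-mers;
                # equal-length pairs get a cheap positional-identity rescue
                and not (len(sa) == len(sb) and _hamming_identity(sa, sb) >= 50.0)
            ):
                continue
            score, _ident, cov_a, cov_b = protein_alignment_stats(sa, sb)
            if score > 0:
                hits[(i, j)] = (score, cov_a, cov_b)

    def _best(axis: int) -> dict[str, tuple[str, float]]:
        best: dict[str, tuple[str, float]] = {}
        for (i, j), (score, cov_a, cov_b) in hits.items():
            q, t = (i, j) if axis == 0 else (j, i)
            cov = (cov_a, cov_b)[axis]
            if score < score_floor or cov < coverage_floor:
                continue
            cur = best.get(q)
            # ties broken by lexicographically smaller target id
            if cur is None or score > cur[1] or (score == cur[1] and t < cur[0]):
                best[q] = (t, score)
        return best

    best_a = _best(0)  # a -> b, coverage of a
    best_b = _best(1)  # b -> a, coverage of b

    reciprocal: list[tuple[float, str, str]] = []
    for i, (j, score) in best_a.items():
        back = best_b.get(j)
        if back is not None and back[0] == i:
            reciprocal.append((score, i, j))

    # greedy one-to-one resolution, highest score first (best-hit maps are
    # already injective; the sort makes tie handling explicit)
    reciprocal.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    matched: list[tuple[str, str]] = []
    for _score, i, j in reciprocal:
        if i in used_a or j in used_b:
            continue
        matched.append((i, j))
        used_a.add(i)
        used_b.add(j)

    matched.sort()
    return PairComparison(
        genome_a=genome_a,
        genome_b=genome_b,
        n_genes_a=len(ids_a),
        n_genes_b=len(ids_b),
        matched_pairs=matched,
        unmatched_a=[i for i in ids_a if i not in used_a],
        unmatched_b=[j for j in ids_b if j not in used_b],
        percent_shared=percent_shared(len(ids_a), len(ids_b), len(matched), formula),
    )


# ---------------------------------------------------------------------------
# translated-search validation of unmatched proteins


def six_frame_segments(contigs: dict[str, str], min_len: int = 20) -> list[str]:
    """Stop-free amino-acid segments from all six reading frames (table 11)."""
    segments: list[str] = []
    for seq in contigs.values():
        for strand_seq in (seq, reverse_complement(seq)):
            for offset in range(3):
                frame = strand_seq[offset:]
                frame = frame[: len(frame) - len(frame) % 3]
                if not frame:
                    continue
                aa = translate_cds(frame + "TAA")  # helper drops trailing stop
                for seg in aa.split("*"):
                    if len(seg) >= min_len:
                        segments.append(seg)
    return segments


def validate_unmatched(
    protein: str,
    partner_contigs: dict[str, str],
    protein_id: str = "",
    score_floor: float = SCORE_FLOOR,
    identity_floor: float = VALIDATION_IDENTITY,
    coverage_floor: float = VALIDATION_COVERAGE,
) -> ValidationResult:
    """Search a protein against the partner genome's six-frame translation.

    Significant when the best frame hit exceeds both the identity and the
    query-coverage floor (70% each) and reaches the raw-score floor.
    """
    best = (0.0, 0.0, 0.0)  # score, identity, coverage
    for seg in six_frame_segments(partner_contigs):
        score, ident, cov, _ = protein_alignment_stats(protein, seg)
        if score > best[0]:
            best = (score, ident, cov)
    score, ident, cov = best
    significant = score >= score_floor and ident > identity_floor and cov > coverage_floor
    return ValidationResult(
        protein_id=protein_id,
        best_identity=ident,
        best_coverage=cov,
        best_score=score,
        significant=significant,
    )
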