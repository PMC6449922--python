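"""16S excision, artifact flagging, copy statistics, V4 in-silico PCR and
MLSA concatenation."""

import numpy as np
import pytest

from m2f.genomes import GeneRecord, assemble_genome
from m2f.markers import (
    IUPAC_SETS,
    ExtractionReport,
    MarkerRecord,
    apply_artifact_flags,
    build_mlsa,
    copy_statistics,
    extract_16s,
    extract_v4,
    flag_artifacts,
)
from m2f.simulate import (
    MLSA_GENES,
    PRIMER_515F,
    PRIMER_926R,
    PanGenomeModel,
    _build_rrna_backbone,
    generate_ancestor,
    random_nt,
)


def _revcomp_oracle(seq):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def _rrna_gene(seq, strand="+", gid="r1"):
    return GeneRecord(
        gene_id=gid,
        feature_type="rRNA",
        product="16S ribosomal RNA",
        contig="",
        start=0,
        end=0,
        strand=strand,
        sequence=seq,
    )


def _genome_with(genes, gid="G1"):
    rng = np.random.default_rng(0)
    spacers = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(len(genes) + 1)]
    return assemble_genome(gid, genes, spacers)


def test_plus_strand_excision_equals_genomic_substring(rng):
    s1, s2 = random_nt(rng, 1500), random_nt(rng, 1500)
    genome = _genome_with([_rrna_gene(s1, "+", "r1"), _rrna_gene(s2, "+", "r2")])
    records = extract_16s(genome)
    assert [r.sequence for r in records] == [s1, s2]
    contig = genome.contigs["G1"]
    for rec in records:
        _, start, end, _ = rec.source_coords
        assert rec.sequence == contig[start - 1 : end]


def test_minus_strand_record_is_reverse_complement(rng):
    seq = random_nt(rng, 1500)
    genome = _genome_with([_rrna_gene(seq, "-", "r1")])
    (rec,) = extract_16s(genome)
    contig = genome.contigs["G1"]
    _, start, end, strand = rec.source_coords
    assert strand == "-"
    assert rec.sequence == _revcomp_oracle(contig[start - 1 : end])
    assert rec.sequence == seq


def test_short_copy_dropped_and_reported(rng):
    genome = _genome_with([_rrna_gene(random_nt(rng, 900))])
    report = ExtractionReport()
    records = extract_16s(genome, report=report)
    assert records == []
    assert len(report.entries) == 1
    assert report.entries[0]["reason"] == "below_min_length"


def test_unknown_contig_raises_naming_the_feature(rng):
    genome = _genome_with([_rrna_gene(random_nt(rng, 1500), gid="rX")])
    genome.genes[0].contig = "nope"
    with pytest.raises(KeyError, match="rX"):
        extract_16s(genome)


def test_excision_round_trip(small_corpus):
    for gid in sorted(small_corpus.genomes)[:6]:
        genome = small_corpus.genomes[gid]
        for rec in extract_16s(genome):
            contig, start, end, strand = rec.source_coords
            raw = genome.contigs[contig][start - 1 : end]
            assert rec.sequence == (_revcomp_oracle(raw) if strand == "-" else raw)


# ---------------------------------------------------------------------------
# copy statistics


def _records(seqs, genome_id="G1"):
    return [
        MarkerRecord(genome_id=genome_id, marker_type="16S", copy_index=i + 1, sequence=s)
        for i, s in enumerate(seqs)
    ]


def test_identical_copies_have_identity_100(rng):
    seq = random_nt(rng, 1500)
    stats = copy_statistics(_records([seq, seq, seq]))
    assert stats.min_identity == stats.mean_identity == stats.max_identity == 100.0
    assert stats.copy_number == 3


def test_substitution_only_identity_is_exact(rng):
    seq = random_nt(rng, 1500)
    other = list(seq)
    for pos in rng.choice(1500, 45, replace=False):
        other[pos] = next(c for c in "ACGT" if c != seq[pos])
    stats = copy_statistics(_records([seq, "".join(other)]))
    assert stats.mean_identity == pytest.approx(97.0, abs=1e-9)


def test_flagged_copy_excluded_from_statistics(rng):
    """Five copies, one highly diverged with N stretches: statistics are
    computed over the four clean copies."""
    seq = random_nt(rng, 1500)
    bad = seq[:700] + "N" * 40 + seq[740:]
    records = _records([seq, seq, seq, seq, bad])
    apply_artifact_flags(records)
    assert [r.flagged_artifact for r in records] == [False] * 4 + [True]
    stats = copy_statistics(records)
    assert stats.n_flagged == 1
    assert stats.copy_number == 5
    assert stats.min_identity == 100.0


def test_all_copies_flagged_yields_null_identity(rng):
    seq = random_nt(rng, 1500)
    bad = seq[:100] + "N" * 50 + seq[150:]
    records = _records([bad])
    apply_artifact_flags(records)
    stats = copy_statistics(records)
    assert stats.copy_number == 1 and stats.n_flagged == 1
    assert stats.min_identity is None and stats.mean_len is None


def test_copy_statistics_order_invariant(rng):
    seqs = [random_nt(rng, 1500)]
    for _ in range(3):
        other = list(seqs[0])
        for pos in rng.choice(1500, 20, replace=False):
            other[pos] = next(c for c in "ACGT" if c != seqs[0][pos])
        seqs.append("".join(other))
    a = copy_statistics(_records(seqs))
    b = copy_statistics(_records(seqs[::-1]))
    assert (a.min_identity, a.mean_identity, a.max_identity) == pytest.approx(
        (b.min_identity, b.mean_identity, b.max_identity)
    )


# ---------------------------------------------------------------------------
# artifact flags


def test_n_run_flags_copy(rng):
    seq = random_nt(rng, 1500)
    bad = seq[:200] + "N" * 50 + seq[250:]
    assert flag_artifacts(_records([bad])[0], _records([bad]))


def test_clean_identical_copy_not_flagged(rng):
    seq = random_nt(rng, 1500)
    records = _records([seq, seq])
    assert not flag_artifacts(records[0], records)


def test_large_internal_deletion_flags_by_gap_fraction(rng):
    """A 400 nt internal deletion against a 1500 nt sibling gives a gap
    fraction around 27%, above the 20% threshold."""
    seq = random_nt(rng, 1500)
    deleted = seq[:500] + seq[900:]
    records = _records([seq, seq, deleted])
    apply_artifact_flags(records)
    assert [r.flagged_artifact for r in records] == [False, False, True]


# ---------------------------------------------------------------------------
# V4 in-silico PCR


def _brute_force_v4(seq, fwd=PRIMER_515F, rev=PRIMER_926R):
    """Independent oracle: scan every window pair with IUPAC set logic."""
    def matches(i, primer):
        return all(
            seq[i + k] != "N" and seq[i + k] in IUPAC_SETS[c]
            for k, c in enumerate(primer)
        )

    from m2f.genomes import reverse_complement

    rev_site = reverse_complement(rev)
    for i in range(len(seq) - len(fwd) + 1):
        if not matches(i, fwd):
            continue
        for j in range(i + len(fwd), len(seq) - len(rev_site) + 1):
            if matches(j, rev_site):
                return seq[i + len(fwd) : j]
        return None
    return None


def test_v4_excision_matches_brute_force_scan(rng):
    seq = _build_rrna_backbone(rng)
    rec = MarkerRecord("G1", "16S", 1, seq)
    v4 = extract_v4(rec)
    assert v4 is not None
    assert len(v4.sequence) == 373
    assert v4.sequence == _brute_force_v4(seq)
    assert v4.sequence in seq  # strict substring of the parent 16S


def test_missing_forward_primer_gives_no_hit(rng):
    seq = random_nt(rng, 1550)  # no planted sites
    assert extract_v4(MarkerRecord("G1", "16S", 1, seq)) is None


def test_degenerate_positions_match_both_variants(rng):
    # 515f has Y at position 3: C and T variants must both amplify
    base = _build_rrna_backbone(rng)
    from m2f.simulate import FWD_SITE_START

    for variant in "CT":
        seq = list(base)
        seq[FWD_SITE_START + 3] = variant
        rec = MarkerRecord("G1", "16S", 1, "".join(seq))
        v4 = extract_v4(rec)
        assert v4 is not None and len(v4.sequence) == 373


def test_include_primers_flag_extends_amplicon(rng):
    seq = _build_rrna_backbone(rng)
    rec = MarkerRecord("G1", "16S", 1, seq)
    v4 = extract_v4(rec, include_primers=True)
    assert len(v4.sequence) == 373 + len(PRIMER_515F) + len(PRIMER_926R)


# ---------------------------------------------------------------------------
# MLSA


def test_mlsa_concatenation_length_and_order():
    model = PanGenomeModel(seed=21, gene_length_range=(90, 150))
    genome = generate_ancestor(model)
    rec = build_mlsa(genome)
    assert rec is not None
    assert len(rec.sequence) == sum(L for _, _, L in MLSA_GENES)  # 4101
    # canonical order: the concatenation starts with the S12 CDS
    s12 = next(g for g in genome.genes if g.product == "30S ribosomal protein S12")
    assert rec.sequence.startswith(s12.sequence)


def test_missing_gene_excludes_genome_with_report():
    model = PanGenomeModel(seed=22, gene_length_range=(90, 150))
    genome = generate_ancestor(model)
    genome.genes = [g for g in genome.genes if g.product != "CTP synthase"]
    report = ExtractionReport()
    assert build_mlsa(genome, report=report) is None
    assert "missing:pyrG" in report.entries[0]["detail"]


def test_duplicate_gene_excludes_genome():
    model = PanGenomeModel(seed=23, gene_length_range=(90, 150))
    genome = generate_ancestor(model)
    s15 = next(g for g in genome.genes if g.product == "30S ribosomal protein S15")
    genome.genes.append(s15)
    assert build_mlsa(genome) is None
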