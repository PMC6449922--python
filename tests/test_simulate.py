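"""Generator behaviour: determinism, degenerate settings, truth bookkeeping,
and agreement of realized shared-gene fractions with closed-form expectation."""

import numpy as np
import pytest

from m2f.genomes import translate_cds
from m2f.simulate import (
    PanGenomeModel,
    coding_families,
    evolve_pair,
    expected_marker_identity,
    generate_ancestor,
    inject_artifacts,
    simulate_corpus,
    true_shared_fraction,
)


def _n_rrna(genome):
    return sum(1 for g in genome.genes if g.feature_type == "rRNA")


def test_degenerate_copy_range_gives_single_16s():
    model = PanGenomeModel(seed=3, rrna_copy_range=(1, 1))
    genome = generate_ancestor(model)
    assert _n_rrna(genome) == 1


def test_no_accessory_draw_gives_core_plus_mlsa_proteome():
    model = PanGenomeModel(seed=4, n_core=10, p_accessory=0.0)
    genome = generate_ancestor(model)
    cds = [g for g in genome.genes if g.feature_type == "CDS"]
    assert len(cds) == 10 + 5
    assert len(genome.proteins()) == 15


def test_fixed_seed_reproduces_identical_files(tmp_path):
    from m2f.genomes import write_genome

    model = PanGenomeModel(seed=99, n_artifact_prob=0.1)
    for d in ("a", "b"):
        genome = generate_ancestor(model)
        genome = inject_artifacts(genome, model)
        write_genome(genome, tmp_path / d)
    for suffix in (".fna", ".gff", ".faa"):
        fa = (tmp_path / "a" / f"ANC0000{suffix}").read_bytes()
        fb = (tmp_path / "b" / f"ANC0000{suffix}").read_bytes()
        assert fa == fb


def test_generated_cds_translate_without_internal_stops():
    model = PanGenomeModel(seed=5, gene_length_range=(90, 300))
    genome = generate_ancestor(model)
    for gid, prot in genome.proteins().items():
        assert "*" not in prot


def test_zero_divergence_pair_is_identical_in_truth():
    model = PanGenomeModel(seed=6)
    anc = generate_ancestor(model)
    a, b, truth = evolve_pair(anc, model, 0.0)
    assert truth.true_shared_fraction == 1.0
    assert truth.expected_marker_identity == 100.0
    assert coding_families(a) == coding_families(b)


def test_turnover_zero_keeps_all_families_while_markers_diverge():
    model = PanGenomeModel(seed=7, gene_turnover_rate=0.0, marker_sub_rate=0.05)
    anc = generate_ancestor(model)
    a, b, truth = evolve_pair(anc, model, 1.0)
    assert truth.true_shared_fraction == 1.0
    rrna_a = next(g for g in a.genes if g.feature_type == "rRNA")
    rrna_b = next(g for g in b.genes if g.feature_type == "rRNA")
    assert rrna_a.sequence != rrna_b.sequence
    assert truth.expected_marker_identity < 100.0


def test_excessive_divergence_rejected():
    model = PanGenomeModel(seed=8, marker_sub_rate=0.5)
    anc = generate_ancestor(model)
    with pytest.raises(ValueError):
        evolve_pair(anc, model, 3.0)


def test_realized_shared_fraction_matches_closed_form_expectation():
    """200 replicate pairs vs the family-level enumeration of retention
    probabilities: core always shared; an accessory family present in the
    ancestor (prob p) survives in a lineage w.p. r = 1 - g*t, an absent one
    is gained w.p. g*t."""
    g_t = 0.2
    model = PanGenomeModel(
        seed=77,
        n_core=80,
        n_accessory_pool=40,
        p_accessory=0.5,
        gene_turnover_rate=g_t,
        gene_length_range=(60, 120),
        rrna_copy_range=(1, 1),
    )
    p, r, gain = model.p_accessory, 1.0 - g_t, g_t
    n_core_total = model.n_core + 5  # five MLSA genes are core too
    e_shared_per_fam = p * r * r + (1 - p) * gain * gain
    e_present_per_fam = p * r + (1 - p) * gain
    e_inter = n_core_total + model.n_accessory_pool * e_shared_per_fam
    e_size = n_core_total + model.n_accessory_pool * e_present_per_fam
    closed_form = 2 * e_inter / (2 * e_size)

    rng = np.random.default_rng(2027)
    vals = []
    for _ in range(200):
        anc = generate_ancestor(model, rng=rng)
        _, _, truth = evolve_pair(anc, model, 1.0, rng=rng)
        vals.append(truth.true_shared_fraction)
    vals = np.array(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - closed_form) <= 2 * se + 1e-4


def test_artifact_injection_disabled_and_forced():
    model0 = PanGenomeModel(seed=9, n_artifact_prob=0.0)
    genome = generate_ancestor(model0)
    same = inject_artifacts(genome, model0)
    assert same is genome

    model1 = PanGenomeModel(seed=9, n_artifact_prob=1.0, rrna_copy_range=(1, 1))
    genome = generate_ancestor(model1)
    hit = inject_artifacts(genome, model1)
    rrna = next(g for g in hit.genes if g.feature_type == "rRNA")
    assert "N" * 10 in rrna.sequence
    # the assembly carries the Ns too (round-trip stays intact)
    assert hit.gene_sequence(rrna) == rrna.sequence


def test_artifact_count_within_binomial_interval():
    """1000 copies at p=0.5: count inside the 99% binomial interval."""
    model = PanGenomeModel(
        seed=10,
        n_artifact_prob=0.5,
        rrna_copy_range=(10, 10),
        n_core=1,
        n_accessory_pool=0,
        gene_length_range=(60, 90),
    )
    rng = np.random.default_rng(11)
    n_hit = 0
    for _ in range(100):
        genome = generate_ancestor(model, rng=rng)
        genome = inject_artifacts(genome, model, rng=rng)
        for g in genome.genes:
            if g.feature_type == "rRNA" and "N" * 10 in g.sequence:
                n_hit += 1
    half_width = 2.576 * np.sqrt(1000 * 0.25)
    assert abs(n_hit - 500) <= half_width


def test_truth_consistent_with_emitted_gene_lists(small_corpus):
    for truth in small_corpus.pairs:
        a = small_corpus.genomes[truth.genome_id_a]
        b = small_corpus.genomes[truth.genome_id_b]
        assert true_shared_fraction(a, b) == truth.true_shared_fraction


def test_monotone_coupling_over_divergence_grid():
    """Mean truth shared fraction and expected marker identity both
    non-increasing in divergence time."""
    model = PanGenomeModel(seed=12, gene_length_range=(60, 120))
    corpus = simulate_corpus(model, pairs_per_stratum=8)
    means = corpus.truth.groupby("divergence_time")["true_shared_fraction"].mean()
    assert list(means.index) == sorted(means.index)
    assert all(np.diff(means.values) <= 0)
    emi = [
        expected_marker_identity(model, t) for t in sorted(set(corpus.truth["divergence_time"]))
    ]
    assert all(np.diff(emi) <= 0)


def test_corpus_writes_complete_file_set(tmp_path, small_corpus):
    out = tmp_path / "corpus"
    small_corpus.write(out)
    gid = small_corpus.pairs[0].genome_id_a
    for name in (f"{gid}.fna", f"{gid}.gff", f"{gid}.faa", "truth.tsv",
                 "taxonomy.tsv", "go_annotations.tsv", "go_isa.tsv"):
        assert (out / name).exists()
    # protein FASTA ids match GFF IDs and translate from the assembly
    from m2f.genomes import load_genome, read_fasta

    genome = load_genome(gid, out / f"{gid}.fna", out / f"{gid}.gff")
    faa = read_fasta(out / f"{gid}.faa")
    assert set(faa) == set(genome.proteins())
    for pid, prot in genome.proteins().items():
        assert faa[pid] == prot
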