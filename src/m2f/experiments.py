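"""Seeded validation experiments run by the acceptance checks.

Each function builds its own inputs with the synthetic generator (or direct
draws for the pure statistics checks), runs the relevant pipeline stages,
and returns the measured quantity.  Everything is deterministic given the
seed argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import binning, gostats, markers, orthology, simulate
from .align import pairwise_identity


# ---------------------------------------------------------------------------
# parameter recovery (identity-vs-shared-content, with known truth)


def recovery_experiment(
    seed: int,
    gene_sub_rate: float = 0.0,
    pairs_per_stratum: int = 40,
    divergence_times: tuple[float, ...] = simulate.DEFAULT_STRATA,
    measure_marker_identity: bool = True,
) -> pd.DataFrame:
    """Pipeline percent-shared vs generator truth across divergence strata.

    Returns one row per genome pair: divergence time, truth (as percent),
    the reciprocal-best-hit percent shared, and optionally the realized V4
    identity between the pair's first clean 16S copies.
    """
    model = simulate.PanGenomeModel(
        seed=seed,
        gene_sub_rate=gene_sub_rate,
        n_artifact_prob=0.02,
    )
    corpus = simulate.simulate_corpus(
        model,
        divergence_times=divergence_times,
        pairs_per_stratum=pairs_per_stratum,
    )
    rows = []
    for truth in corpus.pairs:
        ga = corpus.genomes[truth.genome_id_a]
        gb = corpus.genomes[truth.genome_id_b]
        comp = orthology.rbh_match(
            ga.proteins(), gb.proteins(), ga.genome_id, gb.genome_id
        )
        row = {
            "divergence_time": truth.divergence_time,
            "true_shared_pct": 100.0 * truth.true_shared_fraction,
            "pipeline_shared_pct": comp.percent_shared,
            "expected_marker_identity": truth.expected_marker_identity,
        }
        if measure_marker_identity:
            row["v4_identity"] = _pair_v4_identity(ga, gb)
        rows.append(row)
    return pd.DataFrame(rows)


def _pair_v4_identity(ga, gb) -> float | None:
    def first_clean_v4(genome):
        recs = markers.extract_16s(genome)
        for rec in recs:
            if markers.flag_artifacts(rec, recs):
                continue
            v4 = markers.extract_v4(rec)
            if v4 is not None:
                return v4.sequence
        return None

    va, vb = first_clean_v4(ga), first_clean_v4(gb)
    if va is None or vb is None:
        return None
    return pairwise_identity(va, vb)


def stratum_recovery_errors(df: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum mean pipeline vs truth percent shared."""
    g = df.groupby("divergence_time")
    out = g[["true_shared_pct", "pipeline_shared_pct"]].mean()
    out["abs_error"] = (out["pipeline_shared_pct"] - out["true_shared_pct"]).abs()
    return out.reset_index()


# ---------------------------------------------------------------------------
# lineage statistics calibration


def lineage_null_type1_rate(
    seed: int,
    reps: int = 100,
    n_lineages: int = 5,
    n_per_group: int = 50,
    alpha: float = 0.05,
) -> float:
    """Fraction of per-lineage Dunn tests rejecting when every lineage is
    drawn from the same distribution."""
    rng = np.random.default_rng(seed)
    labels = [f"L{i}" for i in range(n_lineages) for _ in range(n_per_group)]
    n_sig = 0
    n_total = 0
    for _ in range(reps):
        values = rng.normal(75.0, 8.0, n_lineages * n_per_group)
        results = binning.dunn_vs_rest(values, labels, alpha=alpha)
        n_sig += sum(r.dunn_p_adjusted < alpha for r in results)
        n_total += len(results)
    return n_sig / n_total


def lineage_power(
    seed: int,
    reps: int = 100,
    shift: float = 15.0,
    n_lineages: int = 5,
    n_per_group: int = 50,
    alpha: float = 0.05,
) -> float:
    """Fraction of replicates detecting a +shift lineage as 'higher'."""
    rng = np.random.default_rng(seed)
    labels = [f"L{i}" for i in range(n_lineages) for _ in range(n_per_group)]
    hits = 0
    for _ in range(reps):
        values = rng.normal(70.0, 8.0, n_lineages * n_per_group)
        values[:n_per_group] += shift  # lineage L0 shifted up
        results = binning.dunn_vs_rest(values, labels, alpha=alpha)
        r0 = next(r for r in results if r.lineage == "L0")
        if r0.direction == "higher":
            hits += 1
    return hits / reps


def fisher_vs_hypergeom_max_diff(seed: int, n_tables: int = 200) -> float:
    """Max |Fisher two-sided p - direct hypergeometric summation| over
    random 2x2 tables with margins <= 200."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        cs = int(rng.integers(0, 60))
        cu = int(rng.integers(0, 60))
        ts = cs + int(rng.integers(1, 140))
        tu = cu + int(rng.integers(1, 140))
        _, p_fisher = sps.fisher_exact(
            [[cs, ts - cs], [cu, tu - cu]], alternative="two-sided"
        )
        rv = sps.hypergeom(ts + tu, cs + cu, ts)
        p_obs = rv.pmf(cs)
        p_direct = sum(
            rv.pmf(k)
            for k in range(max(0, cs + cu - tu), min(cs + cu, ts) + 1)
            if rv.pmf(k) <= p_obs * (1 + 1e-9)
        )
        worst = max(worst, abs(p_fisher - p_direct))
    return worst


# ---------------------------------------------------------------------------
# GO enrichment calibration


def _go_corpus_comparisons(corpus):
    comps = []
    for truth in corpus.pairs:
        ga = corpus.genomes[truth.genome_id_a]
        gb = corpus.genomes[truth.genome_id_b]
        comps.append(
            orthology.rbh_match(ga.proteins(), gb.proteins(), ga.genome_id, gb.genome_id)
        )
    return comps


def _go_enrichment_for(corpus, alpha: float = 0.01):
    comps = _go_corpus_comparisons(corpus)
    closure = gostats.annotate_and_propagate(corpus.go_annotations, corpus.go_edges)
    namespaces = gostats.namespace_map(corpus.go_edges)
    table = gostats.tally(comps, closure, namespaces)
    return gostats.enrich(table, alpha=alpha), table


def go_null_significant_fraction(seed: int, pairs: int = 40, alpha: float = 0.01) -> float:
    """Fraction of tested terms significant on a corpus where GO terms are
    attached to gene occurrences independently of shared status."""
    model = simulate.PanGenomeModel(seed=seed, gene_length_range=(90, 300))
    corpus = simulate.simulate_corpus(
        model, divergence_times=(0.25,), pairs_per_stratum=pairs, go_null=True
    )
    results, _ = _go_enrichment_for(corpus, alpha=alpha)
    if not results:
        return 0.0
    return sum(r.significant for r in results) / len(results)


def go_planted_accessory_recovery(
    seed: int, pairs: int = 25, alpha: float = 0.01
) -> tuple[float, dict[str, str]]:
    """On a deep-divergence corpus, fraction of tested accessory-pool terms
    (transposase activity and friends, which the generator attaches only to
    accessory families) that come out significant with direction 'unshared'."""
    model = simulate.PanGenomeModel(seed=seed, gene_length_range=(90, 300))
    corpus = simulate.simulate_corpus(
        model, divergence_times=(1.0,), pairs_per_stratum=pairs
    )
    results, _ = _go_enrichment_for(corpus, alpha=alpha)
    by_id = {r.go_id: r for r in results}
    outcome: dict[str, str] = {}
    hit = 0
    tested = 0
    for term in simulate.ACCESSORY_GO_POOL:
        r = by_id.get(term)
        if r is None:
            outcome[term] = "absent"
            continue
        tested += 1
        if r.significant and r.direction == "unshared":
            hit += 1
            outcome[term] = "unshared"
        else:
            outcome[term] = f"{r.direction}:{r.p_value:.2g}"
    return (hit / tested if tested else 0.0), outcome


# ---------------------------------------------------------------------------
# translated-search validation of unmatched genes


def validation_failure_rate(
    seed: int, pairs: int = 8, max_proteins_per_pair: int = 5
) -> float:
    """Percent of unmatched (truly absent) genes NOT found in the partner
    genome at > 70% identity by the six-frame search."""
    model = simulate.PanGenomeModel(seed=seed, gene_length_range=(90, 300))
    corpus = simulate.simulate_corpus(
        model, divergence_times=(1.0,), pairs_per_stratum=pairs
    )
    n_fail = 0
    n_total = 0
    for truth in corpus.pairs:
        ga = corpus.genomes[truth.genome_id_a]
        gb = corpus.genomes[truth.genome_id_b]
        comp = orthology.rbh_match(ga.proteins(), gb.proteins())
        prots = ga.proteins()
        for pid in comp.unmatched_a[:max_proteins_per_pair]:
            res = orthology.validate_unmatched(prots[pid], gb.contigs, pid)
            n_total += 1
            if not (res.best_identity > 70.0 and res.best_coverage > 70.0):
                n_fail += 1
    return 100.0 * n_fail / n_total if n_total else float("nan")
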