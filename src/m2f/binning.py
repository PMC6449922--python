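"""Marker-identity binning of genome pairs and the lineage statistics.

A genome pair is assigned to the HIGHEST clustering threshold at which the
two genomes have marker records sharing a cluster group (any-copy rule for
multi-copy genomes); pairs that never co-cluster at the lowest threshold
are excluded.  Per-bin boxplot statistics use linear-interpolation (type 7)
quartiles and 1.5 x IQR whiskers.

The lineage analysis is a Kruskal-Wallis omnibus across lineage groups
followed by Dunn z-tests of each lineage against the pooled remainder, with
Bonferroni correction over the number of lineages tested.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clustering import ClusterGroup
from .orthology import PairComparison


@dataclass
class LineageTestResult:
    lineage: str
    n_comparisons: int
    mean_shared: float
    median_shared: float
    z: float
    p_raw: float
    dunn_p_adjusted: float
    direction: str  # "higher", "lower" or "ns"


def _co_clustered(groups: list[ClusterGroup], genome_a: str, genome_b: str) -> bool:
    for grp in groups:
        if genome_a in grp.unique_genomes and genome_b in grp.unique_genomes:
            return True
    return False


def assign_bins(
    cluster_runs: dict[float, list[ClusterGroup]],
    comparisons: list[PairComparison],
    thresholds: tuple[float, ...] | None = None,
) -> tuple[list[PairComparison], list[PairComparison]]:
    """Assign each comparison its highest co-clustering threshold.

    Returns (retained, excluded); retained comparisons have ``marker_bin``
    set, excluded ones never co-cluster at the lowest threshold.
    """
    if thresholds is None:
        thresholds = tuple(sorted(cluster_runs))
    missing = [t for t in thresholds if t not in cluster_runs]
    if missing:
        raise KeyError(f"missing clustering runs for thresholds {missing}")
    ordered = sorted(thresholds, reverse=True)

    retained: list[PairComparison] = []
    excluded: list[PairComparison] = []
    for comp in comparisons:
        assigned = None
        for t in ordered:
            if _co_clustered(cluster_runs[t], comp.genome_a, comp.genome_b):
                assigned = t
                break  # highest threshold wins; lower ones necessarily follow
        comp.marker_bin = assigned
        (retained if assigned is not None else excluded).append(comp)
    return retained, excluded


def bin_summary(
    comparisons: list[PairComparison],
    thresholds: tuple[float, ...],
) -> pd.DataFrame:
    """Boxplot statistics of percent shared genes per marker-identity bin."""
    if not comparisons:
        raise ValueError("no comparisons given")
    rows = []
    for t in sorted(thresholds, reverse=True):
        vals = np.array(
            [c.percent_shared for c in comparisons if c.marker_bin == t], dtype=float
        )
        if vals.size == 0:
            rows.append(
                {
                    "bin": t,
                    "n": 0,
                    "mean": None,
                    "median": None,
                    "q1": None,
                    "q3": None,
                    "whisker_low": None,
                    "whisker_high": None,
                    "outliers": "",
                }
            )
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interp (type 7)
        iqr = q3 - q1
        lo_fence = q1 - 1.5 * iqr
        hi_fence = q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        outliers = sorted(vals[(vals < lo_fence) | (vals > hi_fence)])
        rows.append(
            {
                "bin": t,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "whisker_low": float(inside.min()),
                "whisker_high": float(inside.max()),
                "outliers": ",".join(f"{v:g}" for v in outliers),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# lineage analysis (Kruskal-Wallis + Dunn vs rest, Bonferroni)


def label_lineages(
    comparisons: list[PairComparison], class_of: dict[str, str]
) -> list[str]:
    """Class label per comparison: the shared class, else "Other".

    Cross-class pairs (highly similar markers spanning different classes)
    are pooled into an "Other" group.
    """
    labels = []
    for c in comparisons:
        ca = class_of[c.genome_a]
        cb = class_of[c.genome_b]
        labels.append(ca if ca == cb else "Other")
    return labels


def dunn_vs_rest(
    values: np.ndarray, labels: list[str], alpha: float = 0.05
) -> list[LineageTestResult]:
    """Dunn z-test of each lineage against the pooled remainder.

    Uses the rank-sum z statistic with tie correction; p-values are
    Bonferroni-adjusted over the number of lineages tested.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    ranks = sps.rankdata(values)
    grand_mean = values.mean()
    lineages = sorted(set(labels))
    k = len(lineages)
    labels_arr = np.asarray(labels)

    # tie correction term of the Dunn variance
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n - 1))) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term

    results: list[LineageTestResult] = []
    for lin in lineages:
        mask = labels_arr == lin
        n1 = int(mask.sum())
        n2 = n - n1
        vals = values[mask]
        if n2 == 0 or base_var <= 0:
            z = 0.0
            p = 1.0
        else:
            mean_r1 = ranks[mask].mean()
            mean_r2 = ranks[~mask].mean()
            se = math.sqrt(base_var * (1.0 / n1 + 1.0 / n2))
            z = (mean_r1 - mean_r2) / se
            p = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p * k)
        if p_adj < alpha:
            direction = "higher" if vals.mean() > grand_mean else "lower"
        else:
            direction = "ns"
        results.append(
            LineageTestResult(
                lineage=lin,
                n_comparisons=n1,
                mean_shared=float(vals.mean()),
                median_shared=float(np.median(vals)),
                z=float(z),
                p_raw=float(p),
                dunn_p_adjusted=float(p_adj),
                direction=direction,
            )
        )
    return results


def lineage_analysis(
    comparisons: list[PairComparison],
    class_of: dict[str, str],
    alpha: float = 0.05,
    all_pairs: bool = False,
) -> tuple[float, float, list[LineageTestResult]]:
    """Kruskal-Wallis omnibus plus per-lineage Dunn tests.

    Returns ``(H, omnibus_p, per-lineage results)``.  With fewer than two
    lineages the omnibus is skipped with a warning and (nan, nan, []) is
    returned.  ``all_pairs=True`` switches the post hoc to all pairwise
    lineage contrasts (Bonferroni over the number of pairs) and reports,
    per lineage, its smallest adjusted p.
    """
    labels = label_lineages(comparisons, class_of)
    values = np.array([c.percent_shared for c in comparisons], dtype=float)
    lineages = sorted(set(labels))
    if len(lineages) < 2:
        warnings.warn("fewer than two lineages; omnibus test skipped")
        return float("nan"), float("nan"), []
    groups = [values[np.asarray(labels) == lin] for lin in lineages]
    if np.ptp(values) == 0:  # every observation tied: no evidence either way
        H, p_omni = 0.0, 1.0
    else:
        H, p_omni = sps.kruskal(*groups)
    if not all_pairs:
        return float(H), float(p_omni), dunn_vs_rest(values, labels, alpha=alpha)

    # all-pairs Dunn (available behind a flag)
    n = values.size
    ranks = sps.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n - 1))) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term
    labels_arr = np.asarray(labels)
    k = len(lineages)
    n_tests = k * (k - 1) // 2
    best_p: dict[str, float] = {lin: 1.0 for lin in lineages}
    z_of: dict[str, float] = {lin: 0.0 for lin in lineages}
    for i in range(k):
        for j in range(i + 1, k):
            m1 = labels_arr == lineages[i]
            m2 = labels_arr == lineages[j]
            se = math.sqrt(base_var * (1.0 / m1.sum() + 1.0 / m2.sum()))
            z = (ranks[m1].mean() - ranks[m2].mean()) / se if se > 0 else 0.0
            p_adj = min(1.0, 2.0 * sps.norm.sf(abs(z)) * n_tests)
            for lin, zz in ((lineages[i], z), (lineages[j], -z)):
                if p_adj < best_p[lin]:
                    best_p[lin] = p_adj
                    z_of[lin] = zz
    grand_mean = values.mean()
    results = []
    for lin in lineages:
        mask = labels_arr == lin
        vals = values[mask]
        p_adj = best_p[lin]
        direction = (
            ("higher" if vals.mean() > grand_mean else "lower")
            if p_adj < alpha
            else "ns"
        )
        results.append(
            LineageTestResult(
                lineage=lin,
                n_comparisons=int(mask.sum()),
                mean_shared=float(vals.mean()),
                median_shared=float(np.median(vals)),
                z=float(z_of[lin]),
                p_raw=float("nan"),
                dunn_p_adjusted=float(p_adj),
                direction=direction,
            )
        )
    return float(H), float(p_omni), results
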