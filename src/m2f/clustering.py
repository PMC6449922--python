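"""Greedy centroid identity clustering (OTU-style) and cluster analytics.

Records are processed in a fixed order (length descending, then record id);
each record joins the best-matching existing centroid at or above the
threshold, otherwise it founds a new group.  Best-hit assignment (rather
than first-hit) makes the outcome independent of centroid scan order; ties
go to the earlier-founded centroid.  Identities are rounded to 4 decimals
before threshold comparison to avoid floating-point boundary flapping.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .align import identity_upper_bound, pairwise_identity
from .markers import MarkerRecord

#: identity thresholds used for the 16S/V4 datasets
DEFAULT_THRESHOLDS = (95.0, 96.0, 97.0, 98.0, 99.0, 100.0)
#: the MLSA dataset adds 93 and 94 percent (few concatenations co-cluster at 95+)
MLSA_THRESHOLDS = (93.0, 94.0) + DEFAULT_THRESHOLDS

#: prescreen safety margin (identity points) on the edit-distance bound
PREFILTER_MARGIN = 1.0


@dataclass
class ClusterGroup:
    threshold: float
    centroid_id: str
    member_ids: list[str] = field(default_factory=list)
    member_identity: dict[str, float] = field(default_factory=dict)
    unique_genomes: set[str] = field(default_factory=set)


@dataclass
class ClusterSummary:
    threshold: float
    n_groups: int
    histogram: dict[int, int]  # unique-genome count -> number of groups
    per_genome_group_spread: dict[str, int]
    genus_concordance: float | None


class IdentityCache:
    """Memoizes pairwise identities across threshold runs of one dataset."""

    def __init__(self, prefilter: bool = True):
        self.prefilter = prefilter
        self._cache: dict[tuple[str, str], float] = {}
        self._bound_cache: dict[tuple[str, str], float] = {}

    @staticmethod
    def _key(a: MarkerRecord, b: MarkerRecord) -> tuple[str, str]:
        return (a.record_id, b.record_id) if a.record_id <= b.record_id else (
            b.record_id,
            a.record_id,
        )

    def identity(self, a: MarkerRecord, b: MarkerRecord) -> float:
        key = self._key(a, b)
        val = self._cache.get(key)
        if val is None:
            val = pairwise_identity(a.sequence, b.sequence)
            self._cache[key] = val
        return val

    def at_least(self, a: MarkerRecord, b: MarkerRecord, threshold: float) -> float | None:
        """Identity if it can reach ``threshold``, else None (may skip work)."""
        key = self._key(a, b)
        if key in self._cache:
            return self._cache[key]
        if self.prefilter:
            bound = self._bound_cache.get(key)
            if bound is None:
                bound = identity_upper_bound(a.sequence, b.sequence)
                self._bound_cache[key] = bound
            if bound < threshold - PREFILTER_MARGIN:
                return None
        return self.identity(a, b)


def clustering_order(records: list[MarkerRecord]) -> list[MarkerRecord]:
    return sorted(records, key=lambda r: (-len(r.sequence), r.record_id))


def greedy_cluster(
    records: list[MarkerRecord],
    threshold: float,
    cache: IdentityCache | None = None,
) -> list[ClusterGroup]:
    """Greedy centroid clustering at one identity threshold (percent)."""
    if not 0.0 <= threshold <= 100.0:
        raise ValueError("threshold must be in [0, 100]")
    if cache is None:
        cache = IdentityCache()
    by_id = {r.record_id: r for r in records}
    if len(by_id) != len(records):
        raise ValueError("duplicate record ids")

    groups: list[ClusterGroup] = []
    centroids: list[MarkerRecord] = []
    for rec in clustering_order(records):
        best_idx = -1
        best_ident = -1.0
        for idx, cen in enumerate(centroids):
            ident = cache.at_least(rec, cen, threshold)
            if ident is None:
                continue
            ident = round(ident, 4)
            if ident >= threshold and ident > best_ident:
                best_ident = ident
                best_idx = idx  # ties keep the earlier-founded centroid
        if best_idx >= 0:
            grp = groups[best_idx]
            grp.member_ids.append(rec.record_id)
            grp.member_identity[rec.record_id] = best_ident
            grp.unique_genomes.add(rec.genome_id)
        else:
            groups.append(
                ClusterGroup(
                    threshold=threshold,
                    centroid_id=rec.record_id,
                    member_ids=[rec.record_id],
                    member_identity={rec.record_id: 100.0},
                    unique_genomes={rec.genome_id},
                )
            )
            centroids.append(rec)
    return groups


def cluster_at_thresholds(
    records: list[MarkerRecord],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    prefilter: bool = True,
) -> dict[float, list[ClusterGroup]]:
    """Cluster one dataset at every threshold, sharing the identity cache."""
    cache = IdentityCache(prefilter=prefilter)
    return {t: greedy_cluster(records, t, cache=cache) for t in sorted(thresholds)}


def summarize_clusters(
    groups: list[ClusterGroup],
    genus_of: dict[str, str],
) -> ClusterSummary:
    """Cluster-level analytics: group-size histogram, per-genome spread of
    marker copies across groups, and genus concordance.

    Genus concordance is computed over genomes that share a group with at
    least one other genome: the fraction whose every group-mate belongs to
    the same genus.  It is None when no multi-genome groups exist.
    """
    all_genomes = set()
    for grp in groups:
        all_genomes |= grp.unique_genomes
    missing = sorted(g for g in all_genomes if g not in genus_of)
    if missing:
        raise KeyError(f"genomes missing from taxonomy: {', '.join(missing)}")

    histogram = Counter(len(grp.unique_genomes) for grp in groups)
    spread: Counter[str] = Counter()
    for grp in groups:
        for genome in grp.unique_genomes:
            spread[genome] += 1

    mates: dict[str, set[str]] = {}
    for grp in groups:
        if len(grp.unique_genomes) < 2:
            continue
        for genome in grp.unique_genomes:
            mates.setdefault(genome, set()).update(
                grp.unique_genomes - {genome}
            )
    if mates:
        ok = sum(
            1
            for genome, others in mates.items()
            if all(genus_of[o] == genus_of[genome] for o in others)
        )
        concordance = ok / len(mates)
    else:
        concordance = None

    threshold = groups[0].threshold if groups else float("nan")
    return ClusterSummary(
        threshold=threshold,
        n_groups=len(groups),
        histogram=dict(sorted(histogram.items())),
        per_genome_group_spread=dict(spread),
        genus_concordance=concordance,
    )
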