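"""GO term tallies over matched/unmatched proteins and Fisher enrichment.

Annotations are closed under ``is_a`` ancestry (true-path rule) before
counting.  Counting is comparison-level: a protein occurring in k genome
comparisons contributes k times.  Each term is tested with a two-sided
Fisher exact test on the 2x2 table

    [[count_shared,   total_shared - count_shared],
     [count_unshared, total_unshared - count_unshared]]

within its namespace, where the totals are the numbers of shared/unshared
protein occurrences carrying at least one term of that namespace.  Classic
per-term Fisher with true-path propagation is used; no DAG decorrelation
heuristic is applied, so ancestor terms of an enriched term tend to be
enriched too.  Significance defaults to raw p < 0.01; Benjamini-Hochberg
adjustment is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats as sps

from .orthology import PairComparison

NAMESPACE_ROOTS = {
    "GO:0003674": "molecular_function",
    "GO:0008150": "biological_process",
    "GO:0005575": "cellular_component",
}


def read_go_annotations(path: str | Path) -> dict[str, tuple[str, ...]]:
    """protein_id <tab> comma-separated GO ids."""
    out: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid, _, terms = line.partition("\t")
            out[pid] = tuple(t for t in terms.strip().split(",") if t)
    return out


def read_isa_edges(path: str | Path) -> list[tuple[str, str]]:
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            child, _, parent = line.partition("\t")
            edges.append((child.strip(), parent.strip()))
    return edges


def ancestor_closure(edges: list[tuple[str, str]]) -> dict[str, frozenset[str]]:
    """Term -> set of the term plus all its is_a ancestors (set semantics).

    Raises ValueError if the edge list contains a cycle.
    """
    parents: dict[str, set[str]] = {}
    terms: set[str] = set()
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)
        terms.add(child)
        terms.add(parent)

    closure: dict[str, frozenset[str]] = {}
    state: dict[str, int] = {}  # 1 = in progress, 2 = done

    def visit(term: str, stack: list[str]) -> frozenset[str]:
        if term in closure:
            return closure[term]
        if state.get(term) == 1:
            cyc = stack[stack.index(term) :] + [term]
            raise ValueError(f"is_a cycle detected: {' -> '.join(cyc)}")
        state[term] = 1
        stack.append(term)
        acc = {term}
        for p in parents.get(term, ()):
            acc |= visit(p, stack)
        stack.pop()
        state[term] = 2
        closure[term] = frozenset(acc)
        return closure[term]

    for t in sorted(terms):
        visit(t, [])
    return closure


def annotate_and_propagate(
    annotations: dict[str, tuple[str, ...]],
    edges: list[tuple[str, str]],
    propagate: bool = True,
) -> dict[str, frozenset[str]]:
    """Close each protein's term set under is_a ancestry (true-path rule)."""
    if not propagate:
        return {pid: frozenset(terms) for pid, terms in annotations.items()}
    closure = ancestor_closure(edges)
    out: dict[str, frozenset[str]] = {}
    for pid, terms in annotations.items():
        acc: set[str] = set()
        for t in terms:
            acc |= closure.get(t, frozenset({t}))
        out[pid] = frozenset(acc)
    return out


def namespace_map(
    edges: list[tuple[str, str]],
    declared: dict[str, str] | None = None,
) -> dict[str, str]:
    """Namespace of every term, inferred from which root it reaches."""
    if declared:
        return dict(declared)
    closure = ancestor_closure(edges)
    out = {}
    for term, ancestors in closure.items():
        for root, ns in NAMESPACE_ROOTS.items():
            if root in ancestors:
                out[term] = ns
                break
    return out


@dataclass
class GOCountTable:
    """Per-term shared/unshared tallies plus namespace totals."""

    counts: pd.DataFrame  # go_id, namespace, count_shared, count_unshared
    totals: dict[str, tuple[int, int]]  # namespace -> (total_shared, total_unshared)
    n_without_annotation: int = 0
    n_occurrences: int = 0


def tally(
    comparisons: list[PairComparison],
    protein_terms: dict[str, frozenset[str]],
    namespaces: dict[str, str],
) -> GOCountTable:
    """Comparison-level GO tallies over matched and unmatched proteins.

    Every protein occurrence in a matched pair adds 1 to ``count_shared``
    for each of its (propagated) terms; every occurrence in an unmatched
    list adds to ``count_unshared``.  Occurrences without GO metadata are
    skipped and counted.
    """
    shared: dict[str, int] = {}
    unshared: dict[str, int] = {}
    totals: dict[str, list[int]] = {}
    skipped = 0
    occurrences = 0

    def _add(pid: str, into: dict[str, int], slot: int) -> None:
        nonlocal skipped, occurrences
        occurrences += 1
        terms = protein_terms.get(pid)
        if not terms:
            skipped += 1
            return
        seen_ns = set()
        for t in terms:
            ns = namespaces.get(t)
            if ns is None:
                continue
            into[t] = into.get(t, 0) + 1
            seen_ns.add(ns)
        for ns in seen_ns:
            totals.setdefault(ns, [0, 0])[slot] += 1

    for comp in comparisons:
        for pid_a, pid_b in comp.matched_pairs:
            _add(pid_a, shared, 0)
            _add(pid_b, shared, 0)
        for pid in comp.unmatched_a:
            _add(pid, unshared, 1)
        for pid in comp.unmatched_b:
            _add(pid, unshared, 1)

    all_terms = sorted(set(shared) | set(unshared))
    counts = pd.DataFrame(
        {
            "go_id": all_terms,
            "namespace": [namespaces.get(t, "") for t in all_terms],
            "count_shared": [shared.get(t, 0) for t in all_terms],
            "count_unshared": [unshared.get(t, 0) for t in all_terms],
        }
    )
    return GOCountTable(
        counts=counts,
        totals={ns: (v[0], v[1]) for ns, v in totals.items()},
        n_without_annotation=skipped,
        n_occurrences=occurrences,
    )


@dataclass
class EnrichmentResult:
    go_id: str
    namespace: str
    count_shared: int
    count_unshared: int
    p_value: float
    odds_ratio: float
    direction: str  # "shared" or "unshared"
    significant: bool


def enrich(
    table: GOCountTable,
    alpha: float = 0.01,
    bh_correction: bool = False,
) -> list[EnrichmentResult]:
    """Two-sided Fisher exact test per term within its namespace.

    Namespace roots are never tested.  Direction compares the term's share
    of shared occurrences against its share of unshared occurrences.
    """
    rows = []
    for rec in table.counts.itertuples():
        if rec.go_id in NAMESPACE_ROOTS:
            continue
        ns = rec.namespace
        if ns not in table.totals:
            continue
        total_s, total_u = table.totals[ns]
        if total_s + total_u == 0 or rec.count_shared + rec.count_unshared == 0:
            continue
        tab = [
            [rec.count_shared, total_s - rec.count_shared],
            [rec.count_unshared, total_u - rec.count_unshared],
        ]
        odds, p = sps.fisher_exact(tab, alternative="two-sided")
        frac_s = rec.count_shared / total_s if total_s else 0.0
        frac_u = rec.count_unshared / total_u if total_u else 0.0
        direction = "unshared" if frac_u > frac_s else "shared"
        rows.append(
            EnrichmentResult(
                go_id=rec.go_id,
                namespace=ns,
                count_shared=int(rec.count_shared),
                count_unshared=int(rec.count_unshared),
                p_value=float(p),
                odds_ratio=float(odds),
                direction=direction,
                significant=False,
            )
        )
    if bh_correction:
        m = len(rows)
        order = sorted(range(m), key=lambda i: rows[i].p_value)
        adj = [0.0] * m
        prev = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            val = min(prev, rows[i].p_value * m / (rank_pos + 1))
            adj[i] = val
            prev = val
        for i, r in enumerate(rows):
            r.p_value = adj[i]
    for r in rows:
        r.significant = r.p_value < alpha
    rows.sort(key=lambda r: (r.p_value, r.go_id))
    return rows
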