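"""Identity kernel exactness and greedy centroid clustering behaviour,
including a brute-force re-execution oracle and threshold monotonicity."""

import numpy as np
import pytest

from m2f.align import pairwise_identity
from hypothesis import given, settings, strategies as st

from m2f.clustering import (
    IdentityCache,
    cluster_at_thresholds,
    greedy_cluster,
    summarize_clusters,
)
from m2f.markers import MarkerRecord
from m2f.simulate import mutate_nt, random_nt


def _rec(rid, seq):
    genome_id, marker_type, idx = rid.split("|")
    return MarkerRecord(
        genome_id=genome_id,
        marker_type=marker_type,
        copy_index=int(idx),
        sequence=seq,
    )


def _records_from(seqs, genome_prefix="G"):
    return [
        MarkerRecord(f"{genome_prefix}{i}", "16S", 1, s) for i, s in enumerate(seqs)
    ]


# ---------------------------------------------------------------------------
# identity kernel


def test_identical_sequences_are_100_percent(rng):
    seq = random_nt(rng, 1500)
    assert pairwise_identity(seq, seq) == 100.0


def test_substitution_only_identity_exact(rng):
    seq = random_nt(rng, 100)
    other = list(seq)
    for pos in (10, 40, 70):
        other[pos] = next(c for c in "ACGT" if c != seq[pos])
    assert pairwise_identity(seq, "".join(other)) == pytest.approx(97.0, abs=1e-12)


def test_symmetry_on_random_pairs(rng):
    for _ in range(50):
        a = random_nt(rng, int(rng.integers(80, 200)))
        b = mutate_nt(random_nt(rng, int(rng.integers(80, 200))), 0.1, rng)
        assert pairwise_identity(a, b) == pairwise_identity(b, a)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    seq_a=st.text(alphabet="ACGT", min_size=1, max_size=60),
    seq_b=st.text(alphabet="ACGT", min_size=1, max_size=60),
)
def test_identity_bounded_symmetric_and_maximal_on_self(seq_a, seq_b):
    val = pairwise_identity(seq_a, seq_b)
    assert 0.0 <= val <= 100.0
    assert val == pairwise_identity(seq_b, seq_a)
    assert pairwise_identity(seq_a, seq_a) == 100.0


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        pairwise_identity("", "ACGT")


def test_n_never_counts_as_match(rng):
    seq = random_nt(rng, 200)
    withn = seq[:50] + "N" + seq[51:]
    assert pairwise_identity(seq, withn) == pytest.approx(100 * 199 / 200)
    assert pairwise_identity(withn, withn) == pytest.approx(100 * 199 / 200)


# ---------------------------------------------------------------------------
# greedy clustering


def test_identical_records_form_single_group(rng):
    seq = random_nt(rng, 300)
    groups = greedy_cluster(_records_from([seq] * 5), 97.0)
    assert len(groups) == 1
    assert len(groups[0].member_ids) == 5


def test_distinct_records_at_threshold_100(rng):
    seqs = [random_nt(rng, 300) for _ in range(6)]
    groups = greedy_cluster(_records_from(seqs), 100.0)
    assert len(groups) == 6


def test_hand_traced_best_hit_assignment(rng):
    """id(A,B)=98, id(A,C)=96, id(B,C)=95 at threshold 97 -> {A,B}, {C}."""
    a = random_nt(rng, 100)

    def sub(seq, pos, avoid):
        choices = [c for c in "ACGT" if c != seq[pos] and c not in avoid]
        return choices[0]

    b = list(a)
    b[0] = sub(a, 0, "")
    b[1] = sub(a, 1, "")
    c = list(a)
    c[0] = sub(a, 0, b[0])  # different substitution than B at site 0
    c[2] = sub(a, 2, "")
    c[3] = sub(a, 3, "")
    c[4] = sub(a, 4, "")
    recs = [
        _rec("A|16S|1", a),
        _rec("B|16S|1", "".join(b)),
        _rec("C|16S|1", "".join(c)),
    ]
    assert pairwise_identity(a, "".join(b)) == pytest.approx(98.0)
    assert pairwise_identity(a, "".join(c)) == pytest.approx(96.0)
    assert pairwise_identity("".join(b), "".join(c)) == pytest.approx(95.0)
    groups = greedy_cluster(recs, 97.0)
    assert [g.centroid_id for g in groups] == ["A|16S|1", "C|16S|1"]
    assert groups[0].member_ids == ["A|16S|1", "B|16S|1"]
    assert groups[1].member_ids == ["C|16S|1"]


def _brute_force_greedy(records, threshold):
    """Independent re-execution of the greedy rule from the full identity
    matrix (no caching, no prescreen)."""
    ident = {}
    for r in records:
        for s in records:
            ident[(r.record_id, s.record_id)] = round(
                pairwise_identity(r.sequence, s.sequence), 4
            )
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.record_id))
    groups = []  # list of (centroid_record, [member ids])
    for rec in ordered:
        best = None
        for gi, (cen, _members) in enumerate(groups):
            val = ident[(rec.record_id, cen.record_id)]
            if val >= threshold and (best is None or val > best[1]):
                best = (gi, val)
        if best is None:
            groups.append((rec, [rec.record_id]))
        else:
            groups[best[0]][1].append(rec.record_id)
    return [members for _, members in groups]


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_matches_brute_force_on_small_inputs(seed):
    rng = np.random.default_rng(seed)
    base = random_nt(rng, 250)
    seqs = [mutate_nt(base, float(rng.choice([0, 0.01, 0.03, 0.06])), rng)
            for _ in range(int(rng.integers(5, 13)))]
    records = _records_from(seqs)
    for threshold in (95.0, 97.0, 99.0, 100.0):
        got = [g.member_ids for g in greedy_cluster(records, threshold)]
        assert got == _brute_force_greedy(records, threshold)


def test_group_count_monotone_on_marker_structured_data(rng):
    """Distinct genomes with near-identical copies: group counts shrink as
    the threshold drops.  (On arbitrary inputs greedy centroid clustering
    does not guarantee this: absorbing a would-be centroid at a low
    threshold can strand records that it would have collected.)"""
    records = []
    for g in range(5):
        base = random_nt(rng, 300)
        for c in range(int(rng.integers(1, 4))):
            seq = base if c == 0 else mutate_nt(base, float(rng.uniform(0.002, 0.01)), rng)
            records.append(MarkerRecord(f"G{g}", "16S", c + 1, seq))
    runs = cluster_at_thresholds(records, (95.0, 96.0, 97.0, 98.0, 99.0, 100.0))
    counts = [len(runs[t]) for t in sorted(runs)]
    assert counts == sorted(counts)  # fewer groups at lower thresholds


def test_partition_property(rng):
    base = random_nt(rng, 300)
    seqs = [mutate_nt(base, 0.02, rng) for _ in range(12)]
    records = _records_from(seqs)
    for threshold in (95.0, 98.0, 100.0):
        groups = greedy_cluster(records, threshold)
        seen = [m for g in groups for m in g.member_ids]
        assert sorted(seen) == sorted(r.record_id for r in records)


def test_prefilter_matches_exhaustive(rng):
    base = random_nt(rng, 400)
    seqs = [mutate_nt(base, float(q), rng) for q in (0, 0.01, 0.05, 0.2, 0.4)] + [
        random_nt(rng, 400) for _ in range(3)
    ]
    records = _records_from(seqs)
    for threshold in (95.0, 97.0):
        with_pf = [g.member_ids for g in greedy_cluster(records, threshold, cache=IdentityCache(True))]
        without = [g.member_ids for g in greedy_cluster(records, threshold, cache=IdentityCache(False))]
        assert with_pf == without


# ---------------------------------------------------------------------------
# summaries


def test_summary_with_no_multi_genome_groups(rng):
    seqs = [random_nt(rng, 200) for _ in range(4)]
    groups = greedy_cluster(_records_from(seqs), 100.0)
    summ = summarize_clusters(groups, {f"G{i}": "GenusX" for i in range(4)})
    assert summ.genus_concordance is None
    assert summ.histogram == {1: 4}
    assert all(v == 1 for v in summ.per_genome_group_spread.values())


def test_concordance_counts_same_genus_groupmates(rng):
    seq1 = random_nt(rng, 200)
    seq2 = random_nt(rng, 200)
    records = [
        MarkerRecord("g1", "16S", 1, seq1),
        MarkerRecord("g2", "16S", 1, seq1),
        MarkerRecord("g3", "16S", 1, seq2),
        MarkerRecord("g4", "16S", 1, seq2),
    ]
    groups = greedy_cluster(records, 100.0)
    assert len(groups) == 2
    genus = {"g1": "A", "g2": "A", "g3": "B", "g4": "C"}
    summ = summarize_clusters(groups, genus)
    assert summ.genus_concordance == 0.5  # g1,g2 concordant; g3,g4 not

    same = summarize_clusters(groups[:1], {"g1": "A", "g2": "A"})
    assert same.genus_concordance == 1.0


def test_missing_taxonomy_is_an_error(rng):
    records = _records_from([random_nt(rng, 200)] * 2)
    groups = greedy_cluster(records, 100.0)
    with pytest.raises(KeyError, match="G1"):
        summarize_clusters(groups, {"G0": "A"})


def test_multi_copy_genome_spread(rng):
    base = random_nt(rng, 300)
    far = mutate_nt(base, 0.2, rng)
    records = [
        MarkerRecord("g1", "16S", 1, base),
        MarkerRecord("g1", "16S", 2, far),  # diverged copy clusters elsewhere
        MarkerRecord("g2", "16S", 1, base),
    ]
    groups = greedy_cluster(records, 97.0)
    summ = summarize_clusters(groups, {"g1": "A", "g2": "A"})
    assert summ.per_genome_group_spread["g1"] == 2
    assert summ.per_genome_group_spread["g2"] == 1
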