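"""Structural priors against brute-force reference implementations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methscore import clustering as cl
from methscore.io import IntervalSet, ValidationError

from conftest import make_annotation, make_matrix


def partition(cs: cl.ClusterSet) -> set:
    return {frozenset(m) for m in cs.members()}


def closure_partition(edges, nodes) -> set:
    """Union-find transitive closure of an adjacency relation."""
    parent = {n: n for n in nodes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in edges:
        parent[find(a)] = find(b)
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return {frozenset(g) for g in groups.values()}


class TestSlidingWindow:
    def test_gap_chaining_example(self):
        ann = make_annotation([100, 3000, 20000])
        cs = cl.sliding_window_clusters(ann, window=5000)
        assert partition(cs) == {frozenset({"cg0000", "cg0001"}), frozenset({"cg0002"})}

    def test_window_one_all_singletons(self):
        ann = make_annotation([10, 20, 40, 80])
        cs = cl.sliding_window_clusters(ann, window=1)
        assert cs.n_clusters == len(ann) == 4

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_closure(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 100))
        pos = np.sort(rng.choice(np.arange(1, 50_000), size=n, replace=False))
        window = int(rng.integers(1, 5000))
        ann = make_annotation(pos)
        cs = cl.sliding_window_clusters(ann, window)
        ids = ann.probe_ids
        edges = [
            (ids[i], ids[j])
            for i in range(n)
            for j in range(i + 1, n)
            if abs(int(pos[j]) - int(pos[i])) <= window
        ]
        assert partition(cs) == closure_partition(edges, ids)

    @pytest.mark.parametrize("seed", [5, 6])
    def test_monotone_in_window(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(np.arange(1, 100_000), size=60, replace=False))
        ann = make_annotation(pos)
        counts = [
            cl.sliding_window_clusters(ann, w).n_clusters
            for w in (10, 100, 1000, 10_000, 100_000)
        ]
        assert counts == sorted(counts, reverse=True)


class TestCmr:
    def test_identical_rows_join(self, rng):
        row = rng.normal(size=8)
        ann = make_annotation([1000, 1500])
        mat = make_matrix(np.vstack([row, row]))
        cs = cl.cmr_clusters(ann, mat, cl.CmrParams(corlo=0.2))
        assert cs.n_clusters == 1

    def test_anticorrelated_rows_split(self, rng):
        row = rng.normal(size=8)
        ann = make_annotation([1000, 1500])
        mat = make_matrix(np.vstack([row, -row]))
        cs = cl.cmr_clusters(ann, mat, cl.CmrParams(corlo=0.2))
        assert cs.n_clusters == 2

    def test_needs_three_samples(self, rng):
        ann = make_annotation([1000, 1500])
        mat = make_matrix(rng.normal(size=(2, 2)))
        with pytest.raises(ValidationError, match="3 samples"):
            cl.cmr_clusters(ann, mat, cl.CmrParams())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_predicates(self, seed):
        """20-probe chromosome vs explicit evaluation of all three predicates."""
        rng = np.random.default_rng(seed)
        n = 20
        pos = np.sort(rng.choice(np.arange(1, 30_000), size=n, replace=False))
        ann = make_annotation(pos)
        mat = make_matrix(rng.normal(size=(n, 12)))
        cpgs = np.sort(rng.choice(np.arange(1, 30_000), size=80, replace=False))
        params = cl.CmrParams(corlo=0.1, maxprbdst=4000, corlodst=1500)
        cs = cl.cmr_clusters(ann, mat, params, cpg_positions={"1": cpgs})

        ids = ann.probe_ids
        edges = []
        for i in range(n - 1):
            gap_ok = pos[i + 1] - pos[i] <= params.maxprbdst
            r = np.corrcoef(mat.values[i], mat.values[i + 1])[0, 1]
            inner = cpgs[(cpgs > pos[i]) & (cpgs < pos[i + 1])]
            pts = np.concatenate(([pos[i]], inner, [pos[i + 1]]))
            cpg_ok = np.all(np.diff(pts) <= params.corlodst)
            if gap_ok and r >= params.corlo and cpg_ok:
                edges.append((ids[i], ids[i + 1]))
        assert partition(cs) == closure_partition(edges, ids)

    def test_tiny_corlo_reproduces_sliding_window(self, rng):
        """Bypassing the correlation test degenerates CMR into the window chaining."""
        n = 40
        pos = np.sort(rng.choice(np.arange(1, 60_000), size=n, replace=False))
        ann = make_annotation(pos)
        mat = make_matrix(rng.normal(size=(n, 10)))
        w = 3000
        cs_cmr = cl.cmr_clusters(
            ann, mat, cl.CmrParams(corlo=1e-10, maxprbdst=w, corlodst=w)
        )
        cs_win = cl.sliding_window_clusters(ann, w)
        assert partition(cs_cmr) == partition(cs_win)


class TestTad:
    def _intervals(self, rows):
        return IntervalSet(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "interval_id"])
        )

    def test_probe_inside_interval(self):
        ann = make_annotation([500])
        tads = self._intervals([("chr1", 0, 1000, "t1")])
        cs = cl.tad_clusters(ann, tads)
        assert cs.n_clusters == 1

    def test_unmapped_chromosome_is_singleton(self):
        ann = make_annotation([500, 600], chroms=["chr1", "chr9"])
        tads = self._intervals([("chr1", 0, 1000, "t1")])
        cs = cl.tad_clusters(ann, tads)
        assert cs.n_clusters == 2
        assert cs.assignment["cg0000"] != cs.assignment["cg0001"]

    def test_overlap_tie_smallest_start_then_end(self):
        ann = make_annotation([500])
        tads = self._intervals(
            [("chr1", 100, 2000, "late"), ("chr1", 0, 3000, "big"), ("chr1", 0, 1000, "small")]
        )
        cs = cl.tad_clusters(ann, tads)
        # winner is start 0 with the smaller end ("small"); a second probe set
        # confirms via the label-free partition: single cluster either way
        assert cs.n_clusters == 1
        # direct check through a 2-probe instance separating the candidates
        ann2 = make_annotation([500, 2500])
        cs2 = cl.tad_clusters(ann2, tads)
        # probe at 2500 only fits "big"; if the first went to "small" they differ
        assert cs2.assignment["cg0000"] != cs2.assignment["cg0001"]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_containment(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        pos = rng.integers(1, 10_000, size=n)
        chroms = [f"chr{1 + i % 2}" for i in range(n)]
        ann = make_annotation(pos, chroms=chroms)
        rows = []
        for i in range(5):
            start = int(rng.integers(0, 8000))
            end = start + int(rng.integers(100, 3000))
            rows.append((f"chr{1 + i % 2}", start, end, f"t{i}"))
        tads = self._intervals(rows)
        cs = cl.tad_clusters(ann, tads)

        labels = {}
        for pid, chrom, p in zip(ann.probe_ids, chroms, pos):
            p0 = int(p) - 1
            hits = [
                (s, e, iid)
                for c, s, e, iid in rows
                if c == chrom and s <= p0 < e
            ]
            labels[pid] = min(hits)[2] if hits else f"single:{pid}"
        expected = {}
        for pid, lab in labels.items():
            expected.setdefault(lab, set()).add(pid)
        assert partition(cs) == {frozenset(v) for v in expected.values()}


class TestRandomClusters:
    def test_partition_and_determinism(self):
        ann = make_annotation(np.arange(1, 501) * 10)
        a, b = cl.random_clusters(ann, n_sets=2, seed=7)
        again_a, _ = cl.random_clusters(ann, n_sets=2, seed=7)
        for cs in (a, b):
            sizes = cs.sizes()
            assert sizes.sum() == len(ann)
            assert sizes.min() >= 1
        assert a.assignment == again_a.assignment
        assert a.assignment != b.assignment

    def test_sets_individually_reproducible(self):
        ann = make_annotation(np.arange(1, 101) * 10)
        sets3 = cl.random_clusters(ann, n_sets=3, seed=5)
        # set k of a larger run equals set 0 of a run seeded at seed + k
        solo = cl.random_clusters(ann, n_sets=1, seed=5 + 2)[0]
        assert sets3[2].assignment == solo.assignment

    def test_size_distribution_median(self):
        rng = np.random.default_rng(123)
        sizes = cl.sample_cluster_sizes(100_000, rng)
        assert abs(np.median(sizes) - 82) < 2

    def test_count_distribution_mean(self):
        rng = np.random.default_rng(123)
        counts = cl.sample_cluster_counts(10_000, rng)
        assert abs(counts.mean() - 2880) < 5


class TestSummaryAndSingletons:
    def _from_sizes(self, sizes):
        labels = []
        pids = []
        for cid, s in enumerate(sizes):
            for i in range(s):
                pids.append(f"p{cid}_{i}")
                labels.append(cid)
        return cl.ClusterSet.from_labels(pids, labels, "toy")

    def test_pct_nonsingleton_example(self):
        cs = self._from_sizes([1, 1, 2])
        s = cl.cluster_summary(cs)
        assert s.min == 1 and s.max == 2
        assert s.pct_nonsingleton_probes == pytest.approx(50.0)

    def test_all_singletons_pct_zero(self):
        s = cl.cluster_summary(self._from_sizes([1, 1, 1]))
        assert s.pct_nonsingleton_probes == 0.0

    def test_quartiles_match_sort_oracle(self, rng):
        sizes = rng.integers(1, 50, size=1000).tolist()
        s = cl.cluster_summary(self._from_sizes(sizes))

        def quantile_sorted(xs, q):
            xs = sorted(xs)
            h = (len(xs) - 1) * q
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

        assert s.q1 == pytest.approx(quantile_sorted(sizes, 0.25))
        assert s.median == pytest.approx(quantile_sorted(sizes, 0.50))
        assert s.q3 == pytest.approx(quantile_sorted(sizes, 0.75))
        assert s.mean == pytest.approx(np.mean(sizes))

    def test_drop_singletons_example(self):
        cs = self._from_sizes([1, 3])
        kept, n_dropped = cl.drop_singletons(cs)
        assert n_dropped == 1
        assert kept.n_clusters == 1 and len(kept) == 3

    def test_drop_singletons_identity_when_none(self):
        cs = self._from_sizes([2, 3])
        kept, n_dropped = cl.drop_singletons(cs)
        assert n_dropped == 0
        assert partition(kept) == partition(cs)

    def test_drop_count_matches_bruteforce(self, rng):
        sizes = rng.integers(1, 4, size=200).tolist()
        cs = self._from_sizes(sizes)
        kept, n_dropped = cl.drop_singletons(cs)
        assert n_dropped == sum(1 for s in sizes if s == 1)
        assert len(kept) == len(cs) - n_dropped

    def test_empty_raises(self):
        with pytest.raises(Exception):
            cl.cluster_summary(cl.ClusterSet(assignment={}, n_clusters=0, label="x"))


@given(
    positions=st.lists(st.integers(1, 1_000_000), min_size=2, max_size=40, unique=True),
    window=st.integers(1, 1_000_000),
)
@settings(max_examples=30, deadline=None, derandomize=True)
def test_sliding_window_partition_property(positions, window):
    """Any instance yields a partition equal to the gap-adjacency closure."""
    ann = make_annotation(sorted(positions))
    cs = cl.sliding_window_clusters(ann, window)
    assert sorted(cs.sizes().sum() for _ in [0])[0] == len(positions)
    assert set(cs.assignment.values()) == set(range(cs.n_clusters))
    pos = sorted(positions)
    ids = ann.probe_ids
    edges = [
        (ids[i], ids[j])
        for i in range(len(pos))
        for j in range(i + 1, len(pos))
        if pos[j] - pos[i] <= window
    ]
    assert partition(cs) == closure_partition(edges, ids)


@given(sizes=st.lists(st.integers(1, 6), min_size=1, max_size=30))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_drop_singletons_partition_property(sizes):
    """Removing singletons keeps a valid partition and the right probe count."""
    labels, pids = [], []
    for cid, s in enumerate(sizes):
        for i in range(s):
            pids.append(f"p{cid}_{i}")
            labels.append(cid)
    cs = cl.ClusterSet.from_labels(pids, labels, "hyp")
    n_singletons = sum(1 for s in sizes if s == 1)
    if n_singletons == len(sizes):
        with pytest.raises(Exception):
            cl.drop_singletons(cs)
        return
    kept, dropped = cl.drop_singletons(cs)
    assert dropped == n_singletons
    assert len(kept) == sum(sizes) - n_singletons
    assert kept.sizes().min() >= 2


def test_cluster_assignments_round_trip(tmp_path, rng):
    sizes = [3, 1, 2]
    pids = [f"p{i}" for i in range(6)]
    labels = [0, 0, 0, 1, 2, 2]
    cs = cl.ClusterSet.from_labels(pids, labels, "toy")
    path = tmp_path / "clusters.tsv"
    cl.write_cluster_assignments(cs, path, header_comment="seed=0")
    back = cl.read_cluster_assignments(path)
    assert back.assignment == cs.assignment
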