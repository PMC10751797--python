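import warnings

import numpy as np
import pytest

import pathstrings as ps
from pathstrings.cluster import (
    ClassReport,
    LinkageTree,
    assign_classes,
    class_probabilities,
    classify_pathways,
    cut_for_n_classes,
    duration_histograms,
    network_edges,
    network_node_weights,
    suggest_cut,
    ward_linkage,
)
from pathstrings.extract import Pathway
from pathstrings.similarity import DistanceMatrix


def make_pathway(symbols, weight=1.0, duration=None):
    if isinstance(symbols, str):
        symbols = tuple(ord(c) - ord("A") for c in symbols)
    return Pathway(
        symbols=tuple(symbols),
        weight=weight,
        start_frame=0,
        end_frame=len(symbols) - 1,
        event_duration_frames=duration or len(symbols),
    )


def ward_bruteforce(d):
    """Independent oracle: naive Lance-Williams Ward agglomeration."""
    d = d.astype(float).copy()
    n = d.shape[0]
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    dist = {frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    nxt = n
    while len(active) > 1:
        pair = min(
            (frozenset((i, j)) for i in active for j in active if i < j),
            key=lambda p: dist[p],
        )
        i, j = sorted(pair)
        h = dist[pair]
        heights.append(h)
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik, djk = dist[frozenset((i, k))], dist[frozenset((j, k))]
            new = np.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * h**2) / (ni + nj + nk)
            )
            dist[frozenset((nxt, k))] = new
        active = [a for a in active if a not in (i, j)] + [nxt]
        sizes[nxt] = ni + nj
        nxt += 1
    return heights


def two_group_matrix():
    # 6 pathways in two tight groups
    d = np.full((6, 6), 0.9)
    np.fill_diagonal(d, 0.0)
    for grp in ([0, 1, 2], [3, 4, 5]):
        for i in grp:
            for j in grp:
                if i != j:
                    d[i, j] = 0.05
    return DistanceMatrix(d)


class TestWardLinkage:
    def test_two_pathways_single_merge(self):
        d = DistanceMatrix(np.array([[0.0, 0.4], [0.4, 0.0]]))
        tree = ward_linkage(d)
        assert tree.Z.shape == (1, 4)
        assert tree.heights[0] == pytest.approx(0.4)

    def test_three_identical_pathways(self):
        d = DistanceMatrix(np.zeros((3, 3)))
        tree = ward_linkage(d)
        assert np.allclose(tree.heights, 0.0)

    def test_two_groups_final_merge_dominates(self):
        tree = ward_linkage(two_group_matrix())
        assert tree.heights[-1] > max(tree.heights[:-1])

    def test_matches_bruteforce_agglomeration(self):
        rng = np.random.default_rng(11)
        n = 7
        raw = rng.uniform(0.1, 0.9, size=(n, n))
        raw = (raw + raw.T) / 2
        np.fill_diagonal(raw, 0.0)
        d = DistanceMatrix(raw)
        tree = ward_linkage(d)
        assert np.allclose(sorted(tree.heights), sorted(ward_bruteforce(raw)), atol=1e-10)

    def test_too_few(self):
        with pytest.raises(ValueError):
            ward_linkage(DistanceMatrix(np.zeros((1, 1))))


class TestSuggestCut:
    def test_largest_gap(self):
        Z = np.array(
            [[0, 1, 0.1, 2], [2, 3, 0.15, 2], [4, 5, 0.9, 4]], dtype=float
        )
        tree = LinkageTree(Z=Z, n_leaves=4)
        cut, k = suggest_cut(tree)
        assert 0.15 < cut < 0.9
        assert k == 2

    def test_degenerate_heights_warn(self):
        Z = np.array([[0, 1, 0.0, 2], [2, 3, 0.0, 3]], dtype=float)
        tree = LinkageTree(Z=Z, n_leaves=3)
        with pytest.warns(UserWarning, match="equal"):
            cut, k = suggest_cut(tree)
        assert k == 1

    def test_tie_breaks_toward_fewer_classes(self):
        # 0.25 and 0.5 are exactly representable, so the gaps tie exactly
        Z = np.array(
            [[0, 1, 0.25, 2], [2, 3, 0.5, 2], [4, 5, 0.75, 4]], dtype=float
        )
        tree = LinkageTree(Z=Z, n_leaves=4)
        cut, k = suggest_cut(tree)
        assert k == 2  # equal gaps: pick the higher one

    def test_matches_exhaustive_gap_search(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            n = 8
            raw = rng.uniform(0.05, 0.95, size=(n, n))
            raw = (raw + raw.T) / 2
            np.fill_diagonal(raw, 0.0)
            tree = ward_linkage(DistanceMatrix(raw))
            h = tree.heights
            gaps = [(h[i + 1] - h[i], i) for i in range(len(h) - 1)]
            best_gap = max(g for g, _ in gaps)
            best_is = [i for g, i in gaps if g == best_gap]
            cut, k = suggest_cut(tree)
            i = max(best_is)  # tie toward fewer classes
            assert h[i] < cut < h[i + 1]
            assert k == n - (i + 1)

    def test_two_route_ensemble_two_classes(self, pathways):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report, tree, _ = classify_pathways(pathways, condense_level=2)
        assert report.n_classes == 2


class TestAssignClasses:
    def test_cut_above_all(self):
        tree = ward_linkage(two_group_matrix())
        labels = assign_classes(tree, tree.heights[-1] + 1)
        assert set(labels) == {1}

    def test_cut_below_all(self):
        tree = ward_linkage(two_group_matrix())
        labels = assign_classes(tree, 1e-9)
        assert len(set(labels)) == 6

    def test_two_group_partition(self):
        tree = ward_linkage(two_group_matrix())
        cut, k = suggest_cut(tree)
        labels = assign_classes(tree, cut)
        assert k == 2
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_numbering_by_decreasing_weight(self):
        tree = ward_linkage(two_group_matrix())
        cut, _ = suggest_cut(tree)
        weights = [0.05, 0.05, 0.05, 0.3, 0.3, 0.25]
        labels = assign_classes(tree, cut, weights=weights)
        assert labels[3] == 1  # heavier group is class 1
        assert labels[0] == 2

    def test_cut_for_n_classes(self):
        rng = np.random.default_rng(4)
        n = 6
        raw = rng.uniform(0.1, 0.9, size=(n, n))
        raw = (raw + raw.T) / 2
        np.fill_diagonal(raw, 0.0)
        tree = ward_linkage(DistanceMatrix(raw))
        for k in range(1, n + 1):
            labels = assign_classes(tree, cut_for_n_classes(tree, k))
            assert len(set(labels)) == k

    def test_cut_for_n_classes_tied_heights(self):
        tree = ward_linkage(DistanceMatrix(np.zeros((3, 3))))
        with pytest.raises(ValueError, match="unattainable"):
            cut_for_n_classes(tree, 2)

    def test_permutation_invariance(self, pathways):
        from pathstrings.similarity import pairwise_distances

        rng = np.random.default_rng(0)
        perm = rng.permutation(len(pathways))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1, _, _ = classify_pathways(pathways, condense_level=2)
            r2, _, _ = classify_pathways([pathways[i] for i in perm], condense_level=2)
        # same partition up to relabeling and same class probabilities
        assert np.array_equal(r1.class_of[perm], r2.class_of)
        assert r1.class_prob == pytest.approx(r2.class_prob)


class TestClassSummaries:
    def test_probabilities_split(self):
        pws = [make_pathway("ABT")] * 4
        labels = [1, 1, 1, 2]
        probs = class_probabilities(pws, labels)
        assert probs == {1: pytest.approx(0.75), 2: pytest.approx(0.25)}

    def test_single_class(self):
        probs = class_probabilities([make_pathway("AT")], [1])
        assert probs == {1: pytest.approx(1.0)}

    def test_zero_total_weight_impossible(self):
        # Pathway construction already rejects non-positive weights
        with pytest.raises(ValueError):
            make_pathway("AT", weight=0.0)

    def test_probabilities_sum_to_one(self, pathways):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report, _, _ = classify_pathways(pathways, condense_level=2)
        assert sum(report.class_prob.values()) == pytest.approx(1.0, abs=1e-9)

    def test_duration_lists(self):
        pws = [make_pathway("ABCT", duration=12), make_pathway("AT", duration=5)]
        durations = duration_histograms(pws, [1, 2])
        assert durations == {1: [12], 2: [5]}

    def test_durations_not_truncated(self):
        pws = [
            make_pathway("AT", duration=3),
            make_pathway("ABT", duration=30),
            make_pathway("BT", duration=4),
            make_pathway("BAT", duration=40),
        ]
        durations = duration_histograms(pws, [1, 1, 2, 2])
        assert durations[1] == [3, 30] and durations[2] == [4, 40]


class TestNetworkEdges:
    def test_simple_chain(self):
        p = make_pathway((0, 3, 1), weight=0.5)
        edges = network_edges([p], condense_level=None)
        assert edges == {None: [(0, 3, 0.5), (3, 1, 0.5)]}

    def test_node_weights(self):
        p = make_pathway((0, 3, 1), weight=0.5)
        nodes = network_node_weights([p], condense_level=None)
        assert nodes == {None: [(0, 0.5), (1, 0.5), (3, 0.5)]}

    def test_empty_input(self):
        assert network_edges([], None) == {}

    def test_condensed_before_edges(self):
        p = make_pathway((1, 1, 2, 2, 5), weight=1.0)
        edges = network_edges([p], condense_level=1)
        assert edges == {None: [(1, 2, 1.0), (2, 5, 1.0)]}

    def test_two_route_discriminating_edges_disjoint(self, pathways, ensemble):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report, _, _ = classify_pathways(pathways, condense_level=2)
        e1 = {(a, b) for a, b, _ in report.edges[1]}
        e2 = {(a, b) for a, b, _ in report.edges[2]}
        # the route-defining transitions never co-occur
        assert ((1, 2) in e1) != ((1, 2) in e2)
        assert ((3, 4) in e1) != ((3, 4) in e2)


class TestClassifyPathways:
    def test_guardrail_warnings(self):
        pws = [make_pathway("ABT", weight=1.0) for _ in range(4)] + [
            make_pathway("AT", weight=1.0) for _ in range(4)
        ]
        with pytest.warns(UserWarning) as rec:
            report, _, _ = classify_pathways(pws, condense_level=None)
        messages = " | ".join(str(w.message) for w in rec)
        assert "pathways" in messages  # fewer than 50 pathways
        assert any("contains only" in str(w.message) for w in rec)

    def test_cut_height_override(self, pathways):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, tree, _ = classify_pathways(pathways, condense_level=2)
            report, _, _ = classify_pathways(
                pathways, condense_level=2, cut_height=tree.heights[-1] + 1
            )
        assert report.n_classes == 1

    def test_n_classes_override(self, pathways):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report, _, _ = classify_pathways(pathways, condense_level=2, n_classes=3)
        assert report.n_classes == 3

    def test_report_serialization(self, tmp_path, pathways):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report, tree, d = classify_pathways(pathways, condense_level=2)
        report.to_json(tmp_path / "report.json")
        report.edges_to_csv(tmp_path / "edges.csv")
        tree.to_csv(tmp_path / "linkage.csv")
        import json

        loaded = json.loads((tmp_path / "report.json").read_text())
        assert loaded["n_classes"] == report.n_classes
        assert len(loaded["class_of"]) == len(pathways)

    def test_probability_sum_validated(self):
        with pytest.raises(ValueError, match="sum"):
            ClassReport(
                class_of=np.array([1, 2]),
                class_prob={1: 0.5, 2: 0.2},
                durations={},
                edges={},
                cut_height=1.0,
                n_classes=2,
            )
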