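"""Distance matrix, background threshold, clustering, and network assembly."""

import itertools

import numpy as np
import pytest

import moanet as m
from conftest import make_profile


def _dm_stub(drugs, D, d_max=None):
    """Wrap a raw symmetric distance matrix as a DistanceMatrix."""
    dm = m.DistanceMatrix.__new__(m.DistanceMatrix)
    dm.drugs = list(drugs)
    dm.S = -np.asarray(D, float)
    dm.D = np.asarray(D, float)
    dm.D_max = float(D.max()) if d_max is None else d_max
    return dm


def _two_gene_profiles():
    """The worked similarity example: S = (3 + 1) / 2 = 2."""
    genes = ["g1", "g2"]
    # values chosen so the across-gene variance (ddof=1) is exactly 1
    a = make_profile("a", genes, [1.0 + np.sqrt(2.0), 1.0], [("g1", 1)])
    b = make_profile("b", genes, [3.0, 3.0 - np.sqrt(2.0)], [("g2", 1)])
    return a, b


class TestPairwiseSimilarity:
    def test_worked_arithmetic(self):
        a, b = _two_gene_profiles()
        assert m.pairwise_similarity(a, b) == pytest.approx(2.0)

    def test_negated_expression_flips_sign(self):
        genes = ["g1", "g2"]
        a = make_profile("a", genes, [np.sqrt(2.0) - 1.0, -1.0], [("g1", 1)])
        b = make_profile("b", genes, [-3.0, np.sqrt(2.0) - 3.0], [("g2", 1)])
        assert m.pairwise_similarity(a, b) == pytest.approx(-2.0)

    def test_symmetric_on_random_profiles(self, rng):
        genes = [f"g{i}" for i in range(40)]
        for _ in range(100):
            sig_a = [(f"g{i}", 1) for i in rng.choice(40, 5, replace=False)]
            sig_b = [(f"g{i}", -1) for i in rng.choice(40, 5, replace=False)]
            a = make_profile("a", genes, rng.normal(size=40), sig_a)
            b = make_profile("b", genes, rng.normal(size=40), sig_b)
            assert m.pairwise_similarity(a, b) == \
                m.pairwise_similarity(b, a)

    def test_missing_signature_genes_skipped_with_warning(self, rng):
        a = make_profile("a", ["g1", "g2"], [2.0, 0.0],
                         [("g1", 1), ("gX", 1)])
        b = make_profile("b", ["g1", "g2"], [3.0, 0.0], [("g2", 1)])
        with pytest.warns(UserWarning, match="skipped"):
            m.pairwise_similarity(a, b)


class TestDistanceMatrix:
    def _random_profiles(self, rng, n=5, n_genes=60):
        genes = [f"g{i}" for i in range(n_genes)]
        return [
            make_profile(f"d{k}", genes, rng.normal(size=n_genes),
                         [(f"g{i}", 1)
                          for i in rng.choice(n_genes, 6, replace=False)])
            for k in range(n)
        ]

    def test_most_similar_pair_has_zero_distance(self, rng):
        dm = m.distance_matrix(self._random_profiles(rng))
        off = dm.off_diagonal()
        assert off.min() == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(dm.D, dm.D_max - dm.S
                                   + np.diag(np.diag(dm.S - dm.D_max)))

    def test_symmetric_and_non_negative(self, rng):
        dm = m.distance_matrix(self._random_profiles(rng, n=6))
        np.testing.assert_allclose(dm.D, dm.D.T)
        assert (dm.D >= -1e-12).all()
        assert np.allclose(np.diag(dm.D), 0.0)

    def test_planted_pairs_closer_than_background(self):
        cfg = m.SimulationConfig(n_genes=3000, n_moas=2, drugs_per_moa=2,
                                 samples_per_drug=3, signature_size=50,
                                 effect_size=5.0, seed=55)
        matrix, metadata, truth = m.generate_dataset(cfg)
        null = m.build_null(matrix, metadata, 100_000, seed=56)
        sigs, _ = m.signatures_for_dataset(matrix, metadata, null)
        profiles = m.build_profiles(matrix, metadata, sigs)
        dm = m.distance_matrix(profiles)
        idx = {d: i for i, d in enumerate(dm.drugs)}
        within, between = [], []
        for a, b in itertools.combinations(dm.drugs, 2):
            same = truth.moa_of_drug[a] == truth.moa_of_drug[b]
            (within if same else between).append(dm.D[idx[a], idx[b]])
        assert max(within) < min(between)

    def test_rank_order_of_similarities_reversed(self, rng):
        dm = m.distance_matrix(self._random_profiles(rng, n=6))
        iu = np.triu_indices(6, k=1)
        assert np.array_equal(np.argsort(dm.S[iu]),
                              np.argsort(-dm.D[iu]))

    def test_requires_two_profiles(self, rng):
        with pytest.raises(ValueError, match=">= 2"):
            m.distance_matrix(self._random_profiles(rng, n=1))


class TestBackgroundThreshold:
    def _dm_from_distances(self, dist):
        return _dm_stub([f"d{i}" for i in range(dist.shape[0])], dist)

    def test_degenerate_equal_distances(self):
        d = np.full((6, 6), 3.0)
        np.fill_diagonal(d, 0.0)
        with pytest.warns(UserWarning, match="degenerate"):
            bg = m.background_threshold(self._dm_from_distances(d))
        assert bg.threshold == 3.0

    def test_uniform_distances_quantile(self, rng):
        n = 150  # 11,175 off-diagonal pairs
        iu = np.triu_indices(n, k=1)
        d = np.zeros((n, n))
        vals = rng.uniform(0, 1, size=iu[0].size)
        d[iu] = vals
        d += d.T
        bg = m.background_threshold(self._dm_from_distances(d), 0.01)
        assert bg.threshold == pytest.approx(0.01, abs=0.005)

    def test_separates_planted_clusters(self, rng):
        # 2 planted pairs among 30 drugs: tight pairs at ~0.05, rest ~N(1,.05)
        n = 30
        d = np.abs(rng.normal(1.0, 0.05, size=(n, n)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.05
        d[2, 3] = d[3, 2] = 0.06
        bg = m.background_threshold(self._dm_from_distances(d), 0.01)
        assert bg.threshold > 0.06            # above all planted pairs
        inter = d[np.triu_indices(n, k=1)]
        inter = inter[inter > 0.5]
        assert np.mean(inter < bg.threshold) < 0.03   # barely clips background

    def test_robust_estimator_ignores_planted_contamination(self, rng):
        # 40% of pairs tiny: pooled quantile collapses, robust stays in gap
        n = 40
        iu = np.triu_indices(n, k=1)
        vals = rng.normal(5.0, 0.1, size=iu[0].size)
        contaminated = rng.random(iu[0].size) < 0.4
        vals[contaminated] = rng.uniform(0, 0.3, size=contaminated.sum())
        d = np.zeros((n, n))
        d[iu] = vals
        d += d.T
        dm = self._dm_from_distances(d)
        pooled = m.background_threshold(dm, 0.01, "pooled").threshold
        robust = m.background_threshold(dm, 0.01, "robust").threshold
        assert pooled < 0.3          # contaminated
        assert 0.3 < robust < 5.0    # in the gap


def _brute_force_agglomerate(D, threshold):
    """Naive average-linkage agglomeration from the raw distance matrix."""
    clusters = [[i] for i in range(D.shape[0])]
    while len(clusters) > 1:
        best, pair = None, None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                avg = np.mean([D[i, j] for i in clusters[a]
                               for j in clusters[b]])
                if best is None or avg < best:
                    best, pair = avg, (a, b)
        if best > threshold:
            break
        a, b = pair
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return clusters


def _partition_sets(moa_of):
    groups = {}
    for d, moa in moa_of.items():
        groups.setdefault(moa, set()).add(d)
    return {frozenset(g) for g in groups.values()}


class TestClusterMoas:
    def _dm(self, rng, n=8):
        genes = [f"g{i}" for i in range(50)]
        profiles = [
            make_profile(f"d{k}", genes, rng.normal(size=50),
                         [(f"g{i}", 1)
                          for i in rng.choice(50, 5, replace=False)])
            for k in range(n)
        ]
        return m.distance_matrix(profiles)

    def test_threshold_below_minimum_gives_singletons(self, rng):
        dm = self._dm(rng)
        part = m.cluster_moas(dm, dm.off_diagonal().min() - 1e-9)
        assert len(set(part.values())) == len(dm.drugs)

    def test_threshold_above_maximum_gives_one_moa(self, rng):
        dm = self._dm(rng)
        part = m.cluster_moas(dm, dm.D.max() * 10)
        assert len(set(part.values())) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_agglomeration(self, seed):
        rng = np.random.default_rng(seed)
        dm = self._dm(rng, n=8)
        threshold = float(np.median(dm.off_diagonal()))
        part = m.cluster_moas(dm, threshold)
        oracle = _brute_force_agglomerate(dm.D, threshold)
        oracle_sets = {frozenset(dm.drugs[i] for i in c) for c in oracle}
        assert _partition_sets(part) == oracle_sets

    def test_invariant_to_drug_order(self, rng):
        dm = self._dm(rng, n=7)
        perm = list(rng.permutation(7))
        dm2 = m.DistanceMatrix([dm.drugs[i] for i in perm],
                               dm.S[np.ix_(perm, perm)],
                               dm.D[np.ix_(perm, perm)], dm.D_max)
        t = float(np.median(dm.off_diagonal()))
        assert _partition_sets(m.cluster_moas(dm, t)) == \
            _partition_sets(m.cluster_moas(dm2, t))


def _betweenness_oracle(nodes, edges):
    """Exhaustive shortest-path counting on a small unweighted graph."""
    import collections
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    score = {u: 0.0 for u in nodes}
    for s, t in itertools.combinations(nodes, 2):
        # BFS from s recording all shortest paths to t
        paths, queue = [], collections.deque([[s]])
        best = None
        while queue:
            path = queue.popleft()
            if best is not None and len(path) > best:
                continue
            if path[-1] == t:
                best = len(path)
                paths.append(path)
                continue
            for w in adj[path[-1]]:
                if w not in path:
                    queue.append(path + [w])
        if not paths:
            continue
        for path in paths:
            for w in path[1:-1]:
                score[w] += 1.0 / len(paths)
    return score


class TestBuildNetwork:

    def test_path_moa_center_is_middle(self):
        drugs = ["a", "b", "c"]
        D = np.array([[0.0, 0.5, 2.0],
                      [0.5, 0.0, 0.5],
                      [2.0, 0.5, 0.0]])
        net = m.build_network({d: "M1" for d in drugs},
                              _dm_stub(drugs, D), threshold=1.0)
        assert net.centers["M1"] == "b"
        assert len(net.intra_edges) == 2

    def test_singleton_moa_is_its_own_center(self):
        drugs = ["a", "b"]
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        net = m.build_network({"a": "M1", "b": "M2"},
                              _dm_stub(drugs, D), threshold=1.0)
        assert net.centers == {"M1": "a", "M2": "b"}
        assert net.intra_edges == []

    def test_single_cross_pair_gives_one_inter_moa_edge(self):
        drugs = ["a1", "a2", "b1", "b2"]
        D = np.full((4, 4), 5.0)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 0.2
        D[2, 3] = D[3, 2] = 0.2
        D[1, 2] = D[2, 1] = 0.9  # just under threshold
        part = {"a1": "M1", "a2": "M1", "b1": "M2", "b2": "M2"}
        net = m.build_network(part, _dm_stub(drugs, D), threshold=1.0)
        assert net.inter_moa_edges == [("M1", "M2", 0.9)]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_center_matches_exhaustive_betweenness(self, seed):
        rng = np.random.default_rng(seed)
        n = 9
        drugs = [f"d{i}" for i in range(n)]
        D = np.full((n, n), 2.0)
        np.fill_diagonal(D, 0.0)
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < 0.45:
                D[i, j] = D[j, i] = 0.5
        net = m.build_network({d: "M1" for d in drugs},
                              _dm_stub(drugs, D), threshold=1.0)
        edges = [(a, b) for a, b, _ in net.intra_edges]
        oracle = _betweenness_oracle(drugs, edges)
        best = min(drugs, key=lambda d: (-oracle[d], d))
        assert net.centers["M1"] == best
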