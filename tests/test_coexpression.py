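"""Signed adjacency, TOM, module detection, eigengenes, kME and activity."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from hepatox.coexpression import (
    CoexpressionNetwork,
    detect_modules,
    kme,
    module_activity,
    module_eigengene,
    pick_soft_threshold,
    signed_adjacency,
    tom_similarity,
)


def _expr(rows, genes=None):
    rows = np.asarray(rows, dtype=float)
    genes = genes or [f"G{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=genes,
                        columns=[f"S{j}" for j in range(rows.shape[1])])


def _tom_bruteforce(a):
    """Literal triple-loop topological overlap (independent oracle)."""
    n = a.shape[0]
    k = a.sum(axis=1) - 1.0
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


class TestSignedAdjacency:
    def test_correlation_limits(self):
        base = np.array([1.0, 2, 3, 4, 5])
        expr = _expr([base, 2 * base + 1, -base, [1, -1, 1, -1, 1]])
        adj = signed_adjacency(expr, power=6)
        assert adj.iloc[0, 1] == pytest.approx(1.0)        # perfect correlation
        assert adj.iloc[0, 2] == pytest.approx(0.0, abs=1e-12)  # anticorrelated
        assert ((adj.to_numpy() >= 0) & (adj.to_numpy() <= 1)).all()

    def test_uncorrelated_pair_at_half_power(self):
        # exactly orthogonal centred profiles: cor = 0 -> a = 0.5^power
        expr = _expr([[1, -1, 1, -1], [1, 1, -1, -1]])
        for power in (1, 2, 6):
            assert signed_adjacency(expr, power).iloc[0, 1] == \
                pytest.approx(0.5 ** power)

    def test_zero_variance_gene_handled(self, caplog):
        expr = _expr([[1, 2, 3, 4], [5, 5, 5, 5]])
        with caplog.at_level("WARNING"):
            adj = signed_adjacency(expr, power=2)
        assert adj.iloc[0, 1] == pytest.approx(0.25)  # cor treated as 0
        assert adj.iloc[1, 1] == 1.0

    def test_power_below_one_rejected(self):
        with pytest.raises(ValueError):
            signed_adjacency(_expr([[1, 2, 3]] * 2), power=0.5)


class TestTomSimilarity:
    def test_hand_computed_three_gene_value(self):
        a = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]])
        adj = pd.DataFrame(a)
        tom = tom_similarity(adj)
        # TOM_12 = (a13*a32 + a12)/(min(k1,k2) + 1 - a12)
        want = (0.2 * 0.4 + 0.5) / (min(0.7, 0.9) + 1 - 0.5)
        assert tom.iloc[0, 1] == pytest.approx(want, abs=1e-12)

    def test_identical_rows_with_binary_neighbours(self):
        # 0/1 shared-neighbour weights: identical rows overlap completely
        a = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        assert tom_similarity(pd.DataFrame(a)).iloc[0, 1] == pytest.approx(1.0)

    def test_symmetry_unit_diagonal_and_range(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, size=(8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(pd.DataFrame(a)).to_numpy()
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)
        assert ((tom >= 0) & (tom <= 1)).all()

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(3, 7))
            a = rng.uniform(0, 1, size=(n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            got = tom_similarity(pd.DataFrame(a)).to_numpy()
            want = _tom_bruteforce(a)
            off = ~np.eye(n, dtype=bool)
            assert np.allclose(got[off], want[off], atol=1e-12)

    def test_asymmetric_input_rejected(self):
        a = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError):
            tom_similarity(pd.DataFrame(a))


class TestDetectModules:
    def test_two_planted_blocks_recovered(self, two_block_expression):
        expr, truth = two_block_expression
        net = CoexpressionNetwork(power=6, min_module_size=20).fit(expr)
        labels = net.labels_
        found = sorted(set(labels) - {"unassigned"})
        assert len(found) == 2
        assert adjusted_rand_score(truth, labels.to_numpy()) >= 0.9

    def test_gene_order_permutation_consistency(self, two_block_expression):
        expr, _ = two_block_expression
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.index)
        adj = signed_adjacency(expr, 6)
        labels, _ = detect_modules(1 - tom_similarity(adj), min_size=20)
        adj_p = signed_adjacency(expr.loc[perm], 6)
        labels_p, _ = detect_modules(1 - tom_similarity(adj_p), min_size=20)
        aligned = labels_p.loc[labels.index]
        assert adjusted_rand_score(labels.to_numpy(), aligned.to_numpy()) == 1.0

    def test_independent_genes_left_unassigned(self):
        rng = np.random.default_rng(3)
        expr = _expr(rng.normal(size=(60, 20)))
        adj = signed_adjacency(expr, 6)
        labels, _ = detect_modules(1 - tom_similarity(adj), min_size=20)
        # independent noise: no structure at module scale survives the cut
        sizes = labels[labels != "unassigned"].value_counts()
        assert (sizes < 60).all()  # never one giant everything-module... or
        assert labels.eq("unassigned").all() or len(sizes) <= 2

    def test_min_size_validation(self, two_block_expression):
        expr, _ = two_block_expression
        adj = signed_adjacency(expr, 6)
        with pytest.raises(ValueError):
            detect_modules(1 - tom_similarity(adj), min_size=1)


class TestPickSoftThreshold:
    def test_single_candidate_returned(self, two_block_expression):
        expr, _ = two_block_expression
        assert pick_soft_threshold(expr, candidate_powers=[4]) in (4.0, 12.0)

    def test_tiny_matrix_falls_back(self, caplog):
        expr = _expr(np.arange(12.0).reshape(4, 3))
        with caplog.at_level("WARNING"):
            assert pick_soft_threshold(expr) == 12.0

    def test_independent_genes_fall_back_to_twelve(self):
        rng = np.random.default_rng(8)
        expr = _expr(rng.normal(size=(100, 10)))
        assert pick_soft_threshold(expr) == 12.0

    def test_stable_across_adjacent_seeds(self):
        powers = []
        for seed in (20, 21):
            rng = np.random.default_rng(seed)
            latent = rng.normal(size=30)
            rows = [3 * latent + rng.normal(size=30) for _ in range(40)]
            rows += [rng.normal(size=30) * 0.5 + 3 * rng.normal() for _ in range(40)]
            powers.append(pick_soft_threshold(_expr(rows)))
        assert np.isfinite(powers).all() and powers[0] == powers[1]


class TestEigengeneAndKme:
    def test_identical_genes_have_unit_kme(self):
        base = np.array([1.0, 3, 2, 5, 4, 6])
        expr = _expr([base, base, base])
        eig = module_eigengene(expr, list(expr.index))
        assert np.linalg.norm(eig) == pytest.approx(1.0)
        assert np.allclose(kme(expr, eig), 1.0)

    def test_negated_gene_has_kme_minus_one(self):
        base = np.array([1.0, 3, 2, 5, 4, 6])
        expr = _expr([base, base, -base])
        eig = module_eigengene(expr, ["G0", "G1"])
        k = kme(expr, eig)
        assert k["G2"] == pytest.approx(-1.0)

    def test_eigengene_explains_most_module_variance(self, two_block_expression):
        expr, _ = two_block_expression
        genes = list(expr.index[:50])
        eig = module_eigengene(expr, genes)
        k = kme(expr.loc[genes], eig)
        # mean squared correlation with the eigengene beats that with any
        # single gene's profile
        best_single = max(
            np.mean([np.corrcoef(expr.loc[g], expr.loc[h])[0, 1] ** 2
                     for g in genes])
            for h in genes[:10]
        )
        assert np.mean(k ** 2) >= best_single - 1e-9

    def test_kme_tracks_signal_to_noise(self):
        rng = np.random.default_rng(17)
        latent = rng.normal(size=40)
        noise_sd = np.linspace(0.2, 3.0, 25)
        rows = [latent + rng.normal(0, s, size=40) for s in noise_sd]
        expr = _expr(rows)
        eig = module_eigengene(expr, list(expr.index))
        k = kme(expr, eig)
        rho = spearmanr(noise_sd, k.to_numpy()).statistic
        assert rho <= -0.9  # noisier genes are less central

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError):
            module_eigengene(_expr([[1, 2, 3]]), [])


class TestModuleActivity:
    def test_top_ranked_module_scores_one(self):
        expr = _expr(np.arange(10.0)[::-1].reshape(10, 1))
        act = module_activity(expr, {"top": ["G0", "G1", "G2"]})
        assert act.loc["top"].iloc[0] == pytest.approx(1.0)

    def test_random_expression_activity_centred_at_zero(self):
        rng = np.random.default_rng(23)
        expr = _expr(rng.normal(size=(60, 1000)))
        act = module_activity(expr, {"m": [f"G{i}" for i in range(15)]})
        vals = act.loc["m"].to_numpy()
        assert ((vals >= -1) & (vals <= 1)).all()
        assert abs(vals.mean()) < 0.02

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        expr = _expr(rng.uniform(1, 5, size=(20, 6)))
        act = module_activity(expr, {"m": [f"G{i}" for i in range(5)]})
        act_t = module_activity(np.exp(expr) + 3, {"m": [f"G{i}" for i in range(5)]})
        pd.testing.assert_frame_equal(act, act_t)

    def test_dose_dependent_module_shift_is_monotone(self):
        """A module shifted upward proportionally to concentration shows
        monotone nondecreasing median activity (the expected behaviour of a
        stress-response module under increasing chemical concentration)."""
        rng = np.random.default_rng(31)
        concs = [0.0, 1.0, 2.0, 4.0]
        cols, shifts = [], []
        for c in concs:
            for _ in range(5):
                cols.append(c)
        expr = rng.normal(size=(80, len(cols)))
        for j, c in enumerate(cols):
            expr[:20, j] += 0.6 * c
        expr = _expr(expr)
        act = module_activity(expr, {"m": [f"G{i}" for i in range(20)]})
        med = [np.median(act.loc["m"].to_numpy()[np.array(cols) == c])
               for c in concs]
        assert all(b >= a for a, b in zip(med, med[1:]))

    def test_module_covering_all_genes_rejected(self):
        expr = _expr(np.arange(8.0).reshape(4, 2))
        with pytest.raises(ValueError):
            module_activity(expr, {"all": list(expr.index)})


def test_network_transform_bounds(two_block_expression):
    expr, _ = two_block_expression
    net = CoexpressionNetwork(power=6, min_module_size=20).fit(expr)
    act = net.transform(expr)
    vals = act.to_numpy()
    assert ((vals >= -1.0 - 1e-12) & (vals <= 1.0 + 1e-12)).all()
    # eigengene rows are unit norm
    assert np.allclose(np.linalg.norm(net.eigengenes_.to_numpy(), axis=1), 1.0)
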