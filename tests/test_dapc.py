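import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from oxysites.dapc import DAPCResult, fit_dapc, fit_pca, infer_groups, run_dapc, top_loading_sites
from oxysites.io_model import Alignment, SiteRecord
from oxysites.site_encoding import encode_sites


class TestFitPCA:
    def test_rank_cap(self, rng):
        base = rng.standard_normal((10, 2))
        X = base @ rng.standard_normal((2, 8))  # rank 2
        m = fit_pca(X, var_target=0.90)
        assert m.retained_count <= 2

    def test_dominant_direction_single_pc(self, rng):
        u = rng.standard_normal(30)
        X = np.outer(u, np.ones(6)) * 10 + rng.standard_normal((30, 6)) * 0.05
        assert fit_pca(X, var_target=0.90).retained_count == 1

    def test_minimal_retention_against_full_spectrum(self, rng):
        # brute-force cumulative-sum check over the whole eigenvalue spectrum
        X = rng.standard_normal((20, 15))
        m = fit_pca(X, var_target=0.90)
        Xc = X - X.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(Xc.T @ Xc / 19))[::-1]
        cum = np.cumsum(eig) / eig.sum()
        assert cum[m.retained_count - 1] >= 0.90
        assert cum[m.retained_count - 2] < 0.90
        assert np.isclose(m.cumulative_variance, cum[m.retained_count - 1])

    def test_loadings_orthonormal(self, rng):
        m = fit_pca(rng.standard_normal((15, 9)))
        G = m.loadings.T @ m.loadings
        assert np.allclose(G, np.eye(m.retained_count), atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_pca(np.ones((5, 4)))


class TestInferGroups:
    def test_two_separated_clouds(self, rng):
        a = rng.standard_normal((15, 3)) * 0.1
        b = rng.standard_normal((15, 3)) * 0.1 + 50
        X = np.vstack([a, b])
        k, labels, _ = infer_groups(X, k_max=8, seed=0)
        assert k == 2
        assert adjusted_rand_score([0] * 15 + [1] * 15, labels) == 1.0

    def test_identical_rows_give_single_group(self):
        X = np.ones((12, 4))
        k, _, _ = infer_groups(X, k_max=5, seed=0)
        assert k == 1

    def test_three_gaussian_clusters(self, rng):
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        X = np.vstack([rng.standard_normal((10, 2)) * 0.1 + c for c in centers])
        k, labels, bic = infer_groups(X, k_max=8, seed=0)
        assert k == 3
        assert adjusted_rand_score(np.repeat([0, 1, 2], 10), labels) == 1.0
        # BIC really is the minimum at 3 among all evaluated k
        assert min(bic, key=bic.get) == 3

    def test_k_max_validation(self, rng):
        with pytest.raises(ValueError):
            infer_groups(rng.standard_normal((5, 2)), k_max=0)
        with pytest.raises(ValueError):
            infer_groups(rng.standard_normal((5, 2)), k_max=5)


def _planted_matrix(rng, n_per=6, p=8, delta=8.0, k=2):
    """k groups separated along the first variable only."""
    X = rng.standard_normal((n_per * k, p)) * 0.3
    for g in range(k):
        X[g * n_per : (g + 1) * n_per, 0] += g * delta
    labels = np.repeat(np.arange(k), n_per)
    return X, labels


class TestFitDAPC:
    def _fit(self, X, labels, var_target=0.999):
        pca = fit_pca(X, var_target=var_target)
        S = pca.transform(X)
        row_ids = [f"s{i}" for i in range(X.shape[0])]
        sites = list(range(1, X.shape[1] // 5 + 1)) or [1]
        # pad site list so 5 descriptors per site divides p when needed
        return pca, fit_dapc(S, labels, pca, row_ids, sites)

    def test_two_groups_single_ld_full_proportion(self, rng):
        X, labels = _planted_matrix(rng, p=10)
        _, res = self._fit(X, labels)
        assert res.n_ld == 1
        assert np.allclose(res.ld_var_prop, [1.0], atol=1e-10)

    def test_four_groups_three_sorted_lds(self, rng):
        X = rng.standard_normal((24, 10))
        X[:6, 0] += 20; X[6:12, 1] += 12; X[12:18, 2] += 6
        labels = np.repeat(np.arange(4), 6)
        _, res = self._fit(X, labels)
        assert res.n_ld == 3
        assert np.all(np.diff(res.ld_var_prop) <= 1e-12)
        assert np.isclose(res.ld_var_prop.sum(), 1.0, atol=1e-10)

    def test_informative_variable_dominates_loading(self, rng):
        X, labels = _planted_matrix(rng, p=10, delta=15.0)
        _, res = self._fit(X, labels)
        assert np.argmax(np.abs(res.var_loadings[:, 0])) == 0

    def test_brute_force_generalized_eigen_oracle(self, rng):
        # dense W^-1 B solve by explicit inversion on a 6x4 matrix
        X = rng.standard_normal((6, 4))
        labels = np.array([0, 0, 1, 1, 2, 2])
        pca = fit_pca(X, var_target=0.9999)
        S = pca.transform(X)
        res = fit_dapc(S, labels, pca, [f"s{i}" for i in range(6)], [1])
        n, p = S.shape
        grand = S.mean(axis=0)
        B = np.zeros((p, p)); W = np.zeros((p, p))
        for g in range(3):
            pts = S[labels == g]
            mu = pts.mean(axis=0)
            B += len(pts) * np.outer(mu - grand, mu - grand)
            W += (pts - mu).T @ (pts - mu)
        B /= n; W = W / n + 1e-8 * np.eye(p)
        ev = np.sort(np.linalg.eigvals(np.linalg.inv(W) @ B).real)[::-1][:2]
        props = ev / ev.sum()
        assert np.allclose(res.ld_var_prop, props, atol=1e-8)

    def test_single_group_rejected(self, rng):
        X = rng.standard_normal((6, 3))
        pca = fit_pca(X, var_target=0.99)
        with pytest.raises(ValueError, match="discriminant"):
            fit_dapc(pca.transform(X), np.zeros(6, dtype=int), pca, list("abcdef"), [1])

    def test_ld_scores_invariant_to_pc_rotation(self, rng):
        X, labels = _planted_matrix(rng, p=10, delta=10.0, k=3)
        pca = fit_pca(X, var_target=0.999)
        S = pca.transform(X)
        res = fit_dapc(S, labels, pca, [f"s{i}" for i in range(len(labels))], [1, 2])
        # rotate the retained PC basis by a random orthogonal matrix
        q, _ = np.linalg.qr(rng.standard_normal((S.shape[1], S.shape[1])))
        pca_rot = fit_pca(X, var_target=0.999)
        pca_rot.loadings = pca.loadings @ q
        res_rot = fit_dapc(S @ q, labels, pca_rot, [f"s{i}" for i in range(len(labels))], [1, 2])
        for j in range(res.n_ld):
            a, b = res.ld_scores[:, j], res_rot.ld_scores[:, j]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8


class TestTopLoadingSites:
    def _result(self, loadings, sites):
        n_ld = loadings.shape[1]
        return DAPCResult(
            k=n_ld + 1,
            assignments=np.zeros(3, dtype=int),
            bic_curve={},
            ld_scores=np.zeros((3, n_ld)),
            ld_var_prop=np.full(n_ld, 1 / n_ld),
            var_loadings=loadings,
            row_ids=["a", "b", "c"],
            site_order=sites,
        )

    def test_single_dominant_site(self):
        L = np.zeros((50, 1))
        L[10:15, 0] = 3.0  # site 3 carries everything
        res = self._result(L, list(range(1, 11)))
        assert top_loading_sites(res, 90)[1] == [3]

    def test_uniform_loadings_tie_policy(self):
        L = np.ones((50, 1))
        res = self._result(L, list(range(1, 11)))
        # all sites tie at the threshold: all are included
        assert top_loading_sites(res, 90)[1] == list(range(1, 11))

    def test_planted_two_site_signal_recovered(self, zscales, rng):
        # groups differ only at codons 5 and 9 of a 20-site alignment
        letters = "ACDEFGHIKL"
        base = "".join(rng.choice(list(letters)) for _ in range(20))
        g2 = base[:4] + "W" + base[5:8] + "R" + base[9:]
        rows = [base] * 5 + [g2] * 5
        a = Alignment(ids=[f"s{i}" for i in range(10)], rows=rows)
        X = encode_sites(a, [SiteRecord("G", c) for c in range(1, 21)], zscales)
        res = run_dapc(X, k_max=4, seed=0)
        assert res.k == 2
        assert set(res.top_sites[1]) == {5, 9}
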