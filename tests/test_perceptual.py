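"""Dissimilarity matrices, MDS, variance partition, Williams' test, RM-ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from stochtex import (
    DissimilarityMatrix,
    build_dissimilarity,
    nonmetric_mds,
    rm_anova_hf,
    variance_partition,
    williams_test,
)
from stochtex.perceptual import align_dimension


def ratings_frame(entries):
    return pd.DataFrame(entries, columns=["stim_i", "stim_j", "rating"])


class TestBuildDissimilarity:
    def test_all_zero_ratings_give_zero_matrix(self):
        rows = [(f"s{i}", f"s{j}", 0.0) for i in range(3) for j in range(3)]
        d = build_dissimilarity(ratings_frame(rows))
        assert np.all(d.d == 0)

    def test_two_orders_averaged_into_both_cells(self):
        rows = [("a", "b", 0.2), ("b", "a", 0.4),
                ("a", "a", 0.0), ("b", "b", 0.0)]
        d = build_dissimilarity(ratings_frame(rows))
        i, j = d.labels.index("a"), d.labels.index("b")
        assert d.d[i, j] == pytest.approx(0.3)
        assert d.d[j, i] == pytest.approx(0.3)

    def test_full_405_trial_table_matches_groupby_oracle(self, rng):
        labels = [f"C{c}A{a}" for c in (1, 2, 3) for a in (1, 2, 3)]
        rows = []
        for _ in range(5):  # 81 ordered pairs x 5 repeats = 405 trials
            for i in labels:
                for j in labels:
                    rows.append((i, j, float(rng.random())))
        frame = ratings_frame(rows)
        d = build_dissimilarity(frame)
        key = frame.apply(
            lambda r: tuple(sorted((r.stim_i, r.stim_j))), axis=1
        )
        means = frame.groupby(key)["rating"].mean()
        for i, a in enumerate(d.labels):
            for j, b in enumerate(d.labels):
                if a != b:
                    assert d.d[i, j] == pytest.approx(means[tuple(sorted((a, b)))])

    def test_missing_pair_flagged(self):
        rows = [("a", "b", 0.1), ("a", "c", 0.2)]  # (b, c) never rated
        with pytest.raises(ValueError, match="unrated"):
            build_dissimilarity(ratings_frame(rows))


def _smacof_oracle(d, k, rng, n_starts=24, n_iter=600):
    """Independent nonmetric SMACOF with isotonic-regression disparities."""
    from sklearn.isotonic import IsotonicRegression

    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    dis = d[iu]
    order = np.argsort(dis)
    best = np.inf

    # classical (Torgerson) start plus random restarts
    j = np.eye(n) - np.ones((n, n)) / n
    b0 = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b0)
    idx = np.argsort(w)[::-1][:k]
    starts = [v[:, idx] * np.sqrt(np.maximum(w[idx], 0))]
    starts += [rng.normal(size=(n, k)) for _ in range(n_starts - 1)]
    for x in starts:
        x = np.array(x, dtype=float)
        for _ in range(n_iter):
            dist = squareform(pdist(x))
            dv = dist[iu]
            iso = IsotonicRegression()
            disp = iso.fit_transform(dis[order], dv[order])
            dhat = np.empty_like(dv)
            dhat[order] = disp
            # scale disparities to the distances (Kruskal's convention)
            dhat *= np.linalg.norm(dv) / max(np.linalg.norm(dhat), 1e-12)
            # Guttman transform
            full = np.zeros((n, n))
            full[iu] = dhat
            full += full.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 1e-12, full / dist, 0.0)
            b = -ratio
            b[np.diag_indices(n)] = ratio.sum(axis=1)
            x_new = b @ x / n
            if np.max(np.abs(x_new - x)) < 1e-10:
                x = x_new
                break
            x = x_new
        dist = squareform(pdist(x))
        dv = dist[iu]
        iso = IsotonicRegression()
        disp = iso.fit_transform(dis[order], dv[order])
        dhat = np.empty_like(dv)
        dhat[order] = disp
        stress = np.sqrt(np.sum((dv - dhat) ** 2) / np.sum(dv**2))
        best = min(best, stress)
    return best


class TestNonmetricMds:
    def test_exact_two_dimensional_recovery(self, rng):
        from scipy.spatial import procrustes

        pts = rng.normal(size=(9, 2))
        d = squareform(pdist(pts))
        dm = DissimilarityMatrix([f"s{i}" for i in range(9)], d)
        sol = nonmetric_mds(dm, dims=(2,), rng=rng)
        assert sol.stress[2] < 1e-3
        assert procrustes(pts, sol.coords[2])[2] < 1e-2

    def test_stress_nesting_in_dimensionality(self, rng):
        d = squareform(np.abs(rng.normal(0.5, 0.2, 36))) + 0.05
        np.fill_diagonal(d, 0.0)
        dm = DissimilarityMatrix([f"s{i}" for i in range(9)], d)
        sol = nonmetric_mds(dm, dims=(1, 2, 3), rng=rng)
        assert sol.stress[1] >= sol.stress[2] - 1e-6
        assert sol.stress[2] >= sol.stress[3] - 1e-6

    def test_stress_agrees_with_independent_smacof(self, rng):
        # noisy 9-point configuration: best-of-starts stress must agree with
        # an independent SMACOF + isotonic-regression implementation
        pts = rng.normal(size=(9, 2))
        d = squareform(pdist(pts)) + squareform(np.abs(rng.normal(0, 0.05, 36)))
        dm = DissimilarityMatrix([f"s{i}" for i in range(9)], d)
        sol = nonmetric_mds(dm, dims=(2,), rng=rng, n_init=24)
        oracle = _smacof_oracle(d, 2, np.random.default_rng(1))
        assert sol.stress[2] == pytest.approx(oracle, abs=1e-3)

    def test_coordinates_centred(self, rng):
        d = squareform(np.abs(rng.normal(0.5, 0.2, 36))) + 0.05
        np.fill_diagonal(d, 0.0)
        dm = DissimilarityMatrix([f"s{i}" for i in range(9)], d)
        sol = nonmetric_mds(dm, dims=(2,), rng=rng)
        np.testing.assert_allclose(sol.coords[2].mean(axis=0), 0.0, atol=1e-9)

    def test_degenerate_all_equal_matrix_rejected(self, rng):
        d = np.full((5, 5), 0.3)
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2
        with pytest.raises(ValueError):
            nonmetric_mds(
                DissimilarityMatrix([f"s{i}" for i in range(5)], d * 0.0), rng=rng
            )

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            DissimilarityMatrix(["a", "b"], d)


class TestVariancePartition:
    def test_statistic_identical_to_coordinates(self, rng):
        y = rng.normal(size=12)
        vp = variance_partition(y, y.copy(), np.zeros(12), standardize=False)
        assert vp.pct_var == pytest.approx(100.0, abs=1e-9)

    def test_orthogonal_statistic_accounts_for_nothing(self):
        y = np.tile([1.0, -1.0], 10)
        s = np.tile([1.0, 1.0, -1.0, -1.0], 5)
        vp = variance_partition(y, s, np.zeros(20), standardize=False)
        assert vp.pct_var == pytest.approx(0.0, abs=1e-9)

    def test_planted_effect_recovered(self, rng):
        # 4 listeners x 9 stimuli with statistic explaining 80% of the
        # non-listener variance; partial eta-squared recovers the plant
        # (raw incremental R^2 is attenuated by whatever the listener
        # dummies absorb by chance)
        target = 0.80
        partial = []
        for _ in range(12):
            s = rng.normal(size=36)
            noise = rng.normal(size=36)
            y = np.sqrt(target) * (s - s.mean()) / s.std()
            y = y + np.sqrt(1 - target) * (noise - noise.mean()) / noise.std()
            listeners = np.repeat(np.arange(4), 9)
            vp = variance_partition(y, s, listeners, standardize=False)
            partial.append(100.0 * vp.partial_eta_sq)
        assert np.mean(partial) == pytest.approx(80.0, abs=5.0)

    def test_collinear_with_listener_factor_rejected(self):
        y = np.arange(8.0)
        listeners = np.repeat([0, 1], 4)
        s = np.repeat([0.0, 1.0], 4)  # pure listener effect
        with pytest.raises(ValueError):
            variance_partition(y, s, listeners, standardize=False)

    def test_alignment_fixes_sign_and_scale(self, rng):
        ref = rng.normal(size=9)
        coords = -3.0 * ref + 0.5
        z = align_dimension(coords, ref)
        assert np.corrcoef(z, ref)[0, 1] > 0.999
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0)


class TestWilliams:
    def test_equal_correlations_give_zero_t(self):
        t, p = williams_test(0.5, 0.5, 0.3, 30)
        assert t == 0.0 and p == 1.0

    def test_sign_antisymmetry(self):
        t1, _ = williams_test(0.9, 0.6, 0.5, 36)
        t2, _ = williams_test(0.6, 0.9, 0.5, 36)
        assert t1 == pytest.approx(-t2)

    def test_textbook_formula_recomputation(self):
        r_jk, r_jh, r_kh, n = 0.9, 0.6, 0.5, 36
        det = 1 - r_jk**2 - r_jh**2 - r_kh**2 + 2 * r_jk * r_jh * r_kh
        rbar = (r_jk + r_jh) / 2
        expected = (r_jk - r_jh) * np.sqrt(
            (n - 1) * (1 + r_kh)
            / (2 * det * (n - 1) / (n - 3) + rbar**2 * (1 - r_kh) ** 3)
        )
        t, p = williams_test(r_jk, r_jh, r_kh, n)
        assert t == pytest.approx(expected, abs=1e-6)
        assert 0 < p < 0.001

    def test_non_psd_triple_rejected(self):
        with pytest.raises(ValueError):
            williams_test(0.9, 0.9, -0.9, 20)

    def test_null_p_values_uniform(self):
        # trivariate normal null with equal dependent correlations
        rng = np.random.default_rng(4)
        from scipy import stats as sps

        rho_jk = rho_jh = 0.5
        rho_kh = 0.3
        cov = np.array([[1, rho_jk, rho_jh], [rho_jk, 1, rho_kh], [rho_jh, rho_kh, 1]])
        chol = np.linalg.cholesky(cov)
        pvals = []
        for _ in range(2000):
            x = rng.standard_normal((36, 3)) @ chol.T
            r = np.corrcoef(x, rowvar=False)
            try:
                _, p = williams_test(r[0, 1], r[0, 2], r[1, 2], 36)
            except ValueError:
                continue
            pvals.append(p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


def _balanced_frame(values):
    n, a, b = values.shape
    rows = []
    for s in range(n):
        for i in range(a):
            for j in range(b):
                rows.append(
                    {"subject": s, "factor_a": i, "factor_b": j, "value": values[s, i, j]}
                )
    return pd.DataFrame(rows)


class TestRmAnovaHf:
    def test_compound_symmetric_data_has_epsilon_one(self, rng):
        # exchangeable covariance satisfies sphericity: epsilon_HF caps at 1
        n, a, b = 12, 3, 2
        subj = rng.normal(size=(n, 1, 1))
        values = subj + rng.normal(size=(n, a, b))
        table = rm_anova_hf(_balanced_frame(values))
        eff_a = table.set_index("effect").loc["factor_a"]
        assert eff_a["eps_hf"] == pytest.approx(1.0, abs=0.11)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        values = rng.normal(size=(8, 3, 3)) + np.arange(3)[None, :, None] * 0.4
        frame = _balanced_frame(values)
        mine = rm_anova_hf(frame).set_index("effect")
        ref = pg.rm_anova(
            data=frame, dv="value", within=["factor_a", "factor_b"],
            subject="subject", correction=True, detailed=True,
        ).set_index("Source")
        for eff, ref_name in [("factor_a", "factor_a"), ("factor_b", "factor_b"),
                              ("factor_a*factor_b", "factor_a * factor_b")]:
            assert mine.loc[eff, "F"] == pytest.approx(ref.loc[ref_name, "F"], rel=1e-9)
        # epsilon: pingouin is exact for main effects (it warns that its own
        # two-way interaction epsilon is unreliable, so only bound that one)
        for eff in ("factor_a", "factor_b"):
            assert mine.loc[eff, "eps_gg"] == pytest.approx(ref.loc[eff, "eps"], rel=1e-6)
        d_int = 4  # (3-1)(3-1)
        assert 1.0 / d_int <= mine.loc["factor_a*factor_b", "eps_gg"] <= 1.0

    def test_type_one_error_rate_under_null(self, rng):
        hits = 0
        n_sims = 1000
        for _ in range(n_sims):
            values = rng.normal(size=(6, 3, 2))
            table = rm_anova_hf(_balanced_frame(values))
            hits += table.set_index("effect").loc["factor_a", "p_hf"] < 0.05
        assert 0.03 <= hits / n_sims <= 0.07

    def test_planted_effect_beats_null_effect(self, rng):
        wins = 0
        for _ in range(40):
            values = rng.normal(size=(5, 3, 2)) + np.linspace(0, 1.5, 3)[None, :, None]
            table = rm_anova_hf(_balanced_frame(values)).set_index("effect")
            wins += table.loc["factor_a", "F"] > table.loc["factor_b", "F"]
        assert wins >= 38

    def test_unbalanced_design_rejected(self, rng):
        frame = _balanced_frame(rng.normal(size=(5, 3, 2))).iloc[:-1]
        with pytest.raises(ValueError):
            rm_anova_hf(frame)
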