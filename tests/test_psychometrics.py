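import numpy as np
import pandas as pd
import pytest

import combkit as ck
from combkit import psychometrics as psy
from combkit.psychometrics import PsychometricsError
from combkit.simulate import GroundTruthParams


def orthonormal_data(rng, n, k):
    """n x k data whose sample covariance is exactly the identity."""
    q, _ = np.linalg.qr(rng.normal(size=(n, k)))
    q = q - q.mean(axis=0)
    q, _ = np.linalg.qr(q)
    return np.sqrt(n - 1) * q


def compound_symmetric_data(rng, n, k, r):
    """Data whose sample correlation matrix is exactly compound symmetric."""
    z = orthonormal_data(rng, n, k)
    c = np.full((k, k), r) + (1 - r) * np.eye(k)
    return pd.DataFrame(z @ np.linalg.cholesky(c).T,
                        columns=[f"x{i}" for i in range(k)])


def three_factor_data(n=2000, seed=9):
    spec = ck.InstrumentSpec(
        domains={"Capability": ("BR", "DM", "KS")},
        items={"BR": ("BR1", "BR2", "BR3"), "DM": ("DM1", "DM2", "DM3"),
               "KS": ("KS1", "KS2", "KS3")},
        behavior_items=("BY1", "BY2", "BY3"),
    )
    params = GroundTruthParams(
        loadings={i: 0.8 for i in spec.all_items},
        second_order_loadings={d: 0.35 for d in spec.non_behavior_domains},
        structural_paths={k: 0.0 for k in ("M~C", "M~O", "B~C", "B~O", "B~M")},
    )
    data = ck.generate_responses(spec, params, n, seed=seed)
    items = [i for d in spec.non_behavior_domains for i in spec.items[d]]
    return data[items]


class TestCorrectedItemTotal:
    def test_parallel_items_give_unity(self):
        col = [1, 2, 3, 4, 5]
        data = pd.DataFrame({"a": col, "b": col, "c": col})
        values = ck.corrected_item_total(data, ["a", "b", "c"])
        assert all(v == pytest.approx(1.0) for v in values.values())

    def test_reversed_item_gives_minus_one(self):
        data = pd.DataFrame({"A": [1, 2, 3, 4], "B": [1, 2, 3, 4],
                             "C": [4, 3, 2, 1]})
        values = ck.corrected_item_total(data, ["A", "B", "C"])
        assert values["C"] == pytest.approx(-1.0)
        # rest scores of A and B (B+C, A+C) are constant: undefined
        assert np.isnan(values["A"]) and np.isnan(values["B"])

    def test_zero_variance_item_identified(self):
        data = pd.DataFrame({"a": [1, 2, 3, 4], "b": [3, 3, 3, 3]})
        with pytest.raises(PsychometricsError, match="'b'"):
            ck.corrected_item_total(data, ["a", "b"])

    def test_low_item_total_flagged_at_threshold(self):
        # an item whose rest-correlation is far below 0.5 must be eliminated
        rng = np.random.default_rng(4)
        common = rng.normal(size=300)
        data = pd.DataFrame({
            "g1": common + 0.3 * rng.normal(size=300),
            "g2": common + 0.3 * rng.normal(size=300),
            "g3": common + 0.3 * rng.normal(size=300),
            "noise": rng.normal(size=300),
        })
        report = psy.screen_item_totals(data, list(data.columns), threshold=0.5)
        assert report.eliminated == {"noise": psy.REASON_LOW_ITEM_TOTAL}
        assert report.item_total["noise"] < 0.5
        assert report.thresholds["item_total"] == 0.5


class TestCronbachAlpha:
    def test_parallel_items_alpha_one(self):
        col = [1, 2, 3, 5]
        data = pd.DataFrame({"a": col, "b": col, "c": col})
        assert ck.cronbach_alpha(data, ["a", "b", "c"]) == pytest.approx(1.0)

    def test_uncorrelated_equal_variance_alpha_zero(self):
        data = pd.DataFrame({"a": [1, 1, 2, 2], "b": [1, 2, 2, 1]})
        assert ck.cronbach_alpha(data, ["a", "b"]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_toy_matrix(self):
        # rows (1,2,1),(2,3,2),(3,4,4),(4,5,5): item variances 5/3, 5/3,
        # 10/3; total-score variance 58/3 -> alpha = 3/2 * 38/58 = 57/58
        data = pd.DataFrame([(1, 2, 1), (2, 3, 2), (3, 4, 4), (4, 5, 5)],
                            columns=list("abc"))
        assert ck.cronbach_alpha(data, list("abc")) == pytest.approx(57 / 58)

    def test_matches_pingouin_on_random_data(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        data = pd.DataFrame(
            rng.normal(size=(120, 5)) + rng.normal(size=(120, 1)),
            columns=list("abcde"),
        )
        ours = ck.cronbach_alpha(data, list("abcde"))
        theirs = pingouin.cronbach_alpha(data)[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_spearman_brown_form_on_parallel_items(self):
        rng = np.random.default_rng(3)
        for k, r in [(3, 0.4), (5, 0.6), (4, 0.2)]:
            data = compound_symmetric_data(rng, 60, k, r)
            expected = k * r / (1 + (k - 1) * r)
            assert ck.cronbach_alpha(data, list(data.columns)) == pytest.approx(
                expected, abs=1e-12)

    def test_invariant_under_item_shift(self):
        rng = np.random.default_rng(8)
        data = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        shifted = data.copy()
        shifted["b"] = shifted["b"] + 7.5
        assert ck.cronbach_alpha(data, list("abcd")) == pytest.approx(
            ck.cronbach_alpha(shifted, list("abcd")), abs=1e-12)


class TestSamplingAdequacy:
    def test_kmo_high_for_strong_common_factor(self):
        rng = np.random.default_rng(21)
        f = rng.normal(size=5000)
        data = pd.DataFrame({
            f"v{i}": 0.9 * f + np.sqrt(1 - 0.81) * rng.normal(size=5000)
            for i in range(3)
        })
        assert ck.kmo(data) > 0.7

    def test_kmo_error_without_common_variance(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(orthonormal_data(rng, 40, 4))
        with pytest.raises(PsychometricsError, match="common variance"):
            ck.kmo(data)

    def test_kmo_matches_regression_partial_correlation_oracle(self):
        from oracles import kmo_via_regression

        rng = np.random.default_rng(17)
        data = pd.DataFrame(
            rng.normal(size=(200, 6)) + 0.6 * rng.normal(size=(200, 1)))
        assert ck.kmo(data) == pytest.approx(
            kmo_via_regression(data.to_numpy()), abs=1e-10)

    def test_bartlett_identity_correlation(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(orthonormal_data(rng, 50, 4))
        chi2, df, p = ck.bartlett_sphericity(data)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_bartlett_df_is_pairs_count(self):
        rng = np.random.default_rng(14)
        data = pd.DataFrame(rng.normal(size=(100, 9)))
        _, df, _ = ck.bartlett_sphericity(data)
        assert df == 36

    def test_bartlett_matches_hand_formula_for_two_items(self):
        rng = np.random.default_rng(6)
        data = pd.DataFrame(rng.normal(size=(80, 2)), columns=["a", "b"])
        data["b"] = 0.5 * data["a"] + data["b"]
        r = data.corr().iloc[0, 1]
        expected = -(80 - 1 - 9 / 6) * np.log(1 - r**2)
        chi2, df, _ = ck.bartlett_sphericity(data)
        assert df == 1
        assert chi2 == pytest.approx(expected, abs=1e-8)


class TestEfaVarimax:
    def test_single_factor_data_retains_one_component(self):
        rng = np.random.default_rng(30)
        f = rng.normal(size=3000)
        data = pd.DataFrame({
            f"v{i}": 0.8 * f + 0.6 * rng.normal(size=3000) for i in range(9)
        })
        solution = ck.efa_pca_varimax(data)
        assert solution.n_factors == 1

    def test_eigenvalue_sum_equals_item_count_and_communalities_preserved(self):
        data = three_factor_data()
        solution = ck.efa_pca_varimax(data)
        assert solution.eigenvalues.sum() == pytest.approx(data.shape[1], abs=1e-8)
        # rotation is orthogonal: communalities equal unrotated ones
        r = data.corr().to_numpy()
        ev, vec = np.linalg.eigh(r)
        order = np.argsort(ev)[::-1]
        ev, vec = ev[order], vec[:, order]
        k = solution.n_factors
        unrotated = vec[:, :k] * np.sqrt(ev[:k])
        assert np.allclose(solution.communalities.to_numpy(),
                           (unrotated**2).sum(axis=1), atol=1e-8)

    def test_sign_convention_dominant_loading_positive(self):
        solution = ck.efa_pca_varimax(three_factor_data())
        arr = solution.loadings.to_numpy()
        for j in range(arr.shape[1]):
            assert arr[np.argmax(np.abs(arr[:, j])), j] > 0

    def test_matches_statsmodels_varimax_oracle(self):
        rotate_factors = pytest.importorskip(
            "statsmodels.multivariate.factor_rotation").rotate_factors
        data = three_factor_data()
        solution = ck.efa_pca_varimax(data, rotation_tol=1e-12,
                                      max_rotation_iter=2000)
        r = data.corr().to_numpy()
        ev, vec = np.linalg.eigh(r)
        order = np.argsort(ev)[::-1]
        ev, vec = ev[order], vec[:, order]
        k = solution.n_factors
        assert k == 3
        unrotated = vec[:, :k] * np.sqrt(ev[:k])
        h = np.sqrt((unrotated**2).sum(axis=1))
        oracle, _ = rotate_factors(unrotated / h[:, None], "varimax",
                                   tol=1e-12, max_tries=2000)
        oracle = oracle * h[:, None]
        ours = solution.loadings.to_numpy()
        aligned = np.zeros_like(ours)
        for j in range(k):
            m = int(np.argmax([abs(oracle[:, j] @ ours[:, c]) for c in range(k)]))
            aligned[:, m] = oracle[:, j] * np.sign(oracle[:, j] @ ours[:, m])
        assert np.abs(aligned - ours).max() < 1e-6

    def test_no_retained_component_is_an_error(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(orthonormal_data(rng, 60, 4))
        with pytest.raises(PsychometricsError, match="no eigenvalue"):
            ck.efa_pca_varimax(data, eigen_threshold=1.5)


class TestRetentionRules:
    @staticmethod
    def _solution(loadings: dict[str, list[float]]):
        frame = pd.DataFrame(loadings).T
        frame.columns = [f"F{j + 1}" for j in range(frame.shape[1])]
        k = frame.shape[1]
        return psy.FactorSolution(
            loadings=frame, eigenvalues=np.ones(len(frame)),
            pct_variance=np.full(k, 100 / k), total_pct_variance=100.0,
            communalities=(frame**2).sum(axis=1), rotation_iterations=1,
        )

    @staticmethod
    def _screening(items):
        return psy.ItemScreeningReport(item_total={i: 0.7 for i in items})

    def test_cross_loading_eliminated(self):
        # loading 0.607 on a second factor alongside 0.61 primary
        loadings = {"k1": [0.61, 0.607], "a1": [0.9, 0.0], "a2": [0.85, 0.1],
                    "a3": [0.8, 0.0], "b1": [0.0, 0.9], "b2": [0.1, 0.85],
                    "b3": [0.0, 0.8]}
        report = psy.apply_item_retention_rules(
            self._solution(loadings), self._screening(loadings))
        assert report.eliminated == {"k1": psy.REASON_CROSS_LOADING}

    def test_low_primary_loading_eliminated(self):
        loadings = {"w": [0.45, 0.2], "a1": [0.9, 0.0], "a2": [0.85, 0.0],
                    "a3": [0.8, 0.0], "b1": [0.0, 0.9], "b2": [0.0, 0.85],
                    "b3": [0.0, 0.8]}
        report = psy.apply_item_retention_rules(
            self._solution(loadings), self._screening(loadings))
        assert report.eliminated == {"w": psy.REASON_LOW_LOADING}

    def test_two_item_factor_dissolved(self):
        loadings = {"a1": [0.9, 0.0], "a2": [0.85, 0.0], "a3": [0.8, 0.0],
                    "x1": [0.0, 0.9], "x2": [0.0, 0.85]}
        report = psy.apply_item_retention_rules(
            self._solution(loadings), self._screening(loadings))
        assert report.eliminated == {"x1": psy.REASON_ORPHAN_FACTOR,
                                     "x2": psy.REASON_ORPHAN_FACTOR}

    def test_clean_solution_keeps_everything(self):
        loadings = {f"{f}{i}": [0.9 if j == k else 0.0 for j in range(2)]
                    for k, f in enumerate("ab") for i in range(3)}
        report = psy.apply_item_retention_rules(
            self._solution(loadings), self._screening(loadings))
        assert report.eliminated == {}


class TestReliabilityValidity:
    @pytest.mark.parametrize("loadings, expected", [
        ([0.821, 0.802, 0.738], 0.621),
        ([0.833, 0.812, 0.722], 0.625),
        ([0.830, 0.827, 0.827], 0.686),
        ([0.849, 0.888, 0.886], 0.765),
        ([0.659, 0.686, 0.71, 0.722, 0.68, 0.709, 0.691], 0.482),
        ([1.0, 1.0], 1.0),
    ])
    def test_ave(self, loadings, expected):
        assert round(ck.ave(loadings), 3) == expected

    @pytest.mark.parametrize("loadings, expected", [
        ([0.821, 0.802, 0.738], 0.830),
        ([0.847, 0.835, 0.703], 0.839),
        ([0.859, 0.817, 0.816], 0.870),
        ([0.849, 0.888, 0.886], 0.907),
        ([1.0, 1.0, 1.0], 1.0),
    ])
    def test_composite_reliability(self, loadings, expected):
        assert round(ck.composite_reliability(loadings), 3) == expected

    def test_empty_loadings_rejected(self):
        with pytest.raises(PsychometricsError):
            ck.ave([])
        with pytest.raises(PsychometricsError):
            ck.composite_reliability([])

    def test_fornell_larcker_sqrt_and_boundary(self):
        corr = pd.DataFrame([[1.0, 0.8], [0.8, 1.0]],
                            index=["A", "B"], columns=["A", "B"])
        sqrt_ave, passes = ck.fornell_larcker({"A": 0.621, "B": 0.64}, corr)
        assert round(sqrt_ave["A"], 3) == 0.788
        # sqrt(0.64) = 0.8 equals the correlation: strictly-greater fails
        assert passes[("B", "A")] is False

    def test_fornell_larcker_perfect_ave_passes(self):
        corr = pd.DataFrame([[1.0, 0.95], [0.95, 1.0]],
                            index=["A", "B"], columns=["A", "B"])
        _, passes = ck.fornell_larcker({"A": 1.0, "B": 1.0}, corr)
        assert all(passes.values())

    def test_missing_ave_rejected(self):
        corr = pd.DataFrame([[1.0, 0.2], [0.2, 1.0]],
                            index=["A", "B"], columns=["A", "B"])
        with pytest.raises(PsychometricsError, match="B"):
            ck.fornell_larcker({"A": 0.6}, corr)


class TestSplitHalf:
    def test_ordered_split_halves(self, responses):
        first, second = psy.split_half(responses)
        assert len(first) == 242 and len(second) == 242
        assert first.index[0] == responses.index[0]

    def test_random_split_is_seeded(self, responses):
        a1, _ = psy.split_half(responses, mode="random", seed=5)
        a2, _ = psy.split_half(responses, mode="random", seed=5)
        assert a1.equals(a2)
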