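"""Population statistics: overlap, EM decomposition, summaries, tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import mechanops as m
from mechanops.errors import DegenerateTableError, InsufficientDataError, ParameterError


def grid_overlap(m1, s1, m2, s2):
    """Brute-force oracle: trapezoidal integration of min(f1, f2)."""
    lo = min(m1 - 8 * s1, m2 - 8 * s2)
    hi = max(m1 + 8 * s1, m2 + 8 * s2)
    x = np.linspace(lo, hi, 200_001)
    y = np.minimum(stats.norm.pdf(x, m1, s1), stats.norm.pdf(x, m2, s2))
    return np.trapezoid(y, x)


class TestOverlap:
    def test_identical_distributions(self):
        assert m.overlap_coefficient(0.7, 0.1, 0.7, 0.1) == 1.0

    def test_disjoint_limit(self):
        assert m.overlap_coefficient(0.0, 0.01, 1.0, 0.01) < 1e-10

    def test_symmetry_and_scale_equivariance(self):
        a = m.overlap_coefficient(0.699, 0.106, 1.230, 0.13)
        assert a == pytest.approx(m.overlap_coefficient(1.230, 0.13, 0.699, 0.106))
        assert a == pytest.approx(
            m.overlap_coefficient(6.99, 1.06, 12.30, 1.3), rel=1e-9
        )

    @settings(derandomize=True, max_examples=100)
    @given(
        m1=st.floats(-2, 2),
        m2=st.floats(-2, 2),
        s1=st.floats(0.05, 2.0),
        s2=st.floats(0.05, 2.0),
    )
    def test_matches_grid_integration(self, m1, m2, s1, s2):
        analytic = m.overlap_coefficient(m1, s1, m2, s2)
        assert 0.0 <= analytic <= 1.0
        assert analytic == pytest.approx(grid_overlap(m1, s1, m2, s2), abs=1e-6)

    def test_equal_sd_single_crossing(self):
        assert m.overlap_coefficient(0.0, 1.0, 2.0, 1.0) == pytest.approx(
            grid_overlap(0.0, 1.0, 2.0, 1.0), abs=1e-6
        )

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ParameterError):
            m.overlap_coefficient(0.0, 0.0, 1.0, 1.0)


class TestSummary:
    def _frame(self, wcdi, classes):
        import pandas as pd

        return pd.DataFrame(
            {"wCDI": wcdi, "strain": 0.3, "recovery_class": classes}
        )

    def test_constant_values_edge(self):
        s = m.summarize_population(self._frame([1.0, 1.0, 1.0], ["instant"] * 3))
        assert s.wcdi_mean == 1.0 and s.wcdi_sd == 0.0 and s.outlier_count == 0

    def test_single_pass_outlier_removal(self):
        rng = np.random.default_rng(1)
        vals = list(rng.normal(0.7, 0.02, 99)) + [10.0]
        s = m.summarize_population(self._frame(vals, ["instant"] * 100), outlier_sd=3.0)
        assert s.n_accepted == 99 and s.outlier_count == 1

    def test_proportions_partition(self):
        classes = ["instant"] * 5 + ["transient"] * 3 + ["prolonged"] * 2
        s = m.summarize_population(self._frame([0.7] * 9 + [0.71], classes))
        assert s.recovery_proportions == {
            "instant": 0.5,
            "transient": 0.3,
            "prolonged": 0.2,
        }
        assert sum(s.recovery_counts.values()) == s.n_accepted

    def test_too_few_cells_rejected(self):
        with pytest.raises(InsufficientDataError):
            m.summarize_population(self._frame([1.0], ["instant"]))

    def test_simulated_mix_recovered_exactly_noise_free(
        self, geometry, acquisition
    ):
        """Pipeline recovery proportions equal the simulated ground truth."""
        cfg = m.SimulationConfig(
            geometry=geometry, acquisition=acquisition, n_cells=30, noise_sd=0.0, seed=29
        )
        trace, truths = m.simulate_trace(cfg)
        records, _ = m.extract_pulses(trace, geometry, acquisition)
        phs = [m.phenotype_from_record(r, geometry) for r in records]
        s = m.summarize_population(phs, outlier_sd=np.inf)
        true_counts = {
            c: sum(t.recovery_class_true == c for t in truths)
            for c in ("instant", "transient", "prolonged")
        }
        assert s.recovery_counts == true_counts


MEP = {"mean": 0.865, "sd": 0.107}
LEP = {"mean": 1.133, "sd": 0.144}


def _mixture(rng, n, alpha):
    n1 = rng.binomial(n, alpha)
    return np.concatenate(
        [
            rng.normal(MEP["mean"], MEP["sd"], n1),
            rng.normal(LEP["mean"], LEP["sd"], n - n1),
        ]
    )


class TestEM:
    def test_pure_component_gives_alpha_near_one(self):
        """Data drawn purely from one lineage is attributed to it.

        Uses the lineage-anchored variant: with all five parameters free,
        two components can converge onto the same blob and split the weight
        arbitrarily, so α is only identified against fixed components.
        """
        rng = np.random.default_rng(0)
        x = rng.normal(MEP["mean"], MEP["sd"], 500)
        fit = m.em_mixture_fraction(x, MEP, LEP, freeze_components=True)
        assert fit.alpha >= 0.95

    def test_log_likelihood_monotone(self):
        rng = np.random.default_rng(1)
        x = _mixture(rng, 500, 0.3)
        for freeze in (False, True):
            fit = m.em_mixture_fraction(x, MEP, LEP, freeze_components=freeze)
            assert np.all(np.diff(fit.log_likelihood) >= -1e-9)

    def test_anchored_alpha_recovery(self):
        rng = np.random.default_rng(2)
        x = _mixture(rng, 500, 0.3)
        fit = m.em_mixture_fraction(x, MEP, LEP, freeze_components=True)
        assert fit.alpha == pytest.approx(0.30, abs=0.05)
        assert fit.comp1 == MEP  # components untouched

    def test_free_fit_matches_reference_em(self):
        """The in-house EM lands on the same optimum as an independent
        implementation (sklearn GaussianMixture) from the same start."""
        GaussianMixture = pytest.importorskip("sklearn.mixture").GaussianMixture
        rng = np.random.default_rng(3)
        x = _mixture(rng, 500, 0.3)
        fit = m.em_mixture_fraction(x, MEP, LEP)
        gm = GaussianMixture(
            2,
            weights_init=[0.5, 0.5],
            means_init=[[MEP["mean"]], [LEP["mean"]]],
            precisions_init=[[[1 / MEP["sd"] ** 2]], [[1 / LEP["sd"] ** 2]]],
            tol=1e-8,
            max_iter=500,
            reg_covar=1e-10,
        ).fit(x.reshape(-1, 1))
        assert fit.alpha == pytest.approx(gm.weights_[0], abs=0.02)
        assert fit.comp1["mean"] == pytest.approx(gm.means_[0, 0], abs=0.02)

    def test_identical_inits_flagged_unidentifiable(self):
        rng = np.random.default_rng(4)
        x = rng.normal(1.0, 0.1, 100)
        fit = m.em_mixture_fraction(x, MEP, dict(MEP))
        assert fit.flag == "identifiability" and not fit.converged

    def test_too_few_values_rejected(self):
        with pytest.raises(InsufficientDataError):
            m.em_mixture_fraction(np.ones(5), MEP, LEP)


class TestHypothesisWrappers:
    def test_identical_recovery_profiles(self):
        a = {"instant": 50, "transient": 30, "prolonged": 20}
        res = m.compare_recovery_profiles(a, dict(a))
        assert res.statistic == 0.0 and res.pvalue == 1.0 and res.dof == 2

    def test_chi2_matches_hand_computation(self):
        """Independent oracle: expected counts from the marginal products."""
        table = np.array([[50.0, 30.0, 20.0], [20.0, 30.0, 50.0]])
        row, col, total = table.sum(1, keepdims=True), table.sum(0), table.sum()
        expected = row * col / total
        by_hand = ((table - expected) ** 2 / expected).sum()
        res = m.compare_recovery_profiles(table[0], table[1])
        assert res.statistic == pytest.approx(by_hand, rel=1e-12)
        assert res.dof == 2

    def test_empty_population_rejected(self):
        with pytest.raises(DegenerateTableError):
            m.compare_recovery_profiles(
                {"instant": 0, "transient": 0, "prolonged": 0},
                {"instant": 1, "transient": 1, "prolonged": 1},
            )

    def test_identical_wcdi_samples(self):
        x = np.linspace(0.5, 1.5, 50)
        res = m.compare_wcdi(x, x.copy())
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_shifted_samples_highly_significant(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.7, 0.1, 50)
        b = a + 1.0  # 10 sd shift
        assert m.compare_wcdi(a, b).pvalue < 1e-6

    def test_unequal_lengths_use_welch(self):
        rng = np.random.default_rng(6)
        res = m.compare_wcdi(rng.normal(0.7, 0.1, 40), rng.normal(0.8, 0.1, 60))
        assert res.method == "welch"

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientDataError):
            m.compare_wcdi([1.0], [1.0, 2.0])
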