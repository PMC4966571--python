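"""Spatial-model machinery: ICAR kernel, diagnostics, categorization, fits.

Model fits here use deliberately small lattices and short chains; the
full-scale calibration and recovery checks live in the acceptance tests.
"""

import numpy as np
import pytest

from smallarea import (
    ModelSpec,
    SimulationConfig,
    categorize_pr,
    ess,
    fit_model1,
    fit_model2,
    fit_model3,
    icar_log_kernel,
    rhat,
    rr_and_trend,
    simulate_study,
    ssmr,
)
from smallarea.graphs import make_city_lattice
from smallarea.models import PR_BIN_LABELS


class TestIcarKernel:
    def test_hand_enumerated_path_value(self):
        # 3-node path, s = (0, 1, -1): edge sum (0-1)^2 + (1-(-1))^2 = 5
        g = make_city_lattice(1, 3)
        assert icar_log_kernel([0.0, 1.0, -1.0], g, 1.0) == pytest.approx(-2.5)

    def test_constant_vector_maximises_kernel(self):
        g = make_city_lattice(2, 3)
        rng = np.random.default_rng(0)
        const = icar_log_kernel(np.full(6, 3.7), g, 1.0)
        assert all(
            icar_log_kernel(rng.standard_normal(6), g, 1.0) <= const for _ in range(20)
        )

    def test_shift_invariance(self):
        g = make_city_lattice(2, 2)
        s = np.array([0.3, -1.2, 0.8, 0.1])
        base = icar_log_kernel(s, g, 0.7)
        for c in (-5.0, 1e3):
            assert icar_log_kernel(s + c, g, 0.7) == pytest.approx(base)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            icar_log_kernel([0.0, 1.0], make_city_lattice(1, 3), 1.0)


class TestDiagnostics:
    def test_white_noise_chains_pass_gate(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((3, 2000))
        assert rhat(chains) <= 1.01
        # iid draws: effective sample size near the total draw count
        assert ess(chains) > 0.8 * chains.size

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((2, 1000))
        chains[1] += 10.0
        assert rhat(chains) > 1.1

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            rhat(np.zeros((1, 100)))


class TestCategorize:
    @pytest.mark.parametrize(
        "p, label",
        [
            (0.0, PR_BIN_LABELS[0]),
            (0.024, PR_BIN_LABELS[0]),
            (0.025, PR_BIN_LABELS[1]),
            (0.049, PR_BIN_LABELS[1]),
            (0.05, PR_BIN_LABELS[2]),
            (0.5, PR_BIN_LABELS[2]),
            (0.949, PR_BIN_LABELS[2]),
            (0.95, PR_BIN_LABELS[3]),
            (0.974, PR_BIN_LABELS[3]),
            (0.975, PR_BIN_LABELS[4]),
            (1.0, PR_BIN_LABELS[4]),
        ],
    )
    def test_boundaries(self, p, label):
        assert categorize_pr(p) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_pr(1.2)


@pytest.fixture(scope="module")
def m1_fit(null_study):
    spec = ModelSpec(model_id=1, chains=2, iterations=1200, burn_in=600, seed=19)
    return fit_model1(null_study.counts, null_study.graphs, spec, sex="men")


class TestModel1:
    def test_null_ssmr_centred_near_100(self, m1_fit):
        sm = ssmr(m1_fit)
        assert sm["ssmr"].mean() == pytest.approx(100, abs=10)
        cover = ((sm["ssmr_lo"] <= 100) & (100 <= sm["ssmr_hi"])).mean()
        assert cover >= 0.9

    def test_spatial_draws_sum_to_zero(self, m1_fit):
        S = m1_fit.draws["S"]
        idx = m1_fit.stratum_index
        for (_, _), grp in idx.groupby(["city", "period"]):
            assert np.abs(S[:, :, grp.index.to_numpy()].sum(axis=-1)).max() < 1e-8

    def test_jensen_inequality_on_ssmr(self, m1_fit):
        u = m1_fit.draws["u"].reshape(-1, m1_fit.draws["u"].shape[-1])
        assert np.all(np.exp(u).mean(axis=0) >= np.exp(u.mean(axis=0)) - 1e-12)

    def test_joint_fit_matches_separate_city_fits(self, small_study):
        """Cities are independent likelihood blocks: fitting two cities
        jointly or one at a time must give the same posteriors up to
        Monte Carlo error."""
        spec = ModelSpec(model_id=1, chains=2, iterations=1400, burn_in=700, seed=41)
        joint = fit_model1(small_study.counts, small_study.graphs, spec, sex="men",
                           store_fields=False)
        b_joint = joint.draws["b"][:, :, :, 0].mean(axis=(0, 1))
        for pos, (city, period) in enumerate(joint.block_labels):
            if city != "city01":
                continue
            solo = fit_model1(
                small_study.counts[small_study.counts["city"] == city],
                {city: small_study.graphs[city]}, spec, sex="men", store_fields=False,
            )
            solo_pos = solo.block_labels.index((city, period))
            b_solo = solo.draws["b"][:, :, solo_pos, 0].mean()
            assert b_joint[pos] == pytest.approx(b_solo, abs=0.03)

    def test_ssmr_requires_model1(self, null_study):
        spec = ModelSpec(model_id=2, chains=2, iterations=200, burn_in=100, seed=1)
        with pytest.raises(ValueError, match="Model 1"):
            ssmr(
                type("FakeFit", (), {"model_id": 2})()
            )


@pytest.fixture(scope="module")
def regression_study():
    """Two cities, strong data, known fixed coefficients (no hyper noise)."""
    cfg = SimulationConfig(
        n_cities=2, tracts_per_city=64,
        beta_true=(0.0, 0.15, -0.1, -0.05), sigma_b_true=(0, 0, 0, 0),
        sigma_s_true=0.1, sigma_h_true=0.05,
        base_population=1500, sexes=("men",), seed=7,
    )
    study = simulate_study(cfg)
    x = study.truth.table[study.truth.table["period"] == 1][["city", "tract", "x"]]
    return study, x


@pytest.fixture(scope="module")
def m2_fit(regression_study):
    study, x = regression_study
    spec = ModelSpec(model_id=2, chains=2, iterations=2000, burn_in=1000, seed=9)
    return fit_model2(
        study.counts, study.graphs, x, spec, sex="men",
        reference=study.reference, store_fields=False,
    )


class TestModel2:
    def test_coefficients_recovered(self, regression_study, m2_fit):
        study, _ = regression_study
        b = m2_fit.draws["b"]
        b2_hat = b[:, :, :, 1].mean(axis=(0, 1))
        b4_hat = b[:, :, :, 3].mean(axis=(0, 1))
        assert np.abs(b2_hat - study.truth.b_city["b2"].to_numpy()).max() < 0.05
        assert np.abs(b4_hat - study.truth.b_city["b4"].to_numpy()).max() < 0.05

    def test_rr_summary_consistent_with_draws(self, m2_fit):
        rr = rr_and_trend(m2_fit)
        row = rr.per_city.iloc[0]
        assert row["rr_p1_lo"] <= row["rr_p1"] <= row["rr_p1_hi"]
        assert 0 <= row["pr_delta"] <= 1
        assert row["category"] in PR_BIN_LABELS
        # negative true interaction: probability of an increase below 1/2
        assert (rr.per_city["pr_delta"] < 0.5).all()
        assert rr.global_summary is None

    def test_wrong_model_id_rejected(self, regression_study):
        study, x = regression_study
        spec = ModelSpec(model_id=3, chains=2, iterations=200, burn_in=100, seed=1)
        with pytest.raises(ValueError, match="model_id"):
            fit_model2(study.counts, study.graphs, x, spec, reference=study.reference)


class TestModel3:
    def test_fewer_than_three_cities_rejected(self, regression_study):
        study, x = regression_study
        spec = ModelSpec(model_id=3, chains=2, iterations=200, burn_in=100, seed=1)
        with pytest.raises(ValueError, match="3 cities"):
            fit_model3(study.counts, study.graphs, x, spec, reference=study.reference)

    def test_partial_pooling_shrinks_city_estimates(self):
        """With a common true slope, the hierarchical fit's city slopes
        should be less dispersed than the unpooled per-city fit's."""
        cfg = SimulationConfig(
            n_cities=4, tracts_per_city=36,
            beta_true=(0.0, 0.12, -0.1, 0.0), sigma_b_true=(0, 0, 0, 0),
            sigma_s_true=0.1, sigma_h_true=0.05,
            base_population=400, sexes=("men",), seed=23,
        )
        study = simulate_study(cfg)
        x = study.truth.table[study.truth.table["period"] == 1][["city", "tract", "x"]]
        common = dict(chains=2, iterations=1500, burn_in=750, seed=31)
        fit2 = fit_model2(
            study.counts, study.graphs, x, ModelSpec(model_id=2, **common),
            sex="men", reference=study.reference, store_fields=False,
        )
        fit3 = fit_model3(
            study.counts, study.graphs, x, ModelSpec(model_id=3, **common),
            sex="men", reference=study.reference, store_fields=False,
        )
        spread2 = fit2.draws["b"][:, :, :, 1].mean(axis=(0, 1)).std()
        spread3 = fit3.draws["b"][:, :, :, 1].mean(axis=(0, 1)).std()
        assert spread3 < spread2
        rr = rr_and_trend(fit3)
        assert rr.global_summary is not None
        g = rr.global_summary.iloc[0]
        assert g["rrg_p1_lo"] <= g["rrg_p1"] <= g["rrg_p1_hi"]


class TestModelSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"model_id": 4},
            {"model_id": 1, "chains": 1},
            {"model_id": 1, "burn_in": 500, "iterations": 500},
            {"model_id": 1, "prior_sd_upper": 0.0},
            {"model_id": 1, "thinning": 0},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelSpec(**kwargs)
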