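import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stoichcal import (
    AttenuationParams,
    CTMeasurement,
    WATER,
    fit_three_param,
    fit_two_param,
    hu_to_ratio,
    mu_ratio,
    relative_electron_density,
    theoretical_hu,
)
from stoichcal.datasets import AUDIT_PHANTOM_MATERIALS, FORMULA_MATERIALS, get_material
from stoichcal.materials import MaterialComposition
from stoichcal.model import ConvergenceError

from conftest import synthetic_measurements


k_strategy = st.tuples(
    st.floats(0.0, 5e-3), st.floats(0.0, 2e-4)
)


class TestMuRatio:
    @given(k=k_strategy)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_water_is_unity_for_any_params(self, k):
        assert mu_ratio(WATER, *k) == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize(
        "name", ["Lung", "Muscle/General", "Mineral Bone", "Tooth", "Air"]
    )
    def test_collapses_to_red_at_zero_params(self, name):
        m = get_material(name)
        assert mu_ratio(m, 0.0, 0.0) == pytest.approx(
            relative_electron_density(m), rel=1e-12
        )

    def test_mineral_bone_red_value(self):
        m = get_material("Mineral Bone")
        assert round(mu_ratio(m, 0.0, 0.0), 3) == 1.784


class TestHuMapping:
    @pytest.mark.parametrize(
        "hu, alpha, expected",
        [(0.0, 1.3, 1.0), (-1000.0, 1.0, 0.0), (-950.0, 0.95, 0.0)],
    )
    def test_hu_to_ratio(self, hu, alpha, expected):
        assert hu_to_ratio(hu, alpha) == pytest.approx(expected, abs=1e-12)

    def test_water_hu_is_zero_for_any_alpha(self):
        for alpha in (0.9, 1.0, 1.3, 2.0):
            p = AttenuationParams(1.24e-3, 3.06e-5, alpha)
            assert theoretical_hu(WATER, p) == 0.0

    def test_air_maps_near_minus_1000_alpha(self):
        air = get_material("Air")
        hu = theoretical_hu(air, AttenuationParams(1.24e-3, 3.06e-5, 1.0))
        # air's mu/mu_w is ~1e-3, not 0, so the CT number is ~-999
        assert -1000 < hu < -998

    @given(
        k=k_strategy,
        alpha=st.floats(0.9, 1.1),
        name=st.sampled_from(
            ["tough_lung", "tough_bone", "tough_water"]
        ),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_hu_ratio(self, k, alpha, name):
        m = AUDIT_PHANTOM_MATERIALS[name]
        p = AttenuationParams(k[0], k[1], alpha)
        hu = theoretical_hu(m, p)
        assert hu_to_ratio(hu, alpha) == pytest.approx(
            mu_ratio(m, *k), rel=1e-12
        )

    def test_hu_increases_with_density(self):
        p = AttenuationParams(1.24e-3, 3.06e-5, 1.0)
        m = AUDIT_PHANTOM_MATERIALS["tough_bone"]
        hus = [
            theoretical_hu(
                MaterialComposition("s", rho, m.weights, m.residual), p
            )
            for rho in (0.5, 1.0, 1.5, 2.0)
        ]
        assert all(b > a for a, b in zip(hus, hus[1:]))


class TestTwoParamFit:
    def test_exact_recovery_from_formula_materials(self):
        truth = AttenuationParams(1.5e-3, 4.0e-5)
        mats = [
            FORMULA_MATERIALS[n]
            for n in ("ldpe", "polystyrene", "acrylic", "delrin", "teflon")
        ]
        fit = fit_two_param(synthetic_measurements(mats, truth))
        assert fit.ssr < 1e-18
        assert fit.params.k1 == pytest.approx(truth.k1, rel=1e-8)
        assert fit.params.k2 == pytest.approx(truth.k2, rel=1e-8)
        assert fit.params.alpha is None
        assert fit.model == "two_param"
        assert len(fit.residuals) == fit.n_materials == 5

    def test_hydrocarbons_only_flagged_unidentifiable(self):
        # PMP, LDPE, polystyrene span only H and C: k1/k2 not determined
        truth = AttenuationParams(1.24e-3, 3.06e-5)
        mats = [FORMULA_MATERIALS[n] for n in ("pmp", "ldpe", "polystyrene")]
        fit = fit_two_param(synthetic_measurements(mats, truth))
        assert not fit.identifiable
        assert fit.n_elements == 2

    def test_parameter_independent_points_flagged(self):
        # water plus air pinned at -1000 HU constrain nothing
        data = [
            CTMeasurement(FORMULA_MATERIALS["water"], 0.0),
            CTMeasurement(get_material("Air"), -1000.0),
        ]
        fit = fit_two_param(data)
        assert not fit.identifiable

    def test_single_measurement_refused(self):
        with pytest.raises(ValueError):
            fit_two_param([CTMeasurement(FORMULA_MATERIALS["ldpe"], -100.0)])


class TestThreeParamFit:
    def test_exact_recovery_on_11_tissues(self, tissues, truth_params):
        data = synthetic_measurements([t.composition for t in tissues], truth_params)
        fit = fit_three_param(data)
        assert fit.params.k1 == pytest.approx(truth_params.k1, rel=1e-6)
        assert fit.params.k2 == pytest.approx(truth_params.k2, rel=1e-6)
        assert fit.params.alpha == pytest.approx(truth_params.alpha, rel=1e-6)
        assert fit.identifiable

    def test_alpha_near_one_when_air_nominal(self, tissues):
        truth = AttenuationParams(1.24e-3, 3.06e-5, 1.0)
        # hydroxyapatite exceeds the extended CT-number range at alpha = 1
        mats = [t.composition for t in tissues if t.name != "Hydroxyapatite"]
        fit = fit_three_param(synthetic_measurements(mats, truth))
        assert fit.params.alpha == pytest.approx(1.0, abs=1e-9)

    def test_water_excluded_automatically(self, audit_pair, truth_params):
        lung, bone = audit_pair
        data = synthetic_measurements([lung, bone], truth_params)
        data.append(CTMeasurement(FORMULA_MATERIALS["water"], 2.0))
        fit = fit_three_param(data)
        assert fit.n_materials == 2
        assert "water" not in fit.material_names

    def test_nesting_alpha_frozen_matches_two_param(self, tissues):
        truth = AttenuationParams(1.4e-3, 3.5e-5)
        mats = [t.composition for t in tissues if t.name != "Hydroxyapatite"]
        data = synthetic_measurements(mats, truth)
        two = fit_two_param(data)
        three = fit_three_param(data, fix_alpha=1.0)
        assert three.params.k1 == pytest.approx(two.params.k1, rel=1e-9)
        assert three.params.k2 == pytest.approx(two.params.k2, rel=1e-9)
        assert three.ssr == pytest.approx(two.ssr, abs=1e-20)

    def test_two_material_audit_fit(self, audit_pair, tissues, truth_params):
        """The under-determined lung+bone fit zeroes its residuals, is
        flagged unidentifiable, predicts the fitted materials exactly, and
        its tissue predictions stay bounded under perturbed initialization."""
        lung, bone = audit_pair
        data = synthetic_measurements([lung, bone], truth_params)
        fit = fit_three_param(data)
        assert fit.ssr < 1e-24
        assert not fit.identifiable
        for m in (lung, bone):
            assert theoretical_hu(m, fit.params) == pytest.approx(
                theoretical_hu(m, truth_params), abs=1e-6
            )
        rng = np.random.default_rng(0)
        preds = []
        for _ in range(10):
            x0 = (
                1.24e-3 * (1 + 0.1 * rng.uniform(-1, 1)),
                3.06e-5 * (1 + 0.1 * rng.uniform(-1, 1)),
                1.0 * (1 + 0.1 * rng.uniform(-1, 1)),
            )
            f = fit_three_param(data, x0=x0)
            assert f.ssr < 1e-24
            preds.append(
                [theoretical_hu(t.composition, f.params) for t in tissues]
            )
        preds = np.array(preds)
        spread = preds.max(axis=0) - preds.min(axis=0)
        # predictions are anchored by the initialization, not the data, in
        # the fit's null direction; dense tissues are the most sensitive
        assert spread.max() < 25.0
        fitted = np.array(
            [[theoretical_hu(m, fit.params) for m in (lung, bone)]]
        )
        assert np.allclose(
            fitted,
            [[theoretical_hu(m, truth_params) for m in (lung, bone)]],
            atol=1e-6,
        )

    def test_optimizer_beats_grid_search(self, audit_pair, truth_params):
        """On <= 3 materials the optimizer's SSR is no worse than a dense
        grid search over (k1, k2, alpha)."""
        lung, bone = audit_pair
        mats = [lung, bone, FORMULA_MATERIALS["teflon"]]
        data = synthetic_measurements(mats, truth_params)
        fit = fit_three_param(data)

        hu = np.array([d.hu for d in data])
        best = np.inf
        for k1, k2, alpha in itertools.product(
            np.linspace(0, 5e-3, 21),
            np.linspace(0, 2e-4, 21),
            np.linspace(0.9, 1.1, 21),
        ):
            model = np.array([mu_ratio(m, k1, k2) for m in mats])
            r = model - (hu / (1000 * alpha) + 1)
            best = min(best, float(r @ r))
        assert fit.ssr <= best + 1e-18

    def test_alpha_recovery_under_noise(self, tissues, truth_params):
        """Median |alpha error| stays below 0.005 with 5-HU Gaussian noise
        on the 11 tissues, across 200 seeded replicates."""
        mats = [t.composition for t in tissues]
        clean = np.array([theoretical_hu(m, truth_params) for m in mats])
        errors = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            noisy = np.clip(clean + rng.normal(0, 5.0, clean.shape), -1100, 4000)
            data = [CTMeasurement(m, h) for m, h in zip(mats, noisy)]
            fit = fit_three_param(data)
            errors.append(abs(fit.params.alpha - truth_params.alpha))
        assert float(np.median(errors)) <= 0.005


class TestValidation:
    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            AttenuationParams(1e-3, 1e-5, -0.5)

    def test_implausible_hu_rejected(self):
        with pytest.raises(ValueError):
            CTMeasurement(FORMULA_MATERIALS["water"], -2000.0)

    def test_convergence_error_carries_params(self):
        assert issubclass(ConvergenceError, RuntimeError)
        err = ConvergenceError("no", AttenuationParams(1e-3, 1e-5, 1.0))
        assert err.params.alpha == 1.0
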