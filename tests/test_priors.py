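import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from informedbf.priors import (
    ElicitationGrid,
    PriorSpec,
    UnderDeterminedFitWarning,
    expert_registry,
    fit_prior_to_grid,
    make_logpdf,
    normalization_integral,
    prior_mass_above,
    prior_pdf,
    registry_from_json,
    registry_to_json,
)
from informedbf.synthetic import gen_elicitation_grid


class TestRegistry:
    def test_contents(self, registry):
        betas = [lab for lab, s in registry.items() if s.family == "beta"]
        ts = [lab for lab, s in registry.items() if s.family == "t_truncated"]
        assert len(betas) == 6 and len(ts) == 6
        assert registry["default (rho)"].family == "uniform"
        cauchy = registry["default (delta)"]
        assert cauchy.family == "cauchy_truncated"
        assert cauchy.params["scale"] == pytest.approx(math.sqrt(2) / 2)
        assert registry["null (rho)"].is_point and registry["null (delta)"].is_point

    def test_elicited_parameters(self, registry):
        assert registry["Expert 4 (beta)"].params == {"alpha": 10.70, "beta": 22.98}
        assert registry["Expert 6 (beta)"].params == {"alpha": 8.65, "beta": 12.39}
        assert registry["Expert 6 (t)"].params == {"mu": 0.31, "sigma": 0.08, "nu": 9}

    def test_every_density_integrates_to_one(self, registry):
        for label, spec in registry.items():
            if spec.is_point:
                continue
            assert normalization_integral(spec) == pytest.approx(1.0, abs=1e-6), label

    def test_json_round_trip(self, registry, tmp_path):
        path = tmp_path / "registry.json"
        registry_to_json(registry, path)
        back = registry_from_json(path)
        assert set(back) == set(registry)
        for lab in registry:
            assert back[lab].family == registry[lab].family
            assert back[lab].params == pytest.approx(registry[lab].params)


class TestDensities:
    def test_uniform_density(self):
        spec = PriorSpec("uniform", {"lower": 0.0, "upper": 1.0})
        assert prior_pdf(spec, 0.5) == pytest.approx(1.0)
        assert prior_pdf(spec, 1.5) == 0.0

    def test_beta11_is_uniform(self):
        spec = PriorSpec("beta", {"alpha": 1.0, "beta": 1.0})
        for x in (0.1, 0.5, 0.9):
            assert prior_pdf(spec, x) == pytest.approx(1.0)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            PriorSpec("beta", {"alpha": -1.0, "beta": 2.0})
        with pytest.raises(ValueError):
            PriorSpec("t_truncated", {"mu": 0.3, "sigma": 0.0, "nu": 5})
        with pytest.raises(ValueError):
            PriorSpec("t_truncated", {"mu": 0.3, "sigma": 0.1, "nu": -2})

    def test_fast_logpdf_matches_generic(self, registry):
        from informedbf.priors import prior_logpdf

        x = np.linspace(0.01, 0.99, 17)
        for label, spec in registry.items():
            if spec.is_point:
                continue
            np.testing.assert_allclose(
                make_logpdf(spec)(x), prior_logpdf(spec, x), rtol=1e-12, err_msg=label
            )

    def test_beta_mode_matches_density_argmax(self, registry):
        grid = np.linspace(1e-4, 1 - 1e-4, 20001)
        for k in range(2, 7):  # expert 1 has alpha < 1 (mode at 0)
            spec = registry[f"Expert {k} (beta)"]
            a, b = spec.params["alpha"], spec.params["beta"]
            analytic = (a - 1) / (a + b - 2)
            empirical = grid[np.argmax(prior_pdf(spec, grid))]
            assert empirical == pytest.approx(analytic, abs=1e-3)
            assert spec.mode() == pytest.approx(analytic)

    def test_truncated_t_mode_is_mu(self, registry):
        grid = np.linspace(1e-4, 2.0, 20001)
        for k in range(1, 7):
            spec = registry[f"Expert {k} (t)"]
            empirical = grid[np.argmax(prior_pdf(spec, grid))]
            assert empirical == pytest.approx(spec.params["mu"], abs=1e-3)


class TestMassAbove:
    def test_uniform_and_point(self):
        assert prior_mass_above(PriorSpec("uniform", {"lower": 0, "upper": 1}), 0.5) == pytest.approx(0.5)
        assert prior_mass_above(PriorSpec("point", {"value": 0.0}), 0.5) == 0.0

    def test_support_bounds(self, registry):
        for label, spec in registry.items():
            if spec.is_point:
                continue
            lo, hi = spec.support
            assert prior_mass_above(spec, lo) == pytest.approx(1.0, abs=1e-9), label
            upper = hi if math.isfinite(hi) else 1e9
            assert prior_mass_above(spec, upper) == pytest.approx(0.0, abs=1e-9), label

    def test_optimistic_experts_exceed_70pct_above_half(self, registry):
        # Experts 2-4 all place >70% prior mass on delta > 0.5
        for k in (2, 3, 4):
            assert prior_mass_above(registry[f"Expert {k} (t)"], 0.5) > 0.70

    @given(cutoff=st.floats(0.0, 1.0))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_mass_above_is_monotone(self, cutoff):
        spec = PriorSpec("t_truncated", {"mu": 0.4, "sigma": 0.15, "nu": 7})
        m1 = prior_mass_above(spec, cutoff)
        m2 = prior_mass_above(spec, cutoff + 0.1)
        assert 0.0 <= m2 <= m1 <= 1.0


class TestElicitationGrid:
    def test_shape_validation(self):
        with pytest.raises(ValueError):
            ElicitationGrid(bin_edges=tuple(np.linspace(0, 1, 10)), chips=(1,) * 9)
        with pytest.raises(ValueError):
            ElicitationGrid(chips=(-1,) + (1,) * 9)

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        path = tmp_path / "grid.csv"
        chips = (0, 1, 4, 8, 5, 2, 0, 0, 0, 0)
        pd.DataFrame({"bin_lower": np.linspace(0, 0.9, 10), "chips": chips}).to_csv(
            path, index=False
        )
        grid = ElicitationGrid.from_csv(path)
        assert grid.chips == tuple(float(c) for c in chips)
        assert grid.bin_edges[-1] == pytest.approx(1.0)

    def test_missing_column_raises(self, tmp_path):
        import pandas as pd

        path = tmp_path / "bad.csv"
        pd.DataFrame({"bin_lower": [0.0], "count": [3]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="chips"):
            ElicitationGrid.from_csv(path)


class TestFitPriorToGrid:
    def test_beta_parameter_recovery(self):
        grid = gen_elicitation_grid(PriorSpec("beta", {"alpha": 5, "beta": 15}), 25)
        fit = fit_prior_to_grid(grid, "beta")
        assert fit.params["alpha"] == pytest.approx(5, rel=0.15)
        assert fit.params["beta"] == pytest.approx(15, rel=0.15)

    def test_truncated_t_parameter_recovery(self):
        true = PriorSpec("t_truncated", {"mu": 0.4, "sigma": 0.1, "nu": 5})
        fit = fit_prior_to_grid(gen_elicitation_grid(true, 25), "t_truncated")
        assert fit.params["mu"] == pytest.approx(0.4, rel=0.15)
        assert fit.params["sigma"] == pytest.approx(0.1, rel=0.15)

    def test_single_bin_normal_mode_inside_bin(self):
        chips = tuple(10.0 if i == 2 else 0.0 for i in range(10))
        grid = ElicitationGrid(chips=chips)
        with pytest.warns(UnderDeterminedFitWarning):
            fit = fit_prior_to_grid(grid, "normal_truncated")
        assert 0.2 <= fit.params["mu"] < 0.3

    def test_symmetric_chips_give_centered_normal(self):
        chips = (0, 0, 1, 3, 6, 6, 3, 1, 0, 0)
        fit = fit_prior_to_grid(ElicitationGrid(chips=chips), "normal_truncated")
        assert fit.params["mu"] == pytest.approx(0.5, abs=0.02)

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError, match="chips"):
            fit_prior_to_grid(ElicitationGrid(chips=(0.0,) * 10), "beta")

    def test_determinism(self):
        grid = gen_elicitation_grid(PriorSpec("beta", {"alpha": 3, "beta": 9}), 25)
        f1 = fit_prior_to_grid(grid, "beta")
        f2 = fit_prior_to_grid(grid, "beta")
        assert f1.params == f2.params
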