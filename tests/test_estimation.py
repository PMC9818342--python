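"""Estimation tests: noise-free parameter recovery, degenerate cases, uncertainty."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from combopd.estimation import (
    DegenerateDataError,
    FitSpec,
    _fit_engine,
    compute_rse,
    default_hill_spec,
    default_pd_spec,
    fit_growth,
    fit_hill,
    fit_interaction_static,
    fit_pd_combo,
    fit_pd_single,
)
from combopd.models import HillParams, InteractionStaticParams, PDAgentParams, hill_response
from combopd.models import competitive_interaction_response
from combopd.reference import HILL_PARAMS, PD_PARAMS

CIS_GRID = np.geomspace(0.05, 25.0, 6)
CIM_GRID = np.geomspace(50.0, 4000.0, 6)
TIMES = np.array([0.0, 24.0, 48.0, 72.0, 96.0])


def _hill_data(params: HillParams, grid: np.ndarray):
    conc = np.repeat(grid, 3)
    return conc, hill_response(params, conc)


class TestHillFit:
    @pytest.mark.parametrize(
        "params,grid,free",
        [
            (HILL_PARAMS[("Huh7", "CIS")], CIS_GRID, ("imax", "ic50")),
            (HILL_PARAMS[("MDA-MB-468", "CIS")], CIS_GRID, ("imax", "ic50")),
            (HILL_PARAMS[("Huh7", "CIM")], CIM_GRID, ("r0", "imax", "ic50", "gamma")),
            (HILL_PARAMS[("MDA-MB-468", "CIM")], CIM_GRID, ("r0", "imax", "ic50", "gamma")),
        ],
        ids=["cis-huh7", "cis-mda", "cim-huh7", "cim-mda"],
    )
    def test_noise_free_recovery(self, params, grid, free):
        conc, y = _hill_data(params, grid)
        spec = default_hill_spec(conc, y, free=free)
        result = fit_hill(conc, y, spec)
        assert result.converged
        assert result.estimates["ic50"] == pytest.approx(params.ic50, rel=1e-4)
        if "gamma" in free:
            assert result.estimates["gamma"] == pytest.approx(params.gamma, rel=1e-3)
        # noise-free residuals carry no parameter uncertainty
        assert all(r < 1e-6 for r in result.rse_pct.values())

    def test_identical_responses_degenerate(self):
        conc = np.repeat(CIS_GRID, 3)
        with pytest.raises(DegenerateDataError):
            fit_hill(conc, np.full_like(conc, 100.0))

    def test_no_effect_data_hits_imax_boundary(self):
        rng = np.random.default_rng(7)
        conc = np.repeat(CIS_GRID, 3)
        y = 100.0 + rng.normal(0, 0.01, conc.size)
        result = fit_hill(conc, y)
        assert result.estimates["imax"] < 1e-3
        assert any(f.startswith("at_bound:imax") for f in result.flags)

    def test_too_few_concentrations_rejected(self):
        conc = np.array([0.1, 1.0, 10.0])
        with pytest.raises(ValueError):
            fit_hill(conc, hill_response(HILL_PARAMS[("Huh7", "CIS")], conc))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(ic50=st.floats(0.2, 10.0), imax=st.floats(0.5, 1.0), gamma=st.floats(0.5, 3.0))
    def test_randomized_noise_free_recovery(self, ic50, imax, gamma):
        """Fitting the model's own forward output recovers the generating truth."""
        params = HillParams(r0=100.0, imax=imax, ic50=ic50, gamma=gamma)
        conc, y = _hill_data(params, CIS_GRID)
        spec = default_hill_spec(conc, y, free=("imax", "ic50", "gamma"))
        result = fit_hill(conc, y, spec)
        assert result.estimates["ic50"] == pytest.approx(ic50, rel=1e-3)
        assert result.estimates["imax"] == pytest.approx(imax, rel=1e-3)

    def test_fixing_true_gamma_does_not_worsen_ic50(self):
        params = HillParams(r0=100.0, imax=0.9, ic50=2.5, gamma=1.6)
        conc, y = _hill_data(params, CIS_GRID)
        all_free = fit_hill(conc, y, default_hill_spec(conc, y, free=("imax", "ic50", "gamma")))
        gamma_fixed = fit_hill(
            conc, y,
            default_hill_spec(conc, y, free=("imax", "ic50"), fixed_values={"gamma": 1.6}),
        )
        err_free = abs(all_free.estimates["ic50"] / 2.5 - 1)
        err_fixed = abs(gamma_fixed.estimates["ic50"] / 2.5 - 1)
        assert err_fixed <= err_free + 1e-6


class TestGrowthFit:
    def test_recovery(self):
        y = 100.0 * np.exp(0.018 * TIMES)
        result = fit_growth(TIMES, y)
        assert result.estimates["kg"] == pytest.approx(0.018, rel=1e-6)

    def test_free_baseline(self):
        y = 88.0 * np.exp(0.011 * TIMES)
        result = fit_growth(TIMES, y, r0=None)
        assert result.estimates["kg"] == pytest.approx(0.011, rel=1e-5)
        assert result.estimates["r0"] == pytest.approx(88.0, rel=1e-5)


class TestInteractionStaticFit:
    @pytest.mark.parametrize("psi_true", [0.5, 0.95, 1.0, 1.27, 2.0])
    def test_noise_free_psi_recovery(self, psi_true):
        a, b = HILL_PARAMS[("Huh7", "CIS")], HILL_PARAMS[("Huh7", "CIM")]
        params = InteractionStaticParams(a, b, psi=psi_true)
        ca, cb = np.meshgrid(CIS_GRID, CIM_GRID, indexing="ij")
        ca, cb = ca.ravel(), cb.ravel()
        y = competitive_interaction_response(params, ca, cb)
        result = fit_interaction_static(ca, cb, y, a, b)
        assert result.estimates["psi"] == pytest.approx(psi_true, rel=1e-4)

    def test_no_combination_rows_rejected(self):
        a, b = HILL_PARAMS[("Huh7", "CIS")], HILL_PARAMS[("Huh7", "CIM")]
        with pytest.raises(ValueError):
            fit_interaction_static(
                np.array([1.0, 0.0]), np.array([0.0, 100.0]), np.array([50.0, 60.0]), a, b
            )


def _single_agent_data(kg, r0, agent: PDAgentParams, grid):
    """Noise-free control + per-concentration trajectories, closed form."""
    conc = np.concatenate([[0.0], grid])
    cc = np.repeat(conc, TIMES.size)
    tt = np.tile(TIMES, conc.size)
    k = np.where(cc > 0, agent.smax * cc / (agent.sc50 + cc), 0.0)
    u = tt / agent.tau
    kill = k * (tt - 3 * agent.tau + agent.tau * np.exp(-u) * (3 + 2 * u + 0.5 * u * u))
    return cc, tt, r0 * np.exp(kg * tt - kill)


class TestPDSingleFit:
    @pytest.mark.parametrize("cell_line", ["Huh7", "MDA-MB-468"])
    def test_cis_recovery(self, cell_line):
        truth = PD_PARAMS[cell_line]
        cc, tt, y = _single_agent_data(truth.kg, truth.r0, truth.cis, CIS_GRID)
        spec = default_pd_spec(cc, free=("kg", "smax", "sc50", "tau"))
        result = fit_pd_single(cc, tt, y, spec)
        assert result.converged
        assert result.estimates["kg"] == pytest.approx(truth.kg, rel=1e-3)
        assert result.estimates["smax"] == pytest.approx(truth.cis.smax, rel=1e-3)
        assert result.estimates["sc50"] == pytest.approx(truth.cis.sc50, rel=1e-3)
        assert 1 / result.estimates["tau"] == pytest.approx(1 / truth.cis.tau, rel=1e-3)

    def test_cim_sc50_beyond_tested_range(self):
        """SC50 far above the top tested concentration is still identified."""
        truth = PD_PARAMS["MDA-MB-468"]
        cc, tt, y = _single_agent_data(truth.kg, truth.r0, truth.cim, CIM_GRID)
        spec = default_pd_spec(cc, free=("smax", "sc50", "tau"),
                               fixed_values={"kg": truth.kg})
        result = fit_pd_single(cc, tt, y, spec)
        assert result.estimates["sc50"] == pytest.approx(21453.95, rel=1e-3)

    def test_no_drug_effect_smax_at_boundary(self):
        kg = 0.015
        cc = np.repeat(np.concatenate([[0.0], CIS_GRID]), TIMES.size)
        tt = np.tile(TIMES, 7)
        y = 100.0 * np.exp(kg * tt)  # pure growth in every arm
        spec = default_pd_spec(cc, free=("kg", "smax", "sc50", "tau"))
        result = fit_pd_single(cc, tt, y, spec)
        assert result.estimates["kg"] == pytest.approx(kg, rel=1e-3)
        assert result.estimates["smax"] < 1e-4

    def test_kg_free_without_control_rejected(self):
        cc = np.repeat(CIS_GRID, TIMES.size)
        tt = np.tile(TIMES, CIS_GRID.size)
        with pytest.raises(ValueError):
            fit_pd_single(cc, tt, np.ones_like(cc), default_pd_spec(cc))


class TestPDComboFit:
    @pytest.mark.parametrize("psi_true", [0.96, 1.0, 2.2])
    def test_psi_recovery(self, psi_true):
        truth = PD_PARAMS["Huh7"]
        pairs = [(a, b) for a in np.geomspace(0.05, 1.0, 4) for b in CIM_GRID]
        cc = np.repeat([p[0] for p in pairs], TIMES.size)
        cm = np.repeat([p[1] for p in pairs], TIMES.size)
        tt = np.tile(TIMES, len(pairs))
        kc = truth.cis.smax * cc / (truth.cis.sc50 * psi_true + cc)
        km = truth.cim.smax * cm / (truth.cim.sc50 + cm)
        uc, um = tt / truth.cis.tau, tt / truth.cim.tau
        kill = kc * (tt - 3 * truth.cis.tau
                     + truth.cis.tau * np.exp(-uc) * (3 + 2 * uc + 0.5 * uc**2))
        kill += km * (tt - 3 * truth.cim.tau
                      + truth.cim.tau * np.exp(-um) * (3 + 2 * um + 0.5 * um**2))
        y = 100.0 * np.exp(truth.kg * tt - kill)
        result = fit_pd_combo(cc, cm, tt, y, kg=truth.kg, r0=100.0,
                              cis=truth.cis, cim=truth.cim)
        assert result.estimates["psi"] == pytest.approx(psi_true, rel=1e-3)


class TestUncertainty:
    def test_noise_free_rse_near_zero(self):
        conc, y = _hill_data(HILL_PARAMS[("Huh7", "CIS")], CIS_GRID)
        result = fit_hill(conc, y)
        assert all(r < 1e-6 for r in result.rse_pct.values())

    def test_linear_toy_matches_textbook_se(self):
        """y = a*x with Gaussian noise: SE(a) = s / sqrt(sum x^2)."""
        rng = np.random.default_rng(11)
        x = np.linspace(1.0, 10.0, 40)
        y = 3.0 * x + rng.normal(0, 0.5, x.size)
        spec = FitSpec(model="toy", free={"a": 1.0}, bounds={"a": (-100.0, 100.0)})
        result = _fit_engine(lambda p: p["a"] * x, y, spec)
        a_hat = np.sum(x * y) / np.sum(x * x)
        ssq = np.sum((y - a_hat * x) ** 2)
        se_expected = np.sqrt(ssq / (x.size - 1) / np.sum(x * x))
        assert result.estimates["a"] == pytest.approx(a_hat, rel=1e-8)
        assert result.se["a"] == pytest.approx(se_expected, rel=1e-4)

    def test_rse_shrinks_with_replication(self):
        """Quadrupling the replicates roughly halves the standard error."""
        a, b = HILL_PARAMS[("Huh7", "CIS")], HILL_PARAMS[("Huh7", "CIM")]
        params = InteractionStaticParams(a, b, psi=1.0)
        ca0, cb0 = np.meshgrid(CIS_GRID, CIM_GRID, indexing="ij")
        rng = np.random.default_rng(5)
        ses = []
        for reps in (2, 8):
            ca = np.repeat(ca0.ravel(), reps)
            cb = np.repeat(cb0.ravel(), reps)
            pred = competitive_interaction_response(params, ca, cb)
            y = pred * (1 + rng.normal(0, 0.1, pred.size))
            ses.append(fit_interaction_static(ca, cb, y, a, b).se["psi"])
        ratio = ses[0] / ses[1]
        assert 1.3 < ratio < 3.2  # target sqrt(4) = 2 with sampling slack

    def test_compute_rse_definition(self):
        conc, y = _hill_data(HILL_PARAMS[("Huh7", "CIS")], CIS_GRID)
        rng = np.random.default_rng(3)
        result = fit_hill(conc, y * (1 + rng.normal(0, 0.05, y.size)))
        result = compute_rse(result)
        for name in result.free_names:
            expected = 100.0 * result.se[name] / abs(result.estimates[name])
            assert result.rse_pct[name] == pytest.approx(expected)
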