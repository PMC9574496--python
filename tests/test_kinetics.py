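"""Reaction network: rate-law orders, stoichiometry, conservation, integration."""

import numpy as np
import pytest

from acidnit.kinetics import (
    ChemKineticsParams,
    GasTransferParams,
    SolutionState,
    integrate_batch,
    reaction_rates,
    species_derivatives,
    strip_gas,
)

N_POOLS = ("TAN", "TNN", "NO3_N", "NO_aq", "NO2g_aq", "N2_cum")


def n_weighted_sum(derivs):
    return sum(derivs[name] for name in N_POOLS)


class TestReactionRates:
    def test_empty_system_has_zero_rates(self):
        r = reaction_rates(SolutionState(TNN=0, NO_aq=0, NO2g_aq=0), ChemKineticsParams())
        assert r.r2 == r.r3 == r.r4 == r.r56 == 0.0

    def test_no_oxidation_requires_oxygen(self):
        state = SolutionState(NO_aq=10.0, DO=0.0, TNN=0.0)
        assert reaction_rates(state, ChemKineticsParams()).r3 == 0.0

    def test_hno2_disproportionation_is_second_order(self, mild_params):
        p = mild_params.with_constants(k2_rev=0.0)
        r1 = reaction_rates(SolutionState(TNN=500, pH=5.0), p).r2
        r2 = reaction_rates(SolutionState(TNN=1000, pH=5.0), p).r2
        assert r2 == pytest.approx(4.0 * r1, rel=1e-9)

    def test_no2_hydrolysis_is_second_order(self, mild_params):
        p = mild_params.with_constants(k4_rev=0.0)
        r1 = reaction_rates(SolutionState(NO2g_aq=1.0), p).r4
        r2 = reaction_rates(SolutionState(NO2g_aq=2.0), p).r4
        assert r2 == pytest.approx(4.0 * r1, rel=1e-9)

    def test_no_oxidation_orders(self, mild_params):
        base = SolutionState(NO_aq=1.0, DO=4.0)
        r0 = reaction_rates(base, mild_params).r3
        assert reaction_rates(SolutionState(NO_aq=2.0, DO=4.0), mild_params).r3 == pytest.approx(
            4 * r0, rel=1e-9
        )
        assert reaction_rates(SolutionState(NO_aq=1.0, DO=8.0), mild_params).r3 == pytest.approx(
            2 * r0, rel=1e-9
        )

    def test_detailed_balance_fixed_point(self):
        # choose NO/NO2 so (R2) sits at its equilibrium ratio, disable the
        # pathways that would drain the intermediates
        p = ChemKineticsParams(
            k2_fwd=1e4, k2_rev=1e6, k3=0.0, k4_fwd=0.0, k4_rev=0.0, k_n2o3=0.0
        )
        state = SolutionState(TNN=1000.0, pH=5.0)
        from acidnit.kinetics import MG_N_PER_MOL
        from acidnit.speciation import IonicContext, free_nitrous_acid

        hno2 = free_nitrous_acid(1000.0, 5.0, IonicContext(ionic_strength=0.0)) / MG_N_PER_MOL
        x = np.sqrt(p.k2_fwd / p.k2_rev) * hno2  # [NO] = [NO2] at equilibrium
        state.NO_aq = x * MG_N_PER_MOL
        state.NO2g_aq = x * MG_N_PER_MOL
        r = reaction_rates(state, p)
        assert r.r2 == pytest.approx(0.0, abs=1e-10)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            reaction_rates(SolutionState(TNN=-1.0), ChemKineticsParams())


class TestStoichiometry:
    def test_zero_state_zero_derivatives(self):
        d = species_derivatives(SolutionState(), ChemKineticsParams())
        assert all(d[name] == 0.0 for name in N_POOLS)

    def test_nitrogen_conservation_without_stripping(self, mild_params):
        state = SolutionState(TAN=900, TNN=700, NO3_N=100, NO_aq=5, NO2g_aq=3, pH=4.5)
        d = species_derivatives(state, mild_params, gas=None)
        assert n_weighted_sum(d) == pytest.approx(0.0, abs=1e-10 * state.total_N)

    def test_conservation_including_gas_fluxes(self, mild_params):
        gas = GasTransferParams(kLa_NO=50.0, kLa_NO2=30.0)
        state = SolutionState(TAN=900, TNN=700, NO_aq=5, NO2g_aq=3, pH=4.5)
        d = species_derivatives(state, mild_params, gas=gas, aerated=True)
        assert n_weighted_sum(d) + d["strip_NO"] + d["strip_NO2"] == pytest.approx(0.0, abs=1e-10)

    def test_no2_hydrolysis_splits_evenly(self, mild_params):
        # only (R4) active: nitrate and nitrite gain at the same rate
        p = mild_params.with_constants(k2_fwd=0.0, k2_rev=0.0, k3=0.0, k4_rev=0.0, k_n2o3=0.0)
        d = species_derivatives(SolutionState(NO2g_aq=10.0), p)
        assert d["NO3_N"] == pytest.approx(d["TNN"], rel=1e-12)
        assert d["NO2g_aq"] == pytest.approx(-2 * d["NO3_N"], rel=1e-12)


class TestStripGas:
    def test_zero_kla_zero_flux(self):
        flux = strip_gas(SolutionState(NO_aq=5.0), GasTransferParams(kLa_NO=0, kLa_NO2=0))
        assert flux == (0.0, 0.0)

    def test_flux_linear_in_concentration(self):
        gas = GasTransferParams(kLa_NO=80.0, kLa_NO2=40.0)
        f1 = strip_gas(SolutionState(NO_aq=2.0, NO2g_aq=1.0), gas)
        f2 = strip_gas(SolutionState(NO_aq=4.0, NO2g_aq=2.0), gas)
        assert f2[0] == pytest.approx(2 * f1[0]) and f2[1] == pytest.approx(2 * f1[1])

    def test_aeration_off_factor(self):
        gas = GasTransferParams(kLa_NO=80.0, kLa_NO2=40.0, aeration_off_factor=0.1)
        on = strip_gas(SolutionState(NO_aq=2.0), gas, aerated=True)
        off = strip_gas(SolutionState(NO_aq=2.0), gas, aerated=False)
        assert off[0] == pytest.approx(on[0] / 10.0)


class TestIntegrateBatch:
    def test_inert_system_constant(self):
        p = ChemKineticsParams(k2_fwd=0, k2_rev=0, k3=0, k4_fwd=0, k4_rev=0, k_n2o3=0)
        traj = integrate_batch(SolutionState(TAN=500, TNN=300, NO3_N=50), p, t_end=2.0)
        assert np.allclose(traj.species["TAN"], 500)
        assert np.allclose(traj.species["TNN"], 300)
        assert np.allclose(traj.species["NO3_N"], 50)

    def test_closed_system_conserves_nitrogen(self, mild_params):
        s0 = SolutionState(TAN=1000, TNN=800, NO3_N=50, pH=4.8)
        traj = integrate_batch(s0, mild_params, gas=None, t_end=5.0)
        tot = sum(traj.species[n] for n in N_POOLS)
        assert np.max(np.abs(tot - tot[0])) / tot[0] < 1e-6

    def test_closed_system_conserves_nitrogen_stiff_defaults(self):
        s0 = SolutionState(TAN=1000, TNN=800, NO3_N=50, pH=5.0)
        traj = integrate_batch(s0, ChemKineticsParams(), gas=None, t_end=0.5)
        tot = sum(traj.species[n] for n in N_POOLS)
        assert np.max(np.abs(tot - tot[0])) / tot[0] < 1e-6

    def test_trajectory_nonnegative(self, mild_params):
        traj = integrate_batch(
            SolutionState(TNN=1000, pH=4.0),
            mild_params,
            gas=GasTransferParams(kLa_NO=50, kLa_NO2=50),
            t_end=2.0,
        )
        for name in N_POOLS:
            assert np.all(traj.species[name] >= 0.0)

    def test_matches_explicit_euler_oracle(self, mild_params):
        # brute-force fixed-step Euler at dt = 1e-5 d over a 0.01 d horizon
        from dataclasses import replace

        s0 = SolutionState(TAN=800, TNN=600, NO3_N=20, NO_aq=1.0, NO2g_aq=0.5, pH=4.5)
        dt, horizon = 1e-5, 0.01
        y = {n: getattr(s0, n) for n in N_POOLS}
        state = replace(s0)
        for _ in range(int(round(horizon / dt))):
            for n in N_POOLS:
                setattr(state, n, y[n])
            d = species_derivatives(state, mild_params, gas=None)
            for n in N_POOLS:
                y[n] += dt * d[n]
        traj = integrate_batch(
            s0, mild_params, gas=None, t_end=horizon, t_eval=np.array([0.0, horizon])
        )
        for n in ("TAN", "TNN", "NO3_N"):
            assert traj.species[n][-1] == pytest.approx(y[n], rel=1e-3)

    def test_failure_reports_diagnostics(self):
        with pytest.raises(ValueError):
            integrate_batch(SolutionState(), ChemKineticsParams(), t_end=-1.0)


class TestMonotonicity:
    """Chemical nitrate production increases with HNO2 and with DO."""

    def _no3_production(self, tnn, do, params):
        s0 = SolutionState(TNN=tnn, DO=do, pH=5.0)
        traj = integrate_batch(s0, params, gas=None, t_end=0.2, t_eval=np.array([0.0, 0.2]))
        return traj.species["NO3_N"][-1]

    def test_monotone_in_hno2(self, mild_params):
        prods = [self._no3_production(tnn, 5.0, mild_params) for tnn in (200, 500, 1000, 2000)]
        assert all(b >= a for a, b in zip(prods, prods[1:]))

    def test_monotone_in_do(self, mild_params):
        prods = [self._no3_production(800.0, do, mild_params) for do in (0.5, 2.0, 5.0, 8.0)]
        assert all(b >= a for a, b in zip(prods, prods[1:]))
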