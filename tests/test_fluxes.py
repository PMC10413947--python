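"""Succinate-pathway regulation and the assembled flux catalog."""

import math

import numpy as np
import pytest

from mitoresp import ThermoContext, default_catalog, evaluate_all_fluxes
from mitoresp.fluxes import (
    FLUX_NAMES,
    RegulationParams,
    civ_flux,
    dccm_flux,
    dccs_flux,
    hleak_flux,
    sdh_flux,
)
from mitoresp.ratelaws import TransporterSpec, antiporter_flux
from mitoresp.states import IDX, N_STATES
from mitoresp.thermo import apparent_keq
from tests.conftest import random_positive_state

REG = RegulationParams(K_MAL_dccs=2.0, K_SUC_dccm=1.0, K_OXA_sdh=0.01, K_MAL_sdh=3.0)


class TestDccs:
    def test_regulation_off_matches_plain_antiporter(self):
        spec = TransporterSpec("d", "antiporter", "SUC", "Pi", K_Ae=1.0, K_Am=1.0,
                               K_Be=1.5, K_Bm=1.5)
        args = (4.0, 0.5, 3.0, 6.0)  # SUCe, SUCm, Pie, Pim
        plain = antiporter_flux(spec, args[0], args[3], args[1], args[2], 7.0)
        regulated = dccs_flux(args[0], args[1], args[2], args[3], 0.0, REG, 7.0)
        assert regulated == pytest.approx(plain, rel=1e-12)

    def test_malate_at_its_constant_doubles_k(self):
        # the apparent succinate constant doubles, so a run with K doubled
        # explicitly must agree exactly
        flux = dccs_flux(4.0, 0.5, 3.0, 6.0, REG.K_MAL_dccs, REG, 7.0, K_SUC=1.0)
        explicit = dccs_flux(4.0, 0.5, 3.0, 6.0, 0.0, REG, 7.0, K_SUC=2.0)
        assert flux == pytest.approx(explicit, rel=1e-12)

    def test_strictly_decreasing_in_malate(self):
        fluxes = [
            dccs_flux(8.0, 0.2, 1.0, 8.0, m, REG, 5.0)
            for m in np.linspace(0, 20, 15)
        ]
        assert fluxes[0] > 0
        assert all(b < a for a, b in zip(fluxes, fluxes[1:]))

    def test_infinite_regulation_constant_recovers_unregulated(self):
        weak = RegulationParams(1e12, 1e12, 1e12, 1e12)
        a = dccs_flux(4.0, 0.5, 3.0, 6.0, 5.0, weak, 7.0)
        b = dccs_flux(4.0, 0.5, 3.0, 6.0, 0.0, weak, 7.0)
        assert a == pytest.approx(b, rel=1e-9)


class TestDccm:
    def test_regulation_off(self):
        spec = TransporterSpec("d", "antiporter", "MAL", "Pi", K_Ae=0.7, K_Am=0.7,
                               K_Be=1.5, K_Bm=1.5)
        plain = antiporter_flux(spec, 2.5, 6.0, 1.0, 3.0, 4.0)
        assert dccm_flux(2.5, 1.0, 3.0, 6.0, 0.0, REG, 4.0) == pytest.approx(
            plain, rel=1e-12
        )

    def test_succinate_at_its_constant_doubles_k(self):
        flux = dccm_flux(2.5, 1.0, 3.0, 6.0, REG.K_SUC_dccm, REG, 4.0, K_MAL=0.7)
        explicit = dccm_flux(2.5, 1.0, 3.0, 6.0, 0.0, REG, 4.0, K_MAL=1.4)
        assert flux == pytest.approx(explicit, rel=1e-12)

    def test_succinate_shrinks_malate_efflux(self):
        # reverse mode (matrix malate, no external malate): raising matrix
        # succinate stalls the outflux toward zero
        effluxes = [
            dccm_flux(0.0, 5.0, 4.0, 1.0, s, REG, 4.0)
            for s in np.linspace(0, 30, 12)
        ]
        assert effluxes[0] < 0
        assert all(b > a for a, b in zip(effluxes, effluxes[1:]))
        assert abs(effluxes[-1]) < 0.25 * abs(effluxes[0])


class TestSdh:
    KEQ = 20.0

    def test_unregulated_when_modifiers_absent(self):
        f0 = sdh_flux(2.0, 0.1, 1.0, 0.5, 0.0, 0.0, REG, self.KEQ, vmax=10.0)
        assert f0 > 0

    def test_oxa_at_constant_doubles_k(self):
        inhibited = sdh_flux(2.0, 0.1, 1.0, 0.5, REG.K_OXA_sdh, 0.0, REG, self.KEQ,
                             vmax=10.0, K_SUC=0.5)
        explicit = sdh_flux(2.0, 0.1, 1.0, 0.5, 0.0, 0.0, REG, self.KEQ,
                            vmax=10.0, K_SUC=1.0)
        assert inhibited == pytest.approx(explicit, rel=1e-12)

    def test_malate_at_constant_halves_k(self):
        stimulated = sdh_flux(2.0, 0.1, 1.0, 0.5, 0.0, REG.K_MAL_sdh, REG, self.KEQ,
                              vmax=10.0, K_SUC=0.5)
        explicit = sdh_flux(2.0, 0.1, 1.0, 0.5, 0.0, 0.0, REG, self.KEQ,
                            vmax=10.0, K_SUC=0.25)
        assert stimulated == pytest.approx(explicit, rel=1e-12)

    def test_monotone_decreasing_in_oxa(self):
        fluxes = [
            sdh_flux(2.0, 0.1, 1.0, 0.5, oxa, 0.0, REG, self.KEQ, vmax=10.0)
            for oxa in np.linspace(0, 0.2, 10)
        ]
        assert all(b < a for a, b in zip(fluxes, fluxes[1:]))

    def test_monotone_increasing_in_malate(self):
        fluxes = [
            sdh_flux(2.0, 0.1, 1.0, 0.5, 0.0, mal, REG, self.KEQ, vmax=10.0)
            for mal in np.linspace(0, 10, 10)
        ]
        assert all(b > a for a, b in zip(fluxes, fluxes[1:]))

    def test_zero_at_equilibrium_regardless_of_regulation(self):
        # SUC*UQ = FUM*UQH2/keq
        suc, uq = 1.0, 1.0
        fum, uqh2 = 4.0, self.KEQ / 4.0
        for oxa, mal in ((0, 0), (0.05, 0), (0, 5.0), (0.02, 2.0)):
            assert sdh_flux(suc, fum, uq, uqh2, oxa, mal, REG, self.KEQ) == pytest.approx(
                0.0, abs=1e-14
            )

    def test_eq19_brute_force(self, rng):
        # two-bracket shared-site denominator, re-derived independently
        for _ in range(500):
            suc, fum, uq, uqh2, oxa, mal = rng.uniform(0, 5, 6)
            vmax = rng.uniform(0.1, 100)
            ks, kf, ku, kh = rng.uniform(0.05, 5, 4)
            keq = 10 ** rng.uniform(-2, 3)
            kpp = ks * (1 + oxa / REG.K_OXA_sdh) / (1 + mal / REG.K_MAL_sdh)
            want = (vmax / (kpp * ku)) * (suc * uq - fum * uqh2 / keq) / (
                (1 + suc / kpp + fum / kf) * (1 + uq / ku + uqh2 / kh)
            )
            got = sdh_flux(suc, fum, uq, uqh2, oxa, mal, REG, keq, vmax,
                           K_SUC=ks, K_FUM=kf, K_UQ=ku, K_UQH2=kh)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-12)


class TestLeakAndOxidase:
    def test_leak_zero_at_zero_pmf(self, ctx):
        # pmf = 0 when the electric term cancels the pH term
        psi0 = -ctx.RT * math.log(10) * ctx.delta_pH / 96485.0 * 1e3
        assert hleak_flux(psi0, 5.0, 3.7, ctx, x_ref=6.455) == pytest.approx(0.0, abs=1e-12)

    def test_leak_increasing_in_potential(self, ctx):
        vals = [hleak_flux(p, 1.0, 3.7, ctx, 6.455) for p in np.linspace(50, 220, 10)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_civ_zero_at_four_electron_equilibrium(self, ctx):
        keq_chem = apparent_keq(-216.6, -4, ctx.pH_matrix, ctx)
        dpsi, o2, o2ref = 150.0, 0.2, 0.05
        u = 96485.0 * dpsi * 1e-3 + ctx.RT * math.log(10) * ctx.delta_pH
        kapp = keq_chem * math.exp(-8 * u / ctx.RT)
        # choose cytc poise exactly at (ox/red)^4 = kapp * (O2/o2ref)
        ratio = (kapp * (o2 / o2ref)) ** 0.25
        red = 1.0 / (1 + ratio)
        flux = civ_flux(red, 1 - red, o2, dpsi, 100.0, 0.025, 1e-4, keq_chem, ctx, o2ref)
        assert flux == pytest.approx(0.0, abs=1e-10)

    def test_civ_oxygen_saturation(self, ctx):
        keq_chem = apparent_keq(-216.6, -4, ctx.pH_matrix, ctx)
        f_lo = civ_flux(0.2, 0.8, 1e-5, 120.0, 100.0, 0.025, 1.2e-4, keq_chem, ctx, 0.05)
        f_hi = civ_flux(0.2, 0.8, 0.2, 120.0, 100.0, 0.025, 1.2e-4, keq_chem, ctx, 0.05)
        assert 0 < f_lo < 0.2 * f_hi


class TestCatalog:
    def test_flux_names_match_parameter_keys(self, heart):
        assert set(FLUX_NAMES) == set(heart.vmax) | set(heart.tmax)

    def test_heart_ant_tmax(self, heart):
        # the translocase row of the published parameter table
        assert heart.tmax["ANT"] == pytest.approx(0.028e5)

    def test_rotenone_only_silences_complex_I(self, heart, rng):
        y = random_positive_state(rng)
        base = evaluate_all_fluxes(y, heart, rotenone=False)
        rot = evaluate_all_fluxes(y, heart, rotenone=True)
        assert rot["CI"] == 0.0
        for name in FLUX_NAMES:
            if name != "CI":
                assert rot[name] == base[name]

    def test_all_zero_metabolites(self, heart, ctx):
        y = np.zeros(N_STATES)
        y[IDX["dpsi"]] = 150.0
        fluxes = evaluate_all_fluxes(y, heart, ctx)
        for name, J in fluxes.items():
            if name == "HLEAK":
                assert J > 0  # driven by the membrane potential alone
            else:
                assert J == pytest.approx(0.0, abs=1e-9)

    def test_evaluator_composes_individual_operations(self, heart, ctx, catalog, rng):
        # the vector evaluation equals element-wise evaluation of the public
        # scalar operations for the regulated steps
        y = random_positive_state(rng)
        fluxes = evaluate_all_fluxes(y, heart, ctx, catalog)
        g = lambda n: float(y[IDX[n]])  # noqa: E731
        tr = catalog.transporters
        want_dccs = dccs_flux(
            g("SUC_e"), g("SUC_m"), g("Pi_e"), g("Pi_m"), g("MAL_m"),
            heart.regulation, heart.tmax["DCCS"],
            K_SUC=tr["DCCS"]["K_Ae"], K_Pi=tr["DCCS"]["K_Be"],
        )
        assert fluxes["DCCS"] == pytest.approx(want_dccs, rel=1e-12)
        want_dccm = dccm_flux(
            g("MAL_e"), g("MAL_m"), g("Pi_e"), g("Pi_m"), g("SUC_m"),
            heart.regulation, heart.tmax["DCCM"],
            K_MAL=tr["DCCM"]["K_Ae"], K_Pi=tr["DCCM"]["K_Be"],
        )
        assert fluxes["DCCM"] == pytest.approx(want_dccm, rel=1e-12)

    def test_fluxes_finite_for_random_states(self, heart, rng):
        for _ in range(50):
            y = random_positive_state(rng)
            vals = evaluate_all_fluxes(y, heart)
            assert all(np.isfinite(v) for v in vals.values())


class TestComparativeStatics:
    """One-at-a-time links of the succinate regulation chain on a fixed state."""

    def _state(self, rng):
        y = random_positive_state(rng)
        y[IDX["SUC_m"]] = 5.0
        y[IDX["MAL_m"]] = 1.0
        y[IDX["OXA_m"]] = 0.0
        return y

    def test_raising_oxa_lowers_sdh(self, heart, rng):
        y = self._state(rng)
        low = evaluate_all_fluxes(y, heart)["CII"]
        y[IDX["OXA_m"]] = 0.02
        high = evaluate_all_fluxes(y, heart)["CII"]
        assert high < low

    def test_raising_matrix_suc_stalls_malate_efflux(self, heart, rng):
        y = self._state(rng)
        y[IDX["MAL_e"]] = 0.0
        y[IDX["MAL_m"]] = 5.0
        base = evaluate_all_fluxes(y, heart)["DCCM"]
        y[IDX["SUC_m"]] = 50.0
        stalled = evaluate_all_fluxes(y, heart)["DCCM"]
        assert base < 0  # malate leaving the matrix
        assert abs(stalled) < abs(base)

    def test_slower_sdh_raises_matrix_succinate_in_toy_pool(self, heart, ctx):
        # closed two-pool toy: succinate enters at a fixed rate and leaves by
        # the regulated dehydrogenase; a lower SDH capacity raises the
        # steady-state matrix succinate level
        from scipy.optimize import brentq

        def steady_suc(vmax_sdh, influx=50.0):
            def balance(suc):
                return (
                    sdh_flux(suc, 0.1, 1.0, 0.5, 0.0, 0.0, heart.regulation,
                             20.0, vmax=vmax_sdh) - influx
                )
            return brentq(balance, 1e-6, 1e4)

        assert steady_suc(500.0) > steady_suc(5000.0)
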