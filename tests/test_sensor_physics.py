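"""Unit and property tests for the single-sensor physics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pegsim.errors import ParameterError
from pegsim.sensor_physics import (
    DEFAULT_PARAMS,
    ION_REGISTRY,
    IonSpecies,
    PhysicsParams,
    SensorState,
    absorb_co2,
    absorb_nh3,
    conductance,
    desorb_dissolved_gas,
    gas_molar_rate,
    impedance,
    make_sensor,
    net_charge,
    total_nitrogen,
    update_water_film,
    water_film_equilibrium,
)

CHARGE_TOL = 1e-18  # mol of elementary charge


class TestIonRegistry:
    def test_printed_mobility_contrast(self):
        """NH4+ is the slow cation that replaces fast H3O+ on acid
        neutralization; both carry unit charge."""
        assert ION_REGISTRY["H3O+"].mobility == pytest.approx(36.23e-4)
        assert ION_REGISTRY["NH4+"].mobility == pytest.approx(7.63e-4)
        assert ION_REGISTRY["H3O+"].charge == ION_REGISTRY["NH4+"].charge == 1

    def test_registry_contains_all_reaction_species(self):
        for name in ("SO4-2", "OH-", "Na+", "HCO3-", "CO3-2"):
            assert name in ION_REGISTRY

    @pytest.mark.parametrize("charge,mobility", [(0, 1e-4), (1, 0.0), (1, -1e-4)])
    def test_invalid_species_rejected(self, charge, mobility):
        with pytest.raises(ParameterError):
            IonSpecies("X", charge, mobility)


class TestMakeSensor:
    def test_acid_deposit_stoichiometry(self):
        """0.01 M x 10 uL H2SO4 -> 2e-7 mol H3O+ and 1e-7 mol SO4(2-)."""
        s = make_sensor("A", 0.01, 10e-6)
        assert s.ion_moles["H3O+"] == pytest.approx(2e-7)
        assert s.ion_moles["SO4-2"] == pytest.approx(1e-7)
        assert abs(net_charge(s)) < CHARGE_TOL

    def test_base_deposit_stoichiometry(self):
        s = make_sensor("B", 0.1, 10e-6)
        assert s.ion_moles["Na+"] == pytest.approx(1e-6)
        assert s.ion_moles["OH-"] == pytest.approx(1e-6)
        assert abs(net_charge(s)) < CHARGE_TOL

    def test_untreated_has_empty_inventory(self):
        s = make_sensor("U", 0.0)
        assert s.ion_moles == {}

    def test_film_equilibrated_at_ambient(self):
        s = make_sensor("A", 0.01)
        assert s.water_film == pytest.approx(water_film_equilibrium(DEFAULT_PARAMS.ambient_rh))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"functionalization": "X"},
            {"functionalization": "A", "molarity": -0.01},
            {"functionalization": "A", "molarity": 0.2},
            {"functionalization": "A", "molarity": 0.01, "volume": -1e-6},
            {"functionalization": "U", "molarity": 0.01},
        ],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ParameterError):
            make_sensor(**kwargs)


class TestConductance:
    def test_empty_inventory_gives_background_plus_film_term(self):
        """With zero intrinsic paper strength, an empty inventory reads
        exactly the background regardless of the film."""
        s = SensorState("U", 0.0, water_film=0.7, intrinsic_strength=0.0)
        assert conductance(s) == pytest.approx(s.background_conductance)

    def test_ionic_term_linear_in_moles(self):
        s = make_sensor("A", 0.01)
        s.intrinsic_strength = 0.0
        g1 = conductance(s) - s.background_conductance
        s2 = s.copy()
        s2.ion_moles = {k: 2 * v for k, v in s.ion_moles.items()}
        g2 = conductance(s2) - s2.background_conductance
        assert g2 == pytest.approx(2 * g1, rel=1e-12)

    def test_cation_swap_scales_by_mobility_ratio(self):
        """Replacing H3O+ by NH4+ mol-for-mol scales the cation term by
        7.63/36.23."""
        a = SensorState("A", 0.01, ion_moles={"H3O+": 2e-7, "SO4-2": 1e-7},
                        water_film=0.5, intrinsic_strength=0.0, background_conductance=0.0)
        b = SensorState("A", 0.01, ion_moles={"NH4+": 2e-7, "SO4-2": 1e-7},
                        water_film=0.5, intrinsic_strength=0.0, background_conductance=0.0)
        anion = SensorState("A", 0.01, ion_moles={"SO4-2": 1e-7},
                            water_film=0.5, intrinsic_strength=0.0, background_conductance=0.0)
        cation_a = conductance(a) - conductance(anion)
        cation_b = conductance(b) - conductance(anion)
        assert cation_b / cation_a == pytest.approx(7.63 / 36.23, rel=1e-9)

    def test_monotone_in_water_film(self):
        s = make_sensor("A", 0.01)
        gs = []
        for w in (0.1, 0.4, 0.9):
            s.water_film = w
            gs.append(conductance(s))
        assert gs[0] < gs[1] < gs[2]

    def test_impedance_within_operating_span(self):
        """Across 20-100% RH and all functionalizations the impedance
        stays in the kilo-ohm to giga-ohm operating window."""
        sensors = [
            make_sensor("U", 0.0),
            make_sensor("A", 0.001),
            make_sensor("A", 0.1),
            make_sensor("B", 0.1),
        ]
        for s in sensors:
            for rh in (20.0, 45.0, 65.0, 90.0, 100.0):
                s.water_film = water_film_equilibrium(rh)
                assert 1e3 <= impedance(s) <= 1e9


class TestWaterFilm:
    def test_equilibrium_shape(self):
        """W_eq is ~0 below 20% RH and near-saturating above 90%."""
        assert water_film_equilibrium(0.0) < water_film_equilibrium(20.0) < 0.05
        assert water_film_equilibrium(90.0) > 0.9
        assert water_film_equilibrium(100.0) <= 1.0

    def test_fixed_point_under_constant_rh(self):
        s = make_sensor("U", 0.0)
        for _ in range(2000):
            s = update_water_film(s, 80.0, 1.0)
        assert s.water_film == pytest.approx(water_film_equilibrium(80.0), rel=1e-6)

    def test_adsorption_desorption_asymmetry(self):
        """An up-step then equal down-step of W_eq over equal time leaves
        the film above where it started (desorption is slower)."""
        s = make_sensor("U", 0.0)
        w0 = s.water_film
        s = update_water_film(s, 90.0, 8.0)
        s = update_water_film(s, 20.0, 8.0)
        assert s.water_film > w0

    def test_cycling_reaches_steady_state_in_7_to_8_minutes(self):
        """Densely integrated 8 s / 4 s humid/dry cycling: the
        cycle-averaged film reaches 95% of its stationary mean within the
        7-8 minute window."""
        p = DEFAULT_PARAMS
        dt = 0.01
        w = water_film_equilibrium(45.0)
        n = int(15 * 60 / dt)
        wa = np.empty(n)
        for i in range(n):
            t = i * dt
            rh = 90.0 if (t % 12.0) < 8.0 else 50.0
            weq = water_film_equilibrium(rh)
            tau = p.tau_adsorb if weq > w else p.tau_desorb
            w = weq + (w - weq) * math.exp(-dt / tau)
            wa[i] = w
        per = int(12 / dt)
        cyc = wa[: (n // per) * per].reshape(-1, per).mean(axis=1)
        stationary = cyc[-10:].mean()
        t95_min = (np.argmax(cyc >= 0.95 * stationary) + 1) * 12 / 60
        assert 7.0 <= t95_min <= 8.0

    def test_rh_validation(self):
        with pytest.raises(ParameterError):
            update_water_film(make_sensor("U", 0.0), 120.0, 1.0)
        with pytest.raises(ParameterError):
            update_water_film(make_sensor("U", 0.0), 50.0, -1.0)


class TestAbsorbNH3:
    def test_exact_acid_depletion(self):
        """2e-7 mol NH3 exactly depletes a 0.01 M x 10 uL acid deposit."""
        s = absorb_nh3(make_sensor("A", 0.01), 2e-7)
        assert s.ion_moles["H3O+"] == pytest.approx(0.0, abs=1e-18)
        assert s.ion_moles["NH4+"] == pytest.approx(2e-7)
        assert s.ion_moles["SO4-2"] == pytest.approx(1e-7)
        assert abs(net_charge(s)) < CHARGE_TOL

    def test_zero_dose_is_noop(self):
        s0 = make_sensor("A", 0.01)
        s1 = absorb_nh3(s0, 0.0)
        assert s1.ion_moles == s0.ion_moles

    def test_untreated_conductance_strictly_increases(self):
        s = make_sensor("U", 0.0)
        g0 = conductance(s)
        s = absorb_nh3(s, 1e-8)
        assert conductance(s) > g0

    def test_acid_conductance_strictly_decreases_while_acid_remains(self):
        s = make_sensor("A", 0.01)
        g = conductance(s)
        for _ in range(5):
            s = absorb_nh3(s, 2e-8)
            assert conductance(s) < g
            g = conductance(s)

    def test_nitrogen_mass_conservation(self):
        s = make_sensor("A", 0.01)
        delivered = 0.0
        for dose in (1e-7, 1e-7, 5e-8, 2e-7):
            s = absorb_nh3(s, dose)
            delivered += dose
        assert total_nitrogen(s) == pytest.approx(delivered, rel=1e-12)

    def test_negative_dose_rejected(self):
        with pytest.raises(ParameterError):
            absorb_nh3(make_sensor("A", 0.01), -1e-9)


class TestAbsorbCO2:
    def test_base_neutralization_drops_conductance(self):
        s = make_sensor("B", 0.1)
        g = conductance(s)
        for _ in range(5):
            s = absorb_co2(s, 5e-8)
            assert conductance(s) < g
            g = conductance(s)

    def test_acidified_film_takes_up_less(self):
        """The same CO2 dose moves an acid-loaded sensor far less than a
        neutral one (low pH suppresses CO2 solubility)."""
        neutral = make_sensor("U", 0.0)
        acid = make_sensor("A", 0.01)
        dg_neutral = abs(conductance(absorb_co2(neutral, 1e-7)) - conductance(neutral))
        dg_acid = abs(conductance(absorb_co2(acid, 1e-7)) - conductance(acid))
        assert dg_acid < 0.05 * dg_neutral

    def test_solubility_scale_monotone_in_ph(self):
        p = DEFAULT_PARAMS
        scales = [p.co2_solubility_scale(ph) for ph in (1.0, 3.0, 5.0, 7.0, 9.0)]
        assert all(a < b for a, b in zip(scales, scales[1:]))
        assert all(0 < s < 1 for s in scales)

    def test_negative_dose_rejected(self):
        with pytest.raises(ParameterError):
            absorb_co2(make_sensor("B", 0.1), -1e-9)


class TestDesorb:
    def test_noop_without_dissolved_pool(self):
        s = make_sensor("B", 0.1)
        s2 = desorb_dissolved_gas(s, 1.0)
        assert s2.ion_moles == s.ion_moles
        assert s2.dissolved_co2 == 0.0

    def test_dissolved_pool_strictly_decays(self):
        s = absorb_co2(make_sensor("U", 0.0), 1e-7)
        pool = s.dissolved_co2
        assert pool > 0
        for _ in range(5):
            s = desorb_dissolved_gas(s, 10.0)
            assert s.dissolved_co2 < pool
            pool = s.dissolved_co2

    def test_untreated_returns_toward_baseline(self):
        """CO2 response of an untreated sensor is reversible: after
        release the conductance relaxes back toward its starting value."""
        s = make_sensor("U", 0.0)
        g0 = conductance(s)
        s = absorb_co2(s, 1e-7)
        g_exposed = conductance(s)
        for _ in range(100):
            s = desorb_dissolved_gas(s, 10.0)
        assert abs(conductance(s) - g0) < 0.05 * abs(g_exposed - g0)


class TestGasMolarRate:
    def test_closed_form(self):
        """5 ppm at 2,000 mL/min with unit efficiency and 24.45 L/mol is
        6.82e-9 mol/s."""
        p = PhysicsParams(capture_efficiency=1.0)
        assert gas_molar_rate(5.0, 2000.0, p) == pytest.approx(6.82e-9, rel=1e-3)

    def test_zero_concentration(self):
        assert gas_molar_rate(0.0, 2000.0) == 0.0

    def test_linear_in_concentration(self):
        r1 = gas_molar_rate(1.0, 2000.0)
        r3 = gas_molar_rate(3.0, 2000.0)
        assert r3 == pytest.approx(3 * r1, rel=1e-12)

    def test_validation(self):
        with pytest.raises(ParameterError):
            gas_molar_rate(-1.0, 2000.0)
        with pytest.raises(ParameterError):
            gas_molar_rate(1.0, 0.0)
        with pytest.raises(ParameterError):
            gas_molar_rate(1.0, 2000.0, gas="O3")


class TestParams:
    def test_tau_ordering_enforced(self):
        with pytest.raises(ParameterError):
            PhysicsParams(tau_adsorb=90.0, tau_desorb=30.0)

    def test_capture_efficiency_bounds(self):
        with pytest.raises(ParameterError):
            PhysicsParams(capture_efficiency=0.0)
        with pytest.raises(ParameterError):
            PhysicsParams(capture_efficiency=1.5)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    molarity=st.floats(0.001, 0.1),
    doses=st.lists(st.floats(0.0, 1e-7), min_size=1, max_size=8),
    co2=st.booleans(),
)
def test_electroneutrality_preserved_by_any_operation_sequence(molarity, doses, co2):
    """Charge balance holds to 1e-18 mol after arbitrary absorb/desorb
    sequences on acid- or base-treated sensors."""
    s = make_sensor("B" if co2 else "A", molarity)
    for d in doses:
        s = absorb_co2(s, d) if co2 else absorb_nh3(s, d)
        s = desorb_dissolved_gas(s, 1.0)
        assert abs(net_charge(s)) < CHARGE_TOL
        assert all(m >= 0 for m in s.ion_moles.values())
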