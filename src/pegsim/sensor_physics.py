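"""Mechanistic model of a single paper-based electrical gas sensor (PEGS).

A PEGS is a strip of chromatography paper with screen-printed carbon
electrodes.  Ambient moisture adsorbs onto the cellulose fibres and, above
roughly 40% relative humidity, behaves like a thin film of bulk water in
which dissolved ions migrate.  The sensor readout is the electrical
conductance of that film,

    G = G_bg + k * w * (S_paper + sum_i c_i * |z_i| * mu_i),

where ``w`` is the water-film filling fraction (0..1), ``c_i`` the molar
concentration of ion species *i* in the deposited liquid volume, ``z_i`` its
charge and ``mu_i`` its electrophoretic mobility, ``S_paper`` a small
humidity-coupled conductivity from ions native to the cellulose, ``k`` a
geometric cell factor and ``G_bg`` the dry-paper background.

Three functionalizations form the selective array:

* ``U`` (untreated): 10 uL of deionized water; responds to humidity only.
* ``A`` (acid): 10 uL of H2SO4 -> 2 H3O+ + SO4(2-) per molecule.  Alkaline
  gases (NH3) neutralize the acid, replacing fast H3O+ with slow NH4+,
  so conductance falls while acid remains.
* ``B`` (base): 10 uL of NaOH -> Na+ + OH-.  Acidic gases (CO2) replace
  fast OH- with slow HCO3-, so conductance falls while base remains.

The chemistry is advanced with stoichiometric (exactly integrated) updates,
so a coarse fixed-step simulation agrees with a dense one to well under 1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import ParameterError

__all__ = [
    "IonSpecies",
    "ION_REGISTRY",
    "PhysicsParams",
    "SensorState",
    "make_sensor",
    "conductance",
    "impedance",
    "water_film_equilibrium",
    "update_water_film",
    "absorb_nh3",
    "absorb_co2",
    "desorb_dissolved_gas",
    "gas_molar_rate",
    "net_charge",
    "total_nitrogen",
]


@dataclass(frozen=True)
class IonSpecies:
    """A dissolved ionic species.

    Parameters
    ----------
    name : str
        Display label, e.g. ``"H3O+"``.
    charge : int
        Signed charge in elementary units; must be nonzero.
    mobility : float
        Electrophoretic mobility in cm^2 V^-1 s^-1; must be positive.
    """

    name: str
    charge: int
    mobility: float

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ParameterError(f"ion {self.name!r}: charge must be nonzero")
        if not self.mobility > 0:
            raise ParameterError(f"ion {self.name!r}: mobility must be positive")


#: Mobilities in cm^2 V^-1 s^-1.  H3O+ and NH4+ are the pair whose contrast
#: makes acid neutralization readable as a conductance drop.  The remaining
#: values are standard infinite-dilution figures derived from limiting molar
#: conductivities (CRC Handbook of Chemistry and Physics, 95th ed., via
#: mu = lambda / (|z| F)).
ION_REGISTRY: dict[str, IonSpecies] = {
    s.name: s
    for s in (
        IonSpecies("H3O+", +1, 36.23e-4),
        IonSpecies("NH4+", +1, 7.63e-4),
        IonSpecies("Na+", +1, 5.19e-4),
        IonSpecies("OH-", -1, 20.5e-4),
        IonSpecies("HCO3-", -1, 4.61e-4),
        IonSpecies("SO4-2", -2, 8.29e-4),
        IonSpecies("CO3-2", -2, 7.18e-4),
    )
}


@dataclass(frozen=True)
class PhysicsParams:
    """Tunable constants of the sensor model.

    capture_efficiency
        Fraction of the NH3 molar flow past one sensor that it absorbs.
        Calibrated so that 5 ppm NH3 at 2,000 mL/min depletes a
        0.01 M x 10 uL acid deposit in about 10 minutes of continuous
        chamber exposure.
    co2_capture_efficiency
        Same for CO2; orders of magnitude smaller because CO2 is far less
        water-soluble and slower to hydrate than NH3 is to protonate.
    tau_adsorb, tau_desorb : s
        First-order time constants of water-film relaxation.  Desorption is
        thermodynamically less favorable than adsorption, so
        tau_desorb > tau_adsorb; the pair is calibrated so that under
        8 s / 4 s humid/dry cycling the cycle-averaged film reaches 95% of
        its stationary value in 7-8 minutes.
    weak_base_fraction
        Ionization fraction of NH3 dissolving after the acid is gone
        (NH3 is a weak base; most stays un-ionized).
    nh3_half_saturation : mol
        Acid amount at which the NH3 sticking probability drops to 1/2.
        An acid-loaded film holds NH3 at negligible vapor pressure; as the
        acid neutralizes, dissolved NH3 increasingly re-evaporates, so
        uptake tails off exponentially instead of stopping abruptly.
    molar_volume : L/mol
        Ideal-gas molar volume at 25 C, 1 atm.
    wfilm_midpoint_rh, wfilm_scale_rh : %RH
        Logistic parameters of the equilibrium film W_eq(RH): near zero
        below 20% RH, near saturation above 90% RH.
    cell_factor
        Geometry constant mapping film-weighted ionic strength to siemens.
    background_conductance : S
        Dry-paper conductance floor.
    intrinsic_strength
        Mobility-weighted ionic strength (same units as c*|z|*mu) of ions
        native to wetted cellulose; gives untreated sensors their humidity
        response.
    ambient_rh : %RH
        Room humidity used to initialize sensors.
    co2_ionization_fraction
        Maximum fraction of absorbed CO2 that ionizes to H3O+ + HCO3- in
        near-neutral water.
    co2_ph_midpoint
        Midpoint of the logistic pH scaling of CO2 ionization: acidifying
        the film suppresses CO2 solubility/ionization.
    tau_outgas : s
        First-order escape time of physically dissolved CO2 once the
        ambient level drops.
    tau_carbonate : s
        Slow conversion OH- + HCO3- -> CO3(2-) + H2O where both coexist;
        responsible for the delayed second conductance drop of strongly
        base-treated sensors after CO2 exposure ends.
    """

    capture_efficiency: float = 0.06
    co2_capture_efficiency: float = 1.5e-5
    tau_adsorb: float = 120.0
    tau_desorb: float = 360.0
    weak_base_fraction: float = 0.15
    nh3_half_saturation: float = 2.5e-8
    molar_volume: float = 24.45
    wfilm_midpoint_rh: float = 60.0
    wfilm_scale_rh: float = 10.0
    cell_factor: float = 0.8
    background_conductance: float = 1e-9
    intrinsic_strength: float = 1.5e-4
    ambient_rh: float = 45.0
    co2_ionization_fraction: float = 0.2
    co2_ph_midpoint: float = 5.0
    tau_outgas: float = 120.0
    tau_carbonate: float = 600.0

    def __post_init__(self) -> None:
        if not 0 < self.capture_efficiency <= 1:
            raise ParameterError("capture_efficiency must be in (0, 1]")
        if not 0 < self.co2_capture_efficiency <= 1:
            raise ParameterError("co2_capture_efficiency must be in (0, 1]")
        if not 0 < self.tau_adsorb < self.tau_desorb:
            raise ParameterError("require tau_desorb > tau_adsorb > 0")
        if not 0 <= self.weak_base_fraction <= 1:
            raise ParameterError("weak_base_fraction must be in [0, 1]")
        if not self.molar_volume > 0:
            raise ParameterError("molar_volume must be positive")

    def co2_solubility_scale(self, ph: float) -> float:
        """Monotone map pH -> relative CO2 ionization yield in (0, 1)."""
        return 1.0 / (1.0 + 10.0 ** (self.co2_ph_midpoint - ph))


DEFAULT_PARAMS = PhysicsParams()

FUNCTIONALIZATIONS = ("U", "A", "B")

# Tolerance (mol) below which an ion amount counts as exhausted.
_EPS_MOL = 1e-24


@dataclass
class SensorState:
    """Chemical inventory and readout state of one sensor.

    ``ion_moles`` holds the deposited/reacted ions only; the paper's native
    ionic background enters through ``intrinsic_strength`` so that the
    deposited inventory stays an exact stoichiometric ledger.  The neutral
    pools track dissolved but un-ionized gas for mass balance
    (``dissolved_nh3``) and reversibility (``dissolved_co2`` and the
    revertible ``co2_ionized`` H3O+/HCO3- pairs).
    """

    functionalization: str
    deposit_molarity: float
    deposit_volume: float = 10e-6
    ion_moles: dict[str, float] = field(default_factory=dict)
    water_film: float = 0.0
    cell_factor: float = DEFAULT_PARAMS.cell_factor
    background_conductance: float = DEFAULT_PARAMS.background_conductance
    intrinsic_strength: float = DEFAULT_PARAMS.intrinsic_strength
    dissolved_nh3: float = 0.0
    dissolved_co2: float = 0.0
    co2_ionized: float = 0.0

    def copy(self) -> "SensorState":
        return replace(self, ion_moles=dict(self.ion_moles))


def net_charge(state: SensorState) -> float:
    """Signed charge (mol of elementary charge) of the ion inventory."""
    return sum(ION_REGISTRY[n].charge * m for n, m in state.ion_moles.items())


def total_nitrogen(state: SensorState) -> float:
    """Moles of nitrogen held by the sensor (NH4+ plus dissolved NH3)."""
    return state.ion_moles.get("NH4+", 0.0) + state.dissolved_nh3


def water_film_equilibrium(rh: float, params: PhysicsParams = DEFAULT_PARAMS) -> float:
    """Equilibrium water-film fraction W_eq(RH): logistic, in [0, 1]."""
    if not 0.0 <= rh <= 100.0:
        raise ParameterError(f"rh must be in [0, 100], got {rh}")
    return 1.0 / (1.0 + math.exp(-(rh - params.wfilm_midpoint_rh) / params.wfilm_scale_rh))


def make_sensor(
    functionalization: str,
    molarity: float = 0.0,
    volume: float = 10e-6,
    params: PhysicsParams = DEFAULT_PARAMS,
    rh: float | None = None,
) -> SensorState:
    """Create a freshly functionalized sensor equilibrated at ambient RH.

    ``A`` deposits H2SO4 (2 H3O+ and 1 SO4-2 per molecule), ``B`` deposits
    NaOH (1 Na+, 1 OH-), ``U`` deposits plain water.  The amount is
    ``molarity * volume`` moles of solute.
    """
    if functionalization not in FUNCTIONALIZATIONS:
        raise ParameterError(
            f"functionalization must be one of {FUNCTIONALIZATIONS}, got {functionalization!r}"
        )
    if molarity < 0 or molarity > 0.1:
        raise ParameterError(f"molarity must be in [0, 0.1] M, got {molarity}")
    if volume <= 0:
        raise ParameterError(f"volume must be positive, got {volume}")
    if functionalization == "U" and molarity != 0:
        raise ParameterError("untreated sensors take molarity 0")

    n = molarity * volume
    if functionalization == "A":
        ions = {"H3O+": 2 * n, "SO4-2": n}
    elif functionalization == "B":
        ions = {"Na+": n, "OH-": n}
    else:
        ions = {}
    return SensorState(
        functionalization=functionalization,
        deposit_molarity=molarity,
        deposit_volume=volume,
        ion_moles=ions,
        water_film=water_film_equilibrium(params.ambient_rh if rh is None else rh, params),
        cell_factor=params.cell_factor,
        background_conductance=params.background_conductance,
        intrinsic_strength=params.intrinsic_strength,
    )


def ionic_strength_weighted(state: SensorState) -> float:
    """sum_i c_i |z_i| mu_i over the deposited inventory (no intrinsic term)."""
    v = state.deposit_volume
    total = 0.0
    for name, moles in state.ion_moles.items():
        sp = ION_REGISTRY[name]
        total += (moles / v) * abs(sp.charge) * sp.mobility
    return total


def conductance(state: SensorState) -> float:
    """Sensor conductance in siemens; total function on valid states."""
    strength = state.intrinsic_strength + ionic_strength_weighted(state)
    return state.background_conductance + state.cell_factor * state.water_film * strength


def impedance(state: SensorState) -> float:
    """Convenience: 1 / conductance, in ohms."""
    return 1.0 / conductance(state)


def update_water_film(state: SensorState, rh: float, dt: float) -> SensorState:
    """Relax the water film toward W_eq(rh) over a step of ``dt`` seconds.

    Adsorption (film rising) uses ``tau_adsorb``; desorption the slower
    ``tau_desorb``.  The per-step update is the exact exponential solution,
    so step size only matters through within-step RH changes.
    """
    if dt <= 0:
        raise ParameterError(f"dt must be positive, got {dt}")
    new = state.copy()
    _update_water_film_inplace(new, rh, dt, DEFAULT_PARAMS)
    return new


def _update_water_film_inplace(
    state: SensorState, rh: float, dt: float, params: PhysicsParams
) -> None:
    w_eq = water_film_equilibrium(rh, params)
    tau = params.tau_adsorb if w_eq > state.water_film else params.tau_desorb
    state.water_film = w_eq + (state.water_film - w_eq) * math.exp(-dt / tau)


def absorb_nh3(
    state: SensorState, mol_nh3: float, params: PhysicsParams = DEFAULT_PARAMS
) -> SensorState:
    """Absorb ``mol_nh3`` moles of NH3 into the film (reaction endpoint).

    While hydronium remains, each NH3 neutralizes one H3O+ into one NH4+
    (two NH3 per H2SO4 deposited).  Once the acid is exhausted, a fraction
    ``weak_base_fraction`` of further NH3 ionizes to NH4+ + OH- and the
    rest joins the neutral dissolved pool.  Electroneutrality and nitrogen
    mass balance (delivered = NH4+ formed + dissolved pool) are exact.

    This is the equilibrium update for a known absorbed amount; the
    simulator additionally applies the kinetic sticking factor of
    :func:`nh3_uptake_step` when converting a gas stream into absorbed
    moles.
    """
    if mol_nh3 < 0:
        raise ParameterError(f"mol_nh3 must be nonnegative, got {mol_nh3}")
    new = state.copy()
    _absorb_nh3_inplace(new, mol_nh3, params)
    return new


def _absorb_nh3_inplace(state: SensorState, mol: float, params: PhysicsParams) -> None:
    if mol <= 0:
        return
    ions = state.ion_moles
    h3o = ions.get("H3O+", 0.0)
    if h3o > _EPS_MOL:
        reacted = min(mol, h3o)
        ions["H3O+"] = h3o - reacted
        ions["NH4+"] = ions.get("NH4+", 0.0) + reacted
        mol -= reacted
    if mol > 0:
        ionized = params.weak_base_fraction * mol
        ions["NH4+"] = ions.get("NH4+", 0.0) + ionized
        ions["OH-"] = ions.get("OH-", 0.0) + ionized
        state.dissolved_nh3 += mol - ionized


def _nh3_uptake_inplace(state: SensorState, mol_offered: float, params: PhysicsParams) -> None:
    """One kinetic uptake step: route an offered NH3 dose into the film.

    The acid-neutralization rate saturates as the acid runs low: a share
    n/(n + K) of the offered dose reacts immediately (K is
    ``nh3_half_saturation``), while the remainder behaves like NH3 on an
    untreated sensor — ``weak_base_fraction`` ionizes (its OH- recombining
    with any residual acid) and the rest accumulates un-ionized.  This
    turns abrupt acid exhaustion into the exponential approach seen in
    slow neutralization, without altering the overall stoichiometry.
    """
    if mol_offered <= 0:
        return
    ions = state.ion_moles
    h3o = ions.get("H3O+", 0.0)
    if h3o > _EPS_MOL:
        stick = h3o / (h3o + params.nh3_half_saturation)
        acid_route = mol_offered * (stick + (1.0 - stick) * params.weak_base_fraction)
        reacted = min(acid_route, h3o)
        ions["H3O+"] = h3o - reacted
        ions["NH4+"] = ions.get("NH4+", 0.0) + reacted
        state.dissolved_nh3 += mol_offered * (1.0 - stick) * (1.0 - params.weak_base_fraction)
        remainder = max(0.0, acid_route - reacted)  # overshoot past exhaustion
    else:
        remainder = mol_offered
    if remainder > 0:
        ionized = params.weak_base_fraction * remainder
        ions["NH4+"] = ions.get("NH4+", 0.0) + ionized
        ions["OH-"] = ions.get("OH-", 0.0) + ionized
        state.dissolved_nh3 += remainder - ionized


def film_ph(state: SensorState) -> float:
    """Crude film pH from the deposited acid or base; 7 when neither is
    present in meaningful quantity.

    Hydronium generated by CO2's own dissolution (``co2_ionized``) is
    excluded: in a bicarbonate-buffered film it does not suppress further
    uptake the way deposited mineral acid does, and counting it would
    self-quench the untreated/base sensors' CO2 response."""
    v = state.deposit_volume
    h3o = max(0.0, state.ion_moles.get("H3O+", 0.0) - state.co2_ionized) / v
    oh = state.ion_moles.get("OH-", 0.0) / v
    if h3o > 1e-7:
        return -math.log10(h3o)
    if oh > 1e-7:
        return 14.0 + math.log10(oh)
    return 7.0


def absorb_co2(
    state: SensorState, mol_co2: float, params: PhysicsParams = DEFAULT_PARAMS
) -> SensorState:
    """Absorb ``mol_co2`` moles of CO2 into the film.

    While hydroxide remains, CO2 + OH- -> HCO3- replaces a fast anion with
    a slow one (conductance drop).  Afterwards CO2 dissolves, a
    pH-dependent fraction ionizing to H3O+ + HCO3- (conductance rise, fully
    revertible) and the rest entering the neutral dissolved pool.
    """
    if mol_co2 < 0:
        raise ParameterError(f"mol_co2 must be nonnegative, got {mol_co2}")
    new = state.copy()
    _absorb_co2_inplace(new, mol_co2, params)
    return new


def _absorb_co2_inplace(state: SensorState, mol: float, params: PhysicsParams) -> None:
    if mol <= 0:
        return
    ions = state.ion_moles
    oh = ions.get("OH-", 0.0)
    if oh > _EPS_MOL:
        reacted = min(mol, oh)
        ions["OH-"] = oh - reacted
        ions["HCO3-"] = ions.get("HCO3-", 0.0) + reacted
        mol -= reacted
    if mol > 0:
        yield_frac = params.co2_ionization_fraction * params.co2_solubility_scale(film_ph(state))
        ionized = yield_frac * mol
        ions["H3O+"] = ions.get("H3O+", 0.0) + ionized
        ions["HCO3-"] = ions.get("HCO3-", 0.0) + ionized
        state.co2_ionized += ionized
        state.dissolved_co2 += mol - ionized


def desorb_dissolved_gas(
    state: SensorState, dt: float, params: PhysicsParams = DEFAULT_PARAMS
) -> SensorState:
    """Advance the slow gas-release chemistry by ``dt`` seconds.

    Physically dissolved CO2 escapes first-order with ``tau_outgas``, and
    the revertible H3O+/HCO3- pairs it created recombine at the same rate
    (this is what makes the untreated-sensor CO2 response reversible).
    Where OH- and HCO3- coexist they slowly form carbonate, which carries
    less mobility-weighted charge and produces the delayed second
    conductance drop of strongly base-treated sensors.
    """
    if dt <= 0:
        raise ParameterError(f"dt must be positive, got {dt}")
    new = state.copy()
    _desorb_inplace(new, dt, params)
    return new


def _desorb_inplace(state: SensorState, dt: float, params: PhysicsParams) -> None:
    ions = state.ion_moles
    decay = 1.0 - math.exp(-dt / params.tau_outgas)
    if state.dissolved_co2 > _EPS_MOL:
        state.dissolved_co2 *= 1.0 - decay
    if state.co2_ionized > _EPS_MOL:
        revert = state.co2_ionized * decay
        revert = min(revert, ions.get("H3O+", 0.0), ions.get("HCO3-", 0.0))
        if revert > 0:
            ions["H3O+"] -= revert
            ions["HCO3-"] -= revert
            state.co2_ionized -= revert
    oh = ions.get("OH-", 0.0)
    hco3 = ions.get("HCO3-", 0.0)
    if oh > _EPS_MOL and hco3 > _EPS_MOL:
        x = min(oh, hco3) * (1.0 - math.exp(-dt / params.tau_carbonate))
        ions["OH-"] = oh - x
        ions["HCO3-"] = hco3 - x
        ions["CO3-2"] = ions.get("CO3-2", 0.0) + x


def gas_molar_rate(
    conc_ppm: float, flow_mL_min: float, params: PhysicsParams = DEFAULT_PARAMS, gas: str = "NH3"
) -> float:
    """Molar uptake rate (mol/s) of one sensor from a gas stream.

    rate = eff * (flow [L/s]) * (ppm * 1e-6) / molar_volume, with the
    gas-specific capture efficiency.
    """
    if conc_ppm < 0:
        raise ParameterError(f"conc_ppm must be nonnegative, got {conc_ppm}")
    if flow_mL_min <= 0:
        raise ParameterError(f"flow must be positive, got {flow_mL_min}")
    if gas == "NH3":
        eff = params.capture_efficiency
    elif gas == "CO2":
        eff = params.co2_capture_efficiency
    else:
        raise ParameterError(f"unknown gas {gas!r}")
    return eff * (flow_mL_min / 1000.0 / 60.0) * (conc_ppm * 1e-6) / params.molar_volume
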