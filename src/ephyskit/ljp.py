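"""Liquid junction potential by the stationary Henderson equation.

Whole-cell potentials are recorded relative to the pipette interior, so the
junction potential that exists between the pipette solution and the bath
before seal formation offsets every reported voltage.  The standard remedy
is to compute the junction potential from the two solution compositions with
the Henderson equation and subtract it once from all recorded potentials.

Conventions
-----------
``henderson_potential`` returns the bath-minus-pipette junction potential
V(bath) - V(pipette).  ``compute_ljp`` returns the *additive correction* for
pipette-referenced recordings, i.e. the negative of that quantity, so that

    V_corrected = V_measured + compute_ljp(pipette, bath)

For a typical K-based internal against a NaCl-based bath the correction is
negative (a few mV hyperpolarizing), matching the sign electrophysiologists
report.  ``ljp_correct`` applies the correction exactly once, guarded by the
trace's ``ljp_corrected`` flag.

Mobility table
--------------
Relative ionic mobilities follow the convention of junction-potential
calculators used with patch-clamp software: u_i = lambda_i / (z_i^2 *
lambda_K), with lambda_i the limiting molar conductivity at 25 C and
K+ as the reference ion (lambda_K = 73.5 S cm^2 / mol).  Inorganic values
derive from standard electrochemical tables; organic anions common in
patch internals (methylsulfate, gluconate, HEPES, phosphocreatine,
Mg-ATP, GTP) use the values circulated with those calculators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "IonSpecies",
    "SolutionComposition",
    "RELATIVE_MOBILITIES",
    "henderson_potential",
    "compute_ljp",
    "ljp_correct",
    "kmeso4_internal",
    "bicarbonate_acsf",
]

R_GAS = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol

#: relative mobility u_i = lambda_molar,i / (z_i^2 * 73.5), lambda at 25 C
RELATIVE_MOBILITIES: dict[str, float] = {
    "H": 4.757,
    "K": 1.0,
    "Na": 0.682,
    "Li": 0.526,
    "Cs": 1.05,
    "NH4": 1.0,
    "TEA": 0.444,
    "Mg": 0.361,
    "Ca": 0.4048,
    "Ba": 0.4332,
    "OH": 2.69,
    "Cl": 1.0388,
    "Br": 1.0638,
    "F": 0.7533,
    "I": 1.0455,
    "NO3": 0.9729,
    "HCO3": 0.6053,
    "H2PO4": 0.4898,
    "HPO4": 0.39,
    "SO4": 0.5443,
    "acetate": 0.5561,
    "gluconate": 0.33,
    "MeSO4": 0.737,   # methylsulfate, CH3OSO3-
    "MeSO3": 0.664,   # methanesulfonate
    "isethionate": 0.52,
    "HEPES": 0.30,
    "EGTA": 0.24,
    "phosphocreatine": 0.33,
    "MgATP": 0.25,
    "GTP": 0.20,
}


@dataclass(frozen=True)
class IonSpecies:
    """One charged species: name, concentration (mM), signed valence and
    relative mobility (``None`` = look up by name in the packaged table)."""

    name: str
    concentration_mm: float
    valence: int
    relative_mobility: float | None = None

    def mobility(self) -> float:
        if self.relative_mobility is not None:
            return self.relative_mobility
        try:
            return RELATIVE_MOBILITIES[self.name]
        except KeyError:
            raise KeyError(
                f"no relative mobility known for species {self.name!r}; "
                "supply relative_mobility explicitly"
            ) from None


@dataclass
class SolutionComposition:
    """A named electrolyte solution as a list of charged species.

    Neutral components (glucose, sucrose) carry no current and are simply
    omitted.  ``temperature_k`` is the temperature at which the junction
    forms (bath temperature for a patch experiment).
    """

    name: str
    species: list[IonSpecies] = field(default_factory=list)
    temperature_k: float = 306.15  # 33 C

    def add(self, name: str, concentration_mm: float, valence: int,
            relative_mobility: float | None = None) -> "SolutionComposition":
        if concentration_mm < 0:
            raise ValueError(f"negative concentration for {name}")
        self.species.append(
            IonSpecies(name, concentration_mm, valence, relative_mobility))
        return self

    def charge_imbalance_mm(self) -> float:
        """Net charge in mM of elementary charge (0 for electroneutrality)."""
        return sum(s.valence * s.concentration_mm for s in self.species)

    def as_dict(self) -> dict[str, tuple[float, int, float]]:
        out: dict[str, tuple[float, int, float]] = {}
        for s in self.species:
            c, z, u = out.get(s.name, (0.0, s.valence, s.mobility()))
            if z != s.valence:
                raise ValueError(f"species {s.name} listed with two valences")
            out[s.name] = (c + s.concentration_mm, s.valence, u)
        return out


def henderson_potential(pipette: SolutionComposition,
                        bath: SolutionComposition,
                        temperature_k: float | None = None) -> float:
    """Bath-minus-pipette junction potential (mV), stationary Henderson form.

    V = (RT/F) * [sum z_i u_i dc_i / sum z_i^2 u_i dc_i]
              * ln[sum z_i^2 u_i c_i(pip) / sum z_i^2 u_i c_i(bath)]

    with dc_i = c_i(bath) - c_i(pipette).  Identical solutions give 0 and
    swapping the two solutions negates the result.
    """
    if temperature_k is None:
        temperature_k = bath.temperature_k
    pip, bat = pipette.as_dict(), bath.as_dict()
    names = sorted(set(pip) | set(bat))
    num = den = cond_pip = cond_bath = 0.0
    for name in names:
        cp, zp, up = pip.get(name, (0.0, 0, 0.0))
        cb, zb, ub = bat.get(name, (0.0, 0, 0.0))
        z = zp if cp else zb
        u = up if cp else ub
        if cp and cb and zp != zb:
            raise ValueError(f"species {name} has different valences in the "
                             "two solutions")
        dc = cb - cp
        num += z * u * dc
        den += z * z * u * dc
        cond_pip += z * z * u * cp
        cond_bath += z * z * u * cb
    if cond_pip <= 0 or cond_bath <= 0:
        raise ValueError("a solution has zero ionic strength")
    if den == 0.0:
        if num == 0.0 and math.isclose(cond_pip, cond_bath):
            return 0.0
        raise ZeroDivisionError("Henderson denominator is zero for these "
                                "compositions")
    v = (R_GAS * temperature_k / FARADAY) * (num / den) \
        * math.log(cond_pip / cond_bath)
    return v * 1e3  # V -> mV


def compute_ljp(pipette: SolutionComposition,
                bath: SolutionComposition,
                temperature_k: float | None = None) -> float:
    """Additive LJP correction (mV) for pipette-referenced potentials.

    Returns ``-(bath-minus-pipette Henderson potential)`` so that
    ``V_true = V_measured + compute_ljp(...)``.
    """
    return -henderson_potential(pipette, bath, temperature_k)


def ljp_correct(value_or_trace, ljp_mv: float):
    """Apply the LJP correction once.

    Accepts a bare number (returns ``value + ljp_mv``) or any object with
    ``voltage_mv``, ``holding_potential_mv`` and an ``ljp_corrected`` flag
    (a :class:`~ephyskit.types.VoltageTrace`); traces are corrected in place
    and returned.  Correcting an already-corrected trace raises.
    """
    if hasattr(value_or_trace, "ljp_corrected"):
        trace = value_or_trace
        if trace.ljp_corrected:
            raise ValueError("trace is already LJP-corrected")
        trace.voltage_mv = trace.voltage_mv + ljp_mv
        trace.holding_potential_mv += ljp_mv
        trace.ljp_corrected = True
        trace.ljp_mv = ljp_mv
        return trace
    return value_or_trace + ljp_mv


def kmeso4_internal(temperature_k: float = 306.15,
                    ph: float = 7.35,
                    hepes_pka: float = 7.5) -> SolutionComposition:
    """K-methyl-sulfate patch internal (mM): 120 K-MeSO4, 10 KCl, 10 HEPES,
    10 Na2-phosphocreatine, 4 Mg-ATP, 0.4 Na3-GTP, pH adjusted with KOH.

    The ionized HEPES fraction at the stated pH is included with matching K+
    from the KOH titration; Mg-ATP is modelled as the MgATP2- complex.
    """
    f_hepes = 1.0 / (1.0 + 10.0 ** (hepes_pka - ph))
    hepes_anion = 10.0 * f_hepes
    sol = SolutionComposition("K-MeSO4 internal", temperature_k=temperature_k)
    sol.add("K", 120.0 + 10.0 + hepes_anion, +1)   # K-MeSO4 + KCl + KOH
    sol.add("MeSO4", 120.0, -1)
    sol.add("Cl", 10.0, -1)
    sol.add("HEPES", hepes_anion, -1)
    sol.add("Na", 2 * 10.0 + 3 * 0.4, +1)          # Na2-PCr + Na3-GTP
    sol.add("phosphocreatine", 10.0, -2)
    sol.add("MgATP", 4.0, -2)
    sol.add("GTP", 0.4, -3)
    return sol


def bicarbonate_acsf(temperature_k: float = 306.15) -> SolutionComposition:
    """Bicarbonate-buffered aCSF (mM): 125 NaCl, 26 NaHCO3, 2.5 KCl,
    1.25 NaH2PO4, 1 MgSO4, 22 glucose (neutral, omitted), 2 CaCl2."""
    sol = SolutionComposition("aCSF", temperature_k=temperature_k)
    sol.add("Na", 125.0 + 26.0 + 1.25, +1)
    sol.add("Cl", 125.0 + 2 * 2.0, -1)
    sol.add("HCO3", 26.0, -1)
    sol.add("K", 2.5, +1)
    sol.add("H2PO4", 1.25, -1)
    sol.add("Mg", 1.0, +2)
    sol.add("SO4", 1.0, -2)
    sol.add("Ca", 2.0, +2)
    return sol
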