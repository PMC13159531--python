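"""Transition-state analysis: GEDT, thermochemistry, asynchronicity and the
GEDT vs activation-free-energy correlation.

The global electron density transfer (GEDT) at a cycloaddition TS is the net
natural charge accumulated on one reacting fragment; large values (>~0.2 e)
mark a polar mechanism.  Asynchronicity dR is the absolute difference of the
two forming-bond lengths.  Activation/reaction thermochemistry follows the
standard differences against the separated reactants, with the reaction
entropy recovered from dS = (dH - dG) * 1000 / T (cal mol^-1 K^-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from scipy import stats

from .constants import DEFAULT_TEMPERATURE_K, GEDT_NEUTRALITY_TOL
from .species_io import ThermoRecord, TSRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnergeticsRow:
    """One pathway's derived thermochemistry (kcal/mol except as noted)."""

    pathway: str
    e_a: Optional[float] = None       #: electronic activation energy
    dH_rxn: Optional[float] = None
    dG_rxn: Optional[float] = None
    dE_rxn: Optional[float] = None
    dH_act: Optional[float] = None
    dG_act: Optional[float] = None
    dS: Optional[float] = None        #: cal mol^-1 K^-1
    dR: Optional[float] = None        #: angstrom
    gedt: Optional[float] = None      #: e
    temperature: float = DEFAULT_TEMPERATURE_K


@dataclass(frozen=True)
class RegressionResult:
    slope: float       #: kcal mol^-1 e^-1
    intercept: float   #: kcal/mol
    r_squared: float
    n: int


def gedt(ts: TSRecord,
         neutrality_tol: float = GEDT_NEUTRALITY_TOL,
         charged: str = "warn") -> tuple[float, Optional[str]]:
    """GEDT magnitude (e) and the donor fragment of a TS.

    For a neutral supersystem the two fragment charge sums are equal and
    opposite, so GEDT = |sum of charges over either fragment|; the value is
    computed as the mean of the two magnitudes, which coincides with that
    definition when neutral and is the documented fallback otherwise.  The
    donor is the fragment left with net positive charge (it has released
    electron density).

    ``charged`` controls non-neutral supersystems beyond ``neutrality_tol``:
    "warn" (default) logs loudly and falls back to the mean of magnitudes,
    "error" raises.
    """
    s1 = ts.fragment_charge("f1")
    s2 = ts.fragment_charge("f2")
    net = s1 + s2
    if abs(net) > neutrality_tol:
        msg = (f"TS {ts.id!r}: supersystem not neutral (net charge "
               f"{net:+.4f} e > tol {neutrality_tol}); GEDT reported as the "
               "mean of the fragment-charge magnitudes")
        if charged == "error":
            raise ValueError(msg)
        log.warning(msg)
    value = (abs(s1) + abs(s2)) / 2.0
    if s1 == s2 == 0:
        donor = None
    else:
        donor = "f1" if s1 > s2 else "f2"
    return value, donor


def asynchronicity(ts: TSRecord) -> float:
    """dR = |r1 - r2| of the two forming bonds (angstrom)."""
    b1, b2 = ts.forming_bonds
    return abs(b1.length - b2.length)


def _sum_field(records: Sequence[ThermoRecord], name: str) -> Optional[float]:
    vals = [getattr(r, name) for r in records]
    if any(v is None for v in vals):
        return None
    return sum(vals)


def energetics(reactants: Sequence[ThermoRecord],
               ts: Union[TSRecord, ThermoRecord],
               product: Optional[ThermoRecord] = None,
               temperature: float = DEFAULT_TEMPERATURE_K,
               pathway: str = "") -> EnergeticsRow:
    """Derive activation and reaction thermochemistry for one pathway.

    Two input conventions are accepted, never mixed:

    * absolute — every thermo record carries absolute E/H/G; activation
      quantities are TS minus the sum over reactants, reaction quantities
      product minus reactants;
    * relative — ``reactants`` is empty, the TS record's E/H/G are already
      the activation deltas and the product record's the reaction deltas
      (``is_relative`` set on each).

    dS is computed from the reaction enthalpy/free-energy split whenever
    both are available.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")

    ts_thermo = ts.thermo if isinstance(ts, TSRecord) else ts
    if ts_thermo is None:
        raise ValueError("TS record carries no thermochemistry")
    all_records = list(reactants) + [ts_thermo]
    if product is not None:
        all_records.append(product)
    rel_flags = {r.is_relative for r in all_records}
    if len(rel_flags) > 1:
        raise ValueError("mixed absolute and relative thermo records")
    relative = rel_flags.pop()
    if relative and reactants:
        raise ValueError("relative thermo records cannot be combined with "
                         "explicit reactant records")

    if relative:
        e_a, dH_act, dG_act = ts_thermo.E, ts_thermo.H, ts_thermo.G
        dE_rxn = product.E if product else None
        dH_rxn = product.H if product else None
        dG_rxn = product.G if product else None
    else:
        if not reactants:
            raise ValueError("absolute mode requires reactant records")

        def delta(state: Optional[ThermoRecord], name: str) -> Optional[float]:
            if state is None or getattr(state, name) is None:
                return None
            total = _sum_field(reactants, name)
            return None if total is None else getattr(state, name) - total

        e_a = delta(ts_thermo, "E")
        dH_act = delta(ts_thermo, "H")
        dG_act = delta(ts_thermo, "G")
        dE_rxn = delta(product, "E")
        dH_rxn = delta(product, "H")
        dG_rxn = delta(product, "G")

    dS = None
    if dH_rxn is not None and dG_rxn is not None:
        dS = (dH_rxn - dG_rxn) * 1000.0 / temperature

    dR_val = asynchronicity(ts) if isinstance(ts, TSRecord) else None
    gedt_val = None
    if isinstance(ts, TSRecord) and ts.atom_charges:
        gedt_val = gedt(ts)[0]

    return EnergeticsRow(
        pathway=pathway or (ts.pathway if isinstance(ts, TSRecord) else ""),
        e_a=e_a, dH_rxn=dH_rxn, dG_rxn=dG_rxn, dE_rxn=dE_rxn,
        dH_act=dH_act, dG_act=dG_act, dS=dS, dR=dR_val, gedt=gedt_val,
        temperature=temperature,
    )


def reaction_entropy(dH_rxn: float, dG_rxn: float,
                     temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """dS = (dH - dG) * 1000 / T in cal mol^-1 K^-1."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return (dH_rxn - dG_rxn) * 1000.0 / temperature


def gedt_regression(
        points: Sequence[tuple[float, float]]) -> RegressionResult:
    """Unweighted OLS of the activation free energy on GEDT.

    ``points`` are (gedt, dG_act) pairs; requires n >= 3 and non-degenerate
    GEDT values.  r_squared is the squared Pearson correlation.
    """
    if len(points) < 3:
        raise ValueError(f"need at least 3 points, got {len(points)}")
    x = [p[0] for p in points]
    y = [p[1] for p in points]
    if max(x) == min(x):
        raise ValueError("GEDT values have zero variance; fit undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(slope=fit.slope, intercept=fit.intercept,
                            r_squared=fit.rvalue ** 2, n=len(points))
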