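"""Global conceptual-DFT reactivity descriptors and pair-level analysis.

All indices derive from the frontier-orbital (Koopmans-style) approximations
I = -E_HOMO and A = -E_LUMO:

* electronic chemical potential  mu  = -(I + A)/2, electronegativity chi = -mu
* chemical hardness eta = I - A, global softness S = 1/eta (atomic units)
* electrophilicity omega = mu^2 / (2 eta)
* electroaccepting / electrodonating powers
  omega+ = A^2 / (2(I - A)),  omega- = I^2 / (2(I - A))
* net electrophilicity  omega+ + omega-  (note omega- - omega+ = chi)
* nucleophilicity N = E_HOMO - E_HOMO(reference), the reference being the
  tetracyanoethylene HOMO at the same level of theory
* inverse-scale nucleophilicities N' = 1/omega and N'' = 10/omega-

Energies are in eV throughout except the softness, reported in atomic units
(1/hartree) as is conventional; the conversion is internal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .constants import (DEFAULT_ELECTROPHILE_CUTOFFS,
                        DEFAULT_POLARITY_THRESHOLD_EV, HARTREE_TO_EV,
                        TCE_HOMO_HARTREE)
from .species_io import OrbitalEnergies, SpeciesRecord

log = logging.getLogger(__name__)


class DomainError(ValueError):
    """Input outside the mathematical domain of a descriptor."""


class ConfigError(ValueError):
    """Inconsistent configuration (e.g. unordered cutoffs)."""


@dataclass(frozen=True)
class GlobalIndices:
    """The scalar global reactivity descriptors of one species (eV unless
    noted)."""

    i_pot: float            #: ionization potential I
    e_aff: float            #: electron affinity A
    mu: float               #: electronic chemical potential
    chi: float              #: electronegativity
    eta: float              #: chemical hardness
    softness: float         #: global softness S, atomic units (1/hartree)
    omega: float            #: electrophilicity index
    omega_plus: float       #: electroaccepting power
    omega_minus: float      #: electrodonating power
    net_electrophilicity: float  #: omega+ + omega-
    n_index: float          #: nucleophilicity N
    n_prime: Optional[float]     #: N' = 1/omega (None when omega = 0)
    n_roy: float            #: N'' = 10/omega-
    electrophile_class: str      #: strong / moderate / marginal
    cutoffs: tuple[float, float] = DEFAULT_ELECTROPHILE_CUTOFFS


@dataclass(frozen=True)
class PairAnalysis:
    """Electron-demand and polarity analysis of a dipole/dipolarophile pair."""

    gap_ned: float          #: LUMO(dipolarophile) - HOMO(dipole), eV
    gap_ied: float          #: LUMO(dipole) - HOMO(dipolarophile), eV
    demand: str             #: "normal" | "inverse"
    delta_omega: float      #: |omega_1 - omega_2|, eV
    polarity: str           #: "polar" | "nonpolar"
    donor_id: str
    acceptor_id: str
    dipole_globals: GlobalIndices = field(repr=False, default=None)
    dipolarophile_globals: GlobalIndices = field(repr=False, default=None)


def classify_electrophile(
        omega: float,
        cutoffs: tuple[float, float] = DEFAULT_ELECTROPHILE_CUTOFFS) -> str:
    """Classify on the (low, high) omega scale: strong above ``high``,
    marginal below ``low``, moderate in between."""
    if omega < 0:
        raise DomainError(f"omega must be non-negative, got {omega}")
    low, high = cutoffs
    if not low < high:
        raise ConfigError(f"cutoffs must be ordered low < high, got {cutoffs}")
    if omega > high:
        return "strong"
    if omega < low:
        return "marginal"
    return "moderate"


def compute_global(
        orbitals: OrbitalEnergies,
        reference_homo: float = TCE_HOMO_HARTREE,
        cutoffs: tuple[float, float] = DEFAULT_ELECTROPHILE_CUTOFFS,
) -> GlobalIndices:
    """Compute every global index from the frontier orbital energies.

    ``reference_homo`` is the nucleophilicity reference HOMO in hartree.
    """
    i_pot = -orbitals.e_homo
    e_aff = -orbitals.e_lumo
    eta = i_pot - e_aff
    if eta <= 0:
        raise DomainError(f"hardness must be positive, got eta = {eta}")
    mu = -(i_pot + e_aff) / 2.0
    omega = mu * mu / (2.0 * eta)
    omega_plus = e_aff * e_aff / (2.0 * eta)
    omega_minus = i_pot * i_pot / (2.0 * eta)
    n_index = orbitals.e_homo - HARTREE_TO_EV * reference_homo
    if omega > 0:
        n_prime = 1.0 / omega
    else:
        n_prime = None
        log.warning("omega = 0: N' undefined, reported as missing")
    return GlobalIndices(
        i_pot=i_pot,
        e_aff=e_aff,
        mu=mu,
        chi=-mu,
        eta=eta,
        softness=HARTREE_TO_EV / eta,
        omega=omega,
        omega_plus=omega_plus,
        omega_minus=omega_minus,
        net_electrophilicity=omega_plus + omega_minus,
        n_index=n_index,
        n_prime=n_prime,
        n_roy=10.0 / omega_minus,
        electrophile_class=classify_electrophile(omega, cutoffs),
        cutoffs=tuple(cutoffs),
    )


def analyze_pair(
        dipole: SpeciesRecord,
        dipolarophile: SpeciesRecord,
        polarity_threshold: float = DEFAULT_POLARITY_THRESHOLD_EV,
        polar_below: bool = True,
        reference_homo: float = TCE_HOMO_HARTREE,
) -> PairAnalysis:
    """Electron-demand gaps, polarity and donor/acceptor roles of a pair.

    Demand is decided by the smaller frontier gap (ties reported as inverse
    with a warning).  The polar/nonpolar call compares the electrophilicity
    difference against ``polarity_threshold``; ``polar_below`` selects the
    comparison direction (default: small difference between a marginal
    electrophile and strong electrophiles, with large charge-transfer
    capacity, signals a polar one-step mechanism; set False for the
    convention where a larger difference means a more polar process).
    """
    gd = compute_global(dipole.orbitals, reference_homo)
    gp = compute_global(dipolarophile.orbitals, reference_homo)

    gap_ned = dipolarophile.orbitals.e_lumo - dipole.orbitals.e_homo
    gap_ied = dipole.orbitals.e_lumo - dipolarophile.orbitals.e_homo
    if gap_ned == gap_ied:
        log.warning("pair %s/%s: demand gaps tie at %.3f eV; "
                    "reporting inverse", dipole.id, dipolarophile.id, gap_ned)
        demand = "inverse"
    else:
        demand = "normal" if gap_ned < gap_ied else "inverse"

    delta_omega = abs(gp.omega - gd.omega)
    if polar_below:
        polarity = "polar" if delta_omega < polarity_threshold else "nonpolar"
    else:
        polarity = "polar" if delta_omega > polarity_threshold else "nonpolar"

    if gd.n_index >= gp.n_index:
        donor, acceptor = dipole, dipolarophile
        if gd.omega > gp.omega:
            log.warning("pair %s/%s: donor by N also has larger omega; "
                        "donor chosen by N", dipole.id, dipolarophile.id)
    else:
        donor, acceptor = dipolarophile, dipole
        if gp.omega > gd.omega:
            log.warning("pair %s/%s: donor by N also has larger omega; "
                        "donor chosen by N", dipole.id, dipolarophile.id)

    return PairAnalysis(
        gap_ned=gap_ned,
        gap_ied=gap_ied,
        demand=demand,
        delta_omega=delta_omega,
        polarity=polarity,
        donor_id=donor.id,
        acceptor_id=acceptor.id,
        dipole_globals=gd,
        dipolarophile_globals=gp,
    )
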