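"""Loader for the bundled benchmark dataset.

``data/dispiro_cycloaddition.json`` carries the literature reference values
(B3LYP/cc-pVTZ) for the polar [3+2] cycloaddition of 9-diazo-9H-fluorene
(DF, id "4") with E/Z 4-arylidene-1-phenylpyrazolidine-3,5-diones (APPs,
ids "Z-3a" … "E-3g"): frontier orbital energies, the printed global and
condensed-site descriptor tables, and the four-pathway transition-state
energetics.  It is the package's regression baseline: tests recompute every
derived column and compare against the printed values.

Printed entries that are internally inconsistent with their own source
table (see docs/methods.md) carry flags (``printed_inconsistent``,
``f_chain_consistent``, ``dS_consistent``) so validation can skip exactly
those entries, and nothing else.

``species_records()`` rebuilds full :class:`~cdftkit.species_io.SpeciesRecord`
objects.  Only Fukui *differences* and spin densities are published, so the
baseline populations are synthetic (a flat 4.0 electrons per atom) — the
finite differences, and hence every descriptor, are unaffected.  The records
cover only the tabulated heavy-atom subset and are therefore flagged
partial-site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .species_io import AtomSite, OrbitalEnergies, SpeciesRecord

_DATA_RESOURCE = "dispiro_cycloaddition.json"

#: Candidate regiochemical pathways of the DF + APP cycloaddition:
#: path A couples the dipole carbon C3 with the exocyclic beta-carbon C2
#: (primary bond) and N5 with C1; path B is the alpha-attack alternative.
PAIRING_MAP = {
    "path A": (("C3", "C2"), ("N5", "C1")),
    "path B": (("C3", "C1"), ("N5", "C2")),
}


@dataclass(frozen=True)
class ReferenceSite:
    label: str
    element: str
    index: int
    printed: dict
    f_chain_consistent: bool


@dataclass(frozen=True)
class ReferenceSpecies:
    id: str
    role: str
    e_homo: float
    e_lumo: float
    printed: dict
    printed_inconsistent: tuple[str, ...]
    printed_gap_ned: Optional[float]
    printed_gap_ied: Optional[float]
    sites: tuple[ReferenceSite, ...]


@dataclass(frozen=True)
class ReferenceTS:
    pathway: str
    e_a: float
    dH_rxn: float
    dG_rxn: float
    dE_rxn: float
    dH_act: float
    dG_act: float
    dS: float
    dR: float
    gedt: float
    dS_consistent: bool


@dataclass(frozen=True)
class ReferenceData:
    reference_homo_hartree: float
    temperature_K: float
    regression_r2_printed: float
    delta_omega_range_printed: tuple[float, float]
    species: tuple[ReferenceSpecies, ...]
    transition_states: tuple[ReferenceTS, ...]

    @property
    def dipole(self) -> ReferenceSpecies:
        return next(s for s in self.species if s.role == "dipole")

    @property
    def dipolarophiles(self) -> tuple[ReferenceSpecies, ...]:
        return tuple(s for s in self.species if s.role == "dipolarophile")

    def by_id(self, sid: str) -> ReferenceSpecies:
        return next(s for s in self.species if s.id == sid)


def load_reference() -> ReferenceData:
    payload = json.loads(
        resources.files("cdftkit.data").joinpath(_DATA_RESOURCE).read_text())
    species = tuple(
        ReferenceSpecies(
            id=s["id"],
            role=s["role"],
            e_homo=s["e_homo"],
            e_lumo=s["e_lumo"],
            printed=s["printed"],
            printed_inconsistent=tuple(s["printed_inconsistent"]),
            printed_gap_ned=s["printed_gap_ned"],
            printed_gap_ied=s["printed_gap_ied"],
            sites=tuple(ReferenceSite(
                label=t["label"], element=t["element"], index=t["index"],
                printed=t["printed"],
                f_chain_consistent=t["f_chain_consistent"],
            ) for t in s["sites"]),
        ) for s in payload["species"])
    ts = tuple(ReferenceTS(**t) for t in payload["transition_states"])
    return ReferenceData(
        reference_homo_hartree=payload["reference_homo_hartree"],
        temperature_K=payload["temperature_K"],
        regression_r2_printed=payload["regression_r2_printed"],
        delta_omega_range_printed=tuple(
            payload["delta_omega_range_printed"]),
        species=species,
        transition_states=ts,
    )


def species_records(ref: Optional[ReferenceData] = None,
                    baseline_population: float = 4.0) -> list[SpeciesRecord]:
    """Materialize the benchmark as loadable species records.

    Populations are reconstructed around a synthetic uniform baseline so the
    published Fukui differences are reproduced exactly; spin densities are
    the published Parr functions.  Records are partial-site (heavy-atom
    subset only).
    """
    ref = ref or load_reference()
    records = []
    for s in ref.species:
        atoms = []
        for t in s.sites:
            p = t.printed
            atoms.append(AtomSite(
                index=t.index,
                element=t.element,
                label=t.label,
                p_neutral=baseline_population,
                p_anion=baseline_population + p["f_plus"],
                p_cation=baseline_population - p["f_minus"],
                asd_anion=p["p_plus"],
                asd_cation=p["p_minus"],
            ))
        records.append(SpeciesRecord(
            id=s.id,
            role=s.role,
            orbitals=OrbitalEnergies(e_homo=s.e_homo, e_lumo=s.e_lumo),
            atoms=atoms,
            partial_site=True,
        ))
    return records
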