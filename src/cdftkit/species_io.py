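"""Data model and file I/O for species and transition-state records.

A *species record* bundles everything the descriptor machinery needs about
one molecule: frontier orbital energies (always stored in eV), and per-atom
electron populations of the N, N+1 and N-1 electron states at the neutral
geometry together with atomic spin densities (ASD) of the radical anion and
radical cation.  A *TS record* carries per-atom natural charges, a
two-fragment assignment, the two forming bonds and optional thermochemistry.

Canonical on-disk format is JSON (``species.json`` / ``ts.json``); a flat CSV
dialect mirrors the species schema with one row per atom.  Both are versioned
through a ``schema_version`` field.

CSV columns (header mandatory, UTF-8, comma separated)::

    species_id, role, homo, lumo, units, absolute_energy,
    atom_index, element, label, p_neutral, p_anion, p_cation,
    asd_anion, asd_cation

A species without atoms occupies a single row with the atom columns empty.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

from pydantic import BaseModel, Field, field_validator, model_validator

from .constants import FUKUI_SUM_TOL, HARTREE_TO_EV

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

Units = Literal["eV", "hartree"]
Role = Literal["dipole", "dipolarophile", "other"]
Fragment = Literal["f1", "f2"]


class SchemaError(ValueError):
    """Malformed input file (parse failure, missing field, bad cardinality)."""


class RecordValidationError(ValueError):
    """A record violates a physical-consistency rule; names record and rule."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class OrbitalEnergies(BaseModel):
    """Frontier orbital energies in eV; ``source_units`` records the on-disk
    units before normalization."""

    e_homo: float
    e_lumo: float
    source_units: Units = "eV"

    @model_validator(mode="after")
    def _ordered(self) -> "OrbitalEnergies":
        if not (self.e_homo < self.e_lumo):
            raise ValueError(
                f"e_homo ({self.e_homo}) must lie strictly below "
                f"e_lumo ({self.e_lumo})"
            )
        return self

    @classmethod
    def from_values(cls, homo: float, lumo: float,
                    units: Units = "eV") -> "OrbitalEnergies":
        """Build from raw numbers, normalizing hartree input to eV."""
        if units == "hartree":
            homo, lumo = homo * HARTREE_TO_EV, lumo * HARTREE_TO_EV
        return cls(e_homo=homo, e_lumo=lumo, source_units=units)

    @property
    def gap(self) -> float:
        return self.e_lumo - self.e_homo


class AtomSite(BaseModel):
    """One atom of a species.

    ``p_*`` are electron populations (dimensionless) of the atom in the N
    (neutral), N+1 (anion) and N-1 (cation) electron states at fixed
    geometry; ``asd_*`` are atomic spin densities of the radical anion and
    radical cation.  Spin densities may be negative.
    """

    index: int = Field(gt=0, description="1-based atom index")
    element: str
    label: str = ""
    p_neutral: Optional[float] = None
    p_anion: Optional[float] = None
    p_cation: Optional[float] = None
    asd_anion: Optional[float] = None
    asd_cation: Optional[float] = None

    @field_validator("p_neutral", "p_anion", "p_cation",
                     "asd_anion", "asd_cation")
    @classmethod
    def _finite(cls, v):
        if v is not None and not math.isfinite(v):
            raise ValueError("populations and spin densities must be finite")
        return v

    @property
    def has_populations(self) -> bool:
        return None not in (self.p_neutral, self.p_anion, self.p_cation)

    @property
    def has_asd(self) -> bool:
        return None not in (self.asd_anion, self.asd_cation)

    @property
    def display_label(self) -> str:
        return self.label or f"{self.element}{self.index}"


class SpeciesRecord(BaseModel):
    id: str
    role: Role = "other"
    orbitals: OrbitalEnergies
    atoms: list[AtomSite] = Field(default_factory=list)
    absolute_energy: Optional[float] = None  # kcal/mol
    partial_site: bool = False

    @field_validator("id")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("species id must be non-empty")
        return v

    @model_validator(mode="after")
    def _unique_atoms(self) -> "SpeciesRecord":
        idx = [a.index for a in self.atoms]
        if len(idx) != len(set(idx)):
            raise ValueError(f"duplicate atom indices in record {self.id!r}")
        return self

    def fukui_sums(self) -> Optional[tuple[float, float]]:
        """(sum f+, sum f-) over all atoms carrying populations, or None."""
        sites = [a for a in self.atoms if a.has_populations]
        if not sites:
            return None
        sp = sum(a.p_anion - a.p_neutral for a in sites)
        sm = sum(a.p_neutral - a.p_cation for a in sites)
        return sp, sm

    def atom_by_label(self, label: str) -> AtomSite:
        for a in self.atoms:
            if a.display_label == label or a.label == label:
                return a
        raise KeyError(f"no atom labelled {label!r} in species {self.id!r}")


class FormingBond(BaseModel):
    atoms: tuple[int, int]
    length: float = Field(gt=0, description="bond length, angstrom")


class ThermoRecord(BaseModel):
    """E/H/G in kcal/mol; absolute values or deltas per ``is_relative``."""

    E: Optional[float] = None
    H: Optional[float] = None
    G: Optional[float] = None
    is_relative: bool = False


class TSRecord(BaseModel):
    id: str
    pathway: str = ""
    atom_charges: dict[int, float]
    fragment_of: dict[int, Fragment]
    forming_bonds: list[FormingBond]
    thermo: Optional[ThermoRecord] = None
    #: optional product-state thermochemistry (same convention as ``thermo``)
    #: so reaction quantities can be derived alongside activation ones.
    product_thermo: Optional[ThermoRecord] = None

    @model_validator(mode="after")
    def _consistent(self) -> "TSRecord":
        missing = [k for k in self.atom_charges if k not in self.fragment_of]
        if missing:
            raise ValueError(
                f"TS {self.id!r}: atoms {missing} carry charges but have no "
                "fragment assignment"
            )
        frags = set(self.fragment_of[k] for k in self.atom_charges)
        if self.atom_charges and frags != {"f1", "f2"}:
            raise ValueError(
                f"TS {self.id!r}: both fragments must be non-empty "
                f"(got {sorted(frags)})"
            )
        if len(self.forming_bonds) != 2:
            raise ValueError(
                f"TS {self.id!r}: exactly two forming bonds required, "
                f"got {len(self.forming_bonds)}"
            )
        return self

    def fragment_charge(self, fragment: Fragment) -> float:
        return sum(q for k, q in self.atom_charges.items()
                   if self.fragment_of[k] == fragment)


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def check_fukui_sums(record: SpeciesRecord, tol: float = FUKUI_SUM_TOL,
                     strict: bool = False) -> SpeciesRecord:
    """Enforce the sum rules sum(f+) = sum(f-) = 1 within ``tol``.

    Records that fail are either rejected (``strict``) or flagged
    ``partial_site`` with a logged warning — tabulated condensed data often
    covers only the chemically relevant atom subset.
    """
    if record.partial_site:
        return record
    sums = record.fukui_sums()
    if sums is None:
        return record
    sp, sm = sums
    if abs(sp - 1.0) <= tol and abs(sm - 1.0) <= tol:
        return record
    msg = (f"record {record.id!r}: Fukui sums ({sp:.4f}, {sm:.4f}) deviate "
           f"from 1 by more than {tol}")
    if strict:
        raise RecordValidationError(msg + " (rule: fukui-sum)")
    log.warning("%s; flagging as partial-site and skipping sum checks", msg)
    record.partial_site = True
    return record


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _species_from_obj(obj: dict, units_override: Optional[Units],
                      charges: bool) -> SpeciesRecord:
    try:
        orb = obj["orbitals"]
        units = units_override or orb.get("units", "eV")
        orbitals = OrbitalEnergies.from_values(orb["homo"], orb["lumo"], units)
        atoms = []
        for a in obj.get("atoms", []):
            a = dict(a)
            if charges:
                # charge convention: q(N), q(N+1), q(N-1) supplied in the
                # population columns.  Storing p = -q preserves every
                # population difference (f+ = q(N) - q(N+1) etc.), so the
                # downstream finite-difference algebra is unchanged.
                for key in ("p_neutral", "p_anion", "p_cation"):
                    if a.get(key) is not None:
                        a[key] = -a[key]
            atoms.append(AtomSite(**a))
        return SpeciesRecord(
            id=obj["id"],
            role=obj.get("role", "other"),
            orbitals=orbitals,
            atoms=atoms,
            absolute_energy=obj.get("absolute_energy"),
            partial_site=bool(obj.get("partial_site", False)),
        )
    except KeyError as exc:
        raise SchemaError(
            f"species object {obj.get('id', '<no id>')!r}: "
            f"missing field {exc}"
        ) from exc
    except ValueError as exc:
        raise RecordValidationError(
            f"record {obj.get('id', '<no id>')!r}: {exc}"
        ) from exc


def _unwrap(payload, key: str) -> list:
    if isinstance(payload, list):
        return payload
    if isinstance(payload, dict) and key in payload:
        return payload[key]
    raise SchemaError(f"expected a list or an object with a {key!r} field")


def load_species(path: Union[str, Path],
                 units_override: Optional[Units] = None,
                 charges: bool = False,
                 tol: float = FUKUI_SUM_TOL,
                 strict: bool = False) -> list[SpeciesRecord]:
    """Load species records from JSON or CSV, normalizing energies to eV.

    Parameters
    ----------
    units_override
        Force interpretation of on-disk orbital energies as eV or hartree,
        overriding the file's ``units`` field.
    charges
        Interpret the population columns as atomic charges of the N, N+1,
        N-1 states instead of electron populations (see ``_species_from_obj``).
    tol, strict
        Fukui sum-rule tolerance and whether violations are fatal.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        objs = _read_species_csv(path)
    else:
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise SchemaError(
                f"{path}: invalid JSON at line {exc.lineno}, "
                f"column {exc.colno}: {exc.msg}"
            ) from exc
        objs = _unwrap(payload, "species")

    records = [_species_from_obj(o, units_override, charges) for o in objs]
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise RecordValidationError(
                f"record {r.id!r}: duplicate species id (rule: unique-id)")
        seen.add(r.id)
        check_fukui_sums(r, tol=tol, strict=strict)
    return records


def _read_species_csv(path: Path) -> list[dict]:
    atom_cols = ("p_neutral", "p_anion", "p_cation", "asd_anion", "asd_cation")
    by_id: dict[str, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "species_id" not in reader.fieldnames:
            raise SchemaError(f"{path}: missing header row with 'species_id'")
        for lineno, row in enumerate(reader, start=2):
            sid = (row.get("species_id") or "").strip()
            if not sid:
                raise SchemaError(f"{path}: line {lineno}: empty species_id")
            try:
                obj = by_id.setdefault(sid, {
                    "id": sid,
                    "role": (row.get("role") or "other").strip() or "other",
                    "orbitals": {
                        "homo": float(row["homo"]),
                        "lumo": float(row["lumo"]),
                        "units": (row.get("units") or "eV").strip() or "eV",
                    },
                    "absolute_energy": float(row["absolute_energy"])
                    if (row.get("absolute_energy") or "").strip() else None,
                    "atoms": [],
                })
                if (row.get("atom_index") or "").strip():
                    atom = {
                        "index": int(row["atom_index"]),
                        "element": (row.get("element") or "").strip(),
                        "label": (row.get("label") or "").strip(),
                    }
                    for col in atom_cols:
                        val = (row.get(col) or "").strip()
                        if val:
                            atom[col] = float(val)
                    obj["atoms"].append(atom)
            except (KeyError, ValueError) as exc:
                raise SchemaError(
                    f"{path}: line {lineno}: {exc}") from exc
    return list(by_id.values())


def load_ts(path: Union[str, Path]) -> list[TSRecord]:
    """Load transition-state records from JSON; invariants verified."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(
            f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    records = []
    for obj in _unwrap(payload, "transition_states"):
        try:
            records.append(TSRecord(
                id=obj["id"],
                pathway=obj.get("pathway", ""),
                atom_charges={int(k): float(v)
                              for k, v in obj["atom_charges"].items()},
                fragment_of={int(k): v
                             for k, v in obj["fragment_of"].items()},
                forming_bonds=[FormingBond(**b)
                               for b in obj["forming_bonds"]],
                thermo=ThermoRecord(**obj["thermo"])
                if obj.get("thermo") else None,
                product_thermo=ThermoRecord(**obj["product_thermo"])
                if obj.get("product_thermo") else None,
            ))
        except KeyError as exc:
            raise SchemaError(
                f"TS object {obj.get('id', '<no id>')!r}: "
                f"missing field {exc}") from exc
        except ValueError as exc:
            raise RecordValidationError(str(exc)) from exc
    return records


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _species_to_obj(r: SpeciesRecord) -> dict:
    return {
        "id": r.id,
        "role": r.role,
        "orbitals": {"homo": r.orbitals.e_homo, "lumo": r.orbitals.e_lumo,
                     "units": "eV"},
        "atoms": [a.model_dump(exclude_none=True) for a in r.atoms],
        "absolute_energy": r.absolute_energy,
        "partial_site": r.partial_site,
    }


def write_species(records: Sequence[SpeciesRecord],
                  path: Union[str, Path]) -> Path:
    """Write records to JSON (energies in eV); load o write is the identity."""
    path = Path(path)
    payload = {"schema_version": SCHEMA_VERSION,
               "species": [_species_to_obj(r) for r in records]}
    path.write_text(json.dumps(payload, indent=1))
    return path


def write_species_csv(records: Sequence[SpeciesRecord],
                      path: Union[str, Path]) -> Path:
    path = Path(path)
    cols = ["species_id", "role", "homo", "lumo", "units", "absolute_energy",
            "atom_index", "element", "label", "p_neutral", "p_anion",
            "p_cation", "asd_anion", "asd_cation"]

    def fmt(v):
        return "" if v is None else (f"{v:.12g}" if isinstance(v, float)
                                     else str(v))

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for r in records:
            base = [r.id, r.role, fmt(r.orbitals.e_homo),
                    fmt(r.orbitals.e_lumo), "eV", fmt(r.absolute_energy)]
            if not r.atoms:
                writer.writerow(base + [""] * 8)
            for a in r.atoms:
                writer.writerow(base + [a.index, a.element, a.label,
                                        fmt(a.p_neutral), fmt(a.p_anion),
                                        fmt(a.p_cation), fmt(a.asd_anion),
                                        fmt(a.asd_cation)])
    return path


def write_ts(records: Sequence[TSRecord], path: Union[str, Path]) -> Path:
    path = Path(path)
    objs = []
    for r in records:
        obj = {
            "id": r.id,
            "pathway": r.pathway,
            "atom_charges": {str(k): v for k, v in r.atom_charges.items()},
            "fragment_of": {str(k): v for k, v in r.fragment_of.items()},
            "forming_bonds": [{"atoms": list(b.atoms), "length": b.length}
                              for b in r.forming_bonds],
        }
        if r.thermo is not None:
            obj["thermo"] = r.thermo.model_dump()
        if r.product_thermo is not None:
            obj["product_thermo"] = r.product_thermo.model_dump()
        objs.append(obj)
    path.write_text(json.dumps(
        {"schema_version": SCHEMA_VERSION, "transition_states": objs},
        indent=1))
    return path
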