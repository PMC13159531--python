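"""Seeded generators for physically consistent mock species and TS data.

The generators emulate the statistical shape of a diazo-dipole /
electron-poor-alkene cycloaddition study: frontier orbital energies drawn
from the empirical windows of such reactants (HOMO in [-6.5, -5.5] eV, LUMO
in [-3.7, -1.9] eV), per-atom population triples built as a neutral baseline
plus unit-sum increment vectors so the Fukui sum rules hold by construction,
normalized spin-density vectors, and TS ensembles whose activation free
energies follow a linear GEDT relationship plus Gaussian noise.

Reproducibility: every record draws from its own counter-derived substream
``default_rng([seed, stream, index])``, so changing the record count never
reshuffles earlier records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .species_io import (AtomSite, FormingBond, OrbitalEnergies,
                         SpeciesRecord, ThermoRecord, TSRecord)

_SPECIES_STREAM = 0
_TS_STREAM = 1

_ELEMENTS = ("C", "N", "O")


@dataclass
class SynthConfig:
    seed: int = 0
    n_species: int = 15
    n_atoms: int = 5
    homo_range: tuple[float, float] = (-6.5, -5.5)   # eV
    lumo_range: tuple[float, float] = (-3.7, -1.9)   # eV
    gedt_slope: float = -55.0        # kcal mol^-1 e^-1
    gedt_intercept: float = 56.0     # kcal/mol
    noise_sd: float = 0.3            # kcal/mol
    n_ts: int = 50
    realistic: bool = False          # add small Fukui-sum leakage

    def __post_init__(self) -> None:
        for name in ("homo_range", "lumo_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be at least 1 when local "
                             "descriptors are requested")


def _rng(seed: int, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream, index])


def _unit_sum(rng: np.random.Generator, n: int) -> np.ndarray:
    """A positive vector summing to 1.0 exactly (last entry closes the sum)."""
    x = rng.random(n) + 0.05
    x = x / x.sum()
    x[-1] = 1.0 - x[:-1].sum()
    return x


def make_species(cfg: SynthConfig) -> list[SpeciesRecord]:
    """Generate ``cfg.n_species`` records; the first is tagged as the dipole,
    the rest as dipolarophiles."""
    records = []
    for i in range(cfg.n_species):
        rng = _rng(cfg.seed, _SPECIES_STREAM, i)
        homo = rng.uniform(*cfg.homo_range)
        lumo = rng.uniform(*cfg.lumo_range)
        while lumo <= homo:  # only possible with overlapping ranges
            lumo = rng.uniform(*cfg.lumo_range)

        f_plus = _unit_sum(rng, cfg.n_atoms)
        f_minus = _unit_sum(rng, cfg.n_atoms)
        asd_plus = _unit_sum(rng, cfg.n_atoms)
        asd_minus = _unit_sum(rng, cfg.n_atoms)
        if cfg.realistic:
            f_plus = f_plus + rng.normal(0.0, 0.004, cfg.n_atoms)
            f_minus = f_minus + rng.normal(0.0, 0.004, cfg.n_atoms)
        p_neutral = rng.integers(1, 7, cfg.n_atoms).astype(float)

        atoms = []
        for k in range(cfg.n_atoms):
            element = _ELEMENTS[k % len(_ELEMENTS)]
            atoms.append(AtomSite(
                index=k + 1,
                element=element,
                label=f"{element}{k + 1}",
                p_neutral=p_neutral[k],
                p_anion=p_neutral[k] + f_plus[k],
                p_cation=p_neutral[k] - f_minus[k],
                asd_anion=asd_plus[k],
                asd_cation=asd_minus[k],
            ))
        records.append(SpeciesRecord(
            id=f"synth-{i:03d}",
            role="dipole" if i == 0 else "dipolarophile",
            orbitals=OrbitalEnergies(e_homo=homo, e_lumo=lumo),
            atoms=atoms,
        ))
    return records


def make_ts_set(cfg: SynthConfig) -> list[TSRecord]:
    """TS ensemble with known GEDT vs activation-free-energy ground truth.

    GEDT targets are uniform on [0.1, 0.5] e; each fragment's four atomic
    charges sum to +-GEDT exactly; dG_act = intercept + slope*GEDT + noise.
    """
    n_frag = 4
    records = []
    for i in range(cfg.n_ts):
        rng = _rng(cfg.seed, _TS_STREAM, i)
        g = rng.uniform(0.1, 0.5)

        def frag_charges(total: float) -> np.ndarray:
            q = rng.normal(0.0, 0.05, n_frag)
            q[-1] = 0.0
            q[-1] = total - q.sum()
            return q

        q1 = frag_charges(+g)
        q2 = frag_charges(-g)
        charges = {k + 1: float(q1[k]) for k in range(n_frag)}
        charges.update({n_frag + k + 1: float(q2[k]) for k in range(n_frag)})
        fragments = {k + 1: "f1" for k in range(n_frag)}
        fragments.update({n_frag + k + 1: "f2" for k in range(n_frag)})

        dg_act = (cfg.gedt_intercept + cfg.gedt_slope * g
                  + (rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd else 0.0))
        r1 = rng.uniform(1.9, 2.4)
        dr = rng.uniform(0.0, 0.8)

        records.append(TSRecord(
            id=f"ts-{i:03d}",
            pathway=f"path-{i:03d}",
            atom_charges=charges,
            fragment_of=fragments,
            forming_bonds=[FormingBond(atoms=(1, 5), length=r1),
                           FormingBond(atoms=(3, 7), length=r1 + dr)],
            thermo=ThermoRecord(G=float(dg_act), is_relative=True),
        ))
    return records
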