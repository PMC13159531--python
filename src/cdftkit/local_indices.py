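"""Condensed per-atom reactivity descriptors and site classification.

Two condensed-site families are computed:

* the finite-difference (Yang-Mortier) Fukui family from electron
  populations of the N+1 / N / N-1 states —
  f+ = p(N+1) - p(N), f- = p(N) - p(N-1), dual descriptor f2 = f+ - f-,
  philicities w_k+- = omega * f+-, multiphilic descriptor dw = omega * f2,
  local softnesses s_k+- = S * f+-, dual softness ds = S * f2 and
  hypersoftness s2 = S^2 * f2;

* the Parr-function family from atomic spin densities of the radical
  anion (P+) and radical cation (P-) — local electrophilicity
  w_k = omega * P+ and local nucleophilicity N_k = N * P-.

The two are combined by the conditional local reactivity difference index
R_k: when w_k and N_k are both positive and their ratio lies strictly
inside (1, 2) either way, the site is ambiphilic with R_k = (w_k + N_k)/2
reported as a magnitude with a +- flag; otherwise R_k = w_k - N_k, negative
for nucleophilic and positive for electrophilic sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

from .global_indices import GlobalIndices
from .species_io import AtomSite, SpeciesRecord

log = logging.getLogger(__name__)


@dataclass
class SiteIndices:
    """All condensed descriptors of one atom; descriptors whose inputs are
    missing stay None."""

    atom: AtomSite
    f_plus: Optional[float] = None
    f_minus: Optional[float] = None
    f2: Optional[float] = None
    w_plus: Optional[float] = None       # eV
    w_minus: Optional[float] = None      # eV
    dw: Optional[float] = None           # eV
    p_plus: Optional[float] = None
    p_minus: Optional[float] = None
    w_local: Optional[float] = None      # eV
    n_local: Optional[float] = None      # eV
    r_k: Optional[float] = None          # eV; magnitude when ambiphilic
    site_class: Optional[str] = None     # nucleophilic/electrophilic/ambiphilic
    s_plus: Optional[float] = None       # a.u.
    s_minus: Optional[float] = None      # a.u.
    ds: Optional[float] = None           # a.u.
    s2: Optional[float] = None           # a.u.^2-scaled

    @property
    def label(self) -> str:
        return self.atom.display_label

    @property
    def r_display(self) -> str:
        """R_k the way report tables print it: signed, or +-magnitude for
        ambiphilic sites."""
        if self.r_k is None:
            return ""
        if self.site_class == "ambiphilic":
            return f"±{abs(self.r_k):.2f}"
        return f"{self.r_k:+.2f}"


class PhilicitySoftness(NamedTuple):
    w_plus: float
    w_minus: float
    dw: float
    s_plus: float
    s_minus: float
    ds: float
    s2: float


def fukui(atom: AtomSite) -> Optional[tuple[float, float]]:
    """Condensed Fukui functions (f+, f-) by finite differences of the
    electron populations; None when populations are missing."""
    if not atom.has_populations:
        log.warning("atom %s: populations missing, Fukui unavailable",
                    atom.display_label)
        return None
    f_plus = atom.p_anion - atom.p_neutral
    f_minus = atom.p_neutral - atom.p_cation
    return f_plus, f_minus


def dual_descriptor(f_plus: float, f_minus: float) -> float:
    """f2 = f+ - f-; negative marks a nucleophilic site, positive an
    electrophilic one."""
    return f_plus - f_minus


def hypersoftness(f2: float, softness: float) -> float:
    """Local hypersoftness s2 = S^2 * f2, the size-extensive companion of
    the dual softness."""
    return softness * softness * f2


def philicity_and_softness(f_plus: float, f_minus: float, omega: float,
                           softness: float) -> PhilicitySoftness:
    """Philicity and softness families from the Fukui pair, scaling by the
    global electrophilicity (eV) and softness (a.u.)."""
    f2 = dual_descriptor(f_plus, f_minus)
    return PhilicitySoftness(
        w_plus=omega * f_plus,
        w_minus=omega * f_minus,
        dw=omega * f2,
        s_plus=softness * f_plus,
        s_minus=softness * f_minus,
        ds=softness * f2,
        s2=hypersoftness(f2, softness),
    )


def parr_local(p_plus: float, p_minus: float, omega: float,
               n_index: float) -> tuple[float, float]:
    """Parr-function local electrophilicity w_k = omega*P+ and local
    nucleophilicity N_k = N*P-."""
    return omega * p_plus, n_index * p_minus


def reactivity_difference(w_local: float,
                          n_local: float) -> tuple[float, str]:
    """Conditional R_k rule combining local electrophilicity and
    nucleophilicity.

    Returns ``(r_k, site_class)`` where ``r_k`` is the magnitude
    (w_k + N_k)/2 for ambiphilic sites and the signed difference w_k - N_k
    otherwise.  The ratio window (1, 2) is strict and only consulted when
    both inputs are positive (a ratio between two quantities of opposite
    sign cannot indicate ambiphilicity).
    """
    if w_local > 0 and n_local > 0:
        ratio = w_local / n_local
        if 1 < ratio < 2 or 1 < 1 / ratio < 2:
            return (w_local + n_local) / 2.0, "ambiphilic"
    r = w_local - n_local
    if r < 0:
        return r, "nucleophilic"
    if r > 0:
        return r, "electrophilic"
    log.warning("R_k = 0 exactly; reporting ambiphilic")
    return 0.0, "ambiphilic"


def compute_site(atom: AtomSite, glob: GlobalIndices) -> SiteIndices:
    """All condensed descriptors of one atom given its species' global
    indices; families with missing inputs are left unset."""
    site = SiteIndices(atom=atom)
    fk = fukui(atom)
    if fk is not None:
        site.f_plus, site.f_minus = fk
        site.f2 = dual_descriptor(site.f_plus, site.f_minus)
        ps = philicity_and_softness(site.f_plus, site.f_minus,
                                    glob.omega, glob.softness)
        (site.w_plus, site.w_minus, site.dw,
         site.s_plus, site.s_minus, site.ds, site.s2) = ps
    if atom.has_asd:
        site.p_plus = atom.asd_anion
        site.p_minus = atom.asd_cation
        site.w_local, site.n_local = parr_local(
            site.p_plus, site.p_minus, glob.omega, glob.n_index)
        site.r_k, site.site_class = reactivity_difference(
            site.w_local, site.n_local)
    return site


def compute_sites(record: SpeciesRecord,
                  glob: GlobalIndices) -> list[SiteIndices]:
    return [compute_site(a, glob) for a in record.atoms]


def rank_sites(sites: Sequence[SiteIndices],
               mode: str = "nucleophilic") -> list[SiteIndices]:
    """Order sites by dominance in the requested role.

    Pure sites of the requested class come first, strongest (largest |R_k|)
    leading; ambiphilic sites follow (they can act in either role but do not
    dominate a committed site); opposite-class sites come last.  Ties break
    toward the lower atom index.
    """
    if mode not in ("nucleophilic", "electrophilic"):
        raise ValueError(f"mode must be nucleophilic or electrophilic, "
                         f"got {mode!r}")
    classified = [s for s in sites if s.r_k is not None and s.site_class]
    if not classified:
        log.warning("no classified sites to rank")
        return []

    def key(s: SiteIndices):
        if s.site_class == mode:
            role_rank = 0
        elif s.site_class == "ambiphilic":
            role_rank = 1
        else:
            role_rank = 2
        return (role_rank, -abs(s.r_k), s.atom.index)

    ordered = sorted(classified, key=key)
    for a, b in zip(ordered, ordered[1:]):
        if a.site_class == b.site_class and a.r_k == b.r_k:
            log.info("sites %s and %s tie at R_k = %s; lower index first",
                     a.label, b.label, a.r_k)
    return ordered
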