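"""Regiochemical pathway prediction from site-level descriptors.

For a polar cycloaddition the favoured regiochemistry couples the dominant
nucleophilic site of the dipole with the dominant electrophilic site of the
dipolarophile (two-center complementarity).  Each candidate pathway is a
named list of site pairs — its first pair is the primary forming bond — and
is scored by how complementary that primary pair is:

    score = nucleophilic strength of the dipole site
          + electrophilic strength of the dipolarophile site

where a pure site contributes |R_k| in its own role and -|R_k| in the
opposite role, and an ambiphilic site contributes its magnitude in either
role (it can be switched off).  The score is a heuristic ranking device —
reported alongside the raw descriptors, not an energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .global_indices import compute_global
from .local_indices import SiteIndices, compute_sites
from .species_io import SpeciesRecord

log = logging.getLogger(__name__)

PairingMap = Mapping[str, Sequence[tuple[str, str]]]


@dataclass(frozen=True)
class PathwayPrediction:
    dipole_site: str
    dipolarophile_site: str
    second_pair: Optional[tuple[str, str]]
    path_label: str
    score: float              # eV
    ranked_alternatives: tuple[tuple[str, float], ...]


def _site_map(sites: Sequence[SiteIndices]) -> dict[str, SiteIndices]:
    return {s.label: s for s in sites}


def _role_strength(site: SiteIndices, role: str,
                   include_ambiphilic: bool) -> float:
    if site.r_k is None or site.site_class is None:
        raise ValueError(f"site {site.label!r} has no R_k classification")
    if site.site_class == "ambiphilic":
        return abs(site.r_k) if include_ambiphilic else 0.0
    if site.site_class == role:
        return abs(site.r_k)
    return -abs(site.r_k)


def predict(dipole_sites: Sequence[SiteIndices],
            dipolarophile_sites: Sequence[SiteIndices],
            pairing_map: PairingMap,
            include_ambiphilic: bool = True) -> PathwayPrediction:
    """Score every pathway in ``pairing_map`` and return the best.

    ``pairing_map`` maps a pathway label to its site pairs
    ``(dipole_label, dipolarophile_label)``; the first pair of each pathway
    is the primary forming bond that gets scored.  Ties are broken by
    lexicographic pathway label, with a warning.
    """
    if not pairing_map:
        raise ValueError("pairing_map must name at least one pathway")
    dmap = _site_map(dipole_sites)
    pmap = _site_map(dipolarophile_sites)

    scores: list[tuple[str, float]] = []
    for label, pairs in pairing_map.items():
        if not pairs:
            raise ValueError(f"pathway {label!r} lists no site pairs")
        d_label, p_label = pairs[0]
        if d_label not in dmap:
            raise KeyError(f"pathway {label!r}: unknown dipole site "
                           f"{d_label!r} (have {sorted(dmap)})")
        if p_label not in pmap:
            raise KeyError(f"pathway {label!r}: unknown dipolarophile site "
                           f"{p_label!r} (have {sorted(pmap)})")
        score = (_role_strength(dmap[d_label], "nucleophilic",
                                include_ambiphilic)
                 + _role_strength(pmap[p_label], "electrophilic",
                                  include_ambiphilic))
        scores.append((label, score))

    scores.sort(key=lambda t: (-t[1], t[0]))
    if len(scores) > 1 and scores[0][1] == scores[1][1]:
        log.warning("pathways %r and %r tie at score %.3f; lexicographic "
                    "order decides", scores[0][0], scores[1][0], scores[0][1])

    best_label, best_score = scores[0]
    best_pairs = list(pairing_map[best_label])
    return PathwayPrediction(
        dipole_site=best_pairs[0][0],
        dipolarophile_site=best_pairs[0][1],
        second_pair=tuple(best_pairs[1]) if len(best_pairs) > 1 else None,
        path_label=best_label,
        score=best_score,
        ranked_alternatives=tuple(scores),
    )


def predict_from_records(dipole: SpeciesRecord,
                         dipolarophile: SpeciesRecord,
                         pairing_map: PairingMap,
                         include_ambiphilic: bool = True,
                         **global_kwargs) -> PathwayPrediction:
    """Convenience wrapper: compute globals and site indices for both
    records, then rank the pathways."""
    d_sites = compute_sites(dipole, compute_global(dipole.orbitals,
                                                   **global_kwargs))
    p_sites = compute_sites(dipolarophile,
                            compute_global(dipolarophile.orbitals,
                                           **global_kwargs))
    return predict(d_sites, p_sites, pairing_map, include_ambiphilic)
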