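#!/usr/bin/env python
"""Transition-state energetics, GEDT polarity and the GEDT correlation.

Recomputes the reaction entropies from the printed enthalpy/free-energy
split, tabulates activation barriers, asynchronicities and GEDT for the
four candidate pathways of the parent reaction, and fits the activation
free energy against GEDT; a synthetic seeded ensemble checks the fit
recovers a known slope. Tables go under results/.

Finding: both beta-attack (endo) transition states lie 2-3 kcal/mol below
the alpha-attack ones in dG_act, carry the larger GEDT (0.32 e vs 0.27 e)
and are markedly more synchronous (dR 0.36-0.38 vs 0.81 A); dG_act
correlates with GEDT at R^2 = 0.97.
"""

from pathlib import Path

import pandas as pd

from cdftkit.cli_report import round_half_away
from cdftkit.reference import load_reference
from cdftkit.synthetic_data import SynthConfig, make_ts_set
from cdftkit.ts_energetics import gedt, gedt_regression, reaction_entropy

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    ref = load_reference()

    rows = []
    for t in ref.transition_states:
        rows.append({
            "pathway": t.pathway, "e_a": t.e_a,
            "dH_rxn": t.dH_rxn, "dG_rxn": t.dG_rxn, "dE_rxn": t.dE_rxn,
            "dH_act": t.dH_act, "dG_act": t.dG_act,
            "dS_recomputed": round_half_away(
                reaction_entropy(t.dH_rxn, t.dG_rxn, ref.temperature_K), 2),
            "dS_printed": t.dS,
            "dR": t.dR, "gedt": t.gedt,
        })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "ts_energetics.csv", index=False)

    fit = gedt_regression([(t.gedt, t.dG_act)
                           for t in ref.transition_states])
    pd.DataFrame([{"slope": round_half_away(fit.slope, 2),
                   "intercept": round_half_away(fit.intercept, 2),
                   "r_squared": round_half_away(fit.r_squared, 4),
                   "n": fit.n}]).to_csv(OUT / "gedt_fit.csv", index=False)

    cfg = SynthConfig(seed=7, n_ts=50, noise_sd=0.3, gedt_slope=-55.0)
    synth_fit = gedt_regression([(gedt(ts)[0], ts.thermo.G)
                                 for ts in make_ts_set(cfg)])

    best = table.loc[table["dG_act"].idxmin()]
    print(f"lowest barrier: {best['pathway']} "
          f"(dG_act = {best['dG_act']} kcal/mol, GEDT = {best['gedt']} e, "
          f"dR = {best['dR']} A)")
    print(f"GEDT regression: slope = {fit.slope:.2f} kcal/mol/e, "
          f"R^2 = {fit.r_squared:.2f} (n = {fit.n})")
    print(f"synthetic check (seed 7, n=50, sigma=0.3): recovered slope "
          f"{synth_fit.slope:.2f} vs programmed -55.00")
    print(f"wrote {OUT / 'ts_energetics.csv'} and {OUT / 'gedt_fit.csv'}")


if __name__ == "__main__":
    main()
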