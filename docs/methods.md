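# Methods

`cdftkit` post-processes scalar quantum-chemistry outputs into conceptual-DFT
reactivity descriptors for polar [3+2] cycloadditions. Nothing electronic-
structure-related is computed here: the inputs are frontier orbital energies,
condensed per-atom electron populations of the N, N+1 and N−1 electron states,
atomic spin densities of the radical ions, and natural atomic charges plus
forming-bond geometry at transition states. The bundled benchmark covers the
cycloaddition of 9-diazo-9H-fluorene (DF, a carbon-centred diazo dipole) with
the E/Z isomers of seven 4-arylidene-1-phenylpyrazolidine-3,5-diones (APPs,
electron-poor exocyclic alkenes).

## Global descriptors

With the frontier-orbital approximations I = −E_HOMO and A = −E_LUMO (eV):

- chemical potential μ = −(I+A)/2, electronegativity χ = −μ;
- hardness η = I − A (eV), softness S = 1/η reported in atomic units, the
  conversion 27.2114 eV/hartree being applied internally;
- electrophilicity ω = μ²/2η; electroaccepting/electrodonating powers
  ω⁺ = A²/2η, ω⁻ = I²/2η; net electrophilicity Δω± = ω⁺ + ω⁻. The identity
  ω⁻ − ω⁺ = χ holds algebraically and is property-tested;
- nucleophilicity N = E_HOMO − E_HOMO(ref), with the tetracyanoethylene HOMO
  (−0.34586 hartree at the benchmark's level of theory) as reference zero;
  alternative scales N′ = 1/ω and N″ = 10/ω⁻.

The electrophile classifier uses configurable cutoffs on ω, default
(0.80, 1.50) eV (marginal / moderate / strong): these are the common
literature values; the benchmark's source tables use an unstated scale that
labels the diazo dipole "marginal" at ω = 1.974 eV, so the classifier
records which cutoffs produced a label rather than hard-coding that reading.

Pair analysis: electron demand is decided by the smaller of the two
HOMO–LUMO gaps (dipole→dipolarophile vs reverse); exact ties report inverse
with a warning. Polarity compares Δω = |ω₁ − ω₂| with a 4.5 eV threshold;
the default direction (Δω below threshold ⇒ polar one-step) follows the
source analysis of this series, and a flag selects the conventional reading
(larger Δω ⇒ more polar). Donor/acceptor roles are assigned by larger N,
with a warning when the ω ordering disagrees.

## Local descriptors

Fukui functions are condensed finite differences over electron populations
p: f⁺ = p(N+1) − p(N), f⁻ = p(N) − p(N−1). A loader option accepts atomic
charges q instead; storing p = −q reproduces every population difference, so
the descriptor algebra is unchanged (with charges the same formulas read
f⁺ = q(N) − q(N+1), f⁻ = q(N−1) − q(N), and only this population-convention
reading makes Σf = +1).

From the Fukui pair: dual descriptor f⁽²⁾ = f⁺ − f⁻ (negative at
nucleophilic, positive at electrophilic sites), philicities ω_k± = ω·f±,
multiphilic descriptor Δω_k = ω·f⁽²⁾, local softnesses s_k± = S·f±, dual
softness Δs_k = S·f⁽²⁾ and hypersoftness s⁽²⁾_k = S²·f⁽²⁾. From the Parr
functions (spin densities of the radical anion P⁺ and cation P⁻, taken as
supplied, with no renormalization — tabulated heavy-atom subsets do not sum
to 1): local electrophilicity ω_k = ω·P⁺ and local nucleophilicity
N_k = N·P⁻.

The conditional R_k classifier: when ω_k > 0, N_k > 0 and the ratio either
way lies strictly inside (1, 2), the site is ambiphilic with
R_k = (ω_k + N_k)/2 reported as a magnitude with a ± flag; otherwise
R_k = ω_k − N_k, negative ⇒ nucleophilic, positive ⇒ electrophilic. The
ratio test is skipped when either input is non-positive (a mixed-sign ratio
cannot indicate ambiphilicity), and R_k = 0 exactly reports ambiphilic with
a warning. Boundary ratios of exactly 1 or 2 fall to the difference branch.

Site ranking orders pure sites of the requested role first by |R_k|, then
ambiphilic sites, then opposite-role sites, ties toward the lower atom
index. Ambiphilic sites rank behind committed ones: in the benchmark the
dipole's ambiphilic N5 (±1.35) must not displace the committed nucleophilic
C3 (−0.96) as the reactive centre, which is also the chemically observed
outcome.

## Regiochemical prediction

Candidate pathways are named lists of site pairs; the first pair is the
primary forming bond. The score of a pathway is the nucleophilic strength
of its dipole site plus the electrophilic strength of its dipolarophile
site, where a pure site contributes |R_k| in its own role and −|R_k| in the
opposite role, and an ambiphilic site contributes |R_k| in either role
(excludable by flag). The source analysis states only the qualitative
matching rule — couple the most nucleophilic dipole site with the most
electrophilic dipolarophile site — so the numeric score is declared a
heuristic ranking device and is reported alongside the raw descriptors.
Ties break lexicographically on the pathway label, with a warning.

## Transition-state analysis

GEDT is evaluated as the mean of the two fragment-charge magnitudes
(|Σq_f1| + |Σq_f2|)/2: for a neutral supersystem this equals the usual
single-fragment sum exactly, it makes the value invariant under swapping
fragment labels, and for supersystems that are non-neutral beyond 0.01 e it
coincides with the documented mean-of-magnitudes fallback (loud warning by
default, strict mode raises). The donor is the fragment with net positive
charge.

Thermochemistry accepts absolute records (activation = TS − Σreactants,
reaction = product − Σreactants) or pre-formed deltas, never mixed. The
reaction entropy is recovered from ΔS = (ΔH − ΔG)·1000/T (cal mol⁻¹ K⁻¹) at
T = 298.15 K; this identity reproduces the benchmark's printed ΔS column.
Asynchronicity ΔR is the absolute difference of the two forming-bond
lengths. The GEDT–ΔG‡ relationship is an unweighted ordinary least squares
fit (scipy), R² being the squared Pearson correlation; it requires at
least three points and non-degenerate GEDT.

## Synthetic data

The generator produces study-shaped mock data for testing without any
quantum-chemistry run. Orbital energies are uniform on the windows the
benchmark species span (HOMO ∈ [−6.5, −5.5] eV, LUMO ∈ [−3.7, −1.9] eV).
Populations are integer baselines plus unit-sum increment vectors, so
Σf⁺ = Σf⁻ = 1 holds by construction (a `realistic` flag adds ~0.004
per-atom leakage to exercise the tolerance paths); spin densities are
normalized to unit sum. TS ensembles draw GEDT on [0.1, 0.5] e, give each
fragment four charges summing exactly to ±GEDT, and set
ΔG‡ = 56 − 55·GEDT + N(0, σ) kcal/mol with σ = 0.3 by default — the slope
matching the −55.9 kcal mol⁻¹ e⁻¹ the four benchmark pathways imply, the
intercept placing barriers in their 38–42 kcal/mol window. Each record uses
a counter-derived substream (`default_rng([seed, stream, index])`) so the
record count never reshuffles earlier records.

What the generator does not emulate: real condensed populations only
approximately obey the sum rules, Parr functions can exceed [0, 1] and take
larger negative values, orbital energies correlate with substituents, and
TS charges have spatial structure. Passing tests on synthetic data
therefore certify the descriptor algebra and plumbing, not the physics of
any particular system; the benchmark tables carry that burden.

## Numerical choices

- Unit conversion fixed at 27.2114 eV/hartree (reproduces the benchmark's
  N = 3.664 eV for the dipole from the TCE reference).
- Report tables round half away from zero, 3 decimals (R_k: 2); internal
  computation is full precision, derived columns are always recomputed from
  inputs and never read from files.
- Fukui sum-rule tolerance defaults to 0.02 (condensed schemes rarely sum
  exactly to 1); failing records are flagged partial-site with a warning
  rather than rejected, unless strict mode is on.
- ω = 0 makes N′ undefined: reported as missing with a warning. η ≤ 0 is a
  domain error (unreachable for validated orbital records).

## Benchmark data and its known misprints

The reference tables ship in `src/cdftkit/data/dispiro_cycloaddition.json`.
Species records rebuilt from it use a synthetic flat baseline population
(4.0 e/atom) because only Fukui differences are published; the finite
differences, and hence every descriptor, are unaffected, and the records
are flagged partial-site (heavy-atom subsets only).

Validation excludes exactly the entries where the source tables are
internally inconsistent, each flagged in the data file:

- on every site row with a negative printed f⁻ (the dipole N4 and most C1
  rows), the printed f⁽²⁾ equals f⁺ − |f⁻| rather than f⁺ − f⁻, while the
  printed ω_k⁻/s_k⁻ follow the true sign; the definitional f⁽²⁾ = f⁺ − f⁻
  is implemented and the f⁽²⁾-from-f± check is skipped on those rows (the
  scaled columns are still checked against the printed f⁽²⁾ they derive
  from);
- the printed softness of two species (E-3d, E-3g) disagrees with the same
  table's own η by ~0.014 a.u., beyond the ±0.01 band that covers every
  other row;
- one printed net-electrophilicity entry (Z-3g) is the sum of the two
  already-rounded addends and misses the recomputed value by 0.0023 eV
  (tolerance elsewhere: 0.002);
- one printed reaction entropy (alpha-attack exo pathway) differs from
  (ΔH−ΔG)/T applied to its own row by 0.018; the other three reproduce at
  two decimals.

The smallest electrophilicity difference of the series recomputes to
0.753 eV versus the 0.754 eV quoted from rounded table values; the largest
(2.509 eV) reproduces exactly.

## Limitations

Frontier-orbital I and A only (no ΔSCF); no solvent model; no steric or
secondary-orbital energetics in the pathway score — systems whose
regiochemistry is sterically controlled will defeat pure descriptor
complementarity; the pathway score has been exercised on one reaction
series and is not calibrated as a general selectivity scale.
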