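# lncoord

Analysis toolkit for lanthanide-ion recognition by short chelating
peptides: trajectory-based coordination-state classification, solvation
shell statistics, distance free-energy landscapes, and isothermal titration
calorimetry (ITC) thermodynamics across the Ln³⁺ series.

## The scientific problem

A 17-residue lanthanide-binding peptide (LBT3, calmodulin-derived)
coordinates a trivalent lanthanide through six donor oxygens — D3-Oγ1,
N5-Oδ1, D7-Oγ1, the W9 backbone carbonyl, and the E11/E14 carboxylates.
Although the Ln³⁺ ionic radius contracts by less than 0.26 Å from La to
Lu, the peptide's affinity varies by well over an order of magnitude
along the series.  The mechanistic picture this package quantifies is that
the discrimination is *structural*: for the large early lanthanides the
weakest donor (N5-Oδ1, a dipole–ion contact) transiently dissociates and
water invades the first coordination shell, while the small late
lanthanides stay fully wrapped.

`lncoord` provides the quantitative machinery for that analysis:

- **Coordination calling with hysteresis.**  A donor is called bound below
  `r_on` = 0.3 nm and released above `r_off` = 0.4 nm; inside the gap the
  previous state is retained, which suppresses chattering near a single
  cutoff.
- **Complex-state classification.**  Each frame is assigned one of five
  states from the N5-Oδ1 state and the first-shell water count *w*:
  (i) N5 bound, w=0; (ii) N5 bound, w=1; (iii) N5 unbound, w=1 (the water
  hydrogen-bonds to the freed N5-Oδ1); (iv) N5 unbound, w=2; (v) N5
  unbound, w=0 — plus `broken`/`other` catch-alls.  Transitions are
  audited against the allowed edge set {i⇄ii, ii⇄iii, iii⇄iv, i⇄v, v⇄iii}.
- **Chelation mode.**  A carboxylate is bidentate when both oxygens are
  within `r_chel` of the ion, monodentate when only one is.
- **Solvation.**  g(r) around a single reference atom,
  g(r) = ⟨n(r, r+dr)⟩ / (4πr²·dr·ρ), with running coordination number and
  first-minimum search to delimit the first shell.
- **Free-energy profiles.**  F(r) = −RT ln h(r) (+ optional removal of the
  2RT ln r radial Jacobian) from optionally reweighted distance samples,
  with associated/dissociated basin-depth differences.
- **ITC.**  The one-site (Wiseman) isotherm with the instrument-style
  half-volume displacement correction; nonlinear least squares for
  (N, K, ΔH) with multistart initialisation, the fixed-N = 1.0 fallback for
  non-sigmoidal (c = N·K·[M]₀ < 1) data, and ΔG = −RT ln K,
  −TΔS = ΔG − ΔH.
- **Series decomposition.**  ΔΔ quantities between ions
  (ΔΔG = ΔΔH + (−TΔΔS)), branch-point detection in ΔH/ΔS trends along
  La…Lu, and the three-regime classification (I: La–Sm, II: Sm–Yb split at
  Tb into IIa/IIb, III: Lu) with explicit dual membership for the boundary
  ions.

Because deposited MD trajectories and raw thermograms are not available, a
first-class synthetic generator emits labelled trajectories (a
continuous-time Markov chain over states i–v plus a geometric emission
model around the 2.1–3.0 Å donor restraint window) and noisy one-site
thermograms, so every stage is testable against ground truth.

## Worked example

```python
import numpy as np
from lncoord.itc import ITCProtocol, fit_one_site
from lncoord.synthetic import generate_itc_thermogram, generate_ln_series_table
from lncoord.series_thermo import (detect_branch_points, classify_regimes,
                                   validate_series_table)

# La-like titration at 10 degC: 15 uM peptide cell, 300 uM Ln3+ syringe,
# 20 injections; K chosen so dG ~ -6.9 kcal/mol, dH = +3.83 kcal/mol
exp = generate_itc_thermogram((1.0, 2.1e5, 3.83), ITCProtocol(),
                              noise_sd=0.1, seed=1)
fit = fit_one_site(exp)
print(f"N = {fit.N:.3f}   K = {fit.K:.3g} 1/M   c = {fit.c_value:.2f}")
print(f"dH = {fit.dH:.2f}  dG = {fit.dG:.2f}  -TdS = {fit.mTdS:.2f}  kcal/mol")

table = generate_ln_series_table()
branches = detect_branch_points(validate_series_table(table)["dH"].to_numpy())
print("branch ions:", branches)
reg = classify_regimes(table, branches)
print("regime I:", reg.ions_in("I"))
print("dual membership:", reg.dual_membership)
```

prints

```
N = 1.002   K = 2.13e+05 1/M   c = 3.20
dH = 3.82  dG = -6.90  -TdS = -10.73  kcal/mol
branch ions: ['Sm', 'Yb']
regime I: ('La', 'Ce', 'Pr', 'Nd', 'Pm', 'Sm')
dual membership: ('Sm', 'Tb')
```

The fit recovers the generating parameters (an endothermic, entropy-driven
binding: ΔH > 0 with a large favourable −TΔS), the ΔH trend along the
series turns at Sm and Yb, and the regime classification places La…Sm in
regime I with Sm and Tb shared between adjacent regimes.

The structural track is symmetric: `generate_complex_trajectory` emits a
labelled trajectory, `distance_series` → `hysteresis_states` →
`water_coordination_count` → `classify_complex_state` recover the state
path, and `transition_stats` audits occupancies and transition edges.
A command line mirrors the library
(`lncoord simulate-traj|simulate-itc|convert|coordinate|rdf|pmf|itc-fit|series|run`).

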