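# Methods

## Scope and units

All structural analysis works on frames of Cartesian coordinates with an
orthorhombic periodic box.  Internal units are nm (coordinates, box, all
cutoffs), ps (time), kelvin, and kcal/mol (energies, with
R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹).  PDB files are read and written in
angstrom and converted at the boundary; XYZ trajectories carry a declared
unit and a plain-text sidecar file with one box-edge triple per frame.
Every interatomic distance in the package uses the minimum-image
convention; only orthorhombic (in practice cubic) boxes are supported.

## Coordination-state model

The peptide binds the ion through six donor oxygens.  Five of them (the
D3/D7 carboxylates, the W9 backbone carbonyl, and the E11/E14
carboxylates) are treated as integrity sites that remain bound in an
intact complex; the sixth, N5-Oδ1, is the switchable site whose
dissociation, together with the first-shell water count w, defines the
five complex states:

| state | N5-Oδ1 | w |
|-------|--------|---|
| i     | bound  | 0 |
| ii    | bound  | 1 |
| iii   | unbound| 1 |
| iv    | unbound| 2 |
| v     | unbound| 0 |

Frames where any integrity site has released the ion are labelled
`broken`; (N5, w) combinations outside the table (e.g. bound with w ≥ 2)
are labelled `other`.  These two catch-alls make the classifier total —
the five named states do not cover the full combinatorial space.
Carboxylate integrity is judged at the site level (either oxygen within
`r_chel`), matching per-residue binding language rather than per-oxygen
bookkeeping.

**Hysteresis calling.**  N5-Oδ1 (or any donor) is called from its distance
series with two thresholds: bound below `r_on` = 0.30 nm, unbound above
`r_off` = 0.40 nm, and state retention inside the gap.  The dual-threshold
rule is the natural reading of a coordination/dissociation boundary
described by two cutoffs with an unspecified 0.3–0.4 nm region: memory
resolves the gap without chattering.  A first frame falling in the gap
takes the label of the nearer threshold, with an exact (floating-point
tolerant) tie resolving to unbound.  The classification is idempotent:
distances strictly inside a state's retention band never change the
label sequence.

**Transition audit.**  Adjacent-frame label changes are counted and
compared against the allowed edge set {i⇄ii, ii⇄iii, iii⇄iv, i⇄v, v⇄iii}.
Off-path transitions are reported, not rejected, because frame-sampled
output can skip a short-lived intermediate and legitimately show e.g.
i→iii.

**Cutoffs.**  `r_water` (first-shell water membership) defaults to
0.30 nm, consistent with the donor window; no published value for the
"direct coordination" cutoff exists, so it is configurable and can be
cross-checked against the first minimum of the ion–water g(r)
(`solvation.first_minimum`), which on generated one-water systems falls at
0.28–0.36 nm.  `r_chel` defaults to 0.30 nm.

## Solvation statistics

g(r) is estimated around a *single* reference atom (the ion, or an amide
proton used as an NMR-visible probe), not site–site averaged, because the
questions posed are about one ion and one proton.  Normalisation uses the
ideal-shell volume 4πr²dr at the mean target density ρ = N/⟨V⟩; the exact
bin-sphere intersection is not used, a deliberate simplification whose
bias is O((dr/r)²) — negligible at the default dr = 0.002 nm and small
(≲1.5%) even at the coarse dr used where counting statistics demand wide
bins.  The running coordination number integrates g(r) and agrees with
the direct mean count within binning error; this identity is tested at
the 1% level.  The first-minimum search smooths g with a 3-bin moving
average and scans for the first local minimum after the first maximum;
monotone profiles raise an explicit no-minimum error.

## Free-energy profiles

F(r) = −RT[ln h(r) − 2 ln r·(jacobian)] + C from a weighted histogram h,
with C chosen so min F = 0 and empty bins carrying NaN rather than a
fake zero.  The radial Jacobian correction is ON by default — for a
distance coordinate in 3-D the r² volume factor is entropic, not
energetic — but both conventions are supported and recorded in the
result, since published landscapes do not always state which they use.
Weights allow samples produced under a known bias b(r) to be reweighted
with w ∝ exp(+b/RT); adaptive-bias sampling itself (AWH/umbrella
machinery) is out of scope — this module consumes its output.  Basin
depths are window minima over the associated ([0.20, 0.30] nm) and
dissociated ([0.40, 0.70] nm) windows, chosen to bracket the hysteresis
thresholds; ΔF = F_dissoc − F_assoc is positive when association is
favoured.  The literature depth values for such landscapes come from
hundreds of ns of biased all-atom MD with backbone restraints and are
not reproducible at desk scale; correctness here is established instead
on constructed ensembles with known answers (harmonic curvature within
5% at 10⁶ samples, an analytic 2.5 kcal/mol double-well gap within
0.05 kcal/mol, exact Jacobian cancellation on shell-uniform samples).

## ITC model and fitting

The one-site isotherm solves, per injection, the quadratic
Θ² − Θ(1 + X/(N·M) + 1/(N·K·M)) + X/(N·M) = 0 on [0, min(1, X/(N·M))],
with cell concentrations diluted by the half-volume displacement rule
M_i = M₀(1 − dV/2V₀)/(1 + dV/2V₀), X_i = X₀(dV/V₀)/(1 + dV/2V₀), total
heat Q_i = N·Θ_i·M_i·ΔH·V₀ and measured injection heat
q_i = Q_i − Q_{i−1} + (v_i/V₀)(Q_i + Q_{i−1})/2.  This mirrors the
convention of instrument analysis software; a no-displacement mode
(constant M, q_i = Q_i − Q_{i−1}) exists because in it the heats sum
exactly to the total binding heat, which makes conservation checks crisp.

The default protocol is a 10 °C titration with 15 µM macromolecule in a
1.4 mL cell, 300 µM ligand in the syringe, and 20 injections (2 µL
pre-injection + 19×10 µL).  The cell volume is an instrument default, not
a published number; it scales heats but cancels in parameter recovery
when generation and fitting share it.  The first injection is excluded
from fit residuals by default (standard practice for the pre-injection)
while still entering the cumulative-volume bookkeeping.

Fitting is least squares over (N, log₁₀K, ΔH) — or (log₁₀K, ΔH) with N
fixed — with multistart over a log K grid to avoid local minima.  The
Wiseman c = N·K·[M]₀ is reported, and c < 1 emits a non-sigmoidal warning
recommending the fixed-N = 1.0 refit, the conventional remedy when the
isotherm shape carries no stoichiometry information.

## Series decomposition

ΔΔ quantities are plain component-wise differences with the identity
ΔΔG = ΔΔH + (−TΔΔS) holding by construction; the sign convention is
always −TΔS (a +TΔΔS literature value must be negated before summing).
Branch detection scans successive differences; steps with |d| ≤ tol
(default 0.05 kcal/mol) inherit the prior direction, so a −0.01 kcal/mol
"no change" step does not create a spurious branch.  Regime
classification takes the detected branch ions: I = La through the first
branch, II = first branch through the second, split at Tb into IIa/IIb,
III = after the second branch.  Because the class boundaries are
inclusive on both sides, Sm and Tb genuinely belong to two classes each;
this is represented as explicit dual membership rather than forcing a
partition.

## The synthetic generator

The generator is an explicit emission model, not an MD surrogate.  Its
job is to produce data with exactly the statistical structure the
analyses assume, with known labels.

- **State dynamics.**  A continuous-time Markov chain over states i–v,
  restricted to the allowed edges, simulated with exact event times
  (Gillespie) and then discretised at the frame interval (default
  dt = 10 ps).  Dwells shorter than a frame are therefore invisible in
  the sampled labels, as in real frame-written MD output.  An optional
  minimum dwell conditions every holding time on exceeding a floor
  (exact by memorylessness: floor + Exp(rate)); it implements the
  "dwell ≥ n frames" study condition used in recovery tests.  N5 binding
  and the water count follow deterministically from the state (table
  above).  No published residence-time statistics exist for these
  states; the default rates (0.2–0.6 ns⁻¹ per directed edge) are chosen
  to give 1–3 ns mean dwells — long against the frame interval, short
  against test-scale trajectories — and are flagged as arbitrary.
- **Geometry.**  Ion at the box centre; six donors on fixed
  near-octahedral directions with small angular jitter, at distances
  N(μ, σ) truncated at ±3σ, with bound μ tied to ion size as
  (ionic radius + 1.40 Å)/10 nm (oxygen contact radius) — this makes the
  mean donor distance contract monotonically La→Lu by construction —
  and σ = 0.01 nm, inside the 2.1–3.0 Å coordination-restraint window;
  unbound μ = 0.50 nm, σ = 0.04 nm.  Carboxylate partner oxygens keep a
  0.22 nm O–O separation, placed symmetric about the donor direction
  (bidentate, both within cutoff) or radially outward (monodentate,
  partner at ~0.47 nm).  Each carboxylate carries an independent
  two-state mono⇄bi chain (default 0.5 ns⁻¹ each way).  Bound waters sit
  at N(0.25, 0.012) nm from the ion, the state-iii water on the N5 axis
  (hydrogen-bond distance ≤ 0.35 nm from the freed N5-Oδ1); one
  designated water tracks the D3 chelation mode near the G8-HN probe
  (0.25 nm when bidentate, 0.45 nm when monodentate), emulating the
  coupling between carboxylate orientation and water access to the amide.
  Remaining waters are uniform in the box outside a 0.35 nm solute
  exclusion radius.  The default box (4.3 nm cube, 2589 waters) matches
  full solvation of such a complex; tests use far fewer waters since the
  analyses are insensitive to bulk count.
- **What it does not emulate.**  No forces or energies, no temporal
  correlation within a state (coordinates are i.i.d. per frame given the
  state; an Ornstein–Uhlenbeck option was considered and left out as the
  analyses assume nothing about autocorrelation), no peptide backbone,
  no hydrogens beyond the two probe protons, no counterions, and no
  water–water structure (bulk waters may overlap).  Consequently,
  passing recovery tests demonstrates the correctness of the
  classifiers and estimators under the stated geometric/kinetic
  assumptions — not that those assumptions hold in any particular
  force field's trajectories.
- **Thermograms.**  Forward one-site heats plus i.i.d. Gaussian noise;
  true parameters travel with the experiment for recovery tests.
- **Series tables.**  ΔH and −TΔS follow piecewise-linear trends over
  La…Lu anchored at ΔH(La) = 3.83 and ΔG(La) = −6.9 kcal/mol with the
  published main-text segment totals (so the down–up–down ΔH/ΔS shape
  with turns at Sm and Yb holds by construction); ΔG is the row-wise
  sum, K_D follows from ΔG at 283.15 K, and the packaged ionic radii are
  Shannon 8-coordinate values (only their ordering and < 0.26 Å spread
  are relied on).

Determinism: all generators take a seed; trajectories are bitwise
reproducible, with independent substreams for the state path and the
coordinate emission so ground truth can be resampled without
regenerating coordinates.

## Numerical and design choices

- Selection grammar (`resid`/`resname`/`name` with and/or/not and
  parentheses) is a deliberate minimal subset; resolution is
  deterministic and empty selections are legal values, not errors.
- PDB I/O delegates to biotite (multi-model MODEL/ENDMDL, CRYST1);
  round trips are exact to 10⁻³ nm (the format's 3-decimal angstrom
  field).  A missing box is an error, never a silent infinite box.
- Test problem sizes (10⁴-frame recovery runs, 10⁵-sample RDFs,
  10⁶-sample free-energy ensembles) are chosen so that statistical
  tolerances in the tests sit at ≥3 standard errors from their
  thresholds; RDF flatness checks use coarse bins sized so every bin
  past 0.2 nm holds thousands of expected counts.  Comparisons across
  the 15-ion sweep use common random numbers (one seed for all ions) so
  the radius-tied shift is isolated from sampling noise.
- The `lncoord` CLI is a thin layer over the library: subcommands per
  stage, a YAML-configured demo pipeline that echoes its resolved
  config and writes a summary JSON (version, seed, parameters), exit
  codes 0/1/2 for ok/analysis error/usage error, logs to stderr.

## Known limitations

- Chelation classification is purely distance-based; no angular
  (ion–O–C) criterion, so near-cutoff geometries can flicker between
  modes — mitigated in practice by the generator's well-separated
  mono/bi geometries but a real limitation on borderline MD data.
- The RDF reference is one atom; ensembles of equivalent sites must be
  averaged by the caller.
- The free-energy module reweights externally biased samples but cannot
  generate biases, and supports only one-dimensional (distance)
  coordinates.
- Regime classification assumes the canonical two-branch topology; other
  branch counts fall back to a single regime (with a warning) or use the
  first two branches.
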