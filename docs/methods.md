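# Methods

## The linkage model

A kinase is treated as a two-state ensemble: an *active* (open) and an
*inactive* (closed, or "closing-competent") conformation, exchanging fast on
the experimental timescale. The unliganded active/inactive population ratio
is `K_eq` (so `K_eq = 0.67` means 40 % active). Two ligand sites — an
orthosteric (ATP-site) inhibitor O and an allosteric modulator A — bind each
conformation with its own dissociation constant, giving eight species.
Relative to inactive-apo = 1, the statistical weights are

```
state s in {inactive, active},  w_inactive = 1,  w_active = K_eq
single-bound:   w_s * [X]/Kd_X,s          (X = O or A, free concentration)
doubly bound:   w_s * [O]/Kd_O,s * [A]/Kd_A,s * c_s
```

with an intrastate coupling factor `c_s` (default 1) multiplying the
doubly-bound weight. With both couplings at 1 the two ligands interact only
through the conformational equilibrium (pure conformational selection);
`c_s != 1` encodes direct interaction between the two bound ligands within
state `s`. `Kd = inf` means "does not bind that state". All concentrations
in the linkage layer are *free* concentrations in nM; conversion to totals
happens only through the mass-balance solvers.

The apparent (ensemble-averaged) dissociation constant of one site at fixed
free partner concentration is the exact ratio of the site-empty to
site-occupied partition-function branches,

```
Kd_app(O; A) = sum_s w_s (1 + A/Kd_A,s)  /  sum_s (w_s/Kd_O,s)(1 + c_s A/Kd_A,s)
```

and "saturating partner" is evaluated as the analytic limit of this
expression, never as a large number. The cooperativity factor is

```
alpha = Kd_app(partner absent) / Kd_app(partner saturating)
```

(`alpha > 1` positive, `< 1` negative); thermodynamic-cycle closure
guarantees the same alpha whichever site it is measured at, and the test
suite checks closure to 1e-9 on random models including couplings. Two
useful exact corollaries, both exercised by the tests:

* two inactive-exclusive ligands with couplings 1 give `alpha = 1 + K_eq` —
  the pure-conformational-selection ceiling (1.67 at `K_eq = 0.67`);
* a state-independent ligand factorises out of the partition function and
  shows `alpha = 1` regardless of the partner.

## Experiment forward models

**ITC.** Thermograms are simulated per injection: the working volume grows
by the injection volume (overfilled-cell convention), all concentrations
dilute accordingly, the one-site (or two-ligand competitive) mass balance is
re-solved, and the heat is the binding enthalpy times the change in *moles*
of complex, plus a constant per-injection offset. Under this convention the
cumulative heat at titrant excess converges exactly to
`n * dH * V0 * [cell]`, which is what makes integrated-heat sanity checks
clean; a strict displaced-volume treatment instead loses the heat of protein
expelled before it binds (several percent under typical schedules) and was
rejected for that reason. Units are centralised: heats uJ, enthalpies
kJ/mol, cell/syringe concentrations uM, ligand Kds nM, volumes uL. The
first injection is flagged for exclusion from fits, following instrument
practice. Competitive-replacement titrations (a too-tight ligand titrated
into protein pre-loaded with a weak same-site competitor, e.g. an ADP
analogue or a myristoylated peptide) are modelled mechanistically by the
full two-ligand mass balance each injection; the analytic shift
`Kd_app = Kd_strong (1 + [C]free/Kd_weak)` is kept as a cross-check and
agrees with the full solver to ~1 % at >= 50-fold competitor excess.

**FRET.** Fluorescence titrations at 10 nM enzyme are in the tight-binding
regime, so the signal model is the Morrison quadratic

```
F = F0 + A * ((I + Et + Kd) - sqrt((I + Et + Kd)^2 - 4 Et I)) / (2 Et)
```

i.e. baseline plus amplitude times the bound enzyme fraction with depletion
handled exactly. A fitted `Kd` well below `Et` is flagged: there the curve
approaches a step function and the estimate is an upper bound, which is why
tighter-Kd simulations look identical.

**Activity.** Rates are modelled under kcat/Km conditions (substrate far
below Km): `k_obs = k_max * sum(species_weight * population)`, with free
ligand concentrations obtained from the exact mass balance at the assay
enzyme concentration (20 nM default). Default catalytic weights: only
active-state species with an empty orthosteric site turn over — the
closing-competent conformation is catalytically silent, an orthosteric
ligand occludes the active site, and an allosteric ligand on the active
state leaves activity untouched. Substrate and ATP are not explicit
species; an ATP-induced equilibrium shift is representable only by
re-parameterising `K_eq` per condition, which is left to the caller.

Dose-response analysis uses the four-parameter logistic
`y = bottom + (top - bottom)/(1 + (x/ic50)^hill)`. The
(top, bottom, hill) <-> (bottom, top, -hill) symmetry is resolved by
canonicalising to `hill > 0` (for descending inhibition data this implies
`top >= bottom`; ascending curves keep their swapped plateaus, since no
positive-hill parameterisation can put the zero-dose value at the bottom).
The dose for a residual activity fraction r (e.g. the 10 %-residual dose) is
the closed-form 4PL inversion at `y = r * reference`, with the reference
taken per-curve (the same row's zero-inhibitor rate); a plateau above the
target raises an explicit "unreachable residual" error rather than
extrapolating. Synergy grids evaluate `k_obs` over an orthosteric x
allosteric dose matrix and report, per allosteric level, the orthosteric
dose reaching 10 % residual (from a 4PL fit of that row) and its
fold-reduction against the zero-allosteric row.

## Estimation

All fitters share one nonlinear least-squares core (Levenberg-Marquardt via
lmfit) with standard errors from the linearised covariance at the optimum;
the 68.3 % CI is reported as +-1 SE, the convention used for binding fits.
Non-convergence triggers a 5-start log-uniform multistart with a fixed
internal seed, so identical inputs always give identical outputs. ITC fit
starting values come from a thermogram heuristic (enthalpy from the early
plateau, stoichiometry from the half-heat molar ratio); a Wiseman c-value
(`n*[cell]/Kd`) outside [1, 1e4] is flagged as poorly identified rather than
failed. Quantities derived from inhibition curves use leave-one-out
jackknife errors, `SE = sqrt((n-1)/n * sum (theta_i - theta_bar)^2)`,
resampled over points. Global linkage fits estimate shared state-resolved
parameters jointly from apparent-Kd observations across conditions
(log-space residuals so disparate Kd scales weigh equally) and refuse
structurally unidentifiable maps — e.g. a single condition cannot constrain
two state affinities.

Numerical choices: the stable quadratic root `2PL/(b + sqrt(b^2 - 4PL))` for
bound complex; Brent bracketing on `[Kd_min*1e-6, Kd_max*1e6]` for
half-occupancy roots, with closed forms required to agree to 1e-9 relative;
the competitive cubic solved by Brent plus one Newton polish step and
required to conserve totals to 1e-10 relative; `c_total = 0` delegates
exactly to the one-ligand quadratic.

## Synthetic data and presets

Generators add instrument-like noise to the forward models — additive
Gaussian heat noise (uJ) for ITC, multiplicative fractional noise for
fluorescence and rates — and are pure functions of parameters and seed.
They emulate equilibrium readouts only: no raw power traces, no baseline
drift, no injection-timing artefacts, no pipetting error in the dose axes,
and no day-to-day instrument variation, so parameter-recovery results bound
statistical (not systematic) error; real titrations carry additional
uncertainty the generators do not model.

Presets encode the studied systems as linkage models pinned to their
published anchors, with every unprinted absolute value invented at a
realistic scale and labelled as such in the preset's provenance notes:

* **aura_mb1/2/3/6** — Aurora A (`K_eq = 0.67`) with danusertib
  (inactive-state binder; inactive Kd set so the apparent apo Kd equals the
  0.87 nM inhibition constant) and one monobody: Mb1 active-preferring with
  the state-preference ratio fixed by its 16-fold negative cooperativity;
  Mb2/Mb3 inactive-exclusive, the printed two/threefold positive
  cooperativity carried by the 1.67 selection ceiling times an
  inactive-state coupling; Mb6 state-independent (`alpha = 1`).
* **abl_kd_imatinib_asciminib** — isolated kinase domain, strongly
  open-shifted (`K_eq = 19`, invented). The 30 % saturating-asciminib
  inhibition fixes the asciminib closed/open preference at ~9.6; because a
  30 % plateau caps pure-selection negative cooperativity at
  `1/(1-0.30) = 1.43`, the printed twofold requires `coupling_active = 5/7`,
  the model's rendering of an additional equilibrium inside the kinase
  domain. The imatinib open-state Kd reproduces the printed 15 nM apparent.
* **abl64_510_imatinib_asciminib** — regulatory-domain construct
  (`K_eq = 3`, invented). With imatinib strictly open-exclusive, pure
  selection would force fold `= 1/(1-0.93) = 14.3`, incompatible with the
  printed fourfold; both anchors are satisfied with couplings 1 by giving
  imatinib a weak closed-state affinity (open preference ~6.6), and the
  93 % plateau fixes the asciminib closed/open ratio at ~54. The apparent
  imatinib Kd reproduces the printed 72.4 nM.
* **abl64_510_ski_asciminib** — SKI as a closed-state binder on an apo
  ensemble modelled as already far closed (`K_eq = 0.01`), so asciminib
  leaves the SKI affinity essentially unchanged (`alpha ~ 1`).

Plateaus are always interpreted as measured: percent inhibition relative to
the uninhibited rate, `1 - p_active(sat)/p_active(apo)`.

## Reference problem sizes

The recovery studies use 20 Monte-Carlo seeds each: paired 25-injection
thermograms (200 uL cell at 5 uM, 50 uM syringe, dH = -40 kJ/mol, heat noise
1 % of the largest injection heat) for cooperativity-fold recovery, and
12-point log-spaced dose-responses spanning 0.01-100x the apparent
allosteric Kd with 2 % rate noise for plateau recovery. Property checks run
on 100-1000 random models per invariant. The whole suite completes in a few
seconds on one CPU.

## Known limitations

* Exactly two conformational states and one ligand per site; no kinetics
  (everything is equilibrium), no substrate/ATP as explicit species, no
  Cheng-Prusoff IC50/Ki interconversion.
* The ITC heat model is an idealised overfilled-cell integrator, not a
  reimplementation of any vendor's (undocumented) dilution convention;
  absolute per-injection heats can differ from instrument software at the
  percent level even when fitted parameters agree.
* Preset absolute scales (monobody/asciminib state Kds, k_max) are invented
  anchors for simulation, not measurements; only the documented folds,
  plateaus and printed apparent Kds are reproduced quantities.
* The jackknife resamples points of a single curve; replicate-level
  variation is out of scope.
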