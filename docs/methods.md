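# Methods

This note records the models implemented in `idrkit`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical choices a maintainer would want to know.

## Disorder prediction and substitution scanning

Per-residue disorder is scored as

    score_i = σ( k · ( c0 + w_q·|⟨q⟩_i| − w_h·⟨H⟩_i ) )

where ⟨·⟩_i is the mean over a window of half-width *h* residues centred on
*i* (truncated, not mirrored, at the termini — the simplest well-defined
behaviour), *q* is formal side-chain charge (D/E = −1, K/R = +1, H = 0 at
the mildly basic pH of typical CD buffers), *H* is Kyte–Doolittle hydropathy
min–max normalised to [0, 1], and σ is the logistic function.  Defaults:
`w_h = 2.785`, `c0 = 1.151` (the FoldIndex pairing of hydropathy and
intercept), `w_q = 0.8`, steepness `k = 3`, `h = 10`.  Orientation is fixed
so higher = more disordered and 0.5 is the disorder boundary.

`w_q` is deliberately below `w_h · ΔH_norm(E→W) = 2.785 · 3.6/9 ≈ 0.805`.
Replacing an acidic residue with tryptophan changes each affected window's
charge magnitude by at most 1/|window| while raising its normalised
hydropathy term by 0.805/|window|, so with `w_q = 0.8 < 0.805` an E→W
substitution can never increase any score: the predictor is guaranteed to
rank aromatic substitutions as order-conferring, the qualitative behaviour
this class of predictor exists to capture.  (With the FoldIndex value
`w_q = 1`, a charge-dense window can invert that ordering.)

This is a composition surrogate, not a trained predictor: absolute scores
are not comparable to PONDR-family or IUPred outputs, and region averages
computed here should not be compared against values those tools report.
The scan procedure on top of it is predictor-agnostic: every variant is
re-scored in full and ranked by Δ = wild mean − variant mean (whole-sequence
mean by default; a `region` argument restricts the comparison window, since
either convention is defensible and callers may prefer the local one).
Ties break by position, then substitute residue, so output order is total
and reproducible.

Column conservation is 1 − H/ln 20 with gaps removed before the entropy;
all-gap columns report a missing score and columns >50 % gaps carry a
`high_gap` flag rather than being silently trusted.

## CD spectral arithmetic

Unit states (`millidegrees`, `MRE`, `ME`) are explicit tags; arithmetic
refuses mixed units and mismatched grids (no silent interpolation — a
separate `resample` exists).  The instrument signal `m°` is interpreted as
ellipticity in millidegrees, the conventional input to
`MRE = m°/(10·l·M·n)`; `ME = MRE/3298`, and the round trip is identity to
machine precision.

For a 1:1 mixture two normalisations are provided.  The `paper` convention
divides by `10·l·mean(M)·mean(n)` exactly as some protocols print it.  That
formula is internally inconsistent with the arithmetic-mean non-interacting
expectation: for a strictly additive, equal-molarity mixture it returns
roughly the sum rather than the mean of the component MREs.  The default
`total-residue` convention divides by `10·l·(M_A·n_A + M_B·n_B)`, under
which a strictly additive signal reproduces the concentration-weighted mean
of the component MREs exactly — so the difference spectrum
(expected − measured, mixture subtracted FROM the expectation, deviations
meaning induced structure) is identically zero for a non-interacting
mixture.  This null-interaction identity is the pipeline's internal
consistency contract and is enforced by tests; both conventions remain
available because reproducing published numbers may require the printed
form.

Dilution planning is plain conservation of moles.  Worth knowing: a
40 % v/v recipe of 160 µL co-solvent into 240 µL of 17 µM protein gives
10.2 µM, not the 10 µM such protocols nominally state; the planner reports
the exact arithmetic and leaves the 2 % discrepancy visible.

## Deconvolution

Fractions solve `min ‖y − Bf‖² + λ‖f‖²` on the probability simplex.  The
solver enumerates all non-empty supports (class subsets), solves each
equality-constrained reduced problem by null-space elimination of the
sum-to-one constraint, and keeps the feasible candidate with the lowest
objective.  Because the optimum restricted to its support satisfies exactly
those reduced stationarity conditions, this is the global optimum to machine
precision — no iterative QP tolerance involved — at 2^K−1 tiny solves,
negligible for the K ≤ 6 classes that occur in practice.  It is verified in
tests against an independent 0.01-step simplex grid search.  The basis
matrix is normalised by its largest column norm before solving so that λ is
comparable across spectra of different magnitude; λ defaults to 0
(constrained least squares).  NRMSD is `√(Σ(fit−y)²/Σy²)` over the fitted
range, which defaults to 190–240 nm where the class spectra are most
distinctive.

The bundled basis is parametric and synthetic: per-class sums of Gaussian
bands at canonical positions (helix +193/−208/−222 nm, sheet +195/−218 nm,
turn weak mixed bands, disordered strong negative near 198 nm with a small
positive tail near 222 nm).  The curated reference databases used by
deconvolution servers are built from measured protein spectra and are not
bundled or cloned; consequently fractions estimated against the synthetic
basis demonstrate the estimator (generator↔estimator consistency, noise
robustness) but are not comparable to database-derived percentages for real
spectra.  Database bias against disordered proteins is addressed only in the
sense that the basis contains an explicit disordered class and any
user-supplied basis (e.g. an IDP-containing one) loads from CSV.

Two-wavelength classification standardises the (θ₂₀₀, θ₂₂₂) plane by the
reference cohorts' pooled within-cohort standard deviation and assigns the
nearest centroid; all per-cohort distances are returned because membership
is graded in practice.  Exact ties report `label=None` rather than an
arbitrary pick.  The discriminant line of the published version of this
plot is not available, so nearest-centroid on user-supplied reference
points is the documented stand-in, and zero-variance references are
rejected rather than guessed at.

## Binding analysis

"16-step 2-fold serial dilution from 40 µM to 610 pM" is read as 16
dilution *steps*, hence 17 concentrations — the only reading for which
40 µM/2¹⁶ = 610 pM reproduces both printed endpoints.  The fraction-bound
model is 1:1 mass action with ligand depletion, evaluated in the
cancellation-free form `2c/(s + √(s²−4·c·c_t))`, `s = c+c_t+K_D`; it is
monotone in *c*, bounded in [0, 1], and reduces to `c/(c+K_D)` as c_t → 0
(property-tested).

K_D is fitted in log-space (positivity for free) by least squares from 13
log-spaced starts over 1 nM–1 mM, keeping the best final SSE; the standard
error comes from the Gauss–Newton covariance at the optimum via the delta
method.  Weights are 1/sd per point when replicate SDs are provided.
Caveat worth stating: SDs estimated from very few replicates (the n = 2
typical of thermophoresis) are themselves extremely noisy, and 1/sd
weighting then inflates estimator variance and degrades nominal coverage —
with duplicate-based weights the ±2·SE interval covers well below 95 % in
simulation.  Provide SDs from adequate replication, or omit them to get the
unweighted fit, which calibrates well (≈92–95 % empirical coverage of
±2·SE over 200 simulated titrations at noise sd 0.02).

The labeled-target concentration is rarely printed in protocols; the
default is 50 nM, typical for His-tag dye chemistries, always overridable
and recorded in outputs.  Saturation requires top concentration ≥ 5·K_D
and model fraction bound at the top ≥ 0.8 (both configurable).  Fits
failing either margin keep the numerical optimum internally but report
"n.d." with a lower bound — what a titration that never saw its plateau can
actually support.  Raw (unnormalised) responses are rescaled by fitting
baseline and plateau jointly with K_D, never by taking the min/max of noisy
data; a flat curve raises rather than silently rescaling.

## Synthetic data

All generators are pure functions of their configs; each call builds a
fresh seeded `numpy.random.Generator` and no global state is touched.
Defaults encode the emulated study conditions: a 112-residue construct
(111 peptide bonds) at 10 µM in a 1 mm cuvette scanned 190–250 nm at 1 nm;
a 228-residue partner (three 76-residue ubiquitin units) at the same 10 µM
in 1:1 mixtures; disorder-biased sequences with probability mass
0.4 + 0.6·bias on the disorder-promoting set {A,R,G,Q,S,P,E,K} (bias
defaults to 0.8, giving a strongly biased composition while keeping all 20
residues reachable); CD noise 0.1 mdeg (a visually realistic
signal-to-noise for a 2.5 s/point acquisition at these concentrations);
titrations of 17 points from 40 µM with duplicate noise sd 0.02
fraction-bound units and a 5 µM true K_D.

The mixture generator applies the induced structural shift only to the
bound portion of the disordered component, with the bound fraction from the
mass-action model at the stated concentrations — the simplest mechanism
consistent with a mixture containing both bound and free protein.  A zero
shift yields strict additivity, which the total-residue normalisation then
maps to an exactly zero difference spectrum.

What the generators do *not* emulate: instrument drift and HT-voltage
artefacts, wavelength-dependent noise, CD band fine structure beyond
Gaussian bands, thermophoresis physics (only the equilibrium binding
curve), or the phylogenetic structure of real alignments.  Tests passing on
this synthetic data therefore demonstrate correctness of the arithmetic,
the estimators, and their statistical calibration under the stated noise
model — not agreement with any particular measured dataset.

## Problem sizes in routine runs

The validation ensembles are sized for completeness at interactive runtimes:
50 noiseless + 100 noisy spectra for deconvolution recovery, 200 titrations
for the K_D Monte-Carlo, scan-oracle equivalence on sequences up to length
8 (19·L = 152 variants), held-out classification on 80-point cohorts.  The
whole suite runs in well under a minute on one core; the ensembles can be
scaled up freely, and estimator behaviour is stable across the seeds tried.

## Known limitations

- Absolute disorder scores and structure fractions are surrogate-scaled
  (see above); only procedures, rankings, unit conversions and fits are
  meant to transfer quantitatively to real data.
- The noisy null-interaction bound (max |difference| < 3·propagated σ at
  every wavelength) is a pointwise 3σ criterion over 61 points, so a
  single-seed check fails by chance in roughly one run in seven; it is a
  smoke alarm, not a calibrated test.
- `fraction_bound_from_raw` assumes the raw response is affine in fraction
  bound; thermophoresis artefacts that violate affinity (aggregation,
  photobleaching) are out of scope.
- The active-set enumeration in the deconvolution solver is exponential in
  the number of basis classes and intended for the small bases of this
  domain (it is exact but would be the wrong tool past ~15 classes).
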