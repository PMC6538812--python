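# Methods

This note records the models `eqdose` implements, the assumptions and
defaults behind them, the numerical choices that matter, and what the
synthetic studies do and do not demonstrate about real data.

## Uptake model and its solution

The three-compartment model tracks extracellular (`C_E`), free
intracellular (`C_F`) and nucleus-bound (`C_B`) drug concentration (nM).
Transport is first order and non-saturable; binding is irreversible
because `k_FB` is a *net* rate lumping DNA binding with repair, so `C_B`
is monotone non-decreasing. Drug metabolism and DNA dissociation are not
modelled. Only the volume ratio `v_ratio = v_E/v_I` enters the dynamics;
it defaults to 1e4 (a ~150 µL well over the aggregate volume of ~1e4
cells). From intracellular data alone only the product
`k_EF · v_ratio` is identifiable, so `v_ratio` is configuration, never a
fit parameter; published influx rates of order 1e-6 h⁻¹ should be read as
carrying an unknown volume ratio absorbed into the fit.

Each inter-event segment is a constant-coefficient linear system. The
live (C_E, C_F) block `[[−a, b], [c, −d]]` has a positive off-diagonal
product whenever `k_EF, k_FE > 0`, so a diagonal similarity makes it
symmetric and `eigh` yields a perfectly conditioned eigenbasis; `C_B`
follows by exact quadrature of `C_F` (`expm1` keeps small exponents
accurate; an exactly zero eigenvalue, which occurs iff `k_EF·k_FB = 0`,
integrates to `t`). Triangular corner cases (`k_EF = 0` or `k_FE = 0`)
fall back to a per-time `scipy.linalg.expm`. This analytic path is exact
to machine precision at any horizon — mass drift is ~1e-15 — and costs
microseconds, which is what makes the fitting and inversion layers cheap.
An LSODA integration (`rtol = atol = 1e-12`) is kept solely as an
independent cross-check; the two paths agree to better than 1e-9 on
random rate draws spanning six decades.

A media-replacement event instantaneously sets `C_E` while `C_F`, `C_B`
are continuous; a sample falling exactly on an event reports the
post-event state.

## Equivalent dose

`D_eq` is the maximum of `C_B` over the schedule evaluation window.
Because `C_B` is monotone, this is the terminal value. By default the
final segment is extended past the horizon until `C_F` has drained below
1e-6 of its peak ("washout tail"), capturing the residual binding of drug
still inside the cell when the schedule ends. The crossing time is
bracketed by doubling steps and refined by bisection on the analytic
propagator, so `D_eq` varies smoothly with the rate constants — important
for the inverse problem, which differentiates through it numerically.

Two consequences worth knowing:

* For a schedule that ends with drug still in the medium, the tail
  converges to the all-drug-binds limit; include the washout event if the
  experiment had one.
* Periodic media refreshes matter. After washout, effluxed drug slowly
  re-enters (the slow eigenmode is ~1e-7 h⁻¹ at typical rates) and would
  eventually all bind. Real response assays refresh media every ~3 days;
  the study generator includes those refresh events, which keeps `D_eq`
  close to the bound pool at washout and preserves its sensitivity to
  `k_FB` (d ln D_eq / d ln k_FB ≈ 0.94 with refreshes vs ≈ 0.3 without).

`D_eq` is verified to be monotone in applied concentration, exposure
duration, `k_EF` and `k_FB`, and antitone in `k_FE`, on the study-course
grids.

## Response model

`dN/dt = (k_p − k_d(t)) N (1 − N/θ)` with `k_d ≡ 0` before treatment and,
after it, a convex mixture of a stable rate `k_d,a` and the transient
kernel `k_d,b · r t e^(1−rt)` (maximum `k_d,b` at `t = 1/r`). The
substitution `u = θ/N − 1` linearises the equation for any time-varying
net rate, and both kernels integrate in closed form, so `simulate_counts`
is exact (overflow-safe via `logaddexp`); an adaptive ODE oracle confirms
it in the tests. θ is the plate's carrying capacity and is fitted per
condition, bounded below by the largest observed count.

The kernel weight λ is **not** a free parameter: the model depends on
`(1−λ)k_d,a` and `λk_d,b` only through those products, so λ is a pure
reparameterisation and cannot be estimated from count data. It is carried
as fixed configuration (default 0.5, equal weighting) and excluded from
the matching vector.

## Fitting

All three fitters (`UptakeModel`, `ResponseModel`, `HillModel`) pool
squared residuals across replicates and minimise with
`scipy.optimize.least_squares` (TRF) from a deterministic Latin-hypercube
multistart (default 16 starts plus the box midpoint) over box bounds,
log₁₀-transforming parameters that span decades. 95% confidence intervals
come from the local curvature (Gauss–Newton covariance `s²(JᵀJ)⁻¹` with a
t quantile); they are asymptotic, and a coverage simulation in the test
suite confirms ≥85% empirical coverage at the assay noise level.
Estimates pinned at a bound are flagged (`at_bound`, `degenerate`) and
their curvature intervals should not be trusted there; every results
object also offers `bootstrap_conf_int(n_boot=500)`, a residual bootstrap
with percentile intervals, for those cases.

Defaults that matter:

* **Uptake observable** is `C_F + C_B` — whole-cell fluorescence cannot
  separate free from bound drug. Bounds default to `k_EF ∈ [1e-9, 1e-2]`,
  `k_FE, k_FB ∈ [1e-4, 10]` h⁻¹ (nM/hour scales with `v_ratio = 1e4`).
* **Response bounds** for the transient kernel default to
  `k_d,b ≤ 0.3 h⁻¹` and `r ∈ [0.002, 0.3] h⁻¹`: daily sampling cannot
  resolve induction faster than a few hours, and without the cap the
  (k_d,b, r) pair wanders along its ridge (only the integrated transient
  `k_d,b·e/r` is well determined when effects are weak — the same
  degeneracy the underlying assay literature reports for small `k_d,b`).
* **Loss**: raw counts by default; `loss="log"` (log(count+1)) is the
  right choice for multiplicative noise and is what the pipeline uses.
* **`fixed=`** pins any subset of response parameters. The pipeline fixes
  `k_p` per study from an untreated-control fit, since proliferation is a
  cell-line property and freeing it per condition entangles it with
  `k_d,a` in declining populations.
* **Hill fits** `S(D) = E_inf + (1−E_inf)/(1+(D/EC50)^h)` with
  `E_inf ∈ [0,1]`; a survival range under 0.05 is declared
  non-identifiable and no EC50 is returned. Dose bounds are data-driven,
  which makes the fit exactly equivariant under dose rescaling.

## Dose matching and the constrained inverse problem

The monotherapy response surface interpolates `p = [k_d,a, k_d,b, r]`
piecewise-linearly in `D_eq` through the fitted nodes; queries outside the
node range raise (no extrapolation). Matching minimises an L2 distance
over a 512-point grid with bounded scalar refinement in the best bracket
(piecewise-linear surfaces defeat gradient methods); secondary minima of
comparable depth set an `ambiguous` flag, and boundary hits are flagged.

Distance scaling is the one genuinely open design choice. Two schemes are
implemented:

* **Range scaling** (default): each dimension divided by its range over
  the nodes.
* **Local uncertainty scaling** (used by the pipeline when node CIs are
  attached): each dimension divided by the interpolated surface-node CI
  combined with the query fit's CI, floored at 2% of the range. This is a
  local Mahalanobis distance; it prevents the unresolvable
  transient-kernel dimensions at weak effects from injecting full-range
  noise into the match. On the default synthetic study it roughly halves
  the `D_est` error (≈6% vs ≈26% median).

`estimate_kx` minimises `G(k_x) = Σᵢ (D_est,i − Dᵢ(k_x))²` over sensitizer
levels with the hard constraint that the optimised variable is monotone:
increments `δ_q ≥ 0` are the free variables, on `k_x` itself for
increasing targets (net binding under a DNA-repair inhibitor) and on
`1/k_x` for decreasing targets (efflux under a pump inhibitor), so the
returned sequence satisfies the constraint exactly. Warm starts come from
per-condition scalar inversion of the monotone map `D(k_x)` (Brent's
method) followed by an isotonic pass; the all-levels-equal null is also
tried, so the solution is never worse than no-effect. A matched dose
outside the achievable range clamps to the bound with a warning and sets
`constraint_active`.

## Image processing

The forward model is `I = L(C + b)` per channel. The illumination field
`L` is estimated by median-disc filtering each frame (default radius
50 px; tests use smaller frames and radii), averaging over timepoints,
fitting a 2-D polynomial surface (default degree 2; both are exposed) and
normalising to max 1; a non-positive fitted surface raises. The mixing
matrix rows are per-fluorophore channel means from single-fluorophore
controls scaled so the brightest channel is 1; rank deficiency (identical
spectra) raises. Unmixing solves the overdetermined `S·T = I` by QR,
per region by default and per pixel on request, reporting the residual
norm. Doxorubicin signal converts to concentration through the linear
calibration `S = a[Dox] + b`, with sub-background signals clipped to zero
and flagged. Segmentation is plain thresholding with 8-connected
components; the extracellular compartment excludes a 2-px guard band
around cells to avoid edge bleed. Arrays are row-major with 0-based
pixel indices.

## Synthetic studies: what they emulate

The generators reproduce the structure of time-lapse uptake and response
assays: 2-fold dose grids (5000 → ~10 nM), 24 h exposure with washout and
3-day media refreshes, six response replicates imaged daily for 15 days
plus three pre-treatment days, an untreated control, three uptake
replicates at 25-min sampling for 24 h (1 µM, washout at 8 h), additive
Gaussian uptake noise (σ = 50 nM), mean-preserving multiplicative
lognormal count noise (CV 5%), and truncation of each condition once its
mean reaches 95% of θ (counting fails at confluence). Seeded runs are
bitwise reproducible and every generator returns a truth bundle.

Ground-truth choices, made once:

* `BASE_PK` uses rates measured for an MDR1-overexpressing breast-cancer
  line (`k_EF = 3.08e-6`, `k_FE = 0.313`, `k_FB = 0.0212` h⁻¹) and drives
  every equivalent-dose computation.
* `UPTAKE_PK` (`k_EF = 5e-5`, others as above) is the truth for uptake
  *measurement* studies: its influx product (0.5 h⁻¹) makes a 1 µM
  application accumulate to ~1.7 µM intracellularly, the regime such
  assays actually observe, so the 50 nM noise floor is the few-percent
  residual real fits report. With the literature influx rate and
  `v_ratio = 1e4` the synthetic signal would peak near 96 nM, and the
  Cramér–Rao bound at that SNR forbids ~10% rate recovery outright.
* The response map `p(D_eq)` uses saturating Hill-type shapes — `k_d,a`
  and `k_d,b` rising to 0.05 and 0.09 h⁻¹ (half-doses 25 and 50 nM
  bound), `r` falling from 0.2 to 0.06 h⁻¹ — calibrated so the top of the
  dose grid drives the population into decline while the bottom barely
  perturbs growth, with `k_p = 0.0212 h⁻¹`, θ = 18000 and N₀ = 1500.
* Sensitizer curves are Hill-type: efflux inhibited up to 85%
  (`k_FE` 0.313 → 0.071 over a 250 → 3.9 nM 2-fold series, mirroring
  measured pump inhibition) and net binding activated up to ~3.7-fold.
  Co-treatment doxorubicin doses are (156.25, 312.5, 625) nM, chosen so
  every co-treatment equivalent dose stays inside the monotherapy surface
  for both targets.

What passing these studies shows: the estimators are near-efficient at
the stated noise models (which the losses match by construction), and the
inverse machinery recovers rates whose only path to the data is through
the equivalent dose. What it does not show: robustness to model
misspecification — real populations have cell-cycle structure, density
effects, heterogeneity and drifting proliferation that the logistic law
ignores; real noise is not exactly lognormal; real illumination is not
polynomial. The deterministic population model also ignores demographic
stochasticity, which matters at low counts.

## Problem sizes and numerical details

Simulation studies use 20 seeds for the recovery checks and a single
seeded study (10 monotherapy doses + 21 co-treatment conditions) per
sensitizer target; the whole acceptance script runs in well under a
minute on one core. The PK recovery condition is the design's uptake
assay; the PD recovery condition is the 625 nM monotherapy dose (a
clearly treated, θ-constrained condition). Degenerate inputs are policed
at construction time (negative rates, unsorted times, empty grids,
all-zero counts, rank-deficient spectra, duplicate surface nodes) rather
than deep in numerics. Matching tie-breaks: the grid argmin picks the
first minimum; ambiguity is reported rather than resolved. The EC50
framework comparison is evaluated on noise-free survival means because it
asserts a property of the model expectation; with 5% count noise the
EC50 estimator's own sampling error (~10%) dominates any 5% agreement
statement.

## Known limitations

* First-order, non-saturable transport; rates assumed constant over the
  experiment and across doses.
* λ fixed by configuration; if the true kernel weight varies with dose,
  its variation is absorbed into biased `k_d,a`/`k_d,b` estimates.
* The response surface does not extrapolate: co-treatment conditions more
  effective than the strongest monotherapy dose are flagged, not dosed.
* Curvature CIs understate uncertainty near bounds and on the transient
  ridge; prefer the bootstrap intervals there.
* Per-pixel unmixing assumes the mixing matrix is spatially uniform.
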