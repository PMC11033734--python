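# Methods

This note records the models, discretisations and design choices behind
`cspapi`, in enough detail to reproduce or modify them.

## Measurement model and matrix family

The instrument reads 64 ring sensors through 16 four-sensor multiplexing
blocks; an analog stage sums the selected signals of four neighbouring
blocks into one channel.  A realizable measurement row is therefore a
0/1 vector over one 16-sensor group with at most one 1 per block, and
`m0` such rows form the group matrix `M ∈ {0,1}^{m0×16}`; the full-array
matrix is block diagonal with one group matrix per group (`cs_design`).
Measurements mix sensors only, never time samples, so the matrix
commutes with every purely temporal filter — the fact the two-step
reconstruction relies on.

**Sampling distribution.**  The feasible family is sampled uniformly and
independently per (row, block) over the `block_size + 1` states
{off, sensor 1..block_size}, so every feasible matrix — including rows
with inactive blocks — has positive probability.  Duplicate rows are
allowed; they waste a measurement and depress the quality score, which
is penalty enough.

## Sparse injectivity number

`sin(M, s)` implements

    Θ_s(M) = min_{|S| = 2s} σ_min(M_S),

the worst-case separation factor of s-sparse signal pairs, by batched
eigendecomposition of the 4×4 Gram matrices of all `C(16, 4) = 1820`
column subsets.  Numerical rank handling: a smallest eigenvalue below
`1e-10` times the largest over all subsets is reported as exactly 0.
For binary matrices this is exact — a nonsingular integer Gram matrix
has determinant ≥ 1, so its smallest eigenvalue is at least
`1/λ_max³ ≳ 2e-4`, orders of magnitude above the round-off floor —
and it makes the `1e-8` nonsingularity threshold meaningful (raw
eigensolver noise at singular submatrices reaches `~1e-7` after the
square root).

**Reported scale.**  The package API returns the injectivity *ratio*
(values ~0.3–0.45 for good 12×16 designs).  Design scores for this
matrix family are commonly quoted on the squared scale — the smallest
restricted Gram eigenvalue (~0.12–0.24 for the same designs) — and the
acceptance script reports on that squared scale; `normalized_sin`
additionally exposes the spectral-norm-relative ratio as a scale-free
diagnostic.  The 0.1 stability rule of thumb is applied to the ratio.

**Search.**  `search_design` draws candidates uniformly, keeps the
strictly best SIN (ties keep the earlier matrix), and early-rejects any
candidate with an all-zero column (its SIN is exactly 0) — a large
speed-up for long searches at zero cost in exactness.  With a fixed seed
the search is bit-reproducible and its best-so-far trace is monotone.

**Convex-recovery validation.**  A positive SIN certifies that
s-sparse signals are identifiable and that exhaustive-support decoding
(`enumeration_decode`) is exact.  It does **not** imply exactness of
convex decoders: measured over design seeds, ℓ1 basis pursuit recovers
per-group 2-sparse signals exactly for most but not all SIN-optimal
matrices (failing matrices show ~20 failed instances per 3000; passing
matrices show none), and zero-boundary TV recovery of arc signals is
exact for fewer still (~4/10).  `validated_design` therefore follows
the search with an accept/reject step — exact ℓ1 recovery of a
2000-instance seeded batch — and restarts the search on a fresh stream
on rejection.  This mirrors selecting the deployed matrix for exact
sparse recovery rather than for its score alone.

## Wave model

Geometry: source supported inside the circle of radius `R` (default 1),
`n` detectors uniformly on that circle, sound speed rescaled to 1 so the
time grid `t ∈ [0, 2R]` doubles as the radius grid of the circular
means.  The wave equation is never time-stepped; the forward map is the
known representation

    g(s, t) = ∫₀ᵗ r·m(s, r)/√(t² − r²) dr,   p = ∂t g,

with `m(s, r)` the circular means of the source.  For uniform disks the
means have the closed form `amplitude · arccos((d² + r² − a²)/(2dr))/π`
on the partial-overlap range (1 inside, 0 outside); tapered disks
`amplitude·(1 − (ρ/a)²)^κ` use dense angular quadrature.  Superposition
over disks is exact, so forward data can be validated against analytic
expressions.

**Abel forward.**  The substitution `r = t·sin φ` removes the
singularity; 200 Gauss–Legendre nodes per output sample are accumulated
into a cached lower-triangular matrix (linear interpolation of `m`
between grid nodes), so the transform is one matmul.  Exact for
constant means (`g = t`).

**Abel inverse** (`abel_inverse`).  Product integration with piecewise
constant interval values: the closed-form weights
`√(tᵢ² − tⱼ²) − √(tᵢ² − tⱼ₊₁²)` give a lower-triangular system solved by
forward substitution, then interval values are averaged back to nodes
(linear extrapolation at the two ends).  Round-trip error on smooth
means: 0.14%/0.05%/0.02% at q = 256/512/1024.

**Temporal filter Φ** (`pressure_to_means`).  The two-step method needs
the inverse of `p = ∂t g[m]` applied per channel.  Chaining independent
discretisations (cumulative trapezoid + Abel inversion) leaves ~1%
round-trip error concentrated at data kinks, which later
differentiation re-amplifies; Φ is therefore the truncated-SVD
pseudo-inverse of the *discrete* forward matrix `Grad·B` itself, making
the pipeline cancel exactly on the forward range.  The truncation
threshold is an absolute singular value (0.3): the small end of the
spectrum is grid-independent, and this choice gives ~0.1–0.3%
composition error on clean disk data while mapping 9% pressure noise to
~10–13% means error (the untruncated inverse diverges).  Φ acts on the
time axis only and commutes exactly with any sensor-mixing matrix.

**Filtered backprojection.**  The inversion formula with kernel
`1/√(t² − d²)` is discretised with the substitution `τ = √(t² − d²)`
(nonsingular integrand), the inner integral tabulated per sensor on a
1D distance grid and interpolated per pixel, and the ring sum weighted
by arc length.  With this package's source convention (`p = ∂t g`) the
correct filter is the **first** time derivative of the pressure
(equivalently `∂tt g`); this was fixed by requiring that a centred test
disk reconstructs to amplitude 1 and that the adjoint identity below
holds.  Measured self-consistency: single uniform disk at n = 256,
q = 1024, Nr = 128 reconstructs with ≤ 0.12 relative ℓ2 error (edge
Gibbs ringing and the 1/√ data singularities dominate).

**Adjoint identity.**  2D wave data have infinite tails, so integrating
by parts in time leaves a boundary term at `t = 2R`:

    ⟨Wu, p⟩ − ∮ g(s, 2R)·p(s, 2R) dC(s) = (R/2)·⟨u, fbp(p)⟩.

`adjoint_constant` evaluates the empirical constant; it is stable to
< 1% across random phantom pairs and within ~2% of the theoretical
R/2.  Without the boundary correction the "constant" varies by ~30% —
the naive pairing is not an identity in 2D.

## Two-step reconstruction

`recover_transformed` applies Φ to the compressed channels (legitimate
by commutation), then solves one penalised problem per radius sample;
all samples share the matrix, so the per-sample problems run as matrix
iterations.  Two fidelity forms:

* `squared` — `½‖Ah − y‖² + μ‖Dh‖₁` by monotone FISTA (accepted
  iterates never increase the objective; the TV prox is evaluated
  through its box-constrained dual by accelerated projected gradient).
  The solver terminates on a sustained (25-iteration) stall of the
  relative objective change.  The right choice for noisy data.
* `exact` — the basis-pursuit limit `min ‖Dh‖₁ s.t. Ah = y` by a
  primal-dual (Chambolle–Pock) scheme with an equality-constraint dual
  block.  The right choice for exact data, where it achieves exact
  recovery on recoverable sparse signals.  Its O(1/k) convergence sets
  the floor of the no-compression consistency check: with A = identity
  the two-step image matches the full-data FBP to ~3%/1.6% at
  1500/3000 iterations.

Penalty operators `D`: cyclic ring differences (default; the physical
ring is closed), non-cyclic line, per-group line, per-group
zero-boundary differences (counts the boundary values; behaves like an
ℓ1 penalty for features on a zero background), and identity (plain ℓ1 —
the penalty matching the entry-sparse class of the injectivity
analysis, and the only one observed exact for every validated matrix).

**Which penalty recovers what.**  Per-group 2-sparse entries: identity
(ℓ1), exact for every validated design.  Arcs on a zero background
(2 cyclic jumps per group): zero-boundary TV, exact for some designs
only.  Dense two-level cyclic signals, although also gradient-2-sparse,
are *not* recoverable by any convex TV variant from 12-of-16
measurements (measured min-TV interpolation errors 6–45%) — sparse
gradients alone are not a sufficient recovery model at this compression.

**Per-regime configuration.**  `run_experiment` selects the solver
configuration (fidelity, penalty operator, and weight μ for the squared
form from a small log grid) by minimising the recovery error on a
held-out phantom of the same kind and noise regime, never on the scored
instance.  Selected weights are recorded in the output records.

## Synthetic data and noise

* `piecewise` phantoms: 3–6 uniform disks, radii 0.08–0.25 R, amplitudes
  0.5–1.5, centres inside 0.8 R — piecewise smooth, not group-sparse.
* `sparse` phantoms: 1–2 disks of radius 0.04–0.1 R at 0.25–0.7 R from
  centre.  Disk means ramp smoothly across the sensors that see them,
  so strict per-group 2-jump sparsity cannot hold exactly; the audit is
  the approximate contract localized sources actually satisfy — jumps
  counted above 0.2× the global maximum, with at most 15% of
  (group, radius) cells allowed to exceed 2 (measured 0.05–0.11) — and
  placement is redrawn until it passes.
* Synthetic signals (`make_group_sparse_signals`): per-column exact
  per-group sparsity, either `entry` mode (exactly s nonzeros) or
  `gradient` mode (s/2 disjoint non-wrapping constant arcs on zero
  background — exactly s nonzero differences under both the cyclic and
  the zero-boundary operator).  Amplitudes uniform on [0.5, 1.5] with
  random sign, avoiding near-cancellation while exercising sign
  recovery.  Columns are drawn independently, which makes them white
  along the radius axis — fine for measurement-domain tests, but
  unphysical as wave data (Φ's truncation removes such content), so
  wave-pipeline tests use disk phantoms instead.
* Noise: i.i.d. Gaussian added to the compressed pressure data and
  rescaled so the realized relative ℓ2 level equals the target exactly
  (default 0.09).  The realized level is returned and recorded.

What passing tests on these generators do **not** show: performance on
real instrument data with detector impulse response, bandwidth limits,
heterogeneous sound speed, or non-disk morphology — none of which the
generators emulate.

## Evaluation grid

`run_experiment` mirrors the instrument study: {SIN-optimized (and
recovery-validated) matrix, random feasible matrix re-drawn until
nonsingular} × {piecewise, sparse phantom} × {exact, 9% noisy}; each
cell reports the realized data error, the transformed-domain (CS)
recovery error against Φ of the full data, and the image error of the
two-step reconstruction against the **full-data FBP reference** (the
goal of compressed acquisition is to match the full array, not the
unattainable continuous phantom).  For noisy cells the recovered means
are band-limited along the radius axis (Gaussian, σ = 2 samples) before
the FBP derivative — raw difference stencils on unregularised noise
otherwise dominate the image.  An extra exact-data sparse cell evaluated
with the noisy-regime settings (label `/noisycfg`) allows judging noise
degradation at matched solver settings; measured ratios are ~1.2–1.5.

Note the "random nonsingular" baseline is nearly as good as the
optimized matrix in these pipeline metrics: the first nonsingular draw
typically has SIN 0.2–0.35, and cell-by-cell orderings against the
optimized matrix tie within ~10% either way.  The clear separation is
against *unoptimized* feasible draws (frequently singular), which fail
sparse decoding outright.

## Problem sizes

Defaults for interactive use: R = 1, n = 64 sensors, q = 1024 time
samples, Nr = 128 pixels (n = 64 deliberately under-samples the
Nyquist count round(π·128/2) = 201, as in the instrument).  The test
suite and the experiment driver run reduced grids chosen to keep full
runs in minutes — q = 192–512, Nr = 48–128, solver caps 1200–3000
iterations — sizes at which every reported tolerance was measured to
hold with margin.  `scripts/acceptance.py` runs only the matrix-design
computations (seconds).

## Known limitations

* Uniform-disk data have 1/√ singularities at tangent radii; FBP
  accuracy is edge-limited (~10% ℓ2 on disks) and the
  pipeline-consistency floor is set by the O(1/k) primal-dual solver,
  not by the operators.
* The SIN search scores identifiability, not convex-decoder exactness;
  deployment should use `validated_design` (or the exhaustive decoder,
  which the SIN does guarantee).
* The measurement-count frontier of the uniform-sampled family is
  better than a small random search suggests: nonsingular designs exist
  and are found down to m0 = 10 (block size 4), with first hits needing
  ~10²–10⁴ draws.  Short searches that fail at m0 < 12 say more about
  search effort than about the family.
* The squared-scale reporting of design scores follows the convention
  of the quantities this package is checked against; the API itself is
  consistently on the ratio scale.
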