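# Methods

This note documents the models, conventions, and numerical choices
behind `neteff`, stage by stage in pipeline order.

## Synthetic data

**Modular time series.** Node series follow a two-level factor model
`x_i = a·g + b·f_{block(i)} + c·ε_i` with `a² = ρ_between`,
`b² = ρ_within − ρ_between`, `c² = 1 − ρ_within`, so every series has
unit variance and expected pairwise Pearson correlation exactly
`ρ_within` inside a block and `ρ_between` across blocks. The
parameterization is feasible iff `0 ≤ ρ_between ≤ ρ_within < 1`; any
other combination is rejected. Series are scaled to a BOLD-like level
(`baseline` 1000 arbitrary units, `amplitude` 2, i.e. 0.2 % fluctuation)
so that DVARS expressed as percent-of-mean is meaningful; neither
parameter affects correlations. Defaults elsewhere in the pipeline
(159 frames, TR 2 s) mirror a ~5.3-minute acquisition. What the
generator does *not* emulate: hemodynamic autocorrelation, spatial
smoothness, physiological noise spectra, or scanner drift. Passing
tests therefore certify the pipeline's algebra and bookkeeping on data
with known correlation structure, not robustness to real fMRI artifact
structure.

**Motion traces.** Six rigid-body parameters (3 translations mm,
3 rotations rad) are produced by drawing a per-transition framewise
displacement target — uniform in [0.01, 0.08] mm for a "still subject"
baseline, or the requested spike FD at spike frames — and splitting it
across the six parameters with random signs; rotation shares are divided
by the sphere radius so the realized FD equals the target exactly. This
makes scrubbing tests sharp: FD is below 0.1 mm everywhere except
exactly at the injected spikes.

**2-back sessions.** A 100-letter session (20-consonant alphabet;
letter statistics are our choice, vowels excluded to discourage
chunking). The first two trials can never be targets; from trial 3 each
trial repeats the letter from two back with probability `target_rate`
(0.3 by default), otherwise draws a different letter — so `is_target`
is consistent with the sequence by construction. Responses are
Bernoulli ("match" with the hit rate on targets, the false-alarm rate
on non-targets); RTs are log-normal parameterized by arithmetic
mean/SD (700/150 ms defaults).

**Cohorts.** Subject d′ is set from the per-cohort prediction equations
(young: intercept 3.6708, slopes −9.4607·E_local, +20.2928·E_global,
−0.0034·RT; older: intercept 9.2047, slopes −9.4607, −2.7517, −0.0034)
plus `Normal(0, noise_sd)`. Covariate ranges default to plausible
whole-brain values: E_local ∈ [0.35, 0.50], E_global ∈ [0.15, 0.35],
RT ∈ [400, 1500] ms. With `noise_sd = 0` covariates sit on a
deterministic grid — `L = max(3, ⌈n^(1/3)⌉)` levels per covariate cycled
at different periods, and the volumes-removed count cycling 0–3 at yet
another period — chosen so the full candidate design (5 mains, 10
pairwise products, 4 quadratics) is full rank; with only two levels a
squared term would be exactly collinear with its main effect. Per-subject
covariate distributions of the original cohort are unknown; these ranges
are stand-ins, not estimates.

## Preprocessing

Order is fixed and logged: band-pass filter → nuisance regression →
scrubbing.

- **Filter**: order-2 Butterworth, 0.009–0.08 Hz, applied
  forward-backward (`sosfiltfilt`) so the effective response is
  zero-phase — phase lag would distort inter-node correlations. The
  per-node mean is removed first, so constant input maps to exactly
  zero.
- **Nuisance regression**: residualization against an intercept plus
  the supplied columns (the pipeline uses the global mean signal and
  the six motion parameters); residuals are orthogonal to every
  regressor. Rank-deficient regressor sets fall back to the least-norm
  solution with a warning.
- **FD**: `Σ|Δtrans| + r·Σ|Δrot|` with r = 50 mm (standard sphere-radius
  convention for converting rotations to arc length); configurable.
- **DVARS**: RMS over nodes of the frame-to-frame change, as a percent
  of the mean signal. Because filtering removes the DC component, the
  pipeline passes the *pre-filter* grand mean as the reference while the
  numerator is computed on the filtered, regressed data.
- **Scrubbing**: a frame is removed when it terminates a transition with
  FD > 0.5 mm OR DVARS > 0.5 % (OR is the conservative combination).
  Only the offending frame is removed by default; an optional
  before/after extension window exists (default 0). Transitions whose
  surviving frames are not consecutive acquisitions (frame ids differing
  by more than 1 after earlier removal) are not re-evaluated — FD/DVARS
  are defined for consecutive acquisitions only — which makes scrubbing
  idempotent. Removing every frame raises an unusable-subject error.

## Network construction

Pearson correlations over all node pairs (≥ 3 surviving frames, no
zero-variance nodes; diagonal zeroed). Thresholding is rank-based: the
`round(N·K/2)` largest strictly positive off-diagonal correlations
become edges, with `K = N^(1/S)` and S defaulting to 2.5 (brain networks
fragment above S = 3 and are most reproducible for S ∈ [2, 3]).
Numerical conventions: banker's rounding on the edge budget; `r = 0`
counts as non-positive (excluded); ties at the cut broken by (i, j)
lexicographic order so the budget is met exactly and deterministically;
if fewer positive correlations exist than the budget, all are kept and a
warning is logged. Isolated nodes are never dropped — they legitimately
contribute 0 to efficiency averages. The cut depends only on correlation
ranks, so any strictly monotone sign-preserving transform of the
correlations leaves the network unchanged.

## Efficiency

Shortest paths are BFS hop counts written from first principles;
`1/∞ := 0` for disconnected pairs. Global efficiency sums inverse
distances over ordered pairs and normalizes by `N(N−1)` (algebraically
identical to unordered pairs with `N(N−1)/2`). Nodal local efficiency
uses the strict neighborhood construction: paths are confined to the
subgraph induced by the node's neighbors with the node itself removed,
not the full graph minus the node. Degree-0/1 nodes score 0 (the
`k(k−1)` normalizer is degenerate) and *are included* in the network
average over all N nodes; the alternative (excluding them) would change
the metric on sparse graphs. The test suite checks equivalence with an
independent Floyd–Warshall oracle and with networkx on random graphs,
exact to 1e−12.

## Behavioral scoring

Scoreable trials are positions ≥ 3. Omissions count as incorrect
responses: a missed target is a miss; a withheld response on a
non-target is a correct rejection (no false alarm occurred). Extreme
rates use the 1/(2N) correction by default (0 → 1/(2N),
1 → 1 − 1/(2N), N = trials of that type); a "none" policy returning
±∞ is available. The RT control is the mean over correct *responded*
trials after a single-pass exclusion of RTs beyond 3 sample SDs from
their mean (no iteration); incorrect trials never enter.

## Modeling

OLS with intercept; inference from normal theory (statsmodels).
`AIC = n·ln(RSS/n) + 2(p+2)` counting the intercept and the error
variance; AICc (`+ 2k(k+1)/(n−k−1)`) is available behind a flag since
cohorts of ~30 make the small-sample correction a live issue. Cohen's
`f² = R²/(1−R²)`.

**Perfect-fit floor.** On noise-free cohorts a fit can reproduce the
outcome to machine precision, making `ln(RSS)` unbounded below and
numerically noisy. RSS is floored at `1e−12·TSS` in the AIC, so all
perfect fits tie on likelihood and compete on the parameter-count
penalty alone; the floor is far below any noise level of interest and
does not affect fits on noisy data.

**Stepwise search** starts from the full candidate model
(backward-first with forward re-entry): at each iteration every
single-term drop and add is scored, and the move with the lowest AIC is
applied if it strictly improves the current model. Ties among competing
moves are broken by higher adjusted R², then fewer terms, then term
name — the search is fully deterministic. Raw (uncentered) covariates
are used for products and squares because the reference per-cohort
equations are in raw units; the binary group's square is dropped as
redundant. Hierarchy is not enforced by default (a flag exists).
Control variables (RT, volumes removed) are ordinary candidates, not
forced terms. Where AIC and adjusted R² disagree, AIC is primary and
adjusted R² only breaks exact ties — a documented choice, since the two
criteria are not simultaneously optimizable.

A caveat established by simulation: with strongly collinear candidate
sets (raw uncentered products and squares of a few covariates), greedy
AIC search retains more null terms than the `P(χ²₁ > 2) ≈ 0.157`
per-term rate that holds for independent candidates; R's `step()`
behaves identically. Null-behavior checks therefore use independent
candidate columns.

**Cohort deconstruction.** For a fit containing the binary group term,
the group-0 equation is the intercept plus main-effect slopes; the
group-1 equation adds the group coefficient to the intercept and each
group-interaction coefficient to its partner's slope. Higher-order
terms involving the group are rejected as non-deconstructable.

## Pipeline

`run_cohort` has two modes. `"cohort"` draws subject records directly
from the cohort generator (the coefficient-recovery path). `"full"`
simulates raw inputs per subject and runs the whole chain; because
efficiency and behavior are simulated independently there, full mode
exercises plumbing and bookkeeping, not the efficiency–performance
association. Per-subject seeds fan out from the run seed via
`SeedSequence`; a manifest (config, library versions, timestamp) makes
any run replayable. Failed subjects are logged and excluded and the
exit status reflects partial failure. Small cohorts that cannot
estimate the full candidate design fall back to smaller designs
(quadratics dropped first, then interactions) with a logged warning.

## Problem sizes

Checks are sized for a single CPU: correlation-structure convergence at
60 nodes × 5000 frames (±0.05 tolerance from binomial/Monte-Carlo
bounds); oracle equivalence on 200 random graphs with N ≤ 50; density
matching up to N = 2000; confidence-interval coverage over 1000
noisy-cohort refits (n = 100, noise SD 0.3 d′ units, pooled coverage
95 % ± 3 %); null-model selection over 200 replicates (n = 500, 13
independent candidates). The coefficient-recovery cohort uses 40
subjects per group on the deterministic grid.

## Known limitations

- The generators produce temporally white latent signals; spectra and
  autocorrelation of real BOLD are not emulated, so filter behavior on
  realistic spectra is only characterized by the sinusoid contract
  tests.
- Voxel-scale networks (10⁴–10⁵ nodes) are out of reach of the pure-BFS
  implementation; the pipeline defaults to region-scale networks
  (60–100 nodes).
- Whether the original analysis scored omissions as misses, which
  extreme-rate correction it used, and whether its thresholds used
  exact edge counts or the nearest correlation cut-off are not
  documented; the conventions above are ours, chosen for determinism,
  and each is configurable or pluggable where it could matter.
- NIfTI ingestion is not implemented; inputs are plain-text matrices.
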