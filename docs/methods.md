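# Methods

## Model and assumptions

The tracer is assumed to exchange between arterial plasma and two tissue
pools — nonspecific binding (high capacity, low affinity; rate constants
K1 in, k2 out) and receptor-specific binding (low capacity, high
affinity; K3 in, k4 out) — with no transfer between the pools and no
blood–tissue barrier, i.e. a *parallel* connectivity. Consequences the
package relies on:

* the impulse response is exactly biexponential,
  f(t) = K1·e^(−k2·t) + K3·e^(−k4·t);
* the area of each exponential is that pool's distribution volume
  (DV_NS = K1/k2, DV_S = K3/k4), and DV_T = DV_NS + DV_S holds exactly;
* the fast/slow labelling is a convention (k2 > k4), enforced by
  relabelling after every fit.

No urinary-excretion compartment is modelled, and decay correction is
assumed already applied to all inputs. The arterial blood term of the
measurement equation uses the same metabolite-corrected plasma curve as
the convolution term: only one measured blood curve exists in this
protocol, and distinguishing whole-blood from plasma activity is not
possible from the available data. The fractional blood volume BV is
fixed, never fitted.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| BV | 0.15 | — | predetermined value of the protocol |
| fit window | 2–80 min | min | protocol's estimation interval; excludes the bolus transit and the last frames |
| retention time | 80 min | min | Y_ret/f_ret are "80-min value over maximum" |
| deconvolution grid dt | 0.05 min | min | comfortably below the shortest frame (5 s ≈ 0.083 min) |
| regularizer weight γ | 1.0 | — | the literal regularized quotient; γ→0 recovers plain Fourier division, used for roundtrip checks |
| multistart | 5 starts, ×/÷3 jitter | — | LM from (1.0, 0.3, 0.2, 0.013) plus 4 seeded jittered starts; best residual wins |
| mid-scan points | 42.5 … 87.5 | min | truncation analysis; the last point is the reference |

All times are minutes, uptake constants mL/min/mL, washout constants
1/min, activities Bq/mL/MBq (dose-normalized).

## Numerical choices

**Compartment integration.** The ODEs are solved with an exponential
integrator that is exact for a piecewise-linear input: the step update is
a constant-coefficient first-order recursion, evaluated as an IIR filter.
Frame values are computed exactly at frame mid-times by propagating the
grid state across the fractional step (no interpolation of the solution),
so model accuracy is limited only by the sampling of the input curve
itself. Internal grid: 0.01 min. An optional frame-average sampling mode
integrates the fine-grid model over each frame.

**Positivity.** Both fitters work in log-parameter space, which keeps all
four rate constants positive without constrained optimization and gives a
smooth Jacobian. Standard errors for the natural parameters come from the
log-space Jacobian by the delta method. Fits with k2/k4 < 3 are flagged
as poorly identified (the two components of a healthy kidney differ by
more than an order of magnitude); non-convergence after all starts is
flagged, never silent.

**Deconvolution.** The forward convolution and the regularized quotient
are implemented exactly as stated, on grids zero-padded to the next power
of two at least twice the signal length. Two practical refinements feed
the *fitting* route (the primitive itself is untouched):

* *tail extension* — Fourier deconvolution implicitly assumes the
  measured curve is zero beyond the scan; for slowly clearing curves that
  false discontinuity leaks O(5%) error into the estimate well inside the
  scan. Both curves are therefore extrapolated to twice the scan length
  with a monoexponential fitted to their last 20 min (slope clipped at
  zero) before transforming, which confines the artifact to far beyond
  the fitting window;
* *shape-preserving resampling* — the tissue curve is resampled to the
  uniform grid with a monotone cubic (PCHIP) rather than linear chords,
  which would sit systematically above a convex decaying curve across the
  3–5-min late frames.

With both, noiseless parameter recovery through the deconvolution route
is ≲0.2% worst-case; without them it is capped near 3%. The estimate may
still undershoot near t = 0 under regularization, which is one reason the
fitting window starts at 2 min. f_ret from a deconvolved response uses
the sampled maximum within the window's support, since regularization can
displace the t≈0 peak.

**Degenerate inputs.** k2 = k4 makes the two components unidentifiable
and DVR undefined; `distribution_volumes` rejects it, while forward
simulation of such kinetics remains possible. All-zero curves, windows
with fewer than 8 frames, and retention times beyond the sampled support
raise errors.

**Factor analysis.** Principal-component extraction on the correlation
matrix (loadings = eigenvectors scaled by the root eigenvalues), varimax
rotation by Kaiser's pairwise planar rotations with Kaiser row
normalization, factors reordered by explained variance and signed so the
dominant loading is positive. When the criterion is stationary in a plane
(a rank-one loading pattern — e.g. perfectly correlated columns), the
principal orientation is kept, so the limiting case loads 1.0 on factor
one. A caveat worth knowing: when the columns are highly but not
perfectly correlated and *no second structure exists*, Kaiser-normalized
varimax legitimately splits the general factor between the two factors
(a classical property of the criterion); interpretable 0.9+ first-factor
loadings require data in which the short-time points genuinely decouple.
The t-statistics use pooled variance by default (Welch by flag); Pearson
correlations are one-tailed toward positive association; no
multiple-testing correction is applied, matching the reporting
conventions of the protocol this mirrors.

**Truncation analysis.** At each mid-scan point t only frames with
mid-time ≤ t are kept, the fit window's upper edge is clipped to t, and
Y_ret is re-evaluated at t over the truncated maximum. Points beyond the
80-min window edge (82.5, 87.5) therefore fit identical data, and their
bias against the 87.5-min reference is exactly zero. Bias is the signed
mean percent deviation across kidneys.

## What the synthetic data emulate — and what they do not

The generator reproduces the acquisition geometry (57 frames over 90 min
ramping 5 s → 5 min; 24×5 s + 6×10 s for water), a rapid arterial bolus
(gamma-variate, peak < 1 min) with fast biexponential clearance, a slowly
rising metabolite fraction capped at 5%, parallel-model kinetics with
group means and standard deviations taken from the study's fitted
cohort (lognormal, moment-matched, guaranteeing positivity), BV = 0.15,
and additive Gaussian frame noise with sd = level·√(mean/duration) — a
count-statistics surrogate for reconstructed-ROI noise, clipped at zero.
The default noise level (0.2) was calibrated once so that default cohorts
reproduce the qualitative truncation pattern of the method — DVR bias
large at 42.5-min truncation, declining monotonically, below 10% from
57.5 min on — and corresponds to ~1.5% relative noise on late 5-min
frames.

Not emulated: image reconstruction and partial-volume effects, correlated
inter-frame noise, input-function measurement error, metabolite-assay
noise, respiratory motion, and inter-animal covariance between rate
constants (draws are independent per parameter). Passing tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness to every real-data pathology.

The concrete frame ladder (12×5 s, 6×10 s, 6×30 s, 5×60 s, 16×120 s,
6×180 s, 6×300 s) is a package constant chosen to honour the documented
count, span and end-member durations; any contiguous schedule is accepted
by the pipeline.

## Problem sizes

Defaults keep everything desk-scale: a single fit takes ~50 ms; the full
pipeline on a 12-kidney cohort (24 fits + 120 truncation refits + factor
analysis) runs in ~10 s; the test suite exercises cohorts of 3–12 kidneys
and Monte-Carlo loops of 50–200 replicates.

## Known limitations

* The deconvolution route's accuracy depends on the tail-extension
  heuristic when clearance is slow; pathological inputs that are not
  log-linear in their last 20 min fall back to zero-padding.
* With heavy noise and strongly truncated data the likelihood surface for
  k4 flattens and maximum-likelihood DVR can run away (k4 → 0); such fits
  are flagged by the separability guard but still enter cohort bias
  averages, exactly as they would in practice.
* The blood term equals the plasma input by construction; if whole-blood
  and plasma activities differ materially the BV term is misweighted.
* Group statistics assume near-normal parameter distributions; with 2–5
  kidneys per group the t and F tests are indicative only.
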