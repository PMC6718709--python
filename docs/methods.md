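# Methods

This note documents the models, numerical choices, and limitations behind
`bubblerc`. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`.

## Stimulus geometry and indexing

Temporal stimuli are 96 frames at 120 Hz with racket–ball contact at the last
frame, so playback spans the 0.8 s before contact. Frames are indexed
1..n_frames, and time before contact is `(contact_frame − k)/frame_rate`;
frame 86 is 10/120 ≈ 0.083 s before contact. Spatial stimuli are 600×400
pixel grayscale regions with pixel grid coordinates 0..width−1 / 0..height−1
and a per-video contact point (defaulting to the image center).

## Bubble masks

A bubble is a Gaussian density evaluated at grid coordinates (frame indices
or pixel centers) and rescaled so its peak is exactly 1 at the grid point
nearest its continuous-valued center. Centers are *not* snapped to the grid —
snapping would bias the classification array toward grid positions. Gaussians
are truncated at the domain boundary and not renormalized: the mask simply
ends where the video ends, which makes edge frames and pixels less often
revealed (the familiar bubbles edge artifact; the `coverage` diagnostic in
each classification array quantifies it). Bubbles combine as
`1 − ∏(1 − bubble_b)`, which is bounded in [0,1], order-independent, monotone
in every input, and absorbs any bubble equal to 1. A single bubble is
returned as an exact identity rather than through the product (which would
round sub-epsilon tail values to zero).

Temporal centers are drawn uniformly on the continuous interval
[0.5, n_frames + 0.5), so that nearest-frame binning gives every frame an
equal-width bin; spatial centers uniformly on [0, width) × [0, height).
Centers are restricted to the domain; half-bubbles hanging off the edge are
not generated (the alternative — allowing centers slightly outside so edge
coverage is flat — would change the edge artifact but nothing else in the
pipeline). The temporal mask takes one value per frame; within-frame
continuous evaluation is not modeled.

Masking a frame computes `mean + (frame − mean)·mask` in floating point, so
each pixel keeps exactly `mask` times its original Weber contrast; 8-bit
clipping/quantization happens only on export. The mean gray level defaults to
the per-video mean intensity and is recorded with the run.

## Simulated observers

The generator emulates the study design: per participant one block of 384
two-alternative trials, 8 temporal or 20 spatial bubbles per trial, observers
spanning chance to ~75% correct. No observer model is implied by the bubbles
method itself, so one had to be chosen. The default is a linear psychometric
map: with revealed information `I = Σ(profile·kernel)/Σ(kernel)` ∈ [0, 1],

    p(correct) = 0.5 + (p_max − 0.5) · I.

Linearity makes the expected classification array an affine function of the
kernel (restricted to the bubble-coverage weighting), which is precisely the
premise of parameter-recovery testing; logistic and hard-threshold variants
are available (`psychometric` option) for robustness checks. The kernel is an
indicator window in the shipped configurations, but any nonnegative array
works. Stimulus labels are Bernoulli(0.5) by default; exact 50/50 balancing
per block is a flag. Each participant consumes an independent RNG stream
spawned from the master seed, so cohorts are reproducible and uncoupled.

What the generator deliberately omits: learning across trials, per-video
idiosyncrasies, response times and early video termination, eye movements,
and any nonlinear temporal integration of partially revealed evidence.
Passing recovery tests therefore show the *pipeline* recovers a planted
information source under a known observer; they do not validate the linear
observer as a model of human information use.

## Classification arrays

`RCA = Σ_c Bubbles_c − Σ_i Bubbles_i` over trials. The permutation z-score
reassigns correctness labels without replacement — preserving the observed
correct/incorrect counts — and applies one shared shuffled label vector per
iteration to all points simultaneously, preserving the spatial/temporal
correlation structure of the null. 2,000 iterations by default. Points whose
permutation SD is zero (all trials share one profile value there, e.g. fully
unrevealed corners) are flagged degenerate and assigned z = 0 rather than
NaN, keeping group statistics computable; flags propagate to inference,
where such points are barred from cluster membership. Permutation moments
are accumulated in chunked matrix products, so memory stays bounded for 2-D
domains.

Spatial profiles are re-centered before summation (re-center → sum →
permute): each video's profile is translated so its contact point lands on a
common origin. The canvas is symmetric about the origin and sized so the
union of all translated 600×400 regions fits entirely; uncovered cells are
zero and tracked in a coverage mask. Translation uses the integer offset
nearest `origin − contact_point`, since profiles live on the pixel grid.
Z-scoring after re-centering (rather than before) keeps the per-point null
aligned with the coordinates in which group inference happens.

Participants are excluded when bubbles-block accuracy falls below 55%; the
exact one-sided binomial tail P(X ≥ n_correct | p = 0.5) is reported for
context but is not the criterion — at 384 trials the two rules disagree only
in a narrow band, and the accuracy threshold is the operational rule.

## Group inference

The t analysis uses only included participants; the r analysis uses the whole
cohort, since variation in ability is its signal. Cluster-forming threshold:
the parametric two-tailed p = .05 critical value of the statistic at the
sample's degrees of freedom (one-tailed for one-tailed tests); it is
configurable, and maps are also reported normalized by it, so |normalized| > 1
marks potential cluster membership. Contiguity is frame adjacency in 1-D and
4-connectivity in 2-D (8-connectivity by option). The cluster metric defaults
to mass (sum of suprathreshold |statistic|), with extent available.

Null distributions: sign-flipping each participant's whole array (t), exact
when per-participant arrays are symmetric about zero under the null, or
permuting the accuracy vector across participants (r). When 2^n sign patterns
(or n! orderings) fit within the permutation budget the null is enumerated
exhaustively and p-values are exact counts; otherwise Monte-Carlo sampling is
used with the add-one estimator `(1 + #{null ≥ observed})/(1 + n_perm)`,
which is unbiased conservative and never returns p = 0. Two-tailed tests
compare against the null maximum of |statistic| (and clusters of both signs);
the r analysis defaults to one-tailed in the pipeline report. Constant
confidence bands for r use the Fisher z transform with SE = 1/√(n − 3); the
transform choice is recorded in the report metadata. |r| = 1 points are
flagged as infinite on the transformed scale.

## Problem sizes and calibration studies

The characterization studies run the temporal pipeline at the study's design
scale — 27 observers × 384 trials, 8 bubbles of σ = 3 over 96 frames — with
500 within-participant and 2,000 group permutations per replicate, 200
replicates for type-I calibration and 50 for recovery; pooled-z calibration
uses 105 guesser blocks at the full 2,000 within-participant permutations
(~10^4 points). These sizes give binomial error bars a few percentage points
wide on the estimated rates while keeping a full run in the low minutes on a
single core. Quick tests and the spatial examples use reduced grids (e.g.
60×40); the 600×400 geometry is the documented full-scale setting, and the
chunked permutation code handles it at the cost of proportionally longer
runs.

## Known limitations

* The linear-overlap observer is an assumption; real observers integrate
  information in unknown, probably nonlinear ways.
* Edge truncation makes expected coverage dip near domain boundaries, so the
  classification array is slightly less sensitive there.
* Negative flanking clusters are expected under a fixed bubble count: trials
  revealing more of the kernel window necessarily reveal relatively less
  elsewhere, inducing weak negative classification weight outside the window.
* Sign-flip exactness relies on per-participant symmetry about zero; the
  within-participant permutation z satisfies this only approximately at
  finite trial counts (the type-I calibration study measures the practical
  consequence).
* No parametric random-field or FDR corrections, no between-group contrasts,
  no color/audio/display-timing modeling.
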