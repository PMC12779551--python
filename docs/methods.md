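# Methods

This note records the models, estimators, defaults and numerical choices
behind `mnscreen`, and what the synthetic-data experiments do and do not
demonstrate.

## The neurite survival model

Each well contributes a daily series of total neurite length (µm). The
synthetic generator's latent curve is the product of two logistic
sigmoids,

    L(t) = A · σ((t − t_g)/τ_g) · σ((t_d − t)/τ_d),

the simplest form with the observed three phases (growth, plateau,
decline). Observations multiply L(t) by (1 + ε) with ε ~ N(0, cv²) —
multiplicative, CV-scaled noise is an assumption, not an observed
distribution — and each day is independently marked "failed
quantification" with a dropout probability. Dropout is a distinct state
rather than a zero because the QC rules treat failed time points
differently from low signal.

Defaults emulate the screening protocol: daily imaging on days 22–60
(reporter delivered day 21, screens end by day 60), six replicate wells
per donor (two for drug-screen treatments, which were run in duplicate),
peak amplitude 200,000 µm, growth midpoint day 28 with 2-day scale,
well noise CV 0.10, donor LD50 s.d. 2 days around group means of 50
(control) and 44 (case) days.

The generator's true LD50 is solved on a 0.01-day grid restricted to
t ≥ argmax L, matching the "after peak" semantics of the observed
statistic; if the curve never reaches half its maximum in range, the
endpoint day is returned. Because the crossing day of the logistic
product is not a pure translation of t_d, donor and treatment LD50
targets are mapped to decline midpoints by bisection
(`calibrate_decline_midpoint`), so a "+4 day" treatment effect shifts the
analytic LD50 by exactly 4 days.

## Per-well phenotypes

- **Peak normalization** divides by the well's maximum over non-failed
  days (×100); the maximum of every normalized curve is exactly 100.
  A pre-treatment variant normalizes to a reference day (e.g. day 36).
- **Growth / decline rates** are the maximum percentage change over
  ordered day pairs exactly 5 days (growth) or 2 days (decline) apart.
  Pairs whose partner day failed are skipped, not interpolated — the
  simplest faithful reading of "over 5 days"/"over 2 days". A 2-day
  growth-window variant exists as an option.
- **LD50** is the first *sampled* day at or after the peak day with value
  ≤ 0.5 × peak, or the endpoint. No smoothing is applied first, ties go
  to the first qualifying day, and the statistic is not interpolated by
  default (imaging is daily; donor means become fractional through
  averaging). A linear-interpolation mode exists but is off by default.
  The search deliberately starts at the peak day: an early sub-50% dip
  during growth is not degeneration.
- **QC rules** exclude wells that (a) never reach 12,500 µm total length,
  (b) fail quantification on more than 25% of scheduled days, counting
  only days outside the 50–60 window (where failure can be genuine
  degeneration) in both numerator and denominator — the denominator
  convention is ours, the rule's source does not define it — or
  (c) have an LD50 before day 39 (pre-maturation). Reasons are
  cumulative. Donors need ≥3 passing wells to be reported; donor
  summaries are means ± s.e.m. (ddof = 1).

## Image quantification

The per-field pipeline is enhance → segment → skeletonize → measure:

1. **Enhance**: grayscale morphological opening (disc, default radius
   20 px) estimates background; the clipped residual passes through a
   Sato tubeness filter (scales 1 and 2 px) that amplifies curvilinear
   structures.
2. **Segment**: the ridge response is thresholded with Li's cross-entropy
   method by default. Otsu is selectable but misplaces the cut on ridge
   images, whose histogram is a near-zero mass with a sparse bright tail
   rather than bimodal. Somata are thresholded from the raw image (Otsu —
   the raw histogram *is* bimodal), opened with a 3-µm disc so thin
   filaments cannot masquerade as cell bodies, and area-filtered
   (default ≥40 µm²). Soma pixels plus a 4-µm rim are excluded from the
   neurite mask: the ridge filter responds strongly at soma edges and
   would otherwise contribute ring-shaped skeleton artifacts. Neurite
   objects shorter than 10 µm are dropped.
3. **Measure**: topology-preserving skeletonization; terminal branches
   shorter than 5 µm that end at junctions are pruned as skeletonization
   artifacts; length is the sum over adjacent skeleton-pixel pairs of
   1 (4-neighbors) or √2 (diagonals) × pixel size. Geometric weighting is
   stated explicitly because raw pixel counting understates diagonal runs
   by up to 41%. A mask-area-derived length (area / typical width) is
   available for comparison; skeleton length is the reported readout.
   Soma pixels never contribute to neurite length (a process, not a cell
   body).

Per-well quantification averages 1–8 fields; a well-day is "failed" when
segmentation raises or all fields are blank. On rendered synthetic fields
(256², PSF σ 1.5 px, Poisson noise) the median absolute relative error of
total length is ~2–4%, and the measure is rotation-robust at 0°/45°/90°
and stable under 2× supersampling when the pixel-denominated parameters
are scaled accordingly.

## Drug-screen analytics

Days of rescue = treated LD50 − matched DMSO LD50; negative values
(toxicity) are reported and never truncated. Large screens are expressed
relative to the donor's mean LD50 over all screened treatments (zero-sum
by construction; DMSO is excluded from the averaging denominator by
default, includable by flag) and truncated one-sidedly at +5 days because
imaging stops 5 days past the DMSO LD50. Responder fractions report
donors with rescue > 10 days, rounded to the nearest integer percent.
Fold ratios versus a reference drug are rounded to one decimal and
require a positive reference rescue.

Significance uses a Kruskal–Wallis omnibus (tie-corrected H, chi-square
p) followed by Dunn z-comparisons of each drug against the DMSO reference
on the pooled ranks with Bonferroni control over the k−1 comparisons —
implemented from the rank formulas and cross-checked against
`scipy.stats.kruskal`. On null screens (107 drugs × 16 donors) the
gatekept per-drug false-positive rate is far below the nominal 5%.

## Calcium transients

ΔF/F = (F − F0)/F0 with F0 the median fluorescence of the session (a raw
F/F0 mode exists since both readings of "ratio to baseline" are
defensible). Traces are smoothed with a Savitzky–Golay filter (window 9
samples ≈ 0.9 s at 10 Hz, order 3 — unpublished choices, recorded as
defaults only; edges use the terminal window's polynomial). Events are
detected on the smoothed trace (the filter immediately precedes
detection) at upward crossings of k × s.d. (k = 3). The baseline s.d.
estimator is robust by default (1.4826 × MAD of the smoothed ΔF/F),
which approximates baseline noise while ignoring events; a global-s.d.
estimator is selectable. A 5-sample refractory period suppresses
threshold chatter, and a renewed peak of prominence ≥ 0.5 × threshold
while the trace is still elevated is called as a further event, so
transients arriving before the previous one has decayed are not silently
merged. Amplitudes are taken from the *unsmoothed* ΔF/F within the event
span, because the smoothing window flattens peaks whose decay is of the
same order (a τ = 0.5 s transient loses ~25% of its smoothed peak).

The generator injects Poisson-timed events adding a·exp(−Δt/τ) in ΔF/F
units on a constant baseline with Gaussian noise. Defaults: 10 Hz,
amplitude 0.8 ΔF/F (8× the 0.1 noise s.d.), τ = 0.5 s — a typical fast
somatic transient decay, and one for which events at the simulated rates
remain resolvable at 10-Hz sampling. At 0.2 Hz the detected frequency
undershoots truth by ~12% purely from Poisson pileup (events closer than
the refractory period are unresolvable without deconvolution, which is
out of scope); at 0.1 Hz recall exceeds 99% with <0.002 false events/s.

Group summaries average frequency over ROIs and pool amplitude over
events (deliberately different n). Comparisons use the two-sided
Mann–Whitney U test: exact enumeration when min(n) ≤ 8, tie-corrected
normal approximation otherwise (via scipy, validated against brute-force
enumeration).

## Survival, correlation and power statistics

LD50 days are survival times. Wells or donors whose curve never crossed
50% carry the endpoint day and enter the Kaplan–Meier product-limit
estimate and log-rank test as **censored** — the only convention that
avoids treating "no degeneration" as an event; survival units default to
donors (well-level mode available). The log-rank chi-square (1 df) is
built from observed-vs-expected events at each distinct event time with
the hypergeometric variance, matches an independent O/E tabulation to
1e-9 and `lifelines` to machine precision, and its null rejection rate is
calibrated at 5% ± 2%.

Clinical correlations are pairwise-complete Pearson or Spearman
coefficients; clinical variables may be log-transformed first (used when
they look log-normal). Spearman p-values use exact permutation below
n = 10 and the t approximation above. Signature comparisons compute
Spearman rho between paired log2 fold-change vectors and build a control
distribution by randomizing the order of the reference vector (seeded,
n_perm ≥ 100), reporting the analytic p alongside the permutation
quantile; the null is centered to within 3/√n_perm.

Prospective sample sizes come from a noncentral-t power calculation for
the two-sample t-test (Welch correction is the default elsewhere for
unequal-variance comparisons): the smallest per-group n with power
≥ 1 − β, floored at 2. At d = 2, α = 0.05 two-sided, power 0.8 the
answer is 6 per group, confirmed by a 20,000-replicate simulation oracle
(power ≈ 0.79 at n = 5, ≈ 0.875 at n = 6).

## Problem sizes and determinism

Every generator and experiment is deterministic under its seed. The
validation experiments run at: 100 noiseless curve draws and 100 noisy
donor recoveries (LD50 fidelity), 50 rendered 256² fields (image
quantification), 50 screen replicates of 107 drugs × 16 donors (ranking)
and 200 null screens (calibration), 1000 log-rank null replicates, 50
calcium traces of 100 s (detector performance), and 1000 permutations
(signature null) — sizes chosen so the full suite completes in minutes
on a single core while keeping Monte-Carlo error well inside the margins
being tested.

## Known limitations

- The synthetic plate does not model spatial plate effects, batch/run
  effects, or donor-specific curve shapes beyond the LD50 shift, so
  passing tests show estimator correctness under the stated noise model,
  not robustness to real-world systematic error.
- Rendered images stress skeletonization (curved, crossing filaments,
  bright somata, PSF, Poisson noise) but not full neuronal morphology,
  uneven illumination, or debris; segmentation parameters are exposed for
  real data.
- The whole-trace median ΔF/F baseline assumes events are sparse; dense
  activity inflates both the baseline and the robust s.d. estimate,
  raising the detection threshold.
- No dose–response modeling, Cox regression, mixed models, or
  differential-expression computation: fold-change vectors and ROI traces
  are inputs, per the module contracts.
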