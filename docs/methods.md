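# Methods

## Study-design arithmetic

A rider×horse combination is summarised by the bodyweight ratio
R/H = 100·(rider bodyweight + saddle weight)/horse bodyweight (%), where the
rider is weighed with full equipment and each horse carries its own fitted
saddle. Ratios and BMIs are rounded **half-up to one decimal before**
banding and summarising, because the design tables print one-decimal values
and the published group ranges quote those rounded numbers; reproducing the
72-cell ratio grid exactly requires this order of operations. Band edges are
read literally: a rounded ratio of exactly 12.0 is light, 15.0 is moderate.
Ratios outside [10, 18) are labelled `out-of-design` rather than rejected so
the generator may stress the bands. Group ranges are always reported as
(min, max) even where a source table prints them inverted.

## Texture features

All texture math operates on a single component plane (R, G or B) restricted
to an ROI mask; masks are binary rasters, with rectangle/polygon geometries
rasterized by pixel-center inclusion. Only member pixels enter the
histogram, and runs/pixel-pairs must lie wholly inside the mask — mask gaps
terminate runs and invalidate pairs, so bounding-box fill values can never
leak in.

**Histogram statistics.** H(k) = count(k)/NM over the ROI's NM member
pixels, k = 0..2ⁿ−1 with n = 8 bits by default. Moments are population
moments of H; Skewness and Kurtosis are normalised by Variance^{3/2} and
Variance² (excess form, −3), and defined as 0 on a zero-variance plane.
PercXX is the smallest gray level whose cumulative histogram reaches XX %.
Domn01/Maxm01 are the argmax and maximum of H; Domn10/Maxm10 the argmax and
maximum of the r-bin moving sum of H with r = 10, ties broken toward the
smallest gray level. The r = 10 window and the moving-sum reading follow
the "10"-suffix naming convention of the MaZda feature set; the upstream
printed formulas for these four features are typographically corrupted, so
this is a documented interpretation, not a transcription.

**GLRLM.** Runs are maximal stretches of equal gray level along one scan
direction (0°, 45°, 90° or 135°); the default direction is horizontal, the
only one worked through in the source material. With np = ΣΣ p(i,j) runs:
GLN = Σᵢ(Σⱼp)²/np, RLN = Σⱼ(Σᵢp)²/np, LRE = ΣΣ j²p/np, SRE = ΣΣ p/j²/np,
Fraction = np / ΣΣ j·p (the fraction of the ROI's pixels that start a run),
and the moment variants MRLN = Σⱼ(Σᵢp)²/np², MGLN = Σᵢ(Σⱼp)²/np² — the
natural reading of the printed 1/np² prefactor.

**GLCM.** Co-occurrences are accumulated symmetrically (each ordered pair
increments both p(a,b) and p(b,a)) at distance d = 1 and normalised to sum
to one; symmetrisation and normalisation commute, so the order is
immaterial. Features use 0-based gray values; μ/σ are the mean/standard
deviation of the marginal distribution (so Correlat is a true correlation in
[−1, 1]); the sum/difference marginals are p_{i+j}(k), k = 0..2K−2 and
p_{|i−j|}(k), k = 0..K−1. Entropies use log base 2 (bits) with 0·log 0 = 0;
a zero-variance marginal gives Correlat = 0 by convention. InvDefMom uses
the standard 1/(1+(i−j)²) kernel. Features are computed per direction and
averaged over the four canonical directions by default (the per-direction
values remain available); direction averaging at the feature level keeps
each direction's matrix a proper probability distribution.

These conventions make the degenerate cases total: a constant ROI yields
Variance = Contrast = Entropy = SumEntrp = DifEntrp = 0 and
AngScMom = InvDefMom = 1 with no errors.

Every feature implementation is cross-validated against an independent
brute-force oracle (dictionary-based pair/run enumeration and direct
summation, in `tests/oracles.py`) to 1e−9 relative tolerance on over a
hundred seeded random planes.

## Statistical screen

Stage 1 compares pre- vs post-exercise per feature key and per group, with
realizations paired by rider×horse. The Shapiro–Wilk gate (α = 0.05 — the
source states only the comparison α, and the same value is adopted for the
gate) is applied to **both** paired series; the paired t-test runs only when
both pass, which is the conservative reading of a normality-gated protocol.
Wilcoxon discards zero differences and uses the exact distribution up to 25
non-zero pairs, else a continuity-corrected normal approximation; an
all-zero difference series is reported as non-significant rather than an
error. A key is carried forward only when p < α in L, M and H
simultaneously — a deliberately strict triple conjunction whose null
selection probability per key is about α³.

Stage 2 compares the post-exercise series across groups: ANOVA + Tukey HSD
when all three series pass the gate, else Kruskal–Wallis + Dunn. Dunn's test
is the standard z-test on joint mean ranks with tie correction and, by
default, no further p-adjustment (an adjustment method can be supplied);
it is implemented in-package and verified against the closed-form rank
computation. Patterns: III when all three pairs differ, II when L–H and M–H
differ but L–M does not, I when only L–H differs; configurations outside
these (e.g. only L–M significant) are reported verbatim as `other`.

No multiplicity correction is applied across the 372 keys, matching the
per-feature α = 0.05 protocol being emulated; a Benjamini–Hochberg column is
emitted for inspection but never drives selection.

## Synthetic study generator

The generator emulates the design, not the anatomy: each combination's
image is a smooth spatially-correlated Gaussian field (low-pass-filtered
white noise, correlation length 8 px, sd 0.8 °C) around a 30 °C baseline,
plus 0.5 °C white sensor noise, on a 120×160 grid (the resolution class of
the compact thermal cameras used for such studies). Post-exercise fields add
a uniform 1.5 °C warming — an order-of-magnitude choice for a 30-min ridden
exercise bout, as the emulated study does not print per-feature means — and
extra white heterogeneity noise confined to the muscle-rich ROIs 1, 3 and 4,
with group sd multipliers L/M/H = 0.3/0.6/0.9 °C. Cohort draws follow the
published moments (horses ≈ N(566.7, 13.7²) kg, heights N(160.3, 3.9²) cm,
saddles U(4.1, 4.5) kg; rider weights near 59/76/91.5 kg with heights set
from group-typical BMIs). Per-(combination, timepoint) random streams are
spawned from the master seed via `numpy.random.SeedSequence` spawn keys, so
any subset regenerates identically.

Rendering uses an explicit 6-control-point iron-like palette over the
camera working range 10–50 °C (vendor palettes are proprietary), with a
**non-decreasing red channel** — this monotonicity is what converts
temperature heterogeneity into red-component texture heterogeneity, the
coupling the screen is designed to detect. Effects are injected in
temperature space so the conventional and texture pipelines see one
coherent physical signal.

What the generator does *not* emulate: anatomical structure and
left/right asymmetries, palette banding of real FLIR exports, JPEG
compression artefacts, motion/angle variation between shots, and
between-horse baseline differences beyond the random field. Passing tests
therefore demonstrate the pipeline's correctness and statistical
calibration under a controlled signal, not field performance on real
thermograms.

One property of the model worth knowing: because post-exercise
heterogeneity noise also deepens the ROI *minimum*, Tmin in muscle-rich
ROIs can be pulled back toward its pre-exercise value in the heaviest
group; Taver rejects pre/post in every ROI and group, but the full
conventional triple need not.

## Problem sizes and numerical choices

The default study is 72 combinations × 2 timepoints = 144 images;
extraction of all 372 texture + 12 conventional columns takes ~10 s and the
full screen a few seconds more. Calibration checks use 1000 data-level null
replicates at n = 24 realizations per group; effect-recovery checks use
50 replicate studies (tests) / 30 (acceptance script) with the default
effect sizes, and a doubled-multiplier study for the pattern-III check.
Oracle equivalence uses 8×8 to 16×16 planes whose pixel counts are powers
of two, so histogram probabilities are exactly representable and the 1e−9
comparison is meaningful down to floating-point noise.

## Known limitations

* Decoding proprietary radiometric JPEG payloads is out of scope;
  conventional features require an explicit temperature matrix (CSV).
* Automatic ROI segmentation is out of scope; masks are supplied as rasters
  or geometry files.
* The screen is a faithful re-implementation of a per-feature α = 0.05
  protocol; users wanting family-wise guarantees should use the emitted FDR
  column or supply a Dunn adjustment method.
* Real-study significance counts cannot be reproduced without the original
  images; the package's claims are calibration and recovery on synthetic
  studies plus exact reproduction of the printed design arithmetic.
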