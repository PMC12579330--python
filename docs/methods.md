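# Methods

This note documents the models, defaults, and numerical choices behind
sporescope, and what the synthetic fixtures do and do not establish about
real data.

## Micrograph morphometry

Segmentation is deliberately minimal and reproducible: Otsu global
threshold on the darker-object polarity (conidia are darker than the agar
background in transmitted light), binary hole filling, 8-connected
labelling, exclusion of border-touching components, and an area gate in
µm² (defaults 1–50 µm², generous around the ~7 µm² spores of interest).
Labels are renumbered 1..k in raster order so outputs are stable.

"Sagittal plane" — a spore lying flat so its full long-axis profile is
visible — is operationalized as a shape gate with three configurable
criteria: solidity ≥ 0.90, ellipse aspect ratio in [1.2, 4.0], and a
symmetric-difference residual between the region and its moment-fitted
ellipse of ≤ 10 % of the region area. The defaults were chosen so an
isolated rasterized ellipse passes while overlapping pairs (low
solidity), near-circular end-on spores (low aspect), and concave merges
(high residual) fail. The gate is geometric, not photometric: defocused
but well-shaped objects will pass.

Length and width are the major/minor axes of the ellipse with the same
normalized second central moments as the pixel set — a deterministic
choice that matches ellipse-like conidia; Feret diameters would run
1–2 % larger on rough boundaries. Area is the raw pixel count divided by
s², not the fitted-ellipse area, so irregular spores are measured as
imaged; consequently `area_um2 · s² = area_px` holds exactly, which the
tests assert to 1e-8.

Conidiophore length is the longest geodesic path through the
morphological skeleton (8-neighbour graph, diagonal steps weighted √2),
extended at each end by the endpoint's Euclidean distance to the
boundary, because thinning retreats about half a width from each tip.
For an L-shaped stalk this measures the tip-to-tip centerline, which is
shorter than the naive sum of overlapping arm lengths. "Width at the
base" is ambiguous on a micrograph; here it is twice the distance
transform averaged over the 3 skeleton pixels nearest the basal endpoint,
the basal end being the endpoint with the larger local width. Ring-like
regions (no skeleton endpoints) and compact blobs (centerline length ≤ 2×
mean width) are rejected.

Calibration is a single isotropic scale, default 15.8097 px/µm; all
module outputs are µm/µm².

## Flow cytometry

Peaks are single Gaussians — no S-phase/doublet modeling — because the
quantities of interest are G1 peak means and CVs. Candidates come from
prominence-ranked local maxima on a Savitzky–Golay-smoothed histogram
(window 11 bins, order 3, both configurable); each candidate is refined
by least-squares Gaussian fit within ±2 FWHM, and a peak must hold at
least 1 % of total events. Event lists are binned to 1024 equal-width
bins by default.

Genome size is linear in the sample/standard channel ratio by
construction. The standards registry carries the four internal standards
used in this line of work (Solanum 1.96, Pisum 9.09, Secale 16.19 pg/2C;
Colletotrichum acutatum PT812 at 68 Mb ≈ 0.069 pg/1C). QC is a hard gate:
≥ 5,000 events in both peaks and CV at or below 3 % (plant nuclei) or
10 % (fungal nuclei); boundaries are inclusive, so a peak at exactly
5,000 events / 3.00 % CV passes, and loosening the policy can never turn
a pass into a fail.

pg ↔ Mbp uses 978 Mbp/pg, configurable. Note that a printed pair such as
0.045 pg / 42.8 Mb is not internally consistent with 978 (0.045 × 978 =
44.0); such pairs typically come from converting an unrounded mean, so
the constant is exposed rather than hidden.

Ploidy is assigned by minimizing |pg_2C / p − 1Cx| over a candidate set
(default {4, 6, 8}), ties toward the smaller ploidy. The default
monoploid reference 1Cx = 1.95 pg is a convention — roughly the mean
monoploid content implied by the three host cytotypes this toolkit was
built around — and should be overridden for other systems.

FCS input is not supported; delimited histograms (`channel,count`) and
event lists are first-class.

## Permutation statistics

PERMANOVA uses the Gower-centered inner-product matrix G = J(−D²/2)J and
sequential (Type-I) sums of squares: terms are added in the listed order,
SS_term = tr((H_k − H_{k−1})G) with hat matrices built by QR, pseudo-F =
(SS_term/df)/(SS_resid/df_resid). Term order is therefore user-visible
and meaningful for unbalanced designs. The null permutes rows/columns of
G jointly — free permutation by default, optionally restricted within
the levels of a strata column for nested designs. p-values use
(1 + b)/(1 + B), never zero; permuted statistics within a 1e-9 relative
tolerance of the observed value count as ties (without this, exact
symmetry permutations drift below the observed F by float noise and the
null distribution loses its tie mass).

Pairwise permutation tests default to the Euclidean distance between
multivariate group centroids on z-scored traits (per-trait mean
difference available), permuting labels within each pair; Holm–Bonferroni
is applied across all pairs. Traits are z-scored by default everywhere a
distance or component is computed, because the trait set mixes µm and
µm² scales.

PCA is a plain SVD of the centered (optionally z-scored) matrix with a
deterministic sign convention (largest-magnitude loading positive). LDA
uses pooled within-class covariance with equal priors and a 1e-8 ridge on
the covariance trace — with 16 observations and 4–5 traits the pooled
covariance is close to singular — and is evaluated by leave-one-out
cross-validation with Cohen's κ computed from the confusion-matrix
marginals. Tukey HSD p-values come from the studentized-range
distribution; the compact letter display is assigned greedily from the
largest group mean, then repaired so that two groups share a letter
exactly when they are not significantly different (the pure greedy pass
can strand a non-significant pair in disjoint letter sets). With zero
within-group variance and unequal means the pairwise p-values sit at the
0 floor and every distinct mean receives its own letter.

Growth rate is the endpoint difference quotient (final − initial
diameter)/Δt in mm/day; intermediate time points are recorded but do not
enter the rate.

## Sequence variability

A column is variable when ≥ 2 distinct unambiguous bases occur among
retained residues, parsimony-informative when ≥ 2 bases each occur in
≥ 2 sequences. The default gap policy drops gaps and IUPAC ambiguity
codes from each column's denominator, so gap-only variation is never
reported; a strict mode drops any column containing them. SNP calls
report columns whose most frequent non-majority base reaches the
threshold, inclusive — with four haplotypes a singleton at exactly 25 %
must be callable, which fixes the boundary convention. Positions are
1-based; majority ties break alphabetically for determinism.

## Synthetic fixtures

The spore-field generator renders anti-aliased filled ellipses (4×4
subpixel coverage) with lengths from a truncated normal 4.4 ± 0.4 µm on
[3.4, 5.5] and widths 2.0 ± 0.2 µm on [1.5, 2.6] — the regime of haploid
*Epichloë*-type conidia — at random orientation, with Gaussian blur
(σ = 0.8 px) and additive noise (σ = 0.02 of the intensity range).
Truncated normals are sampled by rejection, which keeps the support
exact. Oblique/off-plane objects are modeled as overlapping ellipse
pairs so the sagittal gate has true negatives. Placement is rejection
sampling with a minimum clearance; ground truth (analytic length, width,
πab area) is always returned.

The cytometry generator draws per-peak events from N(mean, cv·mean/100)
plus an optional exponential low-channel debris tail and bins over a
fixed (0, 1024] channel range, so adding debris does not shift the
binning of the G1 peak. The table generator produces the nested layout
site×ploidy cell → individual → replicate (defaults: 4 cells, 4
individuals, 10 replicates: 160 rows) with additive cell effects, an
individual-level random effect, and replicate noise per trait.

What passing on these fixtures does **not** show: robustness to uneven
illumination, touching spore chains, hyphal clutter, or debris-heavy
histograms with non-exponential shape; the generators are clean-world
models whose purpose is to verify the measurement and inference chain,
not the optics.

## Problem sizes and determinism

The test and acceptance runs use 200 rendered spores (10 fields of 20),
500 null replicates at 999 permutations for PERMANOVA calibration, full
720-permutation enumeration at n = 6, 1,000 random alignments against a
brute-force column oracle, and 6,000-event histograms — sizes chosen so
the whole verification chain recomputes in well under a minute on one
CPU while keeping Monte-Carlo tolerances meaningful. Every stochastic
step takes an explicit seed (NumPy `default_rng`), and all generators are
pure functions of (spec, seed).

## Known limitations

No cell-cycle modeling or spectral compensation in cytometry; no mixed
effects models for growth curves (the rate statistic plus permutation
tests cover the implementable content); LDA assumes shared class
covariance; the PERMANOVA strata option restricts permutations but does
not implement full multi-level exchangeability restrictions; conidiophore
base-width is a skeleton-local convention, not a botanical landmark.
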