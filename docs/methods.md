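# Methods

This note records the models implemented by `synletscreen`, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter.

## Viability normalization and effects

Raw plate reads are normalized per (cell line, compound pair, replicate)
group by the arithmetic mean of that group's vehicle wells
(conc_A = conc_B = 0), so vehicle wells average to 1 and values above 1
(growth stimulation) survive normalization. The inhibition effect is
α = 1 − viability, clipped to [0, 1] by default: the Bliss model composes
effects as probabilities, and an effect outside [0, 1] has no probabilistic
reading. Clipping is a flag (`clip=False` keeps α + viability = 1 exactly)
and the choice is recorded in run manifests. Normalization is idempotent:
re-normalizing a normalized group divides by a vehicle mean of 1.

## Bliss scoring

For a dose matrix with single-agent edges α_A(i) (column conc_B = 0) and
α_B(j) (row conc_A = 0), the expected combined effect is
α_exp(i,j) = α_A(i) + α_B(j) − α_A(i)·α_B(j) and the excess is
Δα(i,j) = α_obs(i,j) − α_exp(i,j). Single-agent effects come from the
matrix's own edges, not from refitted curves — the screen design puts the
single agents on the same plate precisely so the null is internally
controlled. Edge cells are identically zero by construction (to floating
point; asserted at 1e-12).

The scalar score is 100 × mean(Δα). The default aggregation domain is the
25 cells with both concentrations positive (`combinations_only`): edge
deltas are structural zeros and averaging them in only rescales a given
signal by 25/36, which both modes expose and a flag toggles. The >15-point
synergy call uses a strict inequality. Replicates are scored individually
and then summarized (mean, sample SD with n−1), matching how replicate
synergy values are conventionally reported; averaging viabilities before
scoring is available by flag but is not the default because it hides
replicate scatter.

## Differential ranking

Per-genotype means are unweighted across cell lines (the target design has
two lines per genotype; nothing supports weighting). Compounds are ranked
by mean(deficient) − mean(proficient), descending, ties broken by the
deficient mean and then compound name so ranking is deterministic. A "hit"
is a rank-1 compound whose deficient mean also clears the synergy
threshold — the two criteria the screening logic applies jointly. Compounds
lacking any scored line in one genotype are excluded and reported, never
silently dropped; incomplete dose matrices likewise go to a QC list.

## Dose–response fitting

The 4PL v(c) = bottom + (top − bottom)/(1 + (c/IC50)^hill) is fitted by
nonlinear least squares on log10 concentration (scipy `curve_fit`,
bounded), with three midpoint starts bracketing the concentration range;
the best SSE wins. Defaults let top float in [0.8, 1.2] and bottom in
[0, 1]; both plateaus can be pinned (fixed-plateau "logistic
interpolation" behavior) since plate software differs on this and the
convention behind any given published IC50 is rarely stated. Flat data
(variance < 1e-6) raise a degenerate-fit error; an optimizer failure
returns `converged=False` with NaN parameters rather than raising, so
batch fitting can triage. Effect levels are read off the fitted curve by
closed-form inversion, valid only strictly between the plateaus. Fits are
invariant to point order and, at the screen's 10-point ladder, recover
noiseless generator parameters to well under 1%.

## Focus counting

Background correction fits a degree-2 polynomial surface by iteratively
reweighted least squares (pixels more than one residual SD above the
surface are dropped each round, so the surface tracks empty regions), on a
4× subsampled grid for speed; a morphological-opening background is
available as an alternative. The correction is approximately idempotent
and exact for constant and planar backgrounds.

Nuclei are Otsu-thresholded connected components; per-object area,
isoperimetric shape ratio (perimeter²/4πA), length/width ratio (major/minor
axis), and mean/total intensity are checked against the standard
high-content windows (defaults: 100–1500 µm², 1–5, 1–5, 500–8000,
2×10⁵–5×10⁷ a.u.), with excluded objects tallied by the first violated
rule. All geometric filters are in µm², so the pixel scale is explicit
(default 0.65 µm/px for a 20× objective with 2×2 binning; vendor docs give
magnification but not scale, so it is a parameter, not a constant).

The vendor "box method" spot detector is proprietary; it is implemented
here as its published intuition: square-kernel local background removal — a
white top-hat with a (2·box+1)² footprint, box = 3 by default — after light
Gaussian smoothing (σ = 1 px), followed by positive-residual thresholding.
The threshold is the largest of (i) 4 robust SDs (MAD-based) of the
within-nucleus residuals, (ii) 15% of the peak residual (prevents faint
spot shoulders from bridging neighbors in low-noise fields), and (iii) an
absolute 20 a.u. floor (far below the 500 a.u. average-intensity window a
countable focus must reach, above the few-a.u. residue segmentation edges
leave in the top-hat). Detection is restricted to nucleus masks eroded by
the box half-width so the enhancement window stays interior; candidate
spots then pass the focus windows (1–30 µm², same shape ratios, 500–16000,
3×10²–10⁶ a.u.) measured on the corrected channel. Blobs larger than the
box are flattened by the opening itself — by design such structures are
not point foci. Per-condition statistics are mean foci per cell ± SEM and
cells per field.

## Tumor endpoints

Volume is the caliper ellipsoid 0.5·L·W² (mm³); swapped length/width are
corrected with a warning since the caliper convention defines length as
the larger diameter. RTV divides by the day-0 volume (RTV(0) = 1 exactly).
Progression is the first *measurement* day with RTV ≥ 10 — no between-visit
interpolation, because twice-weekly calipering defines the resolution of
the endpoint. Animals without a crossing are censored at their last
measurement, or at a recorded removal day (death, open tumor). The log-rank
test is the unweighted Mantel–Cox variant and Kaplan–Meier estimation is
the product-limit estimator, both via lifelines.

A note on small-sample log-rank p-values: with 3 + 3 animals the exact
permutation distribution of the statistic has only C(6,3) = 20 atoms, so
the chi-square p can differ from the exact permutation p by ~0.1 in the
small-p range; the two converge for interleaved (null-like) data. The test
suite checks the implementation against a seeded permutation oracle on a
fixture in that convergent regime and documents the gap.

## Synthetic-data generators

All generators are pure functions of (spec, seed), using numpy's seeded
`default_rng`; identical seeds give byte-identical outputs.

*Screens.* Viability is multiplicative in the single-agent responses
(v[i,j] = v_A(i)·v_B(j)), which is exactly the Bliss null, minus an
injectable delta on combination cells, plus additive Gaussian noise
truncated at zero (σ default 0.05, the order of replicate scatter such
screens report on the score scale). Single-agent responses are 4PL with
plateaus in [0.45, 0.6] and hills in [1, 1.8] — shallow partial-response
curves typical of a 72-h viability screen titrated around the IC50 — on
5-point two-fold-spaced ladders centered on the per-compound IC50 (clipped
to the 0.02–20 µM screen range). These plateaus also keep the null surface
far enough from zero that injected deltas up to 0.25 pass through the
viability floor unclipped, which is what makes `score = 100·delta` exact
in the noise-free case. The default panel is 4 cell lines (2 per genotype)
× 27 compounds against one anchor compound, matching the bookkeeping scale
of the target screen design; anchor potencies default to the published
genotype-dependent IC50s (13.4/17.6/44.9/148.9 µM) used purely as
generator parameters. What is *not* emulated: plate-position effects,
compound cross-reactivity, non-multiplicative biology — so passing tests
demonstrate correctness of the arithmetic and calibration of the score
under the stated noise model, not fidelity to any particular cell line.

*Curves.* 4PL samples on the 10-point screen ladder with Gaussian noise.

*Images.* Non-overlapping uniform discs (default area 400 µm², intensity
2000 a.u.) on a low base, an optional planar gradient, and Gaussian point
foci (σ = 1.2 px) planted at least 6 px inside the nucleus edge with a
minimum pairwise separation (default 10 px) so planted foci are resolvable
— the generator models distinct damage sites, not confluent damage. Noise
is none, additive Gaussian, or Poisson counting noise;
`poisson_amplitude_for_snr` converts a peak SNR into a spot amplitude.
Undersized nuclei and oversized blobs can be planted to exercise the
acceptance windows; ground truth flags them. Real images differ in
texture, focus drift, and intensity calibration (a.u. windows are
instrument-specific), so transfer to a specific instrument requires
re-checking the intensity windows.

*Tumors.* V(day) = 100·exp(r·day) mm³ with lognormal measurement noise
(σ_log default 0.1), rendered as length/width with a fixed aspect ratio of
1.3 through V = 0.5·L·W². Default arms: vehicle r = 0.11/day (10× RTV near
day 21) and treated at half that; twice-weekly measurements through day
60. Deaths/removals enter as per-animal censor days.

## Problem sizes

The test suite and the acceptance script use the sizes the analyses are
designed around: ~1,000 matrices for null calibration, 100 screen
replicates for ranking recovery, 200 curves for IC50 recovery, 5-nucleus
512×512 fields (half the linear size of the real 1104×1104 fields, purely
a convenience — all geometry is in µm), 10,000 permutation draws, and
8-animal arms. The full suite runs in about two minutes on one CPU.

## Known limitations

- The box-method implementation reproduces the published description of
  the vendor algorithm (box value, windows), not its exact binary
  behavior, which is undocumented.
- Synergy models other than Bliss (Loewe, ZIP, HSA) and >2-drug
  combinations are out of scope.
- The score's null calibration is established under additive Gaussian
  viability noise; heavy-tailed plate artifacts would widen the null and
  the >15 threshold should then be re-examined.
- No statistical test is attached to the differential ranking; it is a
  prioritization, not an inference.
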