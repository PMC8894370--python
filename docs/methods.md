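# Methods

## Measurement model and preprocessing

An STK peptide microarray reports, per spot, a background-subtracted
median fluorescence at several camera exposure times. Within the camera's
linear range the signal is proportional to exposure and must vanish at
zero exposure, so the stack is collapsed per (sample, peptide) by a least
squares fit of intensity = slope × exposure constrained through the
origin (slope = Σ t·y / Σ t²), evaluated at a reference exposure of
100 ms. The operation is linear in the intensities, exact on noiseless
linear data, and equivariant under rescaling. An unconstrained-intercept
variant (`fit_intercept=True`) exists for robustness comparisons, e.g.
against additive background drift; it is off by default because it spends
a degree of freedom the physical model says is zero.

Combined values are clipped below at a floor (default 1.0 signal unit)
and log₂-transformed. A negative fitted slope — possible when a spot
sits below background at all exposures — therefore maps to log₂ value 0
rather than being dropped, keeping the matrix complete for clustering and
permutation analysis. No between-sample normalisation is applied by
default; an optional median-centering mode exists but changes the
interpretation of global phosphorylation shifts (which are real signal in
disease-vs-control kinome profiling) and so must be opted into.

QC flags a sample whose median log₂ signal deviates from the cohort
median of sample medians by more than 3× the cohort IQR of those medians
(strict inequality, so identical samples are never flagged). The flag is
informational; nothing is removed automatically. In three-group designs
with real group effects the group structure itself can trip the flag —
it marks "look at this sample", not "discard it".

## Differential phosphorylation

Per peptide, an unpaired two-sided t-test between two groups on the log₂
matrix; the log fold change is mean(first-named group) − mean(second),
and contrast names encode the orientation ("rd1_vs_WT" ⇒ rd1 − WT).
The pooled-variance Student's t is the default, as the classical reading
of "unpaired t-test"; Welch is available by flag. Peptide p-values are
deliberately left uncorrected — the field convention for these arrays
reports raw p < 0.05 and p < 0.1 peptide lists — and a BH adjustment can
be applied downstream where wanted. Degenerate peptides (zero variance in
both groups) get p = 1 when the means agree, else the smallest positive
double with a `degenerate` flag; this keeps p strictly in (0, 1] without
inventing a variance.

Heatmap ordering uses average-linkage (UPGMA) agglomerative clustering on
euclidean distances, applied independently to peptide profiles and sample
profiles; exports carry leaf orders and merge trees, not rendered figures
(the volcano PNG is a convenience, the TSV is the artifact).

## Upstream kinase inference

A kinase's fingerprint is its set of array peptides with integer
specificity weights 1–10 (0 means non-substrate and is dropped at load
time). For a contrast:

* **Kinase Statistic** — mean LFC over the fingerprint's measured
  peptides; optionally the weight-proportional mean (Σ wᵢ·lfcᵢ / Σ wᵢ).
  Its sign carries direction (positive = more active in the first-named
  group); its magnitude is on the LFC scale.
* **Significance Score** — the group labels of the contrast's samples are
  permuted B_labels times (default 500) and the statistic recomputed; the
  empirical two-sided p is (r + 1)/(B + 1) with r = #{|perm| ≥ |obs|},
  reported as −log₁₀ p. The permutation null is built in a canonical
  group order so the score is exactly invariant to which group the caller
  names first. When fewer distinct relabellings exist than permutations
  requested, permutations are sampled with replacement and a note logged.
* **Specificity Score** — B_peptides random sets of the fingerprint's
  size are drawn uniformly without replacement from *all* measured
  peptides, the statistic recomputed on each, and the same p estimator
  applied. Resampling from the whole array (rather than from some
  restricted candidate pool) asks the sharpest question — is this
  fingerprint's change distinguishable from any random peptide set of the
  same size — and needs no information beyond the map itself.
* **Kinase Score** = Significance + Specificity; ranking is by descending
  score with ties broken by |statistic| then name. Reports keep kinases
  with score > 1.5 (the conventional cut) while the full ranking is
  always retained. The (r+1)/(B+1) estimator never returns 0, so scores
  are finite and capped at log₁₀(B+1) per component — 2.70 at B = 500,
  5.40 for the sum.

Fingerprints intersecting the array in fewer than `min_set_size = 3`
peptides are skipped: with 1–2 peptides the peptide-permutation null is
too coarse to mean anything. Both permutation analyses draw from named,
seed-derived independent random streams (one per kinase and analysis
kind), so toggling one analysis, reordering kinases, or changing B in one
place never shifts the draws of another; a fixed seed makes the whole
ranking bit-reproducible.

The packaged default substrate map is a fixture, not a database: PKG1 and
PKG2 fingerprints carry the published integer specificity scores of the
22-peptide reference table, and nine synthetic decoy kinases (disjoint
8-peptide sets over the filler peptides, deterministic given a seed)
provide a null background. Real applications should load their own map
(`kinase  peptide_id  weight` TSV).

## Annotation, overlap, enrichment

Substrate-quality bands partition the 0–10 integer score: 8–10 good,
4–7 intermediate, 1–3 poor, 0 non-substrate. "Substrate of both PKG
isoforms" is operationalised as ≥ 4 (intermediate or better) for both;
"PKG1-only" as pkg1 ≥ 4 with pkg2 in 1–3 — the unique reading under the
bands that reproduces the reference table's printed counts (14 dual and 3
PKG1-only among the 22 peptides, verified by enumeration). Contrast
overlap is a plain case-normalised set intersection with percentages
relative to either list.

Over-representation analysis is intentionally minimal: upper-tail
hypergeometric p per gene set, BH q across sets, gene ratio 100·k/K, with
the universe defaulting to the union of all set members and the query
restricted to genes belonging to at least one set. No composite or
combined scores are computed. The packaged pathway collection is a toy
fixture with synthetic membership lists for exercising the machinery;
real analyses should load a curated GMT. Kinase names pass through a
packaged alias table (PKG1 → PRKG1, …); unmapped names are dropped with a
logged warning.

## Synthetic data generator

The generator emulates the features of the assay the analysis depends
on: per-peptide baseline log₂ level (default 8.0), kinase effects planted
multiplicatively on the linear scale and scaled by weight/10 (so
high-specificity substrates respond more — the assumption implicit in
weighted upstream analysis), Gaussian biological noise on the log₂ scale
(default SD 0.35), and per-exposure readout 2^value · (e/100 ms) ·
(1 + ε), ε ~ N(0, CV 0.05), truncated at zero. Exposure times default to
(10, 20, 50, 100, 200) ms, a plausible increasing series for this class
of instrument. Group sizes default to the study design (WT 5, rd1 8,
CN03-treated rd1 10). Treatment is modelled purely as resetting the PKG
multipliers toward 1 in the treated group. An optional saturation ceiling
caps intensities to probe the origin fit's robustness; it is off by
default.

What the generator does *not* emulate: spot morphology and gridding,
spatially correlated background, peptide-specific kinetics or saturation,
batch and chip effects, and any correlation structure between peptides
beyond shared kinase effects. Passing recovery tests therefore show the
statistical chain is correct and calibrated under its own assumptions,
not that those assumptions hold on any particular instrument run.

With all noise zero the full chain is exact: a kinase multiplier of 2
yields LFC = weight/10 per substrate after preprocessing, recovered to
1e-9, which pins the algebra of the whole pipeline.

## Histology profiling

Layer intervals are user-supplied, half-open [start, end), ordered and
non-overlapping; a position exactly on a boundary belongs to the
following layer. Per-layer means are plain arithmetic means of the trace
samples in the interval. The antibody/negative-control ratio is computed
per layer (the control's autofluorescence varies by layer, so a single
scalar control would conflate layers) and the control must be positive —
a zero control mean is an error, not an epsilon-guarded division.
Across-animal summaries use the sample (n−1) standard deviation, the
right choice at n = 3 animals.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations to what
the inference actually needs: 50 replicates at B = 200 permutations for
planted-kinase recovery (the score cap log₁₀(201) ≈ 2.30 is far above the
decoy background), 3000 peptide-tests for t-test calibration against the
exact binomial 99% interval, and 1000 kinase-level permutation p-values
for the uniformity check. Permutation p-values live on the 1/(B+1) grid;
calibration checks compare against that discrete null where it matters.
Ties in permutation statistics count toward r (conservative). All
tolerances on exact algebra are 1e-9–1e-12; everything stochastic is
seeded and reproducible.
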