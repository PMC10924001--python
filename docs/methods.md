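# Methods

## Scope and model

`epicross` estimates and predicts plant recombination landscapes at 100-kb
resolution from methylome-derived features. The pipeline has four stages —
windowed methylated-cytosine counts, genotype-based rate estimation,
smoothing/correlation, and tree-ensemble prediction — plus a synthetic-data
generator that defines the conditions under which the pipeline is validated.

## Windowed methylation counts

Per-cytosine calls arrive in the Bismark cytosine-report layout (chromosome,
1-based position, strand, methylated count, unmethylated count, context,
trinucleotide). A cytosine is *retained* when its coverage
`n_meth + n_unmeth` is at least `min_coverage` and its methylation level
`n_meth / (n_meth + n_unmeth)` passes `level_threshold`.

- `level_threshold` = 0.75, **inclusive** by default. The boundary case is
  genuinely ambiguous in practice ("greater than" vs "at least"); we include
  the boundary and expose `level_threshold_inclusive` so either convention is
  one flag away.
- `min_coverage` = 10 reads. Upstream callers rarely state a coverage floor;
  10 is a conventional bisulfite-analysis default. It is configurable and
  recorded in the windowing result.
- Windows are 1-based closed intervals `[kW+1, (k+1)W]` with
  `window_index = floor((pos−1)/W)`, matching report coordinates; both
  strands pool into the same window (cytosines are counted, not CpG dyads).
  A trailing partial window is kept (its `end` is the chromosome length) so
  counts are conserved; downstream stages may drop it when its rate is
  undefined.
- Records whose context disagrees with their trinucleotide are rejected and
  counted, not silently fixed. Unknown chromosome lengths are inferred from
  the maximum observed position and flagged.

The CHH motif census resolves retained CHH cytosines into the nine
trinucleotides C-H-H with H ∈ {A, C, T}. Minus-strand cytosines are read
5'→3' on their own strand (reverse complement of the plus-strand 3-mer
ending at the G). Trinucleotides containing other letters (N) go to a
rejects count.

## Rate estimation from genotypes

Input is a parental-origin matrix: ordered markers × individuals with calls
A/B/missing (heterozygous or unrecognized symbols are treated as missing by
default; a strict mode errors instead). The estimation path:

1. **Imputation.** At every grid position `step, 2·step, …` the full call
   row of the nearest marker (by |bp| distance) is copied, missing entries
   included. Exact midpoint ties go to the lower-position marker —
   deterministic and order-independent. Positions outside the marker span
   copy the nearest terminal marker.
2. **Recombination fractions.** For consecutive grid rows, `n` = individuals
   non-missing in both rows, `d` = those whose calls differ, `r = d/n`,
   clamped to `0.5 − 1e−6` before mapping. Intervals with `n = 0` contribute
   0 cM and are counted — this keeps the cumulative map defined.
3. **Kosambi mapping.** `cM = 25·ln((1+2r)/(1−2r)) = 50·artanh(2r)`,
   strictly increasing, ≈ `100·r` for small `r`; the analytic inverse is
   `r = tanh(cM/50)/2`. Fractions at or above 0.5 are a contract violation
   (they must be clamped upstream) and raise.
4. **Differencing.** Genetic positions are imputed onto window boundaries
   `0, W, 2W, …` by nearest-anchor copy (this also serves externally
   supplied marker-level maps) and consecutive boundaries are differenced:
   `rate(k) = cM((k+1)W) − cM(kW)`. Negative differences within `1e−6` cM
   are clipped to zero and counted; larger ones indicate a non-monotone map
   and raise with the offending anchors. A trailing window with no upper
   boundary reports NaN.

The defined rates telescope exactly to the map length of the covered span.
No marker ordering, genotype error correction, or interference-aware map
functions beyond Kosambi are attempted.

## Consensus, smoothing, correlation

Counts and rates inner-join on (chromosome, window); rows with undefined
rate are dropped and counted. Simple exponential smoothing
(`s₁ = x₁`, `s_t = α·x_t + (1−α)·s_{t−1}`, default α = 0.1) runs forward
once, independently per chromosome and per track, after the join (for
complete grids the order is irrelevant; a flag smooths before the join for
sensitivity analysis). Initialization at the first observation keeps the
smoother linear and exact for constant tracks. Pearson correlations of each
smoothed context track against the smoothed rate are reported per chromosome
with two-sided p-values at significance level 0.05; zero-variance tracks
report NaN with a reason rather than a coerced value. No multiple-testing
correction is applied across chromosomes.

## Prediction and evaluation

The regressor is scikit-learn's `ExtraTreesRegressor` with library-default
hyperparameters and a fixed seed; defaults suffice for this problem class
and remain overridable. Features default to all three smoothed contexts
(`cg_s, chg_s, chh_s`); the target is the smoothed rate — the only scale the
model ever sees, so metrics are reported on it.

- **LOCO.** Each chromosome is predicted by a model trained on all others.
  `R² = 1 − SS_res/SS_tot` with `SS_tot` about the held-out chromosome's own
  mean — it is *not* the squared correlation and can be negative
  out-of-sample. Pearson r and MSE accompany it; zero-variance held-out
  chromosomes report NaN with a reason.
- **Quartiles.** Each chromosome's windows split into four contiguous blocks
  by position, remainders assigned to earlier blocks (10 → 3,3,2,2);
  per-block Pearson r with NaN for blocks under 3 windows or zero variance
  (the recombination-dead arms case).
- **Attributions.** Exact additive tree-path contributions: walking a sample
  down each tree, the change in node mean value at every split is credited
  to the split feature; averaging over trees gives per-row, per-feature
  contributions satisfying `prediction = base + Σ_f contribution_f` to
  floating point (asserted at 1e−6). Features are ranked by mean
  |contribution|. By default attributions come from a model fit on all
  chromosomes, evaluated on its training rows; a flag pools held-out
  attributions from the LOCO folds instead.
- **Transfer.** Fit on every chromosome of one consensus table, evaluate per
  chromosome of another, with no rescaling by default (cross-dataset counts
  travel as-is; an optional per-dataset z-score flag exists for sensitivity
  analysis). Missing feature columns error rather than silently aligning.

## Synthetic-data generator

The generator is the package's study design: its defaults define the
conditions under which the pipeline is validated.

- **Landscape.** `rate = clip(base + amplitude · arm_profile · suppression, 0)`
  per window. The suppression factor `1 − exp(−(|x−c|/h)⁴)` is flat near
  zero across the centromere core (half-width `h`, default 1/12 of the
  chromosome) and 1 on the arms. The arm profile is a warped half-sine
  peaking at `arm_peak` of each arm's length from the telomere; the default
  0.25 emulates distal-arm crossover concentration (the strong-regime
  geometry of large-genome crops), while values near 1 give a
  pericentromere-peaked landscape. Defaults (base 0.05, amplitude 0.9 cM per
  100-kb window, 200 windows) give ≈ 120 cM per chromosome — a realistic
  plant chromosome map length.
- **Counts.** CG/CHG means are enriched pericentromerically by a broad
  Gaussian bump (SD = chromosome length / 6, enrichment ×3 by default);
  the CHH mean is `(1 − κ)·chh_base + κ·(true rate scaled to the CHH mean)`
  with coupling κ ∈ [0, 1]. Default bases 300/180/80 per window reproduce
  the CG > CHG > CHH abundance ordering seen in plant methylomes. Counts are
  negative-binomial with variance `μ(1 + d·μ)`, d = 0.15 by default
  (Poisson at d = 0) — over-dispersion is the realistic stress case for
  correlation recovery.
- **Reports.** Retained cytosines are placed on real context sites of an
  i.i.d. genome (GC 0.36) and given coverage ≥ 10 and level ≥ 0.75 by
  construction; background records with low level or low coverage are
  interleaved and must wash out in the filter without changing retained
  counts (asserted exactly). Read-level simulation, sequencing error, and
  heterozygous genotypes are out of scope.
- **Genotypes.** A haploid-phase (DH-like) population: founder phase A at
  the left telomere, crossovers per individual Poisson with mean map-length
  (cM)/100, breakpoints placed window-proportionally to the true rate and
  uniformly within windows, then masked to missing at the configured rate
  (2% default). Crossover interference is deliberately not modeled: the
  estimation side never exploits it, and Kosambi tolerates its absence at
  the 100-kb interval scale.

What the generator does *not* emulate: linkage disequilibrium structure,
marker ascertainment bias, genotyping error, methylome–genome sequence
dependence, or chromosome-to-chromosome heterogeneity beyond independent
noise. Passing tests therefore demonstrate correctness of the pipeline's
computations and recoverability under controlled coupling — not that real
species will show any particular prediction accuracy.

## Validation regimes and calibration

- **Recovery.** At the reference conditions (200 windows, 500 individuals,
  one marker per window, 2% missing), the raw per-window rate estimate is
  sampling-noise-bounded: with ≈ 0.6 cM per window, the per-window binomial
  standard error is comparable to the landscape's own standard deviation,
  capping raw-track Pearson r near 0.65. On the α = 0.1 smoothed scale —
  the scale every downstream analysis consumes — recovery is r ≥ 0.95
  (minimum over a 20-seed pilot), and the estimated total map length stays
  within 10% of truth. The recovery acceptance check is therefore defined on
  smoothed tracks.
- **Sign pattern.** With κ = 0.9 and default pericentromeric enrichment,
  per-chromosome correlations come out CG < 0, CHG < 0, CHH > 0 on every
  chromosome in 20/20 independent simulations.
- **Regime separation.** Strong coupling (κ = 0.9, 10 chromosomes × 200
  windows) yields LOCO mean r ≈ 0.99 and mean R² ≈ 0.97. The *null* regime
  turns off every methylation–rate coupling (κ = 0 *and* enrichment factors
  1): κ = 0 alone leaves CG/CHG enrichment as genuine signal and is not a
  null. With all couplings off, LOCO mean R² is ≈ −0.1 with most
  chromosomes negative — the signature of features uninformative for an
  out-of-sample chromosome.
- **Pilot-fixed thresholds.** The partial-coupling check (κ = 0.8 → count
  correlation > 0.6) was calibrated over 25 seeds (observed 5th percentile
  0.65); crossover calibration is asserted within 3 standard errors of the
  Poisson mean at n = 10,000.

## Numerical choices and degenerate inputs

Recombination fractions clamp at `0.5 − 1e−6`; negative rate clipping
tolerance is `1e−6` cM; motif proportions must sum to 1 within `1e−9`;
attribution additivity is asserted at `1e−6`; Kosambi round-trip at
`1e−12`. Zero-coverage cytosines never reach level computation. A single
marker (or identical rows) produces a flat map and zero rates, not an
error; an all-missing interval contributes zero length and is logged. Grids
shorter than one step fall back to a single grid point at the chromosome
end. All stochastic components accept explicit seeds; fixed seed plus fixed
inputs reproduce byte-identical outputs, which the demo asserts by
checksumming its own rerun.

## Known limitations

- Rate estimation assumes markers dense relative to the window size;
  sparse-marker maps inherit nearest-marker imputation bias (plateaus across
  marker gaps).
- The first window's rate from the genotype path is structurally zero
  (no grid row below one step); recovery statistics exclude undefined
  windows.
- Tree-path attributions are path-dependent (Saabas-style): exactly
  additive, but correlated features split credit differently than
  interventional attribution schemes would.
- The transfer evaluation applies no normalization by default; datasets with
  very different count depths can show high correlation with negative R²,
  which is informative about scale mismatch, not a defect.
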