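# Methods

## Decay model and half-life estimation

Transcript abundance after transcription shut-off is modelled as
first-order decay observed in FPKM with multiplicative noise:

    FPKM_r(t) = F0 · 2^(−t / t1/2) · exp(ε),   ε ~ N(0, σ²),

independently per replicate r and time point t. Because the noise is
multiplicative, ln(FPKM) is linear in time with homoscedastic Gaussian
error — the regression model of the terminal fit is correctly specified.

The terminal fit (`fit_lambda_z`) mirrors noncompartmental pharmacokinetic
lambda-z selection: values that are missing or non-positive (below the
detection limit) are dropped; every suffix of the remaining time-ordered
points with at least `min_points = 3` members is fitted by OLS of ln(conc)
on time; fits with non-negative slope are discarded; the fit maximising
adjusted R² = 1 − (1 − R²)(k − 1)/(k − 2) wins. Ties within 1e-4 are
resolved in favour of more points (the convention of PK selectors), and the
observed-maximum point may be part of the window. The suffix OLS statistics
are computed in closed form from reversed cumulative sums, so the full
candidate enumeration is one O(T) pass; tests verify exact agreement with
an independent scipy-based enumeration.

Replicates are combined by resampling (`estimate_half_life`): each
resampled series takes, per time point, one replicate's value uniformly at
random; fits with adjusted R² ≥ 0.7 contribute t1/2 = ln 2/λz to the
arithmetic mean. `run_halflife_pipeline` repeats this over `n_sim = 10`
independent simulations, keeps transcripts estimated in every simulation,
reports the mean of simulation means with a t-distribution 95% CI
(n_sim − 1 df — the CI construction is this package's choice), and drops
means ≥ 50 h as unresolvable on an 8 h sampling window. Per-transcript RNG
streams are derived from the root seed and a SHA-256 hash of the transcript
id, so results are independent of input order and of which other
transcripts are present.

Known behaviour: half-lives much longer than the sampling window are
biased downward (the terminal slope is dominated by noise), and the
adjusted-R² gate preferentially retains steeper resampled slopes, giving a
small downward bias that vanishes as σ → 0 (the noiseless case is exact to
1e-9 relative, by test).

`direct_half_life` applies one gated fit to a single four-point compartment
time course (0, 6, 12, 24 h), with no resampling.

## Nucleocytoplasmic enrichment

A transcript at one time point is nucleus-enriched iff (N_count > 0 and
C_count > 0 and N_fpkm/C_fpkm ≥ 2) or (C_count = 0 and N_count ≥ 3);
cytoplasm-enriched by the mirrored rules; otherwise "middle". Two corner
decisions are ours: a compartment with fragments but zero recorded FPKM
contributes no ratio evidence (such rows fall to "middle" unless a
zero-count rule fires), and transcripts undetected in both compartments are
"middle" but flagged `undetected` for optional exclusion. Classification is
per time point. Population summaries report counts (total always conserved),
the N/C count ratio to two decimals, per-population mean half-lives, a
two-sample KS p between the nucleus and cytoplasm half-life sets and a
one-way ANOVA p across all three.

The population sequence contrast uses 5461 features — all 4^k k-mers for
k = 1..6 (5460) plus GC content — comparing per-sequence overlapping-window
(K1) frequencies between populations by two-sample KS with Bonferroni
adjustment over the full space. Frequencies, not raw counts, so sequence
length does not dominate.

## Sequence features

* K1 k-mers: overlapping windows, step 1; any window containing an
  ambiguous base is skipped; counts sum to L − k + 1 on unambiguous
  sequence. K2 k-mers: non-overlapping windows from a frame offset (codon
  content when k = 3 and the offset is the CDS start); trailing partial
  windows dropped.
* IUPAC motif counts allow overlaps (a scan via regex lookahead, verified
  against a position-by-position oracle). Total protein-binding ability is
  the sum over the motif set; per-source aggregates sum a protein's motifs.
* miRNA sites come either from parsed miRanda-format output or from a
  clearly labelled stand-in that counts exact reverse-complement matches of
  the miRNA seed (bases 2–8); the stand-in is selected explicitly, never
  silently. Site positions are attributed to 5'UTR/CDS/3'UTR when CDS
  offsets exist.
* End fragments: 5' prefixes / 3' suffixes of lengths 50, 60, …, 300
  (26 lengths); mRNA flanking fragments are windows of total width 100,
  120, …, 600 centred on the start/stop codon boundaries. Windows that
  would overrun the transcript are skipped, not clipped, so fragments of a
  nominal length stay comparable.
* `assemble_feature_matrix` produces the screening matrix: 5460 k-mer
  frequencies + per-motif counts + binding total + per-miRNA counts + site
  total + {MFE, length, GC}; with the full 2297-motif and 2656-miRNA
  complements that is 10,418 columns.

Coordinates are 0-based half-open and transcript-relative; T on input is
normalised to U everywhere.

## Secondary structure

`parse_rnafold_output` reads standard folding-program text blocks (header,
sequence, dot-bracket with trailing energy). The built-in
`predict_mfe_standin` is a Nussinov-style dynamic program over weighted
pairs (GC = −3, AU = −2, GU = −1 kcal/mol on a stand-in scale; hairpin
loops ≥ 3 nt; no pseudoknots), verified against exhaustive enumeration for
short sequences. It is a monotone proxy for thermodynamic folding energy
used to exercise the screening logic — not a Turner-model implementation —
and its O(L³) cost limits it to short sequences; real analyses parse the
external folder's output. Transcripts ≥ 10,000 nt are excluded from
folding by default. Both raw and per-nt energies are emitted, since it is
ambiguous which scale a correlation analysis should use.

## Positional classification

lncRNA genes are classified against coding-gene models as
sense / antisense / intronic / bidirectional / intergenic / unclassified
(rules in `annotation.py`). The precedence when several rules fire
(SENSE > ANTISENSE > INTRONIC > BIDIRECTIONAL > INTERGENIC) is this
package's decision; antisense accepts any overlap by default with an
exon-only mode behind a flag; the 1 kb intergenic distance is measured
between gene bodies, not TSSs.

## Screening statistics

Spearman rho is average-rank Pearson; p is exact permutation enumeration
for n ≤ 8 and the two-sided t approximation (n − 2 df) otherwise. KS is
the asymptotic two-sample test; ANOVA the classical F. Multiplicity control
is Bonferroni — outputs keep the conventional column name `fdr` for the
adjusted values, but the control is family-wise, which this note states
explicitly. Screens report per-feature statistics and a directional
summary "a/b": b features pass adjusted p < alpha, a of which share the
majority sign.

The regulation network connects factor pairs when the Bonferroni-adjusted
p over all pairs is < 0.01 **and** the raw p < 1e-5; edge strength bins on
raw p: strong < 1e-33, medium [1e-33, 1e-26], weak (1e-26, 1e-5). The
two-condition rule resolves an ambiguity between the edge threshold
(stated on adjusted values) and the strength bins (stated on raw p); both
values are emitted so either convention can be audited.

The subsampling power curve draws n transcripts without replacement
`reps` times and counts Spearman p > 0.1 ("missed") per n. The reference
planted correlation in tests is ρ ≈ 0.08 — the regime where ~half of
draws at n ≈ 430 miss the effect and misses fall steeply by n = 3000.

## Regression

Feature pre-selection keeps features with Spearman p (or
Bonferroni-adjusted p) below 0.1/0.05/0.01. The linear baseline is OLS on
log half-life with adjusted R²; rank-deficient designs are rejected with
the collinear columns named. The feed-forward network is sklearn's
MLPRegressor: ReLU activations, minibatch Adam, squared error on log
half-life (the log stabilises the right-skewed half-life distribution; the
loss and input standardisation are unstated choices of this package).
The six-hidden-layer architecture (500/250/100/50/30/10 units, 100 epochs,
batch 1000, validation fraction 0.2) is preserved as the `full` preset;
the tested default is the `desk` preset (32/16/8) because 500-unit layers
on ten thousand features are not a routine-run configuration. Fivefold
cross-validation is stratified by half-life quartile; out-of-fold
predictions cover every sample exactly once, and the report carries both
the in-sample and the cross-validated Spearman correlation — their gap is
the overfitting diagnostic.

## Synthetic data: what it emulates and what it does not

`SimConfig` defaults define the emulated experiment: 3 replicates on the
10-point grid 0, 0.5, 1, 1.5, 2, 3, 4, 5, 6, 8 h (an alternative grid with
2.5/3.0/5.0 h is reachable via `times`), log-normal half-lives (median
2.76 h, log-sd 0.85, matching a skewed population with CV ≈ 1.1),
log-normal initial FPKM (median 10), σ = 0.1 multiplicative noise, a
0.01 FPKM detection floor mapping to recorded zeros (which the fitter
drops), i.i.d. sequences at the target GC, an exon-count law with ~37%
single-exon transcripts, and compartment tables at 0/6/12/24 h with
4-fold planted enrichment, Poisson fragment counts (mean = depth × FPKM)
and σ = 0.2 compartment noise. When the compartment noise scale is 0 the
counts are deterministic rounded means so planted classes are exactly
recoverable. Planted effects add coefficient × standardised feature to log
half-life, optionally within the single- or multi-exon stratum only.

The generator does **not** emulate read-level sampling noise,
library-size/normalisation artefacts, correlated replicates, transcript
families with shared sequence, isoform ambiguity, or non-exponential decay
(biphasic decay, synthesis leakage under incomplete inhibition). Passing
tests therefore demonstrate the correctness and calibration of the
estimators and screens under a correctly specified generative model, not
robustness to those real-data pathologies.

## Problem sizes and numerical choices

Routine runs and the reproduction script use scaled problem sizes chosen
to keep a full run in tens of seconds on one core: 100 resamples per
simulation (the estimator's mean is unbiased in the number of resamples;
more resamples only tighten it), 200 transcripts for noisy recovery, 25
transcripts × 10 simulations for the robustness ANOVA, 1000 series for the
fit-oracle comparison, 500 sequences for counting oracles, sequences ≤ 12
nt for the folding enumeration (the brute-force oracle is exponential),
25 null screens of 100 features at n = 500, subsampling at
n ∈ {400, 1500, 3000} with 300 replicates from a 12,465-transcript
population, and the `desk` network preset. Tolerances: noiseless recovery
asserts 1e-9 relative; suffix-fit agreement asserts slopes to 1e-9
relative; adjusted-R² ties break at 1e-4.

## Known limitations

* The folding stand-in's energies are on an arbitrary scale; only their
  ordering is meaningful.
* The exact Spearman permutation p is enumerated only for n ≤ 8 (8! =
  40,320 permutations); above that the t approximation is used, which is
  slightly approximate in the extreme tails.
* The half-life CI assumes approximate normality of simulation means; with
  n_sim = 10 this is a t-interval on 9 df, not a bootstrap interval.
* `HalfLifeResults.anova_across_simulations` treats simulations as groups
  and transcripts as observations; because between-transcript variance
  dwarfs between-simulation variance, p ≈ 1 is the expected healthy
  outcome, and values well below 1 indicate a seeding or resampling bug
  rather than a biological signal.
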