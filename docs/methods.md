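# Methods

## Calibration model

Absolute quantification is anchored on intact protein standards spiked at
known amounts *f* (fmol at the MS-injection level). The measured
protein-level intensity *I* of an anchor is modelled as log-linear in the
spiked amount,

    log10 I = a + b·log10 f + ε,    ε ~ N(0, σ²),

and (a, b) are estimated by ordinary least squares on the anchors' log-log
points. No robust estimator is used by default: OLS is the reproducible
baseline, its standard errors are exact under the model, and the anchor
design (below) gives high leverage spread. The curve is inverted,
f̂ = 10^((log10 I − a)/b), to estimate every protein's amount. R² is the
squared Pearson correlation of the fitted points and is reported with each
curve.

**Per-sample vs pooled fitting.** The default fits one curve per sample:
spike-ins are per injection, and detector response drifts run to run. A
`sample_scope="pooled"` option fits all samples' anchor points jointly,
matching the single experiment-wide calibration curve some workflows use.
Multiplying a sample's intensities by k > 0 shifts the intercept by
log10 k and changes nothing else — per-sample calibration is therefore
invariant to per-sample scale distortions, pooled calibration is not.

**Anchor matching.** Protein groups are matched to anchor accessions on the
group's *first* accession (anchor tables list single accessions). An anchor
matched by two or more groups is dropped with a warning: the curve point
would be ambiguous. Anchors whose intensity in a sample was imputed are
excluded from fitting by default (`include_imputed=False`) — an imputed
value is not a measurement. At least 3 matched anchors are required.

**The consultant.** Candidate (intensity method, normalization) pairs are
scored by the mean per-sample R² of the anchor fit; larger mean
n_anchors_used breaks ties, then lexicographic order, with R² compared at
1e-12 so numerically identical fits tie cleanly. Because per-sample OLS in
log space is scale-invariant, per-sample scoring cannot distinguish
candidates that differ only by per-sample scaling; the consultant therefore
also accepts `sample_scope="pooled"`, under which run-to-run scale
distortion counts against an unnormalized candidate. Per-sample scoring
remains the default. Residual spread is not part of the score.

## Preprocessing

Work happens in log2 space (the proteomics-QC convention); calibration is
in log10 (the standard-curve convention). Reports always carry raw-scale
intensities between steps; the report-level functions transform in and out
internally, and imputation/flag-removal never alter an observed cell (bit
identity is tested).

Zero intensities are coerced to missing at ingestion: label-free engines
write 0 for "not quantified", and a literal zero is undefined under the log
transforms.

**Replicate-group inference.** Sample labels are tokenized on the
separators `_ - . space`, on letter/digit boundaries and on lower→upper
case changes. If the final token is an integer, a single letter, or a roman
numeral up to IV, it is taken as the replicate token and labels sharing all
remaining tokens form one group; everything else becomes a singleton group.
The procedure is deterministic and invariant to input order. It fails, by
construction, on labels whose replicate letter fuses into the condition
name with no separator or case change ("ctrla") and on condition names that
collide once a trailing digit is stripped — both rare in practice.

**Validity filter.** A protein is kept iff in at least one replicate group
the fraction of non-missing values reaches `min_valid_fraction`
(default 2/3, the common "2 of 3 replicates" rule).

**Normalization.** `median` shifts each sample's log2 values so its median
equals the global median of sample medians; `quantile` replaces each value
by the cross-sample mean quantile curve evaluated at the value's (average,
tie-broken) rank, with per-sample missingness handled by interpolating the
reference curve at the observed ranks; `total_sum` rescales raw values by
mean-total/sample-total. Samples with fewer than 2 finite values are left
untouched with a warning.

**Imputation.** Missing values are drawn per sample from
N(m − 1.8·s, (0.3·s)²) of that sample's observed log2 distribution — the
field-standard down-shift parameters for left-censored label-free data, and
the generator's censoring mechanism matches that assumption. Samples with
fewer than 3 observed values are skipped with a warning. Every imputed cell
is marked and the mark propagates into the final table's `provenance`
column. Order is fixed: normalize, then impute (the down-shifted draws then
live on the normalized scale).

All stochastic steps take an explicit seed; the pipeline derives per-step
seeds from the single run seed, and reruns are byte-identical.

## Absolute units and enrichment

With per-condition parameters (volumes in µL, concentrations in µg/µL,
injected amount in µg, cell density in cells/mL):

- total protein of the digest: SampleVolume × ProteinConcentration (µg)
- `fmol_total` scales the MS-level estimate by total/injected protein,
  under the assumption that the digested extract represents the whole
  harvested biomass;
- `ng_per_ug` = fmol × MW[kDa] × 10⁻³ / AmountMS (1 fmol of a 1 kDa
  protein is 10⁻³ ng);
- `molecules_per_cell` uses Avogadro's number (6.02214076×10²³, SI exact)
  and the harvested cell count CellsPerML × TotalCultureVolume.

TotalCultureVolume is parsed as µL by default, matching the parameter
table's stated unit; `culture_volume_unit="mL"` accommodates the more
common lab convention. Molecular weights come from the report's MW column
when the dialect provides one, else from an optional FASTA (average
residue masses via Biopython), else `ng_per_ug` stays unset.

**Enrichment factors.** For a fraction enriched or concentrated during
preparation, spiked enrichment standards estimate the factor: the expected
MS share of a standard is (stock/dilution)·volume scaled by
injected/total protein, and the factor is the mean over replicates of the
median over standards of measured/expected. Supplied targeted-MS (SRM)
amounts are handled symmetrically — median ratio of calibration-estimated
to supplied fmol, the supplied values taken to be on the MS-injection
basis. Correction divides `fmol_total` before the per-cell conversion:
measured amounts in an enriched fraction overstate native per-cell amounts
by exactly the factor. The "Enrichment" and "Concentration" modes carry the
same arithmetic and are kept as metadata; a factor of 1 provably changes
nothing.

## Synthetic data

The generator emulates the study conditions end to end: log-uniform true
amounts over 10⁻²–10³ fmol, a 48-anchor staggered-decade design (6 levels ×
8 proteins, 0.5–50,000 fmol, mimicking UPS2), log-linear response with
multiplicative lognormal noise (σ is the SD of the base-10 log),
left-censoring below an intensity threshold plus Bernoulli dropout, planted
CON__/REV__ rows, and dialect-faithful files for all four engines
(including MaxQuant's summed bare-method column and Spectronaut's
`[n] sample.PG.Quantity` headers). The grouping benchmark draws 2–6
condition words (lowercase, ~30% containing digits), 2–5 replicates in
integer/letter/repN style and a per-set separator from `_ - . space ""`
(the empty separator is the hard case; uppercase replicate letters keep it
solvable via the case-change rule).

What synthetic data does **not** emulate: peptide-level effects
(digestion/ionization bias that makes real iBAQ only approximately linear
in amount), intensity-dependent missingness beyond a sharp threshold,
correlated noise across samples, isoform ambiguity in protein groups, and
real-world sample-name pathologies. Passing tests demonstrate correctness
of the estimators and arithmetic under the stated model, not MS accuracy on
real data, where anchor-based absolute estimates are typically accurate to
within a few-fold.

## Problem sizes

Tests and the acceptance script run on deliberately compact instances —
hundreds of proteins, six samples, 500 benchmark label sets — chosen
because every statistical check they support (3-SE parameter recovery,
median-relative-error bounds, benchmark accuracy with a Wilson interval
well above the target) is already stable at that size. The pipeline itself
handles thousands of proteins in seconds.

## Known limitations

- One calibration per intensity method; no peptide-level model selection
  (aLFQ-style Top3/iBAQ hybrid models are out of scope).
- Condition-to-sample matching is by exact/prefix match between the
  parameter table's condition label and the inferred group label.
- SIL/QconCAT standards and targeted-MS computation are not implemented;
  SRM results are only consumed as supplied numbers.
- The quantile-normalization reference is the mean of per-sample quantile
  curves on a common grid; with heavy missingness the tails of the
  reference are extrapolated from fewer samples.
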