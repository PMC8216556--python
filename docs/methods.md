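# Methods

## Quantitation model

The observable is the reporter-ion intensity of an identified peptide in
one TMT channel.  The design maps each channel to a condition (T30/T50/T55
by default) and a replicate index; a comparison (A, B) pairs channels by
replicate index, so a triplicate design yields three ratio observations
`r_i = I[A_i] / I[B_i]` per peptide.  Pairing by index keeps three values
per comparison for significance testing instead of collapsing to a single
ratio.

**Normalization.** Only unique peptides (exactly one parent protein)
inform normalization and protein quantitation; shared peptides are carried
through all outputs but excluded from every median.  Normalization is
two-stage, computed per comparison:

1. *Per replicate pair*: each column of ratios is divided by its median
   over unique peptides.  This is the per-sample median-ratio correction;
   it makes the result exactly invariant to rescaling any single channel
   (a loading/labelling artifact).
2. *Grand rescale*: all ratios are divided by the linear-scale median
   (over unique peptides with ≥ 2 replicate ratios) of the
   replicate-averaged ratio.  After this step the median replicate-averaged
   ratio over unique peptides is exactly 1 — the invariant the test suite
   checks at 1e-9.

Stage 2's median is taken on the linear scale (even-sized sets: arithmetic
mean of the two middle values) precisely so the invariant is exact; all
other ratio arithmetic is done in log2.

**Replicate averaging and rollup.** A peptide's comparison ratio is the
geometric mean of its normalized replicate ratios (log2 mean), which makes
a reversed comparison map every peptide ratio to its exact reciprocal.  A
protein's ratio is the linear-scale median of its unique peptides'
comparison ratios, with the even-set median defined as the mean of the two
middle values.  The consequence of mixing a linear median with log-scale
averaging is that direction-reversal exactness at the protein level holds
exactly for odd unique-peptide counts and only up to the even-median
convention otherwise; we accept this in exchange for the conventional
median semantics.

**Missing data and zeros.** A missing reporter intensity ("", NA, NaN) is
distinct from a measured zero.  Neither can form a ratio, so both leave
that replicate pair absent; a peptide (or site) enters a comparison only
with at least 2 replicate ratios, the minimum for a t-test.  Rows the
readers reject are logged with row numbers, never silently dropped.

**Significance testing.** The package exposes one primitive,
`student_t_two_tailed`: the pooled (equal-variance) two-sample t-test, with
two degenerate conventions — two constant equal groups give p = 1, two
constant unequal groups give p = 0.  Group construction differs by level:

- *Proteins*: the test compares log2 protein-level channel abundances
  between the two conditions' replicate channels.  Channel abundances are
  medians over the protein's unique peptides of row-centred (peptide base
  abundance removed) and channel-median-corrected (loading removed) log2
  intensities.  This uses between-replicate variance on both sides of the
  comparison.
- *Glycosites*: the test compares the site's log2 normalized replicate
  ratios against the parent protein's per-replicate log2 ratios — directly
  a test of occupancy change over and above abundance change, matching the
  corrected-ratio definition.

The t-test is applied on the log2 scale throughout (ratio distributions
are closer to log-normal, and up/down become symmetric).

**Site correction.** The reported corrected ratio is exactly
`raw / protein` for the comparison-level ratios; when the parent protein is
unquantified or its ratio non-positive the corrected value is flagged
absent (NaN), never silently left raw.

## Differential calling

Up: ratio > 1.5 and p < 0.05.  Down: ratio < 1/1.5 ≈ 0.667 and p < 0.05 —
the reciprocal threshold is the symmetric reading of a ">1.5-fold" rule
and makes direction reversal map up and down calls onto each other
exactly.  Rows without enough replicate data are "untestable", so the four
call classes always partition the quantified rows.  Raw p-values are used
by default; `bh_correct=True` switches to Benjamini–Hochberg-adjusted
p-values per comparison.

## Sequons and occupancy matrices

The N-glycosylation consensus is Asn–X–Ser/Thr with X ≠ Pro.  Overlapping
sequons are all reported (each Asn is independently glycosylatable:
"NNTS" has two).  Windows are 21-mers centred on the modified Asn; termini
are padded with `_`, and pads are excluded from each position's frequency
denominator so boundary positions are not diluted.  Observed sites that do
not sit in a sequon (e.g. chemical deamidation artifacts) are classified
"non-canonical", reported separately, and excluded from motif matrices.
The site-count distribution bins glycoproteins at {1, 2, 3, 4, ≥5} sites;
the open upper bin follows the convention of reporting "five or more".

## Composition

Percent composition is computed per protein over the 20 standard residues
(B/Z/X/U excluded from numerator and denominator), then averaged
unweighted over proteins so long proteins do not dominate; the dispersion
reported is the SEM over proteins.  Set comparisons run a pooled
two-sample t-test per residue over the per-protein percentages.  The ±
dispersion convention is recorded in the output metadata because external
tables of this kind often leave it undefined.

## Enrichment

Two-sided Fisher's exact p-value uses the minimum-likelihood definition:
the sum of hypergeometric point probabilities not exceeding the observed
one, with a relative slack of 1e-12 to absorb floating-point ties of
symmetric tables.  The implementation enumerates the hypergeometric
support directly; the test suite checks it against an independent
exact-rational enumeration on every 2×2 table with N ≤ 40 (135,750
tables, agreement < 1e-10) and against `scipy.stats.fisher_exact`.

The background defaults to all quantified proteins rather than the whole
proteome, avoiding detection bias; it is a parameter.  Heatmaps take
−log10(p) (p floored at 1e-15) over categories significant in at least one
(comparison × direction) cell and with ≥ 2 foreground members (singleton
categories make unstable rows), clustered with Euclidean distance and
average linkage; categories are sorted by id before clustering so the leaf
order is deterministic and input-order independent.

## Synthetic data generator

The generator emulates the study design rather than a generic experiment:

- 3 conditions × 3 replicates, 9 used channels; comparisons T50/T30,
  T55/T30, T55/T50.
- Protein sequences are random 200–800-mers at natural amino-acid
  frequencies; trypsin-like digestion (cut after K/R, not before P,
  fragments 6–30 aa) yields the peptide pool, 1–10 sampled per protein.
- Intensity model: `intensity = protein abundance × peptide ionization ×
  channel loading × 2^(condition effect) × exp(N(0, σ))` with σ = 0.25
  (natural-log units) by default — log-normal multiplicative noise is the
  standard model for reporter-ion data and has closed-form expectations.
  Channel loadings (σ = 0.10) exercise the per-sample normalization;
  protein abundances span ~10^5–10^7 and peptide ionization factors one
  log-normal decade, matching the dynamic range of typical TMT data.
- Planted effects: per non-baseline condition, 10% of proteins up and 10%
  down at 2× by default.  With `continuous_effects=True` the log2 effects
  are instead drawn N(0, 1), which is the right layout for measuring
  rank-correlation of recovered ratios (a mostly-null discrete layout
  leaves the truth vector ~80% exact ties, capping any estimator's
  Spearman near 0.66 regardless of quality).
- Glycosites are planted inside valid sequons (the generator writes
  N, X ≠ P, S/T into the sequence), at the site-count distribution
  observed in the three-temperature study (59/22/10/5/4% for 1/2/3/4/≥5
  sites per glycoprotein); 20% of sites get an occupancy effect (±1 log2)
  independent of the protein effect.
- Shared peptides arise by copying a tryptic fragment from a donor protein
  into a recipient's sequence, so non-unique attribution is real sequence
  sharing, and a shared peptide's intensity sums its parents' abundances.
- Annotations: GO-BP categories at random prevalences 1–10%, with planted
  categories covering ~50% of the truly-up set vs ~5% of the rest; KEGG
  pathways, domains, and one subcellular label per protein at fixed
  compartment probabilities.

What the generator does **not** emulate: peptide-spectrum-match level
variation and co-isolation interference, isotope-impurity cross-talk
between channels, missing-not-at-random dropout (only uniform dropout is
available), protein-grouping ambiguity beyond simple sharing, and real
sequence homology structure.  Passing tests therefore demonstrate the
correctness of the arithmetic and the statistical behaviour under the
stated noise model, not robustness to every artifact of real TMT data.

## Problem sizes and numerical choices

The test suite and acceptance script run the full pipeline at 1,000
proteins / 200 glycoproteins (the study's order of magnitude for
quantified glycoproteins; about an order of magnitude below its quantified
proteome for speed), 1,000 random fixtures for the normalization and
rollup oracles, 10,000 random sequences for the sequon oracle, 10,000 null
draws for the t-test calibration, and the exhaustive N ≤ 40 Fisher
enumeration.  Tolerances: 1e-9 for the normalization invariant and
occupancy column sums, 1e-10 for Fisher agreement, ±0.01 around 0.05 for
the null rejection rate, and exact equality for the site-correction
identity (asserted as `corrected == raw / protein`, its defining form;
the multiplicative round-trip holds to 1 ulp).  All randomness flows from
a single seed per run.

## Known limitations

- Protein ratios and protein p-values come from two related but distinct
  summaries (ratio-space median vs channel-space medians); a protein can
  in principle pass the fold-change filter while the channel-space test
  disagrees, which is visible as "unchanged" calls at large ratios with
  few peptides.
- No protein grouping/parsimony: accessions are taken as given.
- No isotope-impurity correction; inputs are assumed purity-corrected
  upstream.
- Layer-level reproduction of external study tables requires their
  deposited data and is out of scope here; the acceptance script instead
  certifies the method's behaviour on ground-truth simulations.
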