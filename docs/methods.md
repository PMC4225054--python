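# Methods

## Panel model

A panel is an ordered list of marker declarations: gene symbol, marker id
(rsID or conventional name), marker class (SNP, VNTR, length
polymorphism), chromosome class (autosomal or X-linked), an ordered
allele-label universe, and the risk declaration — either an explicit
label subset or, for VNTRs, a repeat-count predicate `repeats >= k`
resolved against the universe at load time. Labels are case-insensitive
and stored uppercase. Validation enforces: non-empty universe, unique
labels and marker ids, risk set contained in (and predicate evaluable on)
the universe.

Built-in panels:

- `gars9` — the nine-gene panel (DRD2 Taq1 A1, DRD3 Ser9Gly C, DRD4 long
  exon-III allele, MAOA-uVNTR 4R, COMT Val158 G, DAT1 9R, 5-HTTLPR S,
  OPRM1 118G, GABRB3 181). Its single X-linked marker (MAOA-uVNTR) gives
  the 18 (F) / 17 (M) countable-allele accounting. This is the default
  panel because it matches the published severity-scoring study.
- `gars10` — adds DRD1 with risk allele 48G. The ten-gene listing and the
  nine-gene 18/17 accounting coexist in the source material without
  reconciliation; we ship both and default to `gars9`. The DRD1
  literature also associates the −48A/A *genotype* with severity while
  the canonical panel lists 48G as the risk allele; we follow the panel
  listing and note the tension here rather than resolve it.
- `extended` — `gars10` plus the two 5-HT2A receptor SNPs (T102C risk C,
  −1438G/A risk A), which appear in the SNP catalogue but not in the
  canonical ten-gene panel.

Design choices worth flagging:

- **DRD4 risk as a predicate.** The literature calls 6–10 repeats "long"
  but names 7R as the risk allele; the predicate form (`min_repeats: 7`
  by default) keeps both readings configurable.
- **DAT1 risk defaults to 9R** per the canonical panel, although the
  family study counted 10/10 genotypes. Override in a custom panel YAML
  if you need the 10R convention.
- **GABRB3 "181"** is modelled as a length-polymorphism label (the 181-bp
  G1 dinucleotide-repeat allele) against a catch-all `OTHER`; presence of
  the label counts, no repeat arithmetic is attempted.

## Scoring

Per subject: for each non-missing marker, the numerator gains one per
called allele in the risk set (0–2 autosomal, 0–1 male X); the
denominator counts only called slots. Missing markers shrink the
denominator instead of counting as non-risk. The call rate (called slots
over the subject's full sex-specific slot count) is always reported.
Percentage = 100 × carried / countable, exact to double precision; a
subject with every marker missing is unscorable and raises rather than
returning 0.

Severity banding rounds the percentage half-up to an integer first, which
makes the printed integer bands exhaustive; with denominators 17/18 no
achievable percentage is an ambiguous half-integer except via
missing-data denominators (e.g. 7/16 = 43.75 → 44). Half-up (not
banker's) rounding is used everywhere a printed figure is produced. 0 %
is its own ZERO band since the low band starts at 1 %; `zero_as_low=True`
collapses it. No per-gene weighting is applied — the method is an
unweighted count by design.

Edge cases: a male X call exported as "4R/4R" is collapsed to the
hemizygous {4R} with a warning (a common genotyping-export artifact); two
*distinct* alleles for a male X marker is an error. A subject of unknown
sex is scorable only while the X-linked markers are uncalled; for the
call-rate denominator in that case the X marker counts 2 slots (the
choice only affects the reported call rate, never the score).

## Genotype I/O

The canonical format is a tab-delimited table (`subject_id`, `sex`, one
column per marker id; `X/Y` diploid, `X` hemizygous, `.` missing) because
VCF cannot faithfully carry the panel's VNTR and length polymorphisms.
VCF ingestion is therefore SNP-only: sites are matched by the ID field
against an explicit rsID→{ref,alt}-label map (a default covers the
built-in SNPs), non-SNP markers are left missing with a notice,
multi-allelic sites not covered by the map yield missing calls with a
warning, and no strand flipping is attempted — a label mismatch is an
error, never a silent complement.

## Association statistics

For the carrier table (a, b; c, d):

- **Odds ratio** ad/bc; optional Haldane–Anscombe +0.5 on all cells when
  any cell is zero (flagged in the result).
- **Woolf CI** exp(ln OR ± z·SE), SE = √(1/a+1/b+1/c+1/d), z from the
  normal quantile (1.959964 at 95 %). This method is used because it
  reproduces the published family-study interval: on (43, 12, 1, 29) it
  gives 12.81 and 843.23, matching the printed (12.8, 843.2) at one
  decimal. (The frequently quoted z = 1.96 would put the upper bound at
  843.33.)
- **Pearson chi-square**, 1 df, N(ad−bc)²/(r₁r₂c₁c₂). Uncorrected by
  default: the published statistic 43.6 is the uncorrected value on the
  reconstructed table; Yates' correction (≈40.6 there) is available as a
  flag. p from the χ² upper tail.
- **Fisher's exact test**, two-sided, by hypergeometric enumeration:
  exact `Fraction` arithmetic sums all tables with the observed margins
  whose probability does not exceed the observed table's, making the
  probability-ordering tie-break unambiguous. The test suite checks it
  against an independent library implementation for every table with
  N ≤ 40.
- **Bayes PPV** prev·P(c|aff) / [prev·P(c|aff) + (1−prev)·P(c|unaff)],
  generic in its three inputs.

The family-study control cell (1 carrier / 29 non-carriers) used in tests
is a reconstruction: the unique small-integer control group jointly
consistent with the published odds ratio, chi-square and interval given
the printed 78 % carrier rate among 55 genotyped family members. The
OPRM1 A118G table (79/173 vs 36/276) is likewise reconstructed from the
printed allele frequencies 0.31 (126 case subjects → 252 alleles) and
0.12 (156 controls → 312 alleles); it reproduces the published odds ratio
3.501, but not the published CI under any standard method we tried, so
only the odds ratio is checked.

## Cohort simulator

The simulator draws what the scorer and association module assume and
nothing more: Hardy–Weinberg equilibrium at each marker, linkage
equilibrium between markers, sex by one Bernoulli draw per subject at the
configured female fraction, X-linked markers as one allele draw for males
and two for females, and independent per-call missingness. A marker
frequency may be a scalar risk-allele frequency (the marker collapses to
risk vs its canonical non-risk baseline label) or a full per-allele
vector. Three presets encode the published DRD2 Taq1 A1 carrier-rate
contrast — `rds_family` 78 %, `screened_control` 26 %, `super_control`
3 % — with frequencies back-solved under HWE via q = 1 − √(1 − carrier);
that back-solving is an assumption (the sources print carrier rates, not
allele frequencies) and is echoed in the cohort provenance string.
Default frequencies for the remaining markers are round literature-typical
values for European-ancestry populations; they are fixed package
constants, not fitted quantities.

Randomness contract: one root seed; each (population, marker) pair and
each purpose (sex, genotype, missingness) gets a substream keyed by
CRC-32 of the names, so adding or removing a marker never perturbs the
other markers' draws, and identical seed + config reproduces cohorts
byte-identically.

What the simulator deliberately does **not** model: pedigree structure
(the family study spanned five generations; we draw unrelated subjects),
linkage disequilibrium, ascertainment bias, population stratification
beyond named frequency sets, and genotyping error other than missingness.
Passing tests therefore demonstrate the engine's arithmetic and
statistical calibration under the stated null model, not the clinical
validity of the panel on real cohorts.

## Numerical and testing choices

- Percentages are exact double-precision ratios; only display and banding
  round (half-up).
- The statistical fidelity tests use fixed problem sizes chosen for tight
  sampling error at desk scale: allele-frequency recovery within 4 SE at
  n = 10 000 (≈1/16 000 false-alarm rate per marker), HWE goodness of fit
  at α = 0.001, Woolf-interval coverage ≥ 93 % (nominal 95 %) over 2000
  simulated studies of 200 subjects per group.
- The published 72-patient severity distribution (27/74/4 %, which sums
  to 105 % as printed), the ASI severity trend, the 74.4 % Bayesian
  figure and the DAT1 odds ratio 2.3 rest on unpublished inputs and are
  not reproduced; the suite substitutes the property-based checks above.
- The exact-equality sex-symmetry property (male hemizygote vs female
  homozygote at X) holds precisely when the X allele's risk status
  matches the subject's autosomal risk fraction; the tests exercise the
  two homogeneous cases where it is exact.
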