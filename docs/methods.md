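# Methods

Scientific and numerical methods implemented by `pcscreen`.

## Variant quality filtering

A call is retained by the quality gate iff all of:

- sequencing depth ≥ 10 (configurable `min_depth`);
- base quality strictly > 20 (`min_quality`; a call at exactly Q20 fails);
- heterozygous allele ratio strictly > 0.35 (`min_het_ratio`), evaluated
  only for heterozygous calls — homozygous and hemizygous calls skip this
  gate. The strict comparator is a deliberate design choice (retain only
  ratios above 35%); it is configurable via `het_ratio_strict`.

Records from separate assays (structural events, repeat expansions;
represented with `depth = None`) bypass the short-read QC gates entirely.

The classification gate then retains pathogenic / likely-pathogenic calls
with population MAF ≤ 0.01 that are not in the healthy-homozygote index.
Exclusion reasons are assigned in a fixed order so audits are deterministic:
`not_plp` → `common_maf` → `homozygous_in_healthy` (after the quality
reasons `low_depth` → `low_quality` → `low_het_ratio`). Every input call
receives exactly one `FilterDecision`; retained + excluded partition the
input, and this invariant is property-tested.

## Carrier rates and cohort statistics

Carrier rates are carrier counts over the cohort denominator: all
individuals for autosomal genes, females only for X-linked genes. Rates are
displayed as `1/N` with N = denominator/carriers rounded half-up, matching
the convention used in published tables (e.g. 57 carriers of 14,125 →
1/248; 2 female X-linked carriers of 7,464 → 1/3732).

Binomial proportions carry exact Clopper–Pearson 95% intervals, computed
with `statsmodels.stats.proportion.proportion_confint(method="beta")` rather
than a local implementation. Subgroup contrasts use `scipy.stats
.fisher_exact`; tables with a zero margin are reported as degenerate with
p = 1. Note that exact-test p-values are discrete and conservative: under
the null P(p ≤ α) ≤ α but the p-value distribution is *sub-uniform*, not
uniform. The test suite checks sub-uniformity; a Kolmogorov–Smirnov
uniformity check would reject even a correct implementation.

## Fetal disease risk (FDR) models

With CR the carrier rate (probability a random individual of the relevant
sex is a heterozygous carrier):

- **Autosomal recessive:** `FDR = CR_f × CR_m / 4`. Both partners carriers
  (CR_f × CR_m), child inherits both variant alleles (1/4).
- **X-linked recessive:** `FDR = CR_f / 4`. Mother carrier, transmits the
  variant X (1/2), child is male (1/2). Affected female conceptions through
  carrier fathers are neglected, as is standard.
- **FMR1 repeat expansion:** `FDR = ¼ Σ_b freq(b) × P(expansion | b)` over
  maternal premutation size bins. The shipped maternal expansion-risk table
  (`data/fmr1_expansion_maternal.tsv`) uses published bin-wise full-mutation
  expansion risks (Nolin et al. 2003): 55–59: 0.037 up to 95+: 0.981.
- **Alpha-thalassemia:** `FDR = CR(–α3.7) × CR(––MED/––SEA) / 4`, the
  directional pairing convention (one parent from each allele-class pool).
  A symmetric mating model in which either partner may carry either allele
  class would give `/2`; the directional `/4` convention is used throughout,
  and the Monte Carlo oracle draws parents the same way so the dual-route
  check remains meaningful.

Every closed form has a second, independent route:
`simulate_conception_risk(carrier_freqs, model, n_conceptions, seed)` draws
parental genotypes and transmits alleles by Mendelian rules using vectorised
NumPy with `np.random.default_rng(seed)`. Tests require agreement within
three binomial standard errors at n = 10⁶–10⁷.

Aggregate risk over a panel sums per-gene FDRs at or above a severity floor
and is displayed as `1/round(1/total)`. Contribution percentages are
per-gene shares of the aggregate; the X-linked share includes FMR1.

## Panel curation

Gene–condition pairs pass a fixed cascade; the first failing step is
recorded as the exclusion reason and all failing steps are also kept:

1. **prevalence** — modelled FDR < 1e-6 (for an AR gene this equals a
   carrier rate below 1/500 in each partner: (1/500)²/4 is exactly 1e-6 in
   IEEE double arithmetic);
2. **inheritance** — not autosomal recessive or X-linked recessive;
3. **evidence** — gene–disease validity below definitive/strong;
4. **penetrance** — low or moderate excluded, high retained, unknown
   retained (conservative);
5. **onset** — adult/late onset excluded;
6. **severity** — mild (grade 1 on the 1–4 mild/moderate/severe/profound
   scale) excluded.

The ledger partitions its input: every candidate appears exactly once,
retained or with a reason.

## Couple screening

Findings per couple: `AR_shared_gene` (both partners carry P/LP variants in
the same panel AR gene), `XL_female_carrier` (female partner carries a
panel XLR gene), `FMR1_premutation` (female allele with 55 ≤ CGG < 200;
full mutations ≥ 200 are reported separately, risk weighting by expansion
probability happens in the risk model, not the flag), and
`exome_wide_rare` (off-panel gene carried by *both* partners). The
exome-wide scan never reports a gene carried by only one partner — a
confidentiality contract enforced by construction and by tests. FMR1 allele
strings of the form `"30.56*"` are parsed as an allele-size pair.

Cohort summaries report at-risk couples as a proportion with a
Clopper–Pearson interval, with and without couples whose only finding is an
FMR1 premutation.

## Secondary findings

The shipped ACMG SF v2.0 list (`data/acmg_sf_v2.tsv`) has 59 genes.
Screening counts individuals once per gene, uses an independent
secondary-findings classification channel when present
(`sf_classification`), demotes P/LP variants in autosomal-dominant genes
with population MAF > 0.005 (too common for a penetrant dominant allele),
and counts X-linked genes among females over the female denominator. ATP7B
and MUTYH are additionally screened for homozygotes and potential compound
heterozygotes (two or more distinct heterozygous variants in one
individual).

## Synthetic cohort generator

`simulate_population(config)` draws carriers per gene as Bernoulli trials in
carrier-frequency space (not allele-frequency space; optional
Hardy–Weinberg homozygotes can be planted separately), assigns the four
subgroups (patient/donor × female/male) by largest-remainder apportionment,
restricts X-linked carriers to females, plants FMR1 allele sizes from
binned premutation frequencies, plants secondary-findings carriers, and
injects contamination calls each violating exactly one filter (VUS/benign,
common MAF, low depth, low quality, low het ratio) with Poisson per-individual
counts. The generator returns a truth table; planted carrier sets round-trip
exactly through the filters, and planted contamination is recovered exactly
in the filter audit — both property-tested.

Scope and limits: no linkage, no de novo events, no population structure
beyond the four subgroups, no genotype correlation between genes, couples
paired uniformly without replacement. The default configuration
(`default_config`) mirrors a 14,125-exome cohort with subgroups
1,946/5,518/6,334/327 and a 116-row gene table (20 named gene–condition
pairs with published carrier rates plus 94 filler pairs log-spaced between
1/100 and 1/500, two off-panel genes); these sizes are package defaults, all
configurable.

## Numerical and engineering conventions

- All randomness flows through `np.random.default_rng(seed)`; seeds are
  mandatory in configurations and reruns are byte-identical (verified via
  SHA-256 digests in `manifest.json`).
- Display rounding is round-half-up via `decimal.Decimal`, not banker's
  rounding.
- Exact statistics (Clopper–Pearson, Fisher) are delegated to statsmodels
  and scipy; file formats use pandas (TSV) and cyvcf2 (VCF).
- Configuration objects are pydantic models; unknown configuration keys are
  rejected with a diagnostic rather than silently ignored.
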