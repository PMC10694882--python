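# Methods

## The model

Each of the four panel SNPs — *ADRB2* rs1042713 (A/G, risk A), *IL4*
rs2243250 (T/C, risk T), *FCER1B* rs569108 (A/G, risk G), *IL13* rs20541
(A/G, risk G) — contributes one binary feature per child: whether the child
is homozygous for the risk allele. The resulting 4-bit *risk profile* takes
16 values; the four-locus model is a partition of those 16 profiles into
high- and low-risk classes. The canonical fixed partition classes as low the
reference profile (no risk homozygotes), every single risk homozygote, and
the two pairs {ADRB2, FCER1B} and {IL13, FCER1B}; the other four pairs, all
triples and the quadruple are high. The package verifies (exhaustively) that
this enumeration equals the closed-form counting rule "high iff ≥3 risk
homozygotes, or exactly 2 outside the two exempt pairs".

The data-driven construction (`derive_model`) compares each observed
non-reference profile with the reference in a 2×2 profile-by-group table and
labels it high iff p < α and OR > 1, both strict, with no multiple-testing
correction — the rule is deliberately the published one, not a recommended
modern procedure. Fisher's exact test replaces Pearson's χ² whenever any
margin-expected count is below 5, since profile combinations are sparse by
construction. Profiles observed in neither group inherit the fixed class and
are flagged `unobserved`, keeping the classifier total. Ties (p = α or
OR = 1 exactly) resolve to low.

The fixed partition ships as the canonical model because the two built-in
cohorts are far too small to re-derive it: several profiles (anything
requiring an FCER1B risk homozygote, population frequency ≈ 1–5%) have
expected counts near zero at n ≈ 100 per group. `derive_model` exists to
reproduce the construction procedure on data that can support it.

## Statistics

Frequencies are gene-counting estimates: freq(A) = (N_AA + N_AB/2)/N.
Internally everything is kept at full precision; percentage strings are
rendered at 2 decimals only for display.

Association tests are Pearson χ² with expected counts from the margins
(df = (r−1)(c−1)); Yates's 0.5 continuity correction is available for 2×2
tables but off by default. Fisher's exact two-tailed p sums hypergeometric
probabilities ≤ the observed table's probability and requires integral
counts. The automatic 2×2 selection rule is Fisher below expected count 5,
otherwise plain Pearson; every report line logs which test ran. The odds
ratio uses the cross-product with a Woolf (log-normal) interval; a zero cell
raises rather than silently correcting, with the Haldane–Anscombe +0.5
correction as an explicit opt-in. The two-sample t-test accepts mean/SD/n
summaries with pooled (default) or Welch–Satterthwaite variants — summary
input because the published demographics are mean ± SD only. A
normal-approximation Mann–Whitney rank-sum wrapper is provided as an
untargeted utility for non-normal comparisons.

Allele tables support two conventions. `two_n` counts chromosomes
(2·N_AA + N_AB), the statistically correct unit, and is the default.
`per_individual` counts freq(A) × N individuals (= N_AA + N_AB/2, possibly
non-integral); because the Pearson statistic is linear under uniform count
scaling, its χ² is exactly half the `two_n` value, and it is the convention
under which the published allele χ² values reproduce. The
`published_compat` profile (CLI `--published-compat`) bundles
`per_individual`, the fixed model, Woolf CIs and no continuity correction —
reproduction settings kept separate from recommended defaults on purpose.

## Built-in reference data and reconstruction

The original study published only summary tables. `fourlocus.datasets`
stores the printed per-locus genotype percentage rows (in the printed
AA/AG/GG-style column order, converted explicitly to risk orientation),
group sizes (Han 101/92, Kazak 80/93), sex counts, age mean ± SD, and the
high/low risk-class counts (Han 45/56 vs 22/70; Kazak 15/65 vs 16/77).
`reconstruct_counts` maps a percentage row back to integers by rounding
half away from zero, which recovers counts summing exactly to the group
size for all 16 genotype rows; a row that does not sum cleanly triggers a
warning, never an error, because published tables contain typos that must
not halt a pipeline.

Known non-reproducible printed cells, excluded from reproduction assertions
and covered by documented-discrepancy tests instead: the FCER1B genotype χ²
(printed 2.16 Han / 1.38 Kazak; Pearson on reconstructed counts gives
2.23 / 1.28 — possibly a different correction was applied to these sparse
tables), the Han IL4 and IL13 allele χ² (printed 5.51 / 7.17 vs 5.35 / 7.23,
consistent with intermediate rounding), the Han FCER1B allele percentage
cells (inconsistent with their own genotype row), and the Kazak high-risk
percentages (15/80 is 18.75%, printed 16.67%; the counts reproduce the
printed OR and are treated as authoritative). None of these changes any
significance conclusion.

## The simulator

`simulate_cohort` emulates a two-group cohort: per locus, genotypes are
drawn from the group's (risk-hom, het, other-hom) probability vector;
sex is Bernoulli; age is normal truncated to [0, 14] years (the cohorts'
inclusion window) by rejection sampling. Loci are independent within a
group because only marginal distributions were published — `plant_risk_effect`
is the single mechanism inducing cross-locus structure. It multiplies the
case group's joint profile odds (vs the reference profile) by a target odds
ratio and renormalizes, leaving controls untouched, which makes the
profile-level case-control odds ratio equal the planted value. Genotypes are
drawn from the genotype distribution directly rather than from allele
frequencies under Hardy–Weinberg, so simulated marginals match the
published tables even where those deviate from HWE; `hwe_mode=True` switches
to HWE sampling from the implied allele frequency. All randomness flows
through one `numpy.random.default_rng(seed)` stream; identical spec + seed
gives byte-identical cohorts, and the CLI records the seed and a spec hash
in a metadata sidecar.

What the simulator does not model: linkage disequilibrium (IL13 and IL4 are
both at 5q31 and plausibly linked in reality), family structure, admixture,
genotyping error, and missingness. Tests passing on simulated data therefore
validate the statistical machinery and the derivation rule, not robustness
to those real-data features.

## Recovery experiment sizes

The derived-model recovery property runs 20 seeded replicates at n = 2000
per group with a planted OR of 5 on the nine high-risk profiles, using a
balanced genotype spec (risk-hom/het/other = 0.35/0.40/0.25 at every locus
in both groups). The balanced spec is chosen so that all 16 profiles are
well represented — the rarest has probability 0.35⁴ ≈ 1.5%, about 30
expected controls — giving the per-profile 2×2 tests high power; under the
study's own marginals the FCER1B-bearing profiles are essentially
unobservable at any realistic n, which is precisely why the fixed model is
the shipped default. Under these conditions the derived partition matches
the canonical one on ≥95% of observed profiles (in practice ~100%), and
under the null the per-profile false-high rate stays below α (the rule
needs p < α *and* OR > 1, so the two-sided test contributes roughly α/2).

## Numerical and edge-case choices

- Heterozygotes are canonicalized by the locus's allele declaration order,
  so "GA" ≡ "AG"; `normalize_genotype` is idempotent and order-insensitive.
- Orientation is always risk-allele-first internally; printed-order tables
  exist only in `datasets`, which converts explicitly.
- Missing genotype calls exclude a sample from that locus's counts and from
  risk classification (which needs all four loci); they never fail a read.
- Group labels accept asthma/case and control/healthy case-insensitively;
  anything else is a validation error, not a third group.
- A zero table margin raises a degenerate-table error (exit code 3 in the
  CLI); a zero cell makes the pipeline report the χ² but mark the OR
  undefined rather than aborting the whole report.
- p-values are stored at full precision; published-value comparisons in the
  test suite use the printed precision of each cell.
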