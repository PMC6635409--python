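# Methods

This note records the models implemented in `campnets`, the parameters
that matter, the design decisions taken where the design was genuinely
open, and what the synthetic fixtures do and do not establish.

## Interolog scoring

A membrane protein's (MP) cytoplasmic regions — the intervals annotated
as facing the cytosol — are used as queries against a library of curated
interaction templates. A template A–B supports a candidate pair A′–B′
when A′ and B′ are homologs of A and B. Prediction runs in two stages:
templates are first selected by a cytoplasmic-region alignment against
either template protein (the hit side becomes the MP-side protein), then
partner candidates are enumerated from proteome hits against the other
side. Gates: per-protein E ≤ 1e−10 and joint E — the geometric mean of
the two per-protein E-values — ≤ 1e−40.

Each surviving (region, template, partner) combination is scored with six
components, each in [0, 1] (see README for the formulas). Numerical
conventions:

* **E-value floors and clips.** A literal `0.0` E-value is floored at
  1e−180 at parse time so −log₁₀ stays finite. The per-side ratios in
  `S_jss` are clipped to [0, 1]: with floored E-values a cross-alignment
  can appear "better" than the self-alignment, and the component is
  defined to stay within the unit interval.
* **Ranks.** `S_rank` uses fractional (average) ranks over one template's
  candidates, descending by `S_jss`; `r_max` is that template's candidate
  count, and a lone candidate scores 1. Degree ranks for `S_topo` are
  fractional with rank 1 = largest degree, and `R_max` is taken from the
  supplied network rather than any fixed constant.
* **Conservation.** `S_es` sums organism contributions and is clipped at
  1; since every component is defined on [0, 1], the clip is the only
  normalization consistent with that contract when many source organisms
  support a pair. Cross-species templates use the mean distance from the
  target organism to the two source organisms. A helper normalizes raw
  tree distances by the tree's maximum pairwise distance.
* **Aggregation.** One (MP, partner) pair may be supported by several
  (region, template) combinations; the pair's score is the maximum
  `S_SIM` over them, with `S_irs`/`S_qul` attached to the maximizing
  combination. `S_es` is a property of the pair (all supporting
  templates), not of a single combination.

Template curation assigns each experimental detection method a
reliability score in 0–10 (crystallography highest, genetic interference
lowest, high-throughput screens ≤ 5), inherited from the nearest scored
ancestor in the PSI-MI hierarchy; when one annotated term is a subclass
of another, only the child counts (representative-term rule). Direct
physical templates require an experimental detection method (MI:0045
subtree), a direct-interaction type (MI:0407 subtree), and representative
method scores summing to ≥ 6. The shipped reliability map is a small
editable YAML seeded with those anchor scores; exact per-term values are
a configuration concern, not a modeling one. The negative set takes
candidate pairs whose GO relative-specificity similarities fall below 0.4
under an `or` combination by default; an `and` mode is available because
the two published criteria overlap logically and the intended connective
cannot be resolved — neither is asserted as the true intent.

## Differential expression and co-expression

The DEG contract is |log₂FC| ≥ 1 and BH-adjusted P ≤ 0.05. The per-gene
test is Welch's two-sample t on log2 values. An empirical-Bayes moderated
t would share information across genes; the plain Welch test was chosen
because downstream stages consume only the thresholded calls, and parity
with moderated-t machinery is explicitly out of scope. Co-expression is
Pearson correlation over tumor samples only (expression of normals
carries no tumor co-regulation signal), with |r| ≥ h and h = 0.5 by
default ("large effect" convention); constant genes are skipped.

## Enrichment and the permutation null

For community DEGs I and pathway DEGs T, the pair universe excludes
identical-gene pairs: n = |I|·|T| − |I∩T|, and x counts co-expressed
pairs among them. M and N are the analogous counts against the union of
all pathway gene sets (a per-pathway multiset variant is available via
the same counting helper on alternative universes). The enrichment P is
the upper hypergeometric tail Σ_{i=x}^{n} pmf(i; N, M, n); involvement is
−log₁₀P. An instance with no involved or no pathway DEGs is reported as
unevaluable with P = 1.

The permutation null redraws a community's partners without replacement
from the pooled partner multiset of all communities, preserving its size,
and recomputes involvement; the empirical P uses the add-one convention
(1 + hits)/(B + 1) so it is never exactly zero. B = 1000 by default.

Per-cancer P values are floored at 1e−16, transformed z = Φ⁻¹(1 − p), and
combined by Stouffer's unweighted method (Σz/√k); meta-z > 1.64 defines a
pan-cancer enriched association, and a second-level Stouffer combination
gives the global meta-z.

**Homogeneity.** The observed statistic is, per pathway, the fraction of
communities regulating it in at least k cancers (k ∈ {2, 3, 5, 7, 9}),
with regulation requiring enrichment P ≤ 0.05 and empirical P ≤ 0.05.
The expected fractions are medians over B null sets; at desk scale these
are obtained by permuting, within each cancer and pathway, the
significance indicators across communities — a label-permutation null
that preserves each cancer's per-pathway significant-call count without
recomputing B × |communities| enrichments. Externally computed shuffled
result sets can be substituted where full recomputation is affordable.
Observed and expected fractions are compared by a paired one-sided
Wilcoxon signed-rank test over the cancer-related pathway panel.

**Network structure.** Degree = pathways passing the meta-z gate; mean
meta-z = passing sum divided by degree; hubs = top 25% of degrees. The
degree exponent γ is a discrete power-law maximum-likelihood fit
(zeta-normalized likelihood, x_min = 1, bounded scalar optimization); a
log-log least-squares fit to the degree histogram is available for
comparison but is known to be biased and is not used for inference.
Clustering of the community × pathway meta-z matrix uses average linkage
on 1 − Pearson r distances, cut into the 4 largest clusters by default;
constant rows have undefined correlation and are dropped with a warning.

## Survival analysis

Follow-up is administratively censored at 120 months (10-year horizon).
Per-gene statistics come from univariate Cox fits (lifelines, Efron tie
handling); the reported per-gene P is the Wald test of the coefficient,
asymptotically equivalent to the score (log-rank) test for a univariate
fit. Constant genes are flagged without estimates.

The combined score uses sign weights w_j = +1 iff HR_j ≥ 1 (ties to +1;
the sign convention must be deterministic and HR = 1 carries no
direction), MV_t = Σ w_j E_j(t) on the stored log2 scale without
re-standardization, RC = −1 when ≥ 75% of patients have MV < 0, and a
mixed-sign flag when the negative fraction lies in [0.26, 0.74] (adverse
vs favorable direction not evaluable). Weights are estimated on the same
cohort that is subsequently stratified; this in-sample reuse mirrors the
intended usage and is a known optimism source.

Stratification: the median policy splits at the 50th percentile of CS;
the best-cutoff policy scans every observed CS value in the interquartile
25–75% band and reports the minimum two-group log-rank P without
multiplicity correction. The consequence — a null rejection rate well
above the nominal 5% — is documented by a resampling property test
rather than corrected away, because the reported quantity is defined as
the minimum-P cutoff. Group hazard ratios come from a Cox fit on the
group indicator. Per-cancer z-scores combine by unweighted Stouffer;
|meta-z| ≥ 1.96 marks significance (positive = adverse).

## Assay metrics

IPR = (IIP/IIC)·(AIC/AIP)·100%, with positivity requiring both reciprocal
assays strictly above 3%. FRET efficiency is (D_post − D_pre)/D_post for
D_post > D_pre and 0 otherwise — the formula's stated domain is extended
by clamping, since a non-recovering donor carries no transfer signal.
The positivity cut is max(MFE_i + SE_i) over background/negative-control
candidates, and an efficiency must strictly exceed it.

## Synthetic fixtures

The generators are pure functions of a `FixtureConfig` (seed mandatory):

* **Interactome** — E-values are generated directly as
  10^(μ + noise) with μ set by planted identity (strong homology
  exponent −60 for true pairs, −25 for scored decoys, −12 for decoys
  meant to fail the joint gate; self-alignments at −100, typical of a
  ~300-residue self-BLAST), with log-scale noise of 3 decades. No
  aligner runs: the scorer consumes E-values, not sequences. True pairs
  additionally share network neighbors with the MP.
* **Expression/survival** — baseline N(7, 1) per gene on the log2 scale,
  latent-factor co-expression blocks with loading √r for a target
  within-block correlation of 0.7, planted differential expression of
  |log₂FC| = 2 with random sign (20 + 20 samples suffice for ≥ 95%
  recovery), and exponential survival with log-hazard Σβ_g·x_g (centered
  expression) under independent exponential censoring. Defaults: 400
  genes, 120 tumor / 40 normal samples, two blocks of 20, 30 extra DEGs,
  β = 0.3 on 5 genes, baseline hazard 0.02/month, censoring hazard
  0.008/month. With `planted=False` every effect is zeroed, giving exact
  nulls for calibration.
* **Pathways** — 12 sets of ~22 genes; the planted pathway and the
  designated community split the first co-expression block, so the
  planted association is carried by real correlation structure rather
  than by construction of the counts.

What passing tests show: the implementation recovers planted structure
(AUC, DEG sensitivity, block correlation, Cox coefficients, the degree
exponent) and is calibrated under exact nulls. What they do not show:
behavior under real-data pathologies — batch effects, count-level noise,
probe ambiguity, non-proportional hazards, population structure in the
template corpus — none of which the generators emulate.

Null-calibration checks of the permutation P use a permissive
co-expression threshold (h = 0.2) at 40 tumor samples: at h = 0.5 a null
co-expression graph is nearly empty and the involvement statistic
degenerates to a point mass, which tests nothing. Problem sizes
throughout (200–400 genes, 40–300 patients, B = 50–1000, 200–2000
resampling repeats) were chosen so each check exercises the asymptotics
it relies on while the whole suite stays desk-scale.

## Known limitations

* The evidence-cap value (2) and reliability anchors are conventions; the
  direct-template filter is sensitive to the per-term score table, which
  ships as editable configuration.
* The hypergeometric model treats gene pairs as exchangeable draws;
  correlated pairs sharing a gene violate independence, which is exactly
  why the permutation null is computed alongside the analytic P.
* The homogeneity null permutes significance labels rather than
  recomputing enrichment over shuffled communities; both preserve the
  per-cancer significant-call counts, but the label permutation ignores
  between-pathway correlation of a community's calls.
* Best-cutoff survival P values are optimistic by construction (see
  above) and should be treated as ranking scores, not calibrated
  significance.
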