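# Methods

## The triad model

A triad is a female parent F, a male parent M and their F1 hybrid H,
assayed with replicated bulk RNA-seq at one or more time points. The
question the pipeline answers is how the hybrid's expression relates to
its parents gene by gene: additively (at the parental mid-point),
dominantly (indistinguishable from one parent while the parents differ),
or over-dominantly (outside the parental range) — and whether
over-dominant expression co-occurs with phenotypic heterosis.

## Differential expression

Counts for gene g in sample s are modelled negative-binomial with mean
μ·L_s and variance μ + αμ², L_s a per-sample size factor and α the
gene's dispersion.

* **Size factors** are median-of-ratios: factor_s = median over genes
  with all-positive counts of counts_{g,s} / (geometric mean of gene g
  across samples). If no gene is positive everywhere, an explicit
  `allow_pseudo_reference` flag switches to a positive-entries-only
  geometric reference; this is off by default so sparse inputs fail
  loudly. Note the factors are reported exactly as the formula yields
  them (no rescaling to geometric mean 1), so scaling one sample by c
  scales its factor *relative to the others* by c; absolute factors also
  absorb a c^(1/n) shift of the reference. All fold changes are
  invariant to that shift.
* **Dispersion** is method-of-moments on normalised counts pooled over
  the two groups being compared, after centring each group on its own
  mean: α = max((s² − μ̄)/μ̄², 10⁻⁸), with s² the pooled within-group
  variance (df = n_A + n_B − 2) and μ̄ the grand mean. This is a
  deliberately simple plug-in estimate — no shrinkage across genes —
  because the contract of the package is planted-truth recovery, not
  numerical parity with any particular GLM implementation. A user with
  an externally computed DE table can feed calls straight into the
  classifier.
* **Wald test.** Group means m_A, m_B of normalised counts;
  log₂FC = log₂((m_B + 0.5z)/(m_A + 0.5z)) with z = 1 only when either
  group mean is zero, so non-zero genes are unbiased while zeros stay
  finite. The delta method gives Var(m) ≈ (Σ_s μ/L_s + αμ²n)/n² at the
  fitted mean, hence an SE for log₂FC, a standard-normal Wald p, and BH
  adjustment across all genes of the comparison. Genes all-zero in both
  groups report log₂FC 0, p 1.
* **DEG call**: up if adjusted p < α and log₂FC ≥ τ, down if ≤ −τ, else
  ns. Defaults α = 0.05, τ = 1 (two-fold).

With ~3 replicates the moment dispersion is noisy per gene; the BH step
and the fold-change threshold keep the null false-positive fraction
controlled (measured ≈ 2–3% at the 0.05 target in the acceptance run).

## Inheritance-mode classification

Each gene's triple of relations (F:M, H:F, H:M), each in {>, <, =}, maps
through a fixed rule table to classes 1–12, conserved (all three =) or
unclassified (the 13 internally inconsistent triples). The table and the
category grouping are in `triadex.patterns`; properties enforced by
tests: every one of the 27 triples gets exactly one label, and
relabelling the parents permutes classes 1↔2, 3↔5, 4↔6, 8↔9, 11↔12
while fixing 7 and 10 (the parents-equal over-dominant classes, which we
place first within their categories as an internal indexing convention —
analyses should key on categories, not indices).

Two thresholds play different roles, and this is the one place the
package departs from simply reusing the DEG rule everywhere:

* The **classified universe** is the set of genes that are DEGs
  (|log₂FC| ≥ τ, adjusted p < α) in at least one of the three
  comparisons. Genes outside it are reported conserved.
* The **relations** inside the universe use significance plus direction
  only (`tau_relation = 0` by default, configurable). The reason is
  structural: an additive hybrid lies at most half the parental contrast
  from either parent (its true offset from the nearer parent is
  log₂((1+r)/2r) for parent ratio r, e.g. 0.68 log₂ units when parents
  differ 4-fold), so any fold-change filter at τ ≥ half the contrast
  applied to the hybrid–parent relations makes classes 1–2 unreachable
  and silently relabels every additive gene as dominant. Significance
  relations keep all twelve classes attainable while the DEG universe
  still gates noise genes out.

## Heterosis statistics

MPH = ((F1 − MP)/MP)·100 and HPH = ((F1 − HP)/HP)·100 with MP the
parent-mean average and HP the larger parent mean, so HPH ≤ MPH whenever
the parents differ. Percentages are invariant to unit rescaling and
undefined (reported NaN with a warning) when MP or HP is zero.

The hybrid-vs-mid-parent test defaults to a Welch two-sample t-test of
hybrid replicates against pseudo-mid-parent values MP_i = (F_i + M_i)/2
with parents paired by replicate index — this lets parental variability
into the null rather than treating MP as a known constant; a
`one-sample` variant is available. Zero variance in both samples with
unequal means is reported as p = 0 with an infinite t of the
difference's sign.

ANOVA is the standard one-way F test; pairwise comparisons use Tukey's
HSD (studentized range, via statsmodels) at the stated α. The
compact-letter display starts with all groups under one letter, splits
every letter set containing a significantly different pair, absorbs
subset sets, and assigns letters in the order each set's first member
appears — fully deterministic.

## Enrichment

Upper-tail hypergeometric P(X ≥ k) per term (scipy), BH across tested
terms, rich factor k/K. One-sided over-representation only. The
background defaults to all genes of the count matrix rather than the
DEG universe — a conservative, explicitly stated choice; terms smaller
than `min_term` (default 2) are skipped as degenerate.

## qPCR validation

ΔCT = CT_target − CT_reference per sample cancels per-sample loading
offsets; ΔΔCT subtracts the calibrator genotype's mean ΔCT; relative
expression is 2^−ΔΔCT, exactly 1 for the calibrator. Replicates
aggregate at the ΔCT level (standard Livak practice); the per-replicate
2^−ΔΔCT spread is reported as a dispersion summary. Amplification-
efficiency correction (Pfaffl) is out of scope. Concordance with
RNA-seq is the fraction of (gene, genotype-pair) contrasts with agreeing
direction plus a Spearman correlation over shared points.

## The simulator: what it emulates and what it does not

The generator mirrors a two-parent/one-hybrid seedling experiment:
3 replicates per group (configurable), 2 time points, log-normal
baseline expression (log₂ mean 7, sd 2), NB noise at dispersion 0.05,
log-uniform library factors in [0.7, 1.4] to exercise normalisation, and
planted modes at proportions {conserved 0.5, each other mode 0.1} with
effect_log2 = 2 (4-fold parent contrasts and over-dominance offsets).
Phenotypes are normal per-plant draws (30 plants per group in the worked
example); CT tables are derived from counts as
CT = offset − log₂(normalised count + 1) + N(0, 0.1²) with a constant
reference gene.

Deliberately absent: gene–gene correlation, gene-length and GC effects,
batch structure, outlier replicates, time-point-varying means, and any
read-level artefacts (the pipeline starts at the count matrix). Passing
the planted-truth tests therefore shows the machinery is correct under
the stated model, not that real tissue data will classify as cleanly;
on real data the dominant additional error sources are dispersion
mis-estimation at low replication and correlated genes inflating
enrichment significance.

One seed drives a whole bundle; per-generator sub-streams are split
deterministically, so identical configurations are byte-identical.

## Numerical choices and degenerate inputs

* Dispersion floor 10⁻⁸ (Poisson limit); all-zero genes report p = 1.
* BH implemented as the exact step-up min-over-suffix formula; verified
  against an independent reference implementation in tests.
* Ties in the classifier are impossible by construction (the rule table
  is a total function); ties in letter assignment break by group order.
* Problem sizes in tests and the acceptance script (2000 genes, 3
  replicates, ≤ 1000 oracle vectors) were chosen to estimate every
  stochastic property with comfortable Monte-Carlo margins while keeping
  a full run in well under a minute.

## Known limitations

* The moment-based dispersion is inadmissible as a per-gene estimate at
  n = 3; it works here because the Wald statistic only needs it as a
  plug-in and the acceptance properties are aggregate. Shrinkage
  estimation is the natural extension.
* Multi-factor designs, covariates, independent filtering and LFC
  shrinkage are not modelled.
* The additive/dominant boundary depends on power: with weak parent
  contrasts, additive genes are systematically absorbed into the
  dominant classes (the hybrid–nearer-parent difference is the smallest
  effect in the design). Category counts should be read with that
  asymmetry in mind.
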