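# Methods

`mptriage` implements a triage analysis for a 2×2 factorial time-course
transcriptomics experiment: injury (sham vs. spinal cord injury, SCI) crossed
with medication (vehicle EtOH vs. methylprednisolone, MP), sampled at 0, 2,
4, 6, 8, 12, 24 and 48 h with two biological replicates per condition. At
0 h only the two untreated groups exist, giving the 60-array design
(4 groups × 7 times × 2 + 2 groups × 1 time × 2). The goal is to sort genes,
per time point, into three drug-response classes:

- **SEMP** (side effect): unchanged by injury alone, perturbed once the drug
  is given;
- **CPMP** (competence): changed by injury and restored to sham level by the
  drug;
- **ICMP** (incapability): changed by injury and still changed after
  treatment;

and then to ask which Gene Ontology processes each class is enriched for
relative to the rest of the tested genome (ROG).

## Statistical model

At each post-injury time t, four contrasts are formed from the group means
(all data log2):

    A_t: SCI-EtOH vs S-EtOH      (injury response, untreated)
    B_t: SCI-MP  vs SCI-EtOH     (treatment response in the injured)
    C_t: SCI-MP  vs S-EtOH       (residual injury effect under treatment)
    D_t: S-MP    vs S-EtOH       (drug response in shams)

Gene-wise inference is a gatekeeping sequence: a one-way four-group ANOVA per
gene, Benjamini–Hochberg adjustment of the ANOVA p-values across genes within
the time point, and, for genes with adjusted p ≤ 0.05, Tukey's honest
significant difference for the four contrasts. The Tukey statistic is
q = |m_i − m_j| / √(MS_w/2 · (1/n_i + 1/n_j)) referred to the studentized
range with k = 4 groups and the pooled residual degrees of freedom
(Tukey–Kramer form; with two replicates per group and no sample loss,
df = 4). Significance is inclusive at p ≤ 0.05. Membership decisions are
made by comparing q against the critical value q* with SF(q*) = α — one
distribution evaluation per design rather than one per gene — which is
mathematically identical to thresholding the p-value; exact per-gene
p-values are computed from `scipy.stats.studentized_range` and can be
skipped (`exact_p=False`) in large simulation studies where only set
membership matters.

With two replicates per group the residual degrees of freedom are only 4, so
per-contrast power is intrinsically limited; this drives the defaults of the
synthetic generator (below) and the way recovery is scored.

A gene's class at time t follows from its significance pattern over
(A_t, B_t, C_t, D_t): SEMP = (×, o, o, ×), CPMP = (o, o, ×, ×),
ICMP = (o, ×, o, ×); all other 13 patterns are unclassified. Equivalently,
each class is (X_t ∩ Y_t ∩ D_t^c) − Z_t with {X, Y, Z} = {A, B, C} in the
appropriate roles, the complement of D taken within the tested universe
(genes surviving the noise filter). Both routes are implemented and their
equivalence is enforced by tests. The three patterns are mutually exclusive,
so a gene has at most one class per time point. For reporting, time points
are pooled into four phases — 2~6 h, 8 h, 12 h and 24~48 h — by union within
class. Union is the only aggregation that cannot drop a detection; a gene
classified differently at two times of one phase appears in both class sets.
No cross-time consistency or fold-change-direction constraint is imposed:
classification is significance-only.

## Preprocessing

*Normalization.* Arrays are median-aligned: each array is shifted so its
median equals the grand median of array medians. Per-gene median centering
is available but off by default, because the ANOVA is location-invariant
within gene; it matters only for exported fold-changes.

*Outlier arrays.* All pairwise Pearson correlations are computed; the
threshold is mean − 2·SD over the n(n−1)/2 pair values, and an array is
removed when ≥ 90% of its own correlations fall below that threshold. An
array with zero variance (correlation undefined) is removed with a distinct
reason code. Sample PCA coordinates (first two components) are exported for
visual inspection only; no removal decision is based on them.

*Noisy genes.* For every duplicate pair (same group and time, exactly two
replicates) the coefficient of variation of the two intensities is computed
on the linear scale — values are de-logged as 2^x first, and the
two-replicate sample SD is |x1 − x2|/√2 — and a gene is retained only when
at least 16 of its pairs have CV < 50%. The full design provides 30 pairs
(4 groups × 7 times + 2 groups at 0 h). The CV is computed on the linear
scale because a CV of log-values is not scale-invariant and "CV < 50%" is
conventionally a linear-scale criterion; `cv_scale="log2"` reproduces the
alternative reading. The 16-pair threshold is applied verbatim even when
outlier removal reduces the number of complete pairs; conditions with a
missing replicate are skipped and counted in the report.

## GO enrichment

Each class (pooled per phase) is compared against the ROG — all tested genes
not in the class — term by term with a two-sided Fisher's exact test on
[[k_class, n_class − k_class], [k_rog, n_rog − k_rog]]. Annotations are
first propagated to all ancestors along is_a and part_of edges (true-path
rule), so a gene annotated to a leaf counts at every ancestor. A term's
level is its shortest-path depth from the namespace root (root = level 1);
levels 3–9 are tested by default, BP and CC namespaces separately, with BH
adjustment within each level. After all levels, a significant term
(adjusted p ≤ 0.05) is flagged *deepest* when none of its descendants is
also significant; the flagged terms therefore form an antichain in the DAG —
one deepest significant term per ancestry branch — and constitute the
headline output, with the full per-term table as secondary output. The
nested "recurse until the deepest significant level" description could also
be read as stop-at-first-significant-level per branch; the antichain reading
is the implemented choice because it reports exactly the terminal
significant node of every branch regardless of gaps at intermediate levels.

## Synthetic data generator

The generator emulates the study design exactly: 60 arrays, the 0 h
restriction, duplicate replicates. Per gene, a baseline expression is drawn
once from N(8, 1.5²) log2 units and shared across all conditions; replicate
noise is i.i.d. Gaussian on the log2 scale (SD 0.2 by default). Planted
genes add a fixed shift ±Δ (default 2.0 log2 units; sign drawn once per
gene) at the active time points according to their class profile: CPMP
shifts SCI-EtOH only (the drug restores SCI-MP), ICMP shifts SCI-EtOH and
SCI-MP, SEMP shifts SCI-MP only; S-MP is never shifted. Defaults plant 50
genes per class among 2,000 — the conditions used throughout the validation
suite; with df = 4 and Δ/σ = 10 the per-contrast Tukey power is ≈ 0.98, so
per-(gene, time) class recovery is ≈ 0.82–0.94 while gene-level recovery
(the gene enters its class list at ≥ 1 active time; the class lists are the
pipeline's deliverable and the unit on which sensitivity is scored) is
essentially 1.

Noise genes draw replicate noise with SD 2.5 log2 units, which puts a
duplicate pair above the 50% linear CV roughly 76% of the time; retention
(≥ 16 of 30 passing pairs) then has probability ~1e−4. Outlier arrays are
generated by replacing the whole column with an independent draw of the same
marginal distribution, which destroys correlation with every peer without
changing scale or location. What the generator does **not** emulate:
probe-level effects, intensity-dependent variance, correlated gene modules,
batch effects, or heavy-tailed noise. Passing the recovery tests therefore
demonstrates the correctness of the decision chain under the declared model,
not robustness to real-array artifacts.

## Numerical choices and degenerate inputs

- Significance thresholds are inclusive (≤), matching the stated convention.
- A gene with zero pooled within-group variance has an undefined F/Tukey
  statistic; it is treated as significant exactly when the relevant means
  differ, and flagged `tukey_degenerate`.
- Zero-variance arrays are outliers by definition (Pearson undefined).
- BH adjustment is the standard step-up, applied within time point (ANOVA)
  and within DAG level (enrichment).
- The studentized-range critical value is cached per (k, df, α); decisions
  via q ≥ q* coincide with p ≤ α up to the measure-zero boundary.
- Problem sizes in the validation suite and the acceptance script are
  desk-scale by design: 2,000-gene planted studies (10 seeds), a 20,000-gene
  pure-null study, 20 outlier-detection replicates, a 200-term random DAG,
  and the exhaustive Fisher comparison over all 246,015 tables with row
  margins ≤ 30.

## Known limitations

- With duplicate arrays, losing one array to outlier removal leaves a group
  with a single replicate at that time point, and the four-group ANOVA
  precondition (≥ 2 replicates per group) then rejects that time point. The
  Tukey–Kramer standard error handles unbalanced designs with ≥ 2 replicates
  per group.
- Full-array normalization from probe-level data (RMA) is out of scope; the
  pipeline starts from a summarized log2 matrix.
- Real-data reproduction of the original deposited series depends on the
  original summarization software and a 2011-era GO release; the GEO
  series-matrix reader supports such a re-analysis but its results are not
  asserted anywhere.
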