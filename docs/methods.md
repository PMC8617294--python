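# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `epiconnect`. It states no empirical number that
the test suite or `scripts/acceptance.py` does not itself compute.

## The analysis model

The pipeline treats an epichaperomics experiment as a protein x sample LFQ
intensity matrix with a condition/replicate design, plus three reference
inputs: a PPI database, flat term annotations, and a chaperome member list.
Five stages are chained:

1. **Preprocessing** — within-condition quantile normalization,
   group-minimum imputation, log10 transform.
2. **Differential connectivity (DC)** — per-protein two-sided
   pooled-variance Student t-test on log10 intensities between two
   conditions; fold change as the ratio of linear-scale condition means;
   direction as the sign of the log fold change; DC status as
   p <= `dc_alpha` (default 0.1, inclusive: the filter removes p > 0.1).
3. **PPI reference** — parse BioGrid-tab and PSI-MITAB 2.5, remove genetic
   (MI:0208 or a "genetic" type/system label, case-insensitively), the five
   excluded experimental systems (co-localization in either spelling,
   genetic interference, synthetic rescue, synthetic growth defect,
   synthetic lethality; matched case- and hyphen/space-insensitively),
   non-human pairs (any taxid present and != 9606) and self-pairs; records
   with *unknown* annotations are retained, since the filter removes only
   positively matching categories. Evidence is binary: an edge is an edge.
4. **Networks** — per state, the PPI-induced subgraph over that state's
   detected proteins, keeping isolated detected proteins as degree-0 nodes.
   Node attributes: `neg_log10_p` (size), `fold_change` (colour), `grey`
   (DC.p > 0.1 or absent from the DC table). Layout is deliberately not
   computed; SIF/GraphML exports feed external viewers.
5. **iGESA** — per chaperome member and direction, one-sided Fisher
   (hypergeometric upper tail) over-representation of each annotation term
   in the member's DC interactors of that direction, BH-adjusted within the
   (member, direction) stratum; links with adjusted p <= `adj_p_max`
   (default 0.001, inclusive) form the connectivity map. Map comparison is
   set algebra on (member, term, direction) keys.

## Design choices where the design was open

* **"Replicates of the same sample"** is read as replicates of the same
  condition (sample type); all comparisons in the pipeline are
  condition-level.
* **Missing-aware quantile normalization.** Missing cells are excluded from
  ranking. Each condition's reference distribution is the mean of the
  per-column empirical quantile functions evaluated on a common grid of
  size max(observed counts); a column's observed value at average rank r of
  n_obs maps to the reference at quantile (r-1)/(n_obs-1), ties receiving
  the average of tied reference quantiles. For complete equal-length
  columns this reduces to the classic rank-mean construction, and the
  operation is idempotent.
* **Imputation uses raw intensities.** The fill value for a missing cell is
  the minimal *raw* intensity of that protein across the condition's
  replicates, written directly (so an imputed cell never exceeds the
  observed raw minimum of its protein/condition group). Passing the fill
  value through the destination column's raw-to-normalized monotone map is
  available behind `remap=True` but is not the default, because the
  re-mapped value can exceed the raw minimum. A protein entirely missing in
  a condition falls back to the condition's global observed minimum
  (logged). The per-protein reading of "minimal raw intensity across the
  replicates of the same sample type" is the default; the group-global
  reading survives as the fallback.
* **Zeros are missing.** proteinGroups input cells equal to 0 are declared
  missing at read time (the MaxQuant convention); a non-positive value
  reaching the log10 step is a hard error.
* **Fold change on linear means.** The ratio of condition means is computed
  on 10^x, not on the log10 values, so that a direction rule of the form
  "FC > 0 or < 0" is meaningful as the sign of log10(FC); an exact ratio of
  1 maps to direction "0".
* **Student, not Welch, by default.** The pooled-variance test matches the
  classic "Student's t test"; Welch is available via `welch=True`. No
  multiple-testing correction is applied at the DC stage — the DC filter
  operates on raw p at 0.1, and BH is applied only inside iGESA.
* **p floor.** p-values are floored at 1e-300 before -log10 so node-size
  attributes stay finite; zero-variance rows with equal means get p = 1,
  with unequal means p = 0 (logged).
* **Enrichment universe.** By default the universe is the detected proteins
  present in the annotation (experiment-restricted background, the
  conservative choice for AP-MS data); `background="annotation"` switches
  to the whole annotation universe. A detected/annotation identifier
  overlap below 50% aborts with a namespace error.
* **Stratum floor.** A (member, direction) query smaller than
  `min_stratum = 3` proteins is skipped and counted: Fisher on one or two
  proteins is uninformative and would inflate the map.
* **q-values.** `q_value` defaults to the BH-adjusted p; a single-lambda
  Storey estimator (lambda = 0.5, pi0 floored at 1/m) is available behind
  `use_storey=True` and never the default.
* **Connection uniqueness key** includes direction; a direction-collapsed
  count (`collapse_direction=True`, keeping the smallest-p result per
  member/term) is provided because printed connection counts in the
  literature do not always state the key.
* **"Affected" percentages.** Network-diff percentages are
  100 * (gained + lost) / union by default; `denominator="baseline"`
  divides by the first network's size instead, since published percentages
  rarely state the denominator.
* **Identifier space.** Gene symbols by default (BioGrid official symbols;
  MITAB alias-derived symbols with accession fallback); an optional
  accession-to-symbol mapping table can be applied in `build_reference`.
  No live ID-mapping service is ever called.

## The synthetic-data generator

`simulate_intensities` draws per-protein base abundances
10^Normal(`base_log10_mean` = 7, `base_log10_sd` = 0.8) — typical LFQ
magnitudes and dynamic range — multiplies a planted fraction
(`frac_differential` = 0.1) by `effect_fold` = 2 (half up, half down) in
condition B, and applies mean-one log-normal replicate noise with CV
`cv_replicate` = 0.1. Dropout is a mixture of completely-random missingness
(`mcar_rate` = 0.02) and intensity-dependent missingness with probability
logistic(-`mnar_strength` (x - c)) in log10 intensity x, centred 1.5 SD
below the base mean (`mnar_strength` = 3 by default; 0 disables the MNAR
component). Defaults give overall missingness in the single-digit-percent
range concentrated at low intensities, as in typical LFQ data. The default
study size is 2,000 proteins with 2 conditions x 6 replicates, 20 chaperome
members, 200 terms sized 10-100, enrichment fraction 0.8 and at least 8
wired differential interactors per planted link — the scale at which the
planted-recovery tests operate.

`simulate_ppi_sources` samples hub edges (each member to `hub_degree` = 100
uniform partners — chaperome hubs are high-degree, as chaperones are in
real interaction databases), wires each planted link's member to
`min_planted_dc_interactors` = 8 differential proteins of the planted
direction (kept disjoint across members where the pool allows, so planted
enrichment stays specific to its member), and adds
`background_edges_per_protein` = 2 random edges per protein. Records are
split between a BioGrid-tab and a MITAB file (45% / 45% / 10% both), and
decoy records carrying filterable annotations or non-human taxids are mixed
in at configurable fractions; the physical human-human subset equals the
returned true edge set exactly, which is what the filter-conservation tests
check.

`simulate_annotations` draws each planted term's enriched portion
(enrichment fraction x term size, capped by availability) from the planted
member's wired differential interactors and fills the rest, and all
non-planted terms, uniformly from the universe.

What the generator does **not** emulate: peptide-level quantification,
shared/razor peptides, batch effects, correlated protein modules,
annotation-term overlap structure (terms are sampled independently), or the
true missingness mechanism of any particular deposited dataset. Passing
tests therefore demonstrate correctness of the statistical machinery and
end-to-end plumbing under a clean generative model, not performance on real
epichaperomics data.

## Numerical conventions and determinism

Fisher p-values use `scipy.stats.hypergeom.sf(k-1, N, K, n)`, cross-checked
in the tests against an exact integer tail-sum oracle for every table with
N <= 60 at 1e-12. BH uses the statsmodels step-up implementation behind
`bh_adjust`, cross-checked against a literal step-up reference. The t-test
uses `scipy.stats.ttest_ind`, cross-checked against the closed-form
incomplete-beta tail. All tabular outputs are sorted on their primary key,
all randomness flows through `numpy.random.default_rng` seeded from the
config, and two runs with identical config and seed produce byte-identical
artifacts including the manifest (which records versions, thresholds and
SHA-256 input digests, and so fully determines a run).

## Known limitations

* **Quantile normalization mildly distorts null p-values.** With a finite
  number of replicate columns, each condition's reference distribution
  carries order-statistic noise that is shared across proteins at nearby
  ranks; the between-condition component of that noise is invisible to the
  within-protein variance estimate, making raw DC p-values slightly
  anti-conservative after normalization. The null-calibration tests
  therefore feed the DC test its contract input (complete log10 null data),
  which isolates the testing chain; users interpreting DC.p near a
  threshold on heavily normalized data should expect this mild inflation.
  The DC stage is in any case a permissive screen (p <= 0.1) feeding an
  adjusted enrichment stage, not a calibrated discovery procedure.
* Group-minimum imputation reduces within-group variance for proteins with
  many missing cells, which can overstate significance for
  mostly-imputed proteins — shared with the upstream convention it
  implements; rows entirely imputed in both conditions come out degenerate
  and are flagged.
* Annotations are used as flat sets; no ontology-graph propagation
  (ancestor closure) is performed.
* Fisher strata are adjusted independently per (member, direction);
  `global_adjust=True` exists for sensitivity analysis but changes the
  meaning of the map threshold.
* The BioGrid/MITAB parsers cover the tab dialects defined here, not every
  historical variant of those formats.

## Problem sizes used by the shipped checks

The test suite and acceptance script run entirely on generated data: the
planted-recovery check uses ten to twenty studies at the default scale
(2,000 proteins x 12 samples); null calibration uses 1,000-protein studies
with 2 x 6 replicates; preprocessing invariants sweep one hundred 60-protein
matrices; the exhaustive Fisher sweep covers every contingency table with
N <= 60. These sizes keep the whole suite under a minute of compute while
exercising every stage at the scale the statistics are designed for.
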