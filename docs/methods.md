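# Methods

## The inference chain

The package operationalizes a multi-evidence gene-prioritization
procedure for clinical CNV cohorts. Its premise is that a gene spanned
by a pathogenic CNV matters for a behavioral phenotype when several
independent lines of evidence converge: membership in an
over-represented pathway, a high-confidence protein interaction with
another candidate, strong co-expression with another candidate, and
peak expression in a developmentally relevant brain region that belongs
to a neural circuit plausibly serving the behavior. Each line of
evidence is a filter; the procedure is deliberately conjunctive, so the
candidate list can only shrink from stage to stage.

Statistical machinery, by stage:

* **Over-representation.** One-sided hypergeometric upper tail
  `P(X ≥ k)` with background `N`, pathway size `K`, query size `n`,
  overlap `k`, evaluated through `scipy.stats.hypergeom.sf` (log-space
  internally, stable at genome scale; the test suite checks it against
  exact integer pmf enumeration to ≤ 1e-12 on the full grid N ≤ 60).
  Query genes outside the background are dropped with a logged count,
  mirroring how web enrichment tools treat unrecognised identifiers.
  Significance is `p ≤ α` inclusive, α = 0.001 by default, no
  multiple-testing correction by default; Benjamini–Hochberg FDR is an
  explicit opt-in because some published passes of this procedure used
  FDR < 0.05 instead. Only enrichment (not depletion) is tested.
* **PPI filter.** A gene is retained iff it has ≥ 1 edge with
  confidence ≥ 0.9 (inclusive — 0.9 is the conventional
  "highest-confidence" tier, and STRING-style 0–1000 integer scores are
  divided by 1000 on input) to another gene of the *current* set. The
  induced-subgraph reading is the only one under which the filter
  shrinks the set the way the count trail of such analyses shows;
  retention against the whole network would keep almost everything.
* **Co-expression filter.** Same induced rule with |Pearson r|
  strictly > 0.7, sign-agnostic (strong anti-correlation counts),
  computed across *all* samples of the expression bundle — the
  co-expression evidence precedes and is independent of the later
  regional mapping. Zero-variance or absent genes are dropped with a
  logged count rather than propagating undefined correlations.
* **Developmental mapping.** For each gene, the mean expression of
  every populated (region, epoch) cell is computed and the argmax cell
  reported. Epoch boundaries are the standard obstetric trimesters at
  13 / 26 / 38 post-conceptional weeks (inclusive on the left epoch);
  any postnatal-days age, or a pcw beyond 38, is postnatal. The
  postnatal epoch competes in the argmax, so a postnatally peaking gene
  genuinely receives no antenatal site. Cells with no samples are never
  candidates. Ties break toward the earlier epoch, then the
  lexicographically smaller region code — deterministic and biased
  toward the antenatal emphasis of the procedure.
* **Circuit assignment.** A gene joins every circuit whose region set
  contains its argmax region; multi-membership is expected (a striatal
  gene joins Positive Valence, Cognitive and Social Processes at once).
  The default five-system map seeds Positive Valence
  {MPFC, ACC, Amy, STR}, Cognitive {ACC, Ocx, DLPFC, MD, A1C, IPC, STR,
  V1C, VLPFC} and Social Processes {IPC, ACC, Ocx, ITC, V1C, A1C, STR}
  from published circuit/region tables; Negative Valence
  {MPFC, ACC, Amy} and Sensorimotor {MD, IPC} have no published region
  list in that source and are package conventions, chosen once from the
  RDoC construct descriptions and overridable via a YAML circuit map.
* **Group comparison.** Group 1 = all normal-microarray subjects;
  Group 2 = CNV subjects whose CNVs overlap ≥ 1 circuit gene (union
  across a subject's CNVs; CNV subjects with no circuit gene sit out).
  Two-sided Welch *t*-test by default (Satterthwaite df); the pooled
  test is offered for parity with legacy statistics packages, and a
  Mann–Whitney option exists for strictly ordinal use, but Likert items
  are t-tested by default as clinical practice does. The scan emits one
  whole-cohort "inter-group" contrast per item plus one contrast per
  circuit with a non-empty gene list, raw p-values by default (circuit
  tables of this kind print unadjusted p), BH across the scan opt-in.
  `welch_from_summary` reproduces the identical contrast from printed
  (mean, SE, n) rows: t = (m₁−m₂)/√(se₁²+se₂²) with Satterthwaite df
  from the squared SEs.

Degenerate inputs are defined, not accidental: zero variance in both
groups with equal means gives t = 0, p = 1; with unequal means the p
underflow is guarded to the smallest positive double; an empty query
yields k = 0, p = 1 everywhere; items with < 2 scored subjects in
either group are skipped with a logged reason. All coordinates are
0-based half-open internally, with an explicit `one_based_inclusive`
dialect (start − 1 on read) for clinical-style tables; gene symbols are
case-preserved but compared case-insensitively, because microarray
reports mix cases. Any CNV/gene overlap ≥ 1 bp counts by default —
the most inclusive reading of "genes present in the affected locus" —
and deletions and duplications are treated identically at this stage.

## The synthetic study

`SimulationDesign` fixes the study conditions; its defaults are the
conditions the package is calibrated under, not tuning knobs.

| parameter | default | meaning / rationale |
|---|---|---|
| `n_normal`, `n_cnv` | 47, 90 | group sizes of the motivating clinical cohort |
| `vineland_n` | (30, 87) | Vineland interviews obtained per group, as in that cohort |
| `n_genes`, `n_pathways` | 400, 25 | desk-scale universe; pathway sizes 8–25 with sharing |
| `causal_pathway_size` | 20 | the planted causal module |
| `ppi_within_confidence` | 0.95 (sd 0.02) | causal clique sits above the 0.9 filter |
| `ppi_background_confidence` | 0.40 (sd 0.15) | realistic low-evidence background edges |
| `coexpr_latent_loading` | 2.0 (noise sd 1) | implied pairwise r = 4/5 = 0.8, above the 0.7 filter |
| `expression_peak_gain` | +8 | planted argmax margin over ~1.1-sd cell-mean noise |
| `samples_per_cell` | 4 | 12 regions × 4 epochs × 4 = 192 expression samples |
| `carrier_fraction` | 0.5 | share of CNV subjects carrying a causal gene |
| `effect_size_sd` | 1.0 | carriers' shift on the target item, in pooled SDs |
| `target_*` | Positive Valence / STR / trimester1 / PCQ3 | where the structure is planted |

Generation details. Genes sit non-overlapping on synthetic chromosomes
(10 kb genes, 20 kb spacing, 50 per chromosome). Carrier CNVs cover one
causal gene plus 0–5 neighbouring bystanders; causal genes are dealt to
carriers round-robin so every causal gene is covered whenever carriers
outnumber causal genes (a uniform draw would miss ~2 genes per study at
these sizes and make full recovery impossible by construction rather
than by inference). Non-carrier CNVs are placed over non-causal genes
and never extend across a causal one. Expression is homoscedastic
Gaussian on the linear scale around a per-gene baseline (≈ N(50, 5)),
truncated at 0; non-causal genes get independent per-cell profiles
(sd 2) so their argmax cell is arbitrary, while causal genes share one
latent factor per sample plus the planted peak. PCQ items are
latent-normal (mean 2.5, sd 1) rounded and clipped to the 1–5 Likert
range; Vineland subscales are kept continuous at N(75, 10), a plausible
standard-score regime, so the test stage exercises both ordinal and
continuous branches. All randomness flows from one seed through named
substreams; identical designs produce byte-identical files.

What the generator does *not* emulate — and what passing tests
therefore do not show about real data: real genome coordinates and
linkage, real pathway topology and annotation bias, assortative or
scale-free interaction networks, donor sparsity and age gradients of
real developmental atlases, item-level measurement structure of real
questionnaires, covariates, or epistasis. The simulations establish
that the machinery is correct and calibrated under its stated model,
not that the biological conclusions of any particular cohort transfer.

## Operating characteristics and problem sizes

With the default design the package verifies, in its test suite and
acceptance script: type-I error of the association scan 0.05 ± 0.01 at
α = 0.05 (2000 replicate cohorts over a fixed universe); detection of
the planted (circuit, item) effect in ≥ 90% of 200 independent studies
at δ = 1 SD with half the CNV group carrying; full survival of the
causal gene set to circuit assignment in ≥ 95% of those studies; power
monotone in δ over {0, 0.3, 0.6, 1.0}; and exact agreement of every
combinatorial operation (interval overlap, PPI retention, co-expression
retention, argmax site, circuit membership) with brute-force oracles on
≥ 1000 randomized instances. These replicate counts are the package's
chosen verification sizes: large enough that the Monte-Carlo error of
each rate is well inside the asserted band, small enough to run
routinely.

## Known limitations

* The induced-subgraph reading of both evidence filters, and the
  whole-bundle (rather than per-region) co-expression, are documented
  interpretations of an underspecified published procedure; both are
  flagged as design choices rather than derived facts.
* Whether published "maximal expression" lookups used donor-level
  maxima or region-epoch means is unstated; means are used here.
* Subjects sharing a circuit through *different* genes are pooled by
  union into one Group 2 — the implied but never stated convention.
* Likert scores are t-tested by default; with very small carrier groups
  the Mann–Whitney option is the safer choice.
* No dosage modeling (deletion vs duplication), no CNV pathogenicity
  classification, no liftover between genome builds, no covariate
  adjustment or mixed models.
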