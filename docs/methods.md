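# Methods

This note records the model implemented by the package, every tunable that
matters, the design decisions taken where more than one reading was
defensible, what the synthetic test bed does and does not emulate, and the
numerical conventions.

## Scoring model

A pathway is a directed signed graph of *gene units* — individual genes,
native multi-gene nodes, or collapsed coexpression modules.  For one case
sample, pathway *p* scores

    iPANDA_p = ( Σ_i G_ip + Σ_j M_jp ) / N_p^eff
    G_ip = A_ip · w_i^S · w_ip^T · log2 fc_i
    M_jp = A_jp · w_jp^S · w_jp^T · mean_{g∈j} log2 fc_g

Assumptions: expression intensities are approximately log-normal, so fold
changes are taken in log2 against the mean of the normal group's log2 values
(their geometric mean); gene effects combine additively on that scale; a
unit's direction of influence on the pathway is a fixed sign `A`.

### Statistical weight

`w^S(p) = 1` for p ≤ p_min, `0` for p ≥ p_max, and
`½(1 + cos(π (ln p − ln p_min)/(ln p_max − ln p_min)))` between, with
defaults p_min = 10⁻⁷ and p_max = 10⁻¹.  The p-value is a two-sided Welch
t-test of case vs normal samples, computed per dataset independently; a
dataset's weights never depend on any other dataset.  The smooth ramp keeps
pathway scores continuous in the evidence: a gene drifting across an
arbitrary cutoff changes its contribution gradually, which is what makes
scores reproducible between cohorts.  Welch rather than Student is the
default because group sizes and variances are routinely unequal; the choice
is configuration-exposed, as is the log base (base 2 throughout; scores
scale linearly with the base, so this is a convention, not a model choice).

### Topological weight

All simple (node-repetition-free) walks from every zero-in-degree unit to
every zero-out-degree unit are counted; `w^T` is the unit's walk count over
the pathway maximum.  Loops are forbidden by the visited-set rule: a unit
appears at most once per walk.  On acyclic graphs the count is a two-pass
dynamic program (walks into × walks out of each unit), which is exact and
fast; graphs with cycles fall back to depth-first enumeration.  Both paths
are guarded by `max_walks` (default 10⁶) because simple-path counting is
exponential in the worst case; exceeding the budget raises a complexity
error suggesting module collapse.  An isolated unit is both source and sink
and lies on exactly one walk (itself), so topology-free gene sets (GMT
input) score with uniform unit weights.  If a pathway has no complete walk
at all (every node on a cycle), all weights fall back to 1 with a warning.

### Modules

Module construction from a coexpression matrix: distance
`d = sqrt(2 (1 − corr))` (the Euclidean distance between standardized
profiles); DBSCAN (eps 1.0, min_samples 3) and average-linkage hierarchical
clustering (cut at distance 1.0, i.e. correlation 0.5) run on the same
distance matrix and their outputs are pooled; clusters keep only a mean
internal pairwise correlation strictly above 0.3; overlapping clusters
(and transcription-factor target sets, ingested as ready-made gene sets
intersected with the pathway universe) are merged to a fixpoint whenever
their intersection level exceeds 0.7.  "Intersection level" is Jaccard
(|A∩B|/|A∪B|) by default with |A∩B|/min(|A|,|B|) as an option; the final
set is made disjoint by assigning a contested gene to the module with the
higher mean internal correlation (ties: larger module, then lexicographic
id), because the scoring equation partitions genes into module members and
non-members.  The clustering defaults recover planted correlation blocks of
sizes 3–20 at ρ_in = 0.8 exactly, and are all configuration-exposed.

Within each pathway, nodes whose genes share a module are contracted into
one unit that inherits the union of member genes and incident edges;
self-edges are dropped.  The contracted unit takes the majority sign of its
nodes; an exact sign tie splits the module into per-sign sub-units, since a
unit must carry a single `A`.

**Module statistical weight.**  A module is "one collective variable": its
`w^S` comes from a Welch t-test on the members' *averaged* log2 profile, and
its fold change is the members' mean log2 fold change.  This is the load-
bearing choice for why modules help at all.  The alternative reading —
averaging the members' individually weighted fold changes — turns out to be
exactly score-neutral for coexpressed genes in parallel graph positions
(that invariance is deliberate and tested: collapsing parallel equal genes
must not change the score), so under that form a module ablation cannot
change results.  The collective t-test, by contrast, pools member evidence:
private per-gene noise averages down by 1/k, so a coherently responding
battery whose individual members straddle the significance ramp keeps a
high, stable weight.  The per-member form remains available as
`ScoringConfig(module_weight="member")`.

### Size normalization

The unit sum is divided by the number of contributing member genes (genes of
the pathway present in the data), on by default.  Dividing by gene count —
not unit count — is what preserves the exchangeability invariant: a
coexpressed pair entering as two parallel genes or as one collapsed module
yields the identical score.  It also makes pathways of different sizes
directly comparable (a uniform response of δ scores δ regardless of pathway
size).  The raw sum is available with `size_normalize=False`; worked
examples in the tests pin both conventions.

### Significance

`X = −2 Σ w_i ln p_i` over units with non-zero weight, `w_i = w_i^S·w_ip^T`,
referred to a Gamma(shape = Σ w_i, scale = 2) upper tail.  With all weights
1 this is exactly Fisher's χ² with 2N degrees of freedom (tested to 1e-10).
If every weight is zero the test is uninformative and returns 1 with a
warning.  Because the weights are functions of the same p-values being
combined, the statistic is anticonservative under the null; it is a
credibility ranking for pathway calls, not a calibrated hypothesis test, and
is not used by the marker ranking.  Multi-gene units contribute the
collective-variable p-value (or, in member mode, the members' unweighted
Fisher combination).

### Z-normalization

Scores are optionally Z-scored per dataset and pathway: centered on the
balanced expectation (the mean of per-phenotype means when responder /
non-responder labels exist, so a cohort's responder fraction does not shift
the center; the plain mean otherwise) and scaled by the within-dataset
population (n-denominator) standard deviation.  Constant rows map to 0;
single-sample datasets are an error.

### Markers and the CMP index

Marker quality is rank-based (Mann–Whitney) AUC with half-credit for ties.
Because an inhibited pathway separates groups exactly as well as an
activated one, the ranking and the marker rule use the symmetric
max(AUC, 1 − AUC); the raw responder-oriented AUC is reported alongside.
Mean-AUC ties break toward the larger pathway, then the lexicographically
smaller id, so rankings are deterministic.  The robustness index over n
datasets is

    CMP = Σ_{i ∈ common} ln(N_i) · (1/n) Σ_j (AUC_ij − 0.5)

where a pathway is common when its AUC strictly exceeds the threshold
(default 0.75) in *every* dataset, and N_i is its gene count — ln(N_i)
boosts larger pathways, which are less likely to reach a high AUC by
chance.  CMP is zero exactly when the intersection is empty.  The exact
functional form assembles the quantities the method names (n, N_i, AUC_ij,
the random-classifier reference 0.5, the common-marker intersection) in the
simplest way satisfying that zero property, and is documented here as the
package's interpretation.

## Synthetic test bed

The generators produce structurally faithful stand-ins for curated pathway
maps, coexpression databases and case/control microarray series.  All
randomness flows from one integer seed; identical configurations produce
byte-identical files.

* **Pathway graphs** — layered random DAGs (default 4 layers), one gene per
  node, edges only forward (occasionally skipping a layer), ~10% inhibitor
  nodes, pathway sizes 8–25 by default.  Layering guarantees sources and
  sinks and keeps walk counting tractable; an `allow_cycles` flag injects a
  back-edge to exercise the cyclic counting branch.
* **Expression** — log2 intensities: per-gene baseline ~ N(7, 1), unit
  biological spread, coexpressed blocks simulated with a shared driver
  (ρ_in = 0.7 by default).  Blocks are drawn from same-sign genes at the
  same graph depth: a co-regulated battery responds in one direction and
  sits at one level of the cascade.  Planted pathways add the configured
  log2 effect to case samples (responders only, in the phenotype design),
  sign-consistent with each node.
* **Dual platforms** — the same biological matrix plus per-platform
  gene-wise offsets (probe-affinity analogue) and independent Gaussian
  noise; offsets cancel in fold changes, per-sample noise does not.
* **Coexpression matrix** — the nominal block structure with mild
  estimation noise, standing in for a large external compendium.  Its
  correlations are deliberately the *long-run* ones: within one cohort the
  realized correlation of a battery can be much weaker when its shared
  driver is quiet there (`block_driver_scale` < 1), which is exactly the
  situation in which collective module statistics outperform per-gene
  statistics.

The robustness (CMP ablation) study conditions additionally model the two
data features that motivate each weighting, and they are worth stating
because they carry the result:

* **Private regulation of battery members** (`block_gene_noise_sd`): each
  co-regulated gene also answers to its own inputs, so per-gene tests are
  underpowered while the battery's collective variable is clean.  Module
  grouping rescues that signal; treating genes individually loses it.
* **Peripheral bystanders** (`bystander_fraction`, `bystander_shift`,
  `bystander_sd`): pathway maps include genes shared with broad disease
  processes — strongly case-vs-normal regulated, heterogeneous between
  tumours, and irrelevant to the phenotype under study.  Their t-test
  p-values are tiny, so the statistical weight embraces them; only their
  walk-sparse position in the map lets the topological weight discount
  them.  They sit at the periphery by construction (lowest walk share), and
  they are never coexpressed with a battery.

Under these conditions (12 pathways of 15–24 genes, 5 planted at log2
effect 1.5, 4 cohorts of 60 cases / 20 normals, 50 replicates) the full
method's CMP exceeds both single-ablation variants in ≈96% of replicates,
with all three variants finding markers (the comparison is not a
ties-at-zero artefact).  Pilot exploration of these conditions used separate
seeds from the validation runs.

What the test bed does **not** emulate: probe-level physics, background
correction and normalization artifacts, batch effects beyond platform
offsets, gene-gene regulatory dynamics, annotation errors, or shared genes
between pathways (generated pathways are gene-disjoint, which makes planted
truth unambiguous).  Passing tests therefore demonstrate the algorithmic
properties of the method — not that real cohorts satisfy the generative
assumptions.

### Study problem sizes

The shipped studies are desk-scale by design: the dual-platform study uses
20 sample pairs at platform noise sd 1.0; the ablation study 50 replicates ×
4 cohorts; recovery 100 runs of 10 × 10-gene pathways.  These sizes give
stable Monte-Carlo estimates (validated across seeds) while keeping the full
suite and the acceptance script in tens of seconds.

## Numerical conventions and degenerate inputs

* p-values are floored at 1e-300 before logs; p ≤ 0 is a domain error.
* Genes with zero variance in both groups: p = p_min when the means differ
  (an unambiguous change keeps full weight), p = 1 when identical.
* Linear-scale input with zeros gets a pseudo-count of half the smallest
  positive value before log2; negative linear intensities are an error.
* Duplicate gene rows collapse to the row with the highest mean intensity
  (count logged); genes missing a value in a group leave that group's test
  and fold change (logged).
* Genes in a pathway but absent from the data contribute 0; a pathway with
  no measured gene scores 0 with a warning.
* Auto scale detection calls a matrix linear when any value exceeds 50.
* Walk-count fallback, Fisher all-zero-weight fallback, Z-score
  constant-row rule: see above.  All tie-breaks (module disjointness,
  marker ranking) are deterministic.

## Known limitations

* Simple-path counting on cyclic graphs is exponential; `max_walks` turns
  pathological graphs into an explicit error rather than a hang.  An
  SCC-contraction semantics would scale better but changes the counts; the
  strict simple-path reading was chosen and the alternative left out.
* The combined significance is anticonservative under the null (weights and
  p-values share data), as noted.
* Whether edge type (activation/inhibition) should influence unit signs is
  left to the pathway file: signs are taken as declared, and walk counting
  ignores edge signs by design (no SPIA-style perturbation propagation).
* The CMP functional form and the module-weight aggregation are documented
  interpretations; both have configuration switches or stated alternatives.
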