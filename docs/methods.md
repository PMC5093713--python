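# Methods

## Setting

Protein N-glycosylation occurs on asparagine within the sequon
N-X-[S/T/C] with X any residue except proline. In a label-free LC-MS
glycoproteomics experiment, each enriched glycopeptide yields a site-level
intensity per run; comparing those intensities across cell lines, after
appropriate filtering and normalization, identifies sites whose
glycosylation differs between conditions. The package analyses a panel of
cell lines in three biological groups — hiPSC, hESC, and the parental
somatic cells (SC) the hiPSCs were reprogrammed from — with three
replicate runs per line (nine lines in the default design: five hiPSC,
two hESC, two SC; hiPSC-vs-hESC gives 10 pairwise comparisons, and lines
vs relevant SCs another 9, for a 19-comparison plan).

## Identification filtering

Rows flagged as contaminants (`CON__`) or reverse decoys (`REV__`) are
removed. Two localization gates follow, both inclusive: site-localization
score ≥ 50, and localization probability ≥ 0.8 in ≥ 2 replicate runs.
The replicate requirement is evaluated **within each cell line** (a site
passing in any one line is retained globally); an across-all-runs mode is
available (`per_line=False`) because the convention is genuinely
ambiguous in the field. Finally a site is kept only if its reported
position is a true sequon of its protein sequence in the supplied FASTA;
sites on proteins absent from the database are excluded and listed, never
silently dropped. Sequon scanning is a literal triple scan: position i
(1-based) matches iff residue i is N, residue i+1 is one of the 19
non-proline amino acids (unknown letters never match), and residue i+2 is
S, T or C; overlapping sequons all count and nothing wraps past the
C-terminus.

## Quality control

Correlations are Pearson r on **log2** intensities over features
co-observed in both runs (≥ 3 shared features required, otherwise the
value is reported as undefined rather than fabricated). The CV is
computed on the **linear** scale as sample (n−1) standard deviation over
mean of a line's replicates, defined only where ≥ 2 replicates are
present — this is the scale on which a "CV ≤ 20%" gate is conventionally
stated. Cell-line clustering uses average linkage on 1 − r between
line-mean log2 profiles; lines are ordered lexicographically before
linkage so the tree is independent of input order.

## Quantitation

Mean normalization rescales each run by a single multiplicative factor so
every run's mean over non-missing features equals the grand mean of run
means; within-run ratios are untouched and missing values stay missing.
For a comparison of lines a and b, a site is *comparable* iff it has ≥ 2
non-missing replicates and CV ≤ the threshold in **both** lines (the
stricter, reproducibility-oriented reading of a one-sided phrase) and its
peptide carries no variable-modification (oxidation/acetylation) flag,
since such modifications shift peptide intensity for reasons unrelated to
glycosylation. Fold change is the ratio of normalized replicate means
(not the mean of ratios); calls are inclusive: fold ≥ 2 is up, fold ≤ 1/2
is down. Sites detected in only one line are "not comparable" rather than
infinite fold changes — the comparable universe is reported per
comparison. Protein categories: up (≥ 1 up site, no down), down
(symmetric), both (≥ 1 of each), unchanged. The voting rule marks a site
a *general* alteration when it is called in one consistent direction in
≥ k = 5 of the 10 hiPSC-vs-hESC comparisons with zero opposite-direction
calls; consistency prevents a site from being simultaneously a general up-
and down-alteration and can be switched off.

## Calibration

A glyco fold change can reflect protein abundance rather than
glycosylation. Calibration divides the site's glyco fold by the protein's
fold change from a matched proteome (equivalently, subtracts log2 folds);
division in linear space is the minimal operation consistent with
"fold changes before and after calibration". Classification is on the
magnitude of the calibrated log2 fold: ≥ log2(2) → retained; in
[log2(1.75), log2(2)) → retained with an explicit `near_threshold` flag
(the band is kept visible rather than silently lowering the threshold);
below → explained by protein. Proteins absent from the proteome are
`unmatched` and keep their uncalibrated fold. Proteins with several glyco
sites are calibrated per site and summarized per protein (retained if any
site is retained). The summary reports retained% = 100 × retained /
matched, undefined (flagged) when nothing matched.

## Network significance

Candidates (gene symbols of retained altered glycoproteins) are joined to
the PluriNet seed list through a confidence-scored undirected edge list;
only edges with confidence ≥ 0.7 count (inclusive), self-loops are
dropped and duplicate edges keep the highest confidence. A candidate
enters the subnetwork only with ≥ 1 direct retained edge to a PluriNet
node; the subnetwork is the induced subgraph on kept candidates plus the
PluriNet nodes they touch. Metrics: mean local clustering coefficient
(degree < 2 contributes 0) and mean shortest-path length over pairs in
the largest connected component (ties between equal-sized components break
to the one containing the lexicographically smallest node). The null
model is degree-preserving randomization by double-edge swaps, 10 × |E|
attempted swaps per draw (a standard mixing heuristic, configurable),
rejecting self-loops and multi-edges; the degree sequence is asserted on
every draw. Empirical p-values use add-one smoothing,
p = (b + 1)/(n + 1) with b the number of null draws at least as extreme
(≥ observed for clustering, ≤ observed for mean path), so p is never 0
and never below 1/(n + 1). Candidate–PluriNet association is a one-sided
Fisher's exact test on the 2×2 table crossing candidate membership with
"has ≥ 1 high-confidence direct PluriNet interaction" over the gene
universe of the interaction database; PluriNet members themselves are
excluded from the universe rows to avoid trivial self-interaction (the
exact margins of such a test are a genuine design choice; this one is
exposed in the API rather than hidden). Pathway enrichment is the
hypergeometric upper tail per GMT set with Benjamini–Hochberg correction
across sets.

## Reprogramming states

Probes in the bottom 20%-quantile of **every** sample are removed (the
cut is each sample's own quantile; membership must hold in all samples).
Redundant probes per gene collapse to the probe with the highest total
intensity across samples, ties broken by lexicographic probe id.
Significance of the hiPSC-vs-hESC difference is a two-sided Welch
(unequal-variance) t-test on log2 expression, pooling all replicates of
all lines of each type (per-line testing is exposed via the group
arguments); genes with zero variance in both groups get t = 0, p = 1 when
means agree. A significant gene (default α = 0.05) is classified by the
strict inequality pattern of its (hiPSC, hESC, SC) log2 group means into
the four imperfect-reprogramming states; any equality, or
non-significance, yields `unchanged`. The four states exactly partition
the strict-sign space — an exhaustive nine-combination truth table is in
the test suite.

## Synthetic data

The generators plant known truths under the study conditions of the
design above.

* **Protein database**: random sequences over the 20-letter alphabet with
  residue frequencies tilted so sequons occur at a realistic density and
  threonine outnumbers serine (and cysteine is rare) at the sequon's third
  position; every sequon position is recorded in a truth table by
  exhaustive scan.
* **Glycosite intensities** are generated in log2 space: per-site baseline
  ~ N(23, 1.5) (a typical Orbitrap intensity scale), replicate noise
  ~ N(0, cv/ln 2) so the linear-scale CV approximates the configured
  `replicate_cv` (default 0.10 — the mostly-≤ 20% regime of a well-behaved
  label-free run), exported linear. Planted hiPSC-vs-hESC alterations of
  log2(2.5) (default) are applied to 17% of plantable sites (the typical
  altered fraction between the pluripotent groups), and an independent
  43% receive an SC-group shift (the much larger PSC-vs-SC divergence,
  which also drives the two-cluster panel structure). Missingness is
  missing-at-random per run cell (default 5%; real MS missingness is
  partly intensity-dependent — see limitations). Decoy rows (default 5%)
  take `REV__`/`CON__` prefixes; variable-modification flags (5%) and
  localization failures (10%, by score or by probability) are planted so
  the filters have work to do, and alterations are planted only on clean
  rows so truth remains recoverable.
* **Proteome**: ~74% of altered glycoproteins appear in the matched
  proteome table, of which ~9% carry a protein-level change equal to their
  glyco change (planted explained-by-protein cases); all other proteins
  are flat. These two defaults mirror the coverage and explained rate a
  matched proteome typically shows in this setting.
* **Expression**: planted genes receive group means satisfying their
  state's inequality pattern with margin 1 log2 unit and replicate noise
  sd 0.2 (two biological replicates per line — the replication level such
  array data usually has); 10% of genes get a redundant lower-intensity
  probe and a 10% low-intensity probe stratum exercises the filter.
* **Network**: exactly the requested number of candidate–PluriNet edges
  above the confidence threshold (round-robin over candidates); the
  PluriNet seed set is tiled with 5-cliques (protein complexes) plus
  sparse cross-links so its clustering exceeds degree-null expectation;
  random background edges never join candidates to PluriNet nodes, keeping
  the planted link count exact.

All generators are pure functions of their arguments and seed; identical
calls give byte-identical outputs.

### What passing on synthetic data does and does not show

The generator reproduces the *statistical skeleton* the analysis assumes
(log-normal intensities, replicate CV structure, MAR missingness, known
effect sizes and their carriers). It does not emulate intensity-dependent
missingness, shared-peptide ambiguity, retention-time drift, glycan
micro-heterogeneity, batch effects, or correlated noise between sites of
one protein. Recovery rates on synthetic data therefore certify the
pipeline's logic and thresholds, not its performance on any real dataset.

## Orchestration and determinism

A single master seed derives one sub-seed per stage through a seed
sequence (all < 2^31), so a stage re-run alone reproduces its part of a
full run. Every output is plain text (TSV/FASTA/Newick/JSON) written with
fixed float formatting; `report.json` carries SHA-256 checksums of all
outputs, and two runs with the same configuration agree checksum for
checksum. The shipped default problem sizes (150 proteins, 19
comparisons, 1,000 randomized networks, 300 expression genes) complete in
a few seconds on one CPU; the evaluation benchmarks use 20 generator
seeds and ~100 proteins per seed, which keeps the Monte-Carlo estimates
stable at two decimal places while the whole suite stays fast.

## Known limitations

* Fold changes use all non-missing replicates; replicates are never
  excluded retroactively by the CV gate.
* The calibration divides point estimates; no uncertainty is propagated
  into the retained/explained classification, so sites near the
  threshold are sensitive to noise (hence the explicit near-threshold
  band).
* The Fisher-test universe and margins are one defensible construction
  among several; both the universe and the interacting-set definition are
  explicit function arguments.
* No multiple-testing correction is applied across genes in the
  reprogramming stage (per-gene significance tiers are the convention the
  stage follows; BH-corrected enrichment is available in the network
  stage).
* The localization-probability replicate rule is evaluated per cell line
  by default; datasets with different run naming need the design's run
  metadata rather than name parsing.
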