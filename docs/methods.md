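# Methods

This note documents the statistical models, the tunable parameters and
their defaults, the synthetic-data design, and the numerical choices made
where the design was genuinely open.

## Two-group differential expression (`diffexpr`)

Each dataset is a log2-scale gene × sample matrix with every sample
labelled `control` or `treated`. The default test is a moderated t-test:
per-gene residual variances $s_g^2$ (pooled within groups, $d_g = n_1 +
n_2 - 2$ df) are assumed exchangeable draws from a scaled
inverse-chi-square prior with scale $s_0^2$ and $d_0$ df. The prior is
fitted by moment matching on the log scale: with $z_g = \log s_g^2$, the
statistic $e_g = z_g - \psi(d_g/2) + \log(d_g/2)$ has mean
$\log s_0^2 + \psi(d_0/2) - \log(d_0/2)$ and excess variance
$\psi'(d_0/2)$ beyond the $\psi'(d_g/2)$ contributed by estimation noise
($\psi$, $\psi'$: digamma/trigamma). The trigamma equation is inverted by
Newton iteration with a bisection safeguard (tolerance 1e-8); $d_0$
estimates above 1e6 — or an excess variance ≤ 0 — are treated as an
infinite-df prior, in which case every gene receives $\tilde s_g^2 =
s_0^2$ and the statistic is referred to a normal distribution. With a
single gene no prior can be fitted and the statistic reduces to the
ordinary pooled-variance t. Genes with zero within-group variance are
handled by the shrinkage itself ($\tilde s_g^2 > 0$ whenever $s_0^2 >
0$). A Welch test (Satterthwaite df) is available as an unmoderated
fallback; the fold-change filter used for proteome-style comparisons
applies strict `after/before > fold` (default 2) inequalities, with
one-side-only detections assigned to the side where they were detected.

No variance or intensity pre-filters are applied before testing.

## Meta-analysis (`meta_analysis`)

Per-gene p-values are combined with the Wilkinson order statistic
(`wilkinson_r`, default **r = 1**, the common default equivalent to
Tippett's minimum-p; the choice of r is exposed because nothing in the
analysis pins it down). BH-FDR is applied **after** combination, over the
family of aggregated genes. A gene must by default be present in all
datasets (`min_datasets` relaxes this; a gene present in only k studies is
combined with order statistic min(r, k)). The consistency call is
`up`/`down` only when *every* per-dataset direction agrees; an exact-tie
direction (`zero`) breaks consistency. An optional `per_dataset_alpha`
requires each per-study p-value to pass a cutoff before aggregation —
off by default, since applying the 0.05 cutoff per-study versus on the
combined value are both defensible readings and the flag keeps the choice
explicit. Between-platform heterogeneity is intentionally ignored (no
random-effects machinery): the combination uses p-values and directions
only.

## Splicing recurrence (`splicing`)

Input tables are one file per event type in the junction-count caller's
dialect (0-based, half-open coordinates; per-replicate inclusion levels
comma-separated; `IncLevelDifference` = sample1 − sample2). The
orientation flag declares which condition "sample 1" holds, and inclusion
differences are re-signed so positive always means higher inclusion after
treatment. Significance filtering keeps events with `FDR < 0.05` **and**
`|ΔIncLevel| > 0.05` (both strict; ΔIncLevel is a proportion on [0, 1],
so 0.05 is the 5-percentage-point threshold). Event identity is the full
coordinate tuple of the type's defining columns plus the **sign** of the
inclusion change; the gene symbol is not part of the key (coordinates
suffice and are robust to annotation drift), and zero-difference events
carry no key. Recurrence over n samples uses the threshold
`ceil(min_fraction · n)` — "at least half" of 17 samples means 9 — and
each key counts at most once per sample. What a "sample" is (cell line
vs. cell line × drug) is left to how the caller groups its inputs.

## Retained-intron stop scan (`intron_orf`)

Given the retained-form mRNA, the CDS start and the intron interval
(0-based, half-open, intron strictly downstream of the CDS start), codons
are walked in the single annotated frame from `cds_start`. A codon counts
as an intron stop iff it is TAA/TAG/TGA and overlaps the intron by ≥ 1
base: a stop straddling the exon–intron boundary exists only because of
the retention, so it is attributed to the intron. All overlapping
in-frame stops are tallied (the scan does not stop at the first), and the
first offset is reported. Only the annotated frame is scanned by default
— whether the transcript can encode its protein is a frame-specific
question — with an all-frames report available (`scan_all_frames`).
Lowercase and ambiguity codes are rejected rather than guessed.

## Time-course clustering (`timecluster`)

Trajectories (≥ 4 timepoints) are row z-scored (sample sd, n−1
denominator; constant rows map to zeros, never NaN) and clustered with
fuzzy c-means: memberships $u_{ic} = 1/\sum_j (d_{ic}/d_{jc})^{2/(m-1)}$,
centers $v_c = \sum_i u_{ic}^m x_i / \sum_i u_{ic}^m$, objective
$\sum u^m d^2$ with convergence at objective change < 1e-6 (max 500
iterations). A point coincident with a center receives membership 1 there
(the standard singularity rule). Defaults: fuzzifier **m = 2**; the
cluster count is either given or chosen by a minimum-centroid-distance
elbow sweep over candidate counts. Initialization draws c distinct data
rows with a seeded generator — reproducible and fast to converge on
z-scored profiles. Hard assignment for enrichment uses the argmax cluster
when its membership ≥ 0.5. Cluster trends are labelled
increasing/decreasing only when the center is strictly monotone across
all timepoints.

## Co-regulation network (`coreg_network`)

Spearman correlation is the Pearson correlation of average ranks (ties
get the mean rank), with a t-approximation p-value on n−2 df (exact
permutation p available for n ≤ 8; ρ = ±1 reports p = 0, and values
within 1e-12 of ±1 are snapped to ±1). Per dataset, all cross-set
(splicing gene, mitotic gene) pairs are tested; BH-FDR runs over that
dataset's full tested-pair family (per-dataset families mirror the
independent per-dataset identification of pairs), and a pair is retained
iff ρ > 0.7 and q < 0.05 (both strict). TF binding is called when a peak
interval overlaps the strand-agnostic promoter window
[TSS − 2000, TSS + 2000) by ≥ 1 bp — ±2 kb is a conventional ChIP-seq
promoter window, configurable. Per dataset, a TF qualifies if it binds
both members of ≥ 1 retained pair; the common set is the intersection
across all datasets. The gene sets and the TF binding map are explicit
user inputs (GMT / BED + TSS table): shipping fixed annotation lists
would freeze a database version.

## Set statistics (`setstats`)

Over-representation uses the hypergeometric upper tail with a
**mandatory, explicit universe** (measured genes for expression queries,
detected proteins for proteome queries): defaulting to "all genes"
silently inflates significance. Sets are intersected with the universe
before testing and BH runs over the collection. Fisher's overlap test is
the same hypergeometric tail for `greater`; `two-sided` sums all tables
no more probable than the observed one (the dominant convention — noted
because conventions differ). Large-N tails are computed in log space by
the scipy hypergeometric implementation; enumeration oracles exist only
in the test suite. The sample odds ratio (both·neither)/(a_only·b_only)
is reported, infinite when the denominator vanishes. Venn summaries
report exclusive-region counts for 2–3 sets with per-region annotation
subcounts; regions partition the union.

## Synthetic data (`synthetic_data`)

The generator's defaults encode the standard study conditions the
pipeline is tested at:

- **Expression multiset** — 3 datasets × 2000 genes × (3 control + 3
  treated); per-dataset baselines Normal(shift, 1) scaled by a lognormal
  platform factor (shift sd 0.5, scale sd 0.1); i.i.d. Gaussian noise of
  sd 1 on the log2 scale; one planted 100-gene "spliceosome" set shifted
  by −1 log2 units in every treated arm. Noise is Gaussian on the log2
  scale, matching the log-transformed microarray setting; heavier-tailed
  options are deferred.
- **Time course** — three templates (gradually decreasing, increasing,
  transient) over 4 timepoints (0/6/12/24 h), 60 genes each, noise sd
  0.3, z-scored.
- **Splicing tables** — 12 samples; 18 planted events (RI biased 6:2
  toward positive inclusion change, echoing the predominance of
  therapy-induced intron retention, plus SE/A5SS/A3SS/MXE) written into
  75% of samples with FDR < 0.05 and |ΔIncLevel| drawn Uniform(0.1, 0.5)
  — clear of the 0.05 filter boundary — and 40 background events per
  sample with random coordinates, half of them deliberately failing the
  significance filter.
- **Transcripts** — retained-form sequences composed of non-stop codons
  in the annotated frame, with the requested number of stops planted at
  in-frame offsets inside the intron, so truth counts are exact by
  construction.
- **TF fixture** — 3 datasets × 24 samples; 4 planted pairs per dataset
  sharing a per-sample latent factor (noise sd 0.1 → ρ ≈ 1), 6 null genes
  per set; 5 TFs planted with promoter peaks on both members of the
  planted pairs of the datasets they cover (3 covering all datasets, 2
  covering strict subsets). 24 samples per dataset gives the rank
  correlation enough resolution that the ρ > 0.7 / q < 0.05 retention
  rule cleanly separates planted from null pairs (the one-sided null tail
  of ρ > 0.7 is ≈ 7·10⁻⁵ at n = 24), which the exact-recovery tests
  require; real platinum-response expression sets are of this size or
  larger.

All generators are deterministic given the seed (sub-streams are derived
per generator), and every written file round-trips through the package's
readers. What the generators do **not** emulate: probe-level microarray
artifacts, correlated gene-gene backgrounds, read-level splicing noise,
batch effects, or annotation errors — passing the recovery tests
demonstrates the statistics and plumbing are correct under the assumed
model, not robustness to those real-data features.

## Pipeline and reproducibility (`cli`)

`run-all` executes the stages on a self-generated fixture with a single
seed; every stage writes plain-text TSV/JSON, and a manifest records the
tool version, the config snapshot, per-stage parameters/timings and
SHA-256 checksums of all outputs. Reruns with the same seed and config
are checksum-identical (the manifest's wall-clock timestamp is the only
non-deterministic field, which is why determinism is checked on the
output files and the manifest's checksum table). Config validation
failures exit with code 2 naming the offending field; stage failures exit
with code 1 naming the stage.

Raw vendor formats (CEL/IDAT), two-channel ratio construction, alignment
and splicing-caller execution, enrichment-database retrieval and plot
rendering are out of scope: the pipeline starts at numeric matrices,
caller output tables, FASTA + annotations, GMT, BED and TSS tables. The
bead-array detection filter survives only as an optional pre-filter that
drops rows whose supplied detection p exceeds 0.05 in every sample.

## Known limitations

- The meta-analysis is p-value-based; it estimates no pooled effect size
  and models no between-study heterogeneity (by design).
- Under weak effects (e.g. a 1-log2-unit shift with unit noise and 3 + 3
  samples per study), three studies provide limited power, and recall of
  a planted pathway at q < 0.05 with the consistency filter is
  correspondingly low; the worked example in the README uses a stronger
  planted effect to illustrate full recovery.
- The recurrence scan matches coordinates exactly; near-miss boundary
  wobble in real caller output would fragment keys.
- The stop scan assumes the annotated frame and intact sequence upstream
  of the intron; it does not model decay rules or translation
  reinitiation.
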