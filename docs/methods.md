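# Methods

This note documents the models and procedures implemented in
`splicedyn`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the design choices made where
the design was genuinely open.

## Differential splicing calls

PSI is kept on the 0–100 scale everywhere; z-scaling happens only
inside clustering, because the calling thresholds are defined on the
PSI scale. `psi_from_counts` computes PSI = 100·inc/(inc+skip) from
junction reads; a cell with fewer than `min_reads` (default 10) total
reads is flagged VLOW and a cell with none is missing. Missing or
low-quality cells make a comparison *not evaluable* — they never enter
a Δ computation as zeros.

A pairwise call (`call_diff`) requires |ΔPSI| ≥ `dpsi_min` (default
10, inclusive) between condition means **and** a replicate-range
criterion: every cross-condition replicate pair must differ by ≥
`range_min` (default 5) *in the direction of the mean change*. The
sign-consistent reading is the default because the alternative
(absolute gaps) would let an event pass on replicates that disagree in
direction; `sign_consistent=False` switches to absolute gaps. The
union over all condition pairs (`diff_union`) defines the set of
differentially spliced events; an event not evaluable in one pair can
still enter through another.

## Trajectory clustering

Profiles are z-scaled per row (sample standard deviation, ddof = 1);
zero-variance rows carry no shape and are dropped with a report.
Fuzzy c-means alternates the classical updates

    u_ic = 1 / Σ_j (‖x_i − v_c‖ / ‖x_i − v_j‖)^(2/(m−1))
    v_c  = Σ_i u_ic^m x_i / Σ_i u_ic^m

in Euclidean space until the maximal centroid shift drops below `tol`
(1e-6) or `max_iter` (500) is reached (the model is then returned with
a non-convergence flag). An item exactly at a centroid receives
membership 1 there. Initialization is k distinct data points drawn
from a seeded generator; the best of `n_restarts` runs by the
objective Σ u^m d² wins, ties broken toward the earlier restart, so
results are reproducible. The library default is 5 restarts; the
analysis and acceptance runs use 10 — fuzzy c-means is
initialization-sensitive and at unlucky seeds a 5-restart run can
merge two genuine clusters.

The fitting fuzzifier defaults to m = 1.25, in the range typically
estimated for time-course data, where it yields crisp partitions.

**k selection.** The number of clusters is chosen from the minimum
inter-centroid distance (Dmin) curve: once k exceeds the real
structure, new centroids split existing clusters and Dmin collapses.
The selected k is the largest one before the curve falls below a
configurable fraction (0.1) of its value at the smallest k. A
within-cluster-distance criterion is available as an alternative
(`criterion="within"`), since "distance to the cluster centroid" can
be read either way.

## Membership scoring and regulator inference

Arbitrary scaled profiles (RBP expression, host-gene expression) are
scored against the augmented prototype set {v₁..v_k, −v₁..−v_k}: one
normalized membership vector over 2k slots, so correlated and
anti-correlated profiles receive directly comparable scores. A
membership ≥ 0.3 (inclusive) to a centroid calls a positive regulator
of that cluster, to a negated centroid a negative regulator; one RBP
may be called for several clusters.

**Scoring fuzzifier.** Scoring uses the classical soft fuzzifier
m = 2 by default (`scoring_m`), independent of the crisper fuzzifier
the clusters were fit with. This is deliberate: the membership
exponent is 2/(m−1), so at m = 1.25 (exponent 8) the membership of
*any* profile — including pure noise — concentrates almost entirely on
its nearest prototype, and an absolute 0.3 cutoff stops
discriminating. At m = 2 an uncorrelated profile spreads its
membership near-uniformly (≈ 1/(2k) per slot, max rarely above 0.3),
while a profile tracking one centroid still concentrates well above
the cutoff. The formula is unchanged; only the exponent differs.

Candidate RBPs are first filtered for expression (cpm ≥ 5 in at least
⌈n/3⌉ samples, inclusive) and variation (CV = sd/mean ≥ 0.2 over all
samples). Host-gene concordance uses the same machinery: per cluster,
the fraction of host genes whose expression has membership ≥ 0.3 to
the cluster centroid (concordant) or its negative (contrasting), the
remainder counted as neither.

## Perturbation dependency

For a design with baseline b, control endpoint c and treatment
endpoints t_j, ΔΔPSI_j = (mean t_j − mean b) − (mean c − mean b) =
mean t_j − mean c; the baseline cancels algebraically but still gates
evaluability (all contributing cells must be quality-OK). An event is
**dependent** when |ΔΔ_j| ≥ 10 in *every* arm and on the arm average —
the conjunction of the two published readings of the two-shRNA rule,
with both sub-criteria reported. It is **independent** when it passes
the differential-splicing rule baseline→endpoint in the control or any
treatment arm ("any" is the default; a control-only reading is
exposed) and max_j |ΔΔ_j| < 2. Everything else, including
non-evaluable events, is unclassified; the three sets are disjoint by
construction.

Control exon sets ("alternative non-changing") are drawn uniformly
(seeded) from events with 10 < mean PSI < 90 in every condition and a
total shift ≤ 2 between any pair of conditions, minus exclusions. The
PSI-distribution shift test builds the 2×2 table of intermediate
(25 < PSI < 75) versus extreme events per condition and applies a
two-sided Fisher exact test.

APA dependency mirrors the AS logic on poly-A site usage: sites pass
an expression filter (transcript tpm ≥ 3 in ≥ 10 samples) and a
site-count filter (≥ 2 expressed sites per gene), then |ΔΔPAU| ≥ 10 in
every arm calls dependence; no independent class is defined.
AS–APA overlaps use half-open interval intersection (≥ 1 shared base;
adjacent intervals do not overlap) between event spans (largest
junction) and last-exon intervals, strand-agnostic by default.

## ORF impact

All coordinates are 0-based half-open; GTF input is converted on read,
and transcript exons are kept 5′→3′ in transcript orientation. The
annotated transcript defines the default state: an exon matching an
annotated exon has "skipping" as its altered isoform, an exon inside
an annotated intron has "inclusion" as its altered isoform; anything
that matches neither is uncertain. Location is resolved first (5′/3′
UTR by CDS bounds in transcript orientation, ncRNA for non-coding
hosts; an exon straddling a CDS boundary counts as ORF).

For ORF exons both isoform mRNAs are rebuilt from genomic sequence and
translated from the annotated CDS start. An exon length not divisible
by 3 is a frameshift for the altered isoform. Otherwise, a premature
stop introduced in the altered isoform disrupts when it lies more than
`nmd_rule_nt` (default 50, the standard NMD rule — the constant is
configurable since annotation pipelines differ) upstream of the last
exon–exon junction, or when it truncates the protein by more than
`truncation_aa` (300) residues; otherwise the exon is ORF-preserving.
The direction label (disrupt_on_inclusion/on_exclusion) names the
disrupted isoform. With several host transcripts, each votes and the
majority category wins; ties are uncertain.

## Sequence features and RNA maps

Per-event features: exon and flanking-intron lengths, GC of exon and
introns, and splice-site strengths for the canonical windows (5′ss:
3 exonic + 6 intronic nt; 3′ss: 20 intronic + 3 exonic nt). The
default site score is a first-order position-weight log-odds model
trained from a supplied constitutive-site set against a background
composition (uniform by default); externally trained maximum-entropy
score tables can be plugged in by constructing the model from their
frequencies, which keeps the package self-contained. Group comparisons
use the two-sided unpaired Mann–Whitney rank-sum test — the natural
reading of a "paired Mann-Whitney U" description, which is
self-contradictory as written (the U test is unpaired).

RNA maps operate on four uniform-length regions: exon first/last
50 nt, and flanking-intron 150-nt windows. Positions are labelled in
splice-site coordinates: exonic 1..50 and −50..−1; intronic −150..−1
counting toward a 3′ splice site. The downstream-intron window sits at
the intron's 3′ end (upstream of the *distal* 3′ss) — this is where
U-rich repressor motifs concentrate in the system this pipeline
models. Per position, the group statistic is the fraction of
sequences with ≥ 1 whole motif match inside the centered 31-nt window
(binary per-sequence hits, clipped at region boundaries). Motifs are
IUPAC strings supplied by the user, never hard-coded; matches may
overlap.

Significance per position comes from `n_perm` (1000) label exchanges
between the regulated and control groups, statistic |coverage
difference|, with the add-one estimator p = (1 + #{perm ≥ obs})/(n+1);
p is therefore ≥ 1/(n+1) and ties count against significance — a
slightly conservative, safe default. Significant segments are maximal
runs of positions with p ≤ 0.05.

**Calibration audits.** Two facts make a naive calibration check
invalid: adjacent positions share 30/31 of their window (near-total
correlation), and the coverage statistic is discrete, which makes the
add-one estimator conservative. The package therefore provides a
`randomized_p` option — tie mass broken uniformly at random — which is
exactly uniform under the exchangeable null, and the calibration
experiment (`experiments.rna_map_null_calibration`) evaluates it at
positions spaced one window apart across independent null replicates,
where trials are independent and the binomial reference interval
applies.

## Expression, PCA and pseudotime

cpm is plain counts-per-million without between-library scaling
factors. Variable features are those at or above an empirical CV
quantile (3rd quartile by default; the realized threshold is
reported, ties kept). Sample correlation is pairwise-complete Pearson.
For the joint view of two reprogramming systems, PCA runs on scaled
profiles with samples as points; k-means (k = 4, 50 seeded restarts,
best inertia) on the first two components separates starting cells,
early and late intermediates and pluripotent cells. Pseudotime is the
PC1 projection, sign-oriented so a designated starting-state anchor
sample is minimal in its dataset — a deliberately minimal convention
for a shared reprogramming axis, not a trajectory-inference method.
Whether k-means should see 2 or more components is open; 2 is the
default and configurable. Heatmap ordering uses Ward linkage on
Euclidean distances.

## Synthetic data: what it emulates, and what it does not

The generator mirrors a two-dataset reprogramming study design:

- **Time course** — default grid {Bα, day2, day4, day6, day8, iPS} →
  pseudotime {0..5}, two replicates. True PSI follows a logistic curve
  per cluster; observed PSI is 100·Binomial(n, π/100)/n with
  n ~ Poisson(coverage 200 by default), plus Gaussian replicate jitter
  (sd 1 PSI) and clipping to [0,100]. Clipping slightly biases extreme
  PSI values. Coverage is Poisson, not negative binomial — PSI
  sampling noise, not count overdispersion, is the quantity under
  test; NB dispersion would only widen the read-count distribution.
- **Planted clusters** — six logistic shapes (sharp pulse, gradual
  rise, early decline, middle rise/decline, late rise). Shift times
  and steepness are chosen so no two scaled centroids are collinear
  *or anti-collinear* (max pairwise |r| ≈ 0.92): a mirror-image
  centroid pair would make the positive/negative regulator distinction
  undefined in the planted truth itself.
- **RBPs** — positive regulators are the scaled cluster centroid plus
  Gaussian noise (sd 0.3 scaled units), negatives its negation, nulls
  independent noise; profiles map affinely to the cpm scale
  (100 + 25·z), which preserves the scaled shape exactly and puts
  every planted RBP past the expression/variation filters. Optional
  genes are constructed to fail either filter. A padding gene absorbs
  the column remainder so cpm columns sum to one million.
- **Perturbation** — day0 baseline, scrambled-control day12 and n shRNA
  arms, two replicates; independent events shift by 30 PSI everywhere,
  dependent events shift 30 in control but 30 − 20 in every arm,
  unchanged events are static; Gaussian replicate noise (sd 2 PSI).
- **Loci** — uniform-composition sequences (GC adjustable for exons);
  regulated loci receive one concrete motif instance uniformly placed
  inside the planted window (downstream intron −120..−80) with
  probability 0.8; controls carry background frequency only.
- **Stage-structured expression** — four well-separated latent
  progress blobs shared by two datasets; genes load linearly on
  progress, so PC1 recovers the generative order.

What the generator does **not** emulate: realistic genome composition
(beyond GC), splice-site consensus structure, correlated event/gene
structure (each event is independent), overdispersed counts,
batch/library effects, or missing-data patterns of real quantifiers.
Passing the recovery experiments therefore demonstrates that each
caller implements its rule correctly and is calibrated under its
stated noise model — not that those rules are optimal for any real
dataset.

## Problem sizes

The recovery experiments run at: 50 random tables × 200 events for
caller/oracle equivalence; 6 × 300 trajectories for clustering; 120
planted regulators among 500 nulls; 1000 events for dependency
calibration; 300 + 300 loci with 1000 permutations for the RNA map
(30 × 150+150 null replicates at 300 permutations for the calibration
audit); 13 constructed transcripts for ORF impact; 30 samples for
pseudotime. These sizes give stable metrics while keeping the full
suite around a quarter of a minute of compute.

## Known limitations

- The vast-tools quality-score grammar is simplified to {OK, VLOW,
  NA}; real tables carry richer per-cell annotations.
- The independent-event definition inherits the ambiguity of "changing
  in any of the two conditions"; both readings are exposed.
- `uncertain` in ORF impact is a fall-through class (no transcript
  match, conflicting transcripts, missing sequence); upstream
  annotation pipelines enumerate finer sub-cases.
- The PWM splice-site score is a log-odds approximation; true
  maximum-entropy models capture positional dependencies it ignores.
- Pseudotime is a PCA projection and inherits PCA's linearity; it is
  not a substitute for trajectory inference on single-cell data.
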