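# splicedyn

Alternative-splicing dynamics of somatic-cell reprogramming: a tested,
reusable pipeline for calling differential splicing from PSI tables,
clustering inclusion trajectories, inferring RNA-binding-protein (RBP)
regulators, classifying perturbation-dependent events, predicting
ORF impact, and building permutation-tested RNA motif maps.

## The problem

When a differentiated cell is reprogrammed to pluripotency (e.g. mouse
B cells or embryonic fibroblasts driven by the OSKM factors), hundreds
of cassette exons change their inclusion level over the time course.
Characterizing that program means answering, in order:

1. **Which events change?** For an event with inclusion level PSI
   (percent spliced in, 0–100), a pair of conditions is called
   differentially spliced when |ΔPSI| ≥ 10 between condition means
   *and* every cross-condition replicate pair differs by ≥ 5 in the
   direction of the change. Cells supported by fewer than 10 reads are
   flagged VLOW and excluded.
2. **What are the temporal patterns?** Trajectories of the changing
   exons are z-scaled and clustered with fuzzy *c*-means; each exon
   carries a *membership* u ∈ [0,1] toward every cluster centroid.
3. **Who regulates them?** RBPs that are expressed (cpm ≥ 5 in ≥ 1/3
   of samples) and variable (CV ≥ 0.2) are scored against each
   centroid **and its negative**; membership ≥ 0.3 nominates a
   positive or negative regulator of that cluster.
4. **Which events depend on a factor?** In a knockdown/overexpression
   design, ΔΔPSI = (ΔPSI treatment − baseline) − (ΔPSI control −
   baseline) isolates the factor's effect. Dependent: |ΔΔPSI| ≥ 10 in
   every shRNA arm (and on the arm average). Independent: the event
   changes during reprogramming but |ΔΔPSI| < 2. The same logic
   applies to poly-A site usage (ΔΔPAU) for alternative
   polyadenylation.
5. **What do the events do?** Each exon is classified by its predicted
   effect on the transcript ORF: frameshift (length not divisible
   by 3), premature stop triggering NMD (> 50 nt upstream of the last
   exon–exon junction), truncation > 300 aa, ORF-preserving, or
   UTR/ncRNA location.
6. **Where does the regulator act?** RNA maps give, per position
   around the exon (first/last 50 nt of exon, first/last 150 nt of
   flanking introns), the fraction of sequences with a motif match in
   a 31-nt sliding window, compared to a control exon set with a
   1000-permutation label-exchange null.

Every step is exercised end-to-end on synthetic data with planted
ground truth (`splicedyn.synthetic_data`), so sensitivity, precision
and calibration are measured rather than assumed.

## Worked example

```python
import splicedyn.synthetic_data as sd
from splicedyn.psi_diff import diff_union
from splicedyn.temporal_clustering import scale_profiles, fuzzy_cmeans

# two-replicate time course: 6 planted clusters x 300 exons + 600 flat
t, truth = sd.simulate_timecourse(300, n_unregulated=600,
                                  coverage_mean=200, noise_sd_psi=1.0,
                                  seed=20240917)
union, fired = diff_union(t, t.samples.conditions)
scaled, _ = scale_profiles(t.psi.loc[sorted(union)])
model = fuzzy_cmeans(scaled, k=6, m=1.25, seed=20240917, n_restarts=10)
```

The same computation, end to end, is the numbered pipeline under
`analysis/` (each script prints what it found and writes its tables
under `results/`):

```
$ python analysis/01_simulate_data.py
$ python analysis/02_differential_splicing.py
1822 of 2400 events differentially spliced in ≥1 pairwise comparison
planted-event sensitivity 1.000, null false-call rate 0.037
$ python analysis/03_cluster_trajectories.py
selected k = 7 from the inter-centroid-distance curve; 1822 trajectories clustered ...
ARI vs planted clusters (regulated events only): 1.000
$ python analysis/04_infer_regulators.py
509 of 661 RBPs pass the expression/variation filters; 118 regulator calls
precision 0.992, recall 0.975 vs 120 planted regulators
```

Reading the numbers: all 1 800 planted exons are recovered by the
pairwise caller while 3.7% of flat exons slip past the thresholds at
this coverage; clustering reproduces the planted partition; and of the
120 planted regulators hidden among 500 null RBPs, 117 are nominated
with a single false call. Scripts 05–08 continue with the perturbation
classifier, ORF impact, sequence features / RNA maps (the planted
downstream-intron motif window at −120..−80 is recovered as a
significant segment) and the two-dataset PCA pseudotime.

## Layout

```
src/splicedyn/
  core_io.py              data model + TSV/GTF/FASTA readers and writers
  synthetic_data.py       generators with planted ground truth
  psi_diff.py             ΔPSI differential-splicing calling
  temporal_clustering.py  scaling, fuzzy c-means, membership
  regulator_inference.py  RBP filters and regulator calls
  perturbation.py         ΔΔPSI / ΔΔPAU dependency classification
  orf_impact.py           ORF/NMD impact prediction
  seq_features.py         features, splice-site scoring, RNA maps
  expression_pseudotime.py cpm, PCA, k-means groups, pseudotime, Ward
  experiments.py          end-to-end recovery experiments
analysis/                 numbered narrative drivers (01–08)
scripts/acceptance.py     recovery metrics → JSON
tests/                    pytest suite with independent oracles
docs/methods.md           models, parameters, design choices
```
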