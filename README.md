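# clipsplice

An integrative pipeline for studying how an RNA-binding protein shapes
alternative splicing, built around two data types: PAR-CLIP binding profiles
and junction-aware RNA-seq from perturbation experiments (knockdown and
overexpression with paired controls). It calls protein–RNA binding clusters
from T→C conversion evidence, quantifies exon inclusion and intron retention,
detects differential splicing with a coverage-local Z statistic combined
across replicates by rank products, and joins both layers into an RNA
splicing map. A first-class synthetic-data generator plants known binding
sites and splicing effects so every stage can be validated against recorded
ground truth without external downloads.

## The method

**Binding clusters.** Uniquely mapped PAR-CLIP reads are merged by transitive
same-strand overlap into clusters; each cluster's *preferred crosslink site*
is the position with the most T→C conversions. A **consensus cluster** is a
reciprocal pair across two replicates — each replicate's crosslink must fall
inside the other replicate's cluster — and adopts replicate 1's crosslink.

**Splicing quantification.** For an internal exon *E*,

&nbsp;&nbsp;PSI = e_in / (e_in + e_out)

where e_in counts reads mappable only to *E* or to exon junctions containing
*E*, and e_out counts reads mappable only to junctions skipping *E*; every
junction side must overlap its exon by ≥ 6 bp. Intron retention is measured
analogously: PIR = i_in / (i_in + i_out) from intron–exon junction reads
versus skipping exon–exon junction reads. Gene expression uses RPKM. Internal
exons with PSI in [0.02, 0.98] in at least one sample form the cassette-exon
universe.

**Differential testing.** The noise of ΔPSI/ΔPIR/Δlog₂RPKM depends on
coverage, so each Δ is standardized by a *local standard deviation*: features
are sorted by supporting-read totals, the SD of Δ is computed in a sliding
window covering 1% of features, loess-smoothed, and Z = Δ / SD_local. Within
each replicate, features are ranked by Z (separately for each direction) and
the ranks are multiplied across replicates; the **rank product**'s false
discovery rate is estimated by permuting each replicate's rank list. Calls
require fdr < 0.05 and |ΔPSI| ≥ 0.10 (expression: fdr < 0.05, ≥ 1.5-fold).

**Integration.** Consensus crosslinks are profiled around the four splice
sites of each cassette exon's flanking introns (the splicing map), exons are
classified by which sites carry binding within 150 nt on the intronic side,
group CDFs of splicing change are compared (Mann–Whitney U), intron retention
of the flanking introns is stratified by exon response, and splice-site
strength is scored with a trained PWM (log₂ odds vs genome background).

## Worked example

```python
import numpy as np
from clipsplice import *

config = SimulationConfig(seed=11, n_genes=120)
genes, sequences, truth = simulate_genome(config)

# PAR-CLIP: reads -> clusters -> cross-replicate consensus
replicates, truth = simulate_parclip_reads(genes, truth, config, sequences)
rep1, rep2 = (call_clusters(reads) for reads in replicates)
consensus = consensus_clusters(rep1, rep2)
print(f"clusters: {len(rep1)} / {len(rep2)} per replicate, {len(consensus)} consensus")

profile = boundary_density_profile(consensus, genes, window=150, which="intron-exon")
peak = int(np.arange(-150, 151)[profile.argmax()])
print(f"binding density peaks {abs(peak)} nt upstream of the 3' splice site")

# RNA-seq: counts -> PSI -> local-SD Z -> rank-product FDR
tables, truth = simulate_splicing_counts(genes, truth, config)
case, control, coverage, ids = metric_matrices(tables, "KD")
result = differential_test(case, control, coverage, ids, metric="psi",
                           config=DifferentialConfig(seed=11))
calls = result["call"].value_counts().to_dict()
print(f"differential exons (fdr<0.05, |dPSI|>=0.10): {calls}")

planted = set(truth.exons.loc[truth.exons.planted, "exon_id"])
hits = set(result.loc[result.call != "none", "feature_id"])
print(f"planted effects recovered: {len(hits & planted)}/{len(planted)}")
```

Output:

```
clusters: 127 / 126 per replicate, 126 consensus
binding density peaks 71 nt upstream of the 3' splice site
differential exons (fdr<0.05, |dPSI|>=0.10): {'none': 437, 'up': 28, 'down': 7}
planted effects recovered: 34/34
```

The 126 consensus clusters sit where the generator planted binding — the
density profile peaks ~70 nt into the intron upstream of acceptor sites —
and the knockdown contrast (4 replicates, mean depth 100 reads/exon) recovers
all 34 planted ΔPSI effects, with 35 total calls.

## Command line

```bash
clipsplice run --config configs/demo.yaml        # full pipeline, one manifest
clipsplice simulate --seed 7 --outdir out        # synthetic study only
clipsplice clusters call --reads out/clip_reads_rep1.tsv --out rep1.bed
clipsplice diff --counts out/exon_counts.tsv --condition KD --out diff.tsv
clipsplice evaluate --run-dir out                # score calls against truth
```

Every run writes a `manifest.json` with parameters, the seed and SHA-256
digests of all outputs; rerunning the same config reproduces identical
digests.

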