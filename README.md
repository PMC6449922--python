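# m2f — marker-gene identity vs. shared gene content

`m2f` ("markers to functions") asks a question that matters to anyone
interpreting 16S amplicon surveys: **if two prokaryotic genomes have nearly
identical marker genes, how much of their protein-coding gene content do
they actually share?** Marker-gene studies routinely infer community
function from taxonomy; this package implements, as a tested and reusable
pipeline, the comparative-genomics analysis that quantifies how far that
inference can be trusted — together with a synthetic pan-genome generator
that makes every stage verifiable against known truth without downloading
any genome collection.

The pipeline has two tracks:

1. **Marker track** — extract 16S rRNA copies from annotated assemblies
   (with intra-genome copy statistics and assembly-artifact flagging),
   excise the V4 region by in-silico PCR with the degenerate 515f/926r
   primers, build concatenated five-gene MLSA sequences, and cluster each
   marker dataset with greedy centroid (OTU-style) clustering at identity
   thresholds 95–100 % (93–100 % for MLSA).
2. **Gene-content track** — for genome pairs that co-cluster, match
   proteomes by reciprocal best hit (RBH) under local BLOSUM62 alignment
   and compute **percent shared genes**

   $$\text{shared} = 100 \cdot \frac{2M}{n_A + n_B}$$

   where $M$ is the number of matched ortholog pairs and $n_A$, $n_B$ the
   proteome sizes. Pairs are then binned by the *highest* threshold at
   which their markers co-cluster, per-bin boxplot tables are produced, a
   Kruskal–Wallis + Dunn-vs-rest (Bonferroni) test asks which lineages
   share more or less than the pooled data, and Fisher exact tests ask
   which GO terms ride the shared vs. the unshared gene sets (with
   true-path `is_a` propagation).

The synthetic generator (`m2f.simulate`) evolves genome pairs from a common
ancestor under a two-rate model — per-site marker substitution versus
per-family accessory gene gain/loss — so the true shared fraction and the
expected marker identity of every pair are known exactly. See
`docs/methods.md` for the model and its assumptions.

## Worked example

```python
from m2f.simulate import PanGenomeModel, simulate_corpus
from m2f.orthology import rbh_match
from m2f.experiments import _pair_v4_identity

model = PanGenomeModel(seed=42)
corpus = simulate_corpus(model, divergence_times=(0.1, 1.0), pairs_per_stratum=2)
print(f"{'pair':<8}{'t':>5}{'V4 identity':>13}{'shared % (RBH)':>16}{'shared % (truth)':>18}")
for truth in corpus.pairs:
    ga = corpus.genomes[truth.genome_id_a]
    gb = corpus.genomes[truth.genome_id_b]
    ident = _pair_v4_identity(ga, gb)
    comp = rbh_match(ga.proteins(), gb.proteins(), ga.genome_id, gb.genome_id)
    print(f"{truth.genome_id_a[:-1]:<8}{truth.divergence_time:>5.1f}"
          f"{ident:>13.2f}{comp.percent_shared:>16.2f}"
          f"{100*truth.true_shared_fraction:>18.2f}")
```

prints

```
pair        t  V4 identity  shared % (RBH)  shared % (truth)
P0000     0.1        98.93           97.51             97.51
P0001     0.1        98.93           95.14             95.14
P0002     1.0        87.94           82.46             82.46
P0003     1.0        90.88           79.41             79.41
```

Each row is one genome pair evolved for divergence time *t*: the V4
amplicons of shallow pairs are ~99 % identical yet the genomes already
share less than 98 % of their genes, and at deeper divergence the V4 region
still reads ~88–91 % identity while shared gene content has fallen to
~79–82 %. The RBH column reproduces the generator's truth column exactly
here because within-family sequences are identical by default
(`gene_sub_rate=0`); with within-family divergence switched on it stays
within a couple of percentage points (see the acceptance checks).

## Command line

The same workflow is scriptable via the `m2f` entry point:

```bash
m2f simulate --out corpus --seed 7          # synthetic corpus with truth.tsv
m2f extract  --genomes corpus --out markers --markers 16s,v4,mlsa
m2f cluster  --input markers/v4.fasta --thresholds 95,96,97,98,99,100 --out clusters
m2f run-all  --out run1 --seed 7            # full pipeline, manifest + tables
```

`run-all` writes `pairwise_shared.tsv`, per-threshold cluster tables,
`bin_summary_<marker>.tsv` (boxplot statistics per identity bin),
`lineage_tests.tsv` and `go_enrichment.tsv`, plus a `manifest.tsv` and the
resolved config; a rerun with the same seed is byte-identical.

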