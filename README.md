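# tfcobind

Prediction of interacting transcription-factor (TF) pairs from promoter
DNA-binding affinity, with tissue-specific refinement.

The pipeline:

1. **Affinity scoring** — every promoter is scanned with every motif (JASPAR
   PFM) using a biophysical occupancy model: each window on both strands
   contributes `R·K/(1+R·K)` with `K = exp((llr − llr_consensus)/λ)`, so no
   hard site/non-site threshold is needed.
2. **Ranking** — genes are ordered per factor by decreasing affinity
   (deterministic lexicographic tie-break).
3. **Pair scan** — every unordered factor pair is scored by the minimum
   upper-tail hypergeometric p-value of its top-`L1`/top-`L2` overlap over the
   grid `L1, L2 ∈ {10, 20, …, 1000}` (10⁴ cells, computed in log space so
   p ≪ 10⁻²⁰ stays representable).
4. **Motif-similarity filter** — pairs whose motifs are near-identical (a
   log-odds-of-overlapping-hits score ≥ 4 by default) are flagged as
   confounded rather than treated as evidence of cooperation.
5. **Tissue test** — for each tissue gene set, a 2×2×2 contingency table over
   (top-L1 membership, top-L2 membership, tissue specificity) is tested for
   partial independence of the composite XY from Z with a G-statistic
   referred to χ² (df = 3); pairs are called only when the triple-positive
   cell exceeds its expectation.
6. **Network** — calls are thresholded per context (log10 p ≤ −20 global,
   −6 tissue, −11 cell-line), annotated against a known-PPI edge list
   (direct hits and shared-cofactor "trios"), assembled into networks with
   degree-based hub detection and Fisher-exact PPI enrichment.

A fully seeded synthetic-fixture generator (`tfcobind.simulate`) produces
promoters with planted co-occurring motif sites, coupled tissue gene sets,
and a consistent PPI list with a ground-truth manifest, for end-to-end
testing without any external data.

## Command line

```bash
# generate a synthetic data set with one planted pair and one coupled tissue
tfcobind simulate --out demo --seed 7 --n-genes 2000 --n-tfs 10 \
    --plant 0,1,100 --tissue liver,150,0.6

# run the full pipeline on it
tfcobind run-all --promoters demo/promoters.fa --motifs demo/motifs.jaspar \
    --tissues demo/tissues.tsv --ppi demo/ppi.tsv --outdir demo/out

# or stage by stage (artifacts are plain TSV and reruns are byte-identical)
tfcobind affinity  --promoters demo/promoters.fa --motifs demo/motifs.jaspar --outdir demo/out
tfcobind rank      --outdir demo/out
tfcobind pairscan  --outdir demo/out
tfcobind similarity --motifs demo/motifs.jaspar --outdir demo/out
tfcobind tissue    --tissues demo/tissues.tsv --outdir demo/out
tfcobind network   --ppi demo/ppi.tsv --outdir demo/out
```

All options can instead be given in a YAML config (`--config cfg.yaml`);
see `tfcobind.config.PipelineConfig` for the keys. Precomputed gene×factor
affinity tables (`affinity_tsv`) or similarity matrices (`similarity_tsv`)
can replace the built-in scorers.

## Inputs

- promoters: FASTA keyed by gene id, or a genome FASTA + BED6 of TSSs
  (`tfcobind.motifs.extract_promoters`, default window −500..0 of the TSS);
- motifs: JASPAR PFM text (counts; a per-cell pseudocount, default 1.0, is
  added before normalization);
- tissue gene sets: two-column (tissue, gene) TSV or a directory of
  one-gene-per-line `<tissue>.txt` files;
- known PPIs (optional): two-column TSV of interacting factor pairs.

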