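# docknet

Docking-based protein-protein interaction (PPI) inference toolkit:

* **decoy-referenced docking z-scores** — standardize the top pose score of a
  rigid-docking run against the distribution of its high-ranked decoys
  (`z = (top − decoy_mean) / decoy_sd`) and decide interactions at a
  configurable threshold (default `z ≥ 8.8`);
* **imbalance-aware threshold calibration** — shuffled negative sets,
  TPR/FPR/precision/F-measure, ROC/AUC, and F-optimal threshold sweeps as a
  function of the positive:negative ratio;
* **structural model QC** — identity/coverage filtering, Kabsch
  superposition RMSD, and a length-normalized topological similarity score
  with iterative superposition refinement;
* **network construction** — z-thresholded undirected interactomes, degree
  statistics, and overlap with external edge sets;
* **variant impact** — a minimal SNV-only consequence annotator (CDS codon
  arithmetic on both strands), interface-residue detection by inter-chain
  heavy-atom distance, variant-to-interface mapping, and ΔΔG perturbation
  classification (`ΔΔG = ΔG_REF − ΔG_ALT`, strict ±1 kcal/mol bands);
* **orthogonal validation** — interolog transfer through ortholog maps,
  winner-takes-all localization with hypergeometric co-localization
  enrichment, and a rank-sum coexpression shift test;
* **synthetic data** — parametric pose-score generators whose z round-trips
  exactly, benchmark presets with configurable class separations, toy
  poly-alanine structures (including a shape-complementary cup-and-ball
  docking fixture), and toy genomes with planted SNVs plus a truth table.

A toy rigid-body grid-docking engine (surface/core occupancy correlation
over sampled rotations) produces realistic rank-ordered pose lists so the
whole pipeline runs end-to-end with no external docking program.

## Test

```sh
python -m pytest -q tests/
```

The suite includes property tests (hypothesis) and independent brute-force
oracles (rotation-grid RMSD search, exhaustive AUC pair counting, full-mRNA
rebuild-and-diff annotation, exhaustive hypergeometric enumeration) in
`tests/oracles.py`. `tests/test_acceptance.py` holds the acceptance
criteria.

## CLI

```sh
docknet simulate scores --out-dir scratch/scores --seed 1 --n 10
docknet zscore --poses scratch/scores --out scratch/z.tsv
docknet net --zscores scratch/z.tsv --threshold 8.8 --out scratch/edges.tsv

docknet simulate structures --out-dir scratch/s --seed 1 --n 25
docknet dock --receptor scratch/s/receptor.pdb --ligand scratch/s/ligand.pdb \
    --seed 1 --out scratch/poses.txt

docknet simulate genome --out-dir scratch/g --seed 1 --n 5
docknet variants --vcf scratch/g/variants.vcf --gff3 scratch/g/genes.gff3 \
    --fasta scratch/g/genome.fasta --gene gene1 --out scratch/annot.tsv

docknet calibrate --zscores z.tsv --positives pos.tsv --ratio 100 --seed 1 \
    --out sweep.tsv
docknet qc --alignments aln.tsv --out verdicts.tsv
docknet validate --edges edges.tsv --coexpression coex.tsv --locations locs.tsv
```

Pose-score files use a permissive dialect: optional `#` header lines, one
pose per line, whitespace-separated fields with the score in the last
field, rank 1 first.

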