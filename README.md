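# spatiochrom

3D chromosome reconstruction from Hi-C contact maps, plus the comparative
statistics needed to ask whether linear synteny (gene pairs, microsyntenic
blocks, whole-chromosome linkage groups) is reflected in reconstructed
spatial organization.

The package provides:

- **hic_io** — HiC-Pro-style plain-text input (abs-BED bin table +
  3-column sparse matrix), cis-contact extraction, interaction-frequency
  threshold logic (mean / median / percentile cutoffs with strict-above
  retention), FitHiC-style explicit constraint lists, and the
  sequencing-depth formula `(paired_reads * 2 * read_length) / genome_size`.
- **reconstruct** — a beads-on-a-string physics engine: self-avoiding
  random-walk initialization, linear-spring volume exclusion, chain
  tension and contact-restraint forces, damped Newtonian dynamics under
  classic Verlet integration, pseudo-energy and Kabsch-RMSD convergence
  diagnostics, replicate management, Spearman/cosine model validation.
- **model_io** — pseudo-atom PDB (CA trace, CONECT records, REMARK
  metadata carrying chromosome, bin size and nm scale) and plain xyz TSV.
- **intsph** — interaction-sphere contact density: exact closed-ball
  neighbour counts per bead (KD-tree accelerated, bit-identical to brute
  force), radius scans, a 4-parameter logistic fit of mean density vs
  radius with plateau detection, and radius recommendation as a fraction
  (0.5–1.0) of the fitted inflection point.
- **synteny** — midpoint gene-to-bin mapping, ALG/nonALG bin
  classification (a bin with ≥1 ALG gene counts as ALG), order-free
  microsynteny detection (≥3 shared orthogroups, ≤5 intervening genes in
  both species), size-matched random block sampling (genome-wide or
  same-chromosome), and Fisher-exact chromosome homology with
  Benjamini-Hochberg correction.
- **spatial_stats** — nm/Mb spatial ratios, randomized-orthology nulls, a
  permutation-calibrated Fasano–Franceschini 2D two-sample test,
  ALG/nonALG contact-class counts inside interaction spheres,
  microsynteny contact-density comparisons (rank-sum test), and conserved
  spatial-neighbour discovery between two species' models.
- **fixtures** — seeded synthetic data for everything above: known 3D
  structures (SARW / helix / rosette), distance-decay contact matrices in
  HiC-Pro format, and two pseudo-species genomes with planted chromosome
  homology, ALG partition and microsyntenic blocks, with a truth manifest.

## Test

```sh
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance criteria (worked
sequencing-depth examples, physics-engine properties including 50-bead
structure recovery at distance-matrix Spearman ≥ 0.8, interaction-sphere
oracle equivalence, 2D-test type-I calibration over 500 null repetitions,
planted-synteny recovery, threshold retention percentages, and an
end-to-end smoke run). The full suite takes a few minutes on one CPU.

## CLI

```sh
spatiochrom fixture --out fx --seed 1              # synthetic input bundle
spatiochrom depth --reads 174148156 --read-length 150 --genome-size 884566040
spatiochrom thresholds --bins fx/bins_A.bed --matrix fx/matrix_A.tsv --chrom A_chr0
spatiochrom reconstruct --bins fx/bins_A.bed --matrix fx/matrix_A.tsv \
    --chrom A_chr0 --cutoff mean --steps 10000 --replicates 3 --seed 1 \
    --out-dir models/
spatiochrom intsph --model models/A_chr0_rep1.pdb --scan 50:400:25 --fit
spatiochrom intsph --model models/A_chr0_rep1.pdb --radius 150
spatiochrom synteny detect --genes-a fx/genes_A.bed --genes-b fx/genes_B.bed \
    --orthology fx/orthology.tsv --out blocks.tsv
spatiochrom synteny homology --genes-a fx/genes_A.bed --genes-b fx/genes_B.bed \
    --orthology fx/orthology.tsv --out homology.tsv
spatiochrom stats fftest --sample-a a.tsv --sample-b b.tsv --n-perm 999 --seed 1
spatiochrom stats alg-contacts --model models/A_chr0_rep1.pdb \
    --genes fx/genes_A.bed --orthology fx/orthology.tsv --alg fx/alg_A.tsv
```

A YAML config (`--config`) can pre-set any `SimulationParams` field under a
`simulation:` key; explicit CLI flags win.

## Notes on conventions

- Bins are 0-based half-open internally; the abs-BED global id is kept
  1-based as on disk. Self-interactions are discarded; thresholds use
  strict inequality (IF > cutoff); percentiles use linear interpolation.
- Force constants are stability-motivated defaults (m=1, γ=0.5,
  K_rep=K_ten=1, K_HiC=0.3, dt=0.01, bead radius 25 nm for a 150 kb bin),
  all configurable; rest lengths default to two bead radii.
- The microsynteny dialect is order- and strand-free; intervening genes
  are counted over all annotated genes. The Fisher homology test is
  one-sided (enrichment).
- Interaction spheres are bead-centred closed balls; genomic neighbours
  count (a flag excludes them for sensitivity analyses).
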