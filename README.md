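# turboprox

Downstream analysis for TurboID proximity-labeling proteomics and FRAP
imaging, built for experiments that ask "which proteins are near my bait
in vivo?" — e.g. probing the *C. elegans* centrosome by fusing a
promiscuous biotin ligase to a pericentriolar-material scaffold protein,
pulling biotinylated neighbours down on streptavidin, and quantifying
them by label-free mass spectrometry against a ligase-only control.

The package takes MaxQuant-style `proteinGroups` tables (3 experimental
vs 3 control replicates, or any ≥2-vs-≥2 design) through:

1. **Quality filtering** — remove reverse hits, contaminants,
   only-by-site identifications, groups with <2 razor+unique peptides,
   and groups with <2 quantified LFQ values in one group.
2. **log2 transform + imputation** of left-censored missing values, by
   either deterministic **LOD** (lowest observed value per run/column) or
   **ND** (seeded draws from `Normal(m − 1.8·s, (0.3·s)²)` over the
   whole-dataset log2 moments `m`, `s`).
3. **Enrichment calling** — per protein, log2 fold change
   `mean(log2 exp) − mean(log2 ctl)` and a two-sided unpaired (pooled
   Student) t-test; significant iff log2 FC > 1 and p < 0.05. Volcano
   (−log10 p vs log2 FC) and MA (mean log2 intensity vs log2 FC) tables
   are written alongside.
4. **FRAP fitting** — background-subtracted concentric-region
   quantification, pre-bleach normalization, and nonlinear least-squares
   fits of `Y = A·(1 − e^(−kX)) + B` with mobile fraction `A`, half-time
   `t½ = ln 2 / k`, and R² over the post-bleach points.

A synthetic-data module simulates pulldown proteomes with ground-truth
classes (bait, interactors censored in controls, abundant
endogenously-biotinylated carboxylase-like background, decoys) and noisy
recovery traces/image stacks, so the full pipeline is testable without
any external data. See `docs/methods.md` for the statistical details and
assumptions.

## Worked example

Simulate a pulldown and analyse it with both imputation schemes:

```sh
turboprox simulate --seed 4 --output-dir sim
cat > run.yaml <<EOF
protein_groups: sim/proteinGroups.tsv
design: sim/design.tsv
output_dir: out
imputation: both
seed: 4
EOF
turboprox run-enrichment run.yaml
```

Or run the scripted analyses (same machinery, fixed seeds):

```sh
python analysis/01_simulate_proteome.py
python analysis/02_enrichment_lod_vs_nd.py
python analysis/03_frap_recovery.py
```

which print:

```text
simulated 205 protein groups: {'bait': 1, 'interactor': 20, 'carboxylase_like': 4, 'background': 150, 'decoy': 30}
18/21 interactors have at least one censored control value
LOD: 16 significant -> {'interactor': 15, 'bait': 1}
ND: 11 significant -> {'interactor': 10, 'bait': 1}
3 proteins invert enrichment direction between LOD and ND ({'interactor': 2, 'background': 1})
interactor mean log2 FC: LOD 2.36 vs ND 1.60
ensemble of 16 traces: mean A = 0.905 (true 0.9), mean t_half = 4.94 s (true 5.0 s), mean R^2 = 0.963
```

Reading the numbers: every one of the 30 decoy records is removed by
filtering; only true interactors (and the bait) pass the significance
threshold, while the four abundant carboxylase-like background proteins
are correctly rejected by the sample/control comparison. The
deterministic LOD route recovers more of the control-censored
interactors than ND imputation, whose higher fill-in values shrink —
and for some proteins invert — the apparent enrichment; the comparison
table (`out/imputation_comparison.tsv`) flags those inversions. The FRAP
ensemble fit recovers the simulated fast-exchange kinetics (mobile
fraction 0.9, 5 s half-time) to within a few percent.

To apply the published analysis settings to a real processed LFQ sheet
(exported as TSV, with a design file mapping LFQ column suffixes to
groups):

```sh
python scripts/reproduce_published.py --protein-groups sheet.tsv \
    --design design.tsv --column-map map.yaml
```

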