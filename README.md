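# petconn

Individualized whole-body PET connectomics from voxel-wise SUV
distributions.

A subject's PET scan — represented as a labeled voxel point cloud
(position, SUV, TotalSegmentator-style organ label) — is turned into a
fully connected, weighted, undirected organ-interaction graph:

1. **Compression** — each organ's voxel cloud is reduced to ≤ 3500
   weighted representative points by spatially-aware iterative merging
   that preserves distribution shape including heavy tails.
2. **Connectome construction** — pairwise energy distances between organ
   SUV distributions, corrected by normalized mutual information
   (`D* = D·(1 − α·MI)`, α ∈ [0, 1]) and mapped through exponential
   similarity `C = exp(−D*)`; organ graphs are reduced to 13 canonical
   meta-organ ROIs.
3. **Residual networks** — per-edge Gaussian-KDE models fitted on a
   control cohort score how extreme each edge of an individual connectome
   is (`r = sign(m − c)·(1 − p^κ)`, κ ∈ (0, 1]).
4. **Classification** — a small numpy GCN (two graph-conv layers, 16/32
   channels, tanh; mean pooling; MLP head) with repeated stratified
   3×9-fold CV, edge-ablation saliency maps, and a logistic-regression
   baseline (ridge / lasso / stability-weighted lasso).
5. **Robustness** — stochastic boundary label swapping (k-NN boundary
   detection, blur ratio B) with Spearman stability analysis of the
   re-computed connectomes.

Since clinical PET data are not distributable, the package ships a
seeded synthetic phantom module (`petconn.phantom`) producing cohorts
with the spatial and statistical structure the pipeline assumes; all
tests and the acceptance suite run entirely on it.

## CLI

```sh
petconn phantom --controls 20 --patients 10 --seed 1 --out cohort/
petconn compress --in cohort/control_000.csv --target 3500 --lambda 1.0 --seed 1 --out c.csv
petconn connectome --cohort cohort/manifest.json --alpha 1.0 --seed 1 --out conn/
petconn residuals --connectomes conn/ --kappa 0.25 --holdout 5 --seed 1 --out res/
petconn classify --connectomes conn/ --mode gcn --seed 1 --out clf/
petconn perturb --in cohort/control_000.csv --blur 0.5 --k 15 --seed 1 --out noisy.csv
petconn run --config experiment.yaml
```

`petconn run` executes the full experiment (phantom → connectomes →
residual statistics → GCN + logistic classification → boundary-noise
robustness) from one YAML config and writes CSV matrices plus a
deterministic `summary.json`.

Subjects can also be ingested from NIfTI PET volumes plus integer
multi-label masks via `petconn.read_nifti_subject`.

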