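# mhc2lig

Prediction and benchmarking of MHC class II (HLA-DR) ligands by combining
per-allele rescaled peptide–MHC binding scores with peptide-averaged
structural features (relative surface accessibility and secondary
structure), plus the full evaluation machinery around the model:

- **data_io** — FASTA/TSV readers and writers, allele-name normalization,
  per-allele ligand accounting and capped ("balanced") subsampling.
- **window_features** — tiling source proteins into ligand-length windows;
  per-window means of RSA/helix/strand/coil and glycosylation-site counts.
- **scaling_model** — per-allele percentile rescaling of 1-log50k binding
  scores against a random-peptide background ("Rescaled01") and the
  additive combined likelihood score `rescaled + α·feature (+ β·rsa)`.
- **benchmark** — per protein–ligand-pair ROC evaluation (AUC and AUC0.1,
  the partial area up to FPR 0.1 normalized to [0, 1]), dataset means,
  brute-force grid search for α/β, k-fold cross-validation, and paired
  model comparison.
- **matched_analysis** — affinity-matched ligand/non-ligand pairing
  (±5 % relative tolerance, non-overlap, stronger-and-weaker bracketing),
  paired t-tests per feature, and exact two-sided binomial tests for
  glycosylation.
- **synthetic_data** — a seeded generator for complete synthetic datasets
  (proteins, planted ligands, smooth residue tracks, per-window binding
  scores, glycosylation sites, per-allele backgrounds) with configurable
  planted effect sizes, used throughout the tests.
- **cli** — the `mhc2lig` command-line entry point.

## CLI

All subcommands are deterministic given `--seed` and use TSV (tab-separated,
0-based half-open windows) and FASTA formats throughout:

```sh
mhc2lig simulate --n-proteins 100 --delta-rsa 0.1 --seed 1 --outdir data/
mhc2lig validate  --proteins data/proteins.fasta --ligands data/ligands.tsv \
                  --tracks data/tracks.tsv --binding data/binding.tsv
mhc2lig summarize --proteins data/proteins.fasta --ligands data/ligands.tsv
mhc2lig balance   --proteins ... --ligands ... --cap 30 --seed 1 --out balanced.tsv
mhc2lig rescale   --background data/backgrounds.tsv --percentile 1 --out scalers.tsv
mhc2lig benchmark --proteins ... --ligands ... --tracks ... --binding ... \
                  --scalers scalers.tsv --feature rsa --alpha 0.3 --out bench.tsv
mhc2lig optimize  --... --feature rsa --out grid.tsv
mhc2lig cv        --... --feature rsa --k 5 --seed 1 --out cv.tsv
mhc2lig match     --... --tol 0.05 --seed 1 --out matched.tsv
mhc2lig compare   --... --tol 0.05 --seed 1 --out report.tsv
```

Exit codes: 0 ok, 1 validation error, 2 runtime error.

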