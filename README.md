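# emdcsp

A toolkit for two-class motor-imagery EEG analysis built around complex-valued
spatial filtering of the mu (8–13 Hz) and beta (13–25 Hz) rhythms:

- **`emdcsp.synthgen`** — synthetic multichannel EEG with known lateralized
  mu/beta structure (ground-truth mixing, per-trial source amplitudes and
  band powers), including a *difference-only* construction where the summed
  mu + beta power is class-invariant at every channel and only the mu − beta
  power difference discriminates the classes.
- **`emdcsp.memd`** — multivariate empirical mode decomposition (Hammersley
  direction vectors, cubic-spline envelopes, mirror boundaries, Rilling
  stopping rule), a noise-assisted variant, Bartlett-window periodograms, and
  IMF-to-rhythm assignment (fixed or spectrum-driven).
- **`emdcsp.spatial_filters`** — the CSP family: real CSP, complex CSP
  (covariance only) and SUTCCSP (covariance + pseudocovariance via the strong
  uncorrelating transform, with a Takagi factorization computed through the
  real symmetric embedding). The complex trials are z = mu + j·beta, so the
  covariance carries the power sum and the pseudocovariance the power
  difference of the two rhythms.
- **`emdcsp.eval_harness`** — log-power features, repeated stratified
  cross-validation with fold-wise filter refitting (no leakage), built-in
  random-forest (100 trees) and 1-NN backends plus a fit/predict plug-in
  contract, the exact-binomial significant-subject threshold, and paired
  t-test comparisons.
- **`emdcsp.lateralization`** — spatial-pattern maps (filter inverses) and
  per-trial hemispheric asymmetry (CH_L − CH_R)/(CH_L + CH_R) of the mu/beta
  power difference and sum over symmetric channel pairs, with ±k·SD outlier
  exclusion.
- **`emdcsp.io_cli`** — a minimal EDF/EDF+ reader and writer (16-bit signals
  + TAL annotations), 10-10 montage handling with the default 14-channel
  layout, half-open epoch windows, and a configuration-driven pipeline.

## CLI

```sh
# generate a difference-only synthetic dataset
emdcsp simulate --seed 1 --n-trials 100 --difference-only --out ds.npz

# cross-validated comparison of the three variants (shared folds)
emdcsp classify --input ds.npz --classifier rf --reps 5 --seed 0

# noise-assisted MEMD decomposition and rhythm assignment
emdcsp decompose --input ds.npz --out imfs.npz --policy auto --seed 0

# filter bank fitting and the asymmetry table
emdcsp fit-csp --input ds.npz --variant sutccsp --out bank.npz
emdcsp asymmetry --input ds.npz --out asym.csv

# full pipeline from a YAML config
emdcsp run --config pipeline.yaml
```

A pipeline config names the dataset (synthetic parameters or a container
file), the rhythm-extraction method (`bandpass` or `memd`), the variants,
classifier, and CV settings; all stages are deterministic given the seed and
variants share fold assignments so paired comparisons are valid.

Real recordings enter through `io_cli.read_edf` + `epoch` +
`select_channels`. The default montage contains the five symmetric pairs
FC5-FC6, FC1-FC2, C3-C4, CP5-CP6, P1-P2 plus four midline fill-ins (Fz, Cz,
Pz, Oz); the fill-ins are a documented reconstruction and fully overridable.

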