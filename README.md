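# erspconn

Oscillatory EEG analysis pipeline for two-condition, stimulus-locked
paradigms: event-related spectral perturbation (ERSP) maps, seed-based
corrected-imaginary-coherence functional connectivity (ciCOH / ER-ciCOH),
and cluster-based permutation statistics — together with a synthetic EEG
generator that emulates the trial structure with known, ledgered effects so
every stage can be validated against ground truth.

## Modules

| module | contents |
| --- | --- |
| `erspconn.synth` | 32-channel montage preset, 1/f background simulation, injectable effects: band-limited power modulation, phase-lagged coupling, zero-lag mixing, amplitude artifacts; ground-truth ledger |
| `erspconn.preprocess` | linear detrend, linked-mastoid re-reference, zero-phase FIR band-pass (0.5–48 Hz), 6000 ms segmentation, 200 µV frontal amplitude rejection, logistic-infomax ICA with heuristic component flagging |
| `erspconn.ersp` | sliding-window time–frequency power (1–45 Hz, ≈0.48 Hz × 33.33 ms grid), dB baseline normalization to the rest epoch, band × window summaries (α/β/γ × four 250 ms windows) |
| `erspconn.connectivity` | DPSS multitaper cross-spectra (1000 ms window, 5 tapers), coherency, ciCOH, Fisher z, per-trial ER-ciCOH contrast (TOI vs. baseline) seeded at POO1/POO2 |
| `erspconn.clusterstats` | dependent-samples t-maps, electrode neighbor graphs, sign-homogeneous clustering, max-statistic sign-flip permutation test (exact enumeration for small n) |
| `erspconn.io_cli` | BrainVision (.vhdr/.vmrk/.eeg) reader + fixture writer, HDF5 epochs container, TSV tables, YAML run config, CLI |

## CLI

Each stage runs independently on a shared output directory, or everything
at once:

```bash
erspconn simulate   --config run.yaml --seed 1 --out results/
erspconn preprocess --config run.yaml --out results/
erspconn ersp       --config run.yaml --out results/
erspconn connect    --config run.yaml --out results/
erspconn stats      --config run.yaml --out results/
# or
erspconn all --config run.yaml --seed 1 --out results/
```

The YAML config keys mirror `erspconn.io_cli.RunConfig`; every parameter
defaults to the study-standard value (0.5–48 Hz filter, 200 µV rejection
threshold, α 8–14 / β 15–35 / γ 35–45 Hz bands, 1000 ms / 5-taper
multitaper window, 1000 permutations). Exit codes: 0 success, 2 config
error, 3 data error. Outputs: per-subject HDF5 epoch containers, a
ground-truth effect ledger (JSON), `ersp_band_window.tsv`,
`er_cicoh.tsv`, `cluster_report.tsv`, `summary.json` and `run.log`, all
stamped with the config hash.

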