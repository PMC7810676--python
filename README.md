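# wingbeat

Classification of flying insects from the signals of a four-channel
near-infrared optical sensor (co- and de-polarized backscatter at two
wavelengths, sampled at 20 kHz).  The package is aimed at researchers in
entomological remote sensing and precision agriculture who want a
tested, reproducible reference implementation of the full analysis
chain:

1. **Event segmentation** — per-sample SNR (max over channels of
   `|x − median| / σ_MAD`) thresholded at 10, binary-eroded (0.25 ms) to
   delete spikes and dilated (40 ms) to recover event tails.
2. **Spectral processing** — per channel: mean subtraction, zero padding
   to 20,000 samples (1 Hz bins at 20 kHz), DFT magnitude; the 1000
   sub-kHz bins of each channel are resampled to 512 points and
   concatenated into the L2-normalized 2048-point classifier input.
3. **Features** — the dominant in-band frequency taken as the wingbeat
   frequency (WBF), harmonic amplitudes/ratios at 2f₀ and 3f₀, spectral
   centroid, duration, energy, and band-integrated polarization and
   dual-wavelength ratios (12 features).
4. **Classification** — three one-vs-all binary methods: *wbf* (the WBF
   scalar alone), *features* (Random Forest on the 12 features), *nn*
   (2048 → 2000 → 1500 → 1000 → 1 ReLU network with dropout 0.5 on the
   last hidden layer, Adam, cross-entropy).
5. **Evaluation** — per target: 333 target + 8×42 other training events
   (669), 50 test events per species (450); accuracy = (TP + TN)/N;
   repeated over randomized folds with 90% bootstrapping intervals
   (5th–95th percentile), hardest-other-species summaries and pairwise
   accuracy matrices.

Since no public sensor recordings of this kind exist, the package
includes a synthetic generator (`wingbeat.simulate`) producing
harmonic wingbeat events, aperiodic "jumper" transients and
channel-ratio structure with known ground truth; it defines the study
conditions under which everything here is tested.  See
`docs/methods.md` for the signal model and all defaults.

## Worked example

```python
import numpy as np
import wingbeat as wb
from wingbeat.evaluate import OneVsAllExperiment

library = wb.default_species_library()          # 9 synthetic species
rec = wb.simulate_recording(library, event_rate=0.4, total_duration=25.0,
                            noise_sd=1.0, seed=11, peak_snr=50.0)
events = wb.detect_events(rec)
print(f"detected {len(events)} events ({len(rec.truth)} inserted)")

feats = wb.full_feature_set(events[0])
print(f"first event: {events[0].duration*1000:.1f} ms, WBF {feats.wbf:.0f} Hz, "
      f"2H/1H {feats.ratio_2h_1h:.2f}, de/co(l1) {feats.depol_ratio_l1:.2f}")

dataset = wb.simulate_labeled_dataset(library, n_per_species=500, seed=1)
res = OneVsAllExperiment(dataset, methods=("wbf", "features"), n_folds=5).fit(seed=1)
print(res.method_means().round(3))

t = "corynoptera_midge"
for m in ("wbf", "features"):
    other = res.hardest_other(t, m)
    vals = res.pairwise_values(t, m, other)
    lo, hi = wb.bootstrap_interval(vals)
    print(f"{t} / {m:8s}: hardest other = {other}, "
          f"median {np.median(vals):.3f} [{lo:.3f}, {hi:.3f}]")
```

prints

```
detected 4 events (4 inserted)
first event: 158.8 ms, WBF 65 Hz, 2H/1H 0.40, de/co(l1) 0.69
           mean  median    std
method
wbf       0.851   0.909  0.116
features  0.972   0.978  0.019
corynoptera_midge / wbf     : hardest other = zygoneura_midge, median 0.500 [0.452, 0.568]
corynoptera_midge / features: hardest other = pod_midge, median 0.840 [0.806, 0.916]
```

The detector recovers all inserted transits.  The first event is a
sawfly-like flyer: 65 Hz fundamental with a decaying second harmonic and
strong depolarization.  Frequency alone separates most species well
(mean accuracy 0.85) but collapses to chance (0.500) on the two sciarid
midges whose WBF distributions overlap by construction — their hardest
pairing under the *wbf* method is each other — while the feature-based
classifier resolves them through harmonic decay and polarization
ratios (0.972 overall).  The bracketed numbers are 90% bootstrapping
intervals over folds.

The same pipeline is scriptable from the shell:

```
wingbeat simulate --seed 1 --out runs/demo
wingbeat detect runs/demo/recording.h5 --out runs/demo
wingbeat featurize runs/demo/recording.h5 --out runs/demo
printf 'methods: [wbf, features]\n' > quick.yaml
wingbeat evaluate --config quick.yaml --seed 1 --folds 2 --out runs/demo/results
wingbeat report --config quick.yaml --results runs/demo/results --out runs/demo/report
```

Without a config, `evaluate` runs the reference design — 100 folds and
the full-size network — which is a long computation; override the
config (methods, `nn_layers`, `nn_epochs`, split counts) and `--folds`
for quick runs.

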