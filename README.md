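# mscrit — multiscale criticality fingerprints of neural recordings

`mscrit` turns a multichannel continuous recording (EEG/MEG sensor data, or
any channels × samples matrix with a sampling rate) into a **multiscale
criticality (MsCr) fingerprint**: a 33-element feature vector describing how
the signatures of critical brain dynamics change with the temporal grain of
analysis. It is aimed at researchers who want a compact, physiologically
interpretable summary of spatiotemporal neural dynamics for group
comparisons — e.g. patients versus controls — without committing to a single
bin width or detection threshold.

## The method

1. **Events.** Each channel is standardized; a suprathreshold excursion
   (|z| > θ, one polarity) contributes one event at its extremum. Thresholds
   run over a grid (2.5–3.5 std for EEG, 3–4 std for MEG) and detected
   avalanche sets are pooled across the grid.
2. **Avalanches.** At temporal scale kΔt (k = 1..10, Δt = 4 ms at the
   250 Hz base rate) events are binned; an avalanche is a maximal run of
   consecutive bins with at least one event on any channel. Its size s is
   the total event count, its duration d the run length; quiet gaps give
   inter-avalanche intervals (IAI).
3. **Exponents.** Per scale k the package fits
   - σ — branching parameter, mean second-bin/first-bin event ratio
     (σ = 1 marks the critical balance between cascade growth and decay),
   - α, τ, δ — truncated discrete power-law MLE exponents of the size,
     duration and IAI distributions, P(x) ∝ x^(−e) on [xmin, xmax],
   - γ — the slope of log⟨s⟩ versus log d,
   - κ, κ_gen — deviance of the size distribution from a reference power law
     (fixed exponent 3/2, or the self-fit exponent), and the fitted
     exponential drop-off scale of the size distribution.
4. **Fingerprint.** Each parameter's scale curve x(kΔt) is summarized by the
   slope/intercept (a_x, b_x) of a line fit over a k-interval (1–5, 3–7,
   6–10), and each of the 10 parameter pairs by the slope/intercept
   (a_{x,y}, b_{x,y}) of one curve regressed on the other. With κ, κ_gen and
   the cutoff this yields 5×2 + 10×2 + 3 = **33 named features** per
   interval.
5. **Statistics.** Feature-wise t-test/ANOVA (or Mann–Whitney/
   Kruskal–Wallis), Benjamini–Hochberg FDR across the 33-feature family, and
   control-referenced z-score deviance fingerprints.

A mean-field branching-process generator (Poisson offspring with tunable
mean σ, Poisson drive, optional rendering into noisy continuous signals)
provides ground-truth data for every stage.

## Worked example

```python
from mscrit import (BranchingConfig, FingerprintConfig, mscr_fingerprint,
                    render_continuous, simulate_branching_raster)

cfg = BranchingConfig(n_channels=32, n_bins=40_000, branching_ratio=0.9,
                      drive_rate=0.01, seed=3)
raster, _ = simulate_branching_raster(cfg)
recording = render_continuous(raster, cfg)           # 250 Hz, 32 channels
fp = mscr_fingerprint(recording, FingerprintConfig(modality="eeg"))[0]
print(fp.features["a_sigma"], fp.features["kappa"])
```

prints (seed 3) `a_sigma = 0.1306` — the branching parameter rises by
≈ 0.13 per Δt of coarse-graining, the scale-dependence of neural gain that
the fingerprint tracks — and `kappa = 0.836`, a subcritical deficit of large
avalanches relative to an ideal s^(−3/2) power law, as expected at branching
ratio 0.9. Running `python examples/03_mscr_fingerprint.py` prints the full
33-feature vector; the other `examples/` scripts cover detection round-trips,
exponent recovery at criticality, and an end-to-end two-cohort comparison
with FDR-corrected feature tests.

A thin CLI mirrors the library:

```bash
mscrit simulate --ratio 1.0 --channels 64 --bins 100000 --seed 7 --render
mscrit fingerprint simulated_recording.tsv --rate 250 --modality eeg
mscrit compare --fingerprints fingerprints.csv --manifest groups.csv --q 0.01
```

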