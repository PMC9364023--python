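# kymoblink

Tools for deciding whether a DNA-bound, fluorescently labeled protein is a
monomer or a homodimer, built around three independent lines of evidence
from single-molecule and bulk experiments on bZIP transcription factors
(cJun, cFos) bound to DNA tightropes:

1. **Quantum-dot blink statistics.** A quantum dot blinks into dark states
   stochastically, so the number of complete dark intervals per
   fixed-duration kymograph is Poisson-distributed. Two dots on one complex
   go simultaneously dark only rarely — the joint dark probability is the
   product of the individual ones — so a dimer's blink *rate* is the square
   of the monomer's. With observation duration *dur* and monomer expectation
   *bl* blinks/kymograph:

   ```
   p_mon(n)   = bl^n e^(-bl) / n!
   bl_dim     = (bl / dur)^2 · dur
   p_blink(n) = α · p_mon(n) + (1 − α) · p_dim(n)
   ```

   A shared *bl* and one mixture amplitude α per dataset are fitted
   simultaneously to two blink histograms by least squares; 100·(1 − α) is
   the percent of molecules that are dimers. Blinks are counted from
   kymographs by per-frame 1D Gaussian fitting: background-only frames fit
   poorly (R² < 0.7) while a genuine spot fits well (R² > 0.9), and that
   goodness-of-fit gap is the blink detector.

2. **Two-color labeling combinatorics.** With two quantum-dot colors mixed
   at equal probability, a dimer's subunits differ in color only half the
   time (AB/BA out of AA/AB/BA/BB), so the observed dual-colored fraction
   underestimates the dimer fraction by a factor of two:
   `dimer_fraction = dual_fraction / (2 p_A p_B e²)` for color probabilities
   p_A, p_B and labeling efficiency e.

3. **Difference spectra.** If two species do not interact, their mixture's
   spectrum equals the sum of the component spectra. FRET between donor and
   acceptor fusions adds a donor-band peak to the acceptor-emission
   excitation scan (450–650 nm); protein binding to consensus DNA changes
   the DNA circular-dichroism band near 281 nm. Band-localized deviations of
   mixture − sum are scored as a z-score calibrated against out-of-band
   noise.

A synthetic-data module simulates all inputs — kymographs of diffusing,
blinking emitters with ground truth, blink-count samples from the mixture,
two-color labeling outcomes, and component/mixture spectra — so the entire
pipeline is testable end to end without any raw microscopy data.

## Worked example

```python
import kymoblink as kb
from kymoblink import blink, kymo

# simulate one 60 s kymograph at 10 frames/s and count its blinks
km, truth = kb.simulate_kymograph(kb.KymoSimParams(seed=42))
track = kymo.fit_kymograph(km)              # per-frame 1D Gaussian fits
on = kb.classify_frames(track)              # R^2 thresholds 0.7 / 0.9
series = kb.count_blinks(on, frame_interval_s=km.frame_interval_s)
print(truth.true_blink_count, series.n_blinks)   # -> 11 11
```

Fitting two simulated blink-count datasets (50 kymographs each, monomer
expectation 10.8 blinks/60 s, true dimer percents 87.1 / 45.8) with the
linked mixture, as in `examples/02_blink_mixture_fit.py`, prints:

```
shared monomer expectation: 10.50 blinks/kymograph (true 10.8)
derived dimer expectation:  1.837 blinks/kymograph (true 1.944)
mostly_dimer: 94.5% +/- 4.8% dimer (true 87.1%)
half_dimer: 48.1% +/- 7.5% dimer (true 45.8%)
combined fit R^2 = 0.858
```

The monomer expectation is shared between the datasets, the dimer
expectation is derived from it (never fitted), and the amplitudes recover
each condition's dimer percent within bootstrap error at this sample size.
The other capabilities are demonstrated one per script in `examples/`; a
thin CLI (`kymoblink simulate-kymo / analyze-kymo / fit-blinks / dual-color
/ spectra / replicate`) wraps the same functions for shell use.

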