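# expectprofile

Tools for simulating and analyzing how **perceptual expectation reshapes
orientation discrimination**.  When an auditory cue predicts a grating's
orientation, discrimination sensitivity does not simply fall off with the
distance between the expected and shown orientations: it is enhanced at the
expected orientation, *suppressed* for nearby orientations, and recovers
farther away — a center-surround (Mexican-hat) profile in feature space.
This package provides, for psychophysicists and computational modelers:

* a **synthetic-observer generator** for three cue-based paradigms
  (QUEST-controlled 2AFC discrimination, continuous orientation adjustment,
  fixed-offset 2AFC discrimination), so every analysis stage is testable
  without human data;
* a **QUEST adaptive staircase** estimating 75%-correct thresholds (DT);
* **discrimination-sensitivity profiles** DS(d) = DT_baseline − DT_main and
  Mexican-hat vs Gaussian model comparison via AICc/BIC likelihood ratios
  and Bayes factors;
* **channel-tuning models** — equal-energy *sharpening*, location *shift*,
  and a *combined* bank of Gaussian channels fit to interpolated population
  response profiles, compared by RMSD = sqrt(SSE/(N−K));
* a **von Mises + uniform mixture** MLE for adjustment errors (shift mu,
  precision s.d. = sqrt(1/k), guessing g);
* **cumulative-Gaussian psychometric fits** (PSE = shift index, slope =
  sharpening index);
* the matching **group statistics** (paired/one-sample t with Cohen's d,
  repeated-measures ANOVA with partial eta², tie-corrected Wilcoxon z with
  r = z/√n).

The core model-comparison machinery, in the field's notation: for a DS
profile y(x) over distance x, the monotonic and center-surround candidates

    Gaussian:     y = y0 + 2A/(w·√(2π)) · exp(−2(x/w)²)
    Mexican hat:  y = 2H/(√(3m)·π^¼) · exp(−x²/2m²) · (1 − x²/m²) + y1

are each fit by least squares (3 parameters each), and compared with

    AICc = N·ln(RSS/N) + 2K + 2K(K+1)/(N−K−1),  BIC = N·ln(RSS/N) + K·ln N
    LR = e^((AICc_G − AICc_M)/2),               BF = e^((BIC_G − BIC_M)/2)

where LR, BF > 1 favor the Mexican hat.  See `docs/methods.md` for the full
model descriptions, defaults, and numerical choices.

## Worked example

Simulate a 24-participant cohort with a center-surround ground truth
through full adaptive staircases, then test for the inhibitory surround and
compare profile shapes:

```python
import expectprofile as ep
from expectprofile import experiments, shapes, stats

thresholds = experiments.simulate_profile_cohort(24, tasks=("OD",), seed=0)
group = shapes.compute_ds(thresholds, "OD")
print({float(d): float(v) for d, v in zip(group.distances, group.ds.round(3))})

tidy = shapes.ds_table(thresholds, "OD")
wide = tidy.pivot(index="participant", columns="distance", values="ds")
print(stats.paired_t(wide[20.0], wide[0.0]))
print(stats.paired_t(wide[20.0], wide[40.0]))
comp = shapes.compare_shapes(group, seed=0)
print(f"LR = {comp['lr']:.4g}, BF = {comp['bf']:.4g} -> {comp['favored']}")
```

Output:

```
{0.0: 0.835, 10.0: 0.169, 20.0: -0.346, 30.0: -0.14, 40.0: 0.016}
one-sample t: stat=-15.864, df=23, p=7.041e-14, cohen_d=-3.238
one-sample t: stat=-6.330, df=23, p=1.849e-06, cohen_d=-1.292
LR = 9.716e+05, BF = 9.716e+05 -> mexican
```

DS peaks at the expected orientation (+0.84 deg of threshold reduction),
dips *below zero* at distance 20 (worse than baseline), and recovers by
distance 40; both post-hoc contrasts are significant and the evidence ratio
overwhelmingly favors the Mexican hat — the center-surround signature.

The numbered drivers under `analysis/` run the full study pipeline and
write tables under `results/`:

```bash
python analysis/01_simulate_experiments.py      # cohorts for all three experiments
python analysis/02_sensitivity_profiles.py      # DS, ANOVA, shape comparison
python analysis/03_channel_models.py            # sharpening/shift/combined fits
python analysis/04_adjustment_mixture.py        # mixture decomposition
python analysis/05_discrimination_psychometric.py  # PSE/slope analysis
```

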