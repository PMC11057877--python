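# anemonevision

Receptor-noise-limited (RNL) colour-vision modelling and psychophysical
threshold analysis for a UV-sensitive, tetrachromatic reef fish
(*Amphiprion ocellaris*-like visual system).

Behavioural colour-discrimination experiments on anemonefish use a
five-channel LED display (UV 367, violet 395, blue 466, green 526, red
629 nm) to present a coloured target pixel among grey distractors. This
package implements the full analysis chain for such an experiment:

1. **Pigment analysis** — estimate visual-pigment λmax from absorbance
   scans by regressing the long-wavelength limb between 30% and 70% of
   peak absorbance and inverting the Govardovskii A1/A2 rhodopsin
   template at the 50% crossing; extract lens T50 from transmission
   curves normalised at 700 nm.
2. **RNL visual model** — von Kries-adapted quantum catches
   *q*ᵢ = ∫S(λ)Rᵢ(λ)dλ / ∫S_b(λ)Rᵢ(λ)dλ, log signals *f*ᵢ = ln *q*ᵢ,
   per-channel noise *e*ᵢ = σᵢ/√ηᵢ, and chromatic distance ΔS (the
   noise-weighted opponent distance, in just-noticeable-difference
   units); a distance-preserving embedding into noise-corrected *xyz*
   coordinates with hue angles (elevation Θ, azimuth φ), complementary
   pair detection, and non-spectral colour classification.
3. **Stimulus design** — colour lines radiating from the achromatic point
   (constant hue, increasing saturation), 13 grey distractors within 1 ΔS
   of grey and 0.3–0.8 ΔS of each other, and per-target distractor
   subsets that bracket the target's intensity in every cone channel.
4. **Psychophysics** — maximum-likelihood psychometric fits
   P(correct | ΔS) = γ + (1−γ−λ)·F((ΔS−m)/s) with the discrimination
   threshold at P = 0.5, bootstrap confidence intervals, and per-set
   summaries split by UV contrast sign.
5. **Model comparison** — rescore every stimulus under candidate visual
   models (the tetrachromat and each drop-one trichromat, σ scanned over
   [0.05, 0.15]), refit all thresholds, and rank models by mean
   |threshold − 1 ΔS|.
6. **Synthetic data** — a generator that emulates the whole study with
   known ground truth (Gaussian LED channels, logistic lens with T50
   334 nm, cone λmax 386/497/515/535 nm, σ = 0.11/0.14, cone ratio
   1:2:1:1, planted per-set thresholds), so every stage is testable
   without the original data.

## Worked example

```python
from anemonevision import synth, stimuli, pipeline
from anemonevision.psychometric import summarise_thresholds

display = synth.gen_led_display()
vs = synth.gen_visual_system()           # 4 cones behind the lens, e = (0.110, 0.099, 0.140, 0.140)
lines = synth.gen_colour_lines(display, vs)
greys = stimuli.select_grey_set(display, vs, n=13, seed=1)
trials = synth.gen_choice_data(lines, seed=1)

fits = pipeline.fit_thresholds(trials)
summary = summarise_thresholds(fits)
print(summary[["colour_set", "mean", "sem"]].sort_values("mean").to_string(index=False))
```

prints (seed 1):

```
  colour_set     mean      sem
violet-green 0.432658 0.015862
          UV 0.771717 0.050831
      orange 0.773512 0.028287
     UV-blue 0.793932 0.064327
      UV-red 0.929203 0.013146
         red 0.987451 0.024266
       green 1.199604 0.029785
        blue 1.422030 0.065609
      purple 1.588134 0.051452
```

Each `mean` is a colour set's discrimination threshold in ΔS (JND) units,
averaged over the five fish tested on that set, with its standard error.
The UV-bearing sets (violet-green, UV-blue, UV, UV-red) sit well below
the non-UV sets (green, blue, purple) — the ordering the generator
plants and the fits recover.

A single command runs every stage end to end and writes CSV/JSON reports:

```bash
anemonevision run --out results/run --seed 1
```

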