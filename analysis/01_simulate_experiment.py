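#!/usr/bin/env python
"""Generate the synthetic behavioural experiment.

Builds the five-channel LED display, the tetrachromatic visual system
(lens-filtered cone templates), nine colour lines radiating from grey, 13
grey distractors, and per-trial choice data from the planted psychometric
functions.  Everything is written under results/experiment/.
"""

from pathlib import Path

from anemonevision.synth import SyntheticConfig, build_experiment, generate_experiment

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "experiment"


def main() -> None:
    cfg = SyntheticConfig(seed=SEED)
    experiment = build_experiment(cfg)
    generate_experiment(OUT, cfg, experiment=experiment)
    trials = experiment["trials"]
    print(f"display channels peak at {experiment['display'].peak_wavelengths} nm")
    print(f"{len(experiment['lines'])} colour lines, {len(experiment['greys'])} greys")
    print(f"{len(trials)} trials written to {OUT/'trials.csv'}")
    print(f"controls correct: {trials[trials.is_control == 1].correct.sum()} (guess rate 0)")


if __name__ == "__main__":
    main()
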