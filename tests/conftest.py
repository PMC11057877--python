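import numpy as np
import pytest
from hypothesis import settings

from anemonevision import stimuli as st
from anemonevision import synth

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def display():
    return synth.gen_led_display()


@pytest.fixture(scope="session")
def visual_system():
    return synth.gen_visual_system()


@pytest.fixture(scope="session")
def catch_model(display, visual_system):
    return st._CatchModel(display, visual_system, st.DEFAULT_GRID)


@pytest.fixture(scope="session")
def colour_lines(display, visual_system):
    return synth.gen_colour_lines(display, visual_system)


@pytest.fixture(scope="session")
def grey_set(display, visual_system):
    return st.select_grey_set(display, visual_system, n=13, seed=0)


@pytest.fixture(scope="session")
def scan_inputs(display, visual_system, colour_lines, grey_set):
    """Choice data planted at 1 ΔS under the generating model, plus the
    catch tables the model scan needs (targets and grey reference)."""
    from anemonevision import pipeline as pl
    from anemonevision.rnl import quantum_catch

    planted = {k: 1.0 for k in synth.PLANTED_THRESHOLDS}
    trials = synth.gen_choice_data(colour_lines, planted_m=planted, seed=11)
    trials = trials[trials.is_control == 0]
    scored = pl.score_stimuli(display, visual_system, colour_lines, grey_set)
    target_catches = scored.set_index("target_id")[
        ["colour_set"] + [f"q_{lab}" for lab in visual_system.labels]
    ].rename(columns={f"q_{lab}": lab for lab in visual_system.labels})
    grey_catch = quantum_catch(
        st.average_grey_spectrum(display, grey_set),
        display.background,
        visual_system,
    )
    reference = dict(zip(visual_system.labels, grey_catch.q))
    return trials, target_catches, reference
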