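import numpy as np
import pytest

from oddbeat import erp, paradigm, synth


@pytest.fixture(scope="session")
def small_plan():
    """A short passive-listening session (2 long + 2 short trials)."""
    return paradigm.build_session(n_pairs=2, total_min=7.5, seed=3)


@pytest.fixture(scope="session")
def noiseless_subject(small_plan):
    """Full pipeline run on a zero-noise synthetic subject (gain 1.5).

    Yields (params, evoked dict, epoch times, windows) — shared by several
    identity checks since the simulation is the slow part.
    """
    params = synth.SubjectParams(gain=1.5, noise_sd=0.0)
    rec = synth.simulate_recording(small_plan, params, rate=500.0, seed=0)
    markers = erp.decode_triggers(rec.channel("TRIG"), rec.rate)
    rec500, m500 = erp.preprocess(rec, markers)
    epochs = erp.baseline_correct(erp.extract_epochs(rec500, m500))
    epochs, _ = erp.reject_artifacts(epochs)
    evoked = erp.average_evoked(epochs)
    windows = erp.find_component_windows(evoked, epochs.times)
    return params, evoked, epochs.times, windows
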