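"""Simulate one subject's EEG session and recover their expectancy gain.

A synthetic subject responds to every beat with an N1-P2 kernel; deviant
beats evoke the same kernel scaled by (1 + g), where g is the subject's
expectancy gain. The pipeline (trigger decoding, 500-Hz downsampling,
30-Hz FIR, epoching, baseline, artifact rejection, evoked averaging,
window finding) produces the timing response index (TRI): the deviant
N1-P2 magnitude minus the standard N1-P2 magnitude. For a noiseless
subject TRI / standard magnitude equals g exactly; with realistic noise
it comes close.
"""

from oddbeat import erp, synth
from oddbeat.paradigm import build_session

params = synth.SubjectParams(gain=1.2, noise_sd=15.0)
plan = build_session(n_pairs=8, total_min=30.0, seed=7)

rec = synth.simulate_recording(plan, params, rate=500.0, seed=7)
markers = erp.decode_triggers(rec.channel("TRIG"), rec.rate)
rec500, m500 = erp.preprocess(rec, markers)
epochs = erp.baseline_correct(erp.extract_epochs(rec500, m500))
epochs, report = erp.reject_artifacts(epochs)
evoked = erp.average_evoked(epochs)
windows = erp.find_component_windows(evoked, epochs.times)
result = erp.compute_tri(evoked, epochs.times, windows, variant="mean50")

print(f"kept epochs: {report['kept']}")
print(f"N1/P2 windows (standard): "
      f"{[round(1000 * t) for t in windows.n1_window['standard']]} / "
      f"{[round(1000 * t) for t in windows.p2_window['standard']]} ms")
print(f"deviant N1-P2 magnitude:  {result.magnitude['deviant']:.2f} uV")
print(f"standard N1-P2 magnitude: {result.magnitude['standard']:.2f} uV")
print(f"TRI: {result.tri:.2f} uV -> gain estimate "
      f"{result.tri / result.magnitude['standard']:.2f} (true gain {params.gain})")
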