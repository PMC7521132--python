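"""File I/O: events TSV (BIDS-events-like), recordings (TSV, EDF via mne),
WAV tracks, tap-onset TSV, and evoked/TRI outputs.

Recordings are written as tab-separated numeric text, one column per
channel, with a single ``# rate_hz=...`` comment line carrying the sample
rate; EDF files are read through :mod:`mne` when it is installed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .erp import ContinuousRecording, TRIResult
from .tapping import TapSeries

__all__ = [
    "write_events_tsv",
    "read_events_tsv",
    "write_recording_tsv",
    "read_recording_tsv",
    "read_recording_edf",
    "write_wav",
    "read_wav",
    "write_taps_tsv",
    "read_taps_tsv",
    "write_evoked_tsv",
    "tri_results_frame",
]


def write_events_tsv(events: pd.DataFrame, path, duration: float = 0.05) -> None:
    """Write a BIDS-events-like TSV: onset (s, 6 decimals), duration,
    trial_type, trial_index, condition."""
    out = pd.DataFrame(
        {
            "onset": events["onset"].map(lambda v: f"{v:.6f}"),
            "duration": f"{duration:.6f}",
            "trial_type": events["label"],
            "trial_index": events["trial_index"],
            "condition": events["condition"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return pd.DataFrame(
        {
            "onset": df["onset"].astype(float),
            "label": df["trial_type"],
            "condition": df["condition"],
            "trial_index": df["trial_index"].astype(int),
        }
    )


def write_recording_tsv(rec: ContinuousRecording, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={rec.rate:g} units={rec.units}\n")
        fh.write("\t".join(rec.ch_names) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.6f", delimiter="\t")


def read_recording_tsv(path) -> ContinuousRecording:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError("missing '# rate_hz=' header line")
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        names = fh.readline().strip().split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return ContinuousRecording(
        data.T, float(meta["rate_hz"]), names, units=meta.get("units", "uV")
    )


def read_recording_edf(path) -> ContinuousRecording:
    """Read an EDF recording through mne; physical units converted to uV."""
    import mne  # optional dependency

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne loads volts
    return ContinuousRecording(data, float(raw.info["sfreq"]), list(raw.ch_names))


def write_wav(path, track: np.ndarray, rate: float = 44100.0) -> None:
    from scipy.io import wavfile

    wavfile.write(path, int(rate), np.asarray(track, dtype=np.float32))


def read_wav(path) -> tuple[np.ndarray, float]:
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    data = np.asarray(data, dtype=float)
    if data.dtype.kind == "i":  # pragma: no cover - PCM normalisation
        data = data / np.iinfo(data.dtype).max
    return data, float(rate)


def write_taps_tsv(taps: TapSeries, path) -> None:
    pd.DataFrame({"onset": [f"{t:.6f}" for t in taps.onsets]}).to_csv(
        path, sep="\t", index=False
    )


def read_taps_tsv(path, source: str = "detected") -> TapSeries:
    df = pd.read_csv(path, sep="\t")
    return TapSeries(df["onset"].astype(float).to_numpy(), source=source)


def write_evoked_tsv(evoked: dict, times: np.ndarray, path) -> None:
    """Evoked potentials as TSV: time_ms column + one column per condition."""
    cols = {"time_ms": [f"{1000*t:.1f}" for t in times]}
    for cond, wave in sorted(evoked.items()):
        cols[cond] = [f"{v:.6f}" for v in wave]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def tri_results_frame(results: dict) -> pd.DataFrame:
    """Flatten {subject_id: {variant: TRIResult}} into a tidy DataFrame."""
    rows = []
    for sid, by_variant in results.items():
        for variant, r in by_variant.items():
            rows.append(
                {
                    "subject": sid,
                    "variant": variant,
                    "tri": r.tri,
                    "deviant_magnitude": r.magnitude["deviant"],
                    "standard_magnitude": r.magnitude["standard"],
                    "deviant_n1_mean": r.n1_mean["deviant"],
                    "deviant_p2_mean": r.p2_mean["deviant"],
                    "standard_n1_mean": r.n1_mean["standard"],
                    "standard_p2_mean": r.p2_mean["standard"],
                }
            )
    return pd.DataFrame(rows)
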