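"""On-disk session format: one directory per participant.

    <participant>/
        events.csv   event_type, time_s, is_withdrawal
        ecg.csv      time_s, value          (mV, 2048 Hz)
        gsr.csv      time_s, value          (uS, 2048 Hz)
        pupil.csv    time_s, value          (mm, 300 Hz; empty value = missing)
        meta.json    participant_id, pclm_score, rng_seed, sampling rates, ...

Times are seconds from session start (t = 0 at the first sample).  All
files are UTF-8 comma-separated text with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .signal_prep import Channel, RawRecording
from .synth import EventSpec, SyntheticSession


class SessionFormatError(ValueError):
    """A participant directory is missing or malformed."""


def _write_channel(path: Path, ch: Channel) -> None:
    df = pd.DataFrame({"time_s": ch.times(), "value": ch.samples})
    df.to_csv(path, index=False, float_format="%.6g", na_rep="")


def _read_channel(path: Path, rate: float) -> Channel:
    if not path.is_file():
        raise SessionFormatError(f"missing channel file {path.name}")
    df = pd.read_csv(path)
    if not {"time_s", "value"} <= set(df.columns):
        raise SessionFormatError(f"{path.name}: expected columns time_s,value")
    return Channel(df["value"].to_numpy(dtype=float), rate)


def write_session_dir(session: SyntheticSession, out_dir: str | Path) -> Path:
    """Write a synthetic session (with raw channels) as a participant dir."""
    if session.recording is None:
        raise ValueError("session has no raw recording (generated with include_raw=False)")
    out = Path(out_dir) / session.profile.participant_id
    out.mkdir(parents=True, exist_ok=True)

    rows = [
        {"event_type": spec.name, "time_s": t, "is_withdrawal": spec.is_withdrawal}
        for spec in session.events
        for t in spec.occurrence_times
    ]
    pd.DataFrame(rows).sort_values("time_s").to_csv(out / "events.csv", index=False)

    rec = session.recording
    _write_channel(out / "ecg.csv", rec.ecg)
    _write_channel(out / "gsr.csv", rec.gsr)
    _write_channel(out / "pupil.csv", rec.pupil)

    prof = session.profile
    meta = {
        "participant_id": prof.participant_id,
        "pclm_score": prof.pclm_score,
        "rng_seed": prof.rng_seed,
        "session_duration_s": session.session_duration,
        "rates_hz": {"ecg": rec.ecg.rate, "gsr": rec.gsr.rate, "pupil": rec.pupil.rate},
        "habituation_gain": prof.habituation_gain,
        "baseline_hr": prof.baseline_hr,
        "baseline_scl": prof.baseline_scl,
        "blink_rate": prof.blink_rate,
        "noise_sd": prof.noise_sd,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    return out


def read_participant_dir(path: str | Path) -> tuple[list[EventSpec], RawRecording, dict]:
    """Load one participant directory; raises SessionFormatError on problems."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.is_file():
        raise SessionFormatError(f"{path.name}: missing meta.json")
    meta = json.loads(meta_path.read_text())
    rates = meta.get("rates_hz", {})

    ev_path = path / "events.csv"
    if not ev_path.is_file():
        raise SessionFormatError(f"{path.name}: missing events.csv")
    ev = pd.read_csv(ev_path)
    specs = []
    for (name, wd), grp in ev.groupby(["event_type", "is_withdrawal"]):
        specs.append(
            EventSpec(str(name), sorted(grp["time_s"].astype(float)), is_withdrawal=bool(wd))
        )

    recording = RawRecording(
        ecg=_read_channel(path / "ecg.csv", float(rates.get("ecg", 2048.0))),
        gsr=_read_channel(path / "gsr.csv", float(rates.get("gsr", 2048.0))),
        pupil=_read_channel(path / "pupil.csv", float(rates.get("pupil", 300.0))),
    )
    return specs, recording, meta
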