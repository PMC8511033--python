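"""File-format dialects shared by every pipeline stage.

All tabular artifacts are plain CSV with documented headers; stimulus
geometry is JSON; rendered stimuli are 8-bit grayscale PNG; configs are
YAML or JSON (both accepted).  Times are seconds from session start;
epoch times are seconds from stimulus onset.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import Epoch, PupilTrace
from .stimgen import DotArrayStimulus, GeometryConfig, SpectrumProfile

TRACE_COLUMNS = ["time_s", "pupil_mm", "gaze_x_deg", "gaze_y_deg", "valid"]
EVENT_COLUMNS = ["trial", "onset_s", "offset_s", "numerosity", "connectedness", "polarity"]


def write_trace(trace: PupilTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_trace(path) -> PupilTrace:
    return PupilTrace.from_frame(pd.read_csv(path))


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_epochs(epochs: list[Epoch], path) -> None:
    from .preprocess import epochs_to_frame

    epochs_to_frame(epochs).to_csv(path, index=False, float_format="%.6f")


def read_epochs(path) -> list[Epoch]:
    df = pd.read_csv(path)
    cond_cols = [c for c in df.columns if c not in ("trial", "rel_time_s", "pupil_mm", "valid")]
    out = []
    for trial, g in df.groupby("trial", sort=True):
        out.append(
            Epoch(
                trial_id=int(trial),
                rel_time=g["rel_time_s"].to_numpy(float),
                pupil=g["pupil_mm"].to_numpy(float),
                valid=g["valid"].to_numpy(bool),
                condition={c: g[c].iloc[0] for c in cond_cols},
            )
        )
    return out


def write_stimulus(stimulus: DotArrayStimulus, path, extra: dict | None = None) -> None:
    d = stimulus.to_dict()
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=1))


def read_stimulus(path) -> DotArrayStimulus:
    return DotArrayStimulus.from_dict(json.loads(Path(path).read_text()))


def write_stimulus_png(stimulus: DotArrayStimulus, config: GeometryConfig, path) -> None:
    """8-bit grayscale render (luminance linearly mapped to 0-255)."""
    from PIL import Image

    from .stimgen import rasterize

    img, _ = rasterize(stimulus, config)
    lo, hi = config.luminance_min, config.luminance_max
    g = np.clip((img - lo) / (hi - lo) * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(g, mode="L").save(path)


def write_spectrum(profile: SpectrumProfile, path) -> None:
    pd.DataFrame(
        {"frequency_cpd": profile.spatial_frequency, "amplitude": profile.amplitude}
    ).to_csv(path, index=False)


def read_spectrum(path) -> SpectrumProfile:
    df = pd.read_csv(path)
    return SpectrumProfile(
        spatial_frequency=df["frequency_cpd"].to_numpy(float),
        amplitude=df["amplitude"].to_numpy(float),
    )


def write_responses(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_responses(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config_file(path) -> dict:
    """YAML or JSON config; the two are interchangeable here."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def dump_config_file(cfg: dict, path) -> None:
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(cfg, indent=1))
    else:
        p.write_text(yaml.safe_dump(cfg, sort_keys=False))
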