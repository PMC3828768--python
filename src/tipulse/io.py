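"""File I/O for the standard artifact formats.

Frame stacks are multi-page 8-bit grayscale TIFF (tifffile); audio is PCM/
float WAV (scipy.io.wavfile); field potentials are single-column CSV whose
header names the sampling rate, or WAV; ROI tables and run configs are YAML;
ground truth and reports are JSON.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.io import wavfile

from .coherence import FieldPotentialTrace
from .extraction import BrightnessTrace, FrameStack, MovementTrace, RegionSpec
from .stimdetect import AudioTrack, StimulusEvents


def save_frames(stack: FrameStack, path: str | Path) -> None:
    tifffile.imwrite(str(path), stack.frames.astype(np.uint8),
                     metadata={"fps": stack.fps})


def load_frames(path: str | Path, fps: float = 29.97) -> FrameStack:
    """Read a multi-page TIFF; ``fps`` is used if the file carries no rate."""
    with tifffile.TiffFile(str(path)) as tf:
        frames = tf.asarray()
        meta = tf.shaped_metadata or tf.imagej_metadata
        if isinstance(meta, (list, tuple)) and meta:
            meta = meta[0]
        if isinstance(meta, dict) and "fps" in meta:
            fps = float(meta["fps"])
    if frames.ndim == 2:
        frames = frames[None]
    return FrameStack(frames, fps=fps)


def save_audio(audio: AudioTrack, path: str | Path) -> None:
    wavfile.write(str(path), int(round(audio.fs)), audio.values.astype(np.float32))


def load_audio(path: str | Path) -> AudioTrack:
    fs, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return AudioTrack(data.astype(float), fs=float(fs))


def save_field_potential(fp: FieldPotentialTrace, path: str | Path) -> None:
    """Single-column CSV; the header cell names the sampling rate in Hz."""
    header = f"value_fs{fp.fs:g}Hz"
    pd.DataFrame({header: fp.values}).to_csv(path, index=False)


def load_field_potential(path: str | Path) -> FieldPotentialTrace:
    path = Path(path)
    if path.suffix.lower() == ".wav":
        fs, data = wavfile.read(str(path))
        data = np.asarray(data, dtype=float)
        if data.ndim > 1:
            data = data.mean(axis=1)
        return FieldPotentialTrace(data, fs=float(fs))
    df = pd.read_csv(path)
    header = df.columns[0]
    m = re.search(r"fs([\d.]+)Hz", header)
    if not m:
        raise ValueError(f"CSV header {header!r} does not name the sampling rate")
    return FieldPotentialTrace(df[header].to_numpy(dtype=float), fs=float(m.group(1)))


def save_trace_csv(trace: BrightnessTrace | MovementTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": trace.times, "value": trace.values, "region": trace.region}
    ).to_csv(path, index=False)


def save_events_csv(events: StimulusEvents, path: str | Path) -> None:
    pd.DataFrame(
        {
            "modality": events.modality,
            "onset_s": events.onsets_s,
            "offset_s": events.offsets_s,
            "duration_s": events.durations_s,
        }
    ).to_csv(path, index=False)


def load_rois(path: str | Path) -> dict[str, RegionSpec]:
    """ROI table from YAML/JSON: name -> [row0, col0, row1, col1]."""
    raw = yaml.safe_load(Path(path).read_text())
    return {name: RegionSpec(name, *map(int, rect)) for name, rect in raw.items()}


def save_rois(rois: dict[str, RegionSpec], path: str | Path) -> None:
    raw = {name: [r.row0, r.col0, r.row1, r.col1] for name, r in rois.items()}
    Path(path).write_text(yaml.safe_dump(raw))
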