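"""Reading and writing recordings, coordinates and segment archives.

Recordings are stored as uncompressed-friendly ``.npz`` array archives with
channel names and the sampling rate embedded; electrode coordinates travel
as TSV (channel, x, y, z in millimetres). EDF files are read through MNE
when it is installed (``pip install e2sgan[edf]``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Recording, SegmentSet


def write_recording(path, rec: Recording) -> None:
    np.savez_compressed(
        path, data=rec.data, rate=np.float64(rec.rate),
        channel_names=np.array(rec.channel_names),
        coords=np.array([rec.coords[c] for c in rec.channel_names])
        if rec.coords else np.zeros((0, 3)),
    )


def read_recording(path) -> Recording:
    with np.load(path, allow_pickle=False) as f:
        names = [str(c) for c in f["channel_names"]]
        coords = None
        if f["coords"].shape[0] == len(names):
            coords = {c: f["coords"][i] for i, c in enumerate(names)}
        return Recording(f["data"], float(f["rate"]), names, coords=coords)


def read_edf(path, exclude: list[str] | None = None) -> Recording:
    """Load an EDF recording via MNE (optional dependency)."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("EDF support requires mne: pip install e2sgan[edf]") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(raw.get_data() * 1e6, float(raw.info["sfreq"]),
                     list(raw.ch_names), exclude_channels=exclude or [])


def write_coords_tsv(path, coords: dict) -> None:
    rows = [(c, *np.asarray(v, dtype=float)) for c, v in coords.items()]
    pd.DataFrame(rows, columns=["channel", "x", "y", "z"]).to_csv(
        path, sep="\t", index=False)


def read_coords_tsv(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return {r.channel: np.array([r.x, r.y, r.z]) for r in df.itertuples()}


def write_segments(path, segs: SegmentSet) -> None:
    path = Path(path)
    np.savez_compressed(path, segments=segs.segments,
                        start_indices=segs.start_indices)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "channel": segs.channel, "rate": segs.rate,
        "n_segments": int(len(segs)), "window": int(segs.segments.shape[1]),
    }))


def read_segments(path) -> SegmentSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path, allow_pickle=False) as f:
        return SegmentSet(f["segments"], f["start_indices"],
                          meta["channel"], meta["rate"])
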