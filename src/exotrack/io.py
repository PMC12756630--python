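"""TIFF and CSV input/output."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .preprocessing import ImageStack

__all__ = ["read_stack", "write_stack", "write_detections_csv",
           "write_tracks_csv", "write_traces_csv", "write_events_csv"]


def read_stack(path: str | Path, pixel_size_nm: float | None = None,
               frame_interval_s: float | None = None) -> ImageStack:
    """Read a multi-page grayscale TIFF/OME-TIFF into an ImageStack.

    8/16-bit integer data are rescaled by the dtype maximum so downstream
    code always sees floats; float data pass through unchanged.
    """
    data = tifffile.imread(str(path))
    origin = str(data.dtype)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    return ImageStack(data, dtype_origin=origin,
                      pixel_size_nm=pixel_size_nm,
                      frame_interval_s=frame_interval_s)


def write_stack(path: str | Path, stack: ImageStack | np.ndarray) -> None:
    """Write a stack as a float32 multi-page TIFF."""
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    tifffile.imwrite(str(path), data.astype(np.float32))


def write_detections_csv(path: str | Path, particles) -> None:
    from .detection import particles_to_frame

    particles_to_frame(particles).to_csv(path, index=False)


def write_tracks_csv(path: str | Path, tracks) -> None:
    rows = [
        {"track_id": tr.track_id, "frame": f, "y": y, "x": x}
        for tr in tracks for f, (y, x) in zip(tr.frames, tr.positions)
    ]
    pd.DataFrame(rows, columns=["track_id", "frame", "y", "x"]).to_csv(
        path, index=False)


def write_traces_csv(path: str | Path, traces) -> None:
    rows = [
        {"track_id": t.track_id, "frame": t.start_frame + i,
         "intensity": v}
        for t in traces for i, v in enumerate(t.values)
    ]
    pd.DataFrame(rows, columns=["track_id", "frame", "intensity"]).to_csv(
        path, index=False)


def write_events_csv(path: str | Path, events) -> None:
    rows = [
        {"track_id": e.track_id, "onset": e.onset_frame,
         "peak": e.peak_frame, "loss": e.loss_frame,
         "baseline": e.baseline,
         "peak_over_baseline": e.peak_over_baseline}
        for e in events
    ]
    pd.DataFrame(rows, columns=["track_id", "onset", "peak", "loss",
                                "baseline", "peak_over_baseline"]).to_csv(
        path, index=False)
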