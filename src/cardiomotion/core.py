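"""Core data containers shared across the analysis stages.

The raw unit of the imaging assays is a short bright-field movie of a beating
cardiomyocyte monolayer or tissue (:class:`FrameSequence`); the derived unit is
a per-frame-pair motion-amplitude time series (:class:`MotionSignal`), i.e. the
spatially integrated optical-flow magnitude expressed as a speed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FrameSequence", "MotionSignal"]


@dataclass
class FrameSequence:
    """An ordered stack of equal-shape grayscale frames.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Intensity frames, any float or integer dtype.
    frame_interval_s : float
        Time between consecutive frames in seconds (e.g. 1/37 for the
        37 fps high-content screening movies).
    pixel_size_um : float, optional
        Physical pixel size; when present downstream speeds are reported in
        um/s instead of px/s.
    source_id : str
        Free-text provenance tag (file name, plate/well address, ...).
    """

    frames: np.ndarray
    frame_interval_s: float
    pixel_size_um: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n, h, w) stack, got ndim={self.frames.ndim}"
            )
        if self.n_frames < 2:
            raise ValueError("a frame sequence needs at least 2 frames")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive when given")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_s

    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval_s

    # ------------------------------------------------------------------ I/O
    def to_tiff(self, path: str | Path) -> None:
        """Write the stack as a multi-page TIFF (float32)."""
        import tifffile

        tifffile.imwrite(str(path), self.frames.astype(np.float32))

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        frame_interval_s: float,
        pixel_size_um: float | None = None,
    ) -> "FrameSequence":
        import tifffile

        frames = tifffile.imread(str(path))
        return cls(
            frames=np.asarray(frames),
            frame_interval_s=frame_interval_s,
            pixel_size_um=pixel_size_um,
            source_id=str(path),
        )

    @classmethod
    def from_video(
        cls,
        path: str | Path,
        frame_interval_s: float,
        pixel_size_um: float | None = None,
    ) -> "FrameSequence":
        """Read an AVI (or any imageio-readable movie), converting to grayscale."""
        import imageio.v3 as iio

        raw = iio.imread(str(path))
        raw = np.asarray(raw)
        if raw.ndim == 4:  # (n, h, w, channels) -> luminance
            raw = raw[..., :3].mean(axis=-1)
        return cls(
            frames=raw,
            frame_interval_s=frame_interval_s,
            pixel_size_um=pixel_size_um,
            source_id=str(path),
        )


@dataclass
class MotionSignal:
    """Per-frame-pair motion amplitude (a speed) over time.

    ``v[k]`` is the spatial summary of the optical-flow magnitude between
    frames ``k`` and ``k+1``, in units per second; ``t[k]`` is stamped at the
    midpoint of the pair.
    """

    t: np.ndarray
    v: np.ndarray
    units: str = "px_per_s"
    source_id: str = ""
    meta: dict = field(default_factory=dict)

    _ALLOWED_UNITS = ("px_per_s", "um_per_s", "signal_per_s")

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape or self.t.ndim != 1:
            raise ValueError("t and v must be 1-D arrays of equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.v < 0):
            raise ValueError("motion amplitude must be non-negative")
        if self.units not in self._ALLOWED_UNITS:
            raise ValueError(f"units must be one of {self._ALLOWED_UNITS}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        """Median sample interval (s)."""
        return float(np.median(np.diff(self.t))) if len(self.t) > 1 else np.nan

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.t, "value": self.v}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, units: str = "px_per_s") -> "MotionSignal":
        df = pd.read_csv(path, comment="#")
        return cls(
            t=df["time_s"].to_numpy(),
            v=df["value"].to_numpy(),
            units=units,
            source_id=str(path),
        )


def write_json_sidecar(path: str | Path, payload: dict) -> None:
    """Write ground truth / provenance next to a generated artifact.

    Dataclasses and numpy arrays are converted to plain JSON types.
    """

    def _default(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default))
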