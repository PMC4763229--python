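"""In-memory containers for flow events and imaging scenes, with text/TIFF IO."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

LABEL_COLUMN = "label"
SUBPOP_COLUMN = "subpopulation"
TRANSFECTED_COLUMN = "transfected"
_SPECIAL = (LABEL_COLUMN, SUBPOP_COLUMN, TRANSFECTED_COLUMN)


@dataclass
class FlowSample:
    """Per-event multichannel intensity table with optional ground truth.

    ``events`` is an (n_events, n_channels) array of raw (non-negative) or
    compensated intensities; ``labels`` / ``subpop_labels`` / ``transfected``
    carry simulation ground truth when present.
    """

    channels: list[str]
    events: np.ndarray
    labels: np.ndarray | None = None
    subpop_labels: np.ndarray | None = None
    transfected: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 2 or self.events.shape[1] != len(self.channels):
            raise ValueError(
                f"events shape {self.events.shape} does not match "
                f"{len(self.channels)} channels"
            )
        for name in ("labels", "subpop_labels", "transfected"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if len(arr) != len(self.events):
                    raise ValueError(f"{name} length {len(arr)} != n_events")
                setattr(self, name, arr)

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(
                f"channel {channel!r} not in sample (channels: {self.channels})"
            ) from None

    def intensity(self, channel: str) -> np.ndarray:
        return self.events[:, self.channel_index(channel)]

    def select(self, mask: np.ndarray) -> "FlowSample":
        return FlowSample(
            channels=list(self.channels),
            events=self.events[mask],
            labels=None if self.labels is None else self.labels[mask],
            subpop_labels=None
            if self.subpop_labels is None
            else self.subpop_labels[mask],
            transfected=None if self.transfected is None else self.transfected[mask],
            meta=dict(self.meta),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.events, columns=self.channels)
        if self.labels is not None:
            df[LABEL_COLUMN] = self.labels
        if self.subpop_labels is not None:
            df[SUBPOP_COLUMN] = self.subpop_labels
        if self.transfected is not None:
            df[TRANSFECTED_COLUMN] = self.transfected.astype(int)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, meta: dict | None = None) -> "FlowSample":
        channels = [c for c in df.columns if c not in _SPECIAL]
        return cls(
            channels=channels,
            events=df[channels].to_numpy(dtype=float),
            labels=df[LABEL_COLUMN].to_numpy() if LABEL_COLUMN in df else None,
            subpop_labels=df[SUBPOP_COLUMN].to_numpy() if SUBPOP_COLUMN in df else None,
            transfected=df[TRANSFECTED_COLUMN].to_numpy(dtype=bool)
            if TRANSFECTED_COLUMN in df
            else None,
            meta=meta or {},
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FlowSample":
        return cls.from_dataframe(pd.read_csv(path), meta={"source": str(path)})


@dataclass
class ImageScene:
    """Multichannel image with ground-truth nucleus mask and labels.

    ``pixels`` is (n_channels, height, width); ``truth_mask`` labels nucleus
    pixels with integers from 1 (0 = background); ``truth_labels[i]`` is the
    cell type of nucleus ``i + 1``.
    """

    channel_names: list[str]
    pixels: np.ndarray
    truth_mask: np.ndarray | None = None
    truth_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != len(self.channel_names):
            raise ValueError(
                f"pixels shape {self.pixels.shape} does not match "
                f"{len(self.channel_names)} channels"
            )
        if (self.pixels < 0).any():
            raise ValueError("pixel values must be >= 0")
        if self.truth_mask is not None:
            self.truth_mask = np.asarray(self.truth_mask)
            if self.truth_mask.shape != self.pixels.shape[1:]:
                raise ValueError("truth_mask shape does not match channel shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in scene (channels: {self.channel_names})"
            ) from None
        return self.pixels[idx]

    def average_image(self) -> np.ndarray:
        return self.pixels.mean(axis=0)

    def to_tiff(self, path: str | Path, mask_path: str | Path | None = None) -> None:
        import tifffile

        tifffile.imwrite(
            str(path),
            self.pixels.astype(np.float32),
            photometric="minisblack",
            metadata={"axes": "CYX", "channels": ",".join(self.channel_names)},
        )
        if mask_path is not None and self.truth_mask is not None:
            tifffile.imwrite(str(mask_path), self.truth_mask.astype(np.int32))

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        channel_names: Sequence[str],
        mask_path: str | Path | None = None,
    ) -> "ImageScene":
        import tifffile

        pixels = np.asarray(tifffile.imread(str(path)), dtype=float)
        if pixels.ndim == 2:
            pixels = pixels[None]
        mask = None
        if mask_path is not None:
            mask = np.asarray(tifffile.imread(str(mask_path)))
        return cls(list(channel_names), pixels, truth_mask=mask)
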