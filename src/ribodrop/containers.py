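"""In-memory containers shared across modules.

Tabular results (differential-expression tables, droplet records, puncta
records, ground-truth tables) are plain :class:`pandas.DataFrame` objects with
documented column sets; only the containers that bundle several arrays with
metadata get a dataclass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ribodrop.errors import ConfigError

#: Fixed column order of a differential-expression table.
DE_COLUMNS = ("gene", "baseMean", "log2FC", "SE", "p", "padj", "z")

CONTROL = "control"
MUTANT = "mutant"


@dataclass
class CountMatrix:
    """Gene × sample matrix of raw counts with a two-group design.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes as rows (index = gene identifiers),
        samples as columns.
    design
        Per-sample group label, either ``"control"`` or ``"mutant"``, indexed
        by sample identifier in the same order as ``counts.columns``.
    """

    counts: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.to_numpy() < 0).any():
            raise ConfigError("counts: negative entries are not allowed")
        if list(self.design.index) != list(counts.columns):
            raise ConfigError("design: sample labels must match count columns in order")
        bad = set(self.design) - {CONTROL, MUTANT}
        if bad:
            raise ConfigError(f"design: unknown group labels {sorted(bad)}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def group_columns(self, group: str) -> list[str]:
        return [s for s, g in self.design.items() if g == group]


@dataclass
class ImageRaster:
    """Named 2-D channels on a common pixel grid with physical calibration.

    All channels share one shape; ``pixel_size_um`` is the edge length of a
    pixel in micrometres.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um: must be positive")
        shapes = {ch: arr.shape for ch, arr in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ConfigError(f"channels: inconsistent shapes {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]


@dataclass
class KineticSeries:
    """A (time, signal) trace from a plate-reader assay.

    ``time_min`` is strictly increasing; ``signal`` is OD600 for turbidity or
    relative luminescence for translation assays.
    """

    time_min: np.ndarray
    signal: np.ndarray
    condition: str = "sample"
    assay: str = "turbidity"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_min.shape != self.signal.shape:
            raise ConfigError("signal: time and signal must have equal length")
        if np.any(np.diff(self.time_min) <= 0):
            raise ConfigError("time_min: must be strictly increasing")
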