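"""Readers and writers for every on-disk format the pipeline touches.

Coordinate convention, used everywhere downstream:

* arrays are indexed ``[channel, row, col]`` (C x H x W);
* pixel ``(row r, col c)`` has its centre at ``((c + 0.5) * pixel_size_um,
  (r + 0.5) * pixel_size_um)`` in micrometres, i.e. ``x`` is the column axis
  and ``y`` the row axis, both 0-based with a top-left origin;
* image bounds are half-open: valid centroids lie in ``[0, W * pixel_size)``.

Intensities are stored as 64-bit floats regardless of the source integer
type, because normalisation divides.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ChannelEntry",
    "ChannelPanel",
    "IonImageStack",
    "MarkerImageStack",
    "LabelMask",
    "CellTable",
    "read_sims_ascii",
    "write_sims_ascii",
    "read_marker_stack",
    "write_marker_stack",
    "read_ion_stack",
    "write_ion_stack",
    "read_label_mask",
    "write_label_mask",
    "read_cell_table",
    "write_cell_table",
    "read_panel",
    "write_panel",
]

CHANNEL_KINDS = ("metabolite", "protein", "dna")


@dataclass(frozen=True)
class ChannelEntry:
    """One channel of an image stack.

    ``kind`` is ``"metabolite"`` (an m/z peak from TOF-SIMS), ``"protein"``
    (a metal-tagged antibody from IMC) or ``"dna"`` (a nuclear counterstain).
    Metabolite entries carry the mass-to-charge ratio ``mz``.
    """

    index: int
    name: str
    kind: str
    mz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in CHANNEL_KINDS:
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if self.kind == "metabolite":
            if self.mz is None or not self.mz > 0:
                raise ValueError(
                    f"metabolite channel {self.name!r} needs mz > 0, got {self.mz}"
                )


@dataclass(frozen=True)
class ChannelPanel:
    """Ordered channel metadata for an image stack."""

    entries: tuple[ChannelEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        idx = [e.index for e in self.entries]
        if idx != list(range(len(idx))):
            raise ValueError("channel_index values must be contiguous from 0")
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def index_of(self, name: str) -> int:
        for e in self.entries:
            if e.name == name:
                return e.index
        raise KeyError(f"channel {name!r} not in panel")

    @classmethod
    def from_names(
        cls, names: Sequence[str], kind: str, mz: Optional[Sequence[float]] = None
    ) -> "ChannelPanel":
        """Build a homogeneous panel; metabolite panels need ``mz`` values."""
        entries = []
        for i, n in enumerate(names):
            entries.append(
                ChannelEntry(i, n, kind, mz=None if mz is None else float(mz[i]))
            )
        return cls(tuple(entries))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel_index": [e.index for e in self.entries],
                "name": [e.name for e in self.entries],
                "kind": [e.kind for e in self.entries],
                "mz": [np.nan if e.mz is None else e.mz for e in self.entries],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ChannelPanel":
        required = {"channel_index", "name", "kind"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel missing columns {sorted(missing)}")
        df = df.sort_values("channel_index")
        entries = []
        for _, row in df.iterrows():
            mz = row.get("mz", np.nan)
            mz = None if pd.isna(mz) else float(mz)
            entries.append(
                ChannelEntry(int(row["channel_index"]), str(row["name"]), str(row["kind"]), mz)
            )
        return cls(tuple(entries))


def _check_stack(data: np.ndarray, panel: ChannelPanel, pixel_size_um: float) -> np.ndarray:
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"stack must be C x H x W, got shape {data.shape}")
    if len(panel) != data.shape[0]:
        raise ValueError(
            f"panel has {len(panel)} channels but stack has {data.shape[0]} planes"
        )
    if not (np.isfinite(pixel_size_um) and pixel_size_um > 0):
        raise ValueError(f"pixel_size_um must be finite and > 0, got {pixel_size_um}")
    return data


@dataclass
class IonImageStack:
    """C x H x W non-negative ion-count image (one plane per m/z peak)."""

    data: np.ndarray
    panel: ChannelPanel
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.data = _check_stack(self.data, self.panel, self.pixel_size_um)
        if np.any(self.data < 0):
            raise ValueError("ion counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def plane(self, name: str) -> np.ndarray:
        return self.data[self.panel.index_of(name)]


@dataclass
class MarkerImageStack:
    """C x H x W protein/DNA marker image with panel metadata."""

    data: np.ndarray
    panel: ChannelPanel
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.data = _check_stack(self.data, self.panel, self.pixel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def plane(self, name: str) -> np.ndarray:
        return self.data[self.panel.index_of(name)]


@dataclass
class LabelMask:
    """H x W integer label image; 0 is background, label k > 0 is cell k."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError(f"label mask must be 2-D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("label mask must have an integer dtype")
        if labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.labels = labels.astype(np.int32, copy=False)

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


REQUIRED_CELL_COLUMNS = ("cell_id", "centroid_x_um", "centroid_y_um")


@dataclass
class CellTable:
    """Per-cell feature records backed by a pandas DataFrame.

    Required columns: ``cell_id``, ``centroid_x_um``, ``centroid_y_um``.
    Channel columns hold mean intensities; categorical columns (``cluster``,
    ``region``, ``patient_id``...) are kept as strings.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        for col in REQUIRED_CELL_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"cell table missing required column {col!r}")
        if df["cell_id"].duplicated().any():
            dup = df["cell_id"][df["cell_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicated cell_id {dup!r}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def centroids_um(self) -> np.ndarray:
        """n x 2 array of (x, y) centroids in micrometres."""
        return self.df[["centroid_x_um", "centroid_y_um"]].to_numpy(dtype=float)

    def channel_matrix(self, channels: Sequence[str]) -> np.ndarray:
        missing = [c for c in channels if c not in self.df.columns]
        if missing:
            raise KeyError(f"channels not in table: {missing}")
        return self.df[list(channels)].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# SIMS ASCII
# ---------------------------------------------------------------------------

def _parse_xy_int(arr: np.ndarray, what: str) -> np.ndarray:
    if not np.allclose(arr, np.round(arr)):
        bad = arr[~np.isclose(arr, np.round(arr))][0]
        raise ValueError(f"non-integer {what} coordinate {bad!r} in SIMS ASCII")
    return np.round(arr).astype(int)


def read_sims_ascii(
    path,
    layout: str = "long",
    pixel_size_um: float = 1.0,
    panel: Optional[ChannelPanel] = None,
) -> IonImageStack:
    """Read TOF-SIMS peak images exported as ASCII text.

    ``layout="long"`` expects one file with whitespace-delimited columns
    ``(channel_id, x, y, intensity)``; ``layout="per_channel"`` expects a
    directory (or list of files), one file per peak with ``(x, y, intensity)``
    columns, channels ordered by sorted file name.  Unobserved pixels are
    zero-filled; H and W are inferred from the maximum coordinates + 1.
    """
    if layout == "long":
        raw = np.loadtxt(path, ndmin=2)
        if raw.size == 0:
            raise ValueError("empty SIMS ASCII file")
        if raw.shape[1] != 4:
            raise ValueError(f"long layout needs 4 columns, got {raw.shape[1]}")
        chan = _parse_xy_int(raw[:, 0], "channel")
        x = _parse_xy_int(raw[:, 1], "x")
        y = _parse_xy_int(raw[:, 2], "y")
        inten = raw[:, 3]
        n_chan = chan.max() + 1
    elif layout == "per_channel":
        if isinstance(path, (str, os.PathLike)) and Path(path).is_dir():
            files = sorted(Path(path).glob("*"))
        else:
            files = [Path(p) for p in path]
        if not files:
            raise ValueError("no per-channel SIMS ASCII files found")
        chans, xs, ys, intens = [], [], [], []
        for ci, f in enumerate(files):
            raw = np.loadtxt(f, ndmin=2)
            if raw.size == 0:
                continue
            if raw.shape[1] != 3:
                raise ValueError(f"per_channel layout needs 3 columns in {f}")
            xs.append(_parse_xy_int(raw[:, 0], "x"))
            ys.append(_parse_xy_int(raw[:, 1], "y"))
            intens.append(raw[:, 2])
            chans.append(np.full(raw.shape[0], ci, dtype=int))
        n_chan = len(files)
        if chans:
            chan = np.concatenate(chans)
            x = np.concatenate(xs)
            y = np.concatenate(ys)
            inten = np.concatenate(intens)
        else:
            chan = x = y = np.empty(0, dtype=int)
            inten = np.empty(0)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if inten.size and inten.min() < 0:
        raise ValueError(f"negative intensity {inten.min()} in SIMS ASCII")
    if x.size:
        if x.min() < 0 or y.min() < 0:
            raise ValueError("negative pixel coordinate in SIMS ASCII")
        h, w = y.max() + 1, x.max() + 1
    else:
        h = w = 1
    key = (chan.astype(np.int64) * h + y) * w + x
    uniq, counts = np.unique(key, return_counts=True)
    if np.any(counts > 1):
        k = uniq[counts > 1][0]
        c, rem = divmod(int(k), h * w)
        yy, xx = divmod(rem, w)
        raise ValueError(f"duplicate (channel, x, y) = ({c}, {xx}, {yy}) in SIMS ASCII")

    data = np.zeros((n_chan, h, w), dtype=np.float64)
    data[chan, y, x] = inten
    if panel is None:
        panel = ChannelPanel.from_names(
            [f"mz_{i}" for i in range(n_chan)], "metabolite", mz=np.arange(1, n_chan + 1)
        )
    return IonImageStack(data, panel, pixel_size_um)


def write_sims_ascii(stack: IonImageStack, path, layout: str = "long") -> None:
    """Write an ion stack back to ASCII text (inverse of :func:`read_sims_ascii`).

    Only nonzero pixels are written, matching the sparse export style.
    """
    c_idx, y_idx, x_idx = np.nonzero(stack.data)
    vals = stack.data[c_idx, y_idx, x_idx]
    if layout == "long":
        # also write one zero sentinel at the far corner per channel so that
        # shape is recoverable even when border pixels are empty
        rows = [np.column_stack([c_idx, x_idx, y_idx, vals])]
        h, w = stack.data.shape[1:]
        corner = stack.data[:, h - 1, w - 1]
        missing = np.nonzero(corner == 0)[0]
        if missing.size:
            rows.append(
                np.column_stack(
                    [missing, np.full(missing.size, w - 1), np.full(missing.size, h - 1),
                     np.zeros(missing.size)]
                )
            )
        np.savetxt(path, np.vstack(rows), fmt="%d %d %d %.17g")
    elif layout == "per_channel":
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        h, w = stack.data.shape[1:]
        for ci in range(stack.data.shape[0]):
            sel = c_idx == ci
            rows = [np.column_stack([x_idx[sel], y_idx[sel], vals[sel]])]
            if stack.data[ci, h - 1, w - 1] == 0:
                rows.append(np.array([[w - 1, h - 1, 0.0]]))
            np.savetxt(path / f"channel_{ci:04d}.txt", np.vstack(rows), fmt="%d %d %.17g")
    else:
        raise ValueError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# TIFF stacks and masks
# ---------------------------------------------------------------------------

def _read_panel_file(panel_path) -> pd.DataFrame:
    sep = "\t" if str(panel_path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(panel_path, sep=sep)


def read_panel(panel_path) -> ChannelPanel:
    return ChannelPanel.from_dataframe(_read_panel_file(panel_path))


def write_panel(panel: ChannelPanel, panel_path) -> None:
    sep = "\t" if str(panel_path).endswith((".tsv", ".txt")) else ","
    panel.to_dataframe().to_csv(panel_path, sep=sep, index=False)


def _read_tiff_stack(path) -> np.ndarray:
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - exercised via bad files
        raise ValueError(f"unreadable TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a multichannel 2-D TIFF, got shape {data.shape}")
    return data


def read_marker_stack(path, panel_path, pixel_size_um: float = 1.0) -> MarkerImageStack:
    """Read a multichannel TIFF plus its delimited channel-panel table."""
    data = _read_tiff_stack(path)
    panel = read_panel(panel_path)
    if len(panel) != data.shape[0]:
        raise ValueError(
            f"panel has {len(panel)} rows but TIFF has {data.shape[0]} planes"
        )
    return MarkerImageStack(data, panel, pixel_size_um)


def write_marker_stack(stack: MarkerImageStack, path, panel_path=None) -> None:
    tifffile.imwrite(path, stack.data.astype(np.float64))
    if panel_path is not None:
        write_panel(stack.panel, panel_path)


def read_ion_stack(path, panel_path, pixel_size_um: float = 1.0) -> IonImageStack:
    """Read an ion-image stack previously stored as multichannel TIFF."""
    data = _read_tiff_stack(path)
    panel = read_panel(panel_path)
    if len(panel) != data.shape[0]:
        raise ValueError(
            f"panel has {len(panel)} rows but TIFF has {data.shape[0]} planes"
        )
    return IonImageStack(data, panel, pixel_size_um)


def write_ion_stack(stack: IonImageStack, path, panel_path=None) -> None:
    tifffile.imwrite(path, stack.data.astype(np.float64))
    if panel_path is not None:
        write_panel(stack.panel, panel_path)


def read_label_mask(path, pixel_size_um: float = 1.0) -> LabelMask:
    """Read a single-plane 16/32-bit integer label TIFF."""
    data = np.asarray(tifffile.imread(path))
    if data.ndim != 2:
        raise ValueError(f"label mask must be a single plane, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"label mask must be integer-typed, got {data.dtype}")
    return LabelMask(data, pixel_size_um)


def write_label_mask(mask: LabelMask, path) -> None:
    labels = mask.labels
    dtype = np.uint16 if labels.max(initial=0) < 2 ** 16 else np.int32
    tifffile.imwrite(path, labels.astype(dtype))


# ---------------------------------------------------------------------------
# Cell tables
# ---------------------------------------------------------------------------

_CATEGORICAL_COLUMNS = ("cluster", "region", "patient_id", "fov_id", "cell_type")


def read_cell_table(path) -> CellTable:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    for col in _CATEGORICAL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(str)
    return CellTable(df)


def write_cell_table(table: CellTable, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table.df.to_csv(path, sep=sep, index=False)
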