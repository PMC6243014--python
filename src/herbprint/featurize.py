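"""Peak-table parsing and retention-time-free m/z x polarity featurization.

A sample's detected chromatographic peaks are collapsed onto an integer m/z
grid, separately per ionization polarity, keeping only the largest peak area
in each bin.  Retention time is deliberately discarded: it depends on the
chromatographic method and does not transfer between platforms, whereas the
(m/z, polarity, area) fingerprint largely does.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NEGATIVE_CLASS = "negative"

REQUIRED_COLUMNS = ("sample_id", "species", "organ", "polarity", "mz", "rt", "area")

POLARITIES = ("pos", "neg")


class SchemaError(ValueError):
    """A peak-table file does not provide the required columns."""


class PeakValidationError(ValueError):
    """A peak-table row violates the value constraints."""


@dataclass(frozen=True)
class MzGrid:
    """Integer m/z binning grid, half-open ``[mz_lo, mz_hi)`` per polarity.

    With the defaults this gives 800 integer bins per polarity and a total
    feature length of 1600 (positive-mode bins first, then negative-mode).
    """

    mz_lo: int = 100
    mz_hi: int = 900
    polarity_order: tuple[str, str] = POLARITIES

    def __post_init__(self) -> None:
        if self.mz_hi <= self.mz_lo:
            raise ValueError("mz_hi must exceed mz_lo")

    @property
    def n_bins_per_polarity(self) -> int:
        return self.mz_hi - self.mz_lo

    @property
    def n_features(self) -> int:
        return len(self.polarity_order) * self.n_bins_per_polarity

    def index_of(self, mz_bin: int, polarity: str) -> int:
        """Flat feature index of an integer m/z bin in a given polarity."""
        if polarity not in self.polarity_order:
            raise ValueError(f"unknown polarity {polarity!r}")
        if not (self.mz_lo <= mz_bin < self.mz_hi):
            raise ValueError(f"m/z bin {mz_bin} outside [{self.mz_lo}, {self.mz_hi})")
        offset = self.polarity_order.index(polarity)
        return offset * self.n_bins_per_polarity + (mz_bin - self.mz_lo)


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (150.5 -> 151), unlike numpy's banker's rounding."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class FeatureVector:
    """One sample's non-negative peak-area vector on an :class:`MzGrid`."""

    values: np.ndarray
    sample_id: str
    species: str = ""
    organ: str = ""
    n_dropped: int = 0
    grid: MzGrid = field(default_factory=MzGrid)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_features,):
            raise ValueError(
                f"expected length {self.grid.n_features}, got {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("feature values must be non-negative")

    def label(self, label_by: str = "species") -> str:
        if label_by == "species":
            return self.species
        if label_by == "organ":
            return self.organ
        if label_by == "species_organ":
            return f"{self.species}|{self.organ}"
        raise ValueError(f"unknown label_by {label_by!r}")


def load_peak_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    on_invalid: str = "reject",
) -> pd.DataFrame:
    """Read and validate a long-format peak table CSV.

    Parameters
    ----------
    path:
        CSV with header row and columns ``sample_id, species, organ,
        polarity, mz, rt, area`` (possibly under other names, see `schema`).
    schema:
        Optional mapping from canonical column names to the names used in
        the file, e.g. ``{"mz": "m/z", "area": "intensity"}``.
    on_invalid:
        ``"reject"`` drops invalid rows (logged with reason); ``"abort"``
        raises :class:`PeakValidationError` naming the first offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if on_invalid not in ("reject", "abort"):
        raise ValueError("on_invalid must be 'reject' or 'abort'")
    df = pd.read_csv(path)
    rename = {}
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"peak table missing required column(s): {', '.join(missing)}")

    df = df[list(REQUIRED_COLUMNS)].copy()
    mz = pd.to_numeric(df["mz"], errors="coerce")
    area = pd.to_numeric(df["area"], errors="coerce")
    bad = (
        mz.isna()
        | area.isna()
        | (mz <= 0)
        | (area < 0)
        | ~df["polarity"].isin(POLARITIES)
    )
    if bad.any():
        first = int(np.flatnonzero(bad.to_numpy())[0])
        if on_invalid == "abort":
            raise PeakValidationError(
                f"invalid peak row {first} (data row index): "
                f"mz={df['mz'].iloc[first]!r}, area={df['area'].iloc[first]!r}, "
                f"polarity={df['polarity'].iloc[first]!r}"
            )
        for idx in np.flatnonzero(bad.to_numpy())[:20]:
            logger.warning(
                "rejecting peak row %d: mz=%r area=%r polarity=%r",
                idx, df["mz"].iloc[idx], df["area"].iloc[idx], df["polarity"].iloc[idx],
            )
        n_bad = int(bad.sum())
        if n_bad > 20:
            logger.warning("... and %d more rejected rows", n_bad - 20)
    df["mz"] = mz
    df["area"] = area
    df = df.loc[~bad].reset_index(drop=True)
    return df


def featurize_sample(
    peaks: pd.DataFrame, grid: MzGrid | None = None, sample_id: str | None = None
) -> FeatureVector:
    """Bin one sample's peaks onto the grid, keeping the max area per bin.

    m/z values are rounded half-away-from-zero to integers; among all peaks
    of one polarity rounding into the same integer bin, only the highest
    area is retained.  Peaks rounding outside the grid are dropped and
    counted in ``n_dropped``.
    """
    grid = grid or MzGrid()
    ids = peaks["sample_id"].unique() if len(peaks) else []
    if len(ids) > 1:
        raise ValueError(f"featurize_sample got rows from multiple samples: {ids}")
    if sample_id is None:
        sample_id = str(ids[0]) if len(ids) else ""
    values = np.zeros(grid.n_features)
    n_dropped = 0
    species = str(peaks["species"].iloc[0]) if "species" in peaks and len(peaks) else ""
    organ = str(peaks["organ"].iloc[0]) if "organ" in peaks and len(peaks) else ""
    if len(peaks) == 0:
        warnings.warn(f"no peaks for sample {sample_id!r}; returning zero vector")
        return FeatureVector(values, sample_id, species, organ, 0, grid)

    mz_bin = round_half_away(peaks["mz"].to_numpy()).astype(int)
    area = peaks["area"].to_numpy(dtype=float)
    in_range = (mz_bin >= grid.mz_lo) & (mz_bin < grid.mz_hi)
    n_dropped = int((~in_range).sum())
    for k, pol in enumerate(grid.polarity_order):
        sel = in_range & (peaks["polarity"].to_numpy() == pol)
        if not sel.any():
            continue
        flat = k * grid.n_bins_per_polarity + (mz_bin[sel] - grid.mz_lo)
        np.maximum.at(values, flat, area[sel])
    return FeatureVector(values, sample_id, species, organ, n_dropped, grid)


def featurize_peak_table(
    peaks: pd.DataFrame, grid: MzGrid | None = None
) -> list[FeatureVector]:
    """Featurize every sample in a validated peak table, in sample-id order."""
    grid = grid or MzGrid()
    return [
        featurize_sample(g, grid, sample_id=str(sid))
        for sid, g in peaks.groupby("sample_id", sort=True)
    ]


def unfold(T: np.ndarray) -> np.ndarray:
    """Sample-mode unfolding of an (N, J, K) tensor to (N, K*J).

    Column blocks are ordered by the last (polarity) axis so the unfolding
    is compatible with the Kronecker identity ``T_(1) = G_(1) (C kron B)^T``.
    With the default grid the positive-mode 800 bins come first.
    """
    n, j, k = T.shape
    return np.ascontiguousarray(T.transpose(0, 2, 1).reshape(n, k * j))


def fold(X: np.ndarray, n_mz: int, n_pol: int) -> np.ndarray:
    """Inverse of :func:`unfold`: (N, K*J) back to (N, J, K)."""
    n = X.shape[0]
    return np.ascontiguousarray(X.reshape(n, n_pol, n_mz).transpose(0, 2, 1))


@dataclass
class Dataset:
    """Stacked feature vectors as a (sample x m/z x polarity) tensor.

    ``T`` holds non-negative areas; ``y`` holds integer class ids defined by
    ``class_map`` (a bijection between retained class names, plus the pooled
    ``"negative"`` class when present, and contiguous ids).
    """

    T: np.ndarray
    y: np.ndarray
    class_map: dict[str, int]
    sample_ids: list[str]
    grid: MzGrid = field(default_factory=MzGrid)
    normalize: str = "none"
    n_dropped_peaks: int = 0

    @property
    def X(self) -> np.ndarray:
        """Unfolded (N, n_features) view; positive-mode bins first."""
        return unfold(self.T)

    @property
    def classes(self) -> list[str]:
        inv = {v: k for k, v in self.class_map.items()}
        return [inv[i] for i in range(len(inv))]

    def labels(self) -> np.ndarray:
        inv = {v: k for k, v in self.class_map.items()}
        return np.array([inv[i] for i in self.y])

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(
            self.T[idx], self.y[idx], dict(self.class_map),
            [self.sample_ids[i] for i in np.atleast_1d(idx)],
            self.grid, self.normalize, self.n_dropped_peaks,
        )

    def save(self, path: str | Path) -> None:
        """Write the tensor as .npz with a JSON sidecar of the metadata."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), T=self.T, y=self.y)
        meta = {
            "class_map": self.class_map,
            "sample_ids": self.sample_ids,
            "grid": {"mz_lo": self.grid.mz_lo, "mz_hi": self.grid.mz_hi},
            "normalize": self.normalize,
            "n_dropped_peaks": self.n_dropped_peaks,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Dataset":
        path = Path(path)
        arr = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            arr["T"], arr["y"], {k: int(v) for k, v in meta["class_map"].items()},
            list(meta["sample_ids"]),
            MzGrid(meta["grid"]["mz_lo"], meta["grid"]["mz_hi"]),
            meta["normalize"], int(meta["n_dropped_peaks"]),
        )


def build_dataset(
    vectors: Sequence[FeatureVector],
    min_samples_per_class: int = 20,
    normalize: str = "none",
    label_by: str = "species",
) -> Dataset:
    """Stack feature vectors into a :class:`Dataset`, pooling rare classes.

    Classes with fewer than `min_samples_per_class` samples are merged into
    the single ``"negative"`` class, which then participates in training and
    scoring as an ordinary class (winner-takes-all over all states).

    ``normalize="sample_max"`` divides each sample by its maximum entry,
    mapping it into [0, 1] (all-zero samples are left as zeros); this is the
    scaling expected by the autoencoder.  ``"none"`` keeps raw areas, the
    default input for the subspace and Bayesian-network paths.
    """
    if not vectors:
        raise ValueError("no feature vectors given")
    if normalize not in ("none", "sample_max"):
        raise ValueError("normalize must be 'none' or 'sample_max'")
    grid = vectors[0].grid
    for v in vectors:
        if v.grid != grid:
            raise ValueError("all feature vectors must share one grid")

    raw_labels = [v.label(label_by) for v in vectors]
    counts = pd.Series(raw_labels).value_counts()
    retained = sorted(c for c in counts.index if counts[c] >= min_samples_per_class)
    has_negative = len(retained) < len(counts)
    merged = [
        lbl if lbl in set(retained) else NEGATIVE_CLASS for lbl in raw_labels
    ]
    class_names = retained + ([NEGATIVE_CLASS] if has_negative else [])
    class_map = {name: i for i, name in enumerate(class_names)}
    if len(class_map) < 2:
        warnings.warn("dataset has a single class; classifier training is degenerate")

    X = np.stack([v.values for v in vectors])
    if normalize == "sample_max":
        m = X.max(axis=1, keepdims=True)
        m[m == 0] = 1.0
        X = X / m
    T = fold(X, grid.n_bins_per_polarity, len(grid.polarity_order))
    y = np.array([class_map[lbl] for lbl in merged], dtype=int)
    return Dataset(
        T, y, class_map, [v.sample_id for v in vectors], grid, normalize,
        sum(v.n_dropped for v in vectors),
    )
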