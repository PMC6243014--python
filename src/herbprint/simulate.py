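"""Synthetic LC-MS peak-list generator.

Emulates the statistical structure the classifiers rely on: each species
carries a characteristic set of marker compounds (integer m/z, polarity)
with species-specific mean abundances, on top of a background peak set
shared by all species.  Peak areas are log-normal (multiplicative noise),
peaks drop out at random, m/z values are jittered within a bin, and an
optional "second platform" shift rescales intensities, tilts the m/z
response, and adds extra dropout — mimicking data re-acquired with a
different extraction protocol or instrument.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from herbprint.featurize import MzGrid, POLARITIES


@dataclass(frozen=True)
class PlatformShift:
    """Systematic between-platform distortion applied to simulated peaks."""

    global_scale: float = 1.0
    extra_dropout: float = 0.0
    tilt_strength: float = 0.0  # 0 disables the smooth m/z response tilt

    def __post_init__(self) -> None:
        if self.global_scale <= 0:
            raise ValueError("global_scale must be positive")
        if not (0 <= self.extra_dropout < 1):
            raise ValueError("extra_dropout must lie in [0, 1)")

    def response(self, mz: np.ndarray, grid: MzGrid) -> np.ndarray:
        """Multiplicative intensity factor at each m/z (smooth in m/z)."""
        u = (np.asarray(mz, float) - grid.mz_lo) / (grid.mz_hi - grid.mz_lo)
        return self.global_scale * np.exp(self.tilt_strength * (u - 0.5))


@dataclass
class SpeciesLibrary:
    """Per-species marker peaks plus a shared background peak set.

    Each marker is (integer m/z bin, polarity, mean log-area, log-area sd).
    Markers are drawn without replacement from the grid, so each species is
    guaranteed at least one marker bin not present in any other species.
    """

    markers: dict[str, list[tuple[int, str, float, float]]]
    background: list[tuple[int, str, float, float]]
    grid: MzGrid = field(default_factory=MzGrid)
    rng_seed: int = 0

    @property
    def species(self) -> list[str]:
        return list(self.markers)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "markers": self.markers,
            "background": self.background,
            "grid": {"mz_lo": self.grid.mz_lo, "mz_hi": self.grid.mz_hi},
            "rng_seed": self.rng_seed,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpeciesLibrary":
        d = json.loads(Path(path).read_text())
        return cls(
            {s: [tuple(m) for m in ms] for s, ms in d["markers"].items()},
            [tuple(b) for b in d["background"]],
            MzGrid(d["grid"]["mz_lo"], d["grid"]["mz_hi"]),
            d["rng_seed"],
        )


def make_species_library(
    n_species: int,
    n_markers: int = 15,
    n_shared: int = 30,
    seed: int = 0,
    grid: MzGrid | None = None,
    marker_log_mean: float = 11.0,
    background_log_mean: float = 10.0,
    log_sd: float = 0.4,
) -> SpeciesLibrary:
    """Draw a random species library, deterministic given `seed`.

    Marker (bin, polarity) slots are sampled without replacement across all
    species and the background, so every pair of species differs in every
    marker bin.  Mean log-areas vary around `marker_log_mean` so that marker
    intensities span roughly an order of magnitude, as compound abundances
    in real extracts do.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if n_markers < 1:
        raise ValueError("each species needs at least one exclusive marker")
    grid = grid or MzGrid()
    capacity = grid.n_features
    need = n_species * n_markers + n_shared
    if need > capacity:
        raise ValueError(
            f"requested {need} distinct peak slots but the grid has {capacity}"
        )
    rng = np.random.default_rng(seed)
    slots = rng.choice(capacity, size=need, replace=False)
    nb = grid.n_bins_per_polarity

    def slot_to_peak(flat: int, log_mean: float) -> tuple[int, str, float, float]:
        pol = grid.polarity_order[flat // nb]
        mz = grid.mz_lo + flat % nb
        return (int(mz), pol, float(log_mean + rng.normal(0, 0.5)), log_sd)

    markers: dict[str, list[tuple[int, str, float, float]]] = {}
    pos = 0
    for s in range(n_species):
        name = f"species_{s:02d}"
        markers[name] = [
            slot_to_peak(int(slots[pos + m]), marker_log_mean)
            for m in range(n_markers)
        ]
        pos += n_markers
    background = [
        slot_to_peak(int(slots[pos + b]), background_log_mean)
        for b in range(n_shared)
    ]
    return SpeciesLibrary(markers, background, grid, seed)


def simulate_peaklists(
    lib: SpeciesLibrary,
    n_replicates: int = 30,
    dropout: float = 0.1,
    area_cv: float = 1.0,
    shift: PlatformShift | None = None,
    seed: int = 0,
    mz_jitter: float = 0.3,
    organ: str = "herba",
) -> pd.DataFrame:
    """Generate a long-format peak table of replicate extracts per species.

    Each replicate contains every surviving marker and background peak with
    a log-normal area (``area_cv`` scales the library's log-sd), m/z
    jittered uniformly within ``+-mz_jitter`` of the bin center (bounded
    below 0.5 so rounding never crosses bins), and a uniform random
    retention time.  A :class:`PlatformShift` is applied multiplicatively.
    Deterministic given `seed`.
    """
    if not (0 <= dropout < 1):
        raise ValueError("dropout must lie in [0, 1)")
    if not (0 <= mz_jitter < 0.5):
        raise ValueError("mz_jitter must lie in [0, 0.5) to preserve bins")
    rng = np.random.default_rng(seed)
    p_drop = dropout
    if shift is not None:
        p_drop = 1.0 - (1.0 - dropout) * (1.0 - shift.extra_dropout)

    rows = []
    for species in lib.species:
        peaks = lib.markers[species] + lib.background
        for rep in range(n_replicates):
            sid = f"{species}_r{rep:03d}"
            if shift is not None:
                sid += "_shifted"
            for mz, pol, log_mean, log_sd in peaks:
                if rng.random() < p_drop:
                    continue
                area = float(np.exp(log_mean + area_cv * log_sd * rng.normal()))
                if shift is not None:
                    area *= float(shift.response(mz, lib.grid)[()])
                rows.append({
                    "sample_id": sid,
                    "species": species,
                    "organ": organ,
                    "polarity": pol,
                    "mz": mz + rng.uniform(-mz_jitter, mz_jitter),
                    "rt": rng.uniform(0.5, 17.0),
                    "area": area,
                })
    return pd.DataFrame(
        rows, columns=["sample_id", "species", "organ", "polarity", "mz", "rt", "area"]
    )


def default_fixture(
    seed: int = 0,
    n_species: int = 10,
    n_replicates: int = 30,
    dropout: float = 0.1,
    rare_species: int = 3,
    rare_replicates: int = 5,
) -> pd.DataFrame:
    """The standard synthetic test condition: 10 species x 30 replicates
    with 10% dropout, plus 3 rare species x 5 replicates that exercise the
    rare-class pooling rule."""
    lib = make_species_library(n_species + rare_species, seed=seed)
    rare = lib.species[n_species:]
    main_lib = SpeciesLibrary(
        {s: lib.markers[s] for s in lib.species[:n_species]},
        lib.background, lib.grid, lib.rng_seed,
    )
    tables = [simulate_peaklists(main_lib, n_replicates, dropout, seed=seed + 1)]
    if rare_species:
        rare_lib = SpeciesLibrary(
            {s: lib.markers[s] for s in rare}, lib.background, lib.grid, lib.rng_seed
        )
        tables.append(
            simulate_peaklists(rare_lib, rare_replicates, dropout, seed=seed + 2)
        )
    return pd.concat(tables, ignore_index=True)
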