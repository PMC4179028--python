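"""Synthetic FT-NIR spectra and reference chemistry for hardwood biomass.

The real calibration set this package's analysis was designed around — a
37-sample mixed-genus hardwood collection scanned on an FT-NIR instrument
over 10,000–4,000 cm⁻¹ at 4 cm⁻¹ resolution — was never publicly deposited.
This module generates seeded surrogates with the statistical structure the
downstream chemometrics assume:

* per-sample constituent fractions (extractives, lignin, cellulose,
  hemicellulose, % w/w) drawn from plausible hardwood ranges;
* Beer–Lambert mixture spectra built from overlapping Gaussian absorption
  bands centred at literature band-assignment wavenumbers;
* per-sample multiplicative path-length scatter and an additive linear
  baseline (offset + slope), the physical artefacts that first-derivative
  pretreatment is meant to remove;
* white measurement noise on the absorbance and duplicate-measurement
  error on the wet-chemistry reference values.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberGrid",
    "SpectraSet",
    "ChemistryReference",
    "BandTable",
    "NoiseModel",
    "CONSTITUENTS",
    "DEFAULT_RANGES",
    "default_band_table",
    "sample_concentrations",
    "generate_spectra",
    "add_reference_noise",
]

CONSTITUENTS = ("extractives", "lignin", "cellulose", "hemicellulose")

#: Plausible hardwood composition windows, % w/w.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "extractives": (1.0, 8.0),
    "lignin": (18.0, 30.0),
    "cellulose": (38.0, 52.0),
    "hemicellulose": (15.0, 30.0),
}


@dataclass(frozen=True)
class WavenumberGrid:
    """Evenly spaced, strictly ascending wavenumber axis in cm⁻¹."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("grid needs at least two wavenumbers")
        d = np.diff(v)
        if np.any(d <= 0):
            raise ValueError("wavenumber grid must be strictly ascending")
        step = d[0]
        if not np.allclose(d, step, rtol=1e-9, atol=0.0):
            raise ValueError("wavenumber grid spacing must be uniform")
        object.__setattr__(self, "values", v)

    @classmethod
    def default(cls) -> "WavenumberGrid":
        # 4,000–10,000 cm⁻¹ at 4 cm⁻¹: 1,501 points
        return cls(np.arange(4000.0, 10000.0 + 4.0, 4.0))

    @classmethod
    def from_values(cls, values: np.ndarray) -> "WavenumberGrid":
        """Build a grid from values in either instrument order (descending)
        or ascending order; stored ascending."""
        v = np.asarray(values, dtype=float)
        if v.size >= 2 and v[0] > v[-1]:
            v = v[::-1]
        return cls(v)

    @property
    def start_cm1(self) -> float:
        return float(self.values[0])

    @property
    def end_cm1(self) -> float:
        return float(self.values[-1])

    @property
    def step_cm1(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return self.values.size

    def nearest_index(self, wavenumber: float) -> int:
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def contains(self, wavenumber: float) -> bool:
        return self.start_cm1 <= wavenumber <= self.end_cm1


@dataclass
class SpectraSet:
    """Absorbance matrix (n_samples × n_points) on a shared grid — the X block."""

    grid: WavenumberGrid
    absorbance: np.ndarray
    sample_ids: list[str]
    pretreatment: str = "raw"

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        if a.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"{a.shape[0]} spectra but {len(self.sample_ids)} sample ids"
            )
        if a.shape[1] != len(self.grid):
            raise ValueError(
                f"{a.shape[1]} points per spectrum but grid has {len(self.grid)}"
            )
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance contains non-finite values")
        self.absorbance = a
        self.sample_ids = list(self.sample_ids)

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]


@dataclass
class ChemistryReference:
    """Per-sample constituent fractions in % w/w — the Y block."""

    data: pd.DataFrame  # index sample_id, one column per constituent
    #: measured tables carry assay error, so their totals may drift past 100
    measured: bool = False

    def __post_init__(self) -> None:
        df = self.data.astype(float)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if (df.values < 0).any():
            raise ValueError("constituent fractions must be non-negative")
        known = [c for c in df.columns if c in CONSTITUENTS]
        if len(known) == len(CONSTITUENTS) and not self.measured:
            totals = df[known].sum(axis=1)
            if (totals > 100.0 + 1e-9).any():
                bad = totals.index[totals > 100.0 + 1e-9].tolist()
                raise ValueError(f"constituents exceed 100% w/w for samples {bad}")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def constituents(self) -> list[str]:
        return list(self.data.columns)

    def column(self, constituent: str) -> np.ndarray:
        if constituent not in self.data.columns:
            raise KeyError(f"unknown constituent {constituent!r}")
        return self.data[constituent].to_numpy(dtype=float)


@dataclass
class BandTable:
    """Literature band assignments: constituent → absorption-band centres.

    ``center_cm1`` is the assignment wavenumber BA_L; ``width_cm1`` (Gaussian
    sd) and ``amplitude`` (absorbance per unit mass fraction) parameterise the
    synthetic band shape only.
    """

    entries: pd.DataFrame  # columns constituent, center_cm1, width_cm1, amplitude

    REQUIRED = ("constituent", "center_cm1", "width_cm1", "amplitude")

    def __post_init__(self) -> None:
        df = self.entries
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"band table missing columns {missing}")
        self.entries = df.reset_index(drop=True)

    def for_constituent(self, constituent: str) -> pd.DataFrame:
        return self.entries[self.entries["constituent"] == constituent]

    @property
    def constituents(self) -> list[str]:
        return list(dict.fromkeys(self.entries["constituent"]))

    def centers(self, constituent: str) -> np.ndarray:
        return self.for_constituent(constituent)["center_cm1"].to_numpy(float)


def default_band_table() -> BandTable:
    """Packaged literature assignments for the four wood constituents."""
    ref = importlib.resources.files("nirchem.data").joinpath("bands.csv")
    with importlib.resources.as_file(ref) as path:
        return BandTable(pd.read_csv(path))


@dataclass(frozen=True)
class NoiseModel:
    """Instrument / wet-lab error model for the generator.

    baseline_offset_sd   additive offset per sample, absorbance units
    baseline_slope_sd    linear tilt per sample, absorbance per cm⁻¹
    pathlength_cv        multiplicative scatter, sd of a factor centred at 1
    additive_noise_sd    white noise per point, absorbance units
    reference_error_sd   duplicate-assay error on chemistry, % w/w
    """

    baseline_offset_sd: float = 0.02
    baseline_slope_sd: float = 1.0e-5
    pathlength_cv: float = 0.05
    additive_noise_sd: float = 0.001
    reference_error_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "baseline_offset_sd",
            "baseline_slope_sd",
            "pathlength_cv",
            "additive_noise_sd",
            "reference_error_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def silent(self) -> "NoiseModel":
        """Copy with every noise source switched off (seed retained)."""
        return replace(
            self,
            baseline_offset_sd=0.0,
            baseline_slope_sd=0.0,
            pathlength_cv=0.0,
            additive_noise_sd=0.0,
            reference_error_sd=0.0,
        )


def sample_concentrations(
    n_samples: int = 37,
    ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    max_tries: int = 10_000,
) -> ChemistryReference:
    """Draw per-sample constituent fractions uniformly within per-constituent
    ranges, redrawing any sample whose four fractions sum above 100% w/w."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    ranges = dict(DEFAULT_RANGES if ranges is None else ranges)
    lows = np.array([ranges[c][0] for c in ranges])
    highs = np.array([ranges[c][1] for c in ranges])
    if np.any(lows > highs):
        bad = [c for c, (lo, hi) in ranges.items() if lo > hi]
        raise ValueError(f"inverted ranges for {bad}")
    if lows.sum() > 100.0:
        # name the constituents that make the simplex empty
        order = np.argsort(-lows)
        names = list(ranges)
        running, offenders = 0.0, []
        for i in order:
            running += lows[i]
            offenders.append(names[i])
            if running > 100.0:
                break
        raise ValueError(
            f"infeasible ranges: minimum fractions of {offenders} already sum "
            f"above 100% w/w"
        )
    rng = np.random.default_rng(seed)
    rows = np.empty((n_samples, len(ranges)))
    for s in range(n_samples):
        for _ in range(max_tries):
            draw = rng.uniform(lows, highs)
            if draw.sum() <= 100.0:
                rows[s] = draw
                break
        else:
            raise RuntimeError("could not draw a feasible composition")
    ids = [f"S{str(i + 1).zfill(2)}" for i in range(n_samples)]
    return ChemistryReference(pd.DataFrame(rows, index=ids, columns=list(ranges)))


def generate_spectra(
    chem: ChemistryReference,
    bands: BandTable,
    grid: WavenumberGrid | None = None,
    noise: NoiseModel | None = None,
) -> SpectraSet:
    """Beer–Lambert mixture spectra with scatter, baseline and white noise.

    absorbance(s, ν) = path_s · Σ_b conc_s(b)/100 · A_b · exp(−(ν−c_b)²/2w_b²)
                       + offset_s + slope_s · (ν − ν̄) + ε(s, ν)
    """
    grid = grid or WavenumberGrid.default()
    noise = noise or NoiseModel()
    for _, row in bands.entries.iterrows():
        if not grid.contains(row["center_cm1"]):
            raise ValueError(
                f"band {row['constituent']} @ {row['center_cm1']} cm⁻¹ lies "
                f"outside the grid [{grid.start_cm1}, {grid.end_cm1}]"
            )
    nu = grid.values
    n = len(chem.sample_ids)
    pure = np.zeros((n, nu.size))
    for _, row in bands.entries.iterrows():
        if row["constituent"] not in chem.constituents:
            continue
        conc = chem.column(row["constituent"]) / 100.0
        shape = row["amplitude"] * np.exp(
            -((nu - row["center_cm1"]) ** 2) / (2.0 * row["width_cm1"] ** 2)
        )
        pure += np.outer(conc, shape)

    rng = np.random.default_rng(noise.seed)
    path = 1.0 + rng.normal(0.0, noise.pathlength_cv, size=n)
    offset = rng.normal(0.0, noise.baseline_offset_sd, size=n)
    slope = rng.normal(0.0, noise.baseline_slope_sd, size=n)
    eps = rng.normal(0.0, noise.additive_noise_sd, size=(n, nu.size))
    absorb = (
        path[:, None] * pure
        + offset[:, None]
        + slope[:, None] * (nu - nu.mean())[None, :]
        + eps
    )
    return SpectraSet(grid=grid, absorbance=absorb, sample_ids=chem.sample_ids)


def add_reference_noise(
    chem: ChemistryReference, sd: float, seed: int = 0
) -> ChemistryReference:
    """Gaussian duplicate-assay error on the chemistry table, truncated at 0."""
    if sd < 0:
        raise ValueError("reference noise sd must be >= 0")
    if sd == 0:
        return ChemistryReference(chem.data.copy(), measured=chem.measured)
    rng = np.random.default_rng(seed)
    noisy = chem.data.to_numpy(float) + rng.normal(0.0, sd, size=chem.data.shape)
    noisy = np.clip(noisy, 0.0, None)
    return ChemistryReference(
        pd.DataFrame(noisy, index=chem.data.index, columns=chem.data.columns),
        measured=True,
    )
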