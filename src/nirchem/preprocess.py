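"""Spectral pretreatment: Savitzky-Golay first derivative and mean-centering.

The calibration workflow fits models on either the raw absorbance or its
first derivative, computed with a 2nd-order polynomial over a 25-point
window. Differentiation removes the per-sample additive baseline (offset
exactly, slope to first order) at the cost of relocating band maxima to the
inflection points of the native curve — the mechanism behind the systematic
peak shifts the downstream residual analysis quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .synth import SpectraSet, WavenumberGrid

__all__ = ["PretreatmentConfig", "savitzky_golay", "mean_center"]


@dataclass(frozen=True)
class PretreatmentConfig:
    kind: str = "first_derivative"  # raw | first_derivative
    window_points: int = 25
    poly_order: int = 2
    derivative_order: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("raw", "first_derivative"):
            raise ValueError("kind must be 'raw' or 'first_derivative'")
        if self.window_points % 2 == 0:
            raise ValueError("window_points must be odd")
        if self.window_points <= self.poly_order:
            raise ValueError("window_points must exceed poly_order")
        if self.derivative_order > self.poly_order:
            raise ValueError("derivative_order cannot exceed poly_order")


def savitzky_golay(
    spectra: SpectraSet, cfg: PretreatmentConfig | None = None
) -> SpectraSet:
    """Per-row Savitzky-Golay derivative, expressed per cm⁻¹.

    The (window−1)/2 edge points on each side are dropped: the local
    polynomial fit is only fully supported at interior points, and padded
    boundary values could masquerade as loading peaks. The output grid is
    therefore a contiguous sub-grid of the input.
    """
    cfg = cfg or PretreatmentConfig()
    if len(spectra.grid) < cfg.window_points:
        raise ValueError(
            f"grid has {len(spectra.grid)} points, shorter than the "
            f"{cfg.window_points}-point window"
        )
    step = spectra.grid.step_cm1
    deriv = savgol_filter(
        spectra.absorbance,
        window_length=cfg.window_points,
        polyorder=cfg.poly_order,
        deriv=cfg.derivative_order,
        delta=step,
        axis=1,
    )
    half = (cfg.window_points - 1) // 2
    return SpectraSet(
        grid=WavenumberGrid(spectra.grid.values[half:-half]),
        absorbance=deriv[:, half:-half],
        sample_ids=spectra.sample_ids,
        pretreatment="first_derivative",
    )


def mean_center(X: "SpectraSet | np.ndarray") -> tuple[np.ndarray, np.ndarray]:
    """Column-center a matrix; returns (centered, column means).

    The mean vector is retained by fitted models so new samples can be
    projected into the same centred space.
    """
    A = X.absorbance if isinstance(X, SpectraSet) else np.asarray(X, dtype=float)
    if A.ndim != 2 or A.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    mu = A.mean(axis=0)
    return A - mu, mu
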