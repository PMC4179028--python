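"""Loading/coefficient peak detection and band-assignment residuals.

A fitted calibration is interpreted through the local extrema ("peaks") of
its coefficient or loading curve: each peak wavenumber C is matched to the
nearest literature band assignment BA_L for the constituent, and the
residual R = C − BA_L measures how far the model places chemical information
from where the literature says the band sits. Pooled over constituents,
methods and pretreatments, the R values feed the precision (variance)
comparison between PCR and PLS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .synth import BandTable

__all__ = [
    "Peak",
    "ResidualRecord",
    "PeakShift",
    "detect_peaks",
    "match_to_assignments",
    "peak_shift",
    "residual",
]


@dataclass(frozen=True)
class Peak:
    wavenumber_cm1: float  # C
    value: float  # signed coefficient at the extremum
    prominence: float
    polarity: str  # "max" | "min"


@dataclass
class ResidualRecord:
    """One literature assignment and the peak (if any) matched to it."""

    constituent: str
    ba_l_cm1: float
    matched: bool
    c_cm1: float | None = None
    r_cm1: float | None = None
    method: str | None = None
    pretreatment: str | None = None


def residual(c_cm1: float, ba_l_cm1: float) -> float:
    """R = C − BA_L: model peak wavenumber minus literature assignment."""
    return c_cm1 - ba_l_cm1


def detect_peaks(
    wavenumbers: np.ndarray,
    values: np.ndarray,
    min_prominence_frac: float = 0.10,
) -> list[Peak]:
    """Local extrema of a coefficient curve, both polarities.

    Maxima of c and of −c are found separately; a peak is kept when its
    prominence reaches ``min_prominence_frac`` of the global |c| maximum, so
    the detector is invariant to rescaling the curve. A constant curve has
    no peaks.
    """
    wn = np.asarray(wavenumbers, dtype=float)
    v = np.asarray(values, dtype=float)
    if wn.size != v.size:
        raise ValueError("wavenumbers and values disagree in length")
    if v.size < 3:
        raise ValueError("profile too short for peak detection")
    scale = float(np.max(np.abs(v)))
    if scale == 0 or np.ptp(v) == 0:
        return []
    threshold = min_prominence_frac * scale
    out: list[Peak] = []
    for sign, polarity in ((1.0, "max"), (-1.0, "min")):
        idx, props = find_peaks(sign * v, prominence=threshold)
        for i, prom in zip(idx, props["prominences"]):
            out.append(
                Peak(
                    wavenumber_cm1=float(wn[i]),
                    value=float(v[i]),
                    prominence=float(prom),
                    polarity=polarity,
                )
            )
    out.sort(key=lambda p: p.wavenumber_cm1)
    return out


def match_to_assignments(
    peaks: list[Peak],
    bands: BandTable,
    constituent: str,
    window_cm1: float = 60.0,
) -> list[ResidualRecord]:
    """Assign detected peaks to the constituent's literature bands.

    Greedy globally-nearest-first matching: candidate (assignment, peak)
    pairs within ±window are taken in order of |C − BA_L|, each peak and
    each assignment used at most once. Distance ties resolve toward the
    lower assignment wavenumber, then the lower peak wavenumber.
    Assignments left without a peak are returned unmatched and carry no
    C or R.
    """
    if window_cm1 <= 0:
        raise ValueError("matching window must be positive")
    centers = bands.centers(constituent)
    if centers.size == 0:
        raise ValueError(f"no band assignments for {constituent!r}")
    cands = []
    for ai, ba in enumerate(centers):
        for pi, pk in enumerate(peaks):
            d = abs(pk.wavenumber_cm1 - ba)
            if d <= window_cm1:
                cands.append((d, ba, pk.wavenumber_cm1, ai, pi))
    cands.sort()
    assigned: dict[int, Peak] = {}
    used_peaks: set[int] = set()
    for d, ba, c, ai, pi in cands:
        if ai in assigned or pi in used_peaks:
            continue
        assigned[ai] = peaks[pi]
        used_peaks.add(pi)
    records = []
    for ai, ba in enumerate(centers):
        if ai in assigned:
            c = assigned[ai].wavenumber_cm1
            records.append(
                ResidualRecord(
                    constituent=constituent,
                    ba_l_cm1=float(ba),
                    matched=True,
                    c_cm1=c,
                    r_cm1=residual(c, float(ba)),
                )
            )
        else:
            records.append(
                ResidualRecord(constituent=constituent, ba_l_cm1=float(ba), matched=False)
            )
    return records


@dataclass
class PeakShift:
    """Dominant-peak displacement between two profiles over one region."""

    raw_c_cm1: float | None
    fd_c_cm1: float | None

    @property
    def missing(self) -> bool:
        return self.raw_c_cm1 is None or self.fd_c_cm1 is None

    @property
    def shift_cm1(self) -> float | None:
        if self.missing:
            return None
        return self.fd_c_cm1 - self.raw_c_cm1


def _dominant_peak_in(
    profile: tuple[np.ndarray, np.ndarray],
    region: tuple[float, float],
    min_prominence_frac: float,
) -> float | None:
    wn, v = profile
    peaks = [
        p
        for p in detect_peaks(wn, v, min_prominence_frac)
        if region[0] <= p.wavenumber_cm1 <= region[1]
    ]
    if not peaks:
        return None
    return max(peaks, key=lambda p: abs(p.value)).wavenumber_cm1


def peak_shift(
    profile_raw: tuple[np.ndarray, np.ndarray],
    profile_fd: tuple[np.ndarray, np.ndarray],
    target_region: tuple[float, float],
    min_prominence_frac: float = 0.10,
) -> PeakShift:
    """Shift of the dominant peak between a raw-spectra profile and its
    first-derivative counterpart within a wavenumber region.

    The dominant peak is the detected extremum of largest |value| in the
    region. Profiles lacking a peak there come back flagged missing.
    """
    lo, hi = sorted(target_region)
    return PeakShift(
        raw_c_cm1=_dominant_peak_in(profile_raw, (lo, hi), min_prominence_frac),
        fd_c_cm1=_dominant_peak_in(profile_fd, (lo, hi), min_prominence_frac),
    )
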