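"""Extracted-ion-chromatogram construction, peak integration and QC metrics.

Label-free quantification of glycated peptides works on centroided TOF-MS
scan series: for each annotated ion an XIC is built by summing centroid
intensities within a narrow m/z window (default ±0.02 Th) per scan, the
elution peak at the expected retention time is integrated above a local
baseline, and a peak counts as detected only when its signal-to-noise ratio
is at least 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScanSeries",
    "XIC",
    "PeakMeasurement",
    "extract_xic",
    "integrate_peak",
    "rsd",
    "qc_schedule",
]

SNR_THRESHOLD = 3.0
DEFAULT_MZ_TOL = 0.02
DEFAULT_WINDOW_MIN = 0.5

# MAD -> sigma for a normal distribution
_MAD_SCALE = 1.4826


@dataclass
class ScanSeries:
    """A centroided LC-MS run: per-scan retention time plus (m/z, intensity).

    ``times`` are minutes, strictly increasing; each entry of ``peaks`` is a
    ``(n_i, 2)`` array of centroid m/z and non-negative intensity.
    """

    times: np.ndarray
    peaks: list[np.ndarray]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("scan series requires a non-empty 1-D time axis")
        if len(self.peaks) != self.times.size:
            raise ValueError("one peak list per scan required")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("scan times must be strictly increasing")
        cleaned = []
        for p in self.peaks:
            arr = np.asarray(p, dtype=float).reshape(-1, 2)
            if np.any(arr[:, 1] < 0):
                raise ValueError("centroid intensities must be non-negative")
            cleaned.append(arr)
        self.peaks = cleaned

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class XIC:
    """An extracted ion chromatogram on the source run's time axis."""

    target_mz: float
    tolerance: float
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must align")


@dataclass
class PeakMeasurement:
    """Result of integrating one XIC peak."""

    apex_time: float
    apex_height: float
    area: float
    snr: float
    detected: bool = field(init=False)

    def __post_init__(self) -> None:
        self.detected = bool(self.snr >= SNR_THRESHOLD)


def extract_xic(series: ScanSeries, mz: float, tol: float = DEFAULT_MZ_TOL) -> XIC:
    """Build the XIC of ``mz`` ± ``tol`` by per-scan intensity summation."""
    if tol <= 0:
        raise ValueError("m/z tolerance must be positive")
    trace = np.zeros(len(series))
    for i, centroids in enumerate(series.peaks):
        if centroids.size:
            mask = np.abs(centroids[:, 0] - mz) <= tol
            trace[i] = centroids[mask, 1].sum()
    return XIC(mz, tol, series.times.copy(), trace)


def _noise_sigma(trace: np.ndarray, exclude: np.ndarray) -> float:
    """Robust noise estimate: MAD of the trace outside the peak window."""
    outside = trace[~exclude]
    if outside.size < 4:
        outside = trace
    med = np.median(outside)
    mad = np.median(np.abs(outside - med))
    return float(_MAD_SCALE * mad)


def integrate_peak(
    xic: XIC, expected_tr: float, window: float = DEFAULT_WINDOW_MIN
) -> PeakMeasurement:
    """Integrate the elution peak nearest ``expected_tr`` in an XIC.

    The apex is the trace maximum within ``expected_tr ± window``; the area
    is the trapezoidal integral of the contiguous above-baseline region
    around the apex, after subtracting a local linear baseline interpolated
    between the window edges.  S/N is apex height over an MAD-based noise
    sigma estimated from the trace outside the window.
    """
    if window <= 0:
        raise ValueError("integration window must be positive")
    t, y = xic.times, xic.intensities
    if not (t[0] <= expected_tr <= t[-1]):
        raise ValueError(
            f"expected retention time {expected_tr} outside trace span "
            f"[{t[0]}, {t[-1]}]"
        )
    in_win = (t >= expected_tr - window) & (t <= expected_tr + window)
    if not in_win.any():
        raise ValueError("integration window contains no scans")

    idx_win = np.flatnonzero(in_win)
    apex_rel = int(np.argmax(y[idx_win]))
    apex = idx_win[apex_rel]

    lo, hi = idx_win[0], idx_win[-1]
    baseline = np.interp(t, [t[lo], t[hi]], [y[lo], y[hi]])
    resid = y - baseline

    if resid[apex] <= 0:
        noise = _noise_sigma(y, in_win)
        snr = float(y[apex] / noise) if noise > 0 else 0.0
        return PeakMeasurement(float(t[apex]), float(y[apex]), 0.0, snr)

    # contiguous above-baseline region around the apex, clipped to the window
    left = apex
    while left > lo and resid[left - 1] > 0:
        left -= 1
    right = apex
    while right < hi and resid[right + 1] > 0:
        right += 1
    seg = slice(left, right + 1)
    area = float(np.trapezoid(np.clip(resid[seg], 0, None), t[seg]))

    noise = _noise_sigma(y, in_win)
    height = float(resid[apex])
    snr = float(height / noise) if noise > 0 else float("inf")
    return PeakMeasurement(float(t[apex]), height, area, snr)


def rsd(values) -> float:
    """Relative standard deviation in percent (sample SD over mean)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("RSD requires at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def qc_schedule(n_samples: int, period: int = 8) -> list[str]:
    """Injection order with a pooled-QC injection after every ``period``
    analytical samples, mirroring a quality-controlled LC-MS batch."""
    if n_samples < 1:
        raise ValueError("need at least one sample")
    if period < 1:
        raise ValueError("QC period must be >= 1")
    order: list[str] = []
    for i in range(1, n_samples + 1):
        order.append(f"S{i}")
        if i % period == 0:
            order.append("QC")
    return order
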