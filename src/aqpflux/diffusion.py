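"""From n(t) to the osmotic diffusivity D_n and single-channel permeability.

The collective coordinate of each channel is divided into non-overlapping
segments of a fixed time window (default 200 ps), each re-based to start at
zero.  Segments from all channels are pooled and interpreted as independent
realisations of a 1D random walk; the mean squared displacement

    MSD(τ) = ⟨(n(t0 + τ) − n(t0))²⟩

then satisfies the Einstein relation MSD(τ) = 2·D_n·τ, and D_n is half the
slope of an ordinary least-squares line fitted over the window (free
intercept, which absorbs any short-time artifact).  Permeabilities follow by
unit conversion:

    p_u,mon = v_w · D_n        (Å³/ps → cm³/s is a factor 1e−12)
    p_u,tet = 4 · p_u,mon

with v_w the average volume of one water molecule (29.9 Å³ by default, the
bulk molar volume 18.07 cm³/mol divided by Avogadro's number).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .collective_coordinate import CollectiveCoordinateSeries
from .exceptions import InsufficientDataError, SpecError

__all__ = [
    "MsdCurve",
    "PermeabilityEstimate",
    "segment",
    "msd",
    "fit_diffusivity",
    "permeability",
    "estimate_permeability",
    "DEFAULT_WINDOW_PS",
    "DEFAULT_WATER_VOLUME_A3",
]

DEFAULT_WINDOW_PS = 200.0
DEFAULT_WATER_VOLUME_A3 = 29.9
_A3_PER_PS_TO_CM3_PER_S = 1e-12


@dataclass
class MsdCurve:
    """Mean squared displacement of n over lag times τ (ps)."""

    lags_ps: np.ndarray
    msd: np.ndarray
    n_segments: int


@dataclass
class PermeabilityEstimate:
    """D_n with its OLS standard error and the derived permeabilities."""

    d_n: float  # 1/ps
    slope_stderr: float  # on D_n, 1/ps
    v_w: float  # Å³
    p_u_mon: float  # cm³/s
    p_u_tet: float  # cm³/s
    n_segments: int
    window_ps: float
    raw_slope: float  # 2·D_n before any clamping, 1/ps

    def to_dict(self) -> dict:
        return {
            "D_n_per_ps": self.d_n,
            "D_n_stderr_per_ps": self.slope_stderr,
            "v_w_A3": self.v_w,
            "p_u_mon_cm3_s": self.p_u_mon,
            "p_u_tet_cm3_s": self.p_u_tet,
            "n_segments": self.n_segments,
            "window_ps": self.window_ps,
        }


def segment(
    n: np.ndarray, dt_frame: float, window_ps: float = DEFAULT_WINDOW_PS
) -> np.ndarray:
    """Cut an n(t) series into non-overlapping, re-zeroed windows.

    Returns an array of shape (n_segments, w + 1) where w = window_ps /
    dt_frame frame intervals; consecutive segments share their boundary
    frame.  The trailing remainder that does not fill a window is discarded.
    """
    n = np.asarray(n, dtype=np.float64)
    w = window_ps / dt_frame
    if abs(w - round(w)) > 1e-9:
        raise SpecError(
            f"window ({window_ps} ps) must be an integer multiple of the frame "
            f"interval ({dt_frame} ps)"
        )
    w = int(round(w))
    n_intervals = len(n) - 1
    if n_intervals < w:
        raise InsufficientDataError(
            f"series spans {n_intervals * dt_frame} ps, shorter than one "
            f"{window_ps} ps window"
        )
    n_seg = n_intervals // w
    starts = np.arange(n_seg) * w
    segments = n[starts[:, None] + np.arange(w + 1)[None, :]]
    return segments - segments[:, :1]


def msd(segments: np.ndarray, dt_frame: float) -> MsdCurve:
    """Pool re-zeroed segments into a mean-squared-displacement curve."""
    segments = np.asarray(segments, dtype=np.float64)
    if segments.ndim != 2 or segments.shape[0] == 0:
        raise InsufficientDataError("msd requires at least one segment")
    curve = np.mean(segments**2, axis=0)
    lags = np.arange(segments.shape[1], dtype=np.float64) * dt_frame
    return MsdCurve(lags_ps=lags, msd=curve, n_segments=segments.shape[0])


def fit_diffusivity(
    curve: MsdCurve, fit_range: tuple[float, float] | None = None
) -> tuple[float, float]:
    """OLS fit of MSD on τ; returns (D_n, stderr) with D_n = slope / 2."""
    lags, values = curve.lags_ps, curve.msd
    if fit_range is not None:
        lo, hi = fit_range
        mask = (lags >= lo) & (lags <= hi)
        lags, values = lags[mask], values[mask]
    if len(lags) < 3:
        raise InsufficientDataError("fit range must contain at least three lags")
    if np.ptp(lags) == 0:
        raise InsufficientDataError("degenerate fit range: constant lag")
    res = stats.linregress(lags, values)
    return res.slope / 2.0, res.stderr / 2.0


def permeability(
    d_n: float,
    v_w: float = DEFAULT_WATER_VOLUME_A3,
    *,
    slope_stderr: float = 0.0,
    n_segments: int = 0,
    window_ps: float = DEFAULT_WINDOW_PS,
) -> PermeabilityEstimate:
    """Convert a fitted D_n (1/ps) into monomer and tetramer permeabilities."""
    if v_w <= 0:
        raise SpecError("water molecular volume v_w must be positive")
    raw_slope = 2.0 * d_n
    if d_n < 0:
        warnings.warn(
            f"negative fitted diffusivity ({d_n:.3e}/ps); permeability clamped "
            "to zero, raw slope retained",
            stacklevel=2,
        )
        d_n_eff = 0.0
    else:
        d_n_eff = d_n
    p_mon = v_w * d_n_eff * _A3_PER_PS_TO_CM3_PER_S
    return PermeabilityEstimate(
        d_n=d_n_eff,
        slope_stderr=slope_stderr,
        v_w=v_w,
        p_u_mon=p_mon,
        p_u_tet=4.0 * p_mon,
        n_segments=n_segments,
        window_ps=window_ps,
        raw_slope=raw_slope,
    )


def estimate_permeability(
    series: Sequence[CollectiveCoordinateSeries],
    window_ps: float = DEFAULT_WINDOW_PS,
    v_w: float = DEFAULT_WATER_VOLUME_A3,
    fit_range: tuple[float, float] | None = None,
) -> tuple[PermeabilityEstimate, MsdCurve]:
    """Full chain: pool segments from all channels, fit, convert units.

    All series must share the same frame interval; segments from every
    channel are pooled into one MSD before the fit.
    """
    if not series:
        raise InsufficientDataError("no collective-coordinate series supplied")
    dt = series[0].dt_frame
    for s in series[1:]:
        if abs(s.dt_frame - dt) > 1e-9:
            raise SpecError("all channels must share one frame interval")
    pooled = np.vstack([segment(s.n, dt, window_ps) for s in series])
    curve = msd(pooled, dt)
    d_n, stderr = fit_diffusivity(curve, fit_range)
    est = permeability(
        d_n,
        v_w,
        slope_stderr=stderr,
        n_segments=pooled.shape[0],
        window_ps=window_ps,
    )
    return est, curve
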