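"""CD melting-curve analysis: baseline handling and Tm extraction.

The melting temperature is read from the 295 nm ellipticity trace in two
ways: (i) the temperature of the extremum of the smoothed first derivative
after subtracting linear pre- and post-transition baselines — the standard
derivative reading of a sigmoidal melt — and (ii) an explicit two-state
sigmoid fit with sloping baselines, kept as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .core import MeltingCurve, ValidationError


class NoTransitionError(ValueError):
    """The curve shows no resolvable melting transition."""


class FitError(RuntimeError):
    pass


#: Fraction of the temperature range used for each terminal baseline fit.
BASELINE_FRACTION = 0.10


@dataclass
class MeltingResult:
    tm: float  # deg C
    derivative_peak_height: float  # |d ellipticity / dT| at the transition
    method: str  # "derivative" | "two_state_fit"


def _baseline_windows(temp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    span = temp[-1] - temp[0]
    lo = temp <= temp[0] + BASELINE_FRACTION * span
    hi = temp >= temp[-1] - BASELINE_FRACTION * span
    return lo, hi


def extract_tm(curve: MeltingCurve, smooth_window: float = 5.0) -> MeltingResult:
    """Tm as the extremum of the smoothed baseline-subtracted derivative.

    A line fitted to the lowest 10% of the temperature range is subtracted
    (removing the folded-state baseline; the post-transition line is fitted
    as well and used for the noise gate).  The derivative is computed with a
    Savitzky-Golay filter (window ``smooth_window`` deg C, quadratic), and
    the peak position is refined by parabolic interpolation of the three
    points around the extremum.  Raises :class:`NoTransitionError` when the
    derivative extremum does not exceed 3x the baseline derivative noise.
    """
    temp, theta = curve.temperature, curve.ellipticity
    if temp.size < 20:
        raise ValidationError("need >= 20 points for Tm extraction")
    lo, hi = _baseline_windows(temp)
    c_lo = np.polyfit(temp[lo], theta[lo], 1)
    sub = theta - np.polyval(c_lo, temp)

    dT = float(np.median(np.diff(temp)))
    win = max(5, int(round(smooth_window / dT)) | 1)  # odd, >= 5 points
    win = min(win, temp.size if temp.size % 2 else temp.size - 1)
    deriv = savgol_filter(sub, window_length=win, polyorder=2, deriv=1, delta=dT)

    noise = float(np.std(np.concatenate([deriv[lo], deriv[hi]])))
    interior = ~(lo | hi)
    if not np.any(interior):
        raise ValidationError("baseline windows cover the whole curve")
    idx_interior = np.nonzero(interior)[0]
    k = idx_interior[np.argmax(np.abs(deriv[idx_interior]))]
    peak = abs(float(deriv[k]))
    scale = float(np.ptp(theta)) or 1.0
    gate = max(3.0 * noise, 1e-9 * scale / dT)
    if peak <= gate:
        raise NoTransitionError(
            f"derivative extremum {peak:.3g} does not exceed noise gate {gate:.3g}"
        )
    tm = _parabolic_vertex(temp, np.abs(deriv), k)
    return MeltingResult(tm=float(tm), derivative_peak_height=peak, method="derivative")


def _parabolic_vertex(x: np.ndarray, y: np.ndarray, k: int) -> float:
    if k == 0 or k == x.size - 1:
        return float(x[k])
    y0, y1, y2 = y[k - 1], y[k], y[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[k])
    offset = 0.5 * (y0 - y2) / denom
    offset = min(max(offset, -1.0), 1.0)
    return float(x[k] + offset * (x[k] - x[k - 1]))


def _two_state(T, tm, width, af, bf, au, bu):
    alpha = 1.0 / (1.0 + np.exp((tm - T) / width))
    folded = af + bf * (T - T.mean())
    unfolded = au + bu * (T - T.mean())
    return folded * (1 - alpha) + unfolded * alpha


def fit_two_state(curve: MeltingCurve) -> tuple[float, float]:
    """Two-state sigmoid fit with sloping baselines; returns (tm, width).

    The width parameter is the logistic scale in deg C (transition breadth
    ~ 4*width).  Initialized from the derivative method when possible.
    """
    temp, theta = curve.temperature, curve.ellipticity
    if temp.size < 20:
        raise ValidationError("need >= 20 points for a two-state fit")
    lo, hi = _baseline_windows(temp)
    try:
        tm0 = extract_tm(curve).tm
    except (NoTransitionError, ValidationError):
        tm0 = float(temp.mean())
    af0 = float(theta[lo].mean())
    au0 = float(theta[hi].mean())
    p0 = [tm0, 3.0, af0, 0.0, au0, 0.0]
    try:
        popt, _ = curve_fit(
            _two_state,
            temp,
            theta,
            p0=p0,
            bounds=(
                [temp[0], 0.1, -np.inf, -np.inf, -np.inf, -np.inf],
                [temp[-1], (temp[-1] - temp[0]), np.inf, np.inf, np.inf, np.inf],
            ),
            maxfev=20000,
        )
    except RuntimeError as e:
        raise FitError(f"two-state melting fit did not converge: {e}") from None
    return float(popt[0]), float(popt[1])
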