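"""Mono- and bi-exponential fitting of unfolding and conversion kinetics.

HDX decays of protected imino protons, hybridization-trap decays of
quadruplex imino signal, and real-time CD conversion traces are all modelled
as offset exponentials:

    mono:  S(t) = offset + A * exp(-t/tau)
    bi:    S(t) = offset + A * (f1 * exp(-t/tau1) + f2 * exp(-t/tau2)),
           tau1 < tau2, f1 + f2 = 1

with the sign of A auto-detected (negative A gives a rising trace).  The
bi-exponential fit uses variable projection — amplitudes solved linearly for
each (tau1, tau2) — with multi-start over a log-spaced time-constant grid,
which is robust against the notorious local minima of sums of exponentials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import KineticTrace, ValidationError


class FitError(RuntimeError):
    """Kinetic fit failed to converge."""


#: Fitted tau larger than this multiple of the sampled time span is reported
#: as "no decay" (the trace carries no curvature information at that scale).
NO_DECAY_SPAN_FACTOR = 1e4

#: tau2/tau1 below this is flagged as degenerate (use the mono model).
DEGENERACY_RATIO = 1.5


@dataclass
class KineticFit:
    model: str  # "mono" | "bi"
    taus: tuple[float, ...]  # ascending, in the trace's time unit
    amplitudes: tuple[float, ...]  # fractions of total amplitude (sum to 1)
    amplitude_total: float  # signed: >0 decay, <0 rise
    offset: float
    r2: float
    stderr_taus: tuple[float, ...]
    time_unit: str
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def amplitude_percent(self) -> tuple[float, ...]:
        return tuple(100.0 * f for f in self.amplitudes)


@dataclass
class ConditionSummary:
    condition: str  # "na" | "na_k_simultaneous" | "na_k_pretreat"
    mean_tau: float
    sd_tau: float
    n_residues: int
    time_unit: str = "min"


def _prep(trace: KineticTrace, min_points: int) -> tuple[np.ndarray, np.ndarray]:
    t, s = trace.after_dead_time()
    if t.size < min_points:
        raise ValidationError(
            f"need >= {min_points} points after dead time, got {t.size}"
        )
    return t, s


def _r2(s: np.ndarray, fit: np.ndarray) -> float:
    ss_res = float(np.sum((s - fit) ** 2))
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def fit_monoexp(trace: KineticTrace) -> KineticFit:
    """Least-squares fit of S(t) = offset + A*exp(-t/tau).

    Decay vs rise is detected from the endpoints.  A constant trace (no
    resolvable amplitude) or a tau far beyond the sampled span returns a
    result carrying the ``no_decay`` flag instead of raising.
    """
    t, s = _prep(trace, 5)
    span = float(t[-1] - t[0])
    scale = float(np.max(np.abs(s))) or 1.0
    if np.ptp(s) < 1e-9 * scale:
        return KineticFit(
            model="mono",
            taus=(math.inf,),
            amplitudes=(1.0,),
            amplitude_total=0.0,
            offset=float(s.mean()),
            r2=0.0,
            stderr_taus=(math.nan,),
            time_unit=trace.time_unit,
            flags=("no_decay",),
        )

    a0 = float(s[0] - s[-1])  # >0: decay, <0: rise
    off0 = float(s[-1])

    def resid(p: np.ndarray) -> np.ndarray:
        off, a, logtau = p
        return off + a * np.exp(-t / 10.0**logtau) - s

    best = None
    for tau0 in (span / 10.0, span / 3.0, span):
        sol = least_squares(
            resid,
            np.array([off0, a0, math.log10(tau0)]),
            xtol=1e-14,
            ftol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    off, a, logtau = best.x
    tau = 10.0**logtau
    flags: list[str] = []
    if tau > NO_DECAY_SPAN_FACTOR * span:
        flags.append("no_decay")
    fitted = off + a * np.exp(-t / tau)
    se = _tau_stderr(best, index=2, tau=tau)
    return KineticFit(
        model="mono",
        taus=(float(tau),),
        amplitudes=(1.0,),
        amplitude_total=float(a),
        offset=float(off),
        r2=_r2(s, fitted),
        stderr_taus=(se,),
        time_unit=trace.time_unit,
        flags=tuple(flags),
    )


def _tau_stderr(sol, index: int, tau: float) -> float:
    """Delta-method stderr of tau from a log10(tau)-parameterized solution."""
    resid = sol.fun
    n, p = sol.jac.shape
    dof = max(n - p, 1)
    s2 = float(resid @ resid) / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
    except np.linalg.LinAlgError:
        return math.nan
    var = cov[index, index]
    if var < 0:
        return math.nan
    return float(tau * math.log(10.0) * math.sqrt(var))


def fit_biexp(trace: KineticTrace) -> KineticFit:
    """Variable-projection fit of a two-exponential trace.

    For each candidate (tau1, tau2) the offset and the two amplitudes are
    solved by linear least squares; the nonlinear search runs over
    (log tau1, log tau2) from a multi-start grid of time-constant ratios.
    Results with tau2/tau1 < 1.5 are flagged degenerate — the data do not
    support two phases and the mono model should be used.
    """
    t, s = _prep(trace, 8)
    span = float(t[-1] - t[0])
    if np.ptp(s) == 0:
        raise FitError("constant trace: no amplitude to fit")

    def linear_solve(logtaus: np.ndarray):
        taus = 10.0**logtaus
        A = np.column_stack(
            [np.ones_like(t), np.exp(-t / taus[0]), np.exp(-t / taus[1])]
        )
        coef, *_ = np.linalg.lstsq(A, s, rcond=None)
        resid = A @ coef - s
        return resid, coef

    def resid_fn(logtaus: np.ndarray) -> np.ndarray:
        return linear_solve(logtaus)[0]

    tau1_grid = np.array([span / 100.0, span / 30.0, span / 10.0, span / 3.0])
    ratio_grid = np.array([3.0, 10.0, 30.0, 100.0])
    best = None
    for tau1 in tau1_grid:
        for ratio in ratio_grid:
            x0 = np.log10(np.array([tau1, tau1 * ratio]))
            sol = least_squares(resid_fn, x0, xtol=1e-14, ftol=1e-14)
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:  # pragma: no cover
        raise FitError("bi-exponential fit failed from all starts")

    logtaus = np.sort(best.x)
    _, coef = linear_solve(logtaus)
    taus = 10.0**logtaus
    off, a1, a2 = float(coef[0]), float(coef[1]), float(coef[2])
    total = a1 + a2
    flags: list[str] = []
    if taus[1] / taus[0] < DEGENERACY_RATIO:
        flags.append("degenerate_taus")
    if total == 0 or a1 * a2 < 0:
        flags.append("degenerate_amplitudes")
        f1 = 1.0 if abs(a1) >= abs(a2) else 0.0
    else:
        f1 = a1 / total
    if min(f1, 1 - f1) < 1e-3 and "degenerate_taus" not in flags:
        flags.append("degenerate_amplitudes")
    fitted = off + a1 * np.exp(-t / taus[0]) + a2 * np.exp(-t / taus[1])
    se = _biexp_tau_stderr(t, s, taus, np.array([off, a1, a2]))
    return KineticFit(
        model="bi",
        taus=(float(taus[0]), float(taus[1])),
        amplitudes=(float(f1), float(1 - f1)),
        amplitude_total=float(total),
        offset=off,
        r2=_r2(s, fitted),
        stderr_taus=se,
        time_unit=trace.time_unit,
        flags=tuple(flags),
    )


def _biexp_tau_stderr(t, s, taus, lin) -> tuple[float, float]:
    """Covariance over the full 5-parameter model, reported for the taus."""
    off, a1, a2 = lin
    e1 = np.exp(-t / taus[0])
    e2 = np.exp(-t / taus[1])
    J = np.column_stack(
        [
            np.ones_like(t),
            e1,
            e2,
            a1 * e1 * t / taus[0] ** 2,
            a2 * e2 * t / taus[1] ** 2,
        ]
    )
    resid = off + a1 * e1 + a2 * e2 - s
    dof = max(t.size - 5, 1)
    s2 = float(resid @ resid) / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        return (math.nan, math.nan)
    var = np.clip(np.diag(cov)[3:], 0.0, None)
    return (float(math.sqrt(var[0])), float(math.sqrt(var[1])))


def summarize_condition(fits: list[KineticFit], condition: str) -> ConditionSummary:
    """Arithmetic mean and sample SD of per-residue time constants."""
    if not fits:
        raise ValidationError("no fits to summarize")
    taus = np.array([f.taus[0] for f in fits], dtype=float)
    if np.any(~np.isfinite(taus)):
        raise ValidationError("cannot summarize fits flagged as no-decay")
    units = {f.time_unit for f in fits}
    if len(units) != 1:
        raise ValidationError(f"mixed time units {units}")
    sd = float(np.std(taus, ddof=1)) if taus.size > 1 else 0.0
    return ConditionSummary(
        condition=condition,
        mean_tau=float(taus.mean()),
        sd_tau=sd,
        n_residues=int(taus.size),
        time_unit=units.pop(),
    )


def fold_difference(
    a: ConditionSummary, b: ConditionSummary
) -> tuple[float, float]:
    """Ratio mean_b/mean_a with first-order propagated uncertainty.

    The condition SDs are treated as the uncertainties of the two means, so
    sigma_ratio = ratio * sqrt((sd_a/mean_a)**2 + (sd_b/mean_b)**2).
    """
    if a.mean_tau <= 0 or b.mean_tau <= 0:
        raise ValueError("condition means must be positive")
    ratio = b.mean_tau / a.mean_tau
    rel = math.sqrt((a.sd_tau / a.mean_tau) ** 2 + (b.sd_tau / b.mean_tau) ** 2)
    return ratio, ratio * rel
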