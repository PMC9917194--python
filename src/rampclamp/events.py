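"""Event extraction from force and contact time series.

Rupture peaks from ramp force-time curves, dissociation times from buried-
SASA (or contact-count) floor crossings, named-bond breakage, AFM adhesion
event detection with a robust median/MAD noise model, adhesion frequencies,
clamp-phase lifetimes with censoring, force-binned lifetime tables, and a
two-pathway (catch + slip) Bell model of force-dependent bond lifetime

    τ(F) = 1 / ( k_c·exp(−F·x_c/kBT) + k_s·exp(+F·x_s/kBT) )

whose lifetime optimum sits at F* = kBT/(x_c + x_s) · ln(k_c·x_c/(k_s·x_s)).
The two-pathway form is the minimal standard model for catch-slip bonds; it
is fitted here on log lifetimes, statsmodels-style (CatchSlipModel.fit()
returns a CatchSlipResults with estimates, uncertainties and a summary()).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .errors import NumericalError, UsageError
from .io import AFMCurve, ForceLog
from .units import kbt_pn_a


# ---------------------------------------------------------------------------
# Rupture / dissociation / bond breakage (simulation side)
# ---------------------------------------------------------------------------

@dataclass
class RuptureEvent:
    detected: bool
    rupture_force: float | None = None  # pN
    rupture_time: float | None = None   # ns


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(x, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="valid")
    return out[: len(x)] if len(out) > len(x) else out


def rupture_event(
    log: ForceLog,
    smooth_window: float = 0.1,
    drop_fraction: float = 0.5,
) -> RuptureEvent:
    """Locate the rupture peak of a force-time curve.

    The force is smoothed with a centred moving average of ``smooth_window``
    (ns); the peak is the smoothed global maximum, accepted only if the
    smoothed force later falls below ``drop_fraction × peak`` and stays there
    for at least one window. The reported force/time come from the raw sample
    nearest the smoothed peak.
    """
    t = log.times
    f = log.forces
    if len(t) < 10:
        raise UsageError("rupture detection needs at least 10 samples")
    dt = np.median(np.diff(t))
    window = max(1, int(round(smooth_window / dt)))
    if window >= len(t):
        raise UsageError("smoothing window is not shorter than the record")
    smoothed = _moving_average(f, window)
    peak_idx = int(np.argmax(smoothed))
    threshold = drop_fraction * smoothed[peak_idx]
    below = smoothed[peak_idx:] < threshold
    detected = False
    run = 0
    for flag in below:
        run = run + 1 if flag else 0
        if run >= window:
            detected = True
            break
    if not detected:
        return RuptureEvent(detected=False)
    # report the raw extremum nearest the smoothed peak (within one window)
    lo = max(0, peak_idx - window)
    hi = min(len(f), peak_idx + window + 1)
    raw_idx = lo + int(np.argmax(f[lo:hi]))
    return RuptureEvent(
        detected=True,
        rupture_force=float(f[raw_idx]),
        rupture_time=float(t[raw_idx]),
    )


def dissociation_time(
    times: np.ndarray,
    series: np.ndarray,
    floor_fraction: float = 0.1,
    dwell: float = 1.0,
    plateau_window: float = 1.0,
) -> float | None:
    """First time the series drops below ``floor_fraction`` of its initial
    plateau mean and stays below for at least ``dwell`` ns; None if never.

    The initial plateau mean is taken over the first ``plateau_window`` ns.
    """
    times = np.asarray(times, float)
    series = np.asarray(series, float)
    if times.size < 2:
        raise UsageError("dissociation detection needs at least 2 samples")
    if times[-1] - times[0] < plateau_window:
        raise UsageError("record shorter than the initial plateau window")
    plateau = series[times <= times[0] + plateau_window].mean()
    floor = floor_fraction * plateau
    below = series < floor
    i = 0
    n = len(times)
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if times[j - 1] - times[i] >= dwell:
                return float(times[i])
            i = j
        else:
            i += 1
    return None


def bond_breakage(
    presence: np.ndarray,
    log: ForceLog,
    final_gap: float = 1.0,
) -> tuple[float, float] | None:
    """Breakage (time, force) of a named bond: the start of the final absence
    run of length >= ``final_gap`` ns, with force interpolated from the log.

    ``presence`` must be a per-sample boolean aligned with the log's times.
    Returns None if the bond was never present, or if its final absence run
    is shorter than ``final_gap`` (transient flicker), or it never breaks.
    """
    presence = np.asarray(presence, dtype=bool)
    t = log.times
    if presence.shape != t.shape:
        raise UsageError("presence series must align with the force log")
    if not presence.any():
        return None
    last_present = int(np.flatnonzero(presence)[-1])
    if last_present == len(t) - 1:
        return None  # still present at the end
    t_break = t[last_present + 1]
    if t[-1] - t_break < final_gap:
        return None
    force = float(np.interp(t_break, t, log.forces))
    return float(t_break), force


# ---------------------------------------------------------------------------
# AFM adhesion events
# ---------------------------------------------------------------------------

@dataclass
class AdhesionEvent:
    rupture_force: float  # pN above baseline
    start_index: int
    end_index: int
    position_nm: float


def detect_adhesion(
    curve: AFMCurve, noise_k: float = 3.0, min_samples: int = 3
) -> list[AdhesionEvent]:
    """Adhesion events on the retract trace.

    Baseline = median of the final 20% of retract samples; noise σ = 1.4826 ×
    MAD of that segment. Samples above baseline + noise_k·σ are clustered,
    merging clusters separated by at most two sub-threshold samples (noise
    dips inside one excursion); a cluster qualifies as an adhesion event when
    it has at least ``min_samples`` samples and the force returns
    discontinuously at its end: the cluster maximum exceeds the
    post-excursion level (mean of the next ≤3 samples) by more than
    noise_k·σ. Event rupture force = maximum excursion above baseline. The
    width requirement rejects single-sample noise spikes, which a bare
    threshold+step rule would accept far more often than 1% per trace.
    """
    retract = curve.phase("retract")
    if retract.empty:
        raise UsageError("AFM curve has no retract phase")
    f = retract["force_pN"].to_numpy(float)
    z = retract["piezo_nm"].to_numpy(float)
    n_tail = max(1, int(0.2 * len(f)))
    if len(f) < 50:
        raise UsageError("retract trace too short for baseline estimation (< 50 samples)")
    tail = f[-n_tail:]
    baseline = float(np.median(tail))
    sigma = 1.4826 * float(np.median(np.abs(tail - np.median(tail))))
    sigma = max(sigma, 1e-12)
    high = baseline + noise_k * sigma
    idx = np.flatnonzero(f > high)
    events: list[AdhesionEvent] = []
    if idx.size == 0:
        return events
    # cluster threshold crossings, bridging gaps of <= 2 samples
    breaks = np.flatnonzero(np.diff(idx) > 3)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    n = len(f)
    for s, e in zip(starts, ends):
        i, j = int(idx[s]), int(idx[e])
        if e - s + 1 < min_samples:
            continue
        peak = int(i + np.argmax(f[i : j + 1]))
        post = f[j + 1 : j + 4]
        if post.size and (f[peak] - float(np.mean(post))) > noise_k * sigma:
            events.append(
                AdhesionEvent(
                    rupture_force=float(f[peak] - baseline),
                    start_index=i,
                    end_index=j,
                    position_nm=float(z[peak]),
                )
            )
    return events


def adhesion_frequency(
    cycle_results: Sequence[bool],
    spots: Sequence | None = None,
) -> pd.DataFrame:
    """Per-spot adhesion frequency (%) plus a pooled mean ± SEM row.

    ``cycle_results`` are per-cycle booleans; ``spots`` labels group cycles
    into spots (one spot if omitted). Frequencies in percent.
    """
    adhesive = np.asarray(cycle_results, dtype=bool)
    if adhesive.size == 0:
        raise UsageError("no cycles given")
    spots = np.zeros(adhesive.size, dtype=int) if spots is None else np.asarray(spots)
    df = pd.DataFrame({"spot": spots, "adhesive": adhesive})
    per_spot = df.groupby("spot", sort=True)["adhesive"].agg(["sum", "count"])
    per_spot["frequency_pct"] = 100.0 * per_spot["sum"] / per_spot["count"]
    freqs = per_spot["frequency_pct"].to_numpy()
    sem = float(np.std(freqs, ddof=1) / np.sqrt(len(freqs))) if len(freqs) > 1 else float("nan")
    out = per_spot.reset_index().rename(columns={"sum": "adhesive_cycles", "count": "cycles"})
    out.attrs["mean_pct"] = float(np.mean(freqs))
    out.attrs["sem_pct"] = sem
    return out


# ---------------------------------------------------------------------------
# Lifetimes
# ---------------------------------------------------------------------------

@dataclass
class LifetimeRecord:
    clamp_force: float  # pN
    lifetime: float     # s (AFM) or ns (simulation)
    censored: bool = False

    def __post_init__(self):
        if not self.censored and self.lifetime <= 0:
            raise UsageError("lifetime must be positive")


def lifetime_from_clamp(
    log: ForceLog | AFMCurve,
    setpoint: float,
    tolerance: float,
) -> LifetimeRecord:
    """Bond lifetime at a clamped force setpoint.

    Lifetime runs from first entering setpoint ± tolerance to the rupture
    step, defined as the force leaving the band downward (below
    setpoint − tolerance) permanently. Censored if the record ends in-band.
    """
    if isinstance(log, AFMCurve):
        data = log.phase("retract")
        if "time_s" not in data.columns:
            raise UsageError("AFM clamp analysis requires a time_s column")
        t = data["time_s"].to_numpy(float)
        f = data["force_pN"].to_numpy(float)
    else:
        t = log.times
        f = log.forces
    in_band = np.abs(f - setpoint) <= tolerance
    if not in_band.any():
        raise UsageError("no clamp segment within the tolerance band")
    enter = int(np.flatnonzero(in_band)[0])
    below = f < setpoint - tolerance
    for i in range(enter + 1, len(f)):
        if below[i] and below[i:].all():
            return LifetimeRecord(clamp_force=setpoint,
                                  lifetime=float(t[i] - t[enter]), censored=False)
    if in_band[-1]:
        return LifetimeRecord(clamp_force=setpoint,
                              lifetime=float(t[-1] - t[enter]), censored=True)
    raise UsageError("force left the clamp band but not downward-permanently; "
                     "no rupture step identifiable")


def bin_lifetimes(
    records: Sequence[LifetimeRecord],
    bin_edges: Sequence[float],
) -> pd.DataFrame:
    """Force-binned lifetime table (left-closed, right-open bins).

    Censored records are excluded from means but counted per bin. Empty bins
    are reported with count 0 and no mean.
    """
    edges = np.asarray(bin_edges, float)
    if edges.size < 2:
        raise UsageError("need at least two bin edges")
    rows = []
    forces = np.array([r.clamp_force for r in records])
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (forces >= lo) & (forces < hi)
        sel = [records[i] for i in np.flatnonzero(mask)]
        lifetimes = np.array([r.lifetime for r in sel if not r.censored])
        n_cens = sum(r.censored for r in sel)
        row = {
            "force_lo": lo, "force_hi": hi,
            "n": int(lifetimes.size), "n_censored": int(n_cens),
            "mean": float(np.mean(lifetimes)) if lifetimes.size else np.nan,
            "sem": float(np.std(lifetimes, ddof=1) / np.sqrt(lifetimes.size))
            if lifetimes.size > 1 else np.nan,
        }
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Catch-slip model
# ---------------------------------------------------------------------------

def catch_slip_lifetime(force, k_c, x_c, k_s, x_s, kbt):
    """Mean lifetime τ(F) of the two-pathway model (same units as 1/k)."""
    force = np.asarray(force, float)
    rate = k_c * np.exp(-force * x_c / kbt) + k_s * np.exp(force * x_s / kbt)
    return 1.0 / rate


def optimum_force(k_c, x_c, k_s, x_s, kbt):
    """Analytic lifetime-maximising force F*; None if either pathway vanishes."""
    if k_c <= 0 or k_s <= 0 or x_c + x_s <= 0 or x_c <= 0 or x_s <= 0:
        return None
    return kbt / (x_c + x_s) * np.log(k_c * x_c / (k_s * x_s))


@dataclass
class CatchSlipResults:
    """Fit results for the two-pathway model.

    Rates are in inverse lifetime units; barrier distances in Å; ``fstar``
    is the analytic lifetime optimum, and ``classification`` is 'biphasic'
    when that optimum is interior to the observed force range.
    """

    k_c: float
    x_c: float
    k_s: float
    x_s: float
    kbt: float
    fstar: float | None
    classification: str
    cov: np.ndarray | None
    param_se: np.ndarray | None
    residuals: np.ndarray
    forces: np.ndarray
    lifetimes: np.ndarray

    @property
    def params(self) -> dict:
        return {"k_c": self.k_c, "x_c": self.x_c, "k_s": self.k_s, "x_s": self.x_s}

    def predict(self, force) -> np.ndarray:
        return catch_slip_lifetime(force, self.k_c, self.x_c, self.k_s, self.x_s, self.kbt)

    def summary(self) -> str:
        lines = ["Two-pathway catch-slip bond fit",
                 "=" * 34,
                 f"{'param':>8} {'estimate':>12} {'std err':>10}"]
        ses = self.param_se if self.param_se is not None else [np.nan] * 4
        for name, value, se in zip(("k_c", "x_c", "k_s", "x_s"),
                                   (self.k_c, self.x_c, self.k_s, self.x_s), ses):
            lines.append(f"{name:>8} {value:>12.5g} {se:>10.3g}")
        fstar = "n/a" if self.fstar is None else f"{self.fstar:.3g} pN"
        lines.append(f"optimum force F*: {fstar}")
        lines.append(f"classification:  {self.classification}")
        lines.append(f"RSS (log-lifetime): {float(np.sum(self.residuals ** 2)):.4g}")
        return "\n".join(lines)


class CatchSlipModel:
    """Two-pathway Bell model of force-dependent lifetime, fitted on
    log lifetimes by least squares.

    Parameters
    ----------
    forces, lifetimes :
        Per-level mean lifetimes, or raw per-event lifetimes. Raw lifetimes
        enable the exponential maximum-likelihood fit (the default and the
        statistically efficient choice); the least-squares mode fits log
        per-level mean lifetimes.
    temperature :
        Kelvin; sets kBT (pN·Å) for the Bell exponents (x in Å, F in pN).
    """

    def __init__(self, forces, lifetimes, temperature: float = 310.0):
        forces = np.asarray(forces, float)
        lifetimes = np.asarray(lifetimes, float)
        if forces.shape != lifetimes.shape:
            raise UsageError("forces and lifetimes must have the same shape")
        levels = np.unique(forces)
        if levels.size < 4:
            raise UsageError("need lifetimes at >= 4 force levels")
        mean_tau = np.array([lifetimes[forces == f].mean() for f in levels])
        if np.any(mean_tau <= 0):
            raise UsageError("mean lifetimes must be positive")
        self.raw_forces = forces
        self.raw_lifetimes = lifetimes
        self.forces = levels
        self.lifetimes = mean_tau
        self.kbt = kbt_pn_a(temperature)
        self.default_method = "mle"

    @classmethod
    def from_records(cls, records: Sequence[LifetimeRecord], temperature: float = 310.0):
        keep = [r for r in records if not r.censored]
        return cls([r.clamp_force for r in keep], [r.lifetime for r in keep], temperature)

    @classmethod
    def from_binned(cls, table: pd.DataFrame, temperature: float = 310.0):
        """From a bin_lifetimes table; only per-bin means are available, so
        the default fit method becomes least squares."""
        ok = table.dropna(subset=["mean"])
        centers = 0.5 * (ok["force_lo"] + ok["force_hi"])
        model = cls(centers.to_numpy(), ok["mean"].to_numpy(), temperature)
        model.default_method = "ls"
        return model

    def _initial_guesses(self) -> list[np.ndarray]:
        """Data-derived starting points (multi-start guards against local
        optima when the tail-slope estimate is noisy)."""
        f, tau, kbt = self.forces, self.lifetimes, self.kbt
        log_tau = np.log(tau)
        tail = slice(max(0, len(f) - 2), len(f))
        slope_tail = np.polyfit(f[tail], log_tau[tail], 1)[0] if len(f) > 1 else -0.01
        x_tail = max(1e-3, -slope_tail * kbt)
        guesses = []
        for x_s0 in dict.fromkeys((x_tail, 1.0, 2.0, 4.0, 8.0)):
            k_s0 = max(1e-12, 1.0 / tau[-1] * np.exp(-f[-1] * x_s0 / kbt))
            x_c0 = x_s0
            k_c0 = max(1e-12, 1.0 / tau[0] * np.exp(f[0] * x_c0 / kbt))
            guesses.append(np.array([np.log(k_c0), x_c0, np.log(k_s0), x_s0]))
        return guesses

    def fit(self, method: str | None = None) -> CatchSlipResults:
        """Fit the two-pathway model.

        ``method="mle"`` (default for raw lifetimes): exponential maximum
        likelihood over the raw lifetimes — the efficient estimator, needed
        to pin the strongly correlated catch-leg parameters from a few
        hundred events per level. ``method="ls"``: least squares on log
        per-level mean lifetimes (default for binned input).
        """
        method = self.default_method if method is None else method
        f, tau, kbt = self.forces, self.lifetimes, self.kbt
        log_tau = np.log(tau)
        guesses = self._initial_guesses()
        lower = np.array([-50.0, 0.0, -50.0, 0.0])
        upper = np.array([50.0, 50.0, 50.0, 50.0])

        def residual(theta):
            log_kc, x_c, log_ks, x_s = theta
            rate = np.exp(log_kc - f * x_c / kbt) + np.exp(log_ks + f * x_s / kbt)
            return -np.log(rate) - log_tau

        if method == "ls":
            best = None
            for theta0 in guesses:
                sol = least_squares(residual, theta0, bounds=(lower, upper),
                                    xtol=1e-14, ftol=1e-14, gtol=1e-14)
                if sol.success and (best is None or sol.cost < best.cost):
                    best = sol
            if best is None:
                raise NumericalError("catch-slip fit did not converge",
                                     diagnostics={"residuals": residual(guesses[0]).tolist()})
            sol = best
            theta = sol.x
            dof = max(1, len(f) - 4)
            rss = float(np.sum(sol.fun ** 2))
            try:
                cov = np.linalg.pinv(sol.jac.T @ sol.jac) * rss / dof
                param_se = np.sqrt(np.clip(np.diag(cov), 0, None))
            except np.linalg.LinAlgError:  # pragma: no cover
                cov, param_se = None, None
        elif method == "mle":
            rf, rt = self.raw_forces, self.raw_lifetimes

            def nll(theta):
                log_kc, x_c, log_ks, x_s = theta
                rate = np.exp(log_kc - rf * x_c / kbt) + np.exp(log_ks + rf * x_s / kbt)
                return float(-np.sum(np.log(rate) - rate * rt))

            best = None
            for theta0 in guesses:
                sol = minimize(nll, theta0, method="L-BFGS-B",
                               bounds=list(zip(lower, upper)))
                if sol.success and (best is None or sol.fun < best.fun):
                    best = sol
            if best is None:
                raise NumericalError("catch-slip fit did not converge",
                                     diagnostics={"message": "all starts failed"})
            sol = best
            theta = sol.x
            try:
                cov = np.asarray(sol.hess_inv.todense())
                param_se = np.sqrt(np.clip(np.diag(cov), 0, None))
            except Exception:  # pragma: no cover
                cov, param_se = None, None
        else:
            raise UsageError(f"unknown fit method {method!r}; use 'mle' or 'ls'")

        log_kc, x_c, log_ks, x_s = theta
        k_c, k_s = float(np.exp(log_kc)), float(np.exp(log_ks))
        fit_residuals = residual(theta)
        fstar = optimum_force(k_c, x_c, k_s, x_s, kbt)
        interior = fstar is not None and f.min() < fstar < f.max()
        classification = "biphasic" if interior else (
            "monotone-decreasing" if self.lifetimes[0] >= self.lifetimes[-1]
            else "monotone-increasing"
        )
        return CatchSlipResults(
            k_c=k_c, x_c=float(x_c), k_s=k_s, x_s=float(x_s), kbt=kbt,
            fstar=None if fstar is None else float(fstar),
            classification=classification, cov=cov, param_se=param_se,
            residuals=fit_residuals, forces=f, lifetimes=tau,
        )


def fit_catch_slip(
    records_or_forces,
    lifetimes=None,
    temperature: float = 310.0,
) -> CatchSlipResults:
    """Functional wrapper over :class:`CatchSlipModel`."""
    if lifetimes is None:
        first = records_or_forces[0]
        if isinstance(first, LifetimeRecord):
            model = CatchSlipModel.from_records(records_or_forces, temperature)
        else:
            raise UsageError("pass LifetimeRecords, or forces and lifetimes arrays")
    else:
        model = CatchSlipModel(records_or_forces, lifetimes, temperature)
    return model.fit()
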