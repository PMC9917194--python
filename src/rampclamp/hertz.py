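"""Elastic modulus from AFM indentation via the conical Hertz (Sneddon) model.

For a rigid cone of half-opening angle α indenting a half-space of modulus E
and Poisson ratio ν to depth δ, the load is

    F = (2/π) · tanα · E / (1 − ν²) · δ².

ν defaults to 0.5 (incompressible, the usual choice for soft biological
material). Indentation depth δ is taken as piezo travel past the contact
point, without cantilever-deflection correction by default (a corrected mode
exists but changes the meaning of δ). A ``literal_prefactor`` switch
replaces 2/π by 2π for comparison with sources that print the prefactor that
way; the Sneddon 2/π form is the default and the physically standard one.

The fit is statsmodels-flavoured: HertzModel(curve, alpha).fit() returns a
HertzResults carrying E, the contact point, residuals and a summary().
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NumericalError, UsageError
from .io import AFMCurve
from .units import pn_per_nm2_to_pa


def hertz_force(delta, E, alpha, nu=0.5, literal_prefactor=False):
    """Load F (N) on a conical tip at indentation delta (m); E in Pa, α in deg.

    Vectorised over ``delta``. With ``literal_prefactor`` the 2/π coefficient
    is replaced by 2π.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise UsageError("indentation depth must be >= 0")
    if not 0 < alpha < 90:
        raise UsageError("half-opening angle must lie in (0, 90) degrees")
    pref = 2.0 * np.pi if literal_prefactor else 2.0 / np.pi
    return pref * np.tan(np.radians(alpha)) * E / (1.0 - nu ** 2) * delta ** 2


def estimate_contact_point(curve: AFMCurve, min_baseline_fraction: float = 0.3) -> float:
    """Contact point (piezo nm) on the approach trace.

    Changepoint of a piecewise model — flat baseline, then a quadratic
    (Hertzian) rise — minimising total squared error over candidate split
    positions. Raises a diagnostic error when no split beats the flat model
    by a meaningful margin (pure baseline).
    """
    approach = curve.phase("approach")
    if approach.empty:
        raise UsageError("AFM curve has no approach phase")
    z = approach["piezo_nm"].to_numpy(float)
    f = approach["force_pN"].to_numpy(float)
    n = len(z)
    if n < 20:
        raise UsageError("approach trace too short (< 20 samples)")
    lo = max(2, int(min_baseline_fraction * n))
    best = None
    for i in range(lo, n - 5):
        base = f[:i]
        sse_base = float(np.sum((base - base.mean()) ** 2))
        d = z[i:] - z[i]
        seg = f[i:] - base.mean()
        denom = float(np.sum(d ** 4))
        c = float(np.sum(seg * d ** 2) / denom) if denom > 0 else 0.0
        c = max(c, 0.0)
        sse_fit = float(np.sum((seg - c * d ** 2) ** 2))
        total = sse_base + sse_fit
        if best is None or total < best[0]:
            best = (total, i, c)
    total, i, c = best
    flat_sse = float(np.sum((f - f.mean()) ** 2))
    if c <= 0 or total > 0.95 * flat_sse:
        raise NumericalError(
            "no detectable contact: piecewise model does not improve on a flat baseline",
            diagnostics={"flat_sse": flat_sse, "piecewise_sse": total},
        )
    return float(z[i])


@dataclass
class HertzResults:
    """Conical-indentation fit: modulus in Pa, contact point in piezo nm."""

    elastic_modulus: float   # Pa
    alpha: float             # degrees
    nu: float
    contact_point: float     # nm
    rss: float               # pN², post-contact residual sum of squares
    n_points: int
    coefficient_pn_nm2: float
    literal_prefactor: bool = False

    def predict(self, delta_nm) -> np.ndarray:
        """Predicted force (pN) at indentation depth in nm."""
        delta_nm = np.asarray(delta_nm, float)
        return self.coefficient_pn_nm2 * delta_nm ** 2

    def summary(self) -> str:
        lines = [
            "Hertz conical indentation fit",
            "=" * 30,
            f"elastic modulus E : {self.elastic_modulus:,.1f} Pa",
            f"half-opening angle: {self.alpha:.1f} deg",
            f"Poisson ratio     : {self.nu:.2f}",
            f"contact point     : {self.contact_point:.2f} nm",
            f"post-contact n    : {self.n_points}",
            f"residual SS       : {self.rss:.4g} pN^2",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "E_Pa": self.elastic_modulus, "alpha_deg": self.alpha, "nu": self.nu,
            "contact_point_nm": self.contact_point, "rss": self.rss,
            "n_points": self.n_points,
        }


class HertzModel:
    """Conical Hertz fit of an AFM approach curve.

    Parameters: the curve (nm / pN), tip half-opening angle α (deg; the tip
    geometry must be supplied, there is no universal default), Poisson ν,
    optional indentation truncation, and the prefactor convention.
    """

    def __init__(self, curve: AFMCurve, alpha: float, nu: float = 0.5,
                 max_indentation: float | None = None,
                 literal_prefactor: bool = False):
        if not 0 < alpha < 90:
            raise UsageError("half-opening angle must lie in (0, 90) degrees")
        if not 0 <= nu < 0.5 + 1e-9:
            raise UsageError("Poisson ratio must lie in [0, 0.5]")
        self.curve = curve
        self.alpha = alpha
        self.nu = nu
        self.max_indentation = max_indentation
        self.literal_prefactor = literal_prefactor

    def fit(self) -> HertzResults:
        contact = estimate_contact_point(self.curve)
        approach = self.curve.phase("approach")
        z = approach["piezo_nm"].to_numpy(float)
        f = approach["force_pN"].to_numpy(float)
        baseline = float(np.mean(f[z < contact])) if np.any(z < contact) else 0.0
        mask = z >= contact
        delta = z[mask] - contact
        load = f[mask] - baseline
        if self.max_indentation is not None:
            keep = delta <= self.max_indentation
            delta, load = delta[keep], load[keep]
        if delta.size < 20:
            raise UsageError("fewer than 20 post-contact samples")
        denom = float(np.sum(delta ** 4))
        c = float(np.sum(load * delta ** 2) / denom)  # pN/nm²
        if c <= 0:
            raise NumericalError("non-physical fit: negative quadratic coefficient",
                                 diagnostics={"coefficient": c})
        rss = float(np.sum((load - c * delta ** 2) ** 2))
        pref = 2.0 * np.pi if self.literal_prefactor else 2.0 / np.pi
        modulus = pn_per_nm2_to_pa(c) * (1.0 - self.nu ** 2) / (
            pref * np.tan(np.radians(self.alpha))
        )
        return HertzResults(
            elastic_modulus=float(modulus), alpha=self.alpha, nu=self.nu,
            contact_point=contact, rss=rss, n_points=int(delta.size),
            coefficient_pn_nm2=c, literal_prefactor=self.literal_prefactor,
        )


def fit_elastic_modulus(curve: AFMCurve, alpha: float, nu: float = 0.5,
                        max_indentation: float | None = None,
                        literal_prefactor: bool = False) -> HertzResults:
    """Functional wrapper over :class:`HertzModel`."""
    return HertzModel(curve, alpha, nu, max_indentation, literal_prefactor).fit()
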