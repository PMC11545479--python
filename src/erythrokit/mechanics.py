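"""Hertz-model analysis of AFM force curves: contact point and Young's modulus.

The approach curve (piezo-Z vs cantilever deflection) is converted to
force-indentation via F = k*d, delta = (z - z0) - d, and fitted with the
spherical-indenter Hertz law F = (4/3) * E/(1 - nu^2) * sqrt(R) * delta^1.5.
Given a candidate contact point the model is linear in E, so E has a
closed form; the contact point is found by a coarse grid search over z0
minimizing the total squared residual of the piecewise model (flat
baseline before contact, Hertz after), refined by bounded scalar
minimization.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize_scalar

from .io import XYSeries
from .synthetic.signals import ProbeParams, hertz_coefficient

DEFAULT_FIT_MAX_INDENTATION = 500.0  # nm; keeps d << delta while retaining usable SNR


class NoContactError(RuntimeError):
    """Raised when a curve shows no detectable contact region."""


@dataclasses.dataclass(frozen=True)
class ForceCurve:
    """An approach force curve with its probe calibration."""

    piezo_z: np.ndarray        # nm
    deflection: np.ndarray     # nm
    probe: ProbeParams = ProbeParams()

    def __post_init__(self) -> None:
        z = np.asarray(self.piezo_z, dtype=float)
        d = np.asarray(self.deflection, dtype=float)
        object.__setattr__(self, "piezo_z", z)
        object.__setattr__(self, "deflection", d)
        if z.size < 50:
            raise ValueError("force curve needs >= 50 points")
        if not np.all(np.diff(z) > 0):
            raise ValueError("piezo_z must be monotone increasing on the approach")

    @classmethod
    def from_series(cls, series: XYSeries, probe: ProbeParams = ProbeParams()
                    ) -> "ForceCurve":
        return cls(series.x, series.y, probe)


@dataclasses.dataclass(frozen=True)
class ElasticFit:
    E_kPa: float
    contact_z: float           # nm
    rms_residual_nN: float
    n_points_fit: int


def to_force_indentation(curve: ForceCurve, contact_z: float
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Post-contact (indentation nm, force nN) pairs.

    F = k*d (nN for nm deflection and N/m stiffness); delta = (z - z0) - d.
    Only points with positive indentation are returned.
    """
    z, d = curve.piezo_z, curve.deflection
    if not (z.min() <= contact_z <= z.max()):
        raise ValueError("contact point outside the curve's z range")
    if d.max() <= 0:
        raise NoContactError("no positive deflection anywhere on the curve")
    delta = (z - contact_z) - d
    sel = delta > 0
    if not sel.any():
        raise NoContactError("no post-contact points")
    return delta[sel], curve.probe.spring_constant * d[sel]


def _piecewise_sse(curve: ForceCurve, z0: float, fit_max_indentation: float
                   ) -> tuple[float, float, int]:
    """(total SSE in nN^2, closed-form E >= 0, n fit points) for a candidate z0."""
    z, d = curve.piezo_z, curve.deflection
    k = curve.probe.spring_constant
    C = hertz_coefficient(curve.probe)
    pre = z <= z0
    sse = float(np.sum((k * d[pre]) ** 2))          # baseline model: d = 0
    delta = (z - z0) - d
    sel = (~pre) & (delta > 0) & (delta <= fit_max_indentation)
    n = int(sel.sum())
    if n == 0:
        return sse, 0.0, 0
    F = k * d[sel]
    a = C * delta[sel] ** 1.5
    E = max(float(F @ a / (a @ a)), 0.0)
    sse += float(np.sum((F - E * a) ** 2))
    # points past the fit cap still belong to the contact regime; score them
    tail = (~pre) & (delta > fit_max_indentation)
    if tail.any():
        sse += float(np.sum((k * d[tail] - E * C * delta[tail] ** 1.5) ** 2))
    return sse, E, n


def find_contact_point(curve: ForceCurve,
                       fit_max_indentation: float = DEFAULT_FIT_MAX_INDENTATION,
                       n_grid: int = 120) -> float:
    """Contact z0 from the piecewise baseline/Hertz grid search."""
    return fit_hertz(curve, fit_max_indentation, n_grid).contact_z


def fit_hertz(curve: ForceCurve,
              fit_max_indentation: float = DEFAULT_FIT_MAX_INDENTATION,
              n_grid: int = 120) -> ElasticFit:
    """Joint (E, contact point) estimate for one approach curve.

    Raises NoContactError for flat curves (no deflection rise above the
    baseline noise) and ValueError when the best fit has non-positive
    modulus or too few post-contact points.
    """
    z, d = curve.piezo_z, curve.deflection
    baseline_n = max(int(0.15 * len(d)), 10)
    noise = float(np.std(d[:baseline_n]))
    w = 25
    smoothed = np.convolve(d, np.ones(w) / w, mode="same")
    # smoothed noise scales as noise/sqrt(w); require a clear rise above it
    if np.ptp(d) == 0 or smoothed.max() < max(4.0 * noise / np.sqrt(w), 1e-12):
        raise NoContactError("no deflection rise detected")

    candidates = np.linspace(z.min(), z.max() - 0.02 * np.ptp(z), n_grid)
    sses = [_piecewise_sse(curve, z0, fit_max_indentation)[0] for z0 in candidates]
    i = int(np.argmin(sses))
    lo = candidates[max(i - 1, 0)]
    hi = candidates[min(i + 1, n_grid - 1)]
    res = minimize_scalar(lambda z0: _piecewise_sse(curve, z0, fit_max_indentation)[0],
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    z0 = float(res.x)
    sse, E, n = _piecewise_sse(curve, z0, fit_max_indentation)
    if n < 10:
        raise ValueError("fewer than 10 post-contact points within the fit range")
    if E <= 0:
        raise ValueError("Hertz fit failed positivity (E <= 0); "
                         "check curve orientation and contact region")
    return ElasticFit(E_kPa=E, contact_z=z0,
                      rms_residual_nN=float(np.sqrt(sse / len(z))),
                      n_points_fit=n)
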