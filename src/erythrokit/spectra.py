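"""Hemoglobin derivative unmixing of absorption spectra.

The optical density is modelled as a linear mixture

    D(lambda) = eps_HbO2*C1 + eps_Hb*C2 + eps_MetHb*C3 + M + S/lambda^4

with nonnegative concentration-path products C_i, a free background level
M and a nonnegative Rayleigh scattering coefficient S.  The geometric
light path is folded into the C_i since only relative fractions are
reported.  The model is linear in all five unknowns, so the fit is a
bounded linear least-squares problem.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import lsq_linear
from scipy.signal import find_peaks as _sp_find_peaks

from .io import XYSeries
from .synthetic.signals import ExtinctionTable, make_extinction_table

ABSENCE_THRESHOLD_PCT = 1.0   # below this a species is reported absent


@dataclasses.dataclass(frozen=True)
class HbFit:
    """Result of the five-parameter spectral fit."""

    C_HbO2: float
    C_Hb: float
    C_MetHb: float
    M: float                   # OD background
    S: float                   # OD * nm^4 Rayleigh coefficient
    rms_residual: float        # OD

    @property
    def total(self) -> float:
        return self.C_HbO2 + self.C_Hb + self.C_MetHb


def unmix(spectrum: XYSeries, table: ExtinctionTable | None = None) -> HbFit:
    """Fit the mixture model to a spectrum by bounded linear least squares.

    Requires >= 150 points within 500-700 nm; the extinction table is
    interpolated linearly onto the spectrum grid.
    """
    if table is None:
        table = make_extinction_table()
    w, D = spectrum.x, spectrum.y
    in_range = (w >= 500.0) & (w <= 700.0)
    if in_range.sum() < 150:
        raise ValueError("spectrum must cover 500-700 nm with >= 150 points")
    w, D = w[in_range], D[in_range]
    eps = np.column_stack([np.interp(w, table.wavelengths, col)
                           for col in (table.eps_HbO2, table.eps_Hb, table.eps_MetHb)])
    A = np.column_stack([eps, np.ones_like(w), w**-4])
    if not np.any(D != 0.0):
        return HbFit(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    res = lsq_linear(A, D, bounds=([0.0, 0.0, 0.0, -np.inf, 0.0],
                                   [np.inf] * 5), tol=1e-14)
    c1, c2, c3, M, S = res.x
    rms = float(np.sqrt(np.mean((A @ res.x - D) ** 2)))
    return HbFit(float(c1), float(c2), float(c3), float(M), float(S), rms)


def fractions(fit: HbFit, absence_threshold: float = ABSENCE_THRESHOLD_PCT
              ) -> dict[str, float]:
    """Relative percentages of the three species (sum to 100).

    A species below ``absence_threshold`` percent is reported as exactly 0
    (absent), with the remainder renormalized.
    """
    if fit.total <= 0:
        raise ValueError("undefined fractions: zero total hemoglobin signal")
    pct = np.array([fit.C_HbO2, fit.C_Hb, fit.C_MetHb]) / fit.total * 100.0
    pct[pct < absence_threshold] = 0.0
    pct = pct / pct.sum() * 100.0
    return {"HbO2": float(pct[0]), "Hb": float(pct[1]), "MetHb": float(pct[2])}


def find_peaks(spectrum: XYSeries, prominence: float = 0.01) -> list[float]:
    """Prominent local maxima of a spectrum, parabolically refined, in nm."""
    w, D = spectrum.x, spectrum.y
    if len(w) < 20:
        raise ValueError("need >= 20 points for peak finding")
    idx, _ = _sp_find_peaks(D, prominence=prominence)
    out = []
    for i in idx:
        if 0 < i < len(D) - 1:
            denom = D[i - 1] - 2.0 * D[i] + D[i + 1]
            shift = 0.5 * (D[i - 1] - D[i + 1]) / denom if denom != 0 else 0.0
            shift = float(np.clip(shift, -0.5, 0.5))
            step = 0.5 * (w[min(i + 1, len(w) - 1)] - w[max(i - 1, 0)])
            out.append(float(w[i] + shift * step))
        else:
            out.append(float(w[i]))
    return sorted(out)
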