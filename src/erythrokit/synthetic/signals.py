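"""Synthetic 1-D signals: Hertzian force curves, absorption spectra,
amperometric current traces, and the bundled extinction table.

The extinction table is a synthetic standard reproducing the qualitative
features the analysis relies on — an oxyhemoglobin doublet peaking at 542
and 577 nm, a single broad deoxyhemoglobin band at 555 nm and a distinct
methemoglobin band at 630 nm — so the unmixing stage can be validated
end-to-end without external data.  A user-supplied real table in the same
schema can be substituted anywhere an ExtinctionTable is accepted.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ..io import XYSeries


@dataclasses.dataclass(frozen=True)
class ProbeParams:
    """AFM probe: tip radius (nm), cantilever spring constant (N/m), Poisson ratio."""

    radius: float = 150.0
    spring_constant: float = 1.0
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("probe radius must be positive")
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be positive")
        if not (0.0 <= self.poisson_ratio <= 0.5):
            raise ValueError("poisson ratio must be within [0, 0.5]")


def hertz_coefficient(probe: ProbeParams) -> float:
    """C such that F[nN] = C * E[kPa] * delta[nm]^1.5 for a spherical tip."""
    return (4.0 / 3.0) / (1.0 - probe.poisson_ratio**2) * np.sqrt(probe.radius) * 1e-6


def make_force_curve(E: float, probe: ProbeParams = ProbeParams(),
                     contact_z: float = 500.0, max_indentation: float = 800.0,
                     noise_sd: float = 0.0,
                     seed: int | np.random.Generator | None = 0,
                     n_points: int = 800) -> XYSeries:
    """Forward-model an approach force curve (piezo-Z nm vs deflection nm).

    Before ``contact_z`` the deflection is zero (plus noise); after contact
    the cantilever deflection d satisfies the self-consistent Hertz balance
    k*d = C*E*delta^1.5 with indentation delta = (z - contact_z) - d.
    """
    if E <= 0:
        raise ValueError("Young's modulus must be positive")
    if max_indentation < 0:
        raise ValueError("max_indentation must be >= 0")
    rng = np.random.default_rng(seed)
    C = hertz_coefficient(probe)
    k = probe.spring_constant
    z_end = contact_z + max_indentation * 1.05 + 1e-9
    z = np.linspace(0.0, z_end, n_points)
    zeta = np.clip(z - contact_z, 0.0, None)       # total travel past contact
    d = np.zeros_like(z)
    for _ in range(60):                            # fixed point, d << zeta
        d_new = C * E * np.clip(zeta - d, 0.0, None) ** 1.5 / k
        if np.allclose(d_new, d, rtol=0, atol=1e-12):
            d = d_new
            break
        d = d_new
    if noise_sd > 0:
        d = d + rng.normal(0.0, noise_sd, d.shape)
    return XYSeries(z, d, units=("nm", "nm"))


@dataclasses.dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction profiles per hemoglobin species on a common grid.

    Units are an arbitrary consistent OD/(concentration*cm); only relative
    fractions are derived from fits against this table.
    """

    wavelengths: np.ndarray
    eps_HbO2: np.ndarray
    eps_Hb: np.ndarray
    eps_MetHb: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", w)
        for col in ("eps_HbO2", "eps_Hb", "eps_MetHb"):
            e = np.asarray(getattr(self, col), dtype=float)
            object.__setattr__(self, col, e)
            if e.shape != w.shape:
                raise ValueError("all extinction columns must share the grid")
            if (e < 0).any():
                raise ValueError("extinction coefficients must be non-negative")

    def matrix(self) -> np.ndarray:
        """Columns HbO2, Hb, MetHb stacked as (n_wavelengths, 3)."""
        return np.column_stack([self.eps_HbO2, self.eps_Hb, self.eps_MetHb])


def _gauss(w: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-((w - center) ** 2) / (2.0 * sigma**2))


def make_extinction_table(grid: np.ndarray | None = None) -> ExtinctionTable:
    """Synthetic standard extinction table on a 500-700 nm grid.

    HbO2 carries two equal Gaussian bands at 542 and 577 nm (narrow enough
    that the summed profile still peaks exactly there on a 1-nm grid), Hb a
    single band at 555 nm, MetHb a band at 630 nm; small positive baselines
    keep every column strictly positive.
    """
    w = np.arange(500.0, 701.0) if grid is None else np.asarray(grid, dtype=float)
    if w.min() > 500.0 or w.max() < 700.0:
        raise ValueError("grid must cover 500-700 nm")
    eps_hbo2 = 0.9 * (_gauss(w, 542.0, 8.0) + _gauss(w, 577.0, 8.0)) + 0.05
    eps_hb = 1.1 * _gauss(w, 555.0, 15.0) + 0.04
    eps_methb = 0.5 * _gauss(w, 630.0, 20.0) + 0.08
    return ExtinctionTable(w, eps_hbo2, eps_hb, eps_methb)


def make_spectrum(fractions: tuple[float, float, float],
                  total_conc: float = 1.0,
                  M: float = 0.02, S: float = 5e8,
                  table: ExtinctionTable | None = None,
                  noise_sd: float = 0.0,
                  seed: int | np.random.Generator | None = 0) -> XYSeries:
    """Absorption spectrum D(lambda) for a hemoglobin mixture.

    ``fractions`` are (HbO2, Hb, MetHb) percentages summing to 100;
    ``total_conc`` is the concentration-path product (the geometric path is
    folded into it), ``M`` a flat background in OD and ``S`` the Rayleigh
    scattering coefficient contributing S/lambda^4 (OD*nm^4).
    """
    frac = np.asarray(fractions, dtype=float)
    if (frac < 0).any():
        raise ValueError("fractions must be non-negative")
    if abs(frac.sum() - 100.0) > 1e-6:
        raise ValueError("fractions must sum to 100")
    if table is None:
        table = make_extinction_table()
    rng = np.random.default_rng(seed)
    conc = frac / 100.0 * total_conc
    w = table.wavelengths
    D = table.matrix() @ conc + M + S / w**4
    if noise_sd > 0:
        D = D + rng.normal(0.0, noise_sd, D.shape)
    return XYSeries(w, D, units=("nm", "OD"))


def make_current_trace(baseline: float, peak: float, approach_time: float = 5.0,
                       duration: float = 20.0, sample_rate: float = 50.0,
                       rise_tau: float = 0.3, noise_sd: float = 0.0,
                       seed: int | np.random.Generator | None = 0) -> XYSeries:
    """Amperometric trace: baseline, sigmoidal rise at approach_time, plateau.

    Emulates the oxidation current recorded as the nanoelectrode enters a
    cell: flat baseline (pA), a logistic rise of time constant ``rise_tau``
    (s) centred at ``approach_time``, then a plateau at ``peak``.
    """
    if not (peak > baseline >= 0):
        raise ValueError("need peak > baseline >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 1.0 / sample_rate)
    current = baseline + (peak - baseline) / (1.0 + np.exp(-(t - approach_time) / rise_tau))
    if noise_sd > 0:
        current = current + rng.normal(0.0, noise_sd, current.shape)
    return XYSeries(t, current, units=("s", "pA"))
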