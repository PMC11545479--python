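"""Named parameter presets for the synthetic-data generators.

Each preset encodes one experimental condition of the pH-storage study
(incubation pH x storage time).  The control condition is pH 7.4 after
30 min storage; the ``phXX_YY`` names follow pH and duration.  Values are
the group means reported for that condition; generators add the stated
stochastic variation around them.
"""

from __future__ import annotations

from .synthetic.surface import TextureParams
from .synthetic.cells import CellComposition
from .synthetic.mesh import MeshParams

# --- AFM surface texture (waviness h1/L1, roughness h2/L2, nm) -------------
# Control values; other conditions are fold changes relative to control.
TEXTURE_PRESETS: dict[str, TextureParams] = {
    "control": TextureParams(h1=2.7, L1=939.0, h2=0.9, L2=98.5),
    "ph74_7h": TextureParams(h1=2.7, L1=939.0, h2=0.9, L2=98.5 * 1.3),
    "ph64_7h": TextureParams(h1=2.7 * 5.0, L1=939.0 * 1.5, h2=0.9 * 3.3, L2=98.5 * 2.0),
    "ph84_7h": TextureParams(h1=2.7 * 5.0, L1=939.0 * 1.4, h2=0.9 * 3.4, L2=98.5 * 1.8),
}

# --- scene composition (% discocyte / echinocyte / codocyte) ---------------
# Only the 7 h acidic/alkaline conditions are reported numerically; the
# control composition is a nominal healthy smear (discocyte-dominated).
COMPOSITION_PRESETS: dict[str, CellComposition] = {
    "control": CellComposition(discocyte=95.0, echinocyte=5.0, codocyte=0.0),
    "ph64_7h": CellComposition(discocyte=54.0, echinocyte=42.0, codocyte=4.0),
    "ph84_7h": CellComposition(discocyte=56.0, echinocyte=38.0, codocyte=6.0),
}

# --- cytoskeleton mesh (pores per 2x2 um^2, mean max-Feret um) -------------
MESH_PRESETS: dict[str, MeshParams] = {
    "control": MeshParams(pore_density=125.0, mean_pore_length=0.13),
    "ph64_7h": MeshParams(pore_density=125.0 / 2.6, mean_pore_length=0.13 * 1.7),
    "ph84_7h": MeshParams(pore_density=125.0 / 1.7, mean_pore_length=0.13 * 1.4),
}

# --- elasticity (population mean, sd of Young's modulus in kPa) ------------
ELASTIC_PRESETS: dict[str, tuple[float, float]] = {
    "control": (4.1, 1.6),
    "ph74_7h": (5.6, 1.0),
    "ph64_30min": (4.1 * 2.0, 1.6),
    "ph84_30min": (4.1 * 1.85, 1.6),
}

# --- hemoglobin composition (% HbO2 / Hb / MetHb) --------------------------
HB_PRESETS: dict[str, tuple[float, float, float]] = {
    "ph64": (84.0, 16.0, 0.0),
    "ph74": (85.0, 15.0, 0.0),
    "ph84": (86.0, 14.0, 0.0),
}
HB_PRESETS["control"] = HB_PRESETS["ph74"]
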