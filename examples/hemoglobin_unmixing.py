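"""Unmix an absorption spectrum into HbO2 / Hb / MetHb fractions.

Builds a noiseless spectrum at the physiological composition (85% HbO2,
15% Hb) with background and Rayleigh scattering, fits the five-parameter
linear model and locates the oxyhemoglobin doublet.
"""

from erythrokit.spectra import find_peaks, fractions, unmix
from erythrokit.synthetic import make_spectrum

spectrum = make_spectrum((85, 15, 0), M=0.02, S=5e8, noise_sd=0.0)
fit = unmix(spectrum)
frac = fractions(fit)
peaks = find_peaks(spectrum)

print("generated: 85% HbO2, 15% Hb, 0% MetHb, M=0.02 OD")
print("recovered: %.1f%% HbO2, %.1f%% Hb, MetHb %s; M=%.3f OD"
      % (frac["HbO2"], frac["Hb"],
         "absent" if frac["MetHb"] == 0 else f"{frac['MetHb']:.1f}%", fit.M))
print("absorption peaks at: " + ", ".join(f"{p:.1f} nm" for p in peaks))
print("the two peaks near 542 and 577 nm are the oxyhemoglobin doublet.")
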