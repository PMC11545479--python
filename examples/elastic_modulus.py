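"""Young's modulus from AFM force curves via the spherical Hertz model.

Simulates approach curves for a 4.1 kPa cell (R = 150 nm probe, k = 1 N/m)
with and without deflection noise and fits both.
"""

from erythrokit.mechanics import ForceCurve, fit_hertz
from erythrokit.synthetic import make_force_curve

clean = make_force_curve(4.1, contact_z=500.0, noise_sd=0.0)
noisy = make_force_curve(4.1, contact_z=500.0, noise_sd=0.3, seed=1)

fit_clean = fit_hertz(ForceCurve(clean.x, clean.y))
fit_noisy = fit_hertz(ForceCurve(noisy.x, noisy.y))

print("true modulus 4.1 kPa, contact at 500 nm")
print("noiseless fit: E = %.3f kPa, contact z0 = %.1f nm"
      % (fit_clean.E_kPa, fit_clean.contact_z))
print("0.3 nm noise:  E = %.2f kPa, contact z0 = %.1f nm (rms residual %.3f nN)"
      % (fit_noisy.E_kPa, fit_noisy.contact_z, fit_noisy.rms_residual_nN))
print("the fit is linear in E given the contact point, which is found by a "
      "piecewise baseline/Hertz grid search.")
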