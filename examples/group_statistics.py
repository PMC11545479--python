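"""Group comparison workflow: Mann-Whitney U, fold change and stars.

Compares two simulated modulus populations (4.1 vs 8.2 kPa) the way the
pipeline summarizes any pair of experimental groups.
"""

import numpy as np

from erythrokit.stats import fold_change, mann_whitney, pearson, star_code, summarize

rng = np.random.default_rng(1)
control = rng.normal(4.1, 1.6, 30)
acidic = rng.normal(8.2, 1.6, 30)

U, p = mann_whitney(acidic, control)
fc = fold_change(summarize(acidic), summarize(control))
print("control: %.2f +/- %.2f kPa; acidic: %.2f +/- %.2f kPa"
      % (control.mean(), control.std(ddof=1), acidic.mean(), acidic.std(ddof=1)))
print("Mann-Whitney U = %.0f, p = %.2e  -> %s" % (U, p, star_code(p)))
print("fold change (acidic / control) = %.2f" % fc)

z = rng.multivariate_normal([0, 0], [[1, 0.89], [0.89, 1]], 200)
print("Pearson r of correlated pair (rho = 0.89): %.3f" % pearson(z[:, 0], z[:, 1]))
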