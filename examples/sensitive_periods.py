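"""Locate when an interaction operates with a distributed-lag model.

Plants an interaction acting only at ages 4-7 of an 18-year exposure
trajectory, fits the cross-basis DLM, and extracts the sensitive period
from the pointwise confidence intervals.
"""

import numpy as np

import gweistools as gt

rng = np.random.default_rng(31)
n = 3000
E = rng.standard_normal((n, 18))
for t in range(1, 18):  # AR(1) age series
    E[:, t] = 0.5 * E[:, t - 1] + np.sqrt(0.75) * E[:, t]
G = rng.binomial(2, 0.3, n).astype(float)
gs = (G - G.mean()) / G.std()
gamma_true = np.zeros(18)
gamma_true[3:7] = 0.3  # interaction operates at ages 4-7 only
y = (E * gs[:, None]) @ gamma_true + rng.standard_normal(n) * 3.0

fit = gt.fit_dlm(y, E, G)
windows = gt.extract_sensitive_periods(fit)
print("age  gamma    95% CI          flagged")
for age, gm, lo, hi, fl in zip(fit.ages, fit.gamma, fit.ci_lo, fit.ci_hi, fit.flagged):
    mark = "*" if fl else ""
    print(f"{age:3d}  {gm:+.3f}  [{lo:+.3f}, {hi:+.3f}]  {mark}")
print("sensitive period(s):", ", ".join(f"ages {a}-{b}" for a, b in windows))
# The flagged run should cover the planted 4-7 window; the 3-df natural
# spline smooths the edges, so the window is recovered with ~1 year blur.
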