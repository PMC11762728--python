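"""Elevation→climate calibration: a linear lapse model for temperature and a
polynomial model for precipitation, with the adjusted-R² acceptance rule.
"""

import numpy as np

from divelev.climate import fit_lapse_model, predict_climate

elev = np.linspace(0, 3500, 12)

# temperature: 25 degC at sea level, 5.5 degC/km lapse
temp = 25.0 - 0.0055 * elev
m_t = fit_lapse_model(np.column_stack([elev, temp]), "bio1")
print(f"bio1: degree {m_t.degree}, slope {m_t.coef[1]*1000:.2f} degC/km, "
      f"adj R2 {m_t.adj_r2:.3f}, accepted={m_t.accepted}")
print(f"predicted bio1 at 2000 m: {predict_climate(m_t, 2000.0):.1f} degC")

# precipitation: hump-shaped, the quadratic wins the adjusted-R2 selection
precip = 1500 + 1.2 * elev - 3.0e-4 * elev**2 + np.random.default_rng(0).normal(0, 40, 12)
m_p = fit_lapse_model(np.column_stack([elev, precip]), "bio12")
print(f"bio12: degree {m_p.degree}, adj R2 {m_p.adj_r2:.3f}, accepted={m_p.accepted}")

# pure noise fails the adj R2 > 0.5 rule and its predictions are refused
noise = np.random.default_rng(1).normal(1000, 300, 12)
m_bad = fit_lapse_model(np.column_stack([elev, noise]), "bio14")
print(f"bio14 (noise): adj R2 {m_bad.adj_r2:.3f}, accepted={m_bad.accepted}")
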