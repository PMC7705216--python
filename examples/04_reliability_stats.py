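"""Test-retest agreement statistics for CLS functions.

Simulates two visits of the same listener, fits a CLS function per visit and
summarizes their agreement with Bland-Altman bias and limits of agreement,
Cronbach's alpha (with the conventional interpretation band), and rmse.
"""

import numpy as np

from clsmei import (
    CatalogGenParams,
    PairedMeasurements,
    bland_altman,
    cronbach_alpha,
    estimate_dynamic_range,
    generate_catalog,
    ml_cls,
    rmse,
    run_mei_adaptive,
    sample_listeners,
)

catalog = generate_catalog(CatalogGenParams(n_entries=300, seed=1))
listener = sample_listeners(catalog, 1, seed=21)[0]

fits = []
for visit, seed in enumerate((100, 200)):
    # a fresh response stream per visit models day-to-day variability
    listener.seed = seed
    listener.reset()
    dr = estimate_dynamic_range(listener)
    log = run_mei_adaptive(listener, catalog, dr, seed=seed)
    _, fn = ml_cls(log, catalog)
    fits.append(fn)

cus = [cu for cu in range(5, 50, 5)]
v1 = np.array([fits[0].per_cu_levels[cu] for cu in cus], float)
v2 = np.array([fits[1].per_cu_levels[cu] for cu in cus], float)
pm = PairedMeasurements(v1, v2, "visit 1", "visit 2")

ba = bland_altman(pm)
alpha, label = cronbach_alpha([pm.a, pm.b])
print("per-CU levels, visit 1 vs visit 2 (dB SPL):")
for cu, a, b in zip(cus, v1, v2):
    print(f"  CU {cu:2d}: {a:6.1f}  {b:6.1f}")
print(f"\nBland-Altman bias: {ba['bias']:+.2f} dB "
      f"(95% LOA {ba['loa_low']:+.2f} to {ba['loa_high']:+.2f})")
print(f"Cronbach's alpha:  {alpha:.3f} ({label})")
print(f"rmse:              {rmse(pm):.2f} dB")
print("\nbias near 0 and alpha above 0.9 indicate the two visits agree well.")
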