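"""Estimate a CLS loudness-growth function from trial-by-trial responses.

Compares the two estimators: the per-category median level, and the
maximum-likelihood catalog fit (which smooths across categories), then
converts loudness to phons and estimates hearing threshold at 2.5 CU.
"""

from clsmei import (
    CatalogGenParams,
    cu_to_phon,
    estimate_dynamic_range,
    estimate_threshold,
    generate_catalog,
    median_cls,
    ml_cls,
    run_mei_adaptive,
    sample_listeners,
)

catalog = generate_catalog(CatalogGenParams(n_entries=300, seed=1))
listener = sample_listeners(catalog, 1, seed=11)[0]
dr = estimate_dynamic_range(listener)
listener.reset()
log = run_mei_adaptive(listener, catalog, dr, seed=11)

median_fn = median_cls(log)
entry_id, ml_fn = ml_cls(log, catalog)
true_levels = listener.true_mcpf.boundary_levels

print(f"true entry {listener.true_mcpf.entry_id}; ML selected {entry_id}")
print("\nCU | true level | median fit | ML fit  (dB SPL)")
for k in range(1, 10):
    cu = 5 * k
    med = median_fn.per_cu_levels.get(cu)
    med_s = f"{med:7.1f}" if med is not None else "   --  "
    print(f"{cu:2d} | {true_levels[k - 1]:8.1f}   | {med_s}    | {ml_fn.per_cu_levels[cu]:7.1f}")
print("('--' = category never used in 45 trials: the median method leaves it")
print(" missing, while the ML fit smooths across categories)")

phon_fn = cu_to_phon(ml_fn)
print(f"\nloudness unit after conversion: {phon_fn.loudness_unit}")
print(f"threshold estimate (level at 2.5 CU): {estimate_threshold(ml_fn):.1f} dB SPL")
print(f"true CU-5 boundary:                   {true_levels[0]:.1f} dB SPL")
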