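"""Build a multi-category psychometric function and a synthetic catalog.

An MCPF gives, at every stimulus level, a probability for each of the 11
loudness categories (CU 0 "Can't Hear" ... CU 50 "Too Loud").  A catalog of
MCPFs is the hypothesis space the adaptive procedure reasons over.
"""

import numpy as np

from clsmei import MCPF, CatalogGenParams, category_probs, generate_catalog

# A normal-hearing-like listener: boundaries every 10 dB from 10 dB SPL,
# each boundary a logistic with 5 dB width.
mcpf = MCPF(
    boundary_levels=tuple(10.0 * k for k in range(1, 11)),
    boundary_widths=(5.0,) * 10,
    entry_id="example-nh",
)

for level in (15.0, 55.0, 95.0):
    p = category_probs(mcpf, level)
    top = 5 * int(np.argmax(p))
    print(f"{level:5.0f} dB SPL -> most likely CU {top:2d} "
          f"(p = {p.max():.2f}); full distribution sums to {p.sum():.6f}")

# A seeded synthetic catalog spanning normal hearing to moderate loss.
catalog = generate_catalog(CatalogGenParams(n_entries=300, seed=1))
thresholds = [e.boundary_levels[0] for e in catalog]
spans = [e.boundary_levels[-1] - e.boundary_levels[0] for e in catalog]
print(f"\ncatalog: {len(catalog)} entries")
print(f"CU-5 boundary (threshold-like) span: {min(thresholds):.0f} to "
      f"{max(thresholds):.0f} dB SPL")
print(f"dynamic ranges: {min(spans):.0f} to {max(spans):.0f} dB "
      "(hearing-impaired entries are the compressed ones)")
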