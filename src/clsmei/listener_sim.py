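"""Monte-Carlo simulated listeners responding according to a true MCPF.

A simulated listener draws each categorical response from its true MCPF's
category probabilities at the presented level (``stochastic`` mode), using a
private seeded stream so whole sessions replay exactly.  ``modal`` mode
returns the most probable category deterministically, which is useful for
noiseless tests of tracking and fitting.  Listeners are memoryless: the model
carries no sequential context or assimilation bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .catalog import Catalog
from .mcpf_model import MCPF, CU_VALUES, category_probs

__all__ = ["SimulatedListener", "respond", "sample_listeners"]


@dataclass
class SimulatedListener:
    """A responder backed by a known ground-truth MCPF."""

    true_mcpf: MCPF
    seed: int = 0
    mode: Literal["stochastic", "modal"] = "stochastic"
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.mode not in ("stochastic", "modal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self._rng = np.random.default_rng(self.seed)

    def reset(self) -> None:
        """Rewind the private response stream to its seed."""
        self._rng = np.random.default_rng(self.seed)

    def __call__(self, level: float) -> int:
        return respond(self, level)


def respond(listener: SimulatedListener, level: float) -> int:
    """One categorical response (CU 0-50) to a level in dB SPL."""
    p = category_probs(listener.true_mcpf, level)
    if listener.mode == "modal":
        return int(CU_VALUES[np.argmax(p)])
    # guard against float dust before the multinomial draw
    p = np.asarray(p) / np.asarray(p).sum()
    return int(listener._rng.choice(CU_VALUES, p=p))


def sample_listeners(
    catalog: Catalog,
    n: int,
    seed: int = 0,
    mode: Literal["from_catalog", "perturbed"] = "from_catalog",
    response_mode: Literal["stochastic", "modal"] = "stochastic",
    perturb_sd: float = 3.0,
) -> list[SimulatedListener]:
    """Draw a roster of simulated listeners from a catalog; seeded.

    ``from_catalog`` draws entries uniformly with replacement, so every
    listener's true loudness function is inside the hypothesis space.
    ``perturbed`` additionally jitters each boundary level with Gaussian noise
    of SD ``perturb_sd`` dB (re-validated, bounded retries), modelling
    listeners the catalog does not contain exactly.
    """
    if n < 1:
        raise ValueError("need at least one listener")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(catalog), size=n)
    listeners = []
    for j, i in enumerate(idx):
        base = catalog[int(i)]
        mcpf = base
        if mode == "perturbed" and perturb_sd > 0:
            for attempt in range(50):
                levels = np.asarray(base.boundary_levels) + rng.normal(
                    0, perturb_sd, size=len(base.boundary_levels)
                )
                try:
                    mcpf = MCPF(
                        tuple(np.sort(levels)),
                        base.boundary_widths,
                        f"{base.entry_id}-pert{j}",
                        base.frequency_hz,
                        dict(base.metadata),
                    )
                    break
                except ValueError:
                    continue
            else:
                mcpf = base
        elif mode not in ("from_catalog", "perturbed"):
            raise ValueError(f"unknown sampling mode {mode!r}")
        listeners.append(
            SimulatedListener(mcpf, seed=int(rng.integers(2**31)), mode=response_mode)
        )
    return listeners
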