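import numpy as np
import pytest

from clsmei import (
    MCPF,
    Catalog,
    CatalogGenParams,
    generate_catalog,
)

N_B = 10


def uniform_mcpf(entry_id="uniform", lo=10.0, step=10.0, width=5.0):
    """Evenly spaced boundary levels lo, lo+step, ..., common width."""
    levels = tuple(lo + step * k for k in range(N_B))
    return MCPF(levels, (width,) * N_B, entry_id)


@pytest.fixture
def simple_mcpf():
    """Boundaries at 10, 20, ..., 100 dB SPL, width 5 dB."""
    return uniform_mcpf()


@pytest.fixture
def two_entry_catalog():
    """Two entries that differ only in their upper boundaries (> 60 dB)."""
    a = uniform_mcpf("low", lo=10.0)
    levels_b = tuple(10.0 + 10.0 * k if k < 5 else 12.0 + 10.5 * k for k in range(N_B))
    b = MCPF(levels_b, (5.0,) * N_B, "high")
    return Catalog((a, b))


@pytest.fixture(scope="session")
def small_catalog():
    """Seeded 20-entry synthetic catalog for fast tests."""
    return generate_catalog(CatalogGenParams(n_entries=20, seed=42))


@pytest.fixture(scope="session")
def separated_catalog():
    """20 well-separated entries: thresholds 3 dB apart, distinct spans,
    common width, so each entry's response pattern is unambiguous."""
    entries = []
    for i in range(20):
        L1 = 2.0 + 3.0 * i
        span = 40.0 + 10.0 * (i % 3)
        L10 = min(L1 + span, 109.0)
        levels = tuple(np.linspace(L1, L10, N_B))
        entries.append(MCPF(levels, (5.0,) * N_B, f"sep{i:02d}"))
    return Catalog(tuple(entries))


@pytest.fixture(scope="session")
def mid_catalog():
    """Seeded 100-entry synthetic catalog."""
    return generate_catalog(CatalogGenParams(n_entries=100, seed=7))


class ScriptedResponder:
    """Deterministic monotone responder with a hard audible range.

    Levels below ``lower`` are "Can't Hear" (CU 0), levels above ``upper`` are
    "Too Loud" (CU 50), and in between the response ramps linearly over the
    intermediate categories.
    """

    def __init__(self, lower=20.0, upper=90.0):
        self.lower = lower
        self.upper = upper
        self.presented = []

    def __call__(self, level):
        self.presented.append(level)
        if level < self.lower:
            return 0
        if level > self.upper:
            return 50
        frac = (level - self.lower) / (self.upper - self.lower)
        return 5 * (1 + round(frac * 8))


@pytest.fixture
def scripted_responder():
    return ScriptedResponder()


def random_valid_mcpf(rng, entry_id="rand"):
    """A random valid MCPF: sorted distinct levels with a common width."""
    lo = rng.uniform(0, 60)
    hi = rng.uniform(lo + 30, 110)
    interior = np.sort(rng.uniform(lo, hi, size=N_B - 2))
    levels = np.concatenate([[lo], interior, [hi]])
    levels += np.arange(N_B) * 1e-6  # break exact ties
    width = rng.uniform(2, 8)
    return MCPF(tuple(levels), (width,) * N_B, entry_id)
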