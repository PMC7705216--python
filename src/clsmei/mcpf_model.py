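"""Multi-category psychometric functions (MCPFs) for categorical loudness scaling.

A listener's loudness perception is modelled as a probability distribution over
11 ordered loudness categories ("Can't Hear" ... "Too Loud") as a function of
stimulus level in dB SPL.  The distribution is built from 10 ordered *boundary*
psychometric functions: the k-th boundary function gives the probability that
the response is at or above categorical unit (CU) 5k.  Each boundary is a
logistic in level with its own 50% point (``boundary_levels``) and width
(``boundary_widths``); the category probabilities are differences of adjacent
boundary functions, which telescope to an exactly normalized distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from scipy.special import expit

__all__ = [
    "LoudnessScale",
    "LOUDNESS_SCALE",
    "MCPF",
    "CategoryProbabilityVector",
    "boundary_prob",
    "category_probs",
    "category_probs_matrix",
    "cls_function_from_mcpf",
    "LEVEL_MIN",
    "LEVEL_MAX",
]

#: Presentation-level domain in dB SPL.  Levels outside are evaluated
#: mathematically but are outside the procedure's contract.
LEVEL_MIN = 0.0
LEVEL_MAX = 110.0

#: Grid spacing (dB) used to validate non-negativity of category probabilities.
_VALIDATION_GRID_STEP = 1.0
_NEG_TOL = 1e-12

N_CATEGORIES = 11
N_BOUNDARIES = 10


@dataclass(frozen=True)
class LoudnessScale:
    """The ordered 11-category loudness scale with its CU codes."""

    cu_values: tuple[int, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.cu_values) != N_CATEGORIES or len(self.labels) != N_CATEGORIES:
            raise ValueError("loudness scale must have exactly 11 categories")
        diffs = np.diff(self.cu_values)
        if self.cu_values[0] != 0 or not np.all(diffs == 5):
            raise ValueError("cu_values must run 0,5,...,50 in steps of 5")

    def index_of(self, cu: int) -> int:
        """Category index (0-10) for a CU code."""
        if cu % 5 or not 0 <= cu <= 50:
            raise ValueError(f"{cu!r} is not a CU on the scale")
        return cu // 5


#: Canonical scale.  Only seven categories carry meaningful verbal labels;
#: intermediate ones are unlabeled tick positions on the response bar.
LOUDNESS_SCALE = LoudnessScale(
    cu_values=tuple(range(0, 55, 5)),
    labels=(
        "Can't Hear",
        "Very Soft",
        "(5-10)",
        "Soft",
        "(15-20)",
        "Medium",
        "(25-30)",
        "Loud",
        "(35-40)",
        "Very Loud",
        "Too Loud",
    ),
)

CU_VALUES = np.asarray(LOUDNESS_SCALE.cu_values)


@dataclass(frozen=True)
class MCPF:
    """One listener model: 10 ordered logistic boundary functions.

    ``boundary_levels[k-1]`` is the 50% point (dB SPL) of the boundary between
    CU 5(k-1) and CU 5k; ``boundary_widths[k-1]`` is the logistic width in dB.
    Validation rejects parameter sets whose category probabilities go negative
    anywhere on the 1-dB grid over [0, 110] dB SPL (crossing boundaries), so
    downstream normalization is exact rather than clipped.
    """

    boundary_levels: tuple[float, ...]
    boundary_widths: tuple[float, ...]
    entry_id: str = "mcpf"
    frequency_hz: float | None = None
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        levels = np.asarray(self.boundary_levels, dtype=float)
        widths = np.asarray(self.boundary_widths, dtype=float)
        object.__setattr__(self, "boundary_levels", tuple(levels.tolist()))
        object.__setattr__(self, "boundary_widths", tuple(widths.tolist()))
        if levels.shape != (N_BOUNDARIES,) or widths.shape != (N_BOUNDARIES,):
            raise ValueError(
                f"entry {self.entry_id!r}: expected {N_BOUNDARIES} boundary "
                "levels and widths"
            )
        if not np.all(np.diff(levels) > 0):
            raise ValueError(
                f"entry {self.entry_id!r}: boundary levels must be strictly increasing"
            )
        if not np.all(widths > 0):
            raise ValueError(f"entry {self.entry_id!r}: boundary widths must be positive")
        grid = np.arange(LEVEL_MIN, LEVEL_MAX + _VALIDATION_GRID_STEP, _VALIDATION_GRID_STEP)
        probs = category_probs_matrix(self, grid)
        if probs.min() < -_NEG_TOL:
            k = int(np.unravel_index(np.argmin(probs), probs.shape)[1])
            raise ValueError(
                f"entry {self.entry_id!r}: crossing boundaries produce a negative "
                f"probability for CU {5 * k} on the stimulus grid"
            )

    def to_dict(self) -> dict[str, Any]:
        return {
            "entry_id": self.entry_id,
            "frequency_hz": self.frequency_hz,
            "boundary_levels": list(self.boundary_levels),
            "boundary_widths": list(self.boundary_widths),
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "MCPF":
        return cls(
            boundary_levels=tuple(d["boundary_levels"]),
            boundary_widths=tuple(d["boundary_widths"]),
            entry_id=str(d.get("entry_id", "mcpf")),
            frequency_hz=d.get("frequency_hz"),
            metadata=dict(d.get("metadata", {})),
        )


class CategoryProbabilityVector(np.ndarray):
    """An 11-vector of category probabilities indexed by CU/5; sums to 1."""

    def __new__(cls, probs) -> "CategoryProbabilityVector":
        arr = np.asarray(probs, dtype=float).view(cls)
        if arr.shape != (N_CATEGORIES,):
            raise ValueError("expected 11 category probabilities")
        if arr.min() < -_NEG_TOL:
            raise ValueError("category probabilities must be non-negative")
        if abs(float(arr.sum()) - 1.0) > 1e-9:
            raise ValueError("category probabilities must sum to 1")
        return arr


def boundary_prob(mcpf: MCPF, k: int, level: float) -> float:
    """Probability that the response is CU >= 5k at ``level`` dB SPL.

    The boundary function is logistic:
    ``Psi_k(L) = 1 / (1 + exp(-(L - L_k) / w_k))``, monotone in level.
    """
    if not 1 <= k <= N_BOUNDARIES:
        raise ValueError(f"boundary index k={k} out of range 1..{N_BOUNDARIES}")
    L_k = mcpf.boundary_levels[k - 1]
    w_k = mcpf.boundary_widths[k - 1]
    return float(expit((level - L_k) / w_k))


def _cumulative_matrix(mcpf: MCPF, levels: np.ndarray) -> np.ndarray:
    """Psi_j(L) for j=0..11 stacked: shape (len(levels), 12); Psi_0=1, Psi_11=0."""
    L = np.asarray(mcpf.boundary_levels)
    w = np.asarray(mcpf.boundary_widths)
    psi = expit((levels[:, None] - L[None, :]) / w[None, :])
    ones = np.ones((len(levels), 1))
    zeros = np.zeros((len(levels), 1))
    return np.concatenate([ones, psi, zeros], axis=1)


def category_probs_matrix(mcpf: MCPF, levels) -> np.ndarray:
    """Category probabilities at several levels at once; shape (n_levels, 11)."""
    levels = np.atleast_1d(np.asarray(levels, dtype=float))
    psi = _cumulative_matrix(mcpf, levels)
    return psi[:, :-1] - psi[:, 1:]


def category_probs(mcpf: MCPF, level: float) -> CategoryProbabilityVector:
    """P(CU = 5j | level) for j = 0..10, as differences of boundary functions."""
    p = category_probs_matrix(mcpf, [level])[0]
    # Validation guarantees non-negativity on the grid; clamp float dust only.
    return CategoryProbabilityVector(np.clip(p, 0.0, None))


def cls_function_from_mcpf(mcpf: MCPF):
    """Conventional loudness-growth function from the MCPF's boundary functions.

    The level assigned to each CU boundary is the 50% point of its boundary
    psychometric function, which for the logistic parameterization is exactly
    ``boundary_levels``.  CU 0 and CU 50 carry no bounded level (the level sets
    that map to the extreme categories are half-lines).
    """
    from .cls_fit import CLSFunction

    per_cu = {5 * k: mcpf.boundary_levels[k - 1] for k in range(1, N_BOUNDARIES + 1)}
    return CLSFunction(per_cu_levels=per_cu, method="ml", source=mcpf.entry_id)
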