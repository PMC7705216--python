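"""Bayesian inference over a catalog of MCPFs and MEI stimulus selection.

The listener's unknown loudness function is one of the catalog entries.  The
posterior starts uniform, is updated trial by trial from each entry's category
probabilities at the presented level, and its Shannon entropy (bits) measures
the remaining uncertainty.  The maximum-expected-information (MEI) rule picks
the next level as the one minimizing the probability-weighted expected
posterior entropy over the 11 possible responses -- equivalently, the level
whose response is expected to reduce entropy the most.

Per-trial entry likelihoods are floored at ``LIKELIHOOD_FLOOR`` and
renormalized over categories before use, so a single lapse response can never
permanently zero out an entry, and the expected posterior entropy never
exceeds the current entropy (exact concavity of entropy under a proper
Bayes update).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import Catalog
from .mcpf_model import CategoryProbabilityVector, category_probs_matrix

__all__ = [
    "PosteriorState",
    "SelectionConstraints",
    "LikelihoodTable",
    "init_posterior",
    "update_posterior",
    "entropy",
    "predictive_response_dist",
    "expected_posterior_entropy",
    "select_mei_level",
    "LIKELIHOOD_FLOOR",
]

#: Floor applied to per-trial entry likelihoods before renormalization.
LIKELIHOOD_FLOOR = 1e-6

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class PosteriorState:
    """Probability vector over catalog entries; immutable."""

    probs: np.ndarray
    n_trials_absorbed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)
        if p.ndim != 1 or len(p) < 1:
            raise ValueError("posterior must be a non-empty vector")
        if p.min() < 0 or abs(float(p.sum()) - 1.0) > 1e-9:
            raise ValueError("posterior must be non-negative and sum to 1")


@dataclass(frozen=True)
class SelectionConstraints:
    """Presentation constraints for the next-level search.

    The candidate set is the ``level_grid_step`` grid (anchored at 0 dB SPL)
    within [lower_limit, upper_limit], excluding levels more than
    ``max_transition`` dB from ``previous_level`` and, if
    ``forbid_consecutive_repeat``, the previous level itself.
    """

    lower_limit: float = 0.0
    upper_limit: float = 110.0
    level_grid_step: float = 5.0
    max_transition: float = 45.0
    forbid_consecutive_repeat: bool = True
    previous_level: float | None = None

    def __post_init__(self) -> None:
        if not self.lower_limit <= self.upper_limit <= 110.0:
            raise ValueError("need lower_limit <= upper_limit <= 110 dB SPL")
        if self.max_transition <= 0 or self.level_grid_step <= 0:
            raise ValueError("max_transition and level_grid_step must be positive")

    def candidate_levels(self) -> np.ndarray:
        step = self.level_grid_step
        first = np.ceil(self.lower_limit / step - 1e-9) * step
        grid = np.arange(first, self.upper_limit + 1e-9, step)
        if self.previous_level is not None:
            grid = grid[np.abs(grid - self.previous_level) <= self.max_transition + 1e-9]
            if self.forbid_consecutive_repeat:
                grid = grid[np.abs(grid - self.previous_level) > 1e-9]
        return grid


class LikelihoodTable:
    """Cached per-entry category probabilities, floored and renormalized.

    ``raw(level)`` is the (n_entries, 11) matrix of exact category
    probabilities; ``floored(level)`` floors each row at the likelihood floor
    and renormalizes it over categories, giving the conditional distribution
    actually used for posterior updates and expected-entropy evaluation.
    """

    def __init__(self, catalog: Catalog, floor: float = LIKELIHOOD_FLOOR):
        self.catalog = catalog
        self.floor = floor
        self._raw: dict[float, np.ndarray] = {}
        self._floored: dict[float, np.ndarray] = {}

    def raw(self, level: float) -> np.ndarray:
        key = float(level)
        if key not in self._raw:
            mat = np.stack(
                [category_probs_matrix(e, [key])[0] for e in self.catalog.entries]
            )
            self._raw[key] = np.clip(mat, 0.0, None)
        return self._raw[key]

    def floored(self, level: float) -> np.ndarray:
        key = float(level)
        if key not in self._floored:
            mat = np.maximum(self.raw(key), self.floor)
            self._floored[key] = mat / mat.sum(axis=1, keepdims=True)
        return self._floored[key]


def init_posterior(catalog: Catalog) -> PosteriorState:
    """Uniform prior: every catalog entry equally likely before the first trial."""
    n = len(catalog)
    return PosteriorState(np.full(n, 1.0 / n), n_trials_absorbed=0)


def update_posterior(
    state: PosteriorState,
    catalog: Catalog,
    trial,
    table: LikelihoodTable | None = None,
) -> PosteriorState:
    """Bayes update from one (level, response) pair; pure function.

    Each entry's likelihood of the observed response at the presented level is
    multiplied into its prior probability and the vector renormalized.
    ``trial`` is anything with ``level`` and ``response_cu`` attributes, or a
    (level, response_cu) pair.
    """
    if hasattr(trial, "level"):
        level, cu = trial.level, trial.response_cu
    else:
        level, cu = trial
    if cu % 5 or not 0 <= cu <= 50:
        raise ValueError(f"response {cu!r} is not a CU on the scale")
    if table is None:
        table = LikelihoodTable(catalog)
    lik = table.floored(level)[:, int(cu) // 5]
    post = state.probs * lik
    total = post.sum()
    if total <= 0:
        raise ValueError("posterior mass vanished: all entries assign zero likelihood")
    return PosteriorState(post / total, state.n_trials_absorbed + 1)


def entropy(state: PosteriorState) -> float:
    """Shannon entropy in bits, -sum p log2 p with 0 log 0 = 0."""
    p = state.probs[state.probs > 0]
    return float(-(p * np.log2(p)).sum())


def predictive_response_dist(
    state: PosteriorState,
    catalog: Catalog,
    level: float,
    table: LikelihoodTable | None = None,
) -> CategoryProbabilityVector:
    """Posterior-predictive category distribution at a level (11-vector)."""
    if table is None:
        table = LikelihoodTable(catalog)
    p = state.probs @ table.raw(level)
    return CategoryProbabilityVector(np.clip(p, 0.0, None) / p.sum())


def _expected_entropies(
    state: PosteriorState, table: LikelihoodTable, levels: np.ndarray
) -> np.ndarray:
    """Expected posterior entropy (bits) for each candidate level, vectorized.

    For weights w_ic = p_i L(c|i), with column sums s_c, the expectation
    sum_c s_c H(posterior|c) equals -sum_ic w_ic log2 w_ic + sum_c s_c log2 s_c.
    """
    out = np.empty(len(levels))
    for j, lv in enumerate(levels):
        w = state.probs[:, None] * table.floored(lv)
        s = w.sum(axis=0)
        nz = w > 0
        t1 = -(w[nz] * np.log2(w[nz])).sum()
        snz = s[s > 0]
        t2 = (snz * np.log2(snz)).sum()
        out[j] = t1 + t2
    return out


def expected_posterior_entropy(
    state: PosteriorState,
    catalog: Catalog,
    level: float,
    table: LikelihoodTable | None = None,
) -> float:
    """Probability-weighted expected entropy after a hypothetical trial at ``level``.

    Enumerates all 11 responses exactly; never exceeds the current entropy.
    """
    if table is None:
        table = LikelihoodTable(catalog)
    return float(_expected_entropies(state, table, np.asarray([level]))[0])


def select_mei_level(
    state: PosteriorState,
    catalog: Catalog,
    constraints: SelectionConstraints,
    table: LikelihoodTable | None = None,
) -> float:
    """The admissible level whose expected posterior entropy is lowest.

    Ties (within numerical tolerance) are broken toward the lowest level, which
    favors quieter presentations.  Deterministic.
    """
    if table is None:
        table = LikelihoodTable(catalog)
    cands = constraints.candidate_levels()
    if len(cands) == 0:
        raise ValueError("no admissible candidate levels under the constraints")
    h = _expected_entropies(state, table, cands)
    best = h.min()
    return float(cands[np.argmax(h <= best + _TIE_TOL)])
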