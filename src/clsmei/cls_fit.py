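"""CLS loudness-growth function estimation from trial-by-trial responses.

Two estimators are provided.  The *median* method assigns each categorical
unit (CU) the median of the presented levels that received it, with no outlier
removal; sparse categories may rest on a single response and unused categories
stay missing.  The *maximum-likelihood* method instead selects the catalog
MCPF entry maximizing the summed log-likelihood of all responses and reads the
CLS function off that entry's boundary 50% points, which smooths estimates
across categories.

CU 0 ("Can't Hear") and CU 50 ("Too Loud") are excluded from analysis because
the level sets mapping to the extreme categories are unbounded half-lines.
Loudness can be re-expressed in phons through a pluggable monotone anchor
table, and hearing threshold is estimated as the level at 2.5 CU by linear
regression over the CU <= 20 portion of the function.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .bayes_mei import LikelihoodTable
from .catalog import Catalog
from .mcpf_model import cls_function_from_mcpf  # noqa: F401  (re-exported)
from .tracking import SessionLog

__all__ = [
    "CLSFunction",
    "PhonMap",
    "DEFAULT_PHON_MAP",
    "median_cls",
    "ml_cls",
    "cu_to_phon",
    "estimate_threshold",
]

#: CUs included in analysis; the extremes are unbounded.
ANALYSIS_CUS = tuple(range(5, 50, 5))


@dataclass(frozen=True)
class CLSFunction:
    """Per-CU level estimates for one session (dB SPL).

    ``per_cu_levels`` may include CU 0/50 entries for completeness; they are
    flagged excluded from analysis and dropped by :meth:`analysis_points`.
    ``loudness`` optionally maps each CU to a loudness value in ``loudness_unit``
    (CU by default, phon after :func:`cu_to_phon`).
    """

    per_cu_levels: Mapping[int, float]
    method: str = "median"
    source: str | None = None
    loudness_unit: str = "CU"
    loudness: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        levels = dict(self.per_cu_levels)
        for cu, lv in levels.items():
            if cu % 5 or not 0 <= cu <= 50:
                raise ValueError(f"CU {cu} is not on the scale")
            if not 0 <= lv <= 110:
                raise ValueError(f"level {lv} for CU {cu} outside [0, 110] dB SPL")
        object.__setattr__(self, "per_cu_levels", levels)
        if not self.loudness:
            object.__setattr__(
                self, "loudness", {cu: float(cu) for cu in levels}
            )

    def analysis_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(levels, loudness) over CU 5-45, missing categories skipped."""
        cus = [cu for cu in ANALYSIS_CUS if cu in self.per_cu_levels]
        levels = np.asarray([self.per_cu_levels[cu] for cu in cus])
        loud = np.asarray([self.loudness[cu] for cu in cus])
        return levels, loud

    def to_dataframe(self) -> pd.DataFrame:
        cus = sorted(self.per_cu_levels)
        return pd.DataFrame(
            {
                "cu": cus,
                "level_db_spl": [self.per_cu_levels[c] for c in cus],
                f"loudness_{self.loudness_unit.lower()}": [self.loudness[c] for c in cus],
                "method": self.method,
                "in_analysis": [c in ANALYSIS_CUS for c in cus],
            }
        )


@dataclass(frozen=True)
class PhonMap:
    """Monotone anchor table CU -> phon with linear interpolation between anchors."""

    anchors: Mapping[int, float]
    identifier: str = "custom"

    def __post_init__(self) -> None:
        cus = sorted(self.anchors)
        vals = [self.anchors[c] for c in cus]
        if len(cus) < 2 or any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("phon map must have >= 2 anchors, strictly increasing")
        if cus[0] > 5 or cus[-1] < 45:
            raise ValueError("phon map must cover CU 5 through 45")
        object.__setattr__(self, "anchors", dict(self.anchors))

    def __call__(self, cu: float) -> float:
        cus = np.asarray(sorted(self.anchors), dtype=float)
        vals = np.asarray([self.anchors[int(c)] for c in cus])
        return float(np.interp(cu, cus, vals))


#: Generic linear anchor table (2 phon per CU, "Very Soft" at 15 phon).  A
#: placeholder scaling, not an empirically fitted loudness-level conversion;
#: supply a fitted :class:`PhonMap` for quantitative phon-space analyses.
DEFAULT_PHON_MAP = PhonMap(
    anchors={5: 15.0, 15: 35.0, 25: 55.0, 35: 75.0, 45: 95.0},
    identifier="linear-2phon-per-cu",
)


def median_cls(log: SessionLog) -> CLSFunction:
    """Median presented level per CU; even counts use the midpoint convention."""
    if not log.trials:
        raise ValueError("empty session log")
    levels = log.levels()
    responses = log.responses()
    per_cu = {
        int(cu): float(np.median(levels[responses == cu]))
        for cu in np.unique(responses)
    }
    return CLSFunction(per_cu, method="median", source=log.procedure)


def ml_cls(log: SessionLog, catalog: Catalog) -> tuple[str, CLSFunction]:
    """Best-fitting catalog entry by summed log-likelihood, and its CLS function.

    Uses the same floored likelihoods as the Bayesian tracker, so the ML choice
    equals the posterior mode under a uniform prior.  Ties break to the lowest
    catalog index.
    """
    if not log.trials:
        raise ValueError("empty session log")
    table = LikelihoodTable(catalog)
    loglik = np.zeros(len(catalog))
    for t in log.trials:
        loglik += np.log(table.floored(t.level)[:, t.response_cu // 5])
    best = int(np.argmax(loglik))  # argmax returns the first (lowest) index on ties
    entry = catalog[best]
    fn = cls_function_from_mcpf(entry)
    return entry.entry_id, replace(fn, source=f"{log.procedure}:{entry.entry_id}")


def cu_to_phon(fn: CLSFunction, phon_map: PhonMap = DEFAULT_PHON_MAP) -> CLSFunction:
    """Relabel a CLS function's loudness axis in phons; levels untouched."""
    loud = {cu: phon_map(cu) for cu in fn.per_cu_levels}
    return replace(fn, loudness=loud, loudness_unit=f"phon[{phon_map.identifier}]")


def estimate_threshold(fn: CLSFunction) -> float:
    """Hearing-threshold estimate: level at 2.5 CU from the CU <= 20 regression.

    2.5 CU is midway between "Can't Hear" and "Very Soft", i.e. a 50%-audible
    criterion.  With no CU <= 20 data the lowest level in the function is
    returned as the fallback estimate.
    """
    pts = [(lv, cu) for cu, lv in fn.per_cu_levels.items() if cu in ANALYSIS_CUS and cu <= 20]
    if not pts:
        bounded = [lv for cu, lv in fn.per_cu_levels.items() if cu in ANALYSIS_CUS]
        if not bounded:
            raise ValueError("CLS function has no analysable points")
        return float(min(bounded))
    if len(pts) == 1:
        return float(pts[0][0])
    levels = np.asarray([p[0] for p in pts])
    cus = np.asarray([p[1] for p in pts])
    if np.ptp(levels) == 0:
        raise ValueError("degenerate regression: all levels identical")
    res = stats.linregress(levels, cus)
    return float((2.5 - res.intercept) / res.slope)


def write_cls_function(fn: CLSFunction, path: str | Path) -> None:
    fn.to_dataframe().to_csv(path, index=False)
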