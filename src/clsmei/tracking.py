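"""Trial-sequence procedures for categorical loudness scaling.

Every session has two stages.  First, the listener's dynamic range is found
with two interleaved level sequences, one ascending and one descending; the
lower end is the last audible level of the descending sequence and the upper
end the last ascending level not judged "Too Loud".  Second, the loudness
function is measured by one of four procedures:

fixed-level
    Every 5-dB level in the dynamic range, each presented 10 times (up to 22
    levels / 220 trials), in a randomized order where the same level never
    repeats consecutively and consecutive levels never differ by more than
    45 dB.
slope-adaptive
    5 runs of 9 trials; each run presents 9 levels evenly spanning the current
    limits (randomized order within a run).
mei-adaptive
    5 runs of 9 trials; the first level is the dynamic-range midpoint and each
    subsequent level is chosen by the maximum-expected-information rule over
    the MCPF catalog.  The posterior persists across runs.
urd
    5 runs of 9 trials drawn uniformly at random from the 5-dB grid within the
    current limits; emulates an adaptive procedure without informed selection.

All adaptive procedures share the per-run safety rule: any "Too Loud" response
in a run lowers the next run's upper limit by 5 dB; a run without one raises
it by 5 dB, never beyond 110 dB SPL.

A *responder* is any callable mapping a level in dB SPL to a CU response,
e.g. a :class:`~clsmei.listener_sim.SimulatedListener`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from . import bayes_mei
from .bayes_mei import LikelihoodTable, SelectionConstraints
from .catalog import Catalog
from .mcpf_model import LEVEL_MAX, LEVEL_MIN

__all__ = [
    "TrialRecord",
    "DynamicRange",
    "SessionLog",
    "DynamicRangeConfig",
    "estimate_dynamic_range",
    "run_fixed_level",
    "run_slope_adaptive",
    "run_mei_adaptive",
    "run_urd",
    "read_session_log",
    "write_session_log",
]

Responder = Callable[[float], int]

N_RUNS = 5
TRIALS_PER_RUN = 9
REPEATS_PER_LEVEL = 10
GRID_STEP = 5.0
MAX_TRANSITION = 45.0
TOO_LOUD_CU = 50
CANT_HEAR_CU = 0


@dataclass(frozen=True)
class TrialRecord:
    index: int
    run: int
    level: float
    response_cu: int
    procedure: Literal["fixed", "slope", "mei", "urd"]
    entropy_after: float | None = None

    def __post_init__(self) -> None:
        if not LEVEL_MIN <= self.level <= LEVEL_MAX:
            raise ValueError(f"level {self.level} outside [0, 110] dB SPL")
        if self.response_cu % 5 or not 0 <= self.response_cu <= 50:
            raise ValueError(f"response {self.response_cu} not a CU on the scale")


@dataclass(frozen=True)
class DynamicRange:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not LEVEL_MIN <= self.lower < self.upper <= LEVEL_MAX:
            raise ValueError(f"degenerate dynamic range [{self.lower}, {self.upper}]")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


@dataclass
class SessionLog:
    """Ordered trial records for one track, with per-run limits for audit."""

    trials: list[TrialRecord]
    dynamic_range: DynamicRange
    procedure: str
    frequency_hz: float | None = None
    seed: int | None = None
    run_limits: list[tuple[float, float]] = field(default_factory=list)

    def levels(self) -> np.ndarray:
        return np.asarray([t.level for t in self.trials])

    def responses(self) -> np.ndarray:
        return np.asarray([t.response_cu for t in self.trials])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [t.index for t in self.trials],
                "run": [t.run for t in self.trials],
                "procedure": self.procedure,
                "frequency_hz": self.frequency_hz,
                "level_db_spl": self.levels(),
                "response_cu": self.responses(),
                "entropy_bits": [t.entropy_after for t in self.trials],
            }
        )


@dataclass(frozen=True)
class DynamicRangeConfig:
    """Settings for the interleaved ascending/descending pre-phase."""

    start_level: float = 60.0
    step: float = 10.0

    def __post_init__(self) -> None:
        if not LEVEL_MIN <= self.start_level <= LEVEL_MAX or self.step <= 0:
            raise ValueError("invalid dynamic-range configuration")


def estimate_dynamic_range(
    responder: Responder, config: DynamicRangeConfig = DynamicRangeConfig()
) -> DynamicRange:
    """First-stage estimate of the listener's usable level range.

    Two sequences interleave (ascend, descend, ascend, ...), both starting at
    ``start_level``.  The ascending sequence stops at the first "Too Loud" or
    at 110 dB SPL; the descending sequence stops at the first "Can't Hear" or
    at 0 dB SPL.  The upper end is the last ascending level not judged "Too
    Loud"; the lower end is the last audible descending level.  If the start
    level itself is inaudible, the first audible ascending level bounds the
    range from below instead; a listener inaudible everywhere is an error.
    """
    asc_level = config.start_level
    desc_level = config.start_level - config.step
    upper: float | None = None
    lower: float | None = None
    first_audible_asc: float | None = None
    asc_done = desc_done = False
    start_inaudible = False

    # ascending presentation at the shared start level; a "Too Loud" here moves
    # the start down until a tolerable level is found
    cu = responder(asc_level)
    while cu == TOO_LOUD_CU and asc_level > LEVEL_MIN:
        asc_level -= config.step
        desc_level = asc_level - config.step
        cu = responder(asc_level)
    if cu == TOO_LOUD_CU:
        asc_done = True
    else:
        upper = asc_level
        if cu > CANT_HEAR_CU:
            first_audible_asc = asc_level
    if cu == CANT_HEAR_CU:
        start_inaudible = True
        desc_done = True  # nothing softer can be audible for a monotone listener
    asc_level += config.step

    while not (asc_done and desc_done):
        if not asc_done:
            if asc_level > LEVEL_MAX + 1e-9:
                asc_done = True
            else:
                cu = responder(asc_level)
                if cu == TOO_LOUD_CU:
                    asc_done = True
                else:
                    upper = asc_level
                    if cu > CANT_HEAR_CU and first_audible_asc is None:
                        first_audible_asc = asc_level
                    asc_level += config.step
        if not desc_done:
            if desc_level < LEVEL_MIN - 1e-9:
                desc_done = True
            else:
                cu = responder(desc_level)
                if cu == CANT_HEAR_CU:
                    desc_done = True
                else:
                    lower = desc_level
                    desc_level -= config.step

    if lower is None:
        lower = first_audible_asc
    if start_inaudible and first_audible_asc is None:
        raise ValueError("no audible level found; cannot establish a dynamic range")
    if lower is None or upper is None or not lower < upper:
        raise ValueError("degenerate dynamic range; responder gave inconsistent answers")
    return DynamicRange(lower, upper)


def _grid_levels(lower: float, upper: float, step: float = GRID_STEP) -> np.ndarray:
    first = np.ceil(lower / step - 1e-9) * step
    return np.arange(first, upper + 1e-9, step)


def _constrained_order(
    levels: Sequence[float], rng: np.random.Generator, max_restarts: int = 1000
) -> list[float]:
    """Random order of the level multiset with no immediate repeats and
    |consecutive difference| <= 45 dB; sequential sampling with restarts."""
    levels = list(levels)
    for _ in range(max_restarts):
        remaining = list(levels)
        rng.shuffle(remaining)
        order: list[float] = []
        ok = True
        while remaining:
            prev = order[-1] if order else None
            cand_idx = [
                i
                for i, lv in enumerate(remaining)
                if prev is None
                or (abs(lv - prev) > 1e-9 and abs(lv - prev) <= MAX_TRANSITION + 1e-9)
            ]
            if not cand_idx:
                ok = False
                break
            order.append(remaining.pop(cand_idx[int(rng.integers(len(cand_idx)))]))
        if ok:
            return order
    raise RuntimeError("could not find a constraint-satisfying presentation order")


def run_fixed_level(responder: Responder, dr: DynamicRange, seed: int) -> SessionLog:
    """Non-adaptive reference procedure: every grid level 10 times, randomized."""
    grid = _grid_levels(dr.lower, dr.upper)
    if len(grid) == 0:
        raise ValueError("dynamic range contains no 5-dB grid level")
    rng = np.random.default_rng(seed)
    order = _constrained_order(list(grid) * REPEATS_PER_LEVEL, rng)
    trials = [
        TrialRecord(i, 0, lv, int(responder(lv)), "fixed") for i, lv in enumerate(order)
    ]
    return SessionLog(trials, dr, "fixed", seed=seed, run_limits=[(dr.lower, dr.upper)])


def _apply_run_rule(responses: Sequence[int], upper: float) -> float:
    """Per-run upper-limit update: -5 dB after any "Too Loud", else +5 dB
    capped at 110 dB SPL."""
    if any(cu == TOO_LOUD_CU for cu in responses):
        return upper - 5.0
    return min(upper + 5.0, LEVEL_MAX)


def run_slope_adaptive(responder: Responder, dr: DynamicRange, seed: int) -> SessionLog:
    """Emulation of the standard adaptive procedure: evenly spaced levels."""
    rng = np.random.default_rng(seed)
    lower, upper = dr.lower, dr.upper
    trials: list[TrialRecord] = []
    run_limits = []
    for run in range(N_RUNS):
        run_limits.append((lower, upper))
        levels = np.linspace(lower, upper, TRIALS_PER_RUN)
        rng.shuffle(levels)
        responses = []
        for lv in levels:
            cu = int(responder(float(lv)))
            responses.append(cu)
            trials.append(TrialRecord(len(trials), run, float(lv), cu, "slope"))
        upper = _apply_run_rule(responses, upper)
        upper = max(upper, lower + GRID_STEP)  # keep the run span usable
    return SessionLog(trials, dr, "slope", seed=seed, run_limits=run_limits)


def run_mei_adaptive(
    responder: Responder,
    catalog: Catalog,
    dr: DynamicRange,
    constraints: SelectionConstraints | None = None,
    seed: int | None = None,
) -> SessionLog:
    """MEI-adaptive procedure: entropy-minimizing level selection.

    The first level is the dynamic-range midpoint snapped to the grid; every
    later level comes from :func:`clsmei.bayes_mei.select_mei_level`.  The
    posterior over catalog entries persists across the 5 runs and each trial's
    posterior entropy is recorded.
    """
    if constraints is None:
        constraints = SelectionConstraints()
    table = LikelihoodTable(catalog)
    state = bayes_mei.init_posterior(catalog)
    lower, upper = dr.lower, dr.upper
    step = constraints.level_grid_step
    prev: float | None = None
    trials: list[TrialRecord] = []
    run_limits = []
    first = float(np.round(dr.midpoint / step) * step)
    for run in range(N_RUNS):
        run_limits.append((lower, upper))
        responses = []
        for t in range(TRIALS_PER_RUN):
            if prev is None:
                lv = min(max(first, lower), upper)
            else:
                c = replace(
                    constraints,
                    lower_limit=lower,
                    upper_limit=upper,
                    previous_level=prev,
                )
                lv = bayes_mei.select_mei_level(state, catalog, c, table)
            cu = int(responder(lv))
            state = bayes_mei.update_posterior(state, catalog, (lv, cu), table)
            responses.append(cu)
            trials.append(
                TrialRecord(len(trials), run, lv, cu, "mei", bayes_mei.entropy(state))
            )
            prev = lv
        upper = _apply_run_rule(responses, upper)
        upper = max(upper, lower + step)
    return SessionLog(trials, dr, "mei", seed=seed, run_limits=run_limits)


def run_urd(responder: Responder, dr: DynamicRange, seed: int) -> SessionLog:
    """Uniform-random level selection within the current limits (comparison)."""
    rng = np.random.default_rng(seed)
    lower, upper = dr.lower, dr.upper
    trials: list[TrialRecord] = []
    run_limits = []
    for run in range(N_RUNS):
        run_limits.append((lower, upper))
        grid = _grid_levels(lower, upper)
        responses = []
        for _ in range(TRIALS_PER_RUN):
            lv = float(grid[int(rng.integers(len(grid)))])
            cu = int(responder(lv))
            responses.append(cu)
            trials.append(TrialRecord(len(trials), run, lv, cu, "urd"))
        upper = _apply_run_rule(responses, upper)
        upper = max(upper, lower + GRID_STEP)
    return SessionLog(trials, dr, "urd", seed=seed, run_limits=run_limits)


def write_session_log(log: SessionLog, path: str | Path) -> None:
    """Write a session to CSV (one row per trial, limits in a header comment)."""
    buf = io.StringIO()
    buf.write(
        f"# procedure={log.procedure} seed={log.seed} "
        f"dynamic_range={log.dynamic_range.lower},{log.dynamic_range.upper}\n"
    )
    log.to_dataframe().to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_session_log(path: str | Path) -> SessionLog:
    """Read a session CSV written by :func:`write_session_log`."""
    text = Path(path).read_text().splitlines()
    meta = {}
    if text and text[0].startswith("#"):
        for tok in text[0][1:].split():
            k, _, v = tok.partition("=")
            meta[k] = v
    df = pd.read_csv(io.StringIO("\n".join(text)), comment="#")
    lo, _, hi = meta.get("dynamic_range", "").partition(",")
    dr = DynamicRange(float(lo), float(hi)) if lo and hi else DynamicRange(0.0, 110.0)
    proc = meta.get("procedure", str(df["procedure"].iloc[0]))
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    trials = [
        TrialRecord(
            int(r["index"]),
            int(r["run"]),
            float(r["level_db_spl"]),
            int(r["response_cu"]),
            proc,
            None if pd.isna(r["entropy_bits"]) else float(r["entropy_bits"]),
        )
        for _, r in df.iterrows()
    ]
    freq = None if pd.isna(df["frequency_hz"].iloc[0]) else float(df["frequency_hz"].iloc[0])
    return SessionLog(trials, dr, proc, frequency_hz=freq, seed=seed)
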