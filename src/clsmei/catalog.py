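"""Catalogs of MCPF entries: the hypothesis space for Bayesian tracking.

The catalog is a finite set of candidate listener models spanning normal
hearing through moderate hearing loss.  Because the original empirical catalog
is not redistributable, entries are generated synthetically: the softest
boundary (CU 5, roughly threshold) and the loudest boundary (CU 50) are
sampled from configurable ranges, and the interior boundaries are placed by a
two-segment ("bent-line") monotone interpolation.  Hearing-impaired entries
have elevated thresholds and a compressed dynamic range, so their loudness
grows abnormally fast above threshold (recruitment); the knee of the bent line
controls where growth steepens.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Iterator, Sequence

import numpy as np

from .mcpf_model import MCPF, N_BOUNDARIES

__all__ = ["Catalog", "CatalogGenParams", "generate_catalog", "read_catalog", "write_catalog"]

#: Default catalog size, matching the scale of the empirical catalog this
#: generator stands in for.
DEFAULT_N_ENTRIES = 1460


@dataclass(frozen=True)
class CatalogGenParams:
    """Generator settings for a synthetic MCPF catalog.

    threshold_range
        dB SPL interval from which the CU-5 boundary (near-threshold level) is
        drawn; spans normal hearing (~0-20 dB SPL) to moderate loss.
    upper_range
        dB SPL interval for the CU-50 ("Too Loud") boundary.
    min_dynamic_range
        Minimum allowed CU-5..CU-50 span in dB; pairs violating it are redrawn.
    width_range
        dB interval for the logistic boundary widths.
    knee_fraction_range
        Where along the CU axis the bent-line knee sits (fraction of the span
        between the first and last boundary).
    """

    n_entries: int = DEFAULT_N_ENTRIES
    threshold_range: tuple[float, float] = (0.0, 70.0)
    upper_range: tuple[float, float] = (85.0, 110.0)
    min_dynamic_range: float = 25.0
    width_range: tuple[float, float] = (3.0, 8.0)
    knee_fraction_range: tuple[float, float] = (0.25, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_entries < 2:
            raise ValueError("a catalog needs at least 2 entries")
        for name in ("threshold_range", "upper_range", "width_range", "knee_fraction_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} is empty: ({lo}, {hi})")
        if self.min_dynamic_range <= 0:
            raise ValueError("min_dynamic_range must be positive")
        if self.threshold_range[0] + self.min_dynamic_range > self.upper_range[1]:
            raise ValueError(
                "infeasible ranges: no threshold/upper pair can satisfy min_dynamic_range"
            )


@dataclass(frozen=True)
class Catalog:
    """Ordered list of valid MCPF entries with unique ids plus provenance."""

    entries: tuple[MCPF, ...]
    frequency_hz: float | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        if len(self.entries) < 2:
            raise ValueError("a catalog needs at least 2 entries")
        ids = [e.entry_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate entry_id {dup!r} in catalog")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[MCPF]:
        return iter(self.entries)

    def __getitem__(self, i: int) -> MCPF:
        return self.entries[i]

    def boundary_level_matrix(self) -> np.ndarray:
        """All entries' boundary levels, shape (n_entries, 10)."""
        return np.asarray([e.boundary_levels for e in self.entries])


def _interior_boundaries(
    L1: float, L10: float, knee_fraction: float, knee_level_fraction: float
) -> np.ndarray:
    """Place boundaries 1..10 on a two-segment piecewise-linear curve.

    The boundary index axis is normalized to [0, 1]; the knee sits at
    ``knee_fraction`` along it and at ``knee_level_fraction`` of the level span.
    A knee below the diagonal (level fraction < index fraction) packs the upper
    categories closely in level -- the recruitment-like compressed top of the
    dynamic range.
    """
    x = np.linspace(0.0, 1.0, N_BOUNDARIES)
    xk = float(np.clip(knee_fraction, 0.05, 0.95))
    yk = float(np.clip(knee_level_fraction, 0.05, 0.95))
    y = np.where(x <= xk, x * yk / xk, yk + (x - xk) * (1.0 - yk) / (1.0 - xk))
    return L1 + y * (L10 - L1)


def generate_catalog(params: CatalogGenParams) -> Catalog:
    """Generate a seeded synthetic catalog; deterministic for a given seed.

    Each entry: draw the CU-5 and CU-50 boundary levels (rejecting pairs whose
    span is below ``min_dynamic_range``), place interior boundaries on the bent
    line, draw per-boundary widths, and validate.  Width draws that would make
    category probabilities cross into negative territory are retried with a
    common (flat) width, which can never cross.
    """
    rng = np.random.default_rng(params.seed)
    entries: list[MCPF] = []
    width = len(str(params.n_entries))
    for i in range(params.n_entries):
        for _ in range(1000):
            L1 = rng.uniform(*params.threshold_range)
            L10 = rng.uniform(*params.upper_range)
            if L10 - L1 >= params.min_dynamic_range:
                break
        else:
            raise ValueError("could not satisfy min_dynamic_range; ranges too tight")
        xk = rng.uniform(*params.knee_fraction_range)
        # Deeper hearing loss (higher L1) gets a lower knee: faster growth on top.
        severity = (L1 - params.threshold_range[0]) / max(
            params.threshold_range[1] - params.threshold_range[0], 1e-9
        )
        yk = xk * (1.0 - 0.5 * severity) + rng.uniform(-0.05, 0.05)
        levels = _interior_boundaries(L1, L10, xk, yk)
        entry_id = f"syn{i:0{width}d}"
        meta = {"severity": round(float(severity), 4)}
        entry = None
        for _ in range(20):
            widths = rng.uniform(*params.width_range, size=N_BOUNDARIES)
            try:
                entry = MCPF(tuple(levels), tuple(widths), entry_id, None, meta)
                break
            except ValueError:
                continue
        if entry is None:
            flat = float(rng.uniform(*params.width_range))
            entry = MCPF(tuple(levels), (flat,) * N_BOUNDARIES, entry_id, None, meta)
        entries.append(entry)
    # JSON-canonical params (tuples as lists) so write/read is the identity
    provenance = {
        "generator": "clsmei.catalog.generate_catalog",
        "params": json.loads(json.dumps(asdict(params))),
    }
    return Catalog(tuple(entries), frequency_hz=None, provenance=provenance)


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    """Serialize a catalog to JSON."""
    doc = {
        "frequency_hz": catalog.frequency_hz,
        "provenance": catalog.provenance,
        "entries": [e.to_dict() for e in catalog.entries],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_catalog(path: str | Path) -> Catalog:
    """Read and re-validate a catalog; write ∘ read is the identity."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not valid catalog JSON: {exc}") from exc
    if not isinstance(doc, dict) or "entries" not in doc:
        raise ValueError(f"{path}: missing 'entries' key")
    entries = []
    for raw in doc["entries"]:
        try:
            entries.append(MCPF.from_dict(raw))
        except (KeyError, TypeError) as exc:
            raise ValueError(f"{path}: malformed entry {raw.get('entry_id', '?')!r}") from exc
    return Catalog(
        tuple(entries),
        frequency_hz=doc.get("frequency_hz"),
        provenance=doc.get("provenance", {}),
    )
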