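"""Overlay of predicted pockets on the conservation map, and the combined
report.

The central qualitative claim the pipeline supports — predicted contact
residues fall within conserved surface regions — is quantified as a
permutation enrichment test: the mean regional conservation of the
contact cells is compared with the means of random cell sets of the same
size drawn uniformly from the solvent-exposed grid.  The statistic and
its null are this package's formalization (the underlying comparative
analysis is qualitative); all outputs label them as such.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass

import numpy as np

from .rcm import LRRGrid, RCMMap

STATISTIC_LABEL = (
    "mean regional conservation of contact cells vs uniform random cell "
    "sets (package-defined formalization)"
)


@dataclass
class EnrichmentResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_perm: int
    seed: int

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")


def map_residues_to_grid(residues, grid: LRRGrid):
    """Map 1-based reference residue numbers to grid cells.

    Returns (cells dict residue -> (row, col), unmapped dict residue ->
    reason); residues outside the solvent-exposed grid are reported, not
    dropped."""
    cells, unmapped = {}, {}
    lo = int(grid.residue_numbers.min())
    hi = int(grid.residue_numbers.max())
    for res in residues:
        cell = grid.cell_of_residue(int(res))
        if cell is not None:
            cells[int(res)] = cell
        elif res < lo or res > hi:
            unmapped[int(res)] = "outside_repeat_region"
        else:
            unmapped[int(res)] = "not_solvent_exposed"
    return cells, unmapped


def enrichment_test(
    cells, rcm: RCMMap, n_perm: int = 999, seed: int = 0
) -> EnrichmentResult:
    """One-sided permutation enrichment of ``cells`` on the regional map.

    observed = mean regional score over the cells; the null draws
    ``len(cells)`` cells uniformly without replacement from the grid,
    ``n_perm`` times; p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    cells = sorted(set(cells))
    n_cells = rcm.regional.size
    if len(cells) == 0:
        raise ValueError("no cells to test")
    if len(cells) > n_cells:
        raise ValueError("more cells than grid positions")
    flat = rcm.regional.ravel()
    ncol = rcm.regional.shape[1]
    idx = []
    for r, c in cells:
        if not (0 <= r < rcm.regional.shape[0] and 0 <= c < ncol):
            raise ValueError(f"cell ({r}, {c}) outside the grid")
        idx.append(r * ncol + c)
    observed = float(flat[idx].mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        draw = rng.choice(n_cells, size=len(cells), replace=False)
        null[k] = flat[draw].mean()
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return EnrichmentResult(observed=observed, null=null, p_value=p,
                            n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

with (pathlib.Path(__file__).parent / "report_schema.json").open() as _fh:
    REPORT_SCHEMA = json.load(_fh)

_STAGE_NAMES = tuple(REPORT_SCHEMA["properties"]["stages"]["properties"])


def build_report(stage_outputs: dict, seed: int, config: dict | None = None):
    """Deterministic JSON-serialisable bundle of all stage outputs.

    Missing stages are recorded as null rather than failing; field order
    is fixed (sorted keys) so identical inputs give byte-identical
    output."""
    from . import __version__

    stages = {}
    for name in _STAGE_NAMES:
        value = stage_outputs.get(name)
        stages[name] = _jsonable(value) if value is not None else None
    report = {
        "meta": {
            "seed": int(seed),
            "package": {"name": "lrrpockets", "version": __version__},
            "statistic": STATISTIC_LABEL,
            "config": _jsonable(config) if config is not None else None,
        },
        "stages": stages,
    }
    return report


def report_json(report: dict) -> str:
    return json.dumps(report, sort_keys=True, indent=1)


def _jsonable(value):
    if isinstance(value, dict):
        return {str(k): _jsonable(v) for k, v in sorted(
            value.items(), key=lambda kv: str(kv[0]))}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, (set, frozenset)):
        return [_jsonable(v) for v in sorted(value)]
    if isinstance(value, np.ndarray):
        return np.round(value, 6).tolist()
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return value


def validate_report(report: dict):
    """Check the bundle against the shipped schema (minimal structural
    validation: required keys and stage typing)."""
    errors = []
    for key in REPORT_SCHEMA["required"]:
        if key not in report:
            errors.append(f"missing top-level key {key!r}")
    meta = report.get("meta", {})
    for key in REPORT_SCHEMA["properties"]["meta"]["required"]:
        if key not in meta:
            errors.append(f"missing meta key {key!r}")
    stages = report.get("stages", {})
    for name in _STAGE_NAMES:
        if name not in stages:
            errors.append(f"missing stage entry {name!r}")
        elif not (stages[name] is None or isinstance(stages[name], dict)):
            errors.append(f"stage {name!r} must be an object or null")
    if errors:
        raise ValueError("; ".join(errors))
    return True
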