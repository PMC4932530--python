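"""Modelling-input preparation: thinning, minimum-records rule, predictor
screening and pseudo-absence sampling.

Occurrence records are snapped to the analysis grid and thinned to one
record per cell (the natural reading of a minimum-separation rule equal to
the grid resolution), species with too few thinned cells are excluded, and
collinear predictors are dropped by a greedy priority-ordered rule on a
random background sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geo import ClimateStack, GridError, OccurrenceSet, RegionMask, lonlat_to_cell

logger = logging.getLogger(__name__)

#: kept preferentially during screening; reproduces the standard retained
#: bioclim set when all candidates are supplied
DEFAULT_PRIORITY = ["BIO5", "BIO6", "BIO13", "BIO14", "BIO18"]


def snap_and_thin(
    records: list[tuple[float, float]], stack: ClimateStack, species: str = "species"
) -> OccurrenceSet:
    """Snap (lon, lat) records to grid cells; keep at most one per cell.

    Records falling out of bounds or on invalid cells are dropped (count
    logged).  Raises :class:`GridError` if nothing remains.
    """
    cells: set[tuple[int, int]] = set()
    n_dropped = 0
    for lon, lat in records:
        try:
            r, c = lonlat_to_cell(lon, lat, stack.transform, stack.shape)
        except GridError:
            n_dropped += 1
            continue
        if not stack.valid_mask[r, c]:
            n_dropped += 1
            continue
        cells.add((r, c))
    if n_dropped:
        logger.info("%s: dropped %d/%d records (out of bounds or invalid cells)",
                    species, n_dropped, len(records))
    if not cells:
        raise GridError(f"{species}: all {len(records)} records out of bounds or invalid")
    return OccurrenceSet(species=species, cells=cells, n_raw=len(records))


def thin_occurrences(occ: OccurrenceSet, stack: ClimateStack) -> OccurrenceSet:
    """Re-thin an OccurrenceSet (idempotent by construction)."""
    centers = [stack.transform.cell_center(r, c) for r, c in occ.sorted_cells()]
    out = snap_and_thin(centers, stack, species=occ.species)
    out.n_raw = occ.n_raw
    return out


def passes_min_records(occ: OccurrenceSet, min_records: int = 11) -> bool:
    """Minimum-sample-size rule: at least ``min_records`` thinned cells.

    The default of 11 reads a "more than ten records" inclusion rule
    strictly; the threshold is configurable because published guidance on
    minimum SDM sample sizes spans roughly 3-13 records.
    """
    return len(occ) >= min_records


@dataclass
class VariableScreenResult:
    retained: list[str]
    dropped: list[tuple[str, str, float]] = field(default_factory=list)  # (dropped, kept, r)
    sample_cells: int = 0
    seed: int = 0
    correlations: "object" = None  # DataFrame of sample correlations (ordered vars)

    @property
    def dropped_names(self) -> list[str]:
        return [d for d, _, _ in self.dropped]


def screen_collinearity(
    stack: ClimateStack,
    candidate_vars: list[str],
    priority_order: list[str] | None = None,
    r_max: float = 0.8,
    n_sample: int = 10000,
    seed: int = 0,
) -> VariableScreenResult:
    """Drop one variable of each pair with |Pearson r| > ``r_max``.

    Correlations are estimated on ``n_sample`` random valid cells (drawn
    with replacement when fewer are available).  Variables are considered in
    priority order; each is retained unless it exceeds the threshold against
    an already-retained variable, in which case the lower-priority variable
    (the one under consideration) is dropped against the retained partner.
    """
    for var in candidate_vars:
        if var not in stack.variables:
            raise KeyError(f"candidate variable '{var}' not in stack")
    if len(candidate_vars) < 2:
        raise ValueError("need at least 2 candidate variables")

    priority = list(priority_order) if priority_order is not None else list(DEFAULT_PRIORITY)
    ordered = [v for v in priority if v in candidate_vars]
    ordered += [v for v in candidate_vars if v not in ordered]

    rows, cols = np.nonzero(stack.valid_mask)
    if rows.size == 0:
        raise GridError("no valid cells to sample for screening")
    rng = np.random.default_rng(seed)
    replace = rows.size < n_sample
    idx = rng.choice(rows.size, size=n_sample, replace=replace)
    sample = np.column_stack(
        [stack.variables[v][rows[idx], cols[idx]] for v in ordered]
    )
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sample, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)  # constant variable: treat as uncorrelated

    retained: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for i, var in enumerate(ordered):
        clash = None
        for kept in retained:
            r = corr[i, ordered.index(kept)]
            if abs(r) > r_max:
                clash = (kept, float(r))
                break
        if clash is None:
            retained.append(var)
        else:
            dropped.append((var, clash[0], clash[1]))
            logger.info("screening: dropped %s (|r|=%.3f with %s)", var, abs(clash[1]), clash[0])
    import pandas as pd

    return VariableScreenResult(
        retained=retained,
        dropped=dropped,
        sample_cells=n_sample,
        seed=seed,
        correlations=pd.DataFrame(corr, index=ordered, columns=ordered),
    )


def sample_background(
    stack: ClimateStack,
    n: int,
    seed: int,
    exclude: OccurrenceSet | None = None,
    mask: RegionMask | None = None,
) -> list[tuple[int, int]]:
    """Draw ``n`` distinct valid background (pseudo-absence) cells.

    Cells in ``exclude`` are never drawn; ``mask`` optionally restricts the
    draw to land (island or continent) cells of a region labelling.  The
    default pseudo-absence count used by the workflow is 1000 per species,
    a conventional presence-background calibration size.
    """
    eligible = stack.valid_mask.copy()
    if mask is not None:
        eligible &= mask.is_land
    if exclude is not None:
        for r, c in exclude.cells:
            eligible[r, c] = False
    rows, cols = np.nonzero(eligible)
    if n > rows.size:
        raise GridError(f"requested {n} background cells but only {rows.size} eligible")
    rng = np.random.default_rng(seed)
    idx = rng.choice(rows.size, size=n, replace=False)
    return [(int(rows[i]), int(cols[i])) for i in idx]
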