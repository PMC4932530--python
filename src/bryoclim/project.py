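"""Projection of the consensus model, analog-climate (MESS) screening, and
binarization.

The consensus suitability is predicted over every valid cell of a climate
stack (present or scenario).  Extrapolation into non-analog climates is
flagged with a multivariate environmental similarity surface (MESS):
negative values mark cells where at least one variable leaves the range of
the reference sample.  The continuous index is binarized at a
sensitivity-based threshold (the quantile of calibration-presence scores
leaving at most a 5% omission by default) and non-analog cells are masked
out of the binary range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geo import ClimateStack
from .models import EnsembleModel

logger = logging.getLogger(__name__)

#: sentinel used for the -inf similarity of a degenerate (max = min) variable
MESS_SENTINEL = -1.0e6


@dataclass
class SuitabilitySurface:
    grid: np.ndarray  # [0,1] on valid cells, NaN elsewhere
    species: str = ""
    scenario: str = "present"

    def scores_at(self, cells) -> np.ndarray:
        rows = np.array([c[0] for c in cells], dtype=int)
        cols = np.array([c[1] for c in cells], dtype=int)
        return self.grid[rows, cols]


@dataclass
class MESSSurface:
    grid: np.ndarray  # <= 100, unbounded below; NaN on invalid cells
    n_reference: int = 0

    @property
    def analog(self) -> np.ndarray:
        """Boolean grid of analog-climate cells (MESS > 0)."""
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.grid, nan=-np.inf) > 0


@dataclass
class BinaryRange:
    grid: np.ndarray  # boolean
    threshold: float
    omission: float | None = None  # achieved on calibration presences

    @property
    def n_cells(self) -> int:
        return int(self.grid.sum())


def predict_surface(
    ensemble: EnsembleModel, stack: ClimateStack, species: str = "", scenario: str = "present"
) -> SuitabilitySurface:
    """Evaluate the weighted consensus on every valid cell of the stack."""
    for var in ensemble.variables:
        if var not in stack.variables:
            raise KeyError(f"stack lacks training variable '{var}'")
    rows, cols = np.nonzero(stack.valid_mask)
    env = np.column_stack([stack.variables[v][rows, cols] for v in ensemble.variables])
    grid = np.full(stack.shape, np.nan)
    grid[rows, cols] = ensemble.predict(env)
    return SuitabilitySurface(grid=grid, species=species, scenario=scenario)


def mess_scores(reference: np.ndarray, values: np.ndarray) -> np.ndarray:
    """MESS similarity of query values to a 1-D reference sample.

    With ``f`` the percentage of reference values strictly below the query:
    f = 0   -> 100 (v - min) / (max - min)
    0<f<=50 -> 2 f
    50<f<100-> 2 (100 - f)
    f = 100 -> 100 (max - v) / (max - min)
    A degenerate reference (max = min) scores 100 at that value and a large
    negative sentinel elsewhere.
    """
    ref = np.sort(np.asarray(reference, dtype=float))
    v = np.asarray(values, dtype=float)
    lo, hi = ref[0], ref[-1]
    if lo == hi:
        logger.warning("MESS: degenerate reference (min == max == %g)", lo)
        return np.where(v == lo, 100.0, MESS_SENTINEL)
    f = 100.0 * np.searchsorted(ref, v, side="left") / ref.size
    s = np.where(f <= 50, 2 * f, 2 * (100 - f))
    s = np.where(f == 0, 100.0 * (v - lo) / (hi - lo), s)
    s = np.where(f == 100, 100.0 * (hi - v) / (hi - lo), s)
    return s


def compute_mess(
    reference_env: np.ndarray, variables: list[str], stack: ClimateStack
) -> MESSSurface:
    """Cellwise minimum over variables of the MESS similarity score.

    ``reference_env`` holds the reference climate sample (rows) for the
    listed variables (columns) -- by default the species' calibration
    cells.  Positive MESS at a cell means every variable lies within the
    reference min-max there.
    """
    ref = np.asarray(reference_env, dtype=float)
    if ref.ndim != 2 or ref.shape[0] < 2:
        raise ValueError("reference needs at least 2 points")
    if ref.shape[1] != len(variables):
        raise ValueError("reference columns must match the variable list")
    rows, cols = np.nonzero(stack.valid_mask)
    out = np.full(stack.shape, np.nan)
    acc = np.full(rows.size, np.inf)
    for j, var in enumerate(variables):
        s = mess_scores(ref[:, j], stack.variables[var][rows, cols])
        acc = np.minimum(acc, s)
    out[rows, cols] = acc
    return MESSSurface(grid=out, n_reference=ref.shape[0])


def select_threshold(surface_at_presences, error_rate: float = 0.05) -> float:
    """Sensitivity-based binarization threshold.

    Returns the largest calibration-presence score with at most an
    ``error_rate`` fraction of presences strictly below it (the lower
    empirical quantile), so at least ``1 - error_rate`` of presences are
    predicted present.
    """
    scores = np.sort(np.asarray(surface_at_presences, dtype=float))
    if scores.size == 0:
        raise ValueError("need at least one presence score")
    allowed = int(np.floor(error_rate * scores.size))
    thr = scores[0]
    for s in np.unique(scores):
        if np.sum(scores < s) <= allowed:
            thr = s
    return float(thr)


def binarize_and_mask(
    surface: SuitabilitySurface,
    threshold: float,
    mess: MESSSurface | None = None,
    calibration_scores=None,
) -> BinaryRange:
    """Threshold the suitability surface and mask non-analog climates.

    A cell is in the range iff it is valid, its suitability >= threshold,
    and (when a MESS surface is given) its MESS is positive.
    """
    with np.errstate(invalid="ignore"):
        suitable = np.nan_to_num(surface.grid, nan=-np.inf) >= threshold
    if mess is not None:
        if mess.grid.shape != surface.grid.shape:
            raise ValueError("MESS and suitability grids are not aligned")
        suitable &= mess.analog
    omission = None
    if calibration_scores is not None:
        cs = np.asarray(calibration_scores, dtype=float)
        omission = float(np.mean(cs < threshold))
    return BinaryRange(grid=suitable, threshold=float(threshold), omission=omission)
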