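"""Range-change statistics: percent area remaining, threat-status classes,
elevational shifts with paired t-tests, archipelago comparisons by
Kruskal-Wallis with Nemenyi post-hoc, and protected-area coverage.

Counts are of suitable grid cells (~1-km^2 pixels) inside the region of
interest; percentages are future/present * 100, displayed half-up to one
decimal.  Status classes follow the IUCN-style A-criterion mapping used
for oceanic-island endemics: a >= 30% range reduction is Vulnerable and a
>= 50% reduction Endangered, with extra classes for near-total (< 5%,
< 1% remaining) and complete loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import box as shapely_box
from shapely.strtree import STRtree
from shapely.ops import unary_union

from .geo import GridTransform, RegionMask
from .project import BinaryRange

logger = logging.getLogger(__name__)


def round1(x: float) -> float:
    """Round half-up to one decimal (display convention for percentages)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def pct_remaining(n_present: int, n_future: int) -> float | None:
    """Future suitable area as a percent of present, half-up to 1 decimal.

    Values above 100 indicate expansion.  Undefined (None) when nothing is
    suitable at present.
    """
    if n_present < 0 or n_future < 0:
        raise ValueError("cell counts must be non-negative")
    if n_present == 0:
        return None
    return round1(100.0 * n_future / n_present)


class Status(Enum):
    EXPANDING = "expanding"
    BELOW_VU = "below_VU"
    VULNERABLE = "vulnerable"
    ENDANGERED = "endangered"
    SUB5 = "sub5"
    NEAR_EXTINCT = "near_extinct"
    EXTINCT = "extinct"


def classify_status(pct: float) -> Status:
    """Map percent-remaining to a threat class.

    0 -> extinct; (0,1) -> near_extinct; [1,5) -> sub5; [5,50] ->
    endangered (>= 50% reduction); (50,70] -> vulnerable (>= 30%
    reduction); (70,100] -> below_VU; > 100 -> expanding.  Boundary values
    go to the more severe class.
    """
    if pct < 0:
        raise ValueError(f"percent remaining cannot be negative: {pct}")
    if pct == 0:
        return Status.EXTINCT
    if pct < 1:
        return Status.NEAR_EXTINCT
    if pct < 5:
        return Status.SUB5
    if pct <= 50:
        return Status.ENDANGERED
    if pct <= 70:
        return Status.VULNERABLE
    if pct <= 100:
        return Status.BELOW_VU
    return Status.EXPANDING


# ---------------------------------------------------------------------------
# elevational shift


@dataclass
class ElevationShift:
    island_ids: list[int]
    mean_present: np.ndarray  # per usable island
    mean_future: np.ndarray
    t_stat: float | None
    p_value: float | None
    n_dropped: int = 0  # islands lost from the pairing

    @property
    def overall_present(self) -> float | None:
        return float(self.mean_present.mean()) if self.mean_present.size else None

    @property
    def overall_future(self) -> float | None:
        return float(self.mean_future.mean()) if self.mean_future.size else None


def elevation_shift(
    present: BinaryRange,
    future: BinaryRange,
    elevation: np.ndarray,
    mask: RegionMask,
) -> ElevationShift:
    """Per-island mean suitable elevation in each period, with a paired t.

    Islands where either period has no suitable cell are dropped from the
    pairing (disappearance from an island removes the pair and with it
    statistical power).  With fewer than 2 usable pairs the test is
    reported as not computable (t and p are None).
    """
    ids, mp, mf = [], [], []
    n_dropped = 0
    for isl in mask.island_ids:
        on_isl = mask.island_id == isl
        pres_cells = present.grid & on_isl
        fut_cells = future.grid & on_isl
        if not pres_cells.any() or not fut_cells.any():
            n_dropped += 1
            continue
        ids.append(isl)
        mp.append(float(elevation[pres_cells].mean()))
        mf.append(float(elevation[fut_cells].mean()))
    mp = np.array(mp)
    mf = np.array(mf)
    if len(ids) < 2:
        return ElevationShift(ids, mp, mf, None, None, n_dropped)
    diffs = mf - mp
    if np.allclose(diffs, 0):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_rel(mf, mp)
    return ElevationShift(ids, mp, mf, float(t_stat), float(p), n_dropped)


# ---------------------------------------------------------------------------
# archipelago comparison


@dataclass
class ArchipelagoComparison:
    h_stat: float
    p_value: float
    nemenyi: pd.DataFrame  # pairwise p-values, symmetric

    def pairwise_p(self, a, b) -> float:
        return float(self.nemenyi.loc[a, b])


def _nemenyi_chi2(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Nemenyi-style pairwise comparisons on pooled rank sums.

    Chi-square approximation: for groups i, j with mean pooled ranks
    Rbar_i, Rbar_j, the statistic (Rbar_i - Rbar_j)^2 / (C N(N+1)/12 *
    (1/n_i + 1/n_j)) is referred to chi-square with k - 1 degrees of
    freedom, where C is the tie-correction factor 1 - sum(t^3 - t)/(N^3-N).
    """
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(values)
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    c = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n_tot**3 - n_tot) if n_tot > 1 else 1.0
    k = len(names)
    mean_ranks, sizes = [], []
    start = 0
    for v in values:
        mean_ranks.append(ranks[start : start + v.size].mean())
        sizes.append(v.size)
        start += v.size
    p_mat = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for i in range(k):
        for j in range(i + 1, k):
            if c == 0:  # all pooled values identical
                p = 1.0
            else:
                num = (mean_ranks[i] - mean_ranks[j]) ** 2
                den = c * n_tot * (n_tot + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j])
                p = float(stats.chi2.sf(num / den, df=k - 1))
            p_mat.iloc[i, j] = p_mat.iloc[j, i] = p
    return p_mat


def compare_archipelagos(loss_pcts: Mapping[str, Sequence[float]]) -> ArchipelagoComparison:
    """Kruskal-Wallis over per-species loss percentages, Nemenyi post-hoc.

    ``loss_pcts`` maps archipelago -> the per-species percent of suitable
    area remaining (or lost) there.  The H statistic is tie-corrected; the
    post-hoc uses the chi-square rank-sum approximation.
    """
    if len(loss_pcts) < 2:
        raise ValueError("need at least 2 archipelagos to compare")
    for g, v in loss_pcts.items():
        if len(v) == 0:
            raise ValueError(f"archipelago '{g}' has no values")
        if len(v) < 2:
            raise ValueError(f"archipelago '{g}' needs at least 2 values")
    values = [np.asarray(v, dtype=float) for v in loss_pcts.values()]
    pooled = np.concatenate(values)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*values)
    return ArchipelagoComparison(float(h), float(p), _nemenyi_chi2(loss_pcts))


# ---------------------------------------------------------------------------
# protected areas


def protected_cell_mask(
    polygons,
    transform: GridTransform,
    shape: tuple[int, int],
    overlap: float = 0.05,
    candidate_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean grid of cells whose area is covered >= ``overlap`` by reserves.

    The conservative pixel-inclusion rule: a pixel counts as protected if
    at least 5% (by default) of its area intersects the reserve union.
    ``candidate_mask`` restricts the (potentially costly) polygon
    intersection to cells of interest.
    """
    out = np.zeros(shape, dtype=bool)
    polys = [p for p in polygons if not p.is_empty]
    if not polys:
        return out
    union = unary_union(polys)
    tree = STRtree(polys)
    cell_area = transform.cell_size**2
    if candidate_mask is None:
        candidate_mask = np.ones(shape, dtype=bool)
    rows, cols = np.nonzero(candidate_mask)
    for r, c in zip(rows.tolist(), cols.tolist()):
        cell = shapely_box(*transform.cell_box(r, c))
        if len(tree.query(cell)) == 0:
            continue
        if union.intersection(cell).area >= overlap * cell_area:
            out[r, c] = True
    return out


def pa_coverage(
    brange: BinaryRange,
    polygons,
    transform: GridTransform,
    overlap: float = 0.05,
) -> float | None:
    """Percent of suitable cells lying in protected areas (>= 5% rule).

    Returns None (not applicable) for an empty range.
    """
    n_suit = brange.n_cells
    if n_suit == 0:
        return None
    prot = protected_cell_mask(
        polygons, transform, brange.grid.shape, overlap=overlap, candidate_mask=brange.grid
    )
    return 100.0 * int((brange.grid & prot).sum()) / n_suit


# ---------------------------------------------------------------------------
# report tables


@dataclass
class RangeChangeReport:
    species: str
    region: str  # archipelago name/id, 'islands', 'continent', ...
    scenario: str
    n_present: int
    n_future: int
    pct: float | None = None
    status: Status | None = None
    mean_elev_present: float | None = None
    mean_elev_future: float | None = None
    t_stat: float | None = None
    p_value: float | None = None
    pa_coverage_present: float | None = None
    pa_coverage_future: float | None = None

    def __post_init__(self) -> None:
        if self.pct is None:
            self.pct = pct_remaining(self.n_present, self.n_future)
        if self.status is None and self.pct is not None:
            self.status = classify_status(self.pct)


def tabulate(reports: Sequence[RangeChangeReport]) -> tuple[pd.DataFrame, dict]:
    """Render reports as a tidy table plus headline summary counts.

    Summary counts (per scenario, over the 'islands' region rows): number
    extinct, number with under 5% remaining (but not extinct), and the
    number of species with any continental suitability at present.
    """
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    for r in reports:
        rows.append(
            {
                "species": r.species,
                "region": r.region,
                "scenario": r.scenario,
                "n_present": r.n_present,
                "n_future": r.n_future,
                "pct_remaining": r.pct,
                "status": r.status.value if r.status else None,
                "mean_elev_present": r.mean_elev_present,
                "mean_elev_future": r.mean_elev_future,
                "t_stat": r.t_stat,
                "p_value": r.p_value,
                "pa_coverage_present": None
                if r.pa_coverage_present is None
                else round1(r.pa_coverage_present),
                "pa_coverage_future": None
                if r.pa_coverage_future is None
                else round1(r.pa_coverage_future),
            }
        )
    df = pd.DataFrame(rows)
    summary: dict = {}
    isl = df[df.region == "islands"]
    for scen in sorted(isl.scenario.unique()):
        sub = isl[isl.scenario == scen]
        summary[scen] = {
            "n_species": int(len(sub)),
            "n_extinct": int((sub.status == Status.EXTINCT.value).sum()),
            "n_below_5pct": int(sub.status.isin([Status.NEAR_EXTINCT.value, Status.SUB5.value]).sum()),
        }
    cont = df[(df.region == "continent")]
    if len(cont):
        summary["n_with_continental_present"] = int(
            (cont.groupby("species").n_present.first() > 0).sum()
        )
    return df, summary


def summarize_pixel_table(table: pd.DataFrame) -> dict:
    """Headline counts from a species x scenario pixel-count table.

    Expects columns ``n_mac_present, n_cont_present, n_mac_rcp45,
    n_cont_rcp45, n_mac_rcp85, n_cont_rcp85`` (one row per species), e.g.
    the bundled published range-size table or the output of the synthetic
    pipeline.  Returns the counts of species (a) with zero island pixels
    under the high-emission scenario, (b) additionally below 5% of the
    present island area remaining, (c) with any present continental
    suitability, and (d) among those, losing all continental suitability
    under the mitigated scenario.
    """
    pct85 = 100.0 * table.n_mac_rcp85 / table.n_mac_present
    extinct85 = table.n_mac_rcp85 == 0
    below5 = (~extinct85) & (pct85 < 5.0)
    has_cont = table.n_cont_present > 0
    lost_cont45 = has_cont & (table.n_cont_rcp45 == 0)
    return {
        "n_extinct_mac_rcp85": int(extinct85.sum()),
        "n_below_5pct_mac_rcp85": int(below5.sum()),
        "n_with_continental_present": int(has_cont.sum()),
        "n_losing_continental_rcp45": int(lost_cont45.sum()),
        "n_species": int(len(table)),
    }
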