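"""Synthetic landscapes, virtual species, scenarios and protected areas.

Every downstream stage of the pipeline (thinning, screening, model fitting,
projection, change statistics) is exercised on data from this module, so it
generates inputs with the statistical structure the analysis assumes:

* spatially autocorrelated climate surfaces over island-like patches, built
  as smooth elevation bumps plus lapse-rate trends plus kernel-smoothed
  Gaussian noise;
* virtual species whose occurrence probability is a smooth bell-shaped
  function of a few climate variables;
* sparse presence-only samples (tens of records) drawn proportionally to
  true suitability;
* future-scenario climate deltas with magnitudes comparable to published
  2070 projections for Macaronesia (about +2 to +3.2 deg C on the maximum
  temperature of the warmest month and a 17-22% drop in wettest-month
  precipitation, depending on the concentration pathway);
* polygonal protected areas covering a requested fraction of island land.

All generators are pure functions of their spec plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import box as shapely_box
from shapely.ops import unary_union

from .geo import ClimateStack, GridTransform, OccurrenceSet, RegionMask

DEFAULT_CELL_SIZE = 0.0083  # degrees; the ~1-km^2 grid convention


class LandscapeError(RuntimeError):
    """Raised when a landscape spec cannot be realised (e.g. drowned islands)."""


@dataclass(frozen=True)
class VariableDef:
    """One synthetic climate variable.

    ``elevation_lapse`` is the change per metre of elevation (negative for
    temperatures, positive for orographic precipitation); ``noise_sd`` the
    marginal standard deviation of the autocorrelated noise component;
    ``autocorrelation_range`` the Gaussian smoothing scale in cells.
    """

    name: str
    base_mean: float
    elevation_lapse: float = 0.0
    noise_sd: float = 0.0
    autocorrelation_range: float = 1.0

    def __post_init__(self) -> None:
        if self.autocorrelation_range < 1:
            raise ValueError("autocorrelation_range must be >= 1 cell")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def default_variable_defs() -> list[VariableDef]:
    """The five retained bioclim predictors with plausible island magnitudes.

    Sea-level baselines and lapse rates give maximum warmest-month
    temperatures in the mid-20s (deg C) at the coast cooling by ~6.5 deg C/km
    uphill, and precipitation increasing orographically -- the climate
    setting of a subtropical Atlantic archipelago.  The independent noise
    components (local heterogeneity from aspect, rain shadows, cloud
    incidence) are large enough that the five variables are not mutually
    redundant: this is the retained predictor set, so it should typically
    survive its own collinearity screen.
    """
    return [
        VariableDef("BIO5", 26.5, -0.0065, 1.2, 10.0),   # max temp warmest month
        VariableDef("BIO6", 16.0, -0.0065, 1.2, 10.0),   # min temp coldest month
        VariableDef("BIO13", 60.0, 0.05, 12.0, 8.0),     # precip wettest month
        VariableDef("BIO14", 6.0, 0.01, 2.5, 8.0),       # precip driest month
        VariableDef("BIO18", 30.0, 0.04, 8.0, 8.0),      # precip warmest quarter
    ]


@dataclass(frozen=True)
class LandscapeSpec:
    seed: int = 0
    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = DEFAULT_CELL_SIZE
    n_islands: int = 6
    n_archipelagos: int = 3
    variable_defs: tuple[VariableDef, ...] = field(
        default_factory=lambda: tuple(default_variable_defs())
    )
    sea_level: float = 50.0
    n_continent_cols: int = 0
    continent_max_elevation: float = 900.0
    origin_west: float = -20.0
    origin_north: float = 35.0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_islands < 0:
            raise ValueError("n_islands must be non-negative")
        names = [v.name for v in self.variable_defs]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate variable names in {names}")


@dataclass(frozen=True)
class VirtualSpecies:
    """A species whose true suitability is a product of Gaussian responses.

    ``responses`` maps variable name -> (optimum, breadth); breadth is the
    standard deviation of the bell curve.  ``prevalence_target`` is an
    advisory fraction of land expected to be broadly suitable; it is
    validated but does not alter sampling.
    """

    name: str
    responses: Mapping[str, tuple[float, float]]
    prevalence_target: float | None = None

    def __post_init__(self) -> None:
        if not self.responses:
            raise ValueError("species needs at least one response variable")
        for var, (_, breadth) in self.responses.items():
            if breadth <= 0:
                raise ValueError(f"breadth for {var} must be positive")
        if self.prevalence_target is not None and not (0 < self.prevalence_target < 1):
            raise ValueError("prevalence_target must lie in (0, 1)")


@dataclass(frozen=True)
class ScenarioDelta:
    """Cellwise climate transform: new = old * factor + offset per variable.

    ``region_offsets`` optionally adds an archipelago-specific extra offset
    (keyed variable -> archipelago id -> offset), mirroring projections that
    warm some archipelagos more than others.
    """

    label: str
    offsets: Mapping[str, float] = field(default_factory=dict)
    factors: Mapping[str, float] = field(default_factory=dict)
    region_offsets: Mapping[str, Mapping[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for var, f in self.factors.items():
            if f <= 0:
                raise ValueError(f"multiplicative factor for {var} must be > 0, got {f}")

    @property
    def variables(self) -> set[str]:
        return set(self.offsets) | set(self.factors) | set(self.region_offsets)


def default_scenarios() -> list[ScenarioDelta]:
    """Mitigated and high-emission 2070 analogues.

    Magnitudes follow the published archipelago-mean shifts: warmest-month
    maximum temperature +2.0 / +3.2 deg C and wettest-month precipitation
    scaled by 0.83 / 0.78 under the mitigated (RCP 4.5-like) and
    high-emission (RCP 8.5-like) pathways respectively; the remaining
    variables shift in the same directions.
    """
    return [
        ScenarioDelta(
            label="rcp45",
            offsets={"BIO5": 2.0, "BIO6": 2.0},
            factors={"BIO13": 0.83, "BIO14": 0.90, "BIO18": 0.85},
        ),
        ScenarioDelta(
            label="rcp85",
            offsets={"BIO5": 3.2, "BIO6": 3.2},
            factors={"BIO13": 0.78, "BIO14": 0.85, "BIO18": 0.80},
        ),
    ]


def default_species() -> list[VirtualSpecies]:
    """Three virtual endemics along the elevational/thermal gradient.

    Narrow thermal niches (breadth ~1 deg C) with humid preferences,
    emulating cloud-belt laurel-forest specialists rather than climatic
    generalists: suitable climates are rare on the landscape, as for real
    narrow endemics.
    """
    return [
        VirtualSpecies("virtula montana", {"BIO5": (18.5, 1.1), "BIO13": (100.0, 16.0)}),
        VirtualSpecies("virtula nebulosa", {"BIO5": (20.0, 1.1), "BIO13": (90.0, 16.0)}),
        VirtualSpecies("virtula sylvatica", {"BIO5": (21.5, 1.2), "BIO18": (65.0, 7.0)}),
    ]


# ---------------------------------------------------------------------------
# landscape generation


def _autocorrelated_noise(
    shape: tuple[int, int], sd: float, corr_range: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian white noise smoothed with an isotropic kernel, rescaled to sd."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=corr_range, mode="reflect")
    s = smooth.std()
    if s == 0:  # degenerate 1-cell grid
        return np.zeros(shape)
    return smooth * (sd / s)


def _place_island_centres(
    spec: LandscapeSpec, sigma: float, rng: np.random.Generator, usable_cols: int
) -> list[tuple[float, float]]:
    min_sep = 5.6 * sigma
    margin = 2.6 * sigma
    n = spec.n_islands

    # sequential rejection sampling, restarted from scratch if it deadlocks
    for _ in range(100):
        centres: list[tuple[float, float]] = []
        for _ in range(500):
            if len(centres) == n:
                return centres
            r = rng.uniform(margin, spec.n_rows - margin)
            c = rng.uniform(margin, usable_cols - margin)
            if all(np.hypot(r - r0, c - c0) >= min_sep for r0, c0 in centres):
                centres.append((r, c))
        if len(centres) == n:
            return centres

    # guaranteed fallback: pick jittered nodes of a lattice spaced >= min_sep
    def axis(extent: float) -> np.ndarray:
        span = extent - 2 * margin
        k = int(span // min_sep) + 1
        return margin + (np.arange(k) * (span / max(k - 1, 1)) if k > 1 else np.array([span / 2]))

    rows_ax, cols_ax = axis(spec.n_rows), axis(usable_cols)
    nodes = [(r, c) for r in rows_ax for c in cols_ax]
    if len(nodes) >= n:
        idx = rng.choice(len(nodes), size=n, replace=False)
        spacing_r = rows_ax[1] - rows_ax[0] if len(rows_ax) > 1 else min_sep
        spacing_c = cols_ax[1] - cols_ax[0] if len(cols_ax) > 1 else min_sep
        jitter = max(0.0, (min(spacing_r, spacing_c) - min_sep) / 2)
        return [
            (nodes[i][0] + rng.uniform(-jitter, jitter), nodes[i][1] + rng.uniform(-jitter, jitter))
            for i in idx
        ]
    raise LandscapeError(
        f"could not place {n} islands with separation {min_sep:.1f} cells on a "
        f"{spec.n_rows}x{usable_cols} grid; enlarge the grid or reduce n_islands"
    )


def generate_landscape(spec: LandscapeSpec) -> tuple[ClimateStack, RegionMask]:
    """Build a seeded island landscape and its region labelling.

    Elevation is the maximum over Gaussian bumps at well-separated random
    centres; cells above ``sea_level`` are island land, grouped into exactly
    ``n_islands`` connected patches (a mismatch raises
    :class:`LandscapeError` with a diagnostic).  Optionally a continental
    strip occupies the eastern ``n_continent_cols`` columns.  Each climate
    variable is ``base_mean + lapse * elevation + autocorrelated noise``.
    Only land cells are valid for modelling; the sea is missing data.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.n_rows, spec.n_cols)
    elevation = np.zeros(shape)
    island_id = np.zeros(shape, dtype=int)
    continent = np.zeros(shape, dtype=bool)

    usable_cols = spec.n_cols - spec.n_continent_cols
    rows_idx, cols_idx = np.indices(shape)

    if spec.n_islands > 0:
        sigma = 0.055 * min(spec.n_rows, usable_cols)
        centres = _place_island_centres(spec, sigma, rng, usable_cols)
        for r0, c0 in centres:
            height = rng.uniform(500.0, 1500.0)  # volcanic-island peak heights (m)
            bump_sigma = sigma * rng.uniform(0.8, 1.0)
            d2 = (rows_idx - r0) ** 2 + (cols_idx - c0) ** 2
            elevation = np.maximum(elevation, height * np.exp(-d2 / (2 * bump_sigma**2)))

    if spec.n_continent_cols > 0:
        # coastal strip rising inland, so the continent spans the climate
        # gradient the island species occupy
        strip = cols_idx >= usable_cols
        frac = (cols_idx - usable_cols + 1) / spec.n_continent_cols
        cont_elev = spec.sea_level + frac * (spec.continent_max_elevation - spec.sea_level)
        elevation = np.where(strip, np.maximum(elevation, cont_elev), elevation)
        continent = strip & (elevation > spec.sea_level)

    is_island = (elevation > spec.sea_level) & ~continent
    labels, n_found = ndimage.label(is_island, structure=np.ones((3, 3), dtype=int))
    if n_found != spec.n_islands:
        raise LandscapeError(
            f"requested {spec.n_islands} islands but thresholding at sea_level="
            f"{spec.sea_level} produced {n_found} connected patches; "
            f"lower sea_level or enlarge the grid"
        )
    island_id = labels

    archipelago_id = np.zeros(shape, dtype=int)
    if spec.n_islands > 0:
        k = min(spec.n_archipelagos, spec.n_islands)
        centroids = np.array(ndimage.center_of_mass(is_island, labels, range(1, n_found + 1)))
        group = _cluster_islands(centroids, k)
        for isl, g in enumerate(group, start=1):
            archipelago_id[island_id == isl] = g

    variables: dict[str, np.ndarray] = {}
    for vdef in spec.variable_defs:
        grid = vdef.base_mean + vdef.elevation_lapse * elevation
        if vdef.noise_sd > 0:
            grid = grid + _autocorrelated_noise(
                shape, vdef.noise_sd, vdef.autocorrelation_range, rng
            )
        variables[vdef.name] = grid

    transform = GridTransform(spec.origin_west, spec.origin_north, spec.cell_size)
    land = is_island | continent
    stack = ClimateStack(
        variables=variables, elevation=elevation, transform=transform, valid_mask=land
    )
    mask = RegionMask(island_id=island_id, archipelago_id=archipelago_id, continent=continent)
    return stack, mask


def _cluster_islands(centroids: np.ndarray, k: int) -> list[int]:
    """Spatially cluster island centroids into k archipelago groups.

    Agglomerative single-linkage on centroid distance; deterministic, and
    groups are renumbered west to east.
    """
    from scipy.cluster.hierarchy import fcluster, linkage

    n = len(centroids)
    if n == 0:
        return []
    if k >= n:
        raw = np.arange(1, n + 1)
    else:
        z = linkage(centroids, method="single")
        raw = fcluster(z, t=k, criterion="maxclust")
    # renumber by mean column (west -> east) for reproducible labels
    order = sorted(set(raw), key=lambda g: centroids[raw == g, 1].mean())
    remap = {g: i + 1 for i, g in enumerate(order)}
    return [remap[g] for g in raw]


# ---------------------------------------------------------------------------
# scenarios


def apply_scenario(
    stack: ClimateStack, delta: ScenarioDelta, mask: RegionMask | None = None
) -> ClimateStack:
    """Apply a climate delta cellwise; untouched variables pass through.

    Masks and geotransform are preserved.  Unknown variable names raise
    ``KeyError`` naming the variable; per-region offsets require ``mask``.
    """
    for var in delta.variables:
        if var not in stack.variables:
            raise KeyError(f"scenario '{delta.label}' references unknown variable '{var}'")
    if delta.region_offsets and mask is None:
        raise ValueError(f"scenario '{delta.label}' has per-region offsets but no RegionMask")
    out = stack.copy()
    for var in delta.variables:
        grid = out.variables[var]
        grid = grid * delta.factors.get(var, 1.0) + delta.offsets.get(var, 0.0)
        for arch_id, extra in delta.region_offsets.get(var, {}).items():
            grid = np.where(mask.archipelago_id == arch_id, grid + extra, grid)
        out.variables[var] = grid
    return out


# ---------------------------------------------------------------------------
# virtual species


def true_suitability(species: VirtualSpecies, stack: ClimateStack) -> np.ndarray:
    """True suitability surface: product of Gaussian responses, max 1 on land.

    Returns NaN on invalid (sea) cells.  Raises ``KeyError`` if a response
    variable is absent from the stack.
    """
    for var in species.responses:
        if var not in stack.variables:
            raise KeyError(f"species '{species.name}' responds to unknown variable '{var}'")
    suit = np.ones(stack.shape)
    for var, (opt, breadth) in species.responses.items():
        v = stack.variables[var]
        suit = suit * np.exp(-((v - opt) ** 2) / (2 * breadth**2))
    suit = np.where(stack.valid_mask, suit, np.nan)
    peak = np.nanmax(suit)
    if not np.isfinite(peak) or peak == 0:
        raise LandscapeError(f"species '{species.name}' has zero suitability everywhere on land")
    return suit / peak


def sample_occurrences(
    species: VirtualSpecies,
    stack: ClimateStack,
    n: int,
    seed: int,
    effort: Mapping[int, float] | None = None,
    mask: RegionMask | None = None,
) -> OccurrenceSet:
    """Draw n presence cells without replacement, proportional to suitability.

    ``effort`` optionally multiplies sampling weight per archipelago id
    (requires ``mask``); default effort is uniform.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    suit = true_suitability(species, stack)
    weights = np.where(np.isfinite(suit), suit, 0.0)
    if effort:
        if mask is None:
            raise ValueError("per-region effort requires a RegionMask")
        mult = np.ones(stack.shape)
        for arch_id, m in effort.items():
            mult[mask.archipelago_id == arch_id] = m
        weights = weights * mult
    rows, cols = np.nonzero(weights > 0)
    if n > rows.size:
        raise LandscapeError(
            f"cannot draw {n} occurrences: only {rows.size} cells have positive suitability"
        )
    p = weights[rows, cols]
    rng = np.random.default_rng(seed)
    idx = rng.choice(rows.size, size=n, replace=False, p=p / p.sum())
    cells = {(int(rows[i]), int(cols[i])) for i in idx}
    return OccurrenceSet(species=species.name, cells=cells, n_raw=n)


# ---------------------------------------------------------------------------
# protected areas


def island_union(mask: RegionMask, transform: GridTransform):
    """Union polygon of all island cell boxes."""
    boxes = [
        shapely_box(*transform.cell_box(r, c)) for r, c in zip(*np.nonzero(mask.is_island))
    ]
    if not boxes:
        raise LandscapeError("no island cells; cannot build protected areas")
    return unary_union(boxes)


def generate_protected_areas(
    mask: RegionMask,
    transform: GridTransform,
    fraction: float,
    seed: int,
    max_polygons: int = 2000,
):
    """Random square reserves covering ~``fraction`` of island land area.

    Squares of 2-6 cells on a side are centred on random island cells until
    the union covers the requested fraction (measured exactly by polygon
    intersection with the island outline).  ``fraction`` >= 0.95 is treated
    as saturation: each island's bounding rectangle becomes one reserve, so
    every island cell is fully covered.
    """
    if not (0 < fraction < 1):
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    land = island_union(mask, transform)
    cs = transform.cell_size

    if fraction >= 0.95:
        polys = []
        for isl in mask.island_ids:
            rr, cc = np.nonzero(mask.island_id == isl)
            w, s, _, _ = transform.cell_box(rr.max(), cc.min())
            _, _, e, n = transform.cell_box(rr.min(), cc.max())
            polys.append(shapely_box(w, s, e, n))
        return polys

    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(mask.is_island)
    polys = []
    covered = None
    for _ in range(max_polygons):
        i = rng.integers(rows.size)
        lon, lat = transform.cell_center(int(rows[i]), int(cols[i]))
        half = 0.5 * cs * rng.uniform(2.0, 6.0)
        sq = shapely_box(lon - half, lat - half, lon + half, lat + half)
        polys.append(sq)
        covered = sq if covered is None else unary_union([covered, sq])
        if covered.intersection(land).area / land.area >= fraction:
            break
    return polys
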