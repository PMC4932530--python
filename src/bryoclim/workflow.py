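"""End-to-end orchestration: simulate -> prepare -> fit -> project -> report.

A single :class:`RunConfig` (read from YAML) drives the whole pipeline
with a master seed.  Every stage is a pure composition of module
operations; only this module and :mod:`bryoclim.geo` touch files.  All
per-species randomness derives deterministically from the master seed plus
the species name and stage, so re-running a config reproduces every
artifact bit-identically.

Stages write their artifacts into the output directory:

* ``rasters/``      climate + elevation + region grids (ESRI ASCII)
* ``occurrences/``  raw and thinned occurrence CSVs
* ``models/``       evaluation table and model descriptions
* ``surfaces/``     suitability, MESS and binary-range rasters
* ``reports/``      change-analysis tables and summary JSON
* ``manifest.json`` config hash, seed, versions, per-species status
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geo, models, prepare, project, synth
from .change import (
    RangeChangeReport,
    compare_archipelagos,
    elevation_shift,
    pa_coverage,
    tabulate,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, species: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed for '{species}': {cause}")
        self.stage = stage
        self.species = species


def stable_seed(master: int, *tokens) -> int:
    """Deterministic sub-seed (< 2**31) from the master seed and tokens."""
    key = ":".join([str(master), *map(str, tokens)])
    return int.from_bytes(hashlib.sha256(key.encode()).digest()[:4], "big") % (2**31)


@dataclass
class Thresholds:
    r_max: float = 0.8
    min_records: int = 11
    auc_min: float = 0.8
    tss_min: float = 0.7
    error_rate: float = 0.05
    pa_overlap: float = 0.05

    def validate(self) -> None:
        if not (0 < self.r_max <= 1):
            raise ConfigError(f"r_max out of range: {self.r_max}")
        if self.min_records < 1:
            raise ConfigError(f"min_records must be >= 1: {self.min_records}")
        for name in ("auc_min", "error_rate", "pa_overlap"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} out of range: {v}")
        if not (-1 <= self.tss_min <= 1):
            raise ConfigError(f"tss_min out of range: {self.tss_min}")


@dataclass
class RunConfig:
    seed: int = 0
    landscape: synth.LandscapeSpec = field(default_factory=synth.LandscapeSpec)
    species: list[synth.VirtualSpecies] = field(default_factory=synth.default_species)
    scenarios: list[synth.ScenarioDelta] = field(default_factory=synth.default_scenarios)
    n_presences: int = 60
    n_background: int = 1000
    pa_fraction: float = 0.3
    thresholds: Thresholds = field(default_factory=Thresholds)
    reps: int = 10
    split: float = 0.7
    n_trees: int = 100
    screening_sample: int = 10000

    def validate(self) -> None:
        self.thresholds.validate()
        if not (0 < self.split < 1):
            raise ConfigError(f"split must be in (0,1): {self.split}")
        if self.reps < 1:
            raise ConfigError("reps must be >= 1")
        if not (0 < self.pa_fraction < 1):
            raise ConfigError(f"pa_fraction must be in (0,1): {self.pa_fraction}")

    def canonical(self) -> str:
        def enc(o):
            if isinstance(o, (synth.LandscapeSpec, synth.VariableDef, Thresholds)):
                return asdict(o)
            if isinstance(o, (synth.VirtualSpecies, synth.ScenarioDelta)):
                d = asdict(o)
                d["responses" if "responses" in d else "offsets"] = {
                    k: list(v) if isinstance(v, tuple) else v
                    for k, v in d.get("responses", d.get("offsets", {})).items()
                }
                return d
            raise TypeError(type(o))

        return json.dumps(asdict(self), sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config; unknown keys raise :class:`ConfigError`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = {
        "seed", "landscape", "variables", "species", "scenarios", "n_presences",
        "n_background", "pa_fraction", "thresholds", "reps", "split", "n_trees",
        "screening_sample",
    }
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    vdefs = doc.get("variables", "default")
    if vdefs == "default":
        vdefs = synth.default_variable_defs()
    else:
        vdefs = [synth.VariableDef(**v) for v in vdefs]

    land_kw = dict(doc.get("landscape", {}))
    land_kw.setdefault("seed", doc.get("seed", 0))
    landscape = synth.LandscapeSpec(variable_defs=tuple(vdefs), **land_kw)

    sp = doc.get("species", "default")
    if sp == "default":
        species = synth.default_species()
    else:
        species = [
            synth.VirtualSpecies(
                name=s["name"],
                responses={k: tuple(v) for k, v in s["responses"].items()},
                prevalence_target=s.get("prevalence_target"),
            )
            for s in sp
        ]

    sc = doc.get("scenarios", "default")
    if sc == "default":
        scenarios = synth.default_scenarios()
    else:
        scenarios = [
            synth.ScenarioDelta(
                label=s["label"],
                offsets=s.get("offsets", {}),
                factors=s.get("factors", {}),
                region_offsets=s.get("region_offsets", {}),
            )
            for s in sc
        ]

    try:
        cfg = RunConfig(
            seed=int(doc.get("seed", 0)),
            landscape=landscape,
            species=species,
            scenarios=scenarios,
            n_presences=int(doc.get("n_presences", 60)),
            n_background=int(doc.get("n_background", 1000)),
            pa_fraction=float(doc.get("pa_fraction", 0.3)),
            thresholds=Thresholds(**doc.get("thresholds", {})),
            reps=int(doc.get("reps", 10)),
            split=float(doc.get("split", 0.7)),
            n_trees=int(doc.get("n_trees", 100)),
            screening_sample=int(doc.get("screening_sample", 10000)),
        )
        cfg.validate()
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


# ---------------------------------------------------------------------------
# in-memory pipeline


@dataclass
class PipelineState:
    config: RunConfig
    stack: geo.ClimateStack | None = None
    mask: geo.RegionMask | None = None
    pa_polygons: list = field(default_factory=list)
    occurrences: dict = field(default_factory=dict)       # species -> OccurrenceSet
    retained_vars: list[str] = field(default_factory=list)
    screen: prepare.VariableScreenResult | None = None
    backgrounds: dict = field(default_factory=dict)       # species -> cell list
    ensembles: dict = field(default_factory=dict)         # species -> EnsembleModel
    evaluations: dict = field(default_factory=dict)       # species -> list[EvaluationResult]
    excluded: dict = field(default_factory=dict)          # species -> reason
    thresholds_used: dict = field(default_factory=dict)   # species -> float
    surfaces: dict = field(default_factory=dict)          # (species, scenario) -> surface
    ranges: dict = field(default_factory=dict)            # (species, scenario) -> BinaryRange
    mess: dict = field(default_factory=dict)              # (species, scenario) -> MESSSurface
    reports: list = field(default_factory=list)
    archipelago_stats: dict = field(default_factory=dict)


def run_simulate(cfg: RunConfig) -> PipelineState:
    state = PipelineState(config=cfg)
    state.stack, state.mask = synth.generate_landscape(cfg.landscape)
    state.pa_polygons = synth.generate_protected_areas(
        state.mask, state.stack.transform, cfg.pa_fraction, stable_seed(cfg.seed, "pa")
    )
    for sp in cfg.species:
        occ = synth.sample_occurrences(
            sp, state.stack, cfg.n_presences, stable_seed(cfg.seed, "occ", sp.name)
        )
        state.occurrences[sp.name] = occ
    return state


def run_prepare(state: PipelineState) -> PipelineState:
    cfg = state.config
    th = cfg.thresholds
    candidates = list(state.stack.variable_names)
    state.screen = prepare.screen_collinearity(
        state.stack,
        candidates,
        r_max=th.r_max,
        n_sample=cfg.screening_sample,
        seed=stable_seed(cfg.seed, "screen"),
    )
    state.retained_vars = state.screen.retained
    for name, occ in list(state.occurrences.items()):
        thinned = prepare.thin_occurrences(occ, state.stack)
        if not prepare.passes_min_records(thinned, th.min_records):
            state.excluded[name] = (
                f"only {len(thinned)} thinned cells (< {th.min_records})"
            )
            logger.warning("excluding %s: %s", name, state.excluded[name])
            del state.occurrences[name]
            continue
        state.occurrences[name] = thinned
    return state


def _fit_species(state: PipelineState, name: str):
    cfg = state.config
    th = cfg.thresholds
    occ = state.occurrences[name]
    bg_cells = prepare.sample_background(
        state.stack,
        cfg.n_background,
        stable_seed(cfg.seed, "bg", name),
        exclude=occ,
        mask=state.mask,
    )
    state.backgrounds[name] = bg_cells
    var_names = state.retained_vars
    xp = state.stack.env_at(occ.sorted_cells(), var_names)
    xb = state.stack.env_at(bg_cells, var_names)

    fitters = {
        "envelope": lambda p, b: models.fit_envelope(p, var_names),
        "maxent_like": lambda p, b: models.fit_maxent_like(p, b, var_names),
        "random_forest": lambda p, b: models.fit_random_forest(
            p, b, var_names, n_trees=cfg.n_trees, seed=stable_seed(cfg.seed, "rf", name)
        ),
    }
    evaluated = []
    for tech, fitter in fitters.items():
        ev = models.evaluate(
            fitter, xp, xb,
            split=cfg.split, reps=cfg.reps,
            seed=stable_seed(cfg.seed, "eval", name, tech),
            auc_min=th.auc_min, tss_min=th.tss_min, technique=tech,
        )
        final = fitter(xp, xb)  # one fit per technique on the full calibration data
        evaluated.append((final, ev))
    state.evaluations[name] = [e for _, e in evaluated]
    state.ensembles[name] = models.build_consensus(evaluated)


def run_fit(state: PipelineState) -> PipelineState:
    for name in list(state.occurrences):
        try:
            _fit_species(state, name)
        except models.NoPassingModelError as exc:
            state.excluded[name] = str(exc)
            logger.warning("excluding %s: %s", name, exc)
    return state


def run_project(state: PipelineState) -> PipelineState:
    cfg = state.config
    th = cfg.thresholds
    scen_stacks = {
        d.label: synth.apply_scenario(state.stack, d, state.mask) for d in cfg.scenarios
    }
    for name, ens in state.ensembles.items():
        occ = state.occurrences[name]
        ref_env = state.stack.env_at(occ.sorted_cells(), state.retained_vars)
        surf = project.predict_surface(ens, state.stack, species=name)
        pres_scores = surf.scores_at(occ.sorted_cells())
        thr = project.select_threshold(pres_scores, th.error_rate)
        state.thresholds_used[name] = thr
        mess_now = project.compute_mess(ref_env, state.retained_vars, state.stack)
        state.surfaces[(name, "present")] = surf
        state.mess[(name, "present")] = mess_now
        state.ranges[(name, "present")] = project.binarize_and_mask(
            surf, thr, mess_now, calibration_scores=pres_scores
        )
        for label, sstack in scen_stacks.items():
            fsurf = project.predict_surface(ens, sstack, species=name, scenario=label)
            fmess = project.compute_mess(ref_env, state.retained_vars, sstack)
            state.surfaces[(name, label)] = fsurf
            state.mess[(name, label)] = fmess
            # the present-calibration threshold is reused for the future
            state.ranges[(name, label)] = project.binarize_and_mask(fsurf, thr, fmess)
    return state


def run_report(state: PipelineState) -> PipelineState:
    cfg = state.config
    th = cfg.thresholds
    mask = state.mask
    arch_losses: dict[str, dict[str, list[float]]] = {
        d.label: {f"arch{a}": [] for a in mask.archipelago_ids} for d in cfg.scenarios
    }
    for name in state.ensembles:
        present = state.ranges[(name, "present")]
        pres_isl = present.grid & mask.is_island
        n_pres_isl = int(pres_isl.sum())
        n_pres_cont = int((present.grid & mask.continent).sum())
        cov_p = pa_coverage(
            project.BinaryRange(grid=pres_isl, threshold=present.threshold),
            state.pa_polygons, state.stack.transform, overlap=th.pa_overlap,
        )
        for delta in cfg.scenarios:
            fut = state.ranges[(name, delta.label)]
            fut_isl = fut.grid & mask.is_island
            shift = elevation_shift(
                project.BinaryRange(grid=pres_isl, threshold=present.threshold),
                project.BinaryRange(grid=fut_isl, threshold=fut.threshold),
                state.stack.elevation, mask,
            )
            cov_f = pa_coverage(
                project.BinaryRange(grid=fut_isl, threshold=fut.threshold),
                state.pa_polygons, state.stack.transform, overlap=th.pa_overlap,
            )
            state.reports.append(
                RangeChangeReport(
                    species=name, region="islands", scenario=delta.label,
                    n_present=n_pres_isl, n_future=int(fut_isl.sum()),
                    mean_elev_present=shift.overall_present,
                    mean_elev_future=shift.overall_future,
                    t_stat=shift.t_stat, p_value=shift.p_value,
                    pa_coverage_present=cov_p, pa_coverage_future=cov_f,
                )
            )
            state.reports.append(
                RangeChangeReport(
                    species=name, region="continent", scenario=delta.label,
                    n_present=n_pres_cont,
                    n_future=int((fut.grid & mask.continent).sum()),
                )
            )
            for a in mask.archipelago_ids:
                in_arch = mask.archipelago_id == a
                n_p = int((present.grid & in_arch).sum())
                n_f = int((fut.grid & in_arch).sum())
                rep = RangeChangeReport(
                    species=name, region=f"arch{a}", scenario=delta.label,
                    n_present=n_p, n_future=n_f,
                )
                state.reports.append(rep)
                if rep.pct is not None:
                    arch_losses[delta.label][f"arch{a}"].append(rep.pct)
    for label, groups in arch_losses.items():
        usable = {g: v for g, v in groups.items() if len(v) >= 2}
        if len(usable) >= 2:
            cmp_res = compare_archipelagos(usable)
            state.archipelago_stats[label] = {
                "H": cmp_res.h_stat,
                "p": cmp_res.p_value,
                "nemenyi": cmp_res.nemenyi.to_dict(),
            }
        else:
            state.archipelago_stats[label] = None
    return state


# ---------------------------------------------------------------------------
# artifact writing


def _write_artifacts(state: PipelineState, outdir: Path, upto: str) -> None:
    cfg = state.config
    t = state.stack.transform if state.stack is not None else None
    stages = ["simulate", "prepare", "fit", "project", "report"]
    upto_i = stages.index(upto)

    if upto_i >= 0:
        rast = outdir / "rasters"
        rast.mkdir(parents=True, exist_ok=True)
        for name, grid in state.stack.variables.items():
            geo.write_grid(np.where(state.stack.valid_mask, grid, np.nan), t, rast / f"{name}.asc")
        geo.write_grid(np.where(state.stack.valid_mask, state.stack.elevation, np.nan),
                       t, rast / "elevation.asc")
        for name, grid in (
            ("island_id", state.mask.island_id),
            ("archipelago_id", state.mask.archipelago_id),
            ("continent", state.mask.continent.astype(float)),
        ):
            geo.write_grid(grid.astype(float), t, rast / f"{name}.asc")
        geo.write_polygons_geojson(state.pa_polygons, outdir / "protected_areas.geojson")
        occdir = outdir / "occurrences"
        occdir.mkdir(exist_ok=True)
        for name, occ in state.occurrences.items():
            geo.occurrence_lonlat(occ, t).to_csv(
                occdir / f"{name.replace(' ', '_')}.csv", index=False
            )

    if upto_i >= 1 and state.screen is not None:
        pd.DataFrame(
            state.screen.dropped, columns=["dropped", "kept", "correlation"]
        ).to_csv(outdir / "screening.csv", index=False)
        (outdir / "retained_variables.txt").write_text("\n".join(state.retained_vars) + "\n")

    if upto_i >= 2:
        mdir = outdir / "models"
        mdir.mkdir(exist_ok=True)
        rows = []
        for name, evs in state.evaluations.items():
            for ev in evs:
                rows.append(
                    {
                        "species": name, "technique": ev.technique,
                        "mean_auc": ev.mean_auc, "mean_tss": ev.mean_tss,
                        "passed": ev.passed,
                        **{f"auc_{i}": a for i, a in enumerate(ev.aucs)},
                        **{f"tss_{i}": s for i, s in enumerate(ev.tsses)},
                    }
                )
        pd.DataFrame(rows).to_csv(mdir / "evaluation.csv", index=False)
        for name, ens in state.ensembles.items():
            desc = {
                "species": name,
                "variables": ens.variables,
                "weights": {m.technique: float(w) for m, w in zip(ens.members, ens.weights)},
                "members": [_describe_model(m) for m in ens.members],
            }
            (mdir / f"{name.replace(' ', '_')}.json").write_text(
                json.dumps(desc, indent=1, sort_keys=True)
            )

    if upto_i >= 3:
        sdir = outdir / "surfaces"
        sdir.mkdir(exist_ok=True)
        for (name, scen), surf in state.surfaces.items():
            stem = f"{name.replace(' ', '_')}_{scen}"
            geo.write_grid(surf.grid, t, sdir / f"{stem}_suitability.asc")
            geo.write_grid(state.mess[(name, scen)].grid, t, sdir / f"{stem}_mess.asc")
            geo.write_grid(
                state.ranges[(name, scen)].grid.astype(float), t, sdir / f"{stem}_range.asc"
            )
        pd.DataFrame(
            [
                {"species": n, "threshold": thr,
                 "omission": state.ranges[(n, "present")].omission}
                for n, thr in state.thresholds_used.items()
            ]
        ).to_csv(outdir / "thresholds.csv", index=False)

    if upto_i >= 4 and state.reports:
        rdir = outdir / "reports"
        rdir.mkdir(exist_ok=True)
        df, summary = tabulate(state.reports)
        df.to_csv(rdir / "range_change.csv", index=False)
        (rdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        (rdir / "archipelago_tests.json").write_text(
            json.dumps(state.archipelago_stats, indent=1, sort_keys=True)
        )

    manifest = {
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.seed,
        "stage": upto,
        "excluded": state.excluded,
        "versions": _versions(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _describe_model(m) -> dict:
    if m.technique == "envelope":
        return {
            "technique": "envelope",
            "presence_values": [v.tolist() for v in m.presence_values],
        }
    if m.technique == "maxent_like":
        return {
            "technique": "maxent_like",
            "coef": m.coef.tolist(),
            "intercept": m.intercept,
            "feature_means": m.feature_means.tolist(),
            "feature_sds": m.feature_sds.tolist(),
            "features": m.features,
        }
    return {
        "technique": "random_forest",
        "n_trees": m.forest.n_estimators,
        "random_state": m.forest.random_state,
        "note": "refit deterministically from config; not serialized",
    }


def _versions() -> dict:
    import sklearn
    import scipy

    from . import __version__

    return {
        "bryoclim": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "pandas": pd.__version__,
    }


STAGES = ["simulate", "prepare", "fit", "project", "report"]


def run(config: RunConfig, outdir: str | Path, upto: str = "report") -> PipelineState:
    """Run the pipeline through ``upto`` and write artifacts to ``outdir``.

    Earlier stages are recomputed deterministically (model fits are cheap at
    this scale and fully seeded), so any stage can be invoked standalone
    and produces identical artifacts.
    """
    if upto not in STAGES:
        raise ConfigError(f"unknown stage '{upto}'")
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_fns = [run_simulate, run_prepare, run_fit, run_project, run_report]
    state: PipelineState | None = None
    for stage_name, fn in zip(STAGES, stage_fns):
        try:
            state = fn(config) if state is None else fn(state)
        except (ConfigError,):
            raise
        except Exception as exc:  # noqa: BLE001 - reported with stage context
            raise StageError(stage_name, getattr(exc, "species", "-"), exc) from exc
        if stage_name == upto:
            break
    _write_artifacts(state, outdir, upto)
    return state
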