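"""End-to-end runner: synthesize/ingest -> thin/split -> screen -> tune ->
fit -> evaluate -> GSA -> project -> binarize -> decompose -> report.

Every stage writes its artifacts before the next starts, a single master
seed is fanned out deterministically per stage (and per region), and a YAML
manifest records the config echo, per-stage wall-clock and output checksums,
so a run is reproducible bit-for-bit and any stage can be re-run in
isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    ThresholdSet,
    shadow_importance_screen,
    spearman_screen,
    thresholds,
    tune,
)
from .fast import FASTConfig, fit_distributions, run_gsa
from .grids import (
    CLIMATE_LAYERS,
    EnvironmentalStack,
    GridSpec,
    ScenarioSet,
    read_stack,
    write_ascii_grid,
    write_stack,
)
from .maxent import MaxentConfig, cross_validate, fit, sample_background
from .occurrences import (
    OccurrenceSet,
    extract_predictors,
    split_regions,
    thin_occurrences,
)
from .synthetic import (
    default_true_model,
    make_grid,
    make_scenarios,
    sample_occurrences,
)
from .venn import ScenarioHabitats, area_table, binarize, decompose, export_map

logger = logging.getLogger(__name__)

STAGES = (
    "synthesize", "thin_split", "screen", "tune", "fit",
    "evaluate", "gsa", "project", "binarize", "decompose", "report",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the manifest."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic landscape (defaults are the
    desk-scale run: a 100x200-cell 1-km grid, 300 presences)."""

    nrows: int = 100
    ncols: int = 200
    cell_size: float = 1.0
    autocorr_length: float = 5.0
    elevation_max: float = 10.0
    elevation_noise_sd: float = 1.0
    n_presences: int = 300
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: {"Bio02": 6.0, "Elevation": -6.0})
    true_intercept: float = -14.0


@dataclass
class ScenarioConfig:
    """Future-scenario construction: additive offsets on climate layers
    (a warming, wetter-winter future) and a 1-m sea-level rise."""

    climate_deltas: dict[str, float] = field(default_factory=lambda: {
        "Bio02": 1.0, "Bio03": 2.0, "Bio05": 3.0, "Bio08": 3.0,
        "Bio14": -5.0, "Bio15": 10.0, "Bio19": 30.0,
    })
    rise: float = 1.0


@dataclass
class ScreeningConfig:
    r_thresh: float = 0.8
    p_thresh: float = 0.001
    shadow: bool = True
    shadow_rounds: int = 20
    shadow_alpha: float = 0.01
    shadow_max_rows: int = 1500  # subsample cap for the random-forest rounds


@dataclass
class TuningConfig:
    rm_list: list[float] = field(default_factory=lambda: [1.0, 2.0, 3.0, 4.0])
    fc_list: list[str] = field(default_factory=lambda: ["L", "LQ", "LQH"])
    cv_folds: int = 10


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "coastniche_run"
    stack_manifest: str | None = None     # ingest instead of synthesize
    occurrences_csv: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    thinning_cell: float | None = None    # default: one raster cell
    region_boundary: float | None = None  # y threshold; None = single region
    region_labels: tuple[str, str] = ("north", "south")
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    tuning: TuningConfig = field(default_factory=TuningConfig)
    maxent: MaxentConfig = field(default_factory=MaxentConfig)
    fast_M: int = 4
    fast_omega_max: int = 32
    fast_repeats: int = 5
    convention: str = "as_printed"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (("synthetic", SyntheticConfig), ("scenario", ScenarioConfig),
                         ("screening", ScreeningConfig), ("tuning", TuningConfig),
                         ("maxent", MaxentConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        if "region_labels" in kwargs:
            kwargs["region_labels"] = tuple(kwargs["region_labels"])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["region_labels"] = list(d["region_labels"])
        return d

    def validate(self) -> None:
        if not self.tuning.rm_list:
            raise ValueError("tuning.rm_list must be non-empty")
        if not self.tuning.fc_list:
            raise ValueError("tuning.fc_list must be non-empty")
        if self.convention not in ("as_printed", "symmetric"):
            raise ValueError(f"unknown attribution convention {self.convention!r}")
        if self.scenario.rise < 0:
            raise ValueError("sea-level rise must be >= 0")
        bad = set(self.scenario.climate_deltas) - set(CLIMATE_LAYERS)
        if bad:
            raise ValueError(f"climate deltas on non-climate layers: {sorted(bad)}")


def stage_seed(master: int, stage: str, region: str = "") -> np.random.SeedSequence:
    """Deterministic per-stage (and per-region) seed derivation from the
    master seed: SeedSequence(master, hash of stage name, hash of region)."""
    def h(s: str) -> int:
        return int.from_bytes(hashlib.sha256(s.encode()).digest()[:4], "big")
    return np.random.SeedSequence([int(master), h(stage), h(region)])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RegionResult:
    name: str
    mask: np.ndarray
    presences: pd.DataFrame | None = None
    background: pd.DataFrame | None = None
    retained: list[str] | None = None
    tuning: object = None
    model: object = None
    cv: object = None
    threshold_set: ThresholdSet | None = None
    gsa: object = None
    habitats: ScenarioHabitats | None = None
    decomposition: object = None
    areas: object = None


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict[str, float]           # wall-clock seconds per stage
    checksums: dict[str, str]
    failed_stage: str | None = None

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        with open(tmp, "w") as fh:
            yaml.safe_dump({
                "config": self.config,
                "version": self.version,
                "stages": self.stages,
                "checksums": self.checksums,
                "failed_stage": self.failed_stage,
            }, fh, sort_keys=False)
        tmp.rename(path)


def _region_masks(grid: GridSpec, boundary: float | None,
                  labels: tuple[str, str]) -> dict[str, np.ndarray]:
    if boundary is None:
        return {"all": np.ones(grid.shape, dtype=bool)}
    _, y = grid.cell_center(np.arange(grid.nrows), np.zeros(grid.nrows))
    north_rows = y >= boundary
    masks = {
        labels[0]: np.tile(north_rows[:, None], (1, grid.ncols)),
        labels[1]: np.tile(~north_rows[:, None], (1, grid.ncols)),
    }
    return masks


def _restrict(stack: EnvironmentalStack, region_mask: np.ndarray) -> EnvironmentalStack:
    out = stack.copy()
    out.grid.nodata_mask = out.grid.nodata_mask | ~region_mask
    return out


def run_pipeline(config: RunConfig) -> tuple[RunManifest, dict[str, RegionResult]]:
    """Execute the full workflow; returns the manifest and per-region results.

    Artifacts land under ``config.output_dir``; failures raise
    :class:`StageError` after the manifest (noting the failure point) is
    written, so partial outputs stay inspectable.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.to_dict(), __version__, {}, {})
    written: list[Path] = []
    results: dict[str, RegionResult] = {}
    state: dict = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            manifest.failed_stage = name
            manifest.stages[name] = time.perf_counter() - t0
            for p in written:
                if p.exists():
                    manifest.checksums[str(p.relative_to(outdir))] = _sha256(p)
            manifest.write(outdir / "manifest.yaml")
            raise StageError(name, exc) from exc
        manifest.stages[name] = time.perf_counter() - t0

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    # -- synthesize / ingest ------------------------------------------------
    def synthesize():
        if config.stack_manifest:
            stack = read_stack(config.stack_manifest)
            scen = make_scenarios(stack, config.scenario.climate_deltas,
                                  config.scenario.rise)
            if config.occurrences_csv:
                occ = OccurrenceSet.from_csv(config.occurrences_csv)
            else:
                raise ValueError("occurrences_csv required when ingesting a stack")
        else:
            sc = config.synthetic
            rng = np.random.default_rng(stage_seed(config.seed, "synthesize"))
            spec = GridSpec(sc.nrows, sc.ncols, sc.cell_size)
            stack = make_grid(
                spec, autocorr_length=sc.autocorr_length,
                elevation_max=sc.elevation_max,
                elevation_noise_sd=sc.elevation_noise_sd, seed=rng,
            )
            scen = make_scenarios(stack, config.scenario.climate_deltas,
                                  config.scenario.rise)
            truth = default_true_model(stack, dict(sc.true_coefficients),
                                       sc.true_intercept)
            occ = sample_occurrences(stack, truth, sc.n_presences, seed=rng)
            state["truth"] = truth
        state["scenarios"] = scen
        state["occ"] = occ
        for name, st in scen.items():
            emit(write_stack(outdir / "stacks" / name, st))
            for layer in st.layers.values():
                emit(outdir / "stacks" / name / f"{layer.name}.asc")
        occ.to_csv(emit(outdir / "occurrences.csv"))

    # -- thin / split -------------------------------------------------------
    def thin_split():
        scen: ScenarioSet = state["scenarios"]
        cell = config.thinning_cell or scen.CUR.grid.cell_size
        thinned = thin_occurrences(state["occ"], cell)
        logger.info("thinning: %d -> %d records", len(state["occ"]), len(thinned))
        masks = _region_masks(scen.CUR.grid, config.region_boundary,
                              config.region_labels)
        if config.region_boundary is None:
            thinned.region = np.full(len(thinned), "all", dtype=object)
            per_region = {"all": thinned}
        else:
            north, south = split_regions(thinned, config.region_boundary,
                                         config.region_labels)
            per_region = {config.region_labels[0]: north,
                          config.region_labels[1]: south}
        for name, mask in masks.items():
            results[name] = RegionResult(name=name, mask=mask)
        state["per_region_occ"] = per_region
        thinned_all = pd.concat([o.to_frame() for o in per_region.values()])
        thinned_all.to_csv(emit(outdir / "occurrences_thinned.csv"), index=False)

    # -- screen -------------------------------------------------------------
    def screen():
        scen: ScenarioSet = state["scenarios"]
        categorical = {n for n, l in scen.CUR.layers.items() if l.kind == "categorical"}
        state["categorical"] = categorical
        for name, res in results.items():
            occ = state["per_region_occ"][name]
            if len(occ) < 3:
                raise ValueError(f"region {name!r} has too few presences ({len(occ)})")
            region_stack = _restrict(scen.CUR, res.mask)
            bg_seed = stage_seed(config.seed, "background", name)
            bg_points = sample_background(region_stack, config.maxent.n_background,
                                          np.random.default_rng(bg_seed))
            pres_tab = extract_predictors(occ, region_stack, label=1)
            bg_tab = extract_predictors(bg_points, region_stack, label=0)
            # correlation screen over continuous climate layers on the background
            climate = [c for c in CLIMATE_LAYERS if c in bg_tab.data.columns]
            rep = spearman_screen(bg_tab.data[climate], config.screening.r_thresh,
                                  config.screening.p_thresh)
            retained = [c for c in bg_tab.data.columns
                        if c not in climate or c in rep.retained]
            if config.screening.shadow:
                rng = np.random.default_rng(stage_seed(config.seed, "screen", name))
                tab = pd.concat([pres_tab.data, bg_tab.data], ignore_index=True)
                labels = np.concatenate([pres_tab.labels, bg_tab.labels])
                if len(tab) > config.screening.shadow_max_rows:
                    keep_p = np.flatnonzero(labels == 1)
                    n_bg = config.screening.shadow_max_rows - keep_p.size
                    keep_b = rng.choice(np.flatnonzero(labels == 0),
                                        size=max(n_bg, 100), replace=False)
                    sel = np.concatenate([keep_p, keep_b])
                    tab, labels = tab.iloc[sel], labels[sel]
                confirmed = shadow_importance_screen(
                    tab[retained], labels,
                    seed=int(rng.integers(2**31 - 1)),
                    n_rounds=config.screening.shadow_rounds,
                    alpha=config.screening.shadow_alpha,
                )
                # the relevance screen can only veto climate variables the
                # correlation screen kept; soil and elevation always enter
                retained = [c for c in retained
                            if c not in climate or c in confirmed]
            if not retained:
                raise ValueError(f"screening removed every variable in region {name!r}")
            res.retained = retained
            res.presences = pres_tab.data[retained]
            res.background = bg_tab.data[retained]
            rep.rho.to_csv(emit(outdir / f"screen_spearman_{name}.csv"))
            pd.Series(retained, name="variable").to_csv(
                emit(outdir / f"screen_retained_{name}.csv"), index=False)

    # -- tune ---------------------------------------------------------------
    def tune_stage():
        for name, res in results.items():
            cat = {c for c in state["categorical"] if c in res.retained}
            res.tuning = tune(res.presences, res.background,
                              config.tuning.rm_list, config.tuning.fc_list,
                              config.maxent, cat)
            res.tuning.table.to_csv(emit(outdir / f"tuning_{name}.csv"), index=False)

    # -- fit ----------------------------------------------------------------
    def fit_stage():
        for name, res in results.items():
            res.model = res.tuning.best_model
            res.model.save(emit(outdir / f"model_{name}.json"))

    # -- evaluate -----------------------------------------------------------
    def evaluate():
        for name, res in results.items():
            cat = {c for c in state["categorical"] if c in res.retained}
            cfg = dataclasses.replace(config.maxent, rm=res.tuning.best_rm,
                                      fc=res.tuning.best_fc)
            k = min(config.tuning.cv_folds, len(res.presences))
            rng = np.random.default_rng(stage_seed(config.seed, "evaluate", name))
            res.cv = cross_validate(res.presences, res.background, cfg, k=k,
                                    seed=rng, categorical=cat)
            pres_scores = res.model.predict_cloglog(res.presences)
            bg_scores = res.model.predict_cloglog(res.background)
            res.threshold_set = thresholds(pres_scores, bg_scores)
            res.cv.folds.to_csv(emit(outdir / f"cv_{name}.csv"), index=False)
            with open(emit(outdir / f"thresholds_{name}.yaml"), "w") as fh:
                yaml.safe_dump({
                    "thresholds": res.threshold_set.to_dict(),
                    "cv_mean_auc": res.cv.mean_auc,
                    "cv_mean_tss": res.cv.mean_tss,
                }, fh)

    # -- gsa ----------------------------------------------------------------
    def gsa():
        scen: ScenarioSet = state["scenarios"]
        for name, res in results.items():
            region_stack = _restrict(scen.CUR, res.mask)
            sub = EnvironmentalStack(
                region_stack.grid,
                [region_stack[v].copy() for v in res.retained])
            dists = fit_distributions(sub)
            fcfg = FASTConfig(M=config.fast_M, omega_max=config.fast_omega_max,
                              m=len(dists), n_repeats=config.fast_repeats)
            rng = np.random.default_rng(stage_seed(config.seed, "gsa", name))
            res.gsa = run_gsa(res.model, sub, fcfg, dists=dists, seed=rng)
            res.gsa.to_frame().to_csv(emit(outdir / f"sensitivity_{name}.csv"),
                                      index=False)

    # -- project ------------------------------------------------------------
    def project():
        scen: ScenarioSet = state["scenarios"]
        state["suitability"] = {}
        for name, res in results.items():
            maps = {}
            for sname, st in scen.items():
                rst = _restrict(st, res.mask)
                keep = ~rst.grid.nodata_mask
                table = pd.DataFrame(
                    {v: rst[v].values[keep] for v in res.retained})
                values = np.full(rst.grid.shape, np.nan)
                values[keep] = res.model.predict_cloglog(table)
                maps[sname] = (values, rst.grid)
                emit_path = outdir / "suitability" / f"{name}_{sname}.asc"
                emit_path.parent.mkdir(parents=True, exist_ok=True)
                write_ascii_grid(emit(emit_path), np.nan_to_num(values), rst.grid)
            state["suitability"][name] = maps

    # -- binarize -----------------------------------------------------------
    def binarize_stage():
        for name, res in results.items():
            t = res.threshold_set.weighted
            maps = state["suitability"][name]
            res.habitats = ScenarioHabitats(
                HCUR=binarize(maps["CUR"][0], t, maps["CUR"][1]),
                HCLC=binarize(maps["CLC"][0], t, maps["CLC"][1]),
                HSLR=binarize(maps["SLR"][0], t, maps["SLR"][1]),
                HCCS=binarize(maps["CCS"][0], t, maps["CCS"][1]),
            )

    # -- decompose ----------------------------------------------------------
    def decompose_stage():
        for name, res in results.items():
            res.decomposition = decompose(res.habitats, config.convention)
            res.areas = area_table(res.decomposition)
            export_map(res.decomposition,
                       emit(outdir / f"decomposition_{name}.asc"),
                       emit(outdir / f"decomposition_{name}_legend.csv"))
            res.areas.to_csv(emit(outdir / f"areas_{name}.csv"))

    # -- report -------------------------------------------------------------
    def report():
        write_report(results, outdir)
        emit(outdir / "summary.txt")

    stage_fns = {
        "synthesize": synthesize, "thin_split": thin_split, "screen": screen,
        "tune": tune_stage, "fit": fit_stage, "evaluate": evaluate,
        "gsa": gsa, "project": project, "binarize": binarize_stage,
        "decompose": decompose_stage, "report": report,
    }
    for stage in STAGES:
        run_stage(stage, stage_fns[stage])

    for p in written:
        if p.exists() and p.is_file():
            manifest.checksums[str(p.relative_to(outdir))] = _sha256(p)
    manifest.write(outdir / "manifest.yaml")
    return manifest, results


def write_report(results: dict[str, RegionResult], outdir: str | Path) -> Path:
    """Plain-text summary across regions (the CSV artifacts are written by
    their stages; this collates the headline numbers)."""
    outdir = Path(outdir)
    lines = ["coastniche run summary", "======================", ""]
    for name, res in results.items():
        lines.append(f"Region: {name}")
        if res.tuning is not None:
            lines.append(f"  best model: RM={res.tuning.best_rm:g} "
                         f"FC={res.tuning.best_fc} "
                         f"(AICc={res.tuning.table['aicc'].min():.2f}, "
                         f"k={res.model.n_nonzero})")
        if res.cv is not None:
            lines.append(f"  cross-validation: mean AUC={res.cv.mean_auc:.3f}, "
                         f"mean TSS={res.cv.mean_tss:.3f}")
        if res.threshold_set is not None:
            t = res.threshold_set
            lines.append(f"  thresholds: MTSS={t.mtss:.4f} PTSS={t.ptss:.4f} "
                         f"ETSS={t.etss:.4f} weighted={t.weighted:.4f}")
        if res.gsa is not None:
            order = np.argsort(-res.gsa.s_t)
            top = ", ".join(f"{res.gsa.variables[i]} (S_T={res.gsa.s_t[i]:.3f})"
                            for i in order[:3])
            s = res.gsa.sums
            lines.append(f"  sensitivity: sum S_F={s['S_F']:.4f}, "
                         f"sum S_T={s['S_T']:.4f}; top: {top}")
        if res.areas is not None:
            for _, row in res.areas.table.iterrows():
                lines.append(
                    f"  {row['direction']}: changed {row['H_changed']:.0f} km^2 "
                    f"(pure CLC {row['H_p_clc_pct']:.2f}%, "
                    f"pure SLR {row['H_p_slr_pct']:.2f}%, "
                    f"shared {row['H_s_ics_pct']:.2f}%, "
                    f"coupling {row['H_c_ics_pct']:.2f}%)")
        lines.append("")
    path = outdir / "summary.txt"
    path.write_text("\n".join(lines))
    return path
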