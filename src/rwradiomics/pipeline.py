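"""End-to-end pipeline: simulate -> extract -> aggregate -> model -> report.

Every random stage is seeded from one master seed through a documented
seed-sequence fan-out (simulation, split, cross-validation folds and
bootstrap each get a spawned child), so a rerun with the same config
and seed reproduces every table bit for bit.  Defaults mirror the
study's analysis settings: 75:25 split, 500 log-spaced C values in
[1e-4, 1e3], L1 ratio 0.5, 5 folds, 100 bootstrap resamples, Spearman
threshold 0.8, alpha 0.05.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .catalogue import CATALOGUE_VERSION, FEATURE_CODES, export_catalogue
from .features import extract_features_batch
from .modelling import (
    DEFAULT_GUARD_Z,
    ModelResult,
    OptimalWeek,
    SplitSpec,
    SweepResult,
    select_optimal_week,
    split_cohort,
    summarise_outcomes,
    sweep_timepoints,
)
from .roi import build_wall_ring, subimage_stack, tile_subimages
from .synthetic import CohortData, SyntheticCohortSpec, generate_cohort
from .temporal import (
    WEEK_MAP,
    build_week_table,
    time_points_for_regimen,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; defaults are the study's analysis settings."""

    out_dir: str = "runs/run"
    seed: int = 0
    ng: int = 8
    train_fraction: float = 0.75
    c_min: float = 1e-4
    c_max: float = 1e3
    c_points: int = 500
    l1_ratio: float = 0.5
    folds: int = 5
    n_boot: int = 100
    rho_threshold: float = 0.8
    alpha: float = 0.05
    guard_z: float = DEFAULT_GUARD_Z
    modes: tuple[str, ...] = ("separate", "cumulative")
    time_points: tuple[str, ...] | None = None  # None = all for the regimen
    simulate: dict = field(default_factory=dict)  # SyntheticCohortSpec overrides
    manifest: str | None = None  # read an existing cohort instead of simulating
    write_plots: bool = True
    write_artifacts: bool = True

    def c_grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.c_min), np.log10(self.c_max),
                           self.c_points)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("modes", "time_points"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------


def extract_scan_features(scan, contour_polys, ng: int = 8) -> np.ndarray:
    """Scan-level feature vector: per-slice wall ring -> 8x8 subimages ->
    118 features each -> mean over all subimages and slices."""
    polys = {p.slice_index: p for p in contour_polys}
    stacks = []
    for s in scan.slices:
        poly = polys.get(s.slice_index)
        if poly is None:
            continue
        mask = rio.rasterise_contour(poly, s.pixels.shape)
        if not mask.any():
            logger.warning(
                "%s slice %d: contour covers no pixels", scan.patient_id,
                s.slice_index,
            )
            continue
        wall = build_wall_ring(mask, slice_index=s.slice_index)
        subs = tile_subimages(wall, s)
        if subs:
            stacks.append(subimage_stack(subs))
    if not stacks:
        raise rio.ValidationError(
            f"no subimages for {scan.patient_id} "
            f"{scan.modality}/{scan.fraction_index}"
        )
    feats = extract_features_batch(np.concatenate(stacks, axis=0), ng=ng)
    return feats.mean(axis=0)


def per_subimage_features(scan, contour_polys, ng: int = 8) -> pd.DataFrame:
    """Per-subimage feature vectors for one scan (debug output; the
    pipeline itself only keeps scan-level aggregates)."""
    polys = {p.slice_index: p for p in contour_polys}
    rows = []
    for s in scan.slices:
        poly = polys.get(s.slice_index)
        if poly is None:
            continue
        mask = rio.rasterise_contour(poly, s.pixels.shape)
        if not mask.any():
            continue
        wall = build_wall_ring(mask, slice_index=s.slice_index)
        subs = tile_subimages(wall, s)
        if not subs:
            continue
        feats = extract_features_batch(subimage_stack(subs), ng=ng)
        for sub, vec in zip(subs, feats):
            row = {
                "patient_id": scan.patient_id,
                "modality": scan.modality,
                "fraction_index": scan.fraction_index,
                "slice_index": s.slice_index,
                "anchor_row": sub.anchor[0],
                "anchor_col": sub.anchor[1],
            }
            row.update(dict(zip(FEATURE_CODES, vec)))
            rows.append(row)
    return pd.DataFrame(rows)


def needed_fractions(
    regimen: str, time_points: tuple[str, ...] | None
) -> set[int] | None:
    """MVCT fractions required to build the requested time points
    (None = all)."""
    if time_points is None:
        return None
    need: set[int] = set()
    for tp in time_points:
        if tp.startswith("W"):
            week = int(tp[1:])
            if week in WEEK_MAP[regimen]:
                lo, hi = WEEK_MAP[regimen][week]
                need.update(range(lo, hi + 1))
    return need


def extract_cohort_features(
    cohort: CohortData, ng: int = 8,
    time_points: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """One row per scan with patient_id, modality, fraction_index and the
    118 feature columns.  Only scans feeding the requested time points
    are extracted."""
    rows = []
    for pdata in cohort.patients:
        need = needed_fractions(pdata.record.regimen, time_points)
        for scan in pdata.scans:
            if (
                scan.modality == "mvct"
                and need is not None
                and scan.fraction_index not in need
            ):
                continue
            if time_points is not None and scan.modality == "planning_ct" and (
                "CT" not in time_points
            ):
                continue
            vec = extract_scan_features(
                scan, pdata.contours[(scan.modality, scan.fraction_index)], ng=ng
            )
            row = {
                "patient_id": scan.patient_id,
                "modality": scan.modality,
                "fraction_index": (
                    np.nan if scan.fraction_index is None else scan.fraction_index
                ),
            }
            row.update(dict(zip(FEATURE_CODES, vec)))
            rows.append(row)
    return pd.DataFrame(rows)


def extract_from_manifest(
    manifest: rio.ManifestData, ng: int = 8,
    time_points: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Disk-backed variant of :func:`extract_cohort_features`."""
    rows = []
    regimen_of = {r.patient_id: r.regimen for r in manifest.records}
    for _, reg_row in manifest.registry.iterrows():
        pid = str(reg_row["patient_id"])
        modality = reg_row["modality"]
        fx = reg_row["fraction_index"]
        fx = None if pd.isna(fx) or fx == "" else int(fx)
        need = needed_fractions(regimen_of[pid], time_points)
        if modality == "mvct" and need is not None and fx not in need:
            continue
        if time_points is not None and modality == "planning_ct" and (
            "CT" not in time_points
        ):
            continue
        scan = rio.read_scan(reg_row["image_path"])
        polys = rio.read_contours(reg_row["contour_path"])
        vec = extract_scan_features(scan, polys, ng=ng)
        row = {"patient_id": pid, "modality": modality,
               "fraction_index": np.nan if fx is None else fx}
        row.update(dict(zip(FEATURE_CODES, vec)))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# modelling per regimen
# ---------------------------------------------------------------------------


@dataclass
class RegimenResult:
    regimen: str
    train_ids: list[str]
    test_ids: list[str]
    sweeps: dict[str, SweepResult]
    optimal: dict[str, OptimalWeek]


@dataclass
class PipelineResult:
    config: RunConfig
    cohort_summary: pd.DataFrame
    tables: dict[str, pd.DataFrame]  # per regimen week tables
    regimens: dict[str, RegimenResult]
    run_dir: Path | None


def model_regimen(
    regimen: str,
    table: pd.DataFrame,
    labels: pd.Series,
    records,
    config: RunConfig,
    seed: int,
) -> RegimenResult:
    """Split once, then run the requested sweep modes for one regimen."""
    train_ids, test_ids = split_cohort(
        records, SplitSpec(train_fraction=config.train_fraction, seed=seed)
    )
    tps = (
        list(config.time_points)
        if config.time_points is not None
        else time_points_for_regimen(regimen)
    )
    tps = [tp for tp in tps if any(c.startswith(tp + ":") for c in table.columns)]
    sweeps: dict[str, SweepResult] = {}
    optimal: dict[str, OptimalWeek] = {}
    common = dict(
        table=table, labels=labels, train_ids=train_ids, test_ids=test_ids,
        time_points=tps, c_grid=config.c_grid(), l1_ratio=config.l1_ratio,
        folds=config.folds, rho_threshold=config.rho_threshold,
        n_boot=config.n_boot, guard_z=config.guard_z,
    )
    if "separate" in config.modes or "cumulative" in config.modes:
        sep = sweep_timepoints(mode="separate", seed=seed + 1, **common)
        if "separate" in config.modes:
            sweeps["separate"] = sep
            if sep.models:
                optimal["separate"] = select_optimal_week(sep, alpha=config.alpha)
        if "cumulative" in config.modes:
            cum = sweep_timepoints(
                mode="cumulative", selections=sep.selections, seed=seed + 2,
                **common,
            )
            sweeps["cumulative"] = cum
            if cum.models:
                optimal["cumulative"] = select_optimal_week(cum, alpha=config.alpha)
    return RegimenResult(
        regimen=regimen, train_ids=train_ids, test_ids=test_ids,
        sweeps=sweeps, optimal=optimal,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def _fmt_ci(ci) -> str:
    return f"({ci[0]:.3f}--{ci[1]:.3f})"


def sweep_report_table(sweep: SweepResult) -> pd.DataFrame:
    rows = []
    for tp in sweep.time_points:
        m = sweep.models[tp]
        others_tr = sweep.comparisons.query("a == @tp")["p_train_a_gt_b"]
        others_te = sweep.comparisons.query("a == @tp")["p_test_a_gt_b"]
        rows.append(
            {
                "time_point": tp,
                "n_selected": len(m.selection),
                "n_nonzero": int((m.fit.coef != 0).sum()),
                "chosen_C": m.fit.chosen_C,
                "intercept_only": m.fit.degenerate,
                "train_auc": m.train_auc,
                "train_auc_ci": _fmt_ci(m.train_ci),
                "train_sen": m.train_sen,
                "train_spe": m.train_spe,
                "test_auc": m.test_auc,
                "test_auc_ci": _fmt_ci(m.test_ci),
                "test_sen": m.test_sen,
                "test_spe": m.test_spe,
                "highest_p_vs_others_train": (
                    float(others_tr.max()) if len(others_tr) else np.nan
                ),
                "highest_p_vs_others_test": (
                    float(others_te.max()) if len(others_te) else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def coefficients_markdown(model: ModelResult) -> str:
    """Markdown table of the non-zero coefficients of one model, with
    Wald p-values from an unpenalised refit on the selected support."""
    coefs = model.fit.nonzero_coefficients()
    lines = [
        f"### {model.mode} analysis, {model.time_point}",
        "",
        "| Parameter | Coefficient | P-Value |",
        "| --- | --- | --- |",
    ]
    for name, value in coefs.items():
        p = model.coef_pvalues.get(name, np.nan)
        p_str = "n/a" if pd.isna(p) else ("<0.001" if p < 0.001 else f"{p:.3f}")
        lines.append(f"| {name} | {value:.3f} | {p_str} |")
    lines.append("")
    lines.append(
        f"Train AUC {model.train_auc:.3f} {_fmt_ci(model.train_ci)}, "
        f"SEN {model.train_sen:.3f}, SPE {model.train_spe:.3f}; "
        f"Test AUC {model.test_auc:.3f} {_fmt_ci(model.test_ci)}, "
        f"SEN {model.test_sen:.3f}, SPE {model.test_spe:.3f}."
    )
    return "\n".join(lines)


def plot_auc_curves(result: RegimenResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        1, len(result.sweeps), figsize=(5 * max(len(result.sweeps), 1), 4),
        squeeze=False,
    )
    for ax, (mode, sweep) in zip(axes[0], result.sweeps.items()):
        tps = sweep.time_points
        for split_name, attr in (("train", "train"), ("test", "test")):
            mid = [getattr(sweep.models[t], f"{attr}_auc") for t in tps]
            lo = [getattr(sweep.models[t], f"{attr}_ci")[0] for t in tps]
            hi = [getattr(sweep.models[t], f"{attr}_ci")[1] for t in tps]
            x = np.arange(len(tps))
            ax.plot(x, mid, marker="o", label=f"{split_name} AUC")
            ax.fill_between(x, lo, hi, alpha=0.2)
        ax.set_xticks(np.arange(len(tps)), tps)
        ax.axhline(0.5, color="grey", lw=0.5)
        ax.set_ylim(0.2, 1.05)
        ax.set_title(f"{result.regimen}, {mode}")
        ax.set_ylabel("AUC")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, cohort: CohortData | None = None) -> PipelineResult:
    """Run the full workflow and (optionally) write the run directory.

    ``cohort`` short-circuits simulation (used by tests); otherwise the
    cohort is simulated from ``config.simulate`` or read from
    ``config.manifest``.
    """
    seed_root = np.random.SeedSequence(config.seed)
    sim_seed, split_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in seed_root.spawn(2)
    )
    run_dir = None
    log_handler = None
    if config.write_artifacts:
        run_dir = Path(config.out_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        log_handler = logging.FileHandler(run_dir / "run.log")
        log_handler.setLevel(logging.INFO)
        logging.getLogger("rwradiomics").addHandler(log_handler)

    try:
        return _run_pipeline_inner(config, cohort, run_dir, sim_seed, split_seed)
    except Exception as exc:
        if run_dir is not None:  # keep partial artefacts, mark the run
            (run_dir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    finally:
        if log_handler is not None:
            logging.getLogger("rwradiomics").removeHandler(log_handler)
            log_handler.close()


def _run_pipeline_inner(config, cohort, run_dir, sim_seed, split_seed):
    if cohort is None and config.manifest is not None:
        manifest = rio.read_cohort_manifest(config.manifest)
        records = manifest.records
        scan_features = extract_from_manifest(
            manifest, ng=config.ng, time_points=config.time_points
        )
    else:
        if cohort is None:
            spec = SyntheticCohortSpec(**{"seed": sim_seed, **config.simulate})
            cohort = generate_cohort(spec)
        records = cohort.records
        scan_features = extract_cohort_features(
            cohort, ng=config.ng, time_points=config.time_points
        )

    summary = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "regimen": [r.regimen for r in records],
            "endpoint_grade": [r.endpoint_grade for r in records],
            "endpoint_binary": [r.endpoint_binary for r in records],
        }
    )
    labels_all = summary.set_index("patient_id")["endpoint_binary"]

    tables: dict[str, pd.DataFrame] = {}
    regimen_results: dict[str, RegimenResult] = {}
    for regimen in sorted({r.regimen for r in records}):
        recs = [r for r in records if r.regimen == regimen]
        ids = [r.patient_id for r in recs]
        sf = scan_features[scan_features["patient_id"].isin(ids)]
        table = build_week_table(recs, sf)
        tables[regimen] = table
        has_mvct = (sf["modality"] == "mvct").any()
        if not has_mvct:
            logger.warning(
                "%s: no MVCT scans available; sweep reduced to the planning "
                "CT time point", regimen,
            )
        regimen_results[regimen] = model_regimen(
            regimen, table, labels_all.loc[table.index], recs, config,
            seed=split_seed,
        )

    result = PipelineResult(
        config=config, cohort_summary=summary, tables=tables,
        regimens=regimen_results, run_dir=run_dir,
    )
    if run_dir is not None:
        write_run_artifacts(result, scan_features)
    return result


def write_run_artifacts(result: PipelineResult, scan_features: pd.DataFrame) -> None:
    run_dir = result.run_dir
    result.cohort_summary.to_csv(run_dir / "cohort.csv", index=False)
    summarise_outcomes_df = summarise_outcomes(
        [
            rio.CohortRecord(p, r, g)
            for p, r, g in zip(
                result.cohort_summary["patient_id"],
                result.cohort_summary["regimen"],
                result.cohort_summary["endpoint_grade"],
            )
        ]
    )
    summarise_outcomes_df.to_csv(run_dir / "outcomes.csv", index=False)
    scan_features.to_csv(run_dir / "scan_features.csv", index=False)
    export_catalogue(run_dir / "feature_catalogue.csv")
    md_parts = []
    optimal_payload = {}
    for regimen, rres in result.regimens.items():
        result.tables[regimen].to_csv(run_dir / f"week_table_{regimen}.csv")
        for mode, sweep in rres.sweeps.items():
            rep = sweep_report_table(sweep)
            rep.to_csv(run_dir / f"report_{regimen}_{mode}.csv", index=False)
            opt = rres.optimal[mode]
            optimal_payload[f"{regimen}/{mode}"] = {
                "time_point": opt.time_point,
                "annotation": opt.annotation,
            }
            opt.rationale.to_csv(
                run_dir / f"optimal_week_rationale_{regimen}_{mode}.csv",
                index=False,
            )
            best = sweep.models.get(opt.time_point)
            if best is not None:
                md_parts.append(f"## {regimen}\n\n" + coefficients_markdown(best))
        if result.config.write_plots and rres.sweeps:
            plot_auc_curves(rres, run_dir / f"auc_{regimen}.png")
    (run_dir / "best_models.md").write_text("\n\n".join(md_parts) + "\n")
    (run_dir / "optimal_week.json").write_text(json.dumps(optimal_payload, indent=2))
    manifest = {
        "config": dataclasses.asdict(result.config),
        "config_hash": result.config.config_hash(),
        "seed": result.config.seed,
        "catalogue_version": CATALOGUE_VERSION,
        "n_patients": int(len(result.cohort_summary)),
    }
    (run_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )
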