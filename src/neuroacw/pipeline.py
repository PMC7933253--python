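"""Config-driven orchestration of the full timescale analysis.

``run_pipeline`` sequences the stages — simulate or load recordings,
estimate per-region ACW, core-periphery statistics at rest and during
tasks, rest-task similarity and difference, pooled densities, and the
classification layer — writing TSV/JSON reports plus a manifest with
seeds and file hashes. All randomness flows from one root seed, split
per stage in a fixed order, so a rerun of the same config is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import classify as cls
from . import density as dens
from . import rest_task as rt
from . import stats as gs
from .acw import ParcellatedRecording, acw_map
from .parcellation import (
    assign_cp,
    builtin_divisions,
    load_region_table,
)
from .simulate import CohortSpec, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "acw_long_table"]

SCALES = ("acw50", "acw0")
_SCALE_COL = {"acw50": "acw50_ms", "acw0": "acw0_ms"}


@dataclass
class RunConfig:
    """Validated run configuration.

    ``mode`` is ``synthetic`` (generate cohorts from ``cohort``
    overrides applied per template) or ``files`` (load recordings listed
    in ``recordings`` plus a ``region_table`` path).
    """

    out_dir: Path
    mode: str = "synthetic"
    seed: int = 0
    alpha: float = 0.05
    max_lag: int | None = None
    divisions: tuple[str, ...] = ("SCP", "JCP", "RCP")
    scales: tuple[str, ...] = SCALES
    cohort: dict[str, Any] = field(default_factory=dict)
    region_table: Path | None = None
    recordings: tuple[Path, ...] = ()

    @classmethod
    def from_dict(cls, raw: dict[str, Any], out_dir: str | Path | None = None) -> "RunConfig":
        known = {
            "mode",
            "seed",
            "alpha",
            "max_lag",
            "divisions",
            "scales",
            "cohort",
            "region_table",
            "recordings",
            "out_dir",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        out = out_dir if out_dir is not None else raw.get("out_dir")
        if out is None:
            raise ValueError("config needs an out_dir")
        config = cls(
            out_dir=Path(out),
            mode=raw.get("mode", "synthetic"),
            seed=int(raw.get("seed", 0)),
            alpha=float(raw.get("alpha", 0.05)),
            max_lag=raw.get("max_lag"),
            divisions=tuple(raw.get("divisions", ("SCP", "JCP", "RCP"))),
            scales=tuple(raw.get("scales", SCALES)),
            cohort=dict(raw.get("cohort", {})),
            region_table=Path(raw["region_table"]) if raw.get("region_table") else None,
            recordings=tuple(Path(p) for p in raw.get("recordings", ())),
        )
        config.validate()
        return config

    @classmethod
    def from_json(cls, path: str | Path, out_dir: str | Path | None = None) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()), out_dir=out_dir)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"mode must be synthetic or files, got {self.mode!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(self.divisions) - set(builtin_divisions())
        if unknown:
            raise ValueError(f"unknown divisions: {sorted(unknown)}")
        unknown = set(self.scales) - set(SCALES)
        if unknown:
            raise ValueError(f"unknown scales: {sorted(unknown)}")
        if self.mode == "files":
            if self.region_table is None or not self.recordings:
                raise ValueError("files mode needs region_table and recordings")
            missing = [str(p) for p in self.recordings if not Path(p).exists()]
            sidecars = [
                str(p)
                for p in self.recordings
                if not Path(str(p) + ".json").exists()
            ]
            if missing:
                raise ValueError(f"missing recording files: {missing}")
            if sidecars:
                raise ValueError(f"missing sidecar files: {sidecars}")

    def resolved(self) -> dict[str, Any]:
        # out_dir is run-location metadata, deliberately not part of the
        # resolved config so identical runs produce identical files
        out = {
            "mode": self.mode,
            "seed": self.seed,
            "alpha": self.alpha,
            "max_lag": self.max_lag,
            "divisions": list(self.divisions),
            "scales": list(self.scales),
            "cohort": self.cohort,
        }
        if self.region_table is not None:
            out["region_table"] = str(self.region_table)
        if self.recordings:
            out["recordings"] = [str(p) for p in self.recordings]
        return out


def acw_long_table(
    recordings: list[ParcellatedRecording], max_lag: int | None = None
) -> pd.DataFrame:
    """One row per (subject, condition, region) with both ACW scales."""
    return pd.concat(
        [acw_map(rec, max_lag=max_lag) for rec in recordings], ignore_index=True
    )


def _region_means(acw: pd.DataFrame, condition: str, scale: str) -> pd.Series:
    """Subject-averaged regional values for one condition and scale."""
    sub = acw[acw["condition"] == condition]
    return sub.groupby("region_id", sort=False)[_SCALE_COL[scale]].mean()


def _division_tables(
    region_table: pd.DataFrame, divisions: tuple[str, ...]
) -> dict[str, pd.DataFrame]:
    out = {}
    for name in divisions:
        spec = builtin_divisions()[name]
        table = region_table[region_table["template"] == spec.template]
        if table.empty:
            continue
        out[name] = assign_cp(table, spec).set_index("region_id")
    return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def rest_cp_stage(
    acw: pd.DataFrame,
    region_table: pd.DataFrame,
    divisions: tuple[str, ...],
    scales: tuple[str, ...],
) -> pd.DataFrame:
    """Resting-state core-vs-periphery t-tests, raw and axis-residualized."""
    rows = []
    for name, labelled in _division_tables(region_table, divisions).items():
        for scale in scales:
            means = _region_means(acw, "Rest", scale).reindex(labelled.index)
            # regions without a crossing (not-found) are excluded explicitly
            valid = means.notna()
            means = means[valid]
            table = labelled.loc[valid.index[valid]]
            residuals = pd.Series(
                gs.regress_out_axis(means.to_numpy(), table["y_mm"].to_numpy()),
                index=means.index,
            )
            keep = table["cp"] != "excluded"
            for variant, values in (("raw", means), ("residual", residuals)):
                report = gs.ttest_core_periphery(
                    values[keep], table.loc[keep, "cp"], division_name=name
                )
                rows.append(
                    {"division": name, "scale": scale, "variant": variant}
                    | report.to_dict()
                )
    return pd.DataFrame(rows)


def network_anova_stage(
    acw: pd.DataFrame, region_table: pd.DataFrame, scales: tuple[str, ...]
) -> pd.DataFrame:
    """One-way ANOVA of resting regional values across networks."""
    rows = []
    for template, table in region_table.groupby("template"):
        table = table.set_index("region_id")
        for scale in scales:
            means = _region_means(acw, "Rest", scale).reindex(table.index).dropna()
            report = gs.one_way_anova(
                means.to_numpy(), table.loc[means.index, "network"].to_numpy()
            )
            effect = report["group"]
            rows.append(
                {
                    "template": template,
                    "scale": scale,
                    "F": effect.F,
                    "df_effect": effect.df_effect,
                    "df_error": effect.df_error,
                    "p": effect.p,
                    "eta_sq": effect.eta_sq,
                }
            )
    return pd.DataFrame(rows)


def _task_design(
    acw: pd.DataFrame, labelled: pd.DataFrame, scale: str, tasks: list[str]
) -> pd.DataFrame:
    """Region-level (subject-averaged) values in the task x CP design."""
    frames = []
    for task in tasks:
        means = _region_means(acw, task, scale).reindex(labelled.index)
        frames.append(
            pd.DataFrame(
                {"value": means, "task": task, "cp": labelled["cp"]}
            ).reset_index()
        )
    design = pd.concat(frames, ignore_index=True)
    design = design.dropna(subset=["value"])  # regions without a crossing
    return design[design["cp"] != "excluded"]


def task_cp_stage(
    acw: pd.DataFrame,
    region_table: pd.DataFrame,
    divisions: tuple[str, ...],
    scales: tuple[str, ...],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way task x CP ANOVA and Tukey post-hoc per division and scale."""
    tasks = sorted(set(acw["condition"]) - {"Rest"})
    anova_rows, tukey_rows = [], []
    for name, labelled in _division_tables(region_table, divisions).items():
        for scale in scales:
            design = _task_design(acw, labelled, scale, tasks)
            report = gs.two_way_anova(design["value"], design["task"], design["cp"])
            for effect in report.effects:
                if effect.name == "residual":
                    continue
                anova_rows.append(
                    {"division": name, "scale": scale, "effect": effect.name}
                    | {
                        "F": effect.F,
                        "df_effect": effect.df_effect,
                        "df_error": effect.df_error,
                        "p": effect.p,
                        "eta_sq": effect.eta_sq,
                    }
                )
            posthoc = gs.tukey_posthoc(design["value"], design["task"], design["cp"])
            for contrast in posthoc.contrasts:
                tukey_rows.append(
                    {"division": name, "scale": scale} | vars(contrast)
                )
    return pd.DataFrame(anova_rows), pd.DataFrame(tukey_rows)


def rest_task_stage(
    acw: pd.DataFrame,
    region_table: pd.DataFrame,
    divisions: tuple[str, ...],
    scales: tuple[str, ...],
    alpha: float,
) -> dict[str, Any]:
    """Similarity (spatial r, regression, regional r) and percent change."""
    tasks = sorted(set(acw["condition"]) - {"Rest"})
    similarity = []
    regional = {}
    change_anova = []
    change_tables = {}
    for template, table in region_table.groupby("template"):
        region_ids = table["region_id"].tolist()
        for scale in scales:
            col = _SCALE_COL[scale]
            wide = acw.pivot_table(
                index=["subject_id", "condition"],
                columns="region_id",
                values=col,
                sort=False,
            ).reindex(columns=region_ids)
            rest_wide = wide.xs("Rest", level="condition")
            rest_map = _region_means(acw, "Rest", scale).reindex(region_ids)
            for task in tasks:
                task_map = _region_means(acw, task, scale).reindex(region_ids)
                finite = rest_map.notna() & task_map.notna()
                r, p = rt.spatial_correlation(rest_map[finite], task_map[finite])
                slope, intercept, r2 = rt.rest_task_regression(
                    rest_map[finite], task_map[finite]
                )
                similarity.append(
                    {
                        "template": template,
                        "scale": scale,
                        "task": task,
                        "spatial_r": r,
                        "spatial_p": p,
                        "slope": slope,
                        "intercept": intercept,
                        "r_squared": r2,
                    }
                )
                task_wide = wide.xs(task, level="condition").reindex(rest_wide.index)
                regional[(template, scale, task)] = rt.regional_correlation(
                    rest_wide, task_wide, alpha=alpha
                )
    # Percent change per region per subject, then subject-averaged and
    # tested in the task x CP design per division.
    for name, labelled in _division_tables(region_table, divisions).items():
        template = labelled["template"].iloc[0]
        for scale in scales:
            col = _SCALE_COL[scale]
            wide = acw.pivot_table(
                index=["subject_id", "condition"],
                columns="region_id",
                values=col,
                sort=False,
            ).reindex(columns=labelled.index)
            rest_wide = wide.xs("Rest", level="condition")
            frames = []
            for task in tasks:
                task_wide = wide.xs(task, level="condition").reindex(rest_wide.index)
                change = rt.percent_change(
                    rest_wide.to_numpy(), task_wide.to_numpy(), labels=None
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "region_id": np.tile(rest_wide.columns, len(rest_wide)),
                            "subject_id": np.repeat(
                                rest_wide.index.to_numpy(), rest_wide.shape[1]
                            ),
                            "task": task,
                            "pct_change": change.ravel(),
                        }
                    )
                )
            long = pd.concat(frames, ignore_index=True)
            change_tables[(name, scale)] = long
            by_region = (
                long.groupby(["region_id", "task"], sort=False)["pct_change"]
                .mean()
                .reset_index()
            )
            by_region["cp"] = labelled.loc[by_region["region_id"], "cp"].to_numpy()
            by_region = by_region[by_region["cp"] != "excluded"].dropna(
                subset=["pct_change"]
            )
            if len(tasks) < 2:  # the task factor needs >= 2 levels
                continue
            report = gs.two_way_anova(
                by_region["pct_change"], by_region["task"], by_region["cp"]
            )
            for effect in report.effects:
                if effect.name == "residual":
                    continue
                change_anova.append(
                    {"division": name, "scale": scale, "effect": effect.name}
                    | {
                        "F": effect.F,
                        "df_effect": effect.df_effect,
                        "df_error": effect.df_error,
                        "p": effect.p,
                        "eta_sq": effect.eta_sq,
                    }
                )
    return {
        "similarity": pd.DataFrame(similarity),
        "regional": regional,
        "percent_change": change_tables,
        "change_anova": pd.DataFrame(change_anova),
    }


def density_stage(acw: pd.DataFrame, scales: tuple[str, ...]) -> dict[str, Any]:
    """Pooled / region-averaged / subject-averaged densities per scale."""
    curves = {}
    bimodality = {}
    for scale in scales:
        col = _SCALE_COL[scale]
        for pooling in dens.POOLINGS:
            pooled = dens._pool(acw.dropna(subset=[col]), col, pooling)
            if pooled.size < 10:  # e.g. avg_regions with few subjects
                continue
            curves[(scale, pooling)] = dens.estimate_density(pooled)
            if pooled.size >= 20:
                bimodality[f"{scale}/{pooling}"] = dens.bimodality_report(pooled)
    return {"curves": curves, "bimodality": bimodality}


def classification_stage(
    acw: pd.DataFrame,
    region_table: pd.DataFrame,
    divisions: tuple[str, ...],
    seed: int,
) -> dict[str, Any]:
    """Core/periphery classification and MI feature scores per division."""
    reports = []
    mi_scores = []
    for name, labelled in _division_tables(region_table, divisions).items():
        samples = acw[acw["region_id"].isin(labelled.index)].dropna(
            subset=["acw50_ms", "acw0_ms"]
        )
        cp = labelled.loc[samples["region_id"], "cp"].to_numpy()
        keep = cp != "excluded"
        samples = samples[keep]
        cp = cp[keep]
        for classifier in cls.CLASSIFIERS:
            for feature_set in cls.FEATURE_SETS:
                report = cls.cp_classification(
                    samples,
                    cp,
                    classifier=classifier,
                    feature_set=feature_set,
                    seed=seed,
                )
                reports.append({"division": name} | report.to_dict())
        for scale in SCALES:
            mi_scores.append(
                {
                    "division": name,
                    "scale": scale,
                    "mi_nats": cls.mutual_information_score(
                        samples[_SCALE_COL[scale]], cp, seed=seed
                    ),
                }
            )
    return {
        "classifier_report": pd.DataFrame(reports),
        "mi_scores": pd.DataFrame(mi_scores),
    }


def variability_stage(acw: pd.DataFrame, scales: tuple[str, ...]) -> pd.DataFrame:
    """Median-split subject-variability AUROC per task and scale."""
    tasks = sorted(set(acw["condition"]) - {"Rest"})
    rows = []
    for scale in scales:
        col = _SCALE_COL[scale]
        by_subject = acw.groupby(["condition", "subject_id"], sort=False)[col].mean()
        rest = by_subject.xs("Rest")
        for task in tasks:
            task_vals = by_subject.xs(task).reindex(rest.index)
            rows.append(
                {
                    "scale": scale,
                    "task": task,
                    "auroc": cls.variability_split_auroc(rest, task_vals),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _needed_templates(divisions: tuple[str, ...]) -> list[str]:
    specs = builtin_divisions()
    return sorted({specs[name].template for name in divisions})


def _load_inputs(config: RunConfig) -> tuple[pd.DataFrame, list[ParcellatedRecording], pd.DataFrame | None]:
    """Region table, recordings and (synthetic mode) ground truth."""
    if config.mode == "files":
        region_table = load_region_table(config.region_table)
        recordings = [ParcellatedRecording.load(p) for p in config.recordings]
        return region_table, recordings, None
    seeds = np.random.SeedSequence(config.seed).spawn(len(_needed_templates(config.divisions)))
    tables, recordings, truths = [], [], []
    for template, seed_seq in zip(_needed_templates(config.divisions), seeds):
        overrides = {k: v for k, v in config.cohort.items() if k != "rng_seed"}
        if "conditions" in overrides:
            overrides["conditions"] = tuple(overrides["conditions"])
        spec = CohortSpec(
            template=template,
            rng_seed=int(seed_seq.generate_state(1)[0] % (2**31)),
            **overrides,
        )
        cohort = generate_cohort(spec)
        tables.append(cohort.region_table)
        recordings.extend(cohort.recordings)
        truth = cohort.ground_truth.copy()
        truth["template"] = template
        truths.append(truth)
    return (
        pd.concat(tables, ignore_index=True),
        recordings,
        pd.concat(truths, ignore_index=True),
    )


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every stage and write reports under ``config.out_dir``.

    Returns the manifest; stage failures are recorded there and re-raised
    as ``RuntimeError`` after the remaining stages have been attempted.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.resolved(), indent=1))
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}, "files": {}}
    failures = []

    def record(name: str, fn):
        start = time.perf_counter()
        try:
            result = fn()
            manifest["stages"][name] = {
                "status": "ok",
                "wall_s": round(time.perf_counter() - start, 3),
            }
            return result
        except Exception as err:  # noqa: BLE001 - stage isolation
            manifest["stages"][name] = {
                "status": "error",
                "error": f"{type(err).__name__}: {err}",
                "wall_s": round(time.perf_counter() - start, 3),
            }
            failures.append((name, err))
            return None

    def save_tsv(frame: pd.DataFrame, rel: str) -> None:
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(path, sep="\t", index=False)

    inputs = record("inputs", lambda: _load_inputs(config))
    if inputs is None:
        manifest["status"] = "error"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"input stage failed: {failures[0][1]}")
    region_table, recordings, ground_truth = inputs
    save_tsv(region_table, "regions/region_table.tsv")
    if ground_truth is not None:
        save_tsv(ground_truth, "regions/ground_truth.tsv")

    acw = record("acw", lambda: acw_long_table(recordings, max_lag=config.max_lag))
    if acw is None:
        manifest["status"] = "error"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"acw stage failed: {failures[0][1]}")
    save_tsv(acw, "acw/acw_table.tsv")

    result = record(
        "rest_cp",
        lambda: rest_cp_stage(acw, region_table, config.divisions, config.scales),
    )
    if result is not None:
        save_tsv(result, "stats/rest_cp_ttests.tsv")
    result = record(
        "network_anova", lambda: network_anova_stage(acw, region_table, config.scales)
    )
    if result is not None:
        save_tsv(result, "stats/network_anova.tsv")

    task_levels = sorted(set(acw["condition"]) - {"Rest"})
    if len(task_levels) >= 2:
        result = record(
            "task_cp",
            lambda: task_cp_stage(acw, region_table, config.divisions, config.scales),
        )
        if result is not None:
            save_tsv(result[0], "stats/task_anova.tsv")
            save_tsv(result[1], "stats/task_tukey.tsv")
    if task_levels:
        result = record(
            "rest_task",
            lambda: rest_task_stage(
                acw, region_table, config.divisions, config.scales, config.alpha
            ),
        )
        if result is not None:
            save_tsv(result["similarity"], "rest_task/similarity.tsv")
            save_tsv(result["change_anova"], "rest_task/change_anova.tsv")
            for (template, scale, task), frame in result["regional"].items():
                save_tsv(frame, f"rest_task/regional_r_{template}_{scale}_{task}.tsv")
            for (division, scale), frame in result["percent_change"].items():
                save_tsv(frame, f"rest_task/percent_change_{division}_{scale}.tsv")
        result = record("variability", lambda: variability_stage(acw, config.scales))
        if result is not None:
            save_tsv(result, "classify/variability_auroc.tsv")

    result = record("density", lambda: density_stage(acw, config.scales))
    if result is not None:
        for (scale, pooling), estimate in result["curves"].items():
            save_tsv(
                pd.DataFrame({"grid": estimate.grid, "density": estimate.density}),
                f"density/density_{scale}_{pooling}.tsv",
            )
        (out / "density" / "bimodality.json").write_text(
            json.dumps(result["bimodality"], indent=1)
        )

    classify_seed = int(
        np.random.SeedSequence([config.seed, 1]).generate_state(1)[0] % (2**31)
    )
    result = record(
        "classify",
        lambda: classification_stage(acw, region_table, config.divisions, classify_seed),
    )
    if result is not None:
        save_tsv(result["classifier_report"], "classify/classifier_report.tsv")
        save_tsv(result["mi_scores"], "classify/mi_scores.tsv")

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    manifest["status"] = "error" if failures else "ok"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if failures:
        names = ", ".join(name for name, _ in failures)
        raise RuntimeError(f"pipeline stages failed: {names}") from failures[0][1]
    return manifest
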