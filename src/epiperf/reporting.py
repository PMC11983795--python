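"""End-to-end pipeline orchestration and result rendering.

``run_pipeline`` drives simulate -> QC -> metrics -> bootstrap -> regression
and writes every result surface as tidy tab-delimited text plus a JSON
manifest with per-file checksums.  The whole bundle is a deterministic
function of the configuration (seed included), so re-running a config yields
byte-identical outputs.  Stage timings go to a separate run log that is
excluded from the manifest.

``render_figures`` draws the figure analogues: metric heatmaps, bootstrap
difference grids with significance annotations, and an interaction forest
plot with two-tier significance marks.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from . import __version__
from .synthetic_data import (
    SimulationConfig,
    simulate_population,
    truth_table,
    write_population,
    read_population,
)
from .qc_conversions import (
    DEFAULT_SPECS,
    apply_global_qc,
    build_analysis_set,
    spec_by_name,
)
from .performance_metrics import stratified_metrics
from .bootstrap_inference import all_pairwise_comparisons
from .regression_models import fit_interaction_model, significance_tiers

__all__ = ["StudyConfig", "run_pipeline", "render_figures", "build_all_analysis_sets"]

DEFAULT_RACE_BOOT_GROUPS = ("Mexican American", "NH Black", "NH White")
ALL_STAGES = ("qc", "metrics", "bootstrap", "regression")


@dataclass
class StudyConfig:
    """One full study run: cohort source plus analysis settings."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    input_table: str | None = None  # read this table instead of simulating
    predictors: tuple | None = None  # None -> simulation.predictors
    stages: tuple = ALL_STAGES
    bootstrap_iters: int = 10_000
    bootstrap_variants: tuple = ("standard",)
    bootstrap_race_groups: tuple = DEFAULT_RACE_BOOT_GROUPS
    modifiers: tuple = ("race_ethnicity", "sex")
    adjustments: tuple = ("minimal", "full")
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        for key in ("stages", "bootstrap_variants", "bootstrap_race_groups",
                    "modifiers", "adjustments"):
            d[key] = list(d[key])
        d["predictors"] = None if self.predictors is None else list(self.predictors)
        return d

    @classmethod
    def from_dict(cls, d) -> "StudyConfig":
        d = dict(d)
        if "simulation" in d and not isinstance(d["simulation"], SimulationConfig):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        for key in ("stages", "bootstrap_variants", "bootstrap_race_groups",
                    "modifiers", "adjustments", "predictors"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_all_analysis_sets(table: pd.DataFrame, predictors) -> dict:
    """Per-predictor analysis sets from a globally QC'd table."""
    sets = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in predictors:
            sets[name] = build_analysis_set(table, spec_by_name(name))
    return sets


def _qc_audit_frame(global_report, analysis_sets) -> pd.DataFrame:
    rows = [{"predictor": "(global)", "rule": "sex_mismatch",
             "count": global_report.counts.get("sex_mismatch", 0)}]
    for name, aset in analysis_sets.items():
        for rule in sorted(aset.report.counts):
            rows.append({"predictor": name, "rule": rule, "count": aset.report.counts[rule]})
        rows.append({"predictor": name, "rule": "analysable_n", "count": aset.report.n_out})
    return pd.DataFrame(rows)


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.12g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: StudyConfig, out_dir) -> dict:
    """Execute all configured stages; return the result bundle.

    The bundle maps table name -> DataFrame and includes the manifest dict.
    Stage failures abort with a diagnostic naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []
    bundle: dict = {}
    timings: dict[str, float] = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self_t):
                self_t.t0 = time.perf_counter()
                return self_t

            def __exit__(self_t, exc_type, exc, tb):
                dt = time.perf_counter() - self_t.t0
                timings[name] = dt
                if exc is not None:
                    log_lines.append(f"stage {name}: FAILED after {dt:.2f}s: {exc}")
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                log_lines.append(f"stage {name}: ok ({dt:.2f}s)")
                return False

        return _Timer()

    predictors = config.predictors or config.simulation.predictors

    with stage("input"):
        if config.input_table is not None:
            table = read_population(config.input_table)
            truth = None
        else:
            table = simulate_population(config.simulation)
            truth = truth_table(config.simulation)
        bundle["population"] = table
        if truth is not None:
            bundle["truth"] = truth

    with stage("qc"):
        clean, global_report = apply_global_qc(table)
        analysis_sets = build_all_analysis_sets(clean, predictors)
        bundle["qc_audit"] = _qc_audit_frame(global_report, analysis_sets)
        bundle["analysis_sets"] = analysis_sets

    if "metrics" in config.stages:
        with stage("metrics"):
            parts = []
            for strata_var in ("race_ethnicity", "sex"):
                for name, aset in analysis_sets.items():
                    m = stratified_metrics(aset, strata_var)
                    m.insert(1, "strata_var", strata_var)
                    parts.append(m if strata_var == "race_ethnicity" else m[m["stratum"] != "overall"])
            bundle["metrics"] = pd.concat(parts, ignore_index=True)

    if "bootstrap" in config.stages:
        with stage("bootstrap"):
            parts = []
            for variant in config.bootstrap_variants:
                for strata_var, groups in (
                    ("race_ethnicity", config.bootstrap_race_groups),
                    ("sex", ("male", "female")),
                ):
                    t = all_pairwise_comparisons(
                        analysis_sets,
                        groups=groups,
                        variant=variant,
                        n_iter=config.bootstrap_iters,
                        seed=config.seed,
                        strata_var=strata_var,
                    )
                    t.insert(1, "strata_var", strata_var)
                    parts.append(t)
            bundle["bootstrap"] = pd.concat(parts, ignore_index=True)

    if "regression" in config.stages:
        with stage("regression"):
            parts = []
            for adjustment in config.adjustments:
                for modifier in config.modifiers:
                    for name, aset in analysis_sets.items():
                        if adjustment == "full" and aset.spec.family == "cell":
                            continue
                        fit = fit_interaction_model(
                            aset, modifier=modifier, adjustment=adjustment, alpha=config.alpha
                        )
                        t = fit.table.reset_index()
                        t["tier"] = significance_tiers(fit, config.alpha).to_numpy()
                        t.insert(0, "predictor", name)
                        t.insert(1, "modifier", modifier)
                        t.insert(2, "adjustment", adjustment)
                        t["n_used"] = fit.n_used
                        parts.append(t)
            bundle["regression"] = pd.concat(parts, ignore_index=True)

    with stage("write"):
        files = {}
        config.to_yaml(out / "config.yaml")
        files["config.yaml"] = _sha256(out / "config.yaml")
        write_population(bundle["population"], out / "population.tsv")
        files["population.tsv"] = _sha256(out / "population.tsv")
        for key in ("truth", "qc_audit", "metrics", "bootstrap", "regression"):
            if key in bundle:
                path = out / f"{key}.tsv"
                _write_table(bundle[key], path)
                files[f"{key}.tsv"] = _sha256(path)
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "simulation_seed": config.simulation.seed,
            "stages": list(config.stages),
            "n_rows": {
                k: int(len(v)) for k, v in bundle.items() if isinstance(v, pd.DataFrame)
            },
            "files": files,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        bundle["manifest"] = manifest

    # Timings go to the log only; the manifest stays deterministic.
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return bundle


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------


def _save(fig: Figure, path: Path) -> Path:
    FigureCanvasAgg(fig)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    return path


def _metric_heatmap(metrics: pd.DataFrame, value: str, path: Path) -> Path:
    wide = metrics.pivot_table(index="predictor", columns="stratum", values=value, sort=False)
    fig = Figure(figsize=(1.2 * len(wide.columns) + 3, 0.4 * len(wide) + 2))
    ax = fig.add_subplot(111)
    im = ax.imshow(wide.to_numpy(float), aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(wide.columns)), wide.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(wide)), wide.index)
    ax.set_title(value)
    fig.colorbar(im, ax=ax)
    return _save(fig, path)


def _difference_grid(boot: pd.DataFrame, metric: str, path: Path) -> Path:
    sub = boot[(boot["metric"] == metric) & (boot["status"] == "ok")].copy()
    sub["pair"] = sub["group_a"] + " - " + sub["group_b"]
    wide = sub.pivot_table(index="predictor", columns="pair", values="median_diff", sort=False)
    sig = sub.pivot_table(
        index="predictor", columns="pair", values="significant", aggfunc="first", sort=False
    )
    fig = Figure(figsize=(1.6 * max(len(wide.columns), 1) + 3, 0.4 * max(len(wide), 1) + 2))
    ax = fig.add_subplot(111)
    data = wide.to_numpy(float)
    lim = np.nanmax(np.abs(data)) if data.size else 1.0
    im = ax.imshow(data, aspect="auto", cmap="coolwarm", vmin=-lim, vmax=lim)
    for i in range(wide.shape[0]):
        for j in range(wide.shape[1]):
            if bool(sig.iloc[i, j]):
                ax.text(j, i, f"{data[i, j]:.2g}", ha="center", va="center", fontsize=7)
    ax.set_xticks(range(len(wide.columns)), wide.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(wide)), wide.index)
    ax.set_title(f"bootstrapped difference in {metric} (annotated where significant)")
    fig.colorbar(im, ax=ax)
    return _save(fig, path)


def _forest_plot(regression: pd.DataFrame, modifier: str, adjustment: str, path: Path) -> Path:
    sub = regression[
        (regression["modifier"] == modifier)
        & (regression["adjustment"] == adjustment)
        & (regression["role"].isin(["phenotype_main", "interaction"]))
    ].copy()
    sub["label"] = sub["predictor"] + " | " + np.where(
        sub["role"] == "phenotype_main", "phenotype", sub["group"]
    )
    marks = sub["tier"].map({"significant": " **", "suggestive": " *"}).fillna("")
    fig = Figure(figsize=(7, 0.22 * max(len(sub), 4) + 1.5))
    ax = fig.add_subplot(111)
    ypos = np.arange(len(sub))[::-1]
    colors = np.where(sub["role"] == "phenotype_main", "#27408B", "#CD5B45")
    ax.hlines(ypos, sub["ci_low"], sub["ci_high"], color=colors, lw=1.2)
    ax.scatter(sub["estimate"], ypos, c=colors, s=12, zorder=3)
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(ypos, (sub["label"] + marks).tolist(), fontsize=6)
    ax.set_xlabel("estimate (95% CI)")
    ax.set_title(f"interaction model estimates ({modifier}, {adjustment})")
    return _save(fig, path)


def render_figures(bundle: dict, out_dir) -> list[Path]:
    """Render the standard figure set from a result bundle.

    Missing tables are reported and their figures skipped.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    skipped: list[str] = []

    if "metrics" in bundle:
        race = bundle["metrics"]
        race_m = race[race["strata_var"] == "race_ethnicity"]
        written.append(_metric_heatmap(race_m, "pearson_r", out / "fig_metrics_r.png"))
        written.append(_metric_heatmap(race_m, "mae", out / "fig_metrics_mae.png"))
    else:
        skipped.append("metrics")

    if "bootstrap" in bundle:
        boot = bundle["bootstrap"]
        std = boot[boot["variant"] == "standard"] if "variant" in boot.columns else boot
        for metric in ("pearson_r", "mae"):
            if (std["metric"] == metric).any():
                written.append(
                    _difference_grid(std, metric, out / f"fig_bootstrap_{metric}.png")
                )
    else:
        skipped.append("bootstrap")

    if "regression" in bundle:
        reg = bundle["regression"]
        for modifier in reg["modifier"].unique():
            sub = reg[reg["adjustment"] == "minimal"]
            if len(sub):
                written.append(
                    _forest_plot(reg, modifier, "minimal", out / f"fig_forest_{modifier}.png")
                )
    else:
        skipped.append("regression")

    if skipped:
        warnings.warn(f"figures skipped for missing tables: {skipped}", stacklevel=2)
    return written
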