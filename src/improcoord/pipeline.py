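"""End-to-end orchestration: simulate or load a recording, run every
analysis stage, and emit tables, a run manifest, and a markdown report.

Stage order mirrors the analysis flow: pairwise interdependence and
coordination metrics with time-scrambled nulls, group-level alignment
dynamics with the middle-vs-junction window contrast, then factor tables
and regressions.  A single config drives both simulation and analysis so
a full run is one command.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import core_data, factor_analysis, group_dynamics, pairwise_coordination
from .core_data import EnsembleRecording, ValidationError
from .pairwise_coordination import AnalysisConfig, PairCoordination
from .synthetic_ensemble import SimulationConfig, generate_ensemble

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "load_config", "run_pipeline", "report"]

PAIR_REGRESSION_RESPONSES = {
    "actions": ("rho", "sonic_organization"),
    "intentions": ("rho", "mean_slider_distance"),
}
RELATIONAL_TERMS = ("familiarity", "instrumental_proximity", "spatial_proximity")
INDIVIDUAL_TERMS = ("expertise", "familiarity_with_others", "spatial_eccentricity")


@dataclass
class RunManifest:
    """Provenance for one pipeline run: config, digests, timings, warnings."""

    config: dict
    seed: int
    outputs: dict = field(default_factory=dict)   # filename -> sha256
    timings_s: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> dict:
    """Load a YAML/JSON config; missing file -> all defaults."""
    cfg: dict = {}
    if path is not None:
        text = Path(path).read_text()
        cfg = yaml.safe_load(text) or {}
    if overrides:
        for key, value in overrides.items():
            if value is None:
                continue
            section, _, name = key.partition(".")
            if name:
                cfg.setdefault(section, {})[name] = value
            else:
                cfg[key] = value
    return cfg


def _analysis_config(cfg: dict) -> AnalysisConfig:
    section = dict(cfg.get("analysis", {}))
    if "seed" in cfg and "rng_seed" not in section:
        section["rng_seed"] = int(cfg["seed"])
    if "lag_candidates" in section:
        section["lag_candidates"] = tuple(section["lag_candidates"])
    return AnalysisConfig(**section)


def _simulation_config(cfg: dict) -> SimulationConfig:
    section = dict(cfg.get("simulation", {}))
    if "seed" in cfg and "rng_seed" not in section:
        section["rng_seed"] = int(cfg["seed"])
    if "segmentation_boundaries" in section:
        section["segmentation_boundaries"] = tuple(section["segmentation_boundaries"])
    return SimulationConfig(**section)


def _surrogate_summary_cols(summary, prefix: str) -> dict:
    if summary is None:
        return {f"{prefix}_mean": np.nan, f"{prefix}_sd": np.nan}
    return {f"{prefix}_mean": summary.mean, f"{prefix}_sd": summary.sd}


def _pairs_frame(pairs: list[PairCoordination]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        row = {
            "id_a": p.id_a,
            "id_b": p.id_b,
            "causal_density": p.causal_density,
            "p_ab": p.p_ab,
            "p_ba": p.p_ba,
            "rho": p.rho,
            "rho_p": p.rho_p,
            "sonic_organization": p.sonic_organization,
            "mean_slider_distance": p.mean_slider_distance,
            "classification": p.classification,
            "degenerate": p.degenerate,
            "degenerate_reason": p.degenerate_reason,
        }
        row.update(_surrogate_summary_cols(p.null_causal_density, "null_causal_density"))
        row.update(_surrogate_summary_cols(p.null_rho, "null_rho"))
        row.update(_surrogate_summary_cols(p.null_abs_rho, "null_abs_rho"))
        row.update(_surrogate_summary_cols(p.null_distance, "null_distance"))
        rows.append(row)
    return pd.DataFrame(rows)


def _comparison_rows(pairs: list[PairCoordination], dimension: str) -> list[dict]:
    """Real-vs-null paired t-tests over the non-degenerate pairs."""
    ok = [p for p in pairs if not p.degenerate and p.null_causal_density is not None]
    rows = []

    def add(metric: str, real: list[float], null: list[float]) -> None:
        if len(real) < 2:
            return
        res = pairwise_coordination.compare_to_null(real, null)
        rows.append(
            {
                "dimension": dimension, "metric": metric,
                "t": res.t, "df": res.df, "p": res.p, "d": res.d,
                "mean_real": res.mean_real, "mean_null": res.mean_null,
                "n_pairs": len(real), "degenerate": res.degenerate,
            }
        )

    add("causal_density", [p.causal_density for p in ok],
        [p.null_causal_density.mean for p in ok])
    add("rho", [p.rho for p in ok], [p.null_rho.mean for p in ok])
    if dimension == "actions":
        add("sonic_organization", [p.sonic_organization for p in ok],
            [p.null_abs_rho.mean for p in ok])
    else:
        add("mean_slider_distance", [p.mean_slider_distance for p in ok],
            [p.null_distance.mean for p in ok])
    return rows


def run_pipeline(
    config: dict | str | Path | None = None,
    out_dir: str | Path = "improcoord_out",
    recording: EnsembleRecording | None = None,
) -> Path:
    """Run the full analysis; returns the output directory.

    ``config`` may be a path to a YAML/JSON file or an already-loaded
    dict.  A recording is loaded from ``config["input_dir"]`` when given,
    otherwise simulated from the ``simulation`` section (or passed in
    directly for programmatic use).
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config or {})
    seed = int(cfg.get("seed", 0))
    cfg.setdefault("seed", seed)
    analysis_cfg = _analysis_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_jsonable(cfg), seed=seed)
    t_start = time.perf_counter()

    # --- stage: obtain recording -------------------------------------------
    t0 = time.perf_counter()
    if recording is None:
        if cfg.get("input_dir"):
            recording = core_data.read_recording(cfg["input_dir"])
        else:
            sim_cfg = _simulation_config(cfg)
            recording, _ = generate_ensemble(sim_cfg)
    if recording.silent_ids:
        manifest.warnings.append(
            f"silent musicians excluded from action analysis: {list(recording.silent_ids)}"
        )
    manifest.timings_s["load_or_simulate"] = round(time.perf_counter() - t0, 3)

    halfwidth = int(cfg.get("window_halfwidth_s", 16))
    comparisons: list[dict] = []

    # --- stage: pairwise analyses ------------------------------------------
    pairs_by_dim: dict[str, list[PairCoordination]] = {}
    for dimension in ("actions", "intentions"):
        n_series = (
            len(recording.action_ids) - len(recording.silent_ids)
            if dimension == "actions"
            else len(recording.intention_ids)
        )
        if n_series < 2:
            manifest.warnings.append(f"{dimension}: fewer than 2 series, stage skipped")
            continue
        t0 = time.perf_counter()
        pairs = pairwise_coordination.all_pairs(recording, dimension, analysis_cfg)
        frame = _pairs_frame(pairs)
        path = out / f"pairs_{dimension}.csv"
        frame.to_csv(path, index=False)
        manifest.outputs[path.name] = _sha256(path)
        comparisons.extend(_comparison_rows(pairs, dimension))
        n_deg = sum(p.degenerate for p in pairs)
        if n_deg:
            manifest.warnings.append(f"{dimension}: {n_deg} degenerate pair(s)")
        manifest.timings_s[f"pairs_{dimension}"] = round(time.perf_counter() - t0, 3)
        pairs_by_dim[dimension] = pairs

    comp_path = out / "comparisons.csv"
    pd.DataFrame(comparisons).to_csv(comp_path, index=False)
    manifest.outputs[comp_path.name] = _sha256(comp_path)

    # --- stage: group dynamics ---------------------------------------------
    t0 = time.perf_counter()
    have_intentions = recording.intentions.shape[0] >= 1
    if have_intentions:
        series = group_dynamics.compute_alignment_series(
            recording.actions, recording.intentions, analysis_cfg
        )
        gm = pd.DataFrame(
            {
                "t": series.t,
                "fraction_playing": series.fraction_playing,
                "mean_intention": series.mean_intention,
                "alignment": series.alignment,
                "null_alignment": series.null_alignment,
            }
        )
    else:
        series = None
        gm = pd.DataFrame(
            {
                "t": np.arange(recording.duration_s),
                "fraction_playing": group_dynamics.fraction_playing(recording.actions),
            }
        )
    gm_path = out / "group_metrics.csv"
    gm.to_csv(gm_path, index=False)
    manifest.outputs[gm_path.name] = _sha256(gm_path)

    middle = group_dynamics.window_indices(recording.segmentation, "middle", halfwidth)
    junction = group_dynamics.window_indices(recording.segmentation, "junction", halfwidth)
    # map each index to its nearest center for readability
    win_rows = []
    for mask in (middle, junction):
        centers = np.asarray(mask.centers)
        for i in mask.indices:
            center = int(centers[np.argmin(np.abs(centers - i))])
            win_rows.append({"kind": mask.kind, "center_s": center, "index_s": int(i)})
    win_path = out / "windows.csv"
    pd.DataFrame(win_rows).to_csv(win_path, index=False)
    manifest.outputs[win_path.name] = _sha256(win_path)

    window_contrast = None
    alignment_mean_rho = None
    if series is not None:
        window_contrast = group_dynamics.compare_windows(series.alignment, middle, junction)
        try:
            alignment_mean_rho = group_dynamics.alignment_vs_mean(
                series.alignment, series.mean_intention
            )
        except ValidationError as exc:
            manifest.warnings.append(f"alignment_vs_mean degenerate: {exc}")
    manifest.timings_s["group_dynamics"] = round(time.perf_counter() - t0, 3)

    # --- stage: factors and regressions ------------------------------------
    t0 = time.perf_counter()
    regression_rows: list[dict] = []
    factor_frames: dict[str, pd.DataFrame] = {}
    for dimension, pairs in pairs_by_dim.items():
        pair_table, ind_table = factor_analysis.build_factor_table(recording, pairs)
        factor_frames[dimension] = pair_table
        pp = out / f"factors_pairs_{dimension}.csv"
        pair_table.to_csv(pp, index=False)
        manifest.outputs[pp.name] = _sha256(pp)
        ip = out / f"factors_individuals_{dimension}.csv"
        ind_table.to_csv(ip, index=False)
        manifest.outputs[ip.name] = _sha256(ip)

        for response in PAIR_REGRESSION_RESPONSES[dimension]:
            if response not in pair_table or pair_table[response].isna().all():
                continue
            try:
                res = factor_analysis.fit_mixed_regression(
                    pair_table, response, RELATIONAL_TERMS
                )
            except ValidationError as exc:
                manifest.warnings.append(f"pair regression {dimension}/{response}: {exc}")
                continue
            for r in res:
                regression_rows.append(
                    {"level": "pair", "dimension": dimension, "response": response,
                     **dataclasses.asdict(r)}
                )
                if r.singular:
                    manifest.warnings.append(
                        f"singular mixed fit: {dimension}/{response}"
                    )
            try:
                ind_res = factor_analysis.fit_individual_regression(
                    ind_table, response, INDIVIDUAL_TERMS, family_column="instrument_family"
                )
            except ValidationError as exc:
                manifest.warnings.append(f"individual regression {dimension}/{response}: {exc}")
                continue
            for r in ind_res:
                regression_rows.append(
                    {"level": "individual", "dimension": dimension, "response": response,
                     **dataclasses.asdict(r)}
                )
    reg_path = out / "regression_results.csv"
    pd.DataFrame(regression_rows).to_csv(reg_path, index=False)
    manifest.outputs[reg_path.name] = _sha256(reg_path)
    manifest.timings_s["factors"] = round(time.perf_counter() - t0, 3)

    # --- summary + manifest --------------------------------------------------
    summary = {
        "seed": seed,
        "n_action_musicians": len(recording.action_ids) - len(recording.silent_ids),
        "n_intention_musicians": len(recording.intention_ids),
        "duration_s": recording.duration_s,
        "window_contrast": None,
        "alignment_vs_mean": None,
    }
    if window_contrast is not None:
        summary["window_contrast"] = {
            "mean_middle": window_contrast.mean_real,
            "mean_junction": window_contrast.mean_null,
            "t": window_contrast.t, "df": window_contrast.df, "p": window_contrast.p,
        }
    if alignment_mean_rho is not None:
        summary["alignment_vs_mean"] = {
            "spearman_rho": alignment_mean_rho[0], "p": alignment_mean_rho[1]
        }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    manifest.outputs[summary_path.name] = _sha256(summary_path)

    manifest.timings_s["total"] = round(time.perf_counter() - t_start, 3)
    (out / "manifest.json").write_text(manifest.to_json())

    report_path = out / "report.md"
    report_path.write_text(report(out))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _pct(x: float) -> str:
    return f"{100.0 * x:.2f}%"


def report(out_dir: str | Path) -> str:
    """Human-readable markdown summary of a pipeline output directory."""
    out = Path(out_dir)
    if not out.exists() or not any(out.iterdir()):
        raise ValidationError(f"no pipeline outputs found under {out}")
    lines = ["# Ensemble coordination report", ""]
    gaps = []

    comp_path = out / "comparisons.csv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path)
        lines.append("## Real vs. time-scrambled comparisons")
        lines.append("")
        lines.append("| dimension | metric | real mean | null mean | t | df | p | d |")
        lines.append("|---|---|---|---|---|---|---|---|")
        for row in comp.itertuples(index=False):
            d = f"{row.d:.2f}" if pd.notna(row.d) else "-"
            lines.append(
                f"| {row.dimension} | {row.metric} | {row.mean_real:.3f} | "
                f"{row.mean_null:.3f} | {row.t:.2f} | {row.df:.0f} | {row.p:.3g} | {d} |"
            )
        lines.append("")
    else:
        gaps.append("comparisons.csv missing")

    for dimension in ("actions", "intentions"):
        path = out / f"pairs_{dimension}.csv"
        if not path.exists():
            gaps.append(f"pairs_{dimension}.csv missing")
            continue
        pairs = pd.read_csv(path)
        n = len(pairs)
        counts = {
            "positive": int((pairs["classification"] == "positive").sum()),
            "negative": int((pairs["classification"] == "negative").sum()),
            "none": int(
                ((pairs["classification"] == "none") & ~pairs["degenerate"]).sum()
            ),
            "degenerate": int(pairs["degenerate"].sum()),
        }
        assert sum(counts.values()) == n
        lines.append(f"## Pair classification — {dimension} ({n} pairs)")
        lines.append("")
        for key, cnt in counts.items():
            lines.append(f"- {key}: {cnt} ({_pct(cnt / n)})")
        lines.append("")

    summary_path = out / "summary.json"
    if summary_path.exists():
        summary = json.loads(summary_path.read_text())
        wc = summary.get("window_contrast")
        if wc:
            lines.append("## Alignment: middle vs. junction windows")
            lines.append("")
            lines.append(
                f"- mean alignment, middle windows: {wc['mean_middle']:.3f}; "
                f"junction windows: {wc['mean_junction']:.3f}"
            )
            lines.append(
                f"- Welch t = {wc['t']:.2f}, df = {wc['df']:.0f}, p = {wc['p']:.3g}"
            )
            lines.append("")
        am = summary.get("alignment_vs_mean")
        if am:
            lines.append(
                f"- Spearman rho between mean slider value and group alignment: "
                f"{am['spearman_rho']:.2f} (p = {am['p']:.3g})"
            )
            lines.append("")
    else:
        gaps.append("summary.json missing")

    reg_path = out / "regression_results.csv"
    if reg_path.exists():
        reg = pd.read_csv(reg_path)
        if len(reg):
            lines.append("## Factor regressions")
            lines.append("")
            lines.append("| level | dimension | response | term | beta | se | t | p |")
            lines.append("|---|---|---|---|---|---|---|---|")
            for row in reg.itertuples(index=False):
                lines.append(
                    f"| {row.level} | {row.dimension} | {row.response} | {row.term} | "
                    f"{row.beta:.4f} | {row.se:.4f} | {row.t:.2f} | {row.p:.3g} |"
                )
            lines.append("")
    else:
        gaps.append("regression_results.csv missing")

    if gaps:
        lines.append("## Missing outputs")
        lines.append("")
        lines.extend(f"- {g}" for g in gaps)
        lines.append("")
    return "\n".join(lines)
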