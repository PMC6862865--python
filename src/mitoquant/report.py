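"""Report assembly and the end-to-end synthetic pipeline.

``assemble_report`` merges group summaries from any number of analysis
stages into one table, a statistics JSON with the full configuration
snapshot (constants, thresholds, seeds), and a plain-text digest; every
number is traceable to its stage. ``run_pipeline`` exercises the whole
stack on generated data — flux plate, mitochondria images,
tandem-reporter images, cytometry samples — for a configurable set of
treatment groups, then runs ANOVA + Newman-Keuls on each readout. The
default scenario models three groups (a control, an insult that
fragments mitochondria / lowers respiration / blocks autophagic flux,
and a rescue) purely as a demonstration and determinism check.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cytometry, flux, morphometry, puncta, stats, synthetic
from .errors import ReportError


def _stage_rows(stage: str, summary: pd.DataFrame) -> list:
    """Flatten a group-summary table into (stage, group, metric, value) rows."""
    rows = []
    for group, row in summary.iterrows():
        for metric, value in row.items():
            if isinstance(value, (bool, np.bool_)):
                value = bool(value)
            elif isinstance(value, (int, np.integer)):
                value = int(value)
            elif isinstance(value, (float, np.floating)):
                value = float(value)
            rows.append({"stage": stage, "group": str(group),
                         "metric": str(metric), "value": value})
    return rows


def assemble_report(stage_summaries: dict, statistics: dict | None = None,
                    config: dict | None = None, outdir=None) -> dict:
    """Merge stage outputs into one report bundle.

    Parameters
    ----------
    stage_summaries:
        Mapping stage name -> group-summary DataFrame (groups in the
        index, metrics in columns).
    statistics:
        Optional mapping readout name -> ANOVA/post-hoc results (as
        produced by :func:`mitoquant.stats.anova_with_posthoc`).
    config:
        Configuration snapshot (constants, thresholds, seeds) recorded
        verbatim in the JSON.
    outdir:
        When given, writes ``report.csv``, ``report.json`` and
        ``summary.txt`` there. The JSON is written with sorted keys and
        no timestamps, so identical inputs give byte-identical files.

    Raises
    ------
    ReportError
        If the input set is empty or a stage contributes the same
        (group, metric) twice (collisions listed).
    """
    if not stage_summaries:
        raise ReportError("no stage outputs to assemble")
    rows = []
    for stage, summary in stage_summaries.items():
        rows.extend(_stage_rows(stage, summary))
    merged = pd.DataFrame(rows)
    dup = merged.duplicated(subset=["stage", "group", "metric"], keep=False)
    if dup.any():
        collisions = merged.loc[dup, ["stage", "group", "metric"]].drop_duplicates()
        raise ReportError("conflicting group labels across stages: "
                          + ", ".join(f"{r.stage}/{r.group}/{r.metric}"
                                      for r in collisions.itertuples()))
    bundle = {
        "config": config or {},
        "summaries": merged.to_dict(orient="records"),
        "statistics": statistics or {},
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        merged.to_csv(outdir / "report.csv", index=False)
        (outdir / "report.json").write_text(
            json.dumps(bundle, indent=2, sort_keys=True, default=float) + "\n")
        (outdir / "summary.txt").write_text(_text_digest(merged, statistics or {}))
    return bundle


def _text_digest(merged: pd.DataFrame, statistics: dict) -> str:
    lines = ["mitoquant report", "================", ""]
    for stage, g in merged.groupby("stage", sort=True):
        lines.append(f"[{stage}]")
        for group, gg in g.groupby("group", sort=True):
            parts = [f"{r.metric}={r.value:.4g}" if isinstance(r.value, float)
                     else f"{r.metric}={r.value}" for r in gg.itertuples()]
            lines.append(f"  {group}: " + ", ".join(parts))
        lines.append("")
    for name, res in sorted(statistics.items()):
        a = res["anova"]
        lines.append(f"ANOVA [{name}]: F({a['df_between']},{a['df_within']}) = "
                     f"{a['F']:.3f}, p = {a['p']:.4g}")
        for pair in res["pairs"]:
            star = "*" if pair["significant"] else " "
            lines.append(f"  {star} {pair['group_low']} vs {pair['group_high']}: "
                         f"diff {pair['mean_diff']:.3g}, q {pair['q']:.2f} "
                         f"(crit {pair['q_crit']:.2f}, span {pair['span']})")
    return "\n".join(lines) + "\n"


# -------------------------------------------------------------------------
# End-to-end pipeline on synthetic data
# -------------------------------------------------------------------------

#: Default three-group scenario: per-group true parameters for each
#: synthetic readout. Values are per-cell rates (flux), planted shape
#: axes in px (morphometry), planted per-cell vesicle counts (tandem),
#: and high-population mixing fractions (cytometry).
DEFAULT_SCENARIO = {
    "groups": ["control", "insult", "rescue"],
    "flux": {
        "wells_per_group": 6,
        "basal": {"control": 100.0, "insult": 60.0, "rescue": 90.0},
        "maximal": {"control": 180.0, "insult": 75.0, "rescue": 160.0},
        "nonmito": 20.0, "coupled_fraction": 0.75, "ecar": 10.0,
        "noise_sd": 5.0,
    },
    "morphometry": {
        "images_per_group": 2, "n_objects": 12,
        "axes": {"control": (16.0, 4.0), "insult": (6.0, 5.0),
                 "rescue": (14.0, 4.5)},
        "noise_sd": 2.0,
    },
    "tandem": {
        "cell_grid": (2, 2),
        "red_per_cell": {"control": 12, "insult": 12, "rescue": 12},
        "green_per_cell": {"control": 3, "insult": 9, "rescue": 4},
        "noise_sd": 3.0,
    },
    "cytometry": {
        "n_events": 5000,
        "pi_high": {"control": 0.85, "insult": 0.45, "rescue": 0.80},
        "control_quantile": 0.95,
    },
    "alpha": 0.05,
}


def run_pipeline(config: dict | None = None, seed: int = 0,
                 outdir=None) -> dict:
    """Generate synthetic data for every readout, analyze, and report.

    Runs, per treatment group: flux-plate generation → phase summary →
    ATP-rate partitioning; mitochondria-image generation → segmentation
    → morphometry; tandem-reporter generation → puncta detection →
    vesicle classification; cytometry-event generation → positive-control
    gating. Per-unit values (wells / particles / cells / samples) feed
    one-way ANOVA + Newman-Keuls per readout. Deterministic for a given
    (config, seed).
    """
    cfg = json.loads(json.dumps(config if config is not None else DEFAULT_SCENARIO))
    groups = cfg["groups"]
    rng = np.random.default_rng(seed)
    constants = flux.BioenergeticConstants()
    summaries: dict = {}
    statistics: dict = {}

    # --- flux ---
    fc = cfg["flux"]
    truths = {}
    well_groups = {}
    for gi, group in enumerate(groups):
        for w in range(fc["wells_per_group"]):
            well = f"{group}_{w + 1:02d}"
            truths[well] = synthetic.FluxGroundTruth(
                basal_ocr=fc["basal"][group], nonmito_ocr=fc["nonmito"],
                coupled_fraction=fc["coupled_fraction"],
                maximal_ocr=fc["maximal"][group], ecar=fc["ecar"],
                noise_sd=fc["noise_sd"],
                seed=int(rng.integers(2 ** 31)))
            well_groups[well] = group
    plate = synthetic.generate_flux_plate(truths)
    summary = flux.summarize_phases(plate)
    summary = flux.add_atp_rates(summary, constants)
    summary = flux.normalize_by_signal(summary, plate.normalization)
    gser = pd.Series(well_groups).reindex(summary.index)
    flux_summary = summary.groupby(gser).agg(
        n=("ocr_basal", "size"),
        basal_ocr_mean=("ocr_basal", "mean"),
        src_pct_mean=("src_pct", "mean"),
        atp_ox_mean=("atp_ox", "mean"),
        atp_glyc_mean=("atp_glyc", "mean"),
        atp_total_mean=("atp_total", "mean"))
    summaries["flux"] = flux_summary
    for readout in ("src_pct", "atp_ox"):
        statistics[f"flux_{readout}"] = stats.anova_with_posthoc(
            {g: summary.loc[gser == g, readout].to_numpy() for g in groups},
            alpha=cfg["alpha"])

    # --- morphometry ---
    mc = cfg["morphometry"]
    frames = []
    for group in groups:
        a, b = mc["axes"][group]
        for _ in range(mc["images_per_group"]):
            truth = synthetic.random_ellipse_truth(
                mc["n_objects"], a=a, b=b, noise_sd=mc["noise_sd"],
                seed=int(rng.integers(2 ** 31)))
            img, _labels = synthetic.generate_mito_image(truth)
            labels = morphometry.segment_particles(img)
            parts = morphometry.measure_particles(labels)
            parts["group"] = group
            frames.append(parts)
    particles = pd.concat(frames, ignore_index=True)
    summaries["morphometry"] = morphometry.summarize_morphometry(
        particles, particles["group"])
    statistics["morphometry_aspect_ratio"] = stats.anova_with_posthoc(
        {g: particles.loc[particles["group"] == g, "aspect_ratio"].to_numpy()
         for g in groups}, alpha=cfg["alpha"])

    # --- tandem reporter ---
    tc = cfg["tandem"]
    per_cell_frames = []
    for group in groups:
        truth = synthetic.random_tandem_truth(
            tc["red_per_cell"][group], tc["green_per_cell"][group],
            cell_grid=tuple(tc["cell_grid"]), noise_sd=tc["noise_sd"],
            seed=int(rng.integers(2 ** 31)))
        stack, _counts = synthetic.generate_tandem_reporter_image(truth)
        mask = truth.cell_mask()
        pcfg = puncta.PunctaConfig()
        red = puncta.detect_puncta(stack[0], pcfg, cell_mask=mask)
        green = puncta.detect_puncta(stack[1], pcfg, cell_mask=mask)
        classified = puncta.classify_tandem(red, green, pcfg)
        classified["group"] = group
        per_cell_frames.append(classified.reset_index())
    cells = pd.concat(per_cell_frames, ignore_index=True)
    summaries["tandem"] = puncta.summarize_puncta(
        cells[["red", "green", "autophagosomes", "autolysosomes"]],
        cells["group"])
    statistics["tandem_autolysosomes"] = stats.anova_with_posthoc(
        {g: cells.loc[cells["group"] == g, "autolysosomes"].to_numpy(float)
         for g in groups}, alpha=cfg["alpha"])

    # --- cytometry gating ---
    cyc = cfg["cytometry"]
    control_truth = synthetic.CytometryGroundTruth(
        pi_high=0.0, n=cyc["n_events"], seed=int(rng.integers(2 ** 31)))
    control_events = synthetic.generate_cytometry_events(control_truth)
    rows = []
    for group in groups:
        truth = synthetic.CytometryGroundTruth(
            pi_high=cyc["pi_high"][group], n=cyc["n_events"],
            seed=int(rng.integers(2 ** 31)))
        events = synthetic.generate_cytometry_events(truth)
        pct = cytometry.percent_above_threshold(
            events, control_events, q=cyc["control_quantile"])
        es = cytometry.event_statistics(events)
        rows.append({"group": group, "pct_above_threshold": pct,
                     "median_intensity": es["median"], "n_events": es["n"]})
    summaries["cytometry"] = pd.DataFrame(rows).set_index("group")

    config_snapshot = {"scenario": cfg, "seed": int(seed),
                       "constants": constants.as_dict()}
    return assemble_report(summaries, statistics, config_snapshot, outdir=outdir)
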