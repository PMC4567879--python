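"""End-to-end orchestration: generate or load a study, assemble and
aggregate local webs, compute properties, normalize by niche-model
ensembles (ME) and the power-law scaling fit (RV), and summarize every
representation per spatial scale with Tukey boxplot statistics.

Ensembles matched to the same (S, L) pair are generated once and reused
across webs, since connectance is determined by S and L.  All randomness
derives from a single integer seed through spawned child generators, so
a rerun with the same configuration is byte-identical.
"""
from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregation import aggregate_trophic_species
from .assembly import AssemblyConfig, assemble_collection, filter_by_richness
from .io_formats import (
    SCALE_ORDER,
    FoodWeb,
    WebCollection,
    read_catalogs,
    read_web,
    write_manifest,
)
from .metrics import ALL_PROPERTIES, STRUCTURAL_PROPERTIES, records_to_frame, structural_properties
from .niche import model_error, niche_ensemble
from .scaling import fit_scaling, residual_variation
from .synthetic import SyntheticConfig, generate_study

logger = logging.getLogger(__name__)


def tukey_summary(values: np.ndarray) -> dict[str, float]:
    """Tukey boxplot statistics: quartiles (linear interpolation), whiskers
    at the most extreme data within 1.5 IQR of the box, and outlier count."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return {k: np.nan for k in (
            "n", "mean", "median", "q1", "q3",
            "lower_whisker", "upper_whisker", "n_outliers")}
    q1, med, q3 = np.percentile(v, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "n": float(len(v)),
        "mean": float(np.mean(v)),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "lower_whisker": float(inside.min()),
        "upper_whisker": float(inside.max()),
        "n_outliers": float(len(v) - len(inside)),
    }


def summarize_by_scale(
    table: pd.DataFrame, representation: str, properties=None
) -> pd.DataFrame:
    """Per-scale Tukey summaries of a per-web value table.

    ``table`` must carry a ``scale_label`` column plus property columns.
    Scales with no webs are simply absent.  Returns one row per
    (scale, property).
    """
    if properties is None:
        properties = [c for c in table.columns if c in ALL_PROPERTIES]
    rows = []
    for scale, group in table.groupby("scale_label"):
        for prop in properties:
            stats = tukey_summary(group[prop].to_numpy(dtype=float))
            rows.append({"representation": representation,
                         "scale_label": scale, "property": prop, **stats})
    out = pd.DataFrame(rows)
    out["scale_order"] = out["scale_label"].map(SCALE_ORDER)
    return (
        out.sort_values(["property", "scale_order"])
        .drop(columns="scale_order")
        .reset_index(drop=True)
    )


_DEFAULTS: dict = {
    "seed": 0,
    "out": "pipeline_out",
    "synth": None,  # dict of SyntheticConfig overrides, or None when data given
    "data": None,   # {"metaweb": path, "catalogs": path, "ubiquitous": [...]}
    "assembly": {"min_trophic_species": 10, "iterate_drop": False},
    "ensembles": {"enabled": True, "n_webs": 1000, "c_tolerance": 0.05},
    "scaling": {"enabled": True, "min_webs": 10},
}


def _load_config(config: str | Path | Mapping) -> dict:
    if isinstance(config, (str, Path)):
        with Path(config).open(encoding="utf-8") as fh:
            config = yaml.safe_load(fh) or {}
    merged = {}
    for key, default in _DEFAULTS.items():
        value = config.get(key, default)
        if isinstance(default, dict) and isinstance(value, Mapping):
            value = {**default, **value}
        merged[key] = value
    return merged


def run_pipeline(config: str | Path | Mapping, out_dir: str | Path | None = None) -> Path:
    """Run the full analysis and write CSV outputs plus a run log.

    Outputs in the configured directory: ``properties.csv`` (per-web raw
    values), ``me.csv`` (niche-model errors), ``rv.csv`` (power-law
    residual variation), ``fits.csv`` (scaling coefficients),
    ``summary.csv`` (Tukey per-scale summaries for every representation),
    ``manifest.csv``, ``filter_report.csv``, and ``run.log``.
    """
    cfg = _load_config(config)
    out = Path(out_dir or cfg["out"])
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"trophoscale {__version__}", f"seed: {cfg['seed']}"]
    seed_seq = np.random.SeedSequence(int(cfg["seed"]))
    synth_seq, ensemble_seq = seed_seq.spawn(2)

    # --- inputs: synthetic study or real files -------------------------
    if cfg["data"]:
        metaweb = read_web(cfg["data"]["metaweb"], web_id="metaweb")
        catalogs = read_catalogs(cfg["data"]["catalogs"])
        ubiquitous = frozenset(cfg["data"].get("ubiquitous", ()))
        log_lines.append(f"data: metaweb S={metaweb.S} L={metaweb.L}, "
                         f"{len(catalogs)} catalogs")
    else:
        synth_cfg = SyntheticConfig(**(cfg["synth"] or {}))
        study = generate_study(
            synth_cfg, np.random.default_rng(synth_seq), out_dir=out / "synth"
        )
        metaweb, catalogs = study.metaweb, study.catalogs
        ubiquitous = frozenset(study.ubiquitous_taxa)
        log_lines.append(
            f"synthetic study: metaweb S={metaweb.S} L={metaweb.L}, "
            f"{len(catalogs)} catalogs, {len(ubiquitous)} ubiquitous taxa"
        )

    # --- assemble, aggregate, filter ----------------------------------
    asm_cfg = AssemblyConfig(
        ubiquitous_taxa=ubiquitous,
        min_trophic_species=int(cfg["assembly"]["min_trophic_species"]),
        iterate_drop=bool(cfg["assembly"]["iterate_drop"]),
    )
    collection = assemble_collection(metaweb, catalogs, asm_cfg)
    n_empty = int(collection.manifest["empty"].sum())
    filtered, report = filter_by_richness(collection, asm_cfg.min_trophic_species)
    report.to_csv(out / "filter_report.csv", index=False)
    write_manifest(collection.manifest, out / "manifest.csv")
    log_lines.append(
        f"assembled {len(collection)} webs ({n_empty} empty); "
        f"{len(filtered)} webs with >= {asm_cfg.min_trophic_species} trophic species"
    )

    trophic = [aggregate_trophic_species(w).web for w in filtered.webs]

    # --- properties ----------------------------------------------------
    records = [structural_properties(w) for w in trophic]
    props = records_to_frame(records)
    props.to_csv(out / "properties.csv", index=False)
    log_lines.append(f"properties computed for {len(props)} webs")

    summaries = [summarize_by_scale(props, "raw")]

    # --- niche ensembles and model error -------------------------------
    if cfg["ensembles"]["enabled"]:
        n_webs = int(cfg["ensembles"]["n_webs"])
        tol = float(cfg["ensembles"]["c_tolerance"])
        rng = np.random.default_rng(ensemble_seq)
        cache: dict[tuple[int, int], object] = {}
        me_rows = []
        for rec, web in zip(records, trophic):
            key = (web.S, web.L)
            if key not in cache:
                c = web.L / web.S**2
                if not 0 < c < 0.5:
                    cache[key] = None  # outside the niche model's domain
                    logger.warning("web %s: C=%.3f outside (0, 0.5); ME skipped",
                                   web.web_id, c)
                else:
                    try:
                        cache[key] = niche_ensemble(
                            web.S, c, n_webs, rng,
                            c_tolerance=tol, keep_samples=False,
                        )
                    except ValueError as exc:  # e.g. too sparse to connect
                        cache[key] = None
                        logger.warning("web %s: %s; ME skipped", web.web_id, exc)
            if cache[key] is None:
                me = {}
            else:
                me = model_error(rec, cache[key])
            me_rows.append({"web_id": rec.web_id, "scale_label": rec.scale_label,
                            **{p: me.get(p) for p in STRUCTURAL_PROPERTIES}})
        me_df = pd.DataFrame(me_rows)
        me_df.to_csv(out / "me.csv", index=False)
        summaries.append(summarize_by_scale(me_df, "ME",
                                            properties=STRUCTURAL_PROPERTIES))
        log_lines.append(
            f"niche ensembles: {len(cache)} distinct (S, L) pairs x {n_webs} webs"
        )

    # --- power-law scaling and residual variation ----------------------
    if cfg["scaling"]["enabled"]:
        fit_df = props.set_index("web_id")
        fit = fit_scaling(fit_df, min_webs=int(cfg["scaling"]["min_webs"]))
        fit.coefficients_frame().to_csv(out / "fits.csv", index=False)
        rv = residual_variation(fit, fit_df)
        rv_df = rv.reset_index()
        rv_df.insert(1, "scale_label", fit_df["scale_label"].to_numpy())
        rv_df.to_csv(out / "rv.csv", index=False)
        summaries.append(summarize_by_scale(
            rv_df, "RV", properties=list(fit.fits)))
        log_lines.append(f"scaling fits: {len(fit.fits)} properties")

    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(out / "summary.csv", index=False)
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return out
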