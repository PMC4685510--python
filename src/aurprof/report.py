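"""Pipeline orchestration: run the three stages from one config.

``run_all`` executes the requested stages -- biochemical Ki estimation,
image-based cellular potency, live-imaging event statistics -- and writes a
report bundle to the output directory:

* ``ki_table.csv`` and ``selectivity.csv`` (Ki means +/- SD and fold ratios),
* ``cellular_curves.csv`` and ``cellular_potency.csv`` (normalized curves
  and IC50 / NE@X / %Inh@X classifications),
* ``live_summary.csv`` and ``live_fits.csv`` (per-dose event statistics
  and their 4PL parameters),
* ``provenance.json`` (config hash, seed, package versions),
* ``errors.json`` when a stage fails (the bundle is then partial).

Identical config + seed produces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cellular import analyze_dose_series, classify_potency
from .enzymology import (
    TightBindingContext,
    aggregate_ki,
    compute_selectivity_ratios,
    fit_four_parameter_logistic,
    ic50_to_ki,
)
from .io import write_ki_table, write_selectivity_table
from .live_events import fit_event_dose_response, summarize_cytokinesis, summarize_g2
from .synthdata import BiochemSpec, ImagingSpec, LiveSpec, render_image_field, simulate_biochem_plate, simulate_tracks

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger(__name__)

#: default enzyme-pair orientation of the selectivity table
DEFAULT_PAIRS = (
    ("AurA", "AurA-TPX2"),
    ("AurA", "AurB-INCENP"),
    ("AurA-TPX2", "AurB-INCENP"),
    ("AurB-INCENP", "AurA"),
    ("AurB-INCENP", "AurA-TPX2"),
)


@dataclass(frozen=True)
class RunConfig:
    """One config drives all stages; simulation specs stand in for raw data.

    ``biochem`` maps compound -> enzyme -> :class:`BiochemSpec`; each pair is
    simulated ``n_experiments`` times and aggregated.  ``contexts`` supplies
    the per-enzyme ([E]t, [S], Km) conversion triples (derived from the
    specs when omitted).  ``imaging``/``live`` carry the generator settings
    and dose grids for the cellular and live stages.
    """

    seed: int
    out_dir: str
    stages: tuple = ("biochem", "cellular", "live")
    biochem: dict = field(default_factory=dict)
    contexts: dict = field(default_factory=dict)
    n_experiments: int = 3
    ratio_pairs: tuple = DEFAULT_PAIRS
    imaging: ImagingSpec = field(default_factory=ImagingSpec)
    imaging_doses: tuple = (30.0, 100.0, 300.0, 600.0, 1000.0, 3000.0, 9000.0, 30000.0)
    live: LiveSpec = field(default_factory=LiveSpec)
    live_doses: tuple = (50.0, 150.0, 400.0, 800.0, 1600.0, 4000.0, 10000.0)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return float(o)
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()


def _context_for(config: RunConfig, enzyme: str, spec: BiochemSpec) -> TightBindingContext:
    if enzyme in config.contexts:
        return config.contexts[enzyme]
    # S and Km only enter through their ratio; 35 uM is a typical Km(ATP)
    km = 35.0
    return TightBindingContext(Et=spec.Et, S=km * spec.s_over_km, Km=km)


def _run_biochem(config: RunConfig, rng: np.random.Generator, out: Path) -> dict:
    ki_table: dict = {}
    for compound, per_enzyme in config.biochem.items():
        ki_table[compound] = {}
        for enzyme, spec in per_enzyme.items():
            ctx = _context_for(config, enzyme, spec)
            conversions = []
            for _ in range(config.n_experiments):
                seed = int(rng.integers(0, 2**31 - 1))
                ds, _truth = simulate_biochem_plate(
                    spec, seed, compound_id=compound, assay_id=enzyme)
                fit = fit_four_parameter_logistic(ds)
                conversions.append(
                    ic50_to_ki(fit.ic50, ctx, ic50_se=fit.ic50_se))
            ki_table[compound][enzyme] = aggregate_ki(conversions)
    write_ki_table(ki_table, out / "ki_table.csv")
    ratios = compute_selectivity_ratios(ki_table, config.ratio_pairs)
    write_selectivity_table(ratios, out / "selectivity.csv")
    return {"n_compounds": len(ki_table)}


def _run_cellular(config: RunConfig, rng: np.random.Generator, out: Path) -> dict:
    spec = config.imaging
    fields_by_dose = {}
    for dose in (0.0, *config.imaging_doses):
        fields_by_dose[dose] = [
            render_image_field(spec, dose, int(rng.integers(0, 2**31 - 1)),
                               well=f"dose-{dose:g}", field_id=str(i))[0]
            for i in range(spec.fields_per_dose)
        ]
    curves, summaries, _params = analyze_dose_series(fields_by_dose)
    curve_rows, potency_rows = [], []
    for marker, curve in curves.items():
        for d, v in zip(curve.doses, curve.values):
            curve_rows.append(dict(marker=marker, dose_nM=d, normalized=v))
        res = classify_potency(curve)
        potency_rows.append(dict(
            marker=marker, classification=res.classification,
            ic50_nM=res.ic50, top_dose_nM=res.top_dose,
            pct_inhibition_at_top=res.percent_inhibition_at_top,
            label=res.label()))
    pd.DataFrame(curve_rows).to_csv(out / "cellular_curves.csv", index=False)
    pd.DataFrame(potency_rows).to_csv(out / "cellular_potency.csv", index=False)
    return {"n_doses": len(fields_by_dose)}


def _run_live(config: RunConfig, rng: np.random.Generator, out: Path) -> dict:
    spec = config.live
    rows, fit_rows = [], []
    for assay, summarize in (("g2", summarize_g2),
                             ("cytokinesis", summarize_cytokinesis)):
        tracks = []
        for dose in (0.0, *config.live_doses):
            t, _truth = simulate_tracks(spec, dose, int(rng.integers(0, 2**31 - 1)),
                                        assay)
            tracks.extend(t)
        per_dose = summarize(tracks)
        for dose, value in per_dose.items():
            rows.append(dict(assay=assay, dose_nM=dose, statistic=value))
        fit = fit_event_dose_response(per_dose)
        fit_rows.append(dict(assay=assay, ic50_nM=fit.ic50, top=fit.top,
                             bottom=fit.bottom, hill=fit.hill_slope,
                             no_effect=fit.no_effect))
    pd.DataFrame(rows).to_csv(out / "live_summary.csv", index=False)
    pd.DataFrame(fit_rows).to_csv(out / "live_fits.csv", index=False)
    return {"n_assays": 2}


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns a manifest dict with per-stage status and counts; stage
    failures are captured in ``errors.json`` and the manifest rather than
    raised, so a partial bundle is still written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "errors": {}}
    runners = {"biochem": _run_biochem, "cellular": _run_cellular,
               "live": _run_live}
    for i, stage in enumerate(config.stages):
        if stage not in runners:
            raise ValueError(f"unknown stage {stage!r}")
        # independent per-stage seed streams: order of stages does not
        # change any one stage's data
        rng = np.random.default_rng([config.seed, i])
        t0 = time.perf_counter()
        try:
            info = runners[stage](config, rng, out)
            manifest["stages"][stage] = {
                "status": "ok", "seconds": round(time.perf_counter() - t0, 3),
                **info}
        except Exception as exc:  # noqa: BLE001 -- machine-readable manifest
            log.exception("stage %s failed", stage)
            manifest["stages"][stage] = {"status": "failed"}
            manifest["errors"][stage] = f"{type(exc).__name__}: {exc}"
    provenance = {
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "aurprof_version": __version__,
        "numpy_version": np.__version__,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    if manifest["errors"]:
        (out / "errors.json").write_text(json.dumps(manifest["errors"], indent=2))
    return manifest
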