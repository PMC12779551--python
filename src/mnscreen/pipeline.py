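"""Stage orchestration: run pipeline stages and record a manifest.

Each stage reads the tidy-CSV artifacts of earlier stages (or fresh
inputs), writes its own outputs into the run directory and appends itself
to ``manifest.json`` (stages, inputs, outputs, seed, config hash,
versions). Outputs carry no timestamps, so a rerun with the same config
and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .calcium import DetectConfig, FluorTrace, analyze_trace, summarize_rois
from .exceptions import InputError, MnscreenError
from .imagequant import QuantConfig, measure_field, read_field
from .io import (
    read_well_series,
    write_donor_phenotypes,
    write_well_phenotypes,
    write_well_series,
)
from .phenocurves import QCConfig, aggregate_donor, compute_phenotype
from .screen import days_of_rescue, summarize_screen
from .statsreport import SurvivalRecord, km_curve, logrank_test
from .synthgen import SimPlateConfig, simulate_plate

log = logging.getLogger("mnscreen")

STAGES = ("simulate", "quantify", "phenotype", "screen", "calcium", "report")


@dataclass
class RunConfig:
    """Paths plus per-stage configuration for one pipeline run."""

    out_dir: Path
    well_series_path: Optional[Path] = None
    image_dir: Optional[Path] = None
    traces_path: Optional[Path] = None
    pixel_size_um: float = 1.0
    sampling_rate: float = 10.0
    plate: SimPlateConfig = field(default_factory=SimPlateConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    rescue_cap_days: float = 5.0
    responder_threshold_days: float = 10.0
    seed: int = 0
    log_level: str = "INFO"


_PATH_FIELDS = ("out_dir", "well_series_path", "image_dir", "traces_path")


def _config_hash(cfg: RunConfig) -> str:
    # hash the analysis configuration, not where it ran
    payload = {k: v for k, v in asdict(cfg).items() if k not in _PATH_FIELDS}
    blob = json.dumps(payload, default=str, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, stages: Sequence[str]) -> Dict:
    """Run the requested stages in canonical order; returns the manifest.

    A stage failure raises :class:`MnscreenError` naming the stage (the
    CLI converts this into a nonzero exit status).
    """
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise InputError(f"unknown stage(s): {unknown}")
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: Dict = {
        "tool": "mnscreen",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "stages": [],
    }
    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("running stage %s", stage)
        try:
            outputs = _STAGE_FUNCS[stage](cfg, out)
        except MnscreenError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise MnscreenError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append({"name": stage, "outputs": outputs})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(cfg: RunConfig, out: Path) -> List[str]:
    plate_cfg = cfg.plate
    plate_cfg.seed = cfg.seed
    layout, series, truth = simulate_plate(plate_cfg)
    write_well_series(series, out / "well_series.csv")
    layout.wells.to_csv(out / "plate_layout.csv", index=False)
    truth.to_csv(out / "ground_truth.csv", index=False)
    return ["well_series.csv", "plate_layout.csv", "ground_truth.csv"]


def _stage_quantify(cfg: RunConfig, out: Path) -> List[str]:
    if cfg.image_dir is None or not Path(cfg.image_dir).is_dir():
        raise InputError(f"stage 'quantify': image directory not found: {cfg.image_dir}")
    tiffs = sorted(Path(cfg.image_dir).glob("*.tif*"))
    if not tiffs:
        raise InputError(f"stage 'quantify': no TIFF files in {cfg.image_dir}")
    rows = []
    for path in tiffs:
        img = read_field(path, cfg.pixel_size_um, well_id=path.stem)
        seg = measure_field(img, cfg.quant)
        rows.append(
            {
                "well": path.stem,
                "field": 1,
                "total_length_um": seg.total_length_um,
                "soma_count": seg.soma_count,
            }
        )
    pd.DataFrame(rows).to_csv(out / "field_quant.csv", index=False)
    return ["field_quant.csv"]


def _well_phenotypes(cfg: RunConfig, out: Path):
    path = cfg.well_series_path or out / "well_series.csv"
    if not Path(path).is_file():
        raise InputError(f"stage 'phenotype': well-series CSV not found: {path}")
    series = read_well_series(path)
    return [compute_phenotype(s, cfg.qc) for s in series]


def _stage_phenotype(cfg: RunConfig, out: Path) -> List[str]:
    phenos = _well_phenotypes(cfg, out)
    write_well_phenotypes(phenos, out / "well_phenotypes.csv")
    donors = []
    by_donor: Dict[tuple, list] = {}
    for p in phenos:
        by_donor.setdefault((p.donor_id, p.treatment), []).append(p)
    for (_, _), group in sorted(
        by_donor.items(), key=lambda kv: (kv[0][0], kv[0][1] or "")
    ):
        try:
            donors.append(aggregate_donor(group))
        except MnscreenError:
            continue  # donor excluded: fewer than the required passing wells
    write_donor_phenotypes(donors, out / "donor_phenotypes.csv")
    return ["well_phenotypes.csv", "donor_phenotypes.csv"]


def _stage_screen(cfg: RunConfig, out: Path) -> List[str]:
    path = out / "donor_phenotypes.csv"
    if not path.is_file():
        raise InputError(f"stage 'screen': donor phenotypes not found: {path}")
    donors = pd.read_csv(path, keep_default_na=False)
    donors["treatment"] = donors["treatment"].replace("", "DMSO")
    pivot = donors.pivot_table(
        index="donor_id", columns="treatment", values="mean_ld50"
    )
    if "DMSO" not in pivot.columns or pivot.shape[1] < 2:
        raise InputError("stage 'screen': need DMSO plus ≥1 treatment")
    rescue = pivot.drop(columns=[]).copy()
    for col in rescue.columns:
        rescue[col] = [
            days_of_rescue(t, d) if pd.notna(t) and pd.notna(d) else float("nan")
            for t, d in zip(pivot[col], pivot["DMSO"])
        ]
    rescue.to_csv(out / "rescue_table.csv")
    summary = summarize_screen(rescue, reference="DMSO")
    payload = {
        "n_tested": summary.n_tested,
        "n_effective": summary.n_effective,
        "percent_failed": summary.percent_failed,
        "omnibus_h": summary.omnibus_h,
        "omnibus_p": summary.omnibus_p,
        "per_drug": summary.per_drug.to_dict(orient="records"),
    }
    (out / "screen_summary.json").write_text(json.dumps(payload, indent=2))
    return ["rescue_table.csv", "screen_summary.json"]


def _stage_calcium(cfg: RunConfig, out: Path) -> List[str]:
    if cfg.traces_path is None or not Path(cfg.traces_path).is_file():
        raise InputError(f"stage 'calcium': traces CSV not found: {cfg.traces_path}")
    wide = pd.read_csv(cfg.traces_path, comment="#")
    roi_cols = [c for c in wide.columns if c.lower() != "time"]
    if not roi_cols:
        raise InputError("stage 'calcium': no ROI columns in traces CSV")
    event_sets = [
        analyze_trace(
            FluorTrace(c, wide[c].to_numpy(float), cfg.sampling_rate), cfg.detect
        )
        for c in roi_cols
    ]
    rows = [
        {
            "roi_id": e.roi_id,
            "n_events": len(e.event_onsets),
            "frequency_hz": e.frequency,
            "mean_amplitude_dff": e.mean_amplitude,
            "threshold_dff": e.threshold_used,
        }
        for e in event_sets
    ]
    pd.DataFrame(rows).to_csv(out / "calcium_events.csv", index=False)
    (out / "calcium_summary.json").write_text(
        json.dumps(summarize_rois(event_sets), indent=2)
    )
    return ["calcium_events.csv", "calcium_summary.json"]


def _stage_report(cfg: RunConfig, out: Path) -> List[str]:
    path = out / "donor_phenotypes.csv"
    if not path.is_file():
        raise InputError(f"stage 'report': donor phenotypes not found: {path}")
    donors = pd.read_csv(path, keep_default_na=False)
    untreated = donors[donors["treatment"].isin(["", "DMSO"])]
    endpoint = cfg.plate.day_range[1]
    records = {
        g: [
            SurvivalRecord(
                row.donor_id,
                row.mean_ld50,
                event=row.mean_ld50 < endpoint,
                group=g,
            )
            for row in sub.itertuples()
        ]
        for g, sub in untreated.groupby("group")
    }
    report: Dict = {"groups": {}}
    for g, recs in records.items():
        curve = km_curve(recs)
        report["groups"][g] = {
            "n": len(recs),
            "mean_ld50": float(np.mean([r.ld50_day for r in recs])),
            "km_days": curve.days.tolist(),
            "km_survival": curve.survival.tolist(),
        }
    if {"control", "SALS"} <= set(records):
        chi2, p = logrank_test(records["control"], records["SALS"])
        report["logrank_control_vs_SALS"] = {"chi2": chi2, "p": p}
    (out / "stats_report.json").write_text(json.dumps(report, indent=2))
    return ["stats_report.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "phenotype": _stage_phenotype,
    "screen": _stage_screen,
    "calcium": _stage_calcium,
    "report": _stage_report,
}
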