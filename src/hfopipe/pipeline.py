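"""End-to-end orchestration: analyze, simulate, benchmark.

The pipeline stages mirror an HFO reading session: preprocess and
re-reference the recording, screen channels, detect candidate events,
transform each into a scalogram, label it, build occurrence-rate tables
and the volumetric heatmap, and — when SOZ labels are supplied — measure
SOZ concordance.  A manifest with the config hash and seed accompanies
every run so outputs are bit-reproducible.
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

from . import channel_select, evaluation, imaging, seeg_io
from .classifier import ReferenceClassifier, classify_events
from .detector import DetectorConfig, candidates_to_frame, detect_candidates
from .scalogram import ScalogramConfig, event_scalogram
from .simulator import SimConfig, simulate_benchmark

__all__ = ["PipelineConfig", "run_analyze", "run_benchmark", "run_simulate",
           "config_from_dict"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    recording: str | None = None
    contacts: str | None = None
    brain_mask: str | None = None
    gray_mask: str | None = None
    gray_mask_threshold: float = 0.4
    soz_labels: str | None = None
    output_dir: str = "hfopipe_out"
    seed: int = 0
    log_level: str = "INFO"
    notch_base: float = 50.0
    notch_max_harmonic: float = 450.0
    rms_percentile: float = 35.0
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    scalogram: ScalogramConfig = field(default_factory=ScalogramConfig)
    simulation: SimConfig = field(default_factory=SimConfig)


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        coerced[f.name] = v
    return cls(**coerced)


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a PipelineConfig from a parsed YAML/JSON mapping; unknown keys reject."""
    data = dict(data)
    sub = {}
    for key, cls in (("detector", DetectorConfig), ("scalogram", ScalogramConfig),
                     ("simulation", SimConfig)):
        if key in data:
            sub[key] = _build(cls, data.pop(key))
    cfg = _build(PipelineConfig, data)
    for key, val in sub.items():
        setattr(cfg, key, val)
    return cfg


def _config_hash(cfg) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(outdir: Path, cfg, extra: dict | None = None) -> None:
    manifest = {"config_hash": _config_hash(cfg), "seed": cfg.seed,
                "config": dataclasses.asdict(cfg)}
    manifest.update(extra or {})
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n")


def run_analyze(cfg: PipelineConfig) -> dict:
    """Full analysis of one recording; returns the in-memory artifacts.

    Writes to cfg.output_dir: channel_selection.tsv, candidates.tsv,
    labels.tsv, rates.tsv, heatmap.nii.gz (if a brain mask is given),
    soz_roc.csv + soz_summary.json (if SOZ labels are given) and
    manifest.json.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, p in (("recording", cfg.recording), ("contacts", cfg.contacts)):
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"missing required input: {name} ({p})")

    rec = seeg_io.read_recording(cfg.recording)
    contacts = seeg_io.read_contacts(cfg.contacts)
    rec = seeg_io.notch_filter(rec, cfg.notch_base, cfg.notch_max_harmonic)
    bip, channels = seeg_io.make_bipolar(rec, contacts)

    brain_mask = gray_mask = None
    if cfg.brain_mask:
        brain_mask = seeg_io.read_volume(cfg.brain_mask, "brain_mask")
    if cfg.gray_mask:
        gray_mask = seeg_io.read_volume(cfg.gray_mask, "gray_mask",
                                        mask_threshold=cfg.gray_mask_threshold)
    report = channel_select.select_channels(
        bip, channels, brain_mask, gray_mask, rms_percentile=cfg.rms_percentile)
    report.to_csv(outdir / "channel_selection.tsv", sep="\t", index=False)
    logger.info("channel selection: %d/%d included",
                int(report["included"].sum()), len(report))

    included = report.loc[report["included"], "channel"].tolist()
    name_to_row = {n: i for i, n in enumerate(bip.channel_names)}
    model = ReferenceClassifier()
    all_cands, labels_by_channel = [], {}
    for ch in included:
        x = bip.data[name_to_row[ch]]
        cands = detect_candidates(x, bip.fs, cfg.detector, channel=ch)
        sgs = [event_scalogram(x, bip.fs, ev.t_peak, cfg.scalogram)
               for ev in cands]
        labels = classify_events(sgs, model)
        for ev, lab in zip(cands, labels):
            ev.label = lab
        all_cands.extend(cands)
        labels_by_channel[ch] = labels
    cand_df = candidates_to_frame(all_cands)
    if len(cand_df):
        cand_df["category"] = [ev.label.category for ev in all_cands]
        cand_df["qhfo"] = [ev.label.qhfo for ev in all_cands]
    cand_df.to_csv(outdir / "candidates.tsv", sep="\t", index=False)

    from .classifier import labels_to_frame
    label_df = labels_to_frame([ev.label for ev in all_cands])
    if len(label_df):
        label_df.insert(1, "channel", [ev.channel for ev in all_cands])
    label_df.to_csv(outdir / "labels.tsv", sep="\t", index=False)

    duration_min = rec.duration / 60.0
    rates = imaging.build_rate_table(labels_by_channel, duration_min)
    rates.to_csv(outdir / "rates.tsv", sep="\t")

    artifacts = {"channel_report": report, "candidates": cand_df,
                 "rates": rates, "recording": bip, "bipolar_channels": channels}

    if brain_mask is not None:
        heat = imaging.rates_to_volume(rates, channels, brain_mask)
        heat = imaging.smooth_volume(heat)
        seeg_io.write_volume(heat, outdir / "heatmap.nii.gz")
        artifacts["heatmap"] = heat

    if cfg.soz_labels:
        soz = [l.strip() for l in Path(cfg.soz_labels).read_text().splitlines()
               if l.strip()]
        result = evaluation.soz_roc_auc(rates["qhfo_rate"], soz)
        result.roc.to_csv(outdir / "soz_roc.csv", index=False)
        (outdir / "soz_summary.json").write_text(json.dumps(
            {"auc": result.auc, "n_soz": len(result.soz)}, indent=2) + "\n")
        artifacts["soz"] = result

    _write_manifest(outdir, cfg, {"n_candidates": len(cand_df)})
    return artifacts


def run_simulate(cfg: SimConfig, outdir: str | Path) -> dict:
    """Generate the benchmark dataset and write it as EDF + ground-truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rec, truth = simulate_benchmark(cfg)
    seeg_io.write_recording(rec, outdir / "simulated.edf")
    truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    return {"recording": rec, "truth": truth}


def run_benchmark(cfg: SimConfig, outdir: str | Path | None = None,
                  detector_cfg: DetectorConfig = DetectorConfig()) -> dict:
    """Simulate, detect and score; returns per-channel scores + per-SNR summary.

    The summary mirrors the benchmark reporting convention: median and
    range of sensitivity, precision and F1 per SNR level, in percent.
    """
    rec, truth = simulate_benchmark(cfg)
    scores, snr_of = [], {}
    for i, ch in enumerate(rec.channel_names):
        cands = detect_candidates(rec.data[i], rec.fs, detector_cfg, channel=ch)
        peaks = np.array([ev.t_peak for ev in cands])
        sub = truth[truth["channel"] == ch]
        scores.append(evaluation.score_detections(peaks, sub, channel=ch))
        snr_of[ch] = float(sub["snr_db"].iloc[0])
    summary = evaluation.summarize_benchmark(scores, snr_of)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        per_channel = pd.DataFrame([{
            "channel": s.channel, "snr_db": snr_of[s.channel], "tp": s.tp,
            "fp": s.fp, "fn": s.fn, "sensitivity": s.sensitivity,
            "precision": s.precision, "f1": s.f1} for s in scores])
        per_channel.to_csv(outdir / "benchmark_channels.tsv", sep="\t",
                           index=False)
        summary.to_csv(outdir / "benchmark_summary.tsv", sep="\t", index=False)
        (outdir / "benchmark_summary.json").write_text(
            summary.to_json(orient="records", indent=2) + "\n")
    return {"scores": scores, "summary": summary, "snr_of": snr_of,
            "truth": truth}
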