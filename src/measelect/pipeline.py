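"""End-to-end pipeline: simulate/detect -> features -> selectivity -> classify.

Each stage writes its outputs into the run directory together with a
provenance manifest (seed, config hash, library versions).  On a rerun with
an unchanged config hash, stages whose outputs already exist are skipped.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import __version__
from .classification import build_feature_matrix, kmeans_classify, kmeans_pc_classify, svc_classify
from .config import PipelineConfig, config_hash
from .detection import detect_spikes
from .features import build_filter_report, extract_patterns, population_psth
from .selectivity import build_signatures
from .synthetic import generate_recording
from . import io

log = logging.getLogger("measelect")

STAGE_OUTPUTS = {
    "simulate": ["spikes.csv", "stims.csv", "ground_truth.json"],
    "detect": ["spikes.csv"],
    "features": ["patterns.h5", "filter_report.json", "psth.csv"],
    "selectivity": [
        "selectivity_signature.csv", "overlap_signature.csv", "selectivity_summary.json",
    ],
    "classify": ["classification_report.json"],
}


def _versions() -> dict:
    import scipy
    import sklearn

    return {
        "measelect": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
    }


def _stage_done(out: Path, stage: str, manifest: dict, cfg_hash: str) -> bool:
    prior = manifest.get("stages", {}).get(stage)
    if prior != cfg_hash:
        return False
    return all((out / f).exists() for f in STAGE_OUTPUTS[stage])


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every applicable stage; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(cfg)
    manifest_path = out / "manifest.json"
    manifest = io.read_json(manifest_path) if manifest_path.exists() else {}
    manifest.update({"seed": cfg.seed, "config_hash": cfg_hash, "versions": _versions()})
    manifest.setdefault("stages", {})

    def finish(stage: str) -> None:
        manifest["stages"][stage] = cfg_hash
        io.write_json(manifest, manifest_path)

    def fail(stage: str, exc: Exception) -> None:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- acquire spike trains ------------------------------------------------
    if cfg.spikes_path:
        stage = "ingest"
        spikes = io.read_spikes_csv(cfg.spikes_path, n_electrodes=cfg.geometry.n_electrodes)
        stims = io.read_stims_csv(cfg.stims_path, allowed_sites=cfg.protocol.site_labels)
        log.info("loaded spike trains from %s; detection skipped", cfg.spikes_path)
    elif cfg.raw_path:
        stage = "detect"
        if not _stage_done(out, stage, manifest, cfg_hash):
            try:
                raw = io.read_raw_h5(cfg.raw_path)
                stims = io.read_stims_csv(cfg.stims_path, allowed_sites=cfg.protocol.site_labels)
                spikes = detect_spikes(raw, cfg.detection, stims)
                io.write_spikes_csv(spikes, out / "spikes.csv")
            except Exception as exc:
                fail(stage, exc)
            finish(stage)
        else:
            log.info("stage detect up to date; skipping")
            spikes = io.read_spikes_csv(out / "spikes.csv", n_electrodes=cfg.geometry.n_electrodes)
            stims = io.read_stims_csv(cfg.stims_path, allowed_sites=cfg.protocol.site_labels)
    else:
        stage = "simulate"
        if not _stage_done(out, stage, manifest, cfg_hash):
            try:
                model = cfg.build_model()
                spikes, stims, truth = generate_recording(
                    cfg.geometry, cfg.protocol, model, seed=cfg.seed
                )
                io.write_spikes_csv(spikes, out / "spikes.csv")
                io.write_stims_csv(stims, out / "stims.csv")
                io.write_ground_truth(truth, out / "ground_truth.json")
            except Exception as exc:
                fail(stage, exc)
            finish(stage)
        else:
            log.info("stage simulate up to date; skipping")
        spikes = io.read_spikes_csv(
            out / "spikes.csv", n_electrodes=cfg.geometry.n_electrodes
        )
        stims = io.read_stims_csv(out / "stims.csv", allowed_sites=cfg.protocol.site_labels)

    # --- features ------------------------------------------------------------
    if not _stage_done(out, "features", manifest, cfg_hash):
        try:
            patterns = extract_patterns(spikes, stims, cfg.window)
            report = build_filter_report(
                patterns, stationarity_alpha=0.05, per_site=True
            )
            io.write_patterns_h5(
                patterns, out / "patterns.h5", cfg.window,
                metadata={"seed": cfg.seed, "config_hash": cfg_hash},
            )
            io.write_json(
                {"config_hash": cfg_hash, "seed": cfg.seed, **report.to_dict()},
                out / "filter_report.json",
            )
            psth = population_psth(patterns, mode="mean")
            np.savetxt(
                out / "psth.csv", psth[None, :], delimiter=",", fmt="%.4f",
                header=",".join(f"bin{b + 1}" for b in range(len(psth))), comments="",
            )
        except Exception as exc:
            fail("features", exc)
        finish("features")
    else:
        log.info("stage features up to date; skipping")
        patterns, _ = io.read_patterns_h5(out / "patterns.h5")
        report = build_filter_report(patterns, stationarity_alpha=0.05, per_site=True)

    # --- selectivity ---------------------------------------------------------
    if not _stage_done(out, "selectivity", manifest, cfg_hash):
        try:
            sel, ov = build_signatures(
                patterns, report, feature="bin_rate",
                alpha=cfg.alpha_bin, random_state=cfg.kmeans_seed, window=cfg.window,
            )
            io.write_signature_csv(sel, out / "selectivity_signature.csv")
            io.write_signature_csv(ov, out / "overlap_signature.csv")
            defined = ov.overlaps[ov.valid]
            summary = {
                "config_hash": cfg_hash,
                "seed": cfg.seed,
                "alpha": cfg.alpha_bin,
                "n_eligible_cells": int(sel.valid.sum()),
                "n_selective_cells": int(sel.flags.sum()),
                "mean_overlap": float(np.mean(defined)) if defined.size else None,
                "min_overlap": float(np.min(defined)) if defined.size else None,
            }
            io.write_json(summary, out / "selectivity_summary.json")
        except Exception as exc:
            fail("selectivity", exc)
        finish("selectivity")
    else:
        log.info("stage selectivity up to date; skipping")

    # --- classification ------------------------------------------------------
    if not _stage_done(out, "classify", manifest, cfg_hash):
        try:
            reports = []
            for feature in cfg.classifier_features:
                fm = build_feature_matrix(patterns, feature=feature, window=cfg.window)
                for method in cfg.classifier_methods:
                    if method == "kmeans":
                        rep = kmeans_classify(fm, random_state=cfg.kmeans_seed)
                    elif method == "kmeans_pc":
                        rep = kmeans_pc_classify(fm, random_state=cfg.kmeans_seed)
                    elif method == "svc":
                        rep = svc_classify(fm, folds=cfg.svc_folds, random_state=cfg.kmeans_seed)
                    else:
                        raise ValueError(f"unknown classifier method {method!r}")
                    reports.append(rep.to_dict())
            io.write_json(
                {"config_hash": cfg_hash, "seed": cfg.seed, "reports": reports},
                out / "classification_report.json",
            )
        except Exception as exc:
            fail("classify", exc)
        finish("classify")
    else:
        log.info("stage classify up to date; skipping")

    return manifest
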