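"""End-to-end pipeline: simulate -> preprocess -> detect -> stats -> classify.

``run_pipeline`` composes the stages, writes all outputs as plain text /
JSON into an output directory and records provenance (configuration hash,
seeds, package versions, per-stage counts) so every result file can be
reproduced from its config.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import SubsampledSVMClassifier, build_features
from .io import PipelineConfig, config_hash, config_to_dict, write_json, write_table
from .model import LatencyModulation
from .oculosim import CohortDataset, simulate_cohort
from .preprocess import preprocess_trace
from .saccades import (
    DetectionConfig,
    LatencyConfig,
    detect,
    qc_summary,
    records_to_table,
    saccadic_latency,
)

logger = logging.getLogger(__name__)


def extract_latencies(dataset: CohortDataset,
                      detection: DetectionConfig | None = None,
                      validity: LatencyConfig | None = None,
                      *, ceiling_deg_s: float = 750.0,
                      window_ms: float = 20.0,
                      guard_samples: int = 2) -> pd.DataFrame:
    """Run preprocessing, detection and latency extraction over a cohort."""
    detection = detection or DetectionConfig()
    validity = validity or LatencyConfig(
        target_eccentricity_deg=dataset.config.geometry.target_eccentricity_deg)
    records = []
    for subj in dataset.subjects:
        if not subj.traces:
            raise ValueError(
                "dataset has no traces; simulate with include_traces=True")
        for trace, event in zip(subj.traces, subj.events):
            vel = preprocess_trace(trace, ceiling_deg_s=ceiling_deg_s,
                                   window_ms=window_ms, guard_samples=guard_samples)
            events = detect(vel, detection)
            records.append(saccadic_latency(events, event, validity,
                                            group=subj.params.group))
    return records_to_table(records)


def run_pipeline(config: PipelineConfig | None = None, out_dir=None,
                 *, iterations: int | None = None,
                 schemes: tuple[str, ...] = ("P_vs_C", "P_vs_RC", "PR_vs_C")) -> dict:
    """Execute the full pipeline under ``config``.

    Writes ``latency_table.tsv``, ``qc_summary.tsv``, ``stats.json``,
    ``classification.json``, ``summary.txt`` and ``provenance.json`` into
    ``out_dir`` (if given) and returns the results bundle.  ``iterations``
    overrides the configured Monte Carlo count (desk-scale runs use ~1e4
    instead of the full 5e6).
    """
    config = config or PipelineConfig()
    chash = config_hash(config)
    cohort_cfg = config.cohort
    if cohort_cfg.seed != config.seed:
        import dataclasses
        cohort_cfg = dataclasses.replace(cohort_cfg, seed=config.seed)

    logger.info("stage=simulate hash=%s seed=%d", chash, config.seed)
    dataset = simulate_cohort(cohort_cfg)
    n_trials = sum(len(s.events) for s in dataset.subjects)
    logger.info("stage=simulate subjects=%d trials=%d", len(dataset.subjects), n_trials)

    latencies = extract_latencies(
        dataset, config.detection, config.latency_validity,
        ceiling_deg_s=config.preprocess.ceiling_deg_s,
        window_ms=config.preprocess.window_ms,
        guard_samples=config.preprocess.guard_samples)
    qc = qc_summary(latencies)
    logger.info("stage=detect trials=%d valid=%d", len(latencies),
                int(latencies["valid"].sum()))

    model = LatencyModulation(latencies, dataset.behavior_table(),
                              sld_tails=config.stats.sld_tails,
                              levene_center=config.stats.levene_center)
    results = model.fit()
    logger.info("stage=stats tests=%d", len(results.tests))

    n_iter = iterations if iterations is not None else config.classification.iterations
    features = build_features(results.subject_summaries)
    classification = {}
    for scheme in schemes:
        clf = SubsampledSVMClassifier(
            features, scheme=scheme, iterations=n_iter,
            seed=config.seed, config=config.classification.svm_config())
        classification[scheme] = clf.fit()
        logger.info("stage=classify %s", classification[scheme].summary())

    bundle = {
        "config_hash": chash,
        "dataset": dataset,
        "latencies": latencies,
        "qc": qc,
        "results": results,
        "classification": classification,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(latencies, out / "latency_table.tsv")
        write_table(qc.reset_index(), out / "qc_summary.tsv")
        results.to_json(out / "stats.json")
        write_json({k: v.to_dict() for k, v in classification.items()},
                   out / "classification.json")
        (out / "summary.txt").write_text(
            results.summary() + "\n\n" +
            "\n".join(v.summary() for v in classification.values()) + "\n")
        write_json({
            "config_hash": chash,
            "seed": config.seed,
            "config": config_to_dict(config),
            "versions": {
                "sacmod": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "counts": {
                "subjects": len(dataset.subjects),
                "trials": n_trials,
                "valid_latencies": int(latencies["valid"].sum()),
            },
        }, out / "provenance.json")
    return bundle
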