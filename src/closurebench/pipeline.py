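"""Orchestration: generate -> extract -> score -> analyze, with a full
audit trail.

A :class:`RunConfig` pins every knob; the bundle written for a run lives
in a directory named by the config hash and contains the stimulus
manifest, the scored records, the analysis report and the serialized
config, so a completed run is reproducible from its config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import analysis, exp1_stimuli, exp2_stimuli, measures
from .features import get_extractor

log = logging.getLogger("closurebench")

EXPERIMENTS = ("exp1_segments", "exp1_kanizsa", "exp2_line", "exp2_kanizsa")


@dataclass(frozen=True)
class RunConfig:
    experiment: str
    extractor: str = "toy"
    seed: int = 0
    alpha: float = 0.05
    alternative: str = "greater"
    extractor_options: tuple = field(default_factory=tuple)  # sorted (key, value)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {EXPERIMENTS}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["extractor_options"] = dict(self.extractor_options)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _build_extractor(cfg: RunConfig):
    return get_extractor(cfg.extractor, seed=cfg.seed,
                         **dict(cfg.extractor_options))


def run_experiment(cfg: RunConfig, out_dir,
                   write_images: bool = False) -> dict:
    """Execute one full experiment; returns the bundle as in-memory objects.

    Writes ``manifest.csv``, ``records.csv``, ``report.json`` and
    ``config.json`` under ``out_dir/<config hash>/``.  PNG stimuli are
    only written when ``write_images`` is set (they are reproducible from
    the config).
    """
    bundle_dir = Path(out_dir) / cfg.config_hash
    bundle_dir.mkdir(parents=True, exist_ok=True)
    extractor = _build_extractor(cfg)

    if cfg.experiment.startswith("exp1"):
        variant = cfg.experiment.split("_", 1)[1]
        stage = "generate"
        try:
            params = exp1_stimuli.enumerate_exp1_params(variant)
            stimuli = [exp1_stimuli.render_exp1_stimulus(p) for p in params]
            manifest = pd.DataFrame([exp1_stimuli.manifest_row(p) for p in params],
                                    columns=exp1_stimuli.MANIFEST_COLUMNS)
            log.info("generate: %d stimuli (%s)", len(stimuli), variant)
            stage = "extract/score"
            records = measures.score_exp1(stimuli, extractor)
            log.info("score: %d closure records", len(records))
            stage = "analyze"
            reg = analysis.fit_closure_regression(records)
            verdict = analysis.table1_verdict(reg=reg, method="similarity",
                                              alpha=cfg.alpha,
                                              side=analysis.EXP1_SIDE)
            report = {"regression": reg.to_dict(), "verdict": verdict.to_dict()}
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed for {cfg.experiment}: {exc}") from exc
        if write_images:
            for p, img in zip(params, stimuli):
                exp1_stimuli.save_png(
                    bundle_dir / exp1_stimuli.stimulus_filename(p), img.pixels)
    else:
        condition = ("line_segments" if cfg.experiment == "exp2_line"
                     else "kanizsa_squares")
        stage = "generate"
        try:
            set_params = exp2_stimuli.enumerate_exp2_sets(condition)
            pair_sets = [exp2_stimuli.render_pair_set(p) for p in set_params]
            manifest = pd.DataFrame(
                [row for p in set_params for row in exp2_stimuli.manifest_rows(p)],
                columns=exp2_stimuli.MANIFEST2_COLUMNS)
            log.info("generate: %d sets (%s)", len(pair_sets), condition)
            stage = "extract/score"
            records = measures.score_exp2(pair_sets, extractor)
            log.info("score: %d CE records", len(records))
            stage = "analyze"
            tests = analysis.t_tests_by_edge_length(records, cfg.alternative)
            verdict = analysis.table1_verdict(tests=tests, method="CE",
                                              alpha=cfg.alpha,
                                              side=analysis.EXP2_SIDE)
            report = {"t_tests": [t.to_dict() for t in tests],
                      "verdict": verdict.to_dict()}
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed for {cfg.experiment}: {exc}") from exc
        if write_images:
            for p, ps in zip(set_params, pair_sets):
                for row in exp2_stimuli.manifest_rows(p):
                    exp2_stimuli.save_png(bundle_dir / row["filename"],
                                          ps.images[row["role"]].pixels)

    report["config"] = cfg.to_dict()
    report["config_hash"] = cfg.config_hash
    report["extractor_id"] = getattr(extractor, "id", cfg.extractor)

    manifest.to_csv(bundle_dir / "manifest.csv", index=False)
    records.to_csv(bundle_dir / "records.csv", index=False)
    with open(bundle_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    with open(bundle_dir / "config.json", "w") as fh:
        json.dump({"config": cfg.to_dict(), "config_hash": cfg.config_hash},
                  fh, indent=2)
    log.info("bundle written to %s", bundle_dir)
    return {"manifest": manifest, "records": records, "report": report,
            "bundle_dir": bundle_dir}
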