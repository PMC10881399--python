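"""End-to-end orchestration: simulate -> dataset -> train -> attribute ->
scan -> call-functional, from one config with one global seed.

Stage seeds are derived from the global seed as
``sha256(f"{seed}:{stage}") mod 2**31`` so that changing one stage's
configuration never reshuffles another stage's randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import packaged_motifs_path
from .attribution import attribute_window, top_fraction_positions, write_track
from .classifier import ClassifierConfig, evaluate_auroc, train
from .dataset import (
    DatasetConfig,
    assign_splits,
    build_positives,
    sample_gc_matched_negatives,
    split_examples,
    write_examples,
)
from .functional import call_functional, recovery_report, write_calls
from .motifs import calibrate_cutoff, load_jaspar, scan
from .synthetic import (
    SyntheticGenomeConfig,
    SyntheticPeakSetConfig,
    generate_genome,
    plant_enhancers,
    write_fixture,
)

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name, chains the original error."""

    def __init__(self, stage: str, original: BaseException) -> None:
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage


def derive_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    genome: SyntheticGenomeConfig = field(default_factory=SyntheticGenomeConfig)
    peaks: SyntheticPeakSetConfig = field(default_factory=SyntheticPeakSetConfig)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    motifs_path: Optional[str] = None  # None -> packaged synthetic fixture
    target_fpr: float = 0.002
    n_background_windows: int = 5000
    top_fraction: float = 0.2
    min_overlap: int = 3
    attribution_method: str = "deeplift-rescale"

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Rebind the global seed, rederiving every stage seed."""
        return dataclasses.replace(
            self,
            seed=seed,
            genome=dataclasses.replace(
                self.genome, seed=derive_seed(seed, "genome")
            ),
            peaks=dataclasses.replace(
                self.peaks, seed=derive_seed(seed, "peaks")
            ),
            dataset=dataclasses.replace(
                self.dataset, seed=derive_seed(seed, "dataset")
            ),
            classifier=dataclasses.replace(
                self.classifier, seed=derive_seed(seed, "train")
            ),
        )


def validate_config(config: PipelineConfig) -> List[str]:
    """Collect every configuration problem without side effects."""
    issues = []
    if not (0.0 < config.top_fraction <= 1.0):
        issues.append(f"top_fraction must be in (0,1]: {config.top_fraction}")
    if config.target_fpr <= 0 or config.target_fpr > 1:
        issues.append(f"target_fpr must be in (0,1]: {config.target_fpr}")
    elif config.n_background_windows < 10.0 / config.target_fpr:
        issues.append(
            f"n_background_windows={config.n_background_windows} too small "
            f"for target_fpr={config.target_fpr} (need >= "
            f"{int(np.ceil(10.0 / config.target_fpr))})"
        )
    if config.min_overlap < 0:
        issues.append("min_overlap must be >= 0")
    dc = config.dataset
    if dc.validation_chromosome == dc.test_chromosome:
        issues.append("validation and test chromosomes clash")
    for chrom in (dc.validation_chromosome, dc.test_chromosome):
        if chrom not in config.genome.chromosome_lengths:
            issues.append(f"holdout chromosome {chrom} absent from genome")
    if dc.window_length != config.peaks.peak_length:
        issues.append(
            "dataset window_length differs from synthetic peak_length"
        )
    if dc.window_length != config.classifier.window_length:
        issues.append("classifier window_length differs from dataset")
    path = config.motifs_path
    if path is not None and not os.path.exists(path):
        issues.append(f"motifs file not found: {path}")
    if int(np.floor(config.top_fraction * dc.window_length)) == 0:
        issues.append("top_fraction selects zero positions")
    return issues


def run_end_to_end(config: PipelineConfig, out_dir: str) -> Dict:
    """Run the whole pipeline; persist all stage outputs; return the report."""
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    os.makedirs(out_dir, exist_ok=True)
    report: Dict = {"config": _config_snapshot(config), "stages": {}}
    timings: Dict[str, float] = {}

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[stage] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    logger.error("stage %s failed: %s", stage, exc)
                    raise PipelineStageError(stage, exc) from exc
                logger.info("stage %s finished in %.2fs", stage, timings[stage])

        return _T()

    motifs_file = (
        str(packaged_motifs_path())
        if config.motifs_path is None
        else config.motifs_path
    )
    pwms = load_jaspar(motifs_file)

    with timed("simulate"):
        genome = generate_genome(config.genome)
        peaks, truth = plant_enhancers(genome, pwms, config.peaks)
        fixture_paths = write_fixture(genome, peaks, truth, out_dir)
    report["stages"]["simulate"] = {
        "n_peaks": len(peaks),
        "n_truth": len(truth),
        "paths": fixture_paths,
    }

    with timed("dataset"):
        positives = build_positives(peaks, genome, config.dataset)
        negatives = sample_gc_matched_negatives(
            genome, positives, config.dataset
        )
        examples = assign_splits(positives + negatives, config.dataset)
        write_examples(examples, os.path.join(out_dir, "examples.bed"))
    splits = split_examples(examples)
    report["stages"]["dataset"] = {
        "n_positives": len(positives),
        "n_negatives": len(negatives),
        "split_sizes": {
            k: {
                "total": len(v),
                "positive": sum(e.label for e in v),
            }
            for k, v in splits.items()
        },
    }

    with timed("train"):
        model = train(splits["train"], splits["validation"], config.classifier)
        model.save(os.path.join(out_dir, "model.pkl"))
        _write_history(model.history, os.path.join(out_dir, "history.tsv"))
        test_auroc = evaluate_auroc(model, splits["test"])
    best = max(h["val_auroc"] for h in model.history)
    report["stages"]["train"] = {
        "epochs_run": len(model.history),
        "best_val_auroc": round(best, 4),
        "test_auroc": round(test_auroc, 4),
        "config_hash": model.config_hash,
    }

    with timed("calibrate"):
        # exclude every peak (not only the positives): sub-threshold active
        # peaks still carry planted motifs and would contaminate the
        # background score distribution
        background = _calibration_background(
            genome, positives, config, [p.interval for p in peaks]
        )
        calibrations = {
            pwm.motif_id: calibrate_cutoff(
                pwm,
                background,
                target_fpr=config.target_fpr,
                seed=config.dataset.seed,
                background_source="gc_matched_genomic",
            )
            for pwm in pwms
        }
        for pwm in pwms:
            pwm.cutoff = calibrations[pwm.motif_id].cutoff
        with open(os.path.join(out_dir, "calibration.yaml"), "w") as fh:
            yaml.safe_dump(
                {
                    mid: dataclasses.asdict(c)
                    for mid, c in calibrations.items()
                },
                fh,
            )
    report["stages"]["calibrate"] = {
        mid: {
            "cutoff": round(c.cutoff, 4),
            "achieved_fpr": c.achieved_fpr,
            "n_background_windows": c.n_background_windows,
        }
        for mid, c in calibrations.items()
    }

    with timed("attribute_scan_call"):
        tracks_dir = os.path.join(out_dir, "tracks")
        os.makedirs(tracks_dir, exist_ok=True)
        matches_by_seq, top_sets = {}, {}
        for i, ex in enumerate(positives):
            seq_id = f"pos_{i}"
            track = attribute_window(
                model, ex.sequence, config.attribution_method, ex.interval
            )
            top = top_fraction_positions(
                track.scores, config.top_fraction, ex.interval
            )
            top_sets[seq_id] = top
            if i < 50:  # persist a representative subset of tracks
                write_track(track, top, os.path.join(tracks_dir, f"{seq_id}.tsv"))
            window_matches = []
            for pwm in pwms:
                window_matches.extend(
                    scan(
                        pwm,
                        ex.sequence,
                        calibrations[pwm.motif_id].cutoff,
                        chrom=ex.interval.chrom,
                        offset=ex.interval.start,
                    )
                )
            matches_by_seq[seq_id] = window_matches
        calls, summary = call_functional(
            matches_by_seq, top_sets, config.min_overlap
        )
        write_calls(calls, os.path.join(out_dir, "functional_calls.bed"))
    recovery = recovery_report(calls, truth, tolerance_bp=0)
    report["stages"]["calls"] = {
        "per_motif": summary,
        "n_calls": len(calls),
        "n_functional": sum(c.functional for c in calls),
    }
    report["recovery"] = {
        mid: {
            "precision": round(m.precision, 4),
            "recall": round(m.recall, 4),
            "f1": round(m.f1, 4),
            "n_truth": m.n_truth,
            "n_calls": m.n_calls,
        }
        for mid, m in recovery.items()
    }
    report["timings_s"] = timings
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _calibration_background(genome, positives, config: PipelineConfig, exclude):
    """GC-matched random genomic windows, one batch per positive GC profile."""
    n = config.n_background_windows
    reps = -(-n // len(positives))  # ceil
    pool = (list(positives) * reps)[:n]
    bg_seed = derive_seed(config.seed, "calibration_background")
    bg_config = dataclasses.replace(config.dataset, seed=bg_seed)
    windows = sample_gc_matched_negatives(genome, pool, bg_config, exclude)
    return [w.sequence for w in windows]


def _write_history(history, path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\ttrain_loss\tval_auroc\n")
        for h in history:
            fh.write(f"{h['epoch']}\t{h['train_loss']:.6f}\t{h['val_auroc']:.6f}\n")


def _config_snapshot(config: PipelineConfig) -> Dict:
    snap = dataclasses.asdict(config)
    snap["genome"]["chromosome_lengths"] = dict(
        config.genome.chromosome_lengths
    )
    snap["dataset"]["excluded_chromosomes"] = sorted(
        config.dataset.excluded_chromosomes
    )
    return snap


def config_from_yaml(path) -> PipelineConfig:
    """Build a PipelineConfig from a (possibly partial) YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "genome" in raw:
        kwargs["genome"] = SyntheticGenomeConfig(**raw["genome"])
    if "peaks" in raw:
        kwargs["peaks"] = SyntheticPeakSetConfig(**raw["peaks"])
    if "dataset" in raw:
        d = dict(raw["dataset"])
        if "excluded_chromosomes" in d:
            d["excluded_chromosomes"] = frozenset(d["excluded_chromosomes"])
        kwargs["dataset"] = DatasetConfig(**d)
    if "classifier" in raw:
        c = dict(raw["classifier"])
        if "conv_layers" in c:
            c["conv_layers"] = tuple(map(tuple, c["conv_layers"]))
        if "pool_widths" in c:
            c["pool_widths"] = tuple(c["pool_widths"])
        kwargs["classifier"] = ClassifierConfig(**c)
    for key in (
        "seed", "motifs_path", "target_fpr", "n_background_windows",
        "top_fraction", "min_overlap", "attribution_method",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    config = PipelineConfig(**kwargs)
    if "seed" in raw:
        config = config.with_seed(raw["seed"])
    return config
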