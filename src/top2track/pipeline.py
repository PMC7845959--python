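"""End-to-end orchestration: world -> regions -> matrix -> selection ->
cross-validated model -> genome-wide probability track -> evaluation.

A single master seed derives per-stage seeds through fixed offsets so every
stage is independently reproducible, and a rerun with the same config is
bit-identical.  All artifacts (config copy, matrix, selection report, CV
report, model, bedGraph track, predicted peaks, evaluation report) are
written to the output directory.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .classification import (
    CVResult,
    Model,
    cross_validate,
    roc_auc,
    save_model,
    train_classifier,
)
from .core_io import (
    Genome,
    GenomicInterval,
    IntervalSet,
    write_bed,
    write_bedgraph,
)
from .feature_selection import SSParams, SelectionResult, run_selection_cv
from .genome_tracks import (
    ProbabilityTrack,
    overlap_fractions,
    predict_track,
    tile_genome,
    track_to_peaks,
)
from .region_ops import LabeledRegions, gc_matched_regions, random_regions
from .signal_scoring import FeatureSpec, build_feature_matrix
from .synthetic_world import GroundTruth, SimulationConfig, simulate_world

__all__ = ["RunConfig", "run_training", "run_cross_prediction", "default_feature_specs"]

# master-seed offsets per stage
_SEED_BACKGROUND = 101
_SEED_SELECTION = 102
_SEED_CV = 103
_SEED_MODEL = 104


@dataclass
class RunConfig:
    """Configuration of one training run on a (simulated) world."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    background: str = "gc_matched"  # or "random"
    selection: Optional[str] = None  # None | "fcbf" | "ss"
    classifier: str = "tree_ensemble"
    folds: int = 5
    prob_threshold: float = 0.95
    gc_tolerance: float = 1.0 / 300.0
    seed: int = 7
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.background not in ("random", "gc_matched"):
            raise ValueError("background must be 'random' or 'gc_matched'")
        if self.selection not in (None, "fcbf", "ss"):
            raise ValueError("selection must be None, 'fcbf' or 'ss'")
        if not (0.0 < self.prob_threshold < 1.0):
            raise ValueError("prob_threshold must lie in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def to_dict(self) -> dict:
        return {
            "simulation": self.simulation.to_dict(),
            "background": self.background,
            "selection": self.selection,
            "classifier": self.classifier,
            "folds": self.folds,
            "prob_threshold": self.prob_threshold,
            "gc_tolerance": self.gc_tolerance,
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "simulation" in d:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        d.pop("outdir", None)
        return cls(**d)


def default_feature_specs(libraries) -> List[FeatureSpec]:
    """The generalizing three-feature panel: DNase coverage, CTCF and RAD21
    test/input log-ratios (plus coverage scoring for any other simulated
    accessibility-style feature)."""
    specs = []
    for feature in sorted(libraries):
        test, inp = libraries[feature]
        if feature == "dnase":
            specs.append(FeatureSpec(name="dnase", kind="coverage", lib=test))
        else:
            specs.append(
                FeatureSpec(name=feature, kind="chip", test=test, input_=inp)
            )
    return specs


def _make_background(
    peaks: IntervalSet,
    genome: Genome,
    mode: str,
    seed: int,
    gc_tolerance: float,
) -> IntervalSet:
    empty = IntervalSet()
    if mode == "random":
        return random_regions(peaks, genome, empty, empty, seed=seed)

    def factory(n: int, rng: np.random.Generator) -> IntervalSet:
        width = peaks[0].width
        out = []
        chrom_counts = peaks.counts_per_chrom()
        chroms = sorted(chrom_counts)
        weights = np.array([chrom_counts[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        while len(out) < n:
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            length = genome.lengths[chrom]
            s = int(rng.integers(0, length - width + 1))
            cand = GenomicInterval(chrom, s, s + width)
            if peaks.overlaps_any(cand):
                continue
            out.append(cand)
        return IntervalSet(out)

    return gc_matched_regions(
        peaks, genome, factory, tolerance=gc_tolerance, seed=seed
    )


def run_training(config: RunConfig) -> dict:
    """Execute the full training pipeline on the configured world.

    Returns a dict with the world, labeled regions, feature matrix,
    optional selection result, CV result, final model, probability track,
    predicted peaks and the evaluation report; artifacts are written to
    ``config.outdir`` when set.
    """
    genome, truth, libraries, methylation = simulate_world(config.simulation)
    peaks = truth.top2b_sites
    background = _make_background(
        peaks,
        genome,
        config.background,
        seed=config.seed + _SEED_BACKGROUND,
        gc_tolerance=config.gc_tolerance,
    )
    regions = LabeledRegions.from_sites_and_background(
        peaks, background, provenance=config.background
    )
    specs = default_feature_specs(libraries)
    matrix = build_feature_matrix(regions, specs, genome=genome)

    selection: Optional[SelectionResult] = None
    if config.selection is not None:
        selection = run_selection_cv(
            matrix.values,
            matrix.labels,
            matrix.feature_names,
            method=config.selection,
            folds=config.folds,
            seed=config.seed + _SEED_SELECTION,
        )
        # final subset: features selected in a majority of folds
        counts: Dict[str, int] = {}
        for run in selection.runs:
            for f in run:
                counts[f] = counts.get(f, 0) + 1
        chosen = [
            f
            for f in matrix.feature_names
            if counts.get(f, 0) * 2 > len(selection.runs)
        ]
        if chosen:
            matrix = matrix.subset_features(chosen)
            specs = [s for s in specs if s.name in chosen]

    cv = cross_validate(
        matrix,
        k=config.folds,
        kind=config.classifier,
        seed=config.seed + _SEED_CV,
    )
    model = train_classifier(
        matrix, kind=config.classifier, seed=config.seed + _SEED_MODEL
    )

    windows = tile_genome(genome)
    track = predict_track(model, windows, specs, genome=genome)
    predicted = track_to_peaks(track, threshold=config.prob_threshold)
    overlap = overlap_fractions(
        {"predicted": predicted, "true_sites": truth.top2b_sites}
    )
    n_sites = len(truth.top2b_sites)
    n_recovered = sum(
        1 for iv in truth.top2b_sites if predicted.overlaps_any(iv)
    )
    report = {
        "n_sites": n_sites,
        "n_background": len(background),
        "n_windows": len(windows),
        "n_predicted_peaks": len(predicted),
        "site_recovery_fraction": n_recovered / n_sites if n_sites else 0.0,
        "overlap": overlap,
        "cv": cv.to_dict(),
        "provenance": config.background,
    }
    if selection is not None:
        report["selection"] = selection.to_dict()

    result = {
        "genome": genome,
        "truth": truth,
        "libraries": libraries,
        "methylation": methylation,
        "regions": regions,
        "matrix": matrix,
        "selection": selection,
        "cv": cv,
        "model": model,
        "track": track,
        "predicted_peaks": predicted,
        "report": report,
    }
    if config.outdir:
        _write_artifacts(config, result)
    return result


def _write_artifacts(config: RunConfig, result: dict) -> None:
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "run_config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)
    result["matrix"].to_dataframe().to_csv(
        os.path.join(outdir, "feature_matrix.tsv"), sep="\t"
    )
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(result["report"], fh, indent=2, sort_keys=True)
    save_model(result["model"], os.path.join(outdir, "model.pkl"))
    write_bedgraph(result["track"], os.path.join(outdir, "track.bedgraph"))
    write_bed(result["predicted_peaks"], os.path.join(outdir, "predicted_peaks.bed"))


def run_cross_prediction(
    model: Model,
    target_config: SimulationConfig,
    background: str = "gc_matched",
    seed: int = 7,
    gc_tolerance: float = 1.0 / 300.0,
) -> dict:
    """Apply a trained model to another system's labeled matrix.

    Builds the target world's site/background matrix with the same feature
    panel (the model's manifest must match) and reports accuracy and AUC.
    """
    genome, truth, libraries, _ = simulate_world(target_config)
    peaks = truth.top2b_sites
    if len(peaks) == 0:
        raise ValueError("target world contains no sites (single-class data)")
    bg = _make_background(
        peaks, genome, background, seed=seed + _SEED_BACKGROUND, gc_tolerance=gc_tolerance
    )
    regions = LabeledRegions.from_sites_and_background(peaks, bg, provenance=background)
    specs = default_feature_specs(libraries)
    matrix = build_feature_matrix(regions, specs, genome=genome)
    if model.feature_names != matrix.feature_names:
        matrix = matrix.subset_features(model.feature_names)
    probs = model.predict_proba(matrix)[:, 1]
    pred = (probs >= 0.5).astype(int)
    accuracy = 100.0 * float(np.mean(pred == matrix.labels))
    _, auc = roc_auc(probs, matrix.labels)
    return {"accuracy": accuracy, "auc": auc, "n": matrix.n_rows}
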