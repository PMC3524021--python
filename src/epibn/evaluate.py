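"""Detection metrics and replicate experiments.

precision = |detected ∩ truth| / |detected| (0 when nothing is detected),
recall    = |detected ∩ truth| / |truth|,
distance  = sqrt((1 - precision)^2 + (1 - recall)^2),

and power over a replicate set is the fraction of replicates whose detected
set equals the truth exactly — no false positives, no false negatives. The
per-score tallies mirror the usual simulation-study summary: ``o`` counts
replicates in which every planted disease SNP was detected (regardless of
extras), ``plus`` sums extra detected SNPs and ``minus`` sums missed disease
SNPs across replicates.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Iterable

import numpy as np

from .dataset import GenotypeDataset
from .scoring import ScoringConfig
from .screen import McmcConfig, mcmc_screen
from .search import SearchConfig, branch_and_bound
from .simulate import (
    DiseaseModelSpec,
    SimConfig,
    SimTruth,
    replicate_seed,
    simulate_dataset,
)

__all__ = [
    "EvalMetrics",
    "ExperimentSummary",
    "score_detection",
    "default_detector",
    "run_experiment",
]


@dataclasses.dataclass
class EvalMetrics:
    precision: float
    recall: float
    distance: float
    exact_match: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def score_detection(detected: Iterable, truth: Iterable) -> EvalMetrics:
    """Precision/recall/distance of a detected SNP set against the truth."""
    detected, truth = set(detected), set(truth)
    if not truth:
        raise ValueError("truth set must be nonempty")
    hits = len(detected & truth)
    precision = hits / len(detected) if detected else 0.0
    recall = hits / len(truth)
    distance = math.hypot(1.0 - precision, 1.0 - recall)
    return EvalMetrics(
        precision=precision,
        recall=recall,
        distance=distance,
        exact_match=detected == truth,
    )


@dataclasses.dataclass
class ExperimentSummary:
    n_replicates: int
    power: float
    precision_mean: float
    precision_sd: float
    recall_mean: float
    recall_sd: float
    distance_mean: float
    distance_sd: float
    o: int  # replicates with every disease SNP detected (recall = 1)
    plus: int  # total extra detected SNPs across replicates
    minus: int  # total missed disease SNPs across replicates
    per_replicate: list[EvalMetrics]
    detections: list[list[int]]
    failures: list[tuple[int, str]]
    config: dict

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["per_replicate"] = [m.to_dict() for m in self.per_replicate]
        return d


def default_detector(
    ds: GenotypeDataset,
    search_cfg: SearchConfig,
    *,
    screen_threshold: int = 1000,
    screen_cfg: McmcConfig | None = None,
) -> list[int]:
    """Screen (only above ``screen_threshold`` markers) then search.

    Returns the detected SNP column indices. Direct Branch-and-Bound is used
    on panels of at most ``screen_threshold`` markers.
    """
    restrict = None
    if ds.n_snps > screen_threshold:
        cfg = screen_cfg or McmcConfig.for_markers(
            ds.n_snps, scoring=search_cfg.scoring, rng_seed=search_cfg.scoring.rng_seed
        )
        restrict = mcmc_screen(ds, cfg).candidates
        if not restrict:
            return []
    result = branch_and_bound(ds, search_cfg, restrict=restrict)
    return sorted(result.best_parents)


def _sd(values: list[float]) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1))


def run_experiment(
    model: DiseaseModelSpec,
    cfg: SimConfig,
    method_cfg: SearchConfig,
    n_replicates: int,
    base_seed: int,
    *,
    detector: Callable[[GenotypeDataset, SimTruth, int], Iterable] | None = None,
    screen_threshold: int = 1000,
    screen_cfg: McmcConfig | None = None,
) -> ExperimentSummary:
    """Simulate replicates, run detection on each, and aggregate metrics.

    ``detector(ds, truth, replicate_seed)`` may be injected (for harness
    self-tests); it must return detected SNP column indices and must not use
    ``truth`` for detection. The default pipeline screens when the marker
    panel exceeds ``screen_threshold`` and then runs Branch-and-Bound.
    Fully reproducible from ``base_seed``.
    """
    metrics: list[EvalMetrics] = []
    detections: list[list[int]] = []
    failures: list[tuple[int, str]] = []
    o = plus = minus = 0
    for i in range(n_replicates):
        seed_i = replicate_seed(base_seed, i)
        sim_cfg = dataclasses.replace(cfg, rng_seed=seed_i)
        ds, truth = simulate_dataset(model, sim_cfg)
        try:
            if detector is not None:
                detected = set(detector(ds, truth, seed_i))
            else:
                scoring = dataclasses.replace(method_cfg.scoring, rng_seed=seed_i)
                rep_cfg = dataclasses.replace(method_cfg, scoring=scoring)
                detected = set(
                    default_detector(
                        ds,
                        rep_cfg,
                        screen_threshold=screen_threshold,
                        screen_cfg=screen_cfg,
                    )
                )
        except Exception as exc:  # recorded, not silently dropped
            failures.append((i, repr(exc)))
            detected = set()
        truth_set = set(truth.disease_marker_indices)
        m = score_detection(detected, truth_set)
        metrics.append(m)
        detections.append(sorted(int(s) for s in detected))
        o += int(truth_set <= detected)
        plus += len(detected - truth_set)
        minus += len(truth_set - detected)
    return ExperimentSummary(
        n_replicates=n_replicates,
        power=sum(m.exact_match for m in metrics) / n_replicates,
        precision_mean=float(np.mean([m.precision for m in metrics])),
        precision_sd=_sd([m.precision for m in metrics]),
        recall_mean=float(np.mean([m.recall for m in metrics])),
        recall_sd=_sd([m.recall for m in metrics]),
        distance_mean=float(np.mean([m.distance for m in metrics])),
        distance_sd=_sd([m.distance for m in metrics]),
        o=o,
        plus=plus,
        minus=minus,
        per_replicate=metrics,
        detections=detections,
        failures=failures,
        config={
            "base_seed": base_seed,
            "n_replicates": n_replicates,
            "model": dataclasses.asdict(model)
            if model.risk_set is None
            else {
                **{
                    k: v
                    for k, v in dataclasses.asdict(model).items()
                    if k != "risk_set"
                },
                "risk_set": sorted(map(list, model.risk_set)),
            },
            "sim": dataclasses.asdict(cfg),
            "search": {
                "max_parents": method_cfg.max_parents,
                "pruning_mode": method_cfg.pruning_mode,
                "child_ordering": method_cfg.child_ordering,
                "scoring": dataclasses.asdict(method_cfg.scoring),
            },
            "screen_threshold": screen_threshold,
        },
    )
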