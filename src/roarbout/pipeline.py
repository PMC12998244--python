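"""Orchestration of the three roaring-bout experiments.

Each ``run_*`` function executes one experiment end to end on aligned
(annotations, contours) data and, when an output directory is given,
writes a reproducibility manifest (all parameters + seed), the confusion
matrix (tsv) and the metric report (tsv + text).

Experiments:

* ``run_calltype_hmm`` — balance call-type classes, leave-one-call-out
  HMM classification, micro + per-class metrics;
* ``run_calltype_kmeans`` — two-feature K-means call typing at k=4 (all
  types) or k=3 (moans removed), Hungarian-mapped against true labels;
* ``run_individual_id`` — per-lion HMMs on full-throated roars selected
  manually or by K-means, leave-one-bout-out, macro metrics plus a
  per-lion bout/roar count table.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .audio import CallAnnotation
from .classify import classify_calls_loo, classify_individuals_loo_bout
from .cluster import kmeans, map_clusters, predict_ftr
from .f0 import F0Contour
from .features import balance_classes, build_features, standardize
from .hmm import FitConfig
from .metrics import ClassificationReport, confusion, report

__all__ = ["RunConfig", "run_calltype_hmm", "run_calltype_kmeans", "run_individual_id"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Shared experiment settings (desk-scale defaults; the full field
    protocol uses n_repeats=1000 and n_restarts=1000)."""

    seed: int = 0
    n_repeats: int = 10
    n_restarts: int = 5
    k: int = 4
    drop_moans: bool = False
    ftr_source: str = "manual"  # or "kmeans"
    out_dir: str | None = None
    extra: dict = field(default_factory=dict)

    def fit_config(self) -> FitConfig:
        return FitConfig(n_restarts=self.n_restarts, seed=self.seed)


def _write_artifacts(rep: ClassificationReport, cfg: RunConfig, experiment: str,
                     tables: dict[str, pd.DataFrame] | None = None) -> None:
    if cfg.out_dir is None:
        return
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = dataclasses.asdict(cfg)
    manifest["experiment"] = experiment
    manifest["version"] = __version__
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    rep.cm.to_frame().to_csv(out / "confusion.tsv", sep="\t")
    rep.to_frame().to_csv(out / "report.tsv", sep="\t")
    (out / "report.txt").write_text(rep.summary() + "\n")
    for name, frame in (tables or {}).items():
        frame.to_csv(out / f"{name}.tsv", sep="\t", index=False)


def _check_aligned(annotations, contours) -> None:
    if len(annotations) != len(contours):
        raise ValueError("annotations and contours must be aligned 1:1")


def run_calltype_hmm(
    annotations: list[CallAnnotation],
    contours: list[F0Contour],
    cfg: RunConfig = RunConfig(),
) -> ClassificationReport:
    """Class-balanced leave-one-call-out HMM call-type classification."""
    _check_aligned(annotations, contours)
    if any(a.call_type is None for a in annotations):
        raise ValueError("call-type HMM experiment: all calls must be labeled")
    by_id = {id(a): c for a, c in zip(annotations, contours)}
    balanced = balance_classes(annotations, seed=cfg.seed)
    calls = [(by_id[id(a)], a.call_type) for a in balanced]
    rep = classify_calls_loo(calls, cfg.fit_config(), n_repeats=cfg.n_repeats)
    _write_artifacts(rep, cfg, "calltype_hmm")
    return rep


def run_calltype_kmeans(
    annotations: list[CallAnnotation],
    cfg: RunConfig = RunConfig(),
) -> ClassificationReport:
    """Two-feature K-means call typing, evaluated against the true labels
    via the optimal one-to-one cluster->label mapping."""
    if not annotations:
        raise ValueError("no annotations given")
    if cfg.drop_moans:
        annotations = [a for a in annotations if a.call_type != "moan"]
    elif cfg.k == 3 and any(a.call_type == "moan" for a in annotations):
        raise ValueError(
            "k=3 clustering requires moans to be removed first (set drop_moans)"
        )
    table = standardize(build_features(annotations))
    result = map_clusters(kmeans(table, cfg.k, seed=cfg.seed), table.labels())
    rep = report(confusion(table.labels(), result.predicted_labels()))
    _write_artifacts(rep, cfg, "calltype_kmeans")
    return rep


def run_individual_id(
    annotations: list[CallAnnotation],
    contours: list[F0Contour],
    cfg: RunConfig = RunConfig(),
) -> ClassificationReport:
    """Leave-one-bout-out individual identification on full-throated roars.

    ``cfg.ftr_source`` selects the roars fed to the per-lion HMMs:
    ``"manual"`` takes the annotated full-throated roars; ``"kmeans"``
    drops the (manually labeled) moans and uses the K-means-predicted
    full-throated-roar cluster. Lions left with fewer than 2 bouts are
    dropped with a warning (they cannot be cross-validated).
    """
    _check_aligned(annotations, contours)
    if cfg.ftr_source == "manual":
        selected = [
            (a, c) for a, c in zip(annotations, contours)
            if a.call_type == "full_throated_roar"
        ]
    elif cfg.ftr_source == "kmeans":
        pool = [(a, c) for a, c in zip(annotations, contours) if a.call_type != "moan"]
        chosen = predict_ftr([a for a, _ in pool], seed=cfg.seed)
        chosen_ids = {id(a) for a in chosen}
        selected = [(a, c) for a, c in pool if id(a) in chosen_ids]
    else:
        raise ValueError("ftr_source must be 'manual' or 'kmeans'")
    if not selected:
        raise ValueError("no full-throated roars selected")

    grouped: dict[tuple[str, str], list[F0Contour]] = {}
    for a, c in selected:
        grouped.setdefault((a.source_id, a.bout_id), []).append(c)
    by_lion: dict[str, list[tuple[str, list[F0Contour]]]] = {}
    for (lion, bout), cts in grouped.items():
        by_lion.setdefault(lion, []).append((bout, cts))
    kept: list[tuple[str, str, list[F0Contour]]] = []
    counts_rows = []
    for lion in sorted(by_lion):
        bouts = by_lion[lion]
        if len(bouts) < 2:
            log.warning("lion %s has %d bout(s) after roar selection; dropped",
                        lion, len(bouts))
            continue
        for bout, cts in bouts:
            kept.append((lion, bout, cts))
        counts_rows.append({
            "lion_id": lion,
            "n_bouts": len(bouts),
            "n_roars": sum(len(cts) for _, cts in bouts),
        })
    rep = classify_individuals_loo_bout(kept, cfg.fit_config(), n_repeats=cfg.n_repeats)
    _write_artifacts(rep, cfg, f"individual_id_{cfg.ftr_source}",
                     tables={"per_lion": pd.DataFrame(counts_rows)})
    return rep
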