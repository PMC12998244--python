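"""The two-feature call table: duration (s) and maximum frequency (Hz).

Two bounding-box measurements exported per call are enough to separate
the call types of a roaring bout; this module builds that table,
standardizes it (per dataset, never pooled across study sites) and
balances the classes for HMM experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio import CallAnnotation

__all__ = ["FeatureTable", "build_features", "standardize", "balance_classes"]

FEATURES = ("duration_s", "max_freq_hz")


class DegenerateFeatureError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureTable:
    """Per-call feature rows, optionally standardized.

    ``frame`` holds one row per call with columns ``duration_s``,
    ``max_freq_hz``, ``label``, ``bout_id``, ``source_id``. When
    ``scaler`` is set the feature columns are z-scores and ``scaler``
    maps feature name -> (mean, sd) fitted on this table's own rows
    (sample SD, n-1 denominator).
    """

    frame: pd.DataFrame
    scaler: dict[str, tuple[float, float]] | None = None

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def is_standardized(self) -> bool:
        return self.scaler is not None

    def values(self) -> np.ndarray:
        """The (n, 2) feature matrix in FEATURES order."""
        return self.frame[list(FEATURES)].to_numpy(dtype=np.float64)

    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    def inverse(self) -> "FeatureTable":
        """Undo standardization, recovering the original units."""
        if self.scaler is None:
            return self
        frame = self.frame.copy()
        for name, (mean, sd) in self.scaler.items():
            frame[name] = frame[name] * sd + mean
        return FeatureTable(frame, scaler=None)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path, sep="\t"))


def build_features(annotations: list[CallAnnotation]) -> FeatureTable:
    """One row per annotation, order preserved."""
    if not annotations:
        raise ValueError("no annotations given")
    for i, ann in enumerate(annotations):
        if ann.duration_s <= 0:
            raise ValueError(f"annotation {i} (bout {ann.bout_id!r}) has non-positive duration")
        if ann.max_freq_hz <= 0:
            raise ValueError(f"annotation {i} (bout {ann.bout_id!r}) has non-positive max frequency")
    frame = pd.DataFrame(
        {
            "duration_s": [a.duration_s for a in annotations],
            "max_freq_hz": [a.max_freq_hz for a in annotations],
            "label": [a.call_type for a in annotations],
            "bout_id": [a.bout_id for a in annotations],
            "source_id": [a.source_id for a in annotations],
        }
    )
    return FeatureTable(frame)


def standardize(table: FeatureTable) -> FeatureTable:
    """Mean-centre and divide by the sample SD, per feature.

    Fitted on the table's own rows; the (mean, sd) pairs are stored so the
    transform can be inverted. Idempotent up to floating error. A constant
    feature cannot be standardized and raises ``DegenerateFeatureError``.
    """
    if len(table) < 2:
        raise ValueError("standardization needs at least 2 rows")
    frame = table.frame.copy()
    scaler: dict[str, tuple[float, float]] = {}
    for name in FEATURES:
        col = frame[name].to_numpy(dtype=np.float64)
        mean, sd = float(np.mean(col)), float(np.std(col, ddof=1))
        if sd <= 0:
            raise DegenerateFeatureError(f"feature {name!r} has zero variance")
        frame[name] = (col - mean) / sd
        scaler[name] = (mean, sd)
    return FeatureTable(frame, scaler=scaler)


def balance_classes(
    annotations: list[CallAnnotation], seed: int
) -> list[CallAnnotation]:
    """Downsample every call type, without replacement, to the smallest
    class size. Reproducible from ``seed``; within each class the original
    order is kept."""
    labels = [a.call_type for a in annotations]
    if any(lab is None for lab in labels):
        raise ValueError("all annotations must be labeled to balance classes")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 labeled classes")
    by_class = {c: [i for i, lab in enumerate(labels) if lab == c] for c in classes}
    n_min = min(len(idx) for idx in by_class.values())
    if n_min == 0:
        raise ValueError("every class must be non-empty")
    rng = np.random.default_rng(seed)
    kept: list[int] = []
    for c in classes:
        idx = by_class[c]
        chosen = rng.choice(len(idx), size=n_min, replace=False)
        kept.extend(idx[j] for j in sorted(chosen))
    return [annotations[i] for i in sorted(kept)]
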