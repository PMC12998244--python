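"""Leave-one-out HMM classification protocols.

Two experiments share the same engine:

* call types — each call is held out once; per class, an HMM is fitted to
  the remaining calls of that class, and the held-out call goes to the
  class with the highest forward log-likelihood;
* individual lions — each whole bout is held out once (keeping a bout's
  roars together avoids leakage through temporal autocorrelation), per
  lion an HMM is fitted to the lion's remaining bouts, and the bout goes
  to the lion whose HMM scores it highest.

The whole procedure is repeated ``n_repeats`` times with fresh random
initialisations; confusion counts are accumulated over repeats and
normalized (a majority-vote aggregation is available as an option).
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .f0 import F0Contour
from .hmm import FitConfig, GaussianHMM, HMMParams, log_likelihood
from .metrics import ClassificationReport, confusion, report

__all__ = ["classify_calls_loo", "classify_individuals_loo_bout"]

log = logging.getLogger(__name__)


def _fit_params(contours, cfg: FitConfig, seed: int) -> HMMParams:
    return GaussianHMM(contours).fit(replace(cfg, seed=seed)).params


def _refit_params(contours, cfg: FitConfig, seed: int,
                  init: HMMParams | None) -> HMMParams:
    """Fit the held-out-unit training model.

    With ``init`` given, EM starts from the corresponding full-class
    parameters instead of fresh random restarts: removing one unit from a
    class barely moves the optimum, so warm-started EM converges in a few
    iterations to the same model. EM still optimises the training-only
    likelihood. Pass ``init=None`` (``exact_loo``) for the full
    random-restart refit."""
    if init is None:
        return _fit_params(contours, cfg, seed)
    model = GaussianHMM(contours)
    params, _ = model._em(init, cfg)
    return params


def _argmax_label(scores: dict[str, float]) -> str:
    """Highest-scoring label; exact ties break by fixed (sorted) label
    order and are logged."""
    best = max(scores.values())
    winners = sorted(lab for lab, s in scores.items() if s == best)
    if len(winners) > 1:
        log.info("tie between %s at log-likelihood %.6f; choosing %s",
                 winners, best, winners[0])
    return winners[0]


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31 - 1))


def classify_calls_loo(
    calls: list[tuple[F0Contour, str]],
    cfg: FitConfig = FitConfig(),
    n_repeats: int = 1,
    aggregate: str = "counts",
    exact_loo: bool = False,
) -> ClassificationReport:
    """Leave-one-call-out call-type classification.

    ``calls`` pairs each contour with its true call type. Per repeat and
    held-out call, one HMM per class is fitted on all remaining calls of
    that class (only the held-out call's own class model actually changes,
    so the other class models are fitted once per repeat). ``aggregate``
    is ``"counts"`` (confusion counts averaged over repeats, fractional)
    or ``"majority"`` (per-call majority vote across repeats).
    ``exact_loo`` replaces the warm-started held-out refits with full
    random-restart fits (slower, near-identical results).
    """
    by_class: dict[str, list] = {}
    for contour, label in calls:
        by_class.setdefault(label, []).append(contour)
    classes = sorted(by_class)
    if len(classes) < 2:
        raise ValueError("need at least 2 call types")
    for c, members in by_class.items():
        if len(members) < 2:
            raise ValueError(f"class {c!r} has {len(members)} call(s); need >= 2 for LOO")
    if aggregate not in ("counts", "majority"):
        raise ValueError("aggregate must be 'counts' or 'majority'")

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    votes: list[dict[str, int]] = [dict() for _ in calls]
    true_labels = [label for _, label in calls]
    cms = []
    for _ in range(n_repeats):
        full_models = {
            c: _fit_params(by_class[c], cfg, _child_seed(rng)) for c in classes
        }
        predicted = []
        for i, (contour, label) in enumerate(calls):
            train = [x for x in by_class[label] if x is not contour]
            held_out_model = _refit_params(
                train, cfg, _child_seed(rng),
                None if exact_loo else full_models[label],
            )
            scores = {
                c: log_likelihood(held_out_model if c == label else full_models[c], contour)
                for c in classes
            }
            pred = _argmax_label(scores)
            predicted.append(pred)
            votes[i][pred] = votes[i].get(pred, 0) + 1
        cms.append(confusion(true_labels, predicted, labels=classes))

    if aggregate == "majority":
        final = [_argmax_label({lab: float(n) for lab, n in v.items()}) for v in votes]
        cm = confusion(true_labels, final, labels=classes)
    else:
        cm = cms[0]
        for extra in cms[1:]:
            cm = cm + extra
        cm = cm.scaled(1.0 / n_repeats)
    return report(cm)


def classify_individuals_loo_bout(
    bouts: list[tuple[str, str, list[F0Contour]]],
    cfg: FitConfig = FitConfig(),
    n_repeats: int = 1,
    score_mode: str = "sum",
    exact_loo: bool = False,
) -> ClassificationReport:
    """Leave-one-bout-out individual identification.

    ``bouts`` holds (lion_id, bout_id, contours) triples, the contours
    being the bout's full-throated roars. A bout's score under a lion's
    HMM is the sum of its per-contour log-likelihoods (``score_mode
    "sum"``: calls treated as independent) or the log-likelihood of the
    concatenated contour (``"concat"``).
    """
    if score_mode not in ("sum", "concat"):
        raise ValueError("score_mode must be 'sum' or 'concat'")
    by_lion: dict[str, list[tuple[str, list[F0Contour]]]] = {}
    for lion, bout_id, contours in bouts:
        by_lion.setdefault(lion, []).append((bout_id, contours))
    lions = sorted(by_lion)
    if len(lions) < 2:
        raise ValueError("need at least 2 lions")
    for lion, items in by_lion.items():
        if len(items) < 2:
            raise ValueError(f"lion {lion!r} has {len(items)} bout(s); need >= 2 for LOO")

    def bout_score(params: HMMParams, contours: list[F0Contour]) -> float:
        if score_mode == "concat":
            joined = np.concatenate([np.asarray(c.values_hz) for c in contours])
            return log_likelihood(params, joined)
        return sum(log_likelihood(params, c) for c in contours)

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    cms = []
    for _ in range(n_repeats):
        full_models = {
            lion: _fit_params(
                [c for _, contours in by_lion[lion] for c in contours], cfg, _child_seed(rng)
            )
            for lion in lions
        }
        true_labels, predicted = [], []
        for lion in lions:
            for bout_id, contours in by_lion[lion]:
                train = [
                    c
                    for other_id, other in by_lion[lion]
                    if other_id != bout_id
                    for c in other
                ]
                held_out_model = _refit_params(
                    train, cfg, _child_seed(rng),
                    None if exact_loo else full_models[lion],
                )
                scores = {
                    cand: bout_score(
                        held_out_model if cand == lion else full_models[cand], contours
                    )
                    for cand in lions
                }
                true_labels.append(lion)
                predicted.append(_argmax_label(scores))
        cms.append(confusion(true_labels, predicted, labels=lions))

    cm = cms[0]
    for extra in cms[1:]:
        cm = cm + extra
    cm = cm.scaled(1.0 / n_repeats)
    return report(cm)
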