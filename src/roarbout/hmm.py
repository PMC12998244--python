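"""Two-state Gaussian hidden Markov models over F0 contours.

The temporal pattern of a call's F0 contour is modelled as a first-order
HMM whose hidden path alternates between two regimes (e.g. the rise and
fall of a roar's arch), each emitting frame values from a 1-D Gaussian in
Hz. The model is the classification engine for both call types and
individual lions: per class, an HMM is fitted by Baum-Welch EM from many
random restarts, and a test contour is assigned to the class whose HMM
gives the highest forward-algorithm log-likelihood.

The API follows the model/results convention: build a :class:`GaussianHMM`
from contours, call :meth:`~GaussianHMM.fit`, and work with the returned
:class:`HMMResults` (parameters, per-restart diagnostics, ``summary()``).
Frozen parameter sets live in :class:`HMMParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .f0 import F0Contour

__all__ = ["HMMParams", "FitConfig", "GaussianHMM", "HMMResults", "fit_hmm", "log_likelihood"]

_LOG_2PI = math.log(2.0 * math.pi)


def _as_sequences(contours) -> list[np.ndarray]:
    out = []
    for c in contours:
        arr = c.values_hz if isinstance(c, F0Contour) else np.asarray(c, dtype=np.float64)
        arr = np.asarray(arr, dtype=np.float64)
        if arr.size:
            out.append(arr)
    return out


@dataclass(frozen=True)
class HMMParams:
    """Frozen parameters of an n-state Gaussian HMM.

    ``startprob`` is a simplex over states, ``transmat`` row-stochastic,
    ``means``/``variances`` the per-state emission Gaussians in Hz / Hz^2.
    """

    startprob: np.ndarray
    transmat: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.startprob, dtype=np.float64)
        a = np.asarray(self.transmat, dtype=np.float64)
        mu = np.asarray(self.means, dtype=np.float64)
        var = np.asarray(self.variances, dtype=np.float64)
        k = len(p)
        if a.shape != (k, k) or mu.shape != (k,) or var.shape != (k,):
            raise ValueError("inconsistent parameter shapes")
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p < -1e-12):
            raise ValueError("startprob must be a probability simplex")
        if np.any(np.abs(a.sum(axis=1) - 1.0) > 1e-9) or np.any(a < -1e-12):
            raise ValueError("transmat rows must sum to 1")
        if np.any(var <= 0):
            raise ValueError("variances must be positive")
        for name, val in (("startprob", p), ("transmat", a), ("means", mu), ("variances", var)):
            object.__setattr__(self, name, val)

    @property
    def n_states(self) -> int:
        return len(self.startprob)

    def log_emission(self, x: np.ndarray) -> np.ndarray:
        """log N(x | mu_k, var_k), shape (..., n_states)."""
        x = np.asarray(x, dtype=np.float64)[..., None]
        return -0.5 * (_LOG_2PI + np.log(self.variances) + (x - self.means) ** 2 / self.variances)

    def log_likelihood(self, contour) -> float:
        """Exact forward-algorithm log p(contour | params), in nats."""
        return log_likelihood(self, contour)

    def sample(self, n_frames: int, rng: np.random.Generator) -> np.ndarray:
        """Draw one observation sequence of length ``n_frames``."""
        states = np.empty(n_frames, dtype=int)
        states[0] = rng.choice(self.n_states, p=self.startprob)
        for t in range(1, n_frames):
            states[t] = rng.choice(self.n_states, p=self.transmat[states[t - 1]])
        return rng.normal(self.means[states], np.sqrt(self.variances[states]))


@dataclass(frozen=True)
class FitConfig:
    """Baum-Welch settings.

    ``n_restarts`` counts independent random initialisations (the best
    final log-likelihood wins); 1000 matches the full field protocol,
    the default of 5 is desk scale. ``variance_floor`` (Hz^2) stops EM
    collapsing a state onto repeated values.
    """

    n_restarts: int = 5
    max_em_iters: int = 100
    loglik_tol: float = 1e-6
    variance_floor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.loglik_tol <= 0:
            raise ValueError("loglik_tol must be positive")


def _pad(seqs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    t_max = max(len(s) for s in seqs)
    obs = np.zeros((len(seqs), t_max))
    mask = np.zeros((len(seqs), t_max), dtype=bool)
    for i, s in enumerate(seqs):
        obs[i, : len(s)] = s
        mask[i, : len(s)] = True
    return obs, mask


def _forward_backward(
    params: HMMParams, obs: np.ndarray, mask: np.ndarray, compute_posteriors: bool = True
):
    """Scaled forward(-backward) over padded sequences.

    Padded frames are given a uniform pseudo-emission so they scale to 1
    and contribute nothing to the log-likelihood or the sufficient
    statistics (which are masked anyway).
    """
    n_seq, t_max = obs.shape
    k = params.n_states
    logb = params.log_emission(obs)  # (n_seq, T, k)
    m = np.max(logb, axis=2)
    btil = np.exp(logb - m[:, :, None])
    btil[~mask] = 1.0
    m = np.where(mask, m, 0.0)

    a = params.transmat
    alpha = np.empty((n_seq, t_max, k))
    c = np.empty((n_seq, t_max))
    step = params.startprob[None, :] * btil[:, 0, :]
    c[:, 0] = step.sum(axis=1)
    alpha[:, 0, :] = step / c[:, 0, None]
    for t in range(1, t_max):
        step = (alpha[:, t - 1, :] @ a) * btil[:, t, :]
        c[:, t] = step.sum(axis=1)
        alpha[:, t, :] = step / c[:, t, None]
    loglik = float(np.sum(np.where(mask, np.log(c) + m, 0.0)))
    if not compute_posteriors:
        return loglik, None, None

    beta = np.empty((n_seq, t_max, k))
    beta[:, -1, :] = 1.0
    for t in range(t_max - 2, -1, -1):
        beta[:, t, :] = (btil[:, t + 1, :] * beta[:, t + 1, :] / c[:, t + 1, None]) @ a.T

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    gamma[~mask] = 0.0
    # xi summed over all transitions t-1 -> t (t masked-in), per sequence pair (i, j)
    xi_sum = np.zeros((k, k))
    for t in range(1, t_max):
        w = (mask[:, t]).astype(float)[:, None]
        left = alpha[:, t - 1, :] * w
        right = btil[:, t, :] * beta[:, t, :] / c[:, t, None]
        xi_sum += (left.T @ right) * a
    return loglik, gamma, xi_sum


def log_likelihood(params: HMMParams, contour) -> float:
    """Forward-algorithm marginal log-likelihood of one contour (nats).

    Computed with per-frame scaling, so contours of 1e5 frames do not
    underflow. Empty contours are invalid.
    """
    values = contour.values_hz if isinstance(contour, F0Contour) else np.asarray(contour, float)
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot score an empty contour")
    obs, mask = values[None, :], np.ones((1, len(values)), dtype=bool)
    ll, _, _ = _forward_backward(params, obs, mask, compute_posteriors=False)
    return ll


class GaussianHMM:
    """Gaussian-emission HMM model bound to a set of observation sequences.

    Parameters
    ----------
    contours : sequence of F0Contour or 1-D arrays
        The training observation sequences (F0 values in Hz). Empty
        contours are ignored; all-empty input is invalid.
    n_states : int
        Number of hidden states (2 throughout the roaring-bout analysis).
    """

    def __init__(self, contours, n_states: int = 2):
        self.sequences = _as_sequences(contours)
        if not self.sequences:
            raise ValueError("all contours are empty; nothing to fit")
        self.n_states = int(n_states)
        total = sum(len(s) for s in self.sequences)
        if total < 2 * self.n_states:
            raise ValueError(f"need >= {2 * self.n_states} total frames, got {total}")
        self._obs, self._mask = _pad(self.sequences)
        self._pooled = np.concatenate(self.sequences)

    def _init_params(self, rng: np.random.Generator, floor: float) -> HMMParams:
        lo, hi = np.quantile(self._pooled, [0.05, 0.95])
        means = rng.uniform(lo, hi if hi > lo else lo + 1.0, size=self.n_states)
        var = max(float(np.var(self._pooled)), floor)
        startprob = rng.dirichlet(np.full(self.n_states, 5.0))
        transmat = rng.dirichlet(np.full(self.n_states, 5.0), size=self.n_states)
        return HMMParams(startprob, transmat, means, np.full(self.n_states, var))

    def _em(self, params: HMMParams, cfg: FitConfig) -> tuple[HMMParams, list[float]]:
        history: list[float] = []
        prev = -np.inf
        for _ in range(cfg.max_em_iters):
            loglik, gamma, xi_sum = _forward_backward(params, self._obs, self._mask)
            history.append(loglik)
            # M-step
            first = gamma[:, 0, :].sum(axis=0)
            startprob = first / first.sum()
            rows = xi_sum.sum(axis=1, keepdims=True)
            transmat = np.where(rows > 0, xi_sum / np.where(rows > 0, rows, 1.0),
                                1.0 / self.n_states)
            occ = gamma.sum(axis=(0, 1))
            occ_safe = np.where(occ > 0, occ, 1.0)
            means = np.einsum("stk,st->k", gamma, self._obs) / occ_safe
            sq = np.einsum("stk,stk->k", gamma, (self._obs[:, :, None] - means) ** 2)
            variances = np.maximum(sq / occ_safe, cfg.variance_floor)
            params = HMMParams(startprob, transmat, means, variances)
            if np.isfinite(prev) and abs(loglik - prev) <= cfg.loglik_tol * abs(prev):
                break
            prev = loglik
        return params, history

    def fit(self, cfg: FitConfig = FitConfig()) -> "HMMResults":
        """Run Baum-Welch from ``cfg.n_restarts`` random initialisations and
        keep the restart with the highest final training log-likelihood."""
        seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_restarts)
        best = None
        restart_logliks = []
        for ss in seeds:
            rng = np.random.default_rng(ss)
            params, history = self._em(self._init_params(rng, cfg.variance_floor), cfg)
            final, _, _ = _forward_backward(params, self._obs, self._mask,
                                            compute_posteriors=False)
            restart_logliks.append(final)
            if best is None or final > best[1]:
                best = (params, final, history)
        params, loglik, history = best
        return HMMResults(
            model=self, params=params, loglik=loglik, config=cfg,
            restart_logliks=np.array(restart_logliks), history=np.array(history),
        )


@dataclass(frozen=True)
class HMMResults:
    """A fitted HMM: parameters, the winning restart's EM trace, and the
    per-restart final log-likelihoods."""

    model: GaussianHMM
    params: HMMParams
    loglik: float
    config: FitConfig
    restart_logliks: np.ndarray
    history: np.ndarray = field(default_factory=lambda: np.array([]))

    def log_likelihood(self, contour) -> float:
        return log_likelihood(self.params, contour)

    @property
    def n_iter(self) -> int:
        return len(self.history)

    def sorted_by_mean(self) -> HMMParams:
        """Parameters with states reordered by ascending emission mean
        (removes label-switching for comparisons)."""
        order = np.argsort(self.params.means)
        return HMMParams(
            self.params.startprob[order],
            self.params.transmat[np.ix_(order, order)],
            self.params.means[order],
            self.params.variances[order],
        )

    def summary(self) -> str:
        p = self.params
        lines = [
            "Gaussian HMM fit",
            "=" * 44,
            f"states: {p.n_states}   sequences: {len(self.model.sequences)}   "
            f"frames: {sum(len(s) for s in self.model.sequences)}",
            f"log-likelihood: {self.loglik:.4f}   EM iterations: {self.n_iter}   "
            f"restarts: {len(self.restart_logliks)}",
            "",
            f"{'state':>5} {'mean (Hz)':>12} {'sd (Hz)':>10} {'start p':>9}",
        ]
        for k in range(p.n_states):
            lines.append(
                f"{k:>5} {p.means[k]:>12.3f} {math.sqrt(p.variances[k]):>10.3f} "
                f"{p.startprob[k]:>9.4f}"
            )
        lines.append("")
        lines.append("transition matrix:")
        for k in range(p.n_states):
            lines.append("  " + "  ".join(f"{v:.4f}" for v in p.transmat[k]))
        return "\n".join(lines)

    def to_text(self) -> str:
        """Serialize parameters as plain key=value lines."""
        p = self.params
        fmt = "{:.17g}".format
        parts = [
            f"n_states={p.n_states}",
            "startprob=" + ",".join(fmt(v) for v in p.startprob),
            "transmat=" + ";".join(",".join(fmt(v) for v in row) for row in p.transmat),
            "means=" + ",".join(fmt(v) for v in p.means),
            "variances=" + ",".join(fmt(v) for v in p.variances),
        ]
        return "\n".join(parts) + "\n"


def params_from_text(text: str) -> HMMParams:
    """Inverse of :meth:`HMMResults.to_text`."""
    fields = dict(line.split("=", 1) for line in text.strip().splitlines())
    return HMMParams(
        np.array([float(v) for v in fields["startprob"].split(",")]),
        np.array([[float(v) for v in row.split(",")] for row in fields["transmat"].split(";")]),
        np.array([float(v) for v in fields["means"].split(",")]),
        np.array([float(v) for v in fields["variances"].split(",")]),
    )


def fit_hmm(contours, cfg: FitConfig = FitConfig(), n_states: int = 2) -> HMMResults:
    """Convenience wrapper: fit a ``n_states``-state Gaussian HMM to contours."""
    return GaussianHMM(contours, n_states=n_states).fit(cfg)
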