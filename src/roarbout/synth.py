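"""Synthetic roaring-bout generator.

Field recordings of lions are not redistributable, so every stage of the
pipeline is exercised on synthetic bouts with the statistical structure
the analysis assumes:

* a bout's grammar is fixed — moans, then full-throated roars (FTRs),
  then intermediary roars (IRs), then grunts;
* each call type has its own duration and maximum-frequency
  distribution, laid out so grunts are short and low, IRs intermediate,
  FTRs long and high, and moans overlap the roars in duration while
  sitting low in frequency (which is exactly why moans are removed
  before clustering);
* F0 contours follow parametric templates — an asymmetric rise/fall
  arch in log-F0 for roars, a quasi-flat low rumble for moans, a brief
  symmetric pulse for grunts — with Gaussian frame noise;
* each individual lion carries a multiplicative signature (peak-F0
  scale, arch asymmetry, duration scale) that makes its FTRs
  identifiable.

All templates are parametric stand-ins with controllable ground truth,
not estimates of any real population's call parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .audio import AudioClip, CallAnnotation
from .f0 import F0Contour

__all__ = [
    "CallTypeSpec",
    "IndividualSpec",
    "BoutSpec",
    "default_type_specs",
    "gen_contour",
    "gen_bout",
    "gen_dataset",
    "render_audio",
    "Dataset",
]

#: contour frame spacing, matching the F0 extractor's default hop
#: (64 samples at 16 kHz).
FRAME_DT = 0.004

# Feature anchors: grand means the call-type means collapse onto when
# separation -> 0, and the reference scatters that give "separation" its
# units (SD units between adjacent non-moan class means).
_ANCHOR_DURATION = 0.7125
_ANCHOR_FREQ = 190.0
_REF_SD_DURATION = 0.117
_REF_SD_FREQ = 30.0
_REF_SEPARATION = 3.0


@dataclass(frozen=True)
class CallTypeSpec:
    """Distributional spec of one call type.

    ``duration_s`` / ``max_freq_hz`` are (mean, sd) of the per-call
    feature draws; ``contour_shape`` is one of ``arch`` (roars),
    ``flat`` (moans) or ``pulse`` (grunts); ``count_per_bout`` bounds the
    number of calls of this type per bout (inclusive).
    """

    call_type: str
    duration_s: tuple[float, float]
    max_freq_hz: tuple[float, float]
    contour_shape: str
    count_per_bout: tuple[int, int]
    rise_frac: float = 0.25  # arch: fraction of duration spent rising
    start_frac: float = 0.55  # arch/pulse: start F0 as fraction of peak
    end_frac: float = 0.60  # arch: final F0 as fraction of peak
    level_frac: float = 0.50  # flat: contour level as fraction of max freq
    peak_frac: float = 1.0  # pulse/arch: contour peak as fraction of max freq
    noise_hz: float = 4.0  # per-frame Gaussian jitter
    wobble_hz: float = 4.0  # flat: slow sinusoidal drift amplitude

    def __post_init__(self) -> None:
        if self.duration_s[0] <= 0 or self.max_freq_hz[0] <= 0:
            raise ValueError("means must be positive")
        if self.duration_s[1] < 0 or self.max_freq_hz[1] < 0:
            raise ValueError("sds must be non-negative")
        if self.contour_shape not in ("arch", "flat", "pulse"):
            raise ValueError(f"unknown contour_shape {self.contour_shape!r}")


@dataclass(frozen=True)
class IndividualSpec:
    """A lion's multiplicative contour signature."""

    lion_id: str
    peak_scale: float = 1.0  # scales peak F0 (and the max-frequency feature)
    asymmetry_scale: float = 1.0  # scales the arch's rising fraction
    duration_scale: float = 1.0
    bout_count: int = 0

    def __post_init__(self) -> None:
        if min(self.peak_scale, self.asymmetry_scale, self.duration_scale) <= 0:
            raise ValueError("signature scales must be positive")


@dataclass(frozen=True)
class BoutSpec:
    """Grammar of a bout: stage order is fixed; counts come from the type
    specs' ``count_per_bout`` ranges; calls are separated by positive
    inter-call gaps."""

    stage_order: tuple[str, ...] = ("moan", "full_throated_roar", "intermediary_roar", "grunt")
    gap_s: tuple[float, float] = (0.8, 0.3)
    min_gap_s: float = 0.1


def default_type_specs(separation: float = _REF_SEPARATION) -> dict[str, CallTypeSpec]:
    """The default study conditions, optionally rescaled by ``separation``.

    ``separation`` moves the call-type feature means away from their grand
    anchors in units of a (30 Hz, 0.117 s) reference scatter; at 0 all
    types share the same means and are indistinguishable on these two
    features. Within-type sds are fixed.
    """
    base = {
        # Moans are deliberately high-variance: they straddle the roars in
        # duration while sitting low in frequency, which is what defeats
        # the 4-cluster run and motivates removing them before clustering.
        "moan": CallTypeSpec(
            "moan", (1.2, 0.45), (110.0, 45.0), "flat", (1, 3)),
        "full_throated_roar": CallTypeSpec(
            "full_throated_roar", (1.0, 0.06), (320.0, 8.0), "arch", (2, 5)),
        "intermediary_roar": CallTypeSpec(
            "intermediary_roar", (0.5, 0.06), (210.0, 8.0), "arch", (2, 5)),
        "grunt": CallTypeSpec(
            "grunt", (0.15, 0.03), (120.0, 8.0), "pulse", (4, 10)),
    }
    if separation == _REF_SEPARATION:
        return base
    if separation < 0:
        raise ValueError("separation must be >= 0")
    scale = separation / _REF_SEPARATION
    out = {}
    for name, spec in base.items():
        dur = _ANCHOR_DURATION + scale * (spec.duration_s[0] - _ANCHOR_DURATION)
        freq = _ANCHOR_FREQ + scale * (spec.max_freq_hz[0] - _ANCHOR_FREQ)
        out[name] = replace(
            spec, duration_s=(max(dur, 0.08), spec.duration_s[1]),
            max_freq_hz=(max(freq, 50.0), spec.max_freq_hz[1]),
        )
    return out


def contour_template(
    spec: CallTypeSpec, duration_s: float, max_freq_hz: float,
    rise_frac: float | None = None, frame_dt: float = FRAME_DT,
) -> np.ndarray:
    """Deterministic (noise-free) F0 template sampled every ``frame_dt``."""
    n = max(int(round(duration_s / frame_dt)), 2)
    u = np.linspace(0.0, 1.0, n)  # position within the call
    if spec.contour_shape == "flat":
        return np.full(n, spec.level_frac * max_freq_hz)
    peak = spec.peak_frac * max_freq_hz
    if spec.contour_shape == "pulse":
        # symmetric rise/fall in log-F0
        log_f = np.interp(u, [0.0, 0.5, 1.0],
                          np.log([spec.start_frac * peak, peak, spec.start_frac * peak]))
        return np.exp(log_f)
    r = min(max(rise_frac if rise_frac is not None else spec.rise_frac, 0.02), 0.98)
    log_f = np.interp(u, [0.0, r, 1.0],
                      np.log([spec.start_frac * peak, peak, spec.end_frac * peak]))
    return np.exp(log_f)


def gen_contour(
    spec: CallTypeSpec,
    individual: IndividualSpec | None = None,
    rng_seed: int | np.random.Generator = 0,
    duration_s: float | None = None,
    max_freq_hz: float | None = None,
    start_s: float = 0.0,
    frame_dt: float = FRAME_DT,
) -> F0Contour:
    """Sample one call's F0 contour from its type template.

    ``duration_s`` / ``max_freq_hz`` may be given (e.g. drawn upstream by
    :func:`gen_bout`); otherwise they are drawn from the spec, with the
    individual's signature applied multiplicatively.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    ind = individual or IndividualSpec("anon")
    if duration_s is None:
        duration_s = max(
            rng.normal(spec.duration_s[0] * ind.duration_scale, spec.duration_s[1]),
            3 * frame_dt,
        )
    if max_freq_hz is None:
        max_freq_hz = max(
            rng.normal(spec.max_freq_hz[0] * ind.peak_scale, spec.max_freq_hz[1]), 40.0
        )
    values = contour_template(
        spec, duration_s, max_freq_hz,
        rise_frac=spec.rise_frac * ind.asymmetry_scale, frame_dt=frame_dt,
    )
    n = len(values)
    if spec.contour_shape == "flat" and spec.wobble_hz > 0:
        phase = rng.uniform(0, 2 * np.pi)
        values = values + spec.wobble_hz * np.sin(
            phase + np.linspace(0, 2 * np.pi, n)
        )
    if spec.noise_hz > 0:
        values = values + rng.normal(0.0, spec.noise_hz, size=n)
    values = np.maximum(values, 20.0)
    times = start_s + frame_dt * np.arange(n)
    return F0Contour(values, times, meta={"call_type": spec.call_type,
                                          "lion_id": ind.lion_id})


def gen_bout(
    bout_spec: BoutSpec,
    type_specs: dict[str, CallTypeSpec],
    individual: IndividualSpec,
    rng_seed: int | np.random.Generator = 0,
    bout_id: str = "bout0",
    counts: dict[str, int] | None = None,
) -> tuple[list[CallAnnotation], list[F0Contour]]:
    """Generate one bout: annotations in grammar order (moans before FTRs
    before IRs before grunts), non-overlapping in time, each paired 1:1
    with its F0 contour."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    annotations: list[CallAnnotation] = []
    contours: list[F0Contour] = []
    t = 0.0
    for stage in bout_spec.stage_order:
        spec = type_specs[stage]
        if counts is not None:
            n_calls = counts.get(stage, 0)
            if n_calls < 0:
                raise ValueError(f"negative count for stage {stage!r}")
        else:
            lo, hi = spec.count_per_bout
            n_calls = int(rng.integers(lo, hi + 1))
        for _ in range(n_calls):
            duration = max(
                rng.normal(spec.duration_s[0] * individual.duration_scale,
                           spec.duration_s[1]),
                3 * FRAME_DT,
            )
            max_freq = max(
                rng.normal(spec.max_freq_hz[0] * individual.peak_scale,
                           spec.max_freq_hz[1]),
                40.0,
            )
            contour = gen_contour(
                spec, individual, rng, duration_s=duration, max_freq_hz=max_freq,
                start_s=t,
            )
            duration = len(contour) * FRAME_DT  # snap to the frame grid
            annotations.append(
                CallAnnotation(
                    begin_s=t, end_s=t + duration, max_freq_hz=max_freq,
                    duration_s=duration, call_type=stage, bout_id=bout_id,
                    source_id=individual.lion_id,
                )
            )
            contours.append(contour)
            gap = max(rng.normal(*bout_spec.gap_s), bout_spec.min_gap_s)
            t += duration + gap
    return annotations, contours


@dataclass(frozen=True)
class Dataset:
    """A labeled synthetic corpus: per-call annotations and contours,
    grouped by (lion, bout), plus the generating specs."""

    annotations: list[CallAnnotation]
    contours: list[F0Contour]
    individuals: list[IndividualSpec]
    type_specs: dict[str, CallTypeSpec]
    seed: int

    def truth(self) -> pd.DataFrame:
        """Per-call truth table (one row per annotation, file order)."""
        return pd.DataFrame(
            {
                "lion_id": [a.source_id for a in self.annotations],
                "bout_id": [a.bout_id for a in self.annotations],
                "call_type": [a.call_type for a in self.annotations],
                "begin_s": [a.begin_s for a in self.annotations],
                "end_s": [a.end_s for a in self.annotations],
                "duration_s": [a.duration_s for a in self.annotations],
                "max_freq_hz": [a.max_freq_hz for a in self.annotations],
            }
        )

    def labeled_calls(self, call_types=None) -> list[tuple[F0Contour, str]]:
        """(contour, call_type) pairs, optionally restricted to some types."""
        return [
            (c, a.call_type)
            for a, c in zip(self.annotations, self.contours)
            if call_types is None or a.call_type in call_types
        ]

    def bouts(self, call_types=("full_throated_roar",)) -> list[tuple[str, str, list[F0Contour]]]:
        """(lion_id, bout_id, contours) triples holding the chosen call
        types (default: the FTRs, the identity-bearing calls)."""
        grouped: dict[tuple[str, str], list[F0Contour]] = {}
        order: list[tuple[str, str]] = []
        for a, c in zip(self.annotations, self.contours):
            key = (a.source_id, a.bout_id)
            if key not in grouped:
                grouped[key] = []
                order.append(key)
            if a.call_type in call_types:
                grouped[key].append(c)
        return [(lion, bout, grouped[(lion, bout)]) for lion, bout in order
                if grouped[(lion, bout)]]

    def write(self, out_dir, audio: bool = False, rate: int = 16000) -> None:
        """Lay the corpus out on disk: ``truth.tsv`` (per-call truth),
        ``contours.tsv`` (long format, one row per frame), per-bout
        Raven-style selection tables under ``selections/`` and, when
        ``audio`` is set, one rendered WAV per call under ``audio/``."""
        from pathlib import Path

        from .audio import write_selection_table, write_wav

        out = Path(out_dir)
        (out / "selections").mkdir(parents=True, exist_ok=True)
        self.truth().to_csv(out / "truth.tsv", sep="\t", index=False)
        rows = []
        for idx, (a, c) in enumerate(zip(self.annotations, self.contours)):
            for t, f in zip(c.frame_times_s, c.values_hz):
                rows.append((a.source_id, a.bout_id, idx, a.call_type, t, f))
        pd.DataFrame(
            rows,
            columns=["lion_id", "bout_id", "call_idx", "call_type",
                     "frame_time_s", "f0_hz"],
        ).to_csv(out / "contours.tsv", sep="\t", index=False)
        by_bout: dict[str, list[CallAnnotation]] = {}
        for a in self.annotations:
            by_bout.setdefault(a.bout_id, []).append(a)
        for bout_id, anns in by_bout.items():
            write_selection_table(out / "selections" / f"{bout_id}.txt", anns)
        if audio:
            (out / "audio").mkdir(exist_ok=True)
            for idx, c in enumerate(self.contours):
                write_wav(out / "audio" / f"call_{idx:05d}.wav",
                          render_audio(c, rate=rate, seed=self.seed + idx))


def load_calls(path) -> tuple[list[CallAnnotation], list[F0Contour]]:
    """Reload a corpus written by :meth:`Dataset.write` as aligned
    (annotations, contours) lists."""
    from pathlib import Path

    out = Path(path)
    truth = pd.read_csv(out / "truth.tsv", sep="\t")
    long = pd.read_csv(out / "contours.tsv", sep="\t")
    annotations = [
        CallAnnotation(
            begin_s=row.begin_s, end_s=row.end_s, max_freq_hz=row.max_freq_hz,
            duration_s=row.duration_s, call_type=row.call_type,
            bout_id=row.bout_id, source_id=row.lion_id,
        )
        for row in truth.itertuples()
    ]
    contours = []
    for idx, group in long.groupby("call_idx", sort=True):
        contours.append(
            F0Contour(
                group["f0_hz"].to_numpy(), group["frame_time_s"].to_numpy(),
                meta={"call_type": group["call_type"].iloc[0],
                      "lion_id": group["lion_id"].iloc[0]},
            )
        )
    if len(annotations) != len(contours):
        raise ValueError("truth.tsv and contours.tsv disagree on call count")
    return annotations, contours


def gen_dataset(
    n_individuals: int,
    bouts_per_individual: int,
    separation: float = _REF_SEPARATION,
    seed: int = 0,
    identity_spread: float = 0.2,
    bout_spec: BoutSpec = BoutSpec(),
    type_specs: dict[str, CallTypeSpec] | None = None,
) -> Dataset:
    """Generate a full labeled corpus.

    ``separation`` spaces the call-type feature means (see
    :func:`default_type_specs`); ``identity_spread`` is the fractional
    range of the lions' peak-F0 scales (0.2 = 20% between the lowest- and
    highest-pitched lion), with arch asymmetry and duration signatures
    spread alongside. Seeding is counter-based: bout (i, j) is generated
    from ``SeedSequence(seed, spawn_key=(i, j))``, so any subset of the
    corpus regenerates identically.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    specs = type_specs if type_specs is not None else default_type_specs(separation)
    if n_individuals == 1:
        peak = np.array([1.0])
        asym = np.array([1.0])
        durs = np.array([1.0])
    else:
        peak = np.linspace(1 - identity_spread / 2, 1 + identity_spread / 2, n_individuals)
        # interleave the asymmetry signature so neighbours in pitch differ in shape
        asym = 0.7 + 0.6 * ((np.arange(n_individuals) * 2 + 1) % n_individuals) / max(
            n_individuals - 1, 1
        )
        durs = np.linspace(0.95, 1.05, n_individuals)
    individuals = [
        IndividualSpec(f"L{i + 1}", peak_scale=float(peak[i]),
                       asymmetry_scale=float(asym[i]), duration_scale=float(durs[i]),
                       bout_count=bouts_per_individual)
        for i in range(n_individuals)
    ]
    annotations: list[CallAnnotation] = []
    contours: list[F0Contour] = []
    for i, ind in enumerate(individuals):
        for j in range(bouts_per_individual):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(i, j))
            anns, cts = gen_bout(
                bout_spec, specs, ind, rng_seed=np.random.default_rng(ss),
                bout_id=f"{ind.lion_id}_b{j + 1}",
            )
            annotations.extend(anns)
            contours.extend(cts)
    return Dataset(annotations, contours, individuals, specs, seed)


def render_audio(
    contour: F0Contour,
    rate: int = 16000,
    harmonics: int = 3,
    snr_db: float = 40.0,
    seed: int = 0,
) -> AudioClip:
    """Render a contour as a harmonic stack plus white noise.

    Harmonic k of the instantaneous F0 gets amplitude 1/k; noise power is
    set from ``snr_db`` relative to the harmonic signal. The clip spans
    the contour's frame times.
    """
    if len(contour) == 0:
        raise ValueError("contour is empty")
    if harmonics < 1:
        raise ValueError("harmonics must be >= 1")
    f_max = float(np.max(contour.values_hz)) * harmonics
    if rate < 2 * f_max:
        raise ValueError(
            f"rate {rate} Hz cannot represent harmonic content up to {f_max:.0f} Hz"
        )
    t0, t1 = contour.frame_times_s[0], contour.frame_times_s[-1]
    n = max(int(round((t1 - t0) * rate)), rate // 100) + 1
    t = t0 + np.arange(n) / rate
    f_inst = np.interp(t, contour.frame_times_s, contour.values_hz)
    phase = 2 * np.pi * np.cumsum(f_inst) / rate
    x = np.zeros(n)
    for k in range(1, harmonics + 1):
        x += np.sin(k * phase) / k
    rng = np.random.default_rng(seed)
    p_signal = float(np.mean(x**2))
    p_noise = p_signal / (10 ** (snr_db / 10.0))
    x = x + rng.normal(0.0, np.sqrt(p_noise), size=n)
    return AudioClip(x, rate)
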