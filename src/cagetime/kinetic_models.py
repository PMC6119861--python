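"""The four kinetic signatures, their priors, and series normalization.

A promoter time course is summarised by one of four archetypal shapes:

* ``linear`` — slow drift, ``a + b*t``;
* ``decay`` — monotone relaxation toward an asymptote,
  ``base + amp*exp(-k*t)``;
* ``dip`` — transient repression: a drop to a minimum followed by recovery,
  modelled as a depth-normalised difference of exponentials;
* ``peak`` — the immediate-early signature: baseline ``p1`` until a delay
  ``td``, an exponential rise of duration ``ts`` to ``p1 + p2`` at the peak
  time ``t_p = td + ts``, then exponential relaxation back toward ``p1``.

The peak model is fitted in two rate variants, ``fast`` and ``slow`` (the
slow variant has its rate priors scaled down), to capture transcripts
peaking late in the window; the decision step keeps whichever fits best.

All fitting happens on a normalized scale where the per-time median
trajectory spans exactly [0, 10], which lets one set of prior ranges apply
to every series regardless of its absolute expression level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _engine

MODEL_IDS = {
    "linear": _engine.MODEL_LINEAR,
    "decay": _engine.MODEL_DECAY,
    "dip": _engine.MODEL_DIP,
    "peak": _engine.MODEL_PEAK,
    "const": _engine.MODEL_CONST,
}

#: span of the normalized scale (median min -> 0, median max -> NORM_SPAN)
NORM_SPAN = 10.0


class DegenerateSeriesError(ValueError):
    """Raised when a series has a constant median trajectory (unnormalizable)."""


@dataclass(frozen=True)
class ModelSpec:
    """A kinetic signature with named parameters and uniform prior box."""

    name: str
    variant: str
    param_names: tuple
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.size != len(self.param_names) or hi.size != lo.size:
            raise ValueError("prior bounds must match parameter names")
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
            raise ValueError("prior ranges must be finite")
        if not np.all(hi > lo):
            raise ValueError("upper prior bounds must exceed lower bounds")

    @property
    def key(self) -> str:
        return f"{self.name}_{self.variant}" if self.variant else self.name

    @property
    def model_id(self) -> int:
        return MODEL_IDS[self.name]

    @property
    def ndim(self) -> int:
        return len(self.param_names)

    def contains(self, params) -> bool:
        p = np.asarray(params, dtype=float)
        return bool(np.all(p >= self.lower) and np.all(p <= self.upper))


def build_model_set(t_max: float, rate_range=(1e-3, 1.0), slow_factor: float = 10.0,
                    span: float = NORM_SPAN) -> dict:
    """Default model set for series sampled on [0, t_max] minutes.

    Prior boxes (normalized scale): baselines/amplitudes within the [0, span]
    data range, delays up to 0.8*t_max, rise durations up to t_max, rate
    constants in ``rate_range`` per minute; the slow peak variant divides the
    rate range by ``slow_factor``.
    """
    rlo, rhi = rate_range
    if rlo <= 0 or rhi <= rlo:
        raise ValueError("rate_range must be positive and increasing")
    peak_names = ("p1", "p2", "td", "ts", "r_rise", "r_fall")
    peak_lo = [0.0, 0.1, 0.0, 1.0]
    peak_hi = [span, span, 0.8 * t_max, t_max]
    models = {
        "linear": ModelSpec("linear", "", ("intercept", "slope"),
                            np.array([0.0, -span / t_max]),
                            np.array([span, span / t_max])),
        "decay": ModelSpec("decay", "", ("base", "amp", "k"),
                           np.array([0.0, 0.0, rlo]),
                           np.array([span, span, rhi])),
        "dip": ModelSpec("dip", "", ("base", "amp", "k_a", "k_b"),
                         np.array([0.0, 0.0, rlo, rlo]),
                         np.array([span, span, rhi, rhi])),
        "peak_fast": ModelSpec("peak", "fast", peak_names,
                               np.array(peak_lo + [rlo, rlo]),
                               np.array(peak_hi + [rhi, rhi])),
        "peak_slow": ModelSpec("peak", "slow", peak_names,
                               np.array(peak_lo + [rlo / slow_factor] * 2),
                               np.array(peak_hi + [rhi / slow_factor] * 2)),
    }
    return models


def constant_model(lower: float = 0.0, upper: float = NORM_SPAN) -> ModelSpec:
    """Single-parameter constant model; its evidence has a closed form."""
    return ModelSpec("const", "", ("level",),
                     np.array([lower]), np.array([upper]))


def eval_model(spec: ModelSpec, params, times) -> np.ndarray:
    """Evaluate a kinetic signature at the given times (minutes)."""
    p = np.asarray(params, dtype=float)
    t = np.asarray(times, dtype=float)
    if not spec.contains(p):
        raise ValueError(
            f"parameters outside the prior box of model '{spec.key}'")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    return _engine.eval_curve(spec.model_id, p, t)


def peak_time(params) -> float:
    """Peak time t_p = td + ts of a peak-model parameter vector."""
    p = np.asarray(params, dtype=float)
    td, ts = float(p[2]), float(p[3])
    if td < 0 or ts <= 0:
        raise ValueError("require td >= 0 and ts > 0")
    return td + ts


def fold_change(p1: float, p2: float, floor: float) -> float:
    """log2 induction of a peak: (p1+p2) over max(p1, floor).

    Arguments are on the original TPM scale; the floor keeps near-silent
    baselines from producing unbounded ratios.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    if p2 <= 0:
        raise ValueError("p2 must be > 0")
    return float(np.log2((p1 + p2) / max(p1, floor)))


@dataclass
class NormalizedSeries:
    """A replicated series on the normalized scale, with inverse anchors.

    ``anchor_min``/``anchor_max`` are the original-scale minimum and maximum
    of the per-time median trajectory; they define the affine map applied
    (identically) to every replicate and allow magnitudes to be reported
    back on the original TPM scale.
    """

    times: np.ndarray
    values: np.ndarray            # (replicates, times), normalized
    anchor_min: float
    anchor_max: float
    tss_id: str = ""
    gene_id: str = ""
    dataset_id: str = ""
    biotype: str = "coding"

    @property
    def span(self) -> float:
        return self.anchor_max - self.anchor_min

    def inverse(self, normalized_values) -> np.ndarray:
        """Map normalized values back to the original TPM scale."""
        v = np.asarray(normalized_values, dtype=float)
        return self.anchor_min + v * self.span / NORM_SPAN

    def inverse_delta(self, normalized_delta) -> np.ndarray:
        """Map a normalized difference (e.g. p2) back to a TPM difference."""
        return np.asarray(normalized_delta, dtype=float) * self.span / NORM_SPAN


def normalize_series(times, values, *, tss_id: str = "", gene_id: str = "",
                     dataset_id: str = "", biotype: str = "coding",
                     rel_tol: float = 1e-12) -> NormalizedSeries:
    """Affine-map a replicated series so its median trajectory spans [0, 10].

    The per-time median across replicates is computed first; its minimum and
    maximum are mapped to 0 and 10 and the same map is applied to all
    replicates. A constant median trajectory cannot be normalized and raises
    :class:`DegenerateSeriesError`.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[1] != t.size:
        raise ValueError("values must be (replicates, times)")
    med = np.median(v, axis=0)
    lo, hi = float(np.min(med)), float(np.max(med))
    if hi - lo <= rel_tol * max(abs(hi), 1.0):
        raise DegenerateSeriesError(
            f"constant median trajectory for series '{tss_id}'")
    norm = (v - lo) * (NORM_SPAN / (hi - lo))
    return NormalizedSeries(times=t, values=norm, anchor_min=lo, anchor_max=hi,
                            tss_id=tss_id, gene_id=gene_id,
                            dataset_id=dataset_id, biotype=biotype)
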