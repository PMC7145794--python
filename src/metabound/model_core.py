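"""Deterministic mathematics of the suboptimal observer model.

The observer categorises a sequence of oriented stimuli as coming from one of
two overlapping von Mises orientation distributions (period pi, means at
-pi/4 and +pi/4 relative to vertical, concentration ``kappa``).  Each sample
contributes a log-probability-ratio update; accumulation is corrupted by
i.i.d. Gaussian inference noise (``sigma``) and a geometric temporal weighting
(``alpha``: >1 primacy, <1 recency).  The decision terminates when the
accumulated evidence crosses a collapsing bound, and a confidence rating is
read out from a second (Type-II) accumulator against three ordered criteria of
the same collapsing shape.

Everything in this module is deterministic given its inputs; stochastic
simulation lives in :mod:`metabound.simulator` and Monte-Carlo likelihoods in
:mod:`metabound.likelihood`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Literal, Mapping

import numpy as np

__all__ = [
    "CategoryParams",
    "Type1Params",
    "Type2Params",
    "ModelVariant",
    "compute_evidence",
    "sample_weights",
    "bound_value",
    "accumulate",
    "map_confidence",
]

# Stimulus conditions of the stopping task are labelled by their target
# percent-correct; the free task carries its own label.
STOPPING_CONDITIONS = ("70", "85", "90")


@dataclass(frozen=True)
class CategoryParams:
    """Generative stimulus model: two von Mises orientation distributions.

    Orientations live on a period-pi circle (an orientation and its
    180-degree rotation are the same stimulus); the factor 2 inside the
    cosines of the evidence function implements this convention.

    Parameters
    ----------
    mu1, mu2 : float
        Category means in radians (defaults -pi/4 and +pi/4).
    kappa : float
        Concentration of both distributions (default 0.5, a strongly
        overlapping discrimination).
    """

    mu1: float = -np.pi / 4
    mu2: float = np.pi / 4
    kappa: float = 0.5

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if self.mu1 == self.mu2:
            raise ValueError("category means must differ")


def _as_lam_map(lam) -> dict[str, float]:
    if isinstance(lam, Mapping):
        return {str(k): float(v) for k, v in lam.items()}
    return {"default": float(lam)}


@dataclass(frozen=True)
class Type1Params:
    """Type-I (perceptual) observer parameters.

    sigma : inference-noise SD added to each evidence sample.
    alpha : accumulation weight base; weight on sample n of a length-T
        sequence is alpha**(T-n).
    a, b, lam : collapsing-bound shape.  The positive bound at sample n is
        ``n * (a + b * exp(-n / lam))``; ``lam`` may be a single value or a
        mapping from condition label ("70", "85", "90", "free") to value,
        since the bound's decay is the parameter observers adjust between
        target-performance conditions.
    mu_U, sigma_U : mean and SD (in sample units) of the Gaussian
        non-decision lag between the covert decision and the overt response.
    lapse : probability of a stimulus-independent random choice (fixed at
        0.001 by default).
    bias : additive response bias on the decision variable (fixed at 0 by
        default).
    """

    sigma: float = 0.6
    alpha: float = 1.0
    a: float = 0.2
    b: float = 1.5
    lam: float | Mapping[str, float] = 3.0
    mu_U: float = 2.0
    sigma_U: float = 1.0
    lapse: float = 0.001
    bias: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        for lam in _as_lam_map(self.lam).values():
            if not lam > 0:
                raise ValueError("lam must be > 0")
        if self.sigma_U < 0:
            raise ValueError("sigma_U must be >= 0")
        if not 0 <= self.lapse < 1:
            raise ValueError("lapse must be in [0, 1)")

    def lam_for(self, condition: str | None = None) -> float:
        """Bound decay constant for a task condition."""
        lam_map = _as_lam_map(self.lam)
        if condition is not None and str(condition) in lam_map:
            return lam_map[str(condition)]
        if len(lam_map) == 1:
            return next(iter(lam_map.values()))
        raise KeyError(
            f"no lam for condition {condition!r}; available: {sorted(lam_map)}"
        )

    def with_lam(self, lam) -> "Type1Params":
        return replace(self, lam=lam)

    def to_json(self) -> str:
        d = asdict(self)
        if isinstance(self.lam, Mapping):
            d["lam"] = dict(self.lam)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "Type1Params":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class Type2Params:
    """Type-II (confidence) parameters.

    The confidence accumulator shares the Type-I evidence stream (under the
    default partial coupling) but incurs additional noise ``sigma_c`` and its
    own leak ``alpha_c``.  Ratings 1-4 are read out against three criteria
    that share the collapsing shape (``a_c``, ``b_c``) but have separate
    decay constants ``lam1 <= lam2 <= lam3`` so that more evidence is always
    required for higher confidence.

    ``a_bound, b_bound, lam_bound`` parameterise an optional independent
    covert bound on Type-II accumulation (used only by the
    ``type2_bound="independent"`` model variant).
    """

    sigma_c: float = 0.8
    alpha_c: float = 1.0
    a_c: float = 0.2
    b_c: float = 1.5
    lam1: float = 2.0
    lam2: float = 4.0
    lam3: float = 7.0
    a_bound: float | None = None
    b_bound: float | None = None
    lam_bound: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_c < 0:
            raise ValueError("sigma_c must be >= 0")
        if not self.alpha_c > 0:
            raise ValueError("alpha_c must be > 0")
        for lam in (self.lam1, self.lam2, self.lam3):
            if not lam > 0:
                raise ValueError("criterion decay constants must be > 0")

    def criteria(self, n: int) -> np.ndarray:
        """The three confidence criteria evaluated at sample index ``n``."""
        crit = np.array(
            [bound_value(n, self.a_c, self.b_c, lam)
             for lam in (self.lam1, self.lam2, self.lam3)]
        )
        if not (crit[0] <= crit[1] <= crit[2]):
            raise ValueError(
                f"confidence criteria unordered at n={n}: {crit}"
            )
        return crit

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "Type2Params":
        return cls(**json.loads(s))


CovertBound = Literal["none", "absorbing", "reflexive"]
Type2Coupling = Literal["same_z", "independent", "partial"]
Type2Bound = Literal["none", "same_as_type1", "independent"]
Type2NoiseMode = Literal["per_sample", "single_sample"]


@dataclass(frozen=True)
class ModelVariant:
    """Architecture flags spanning the model-comparison space.

    The default configuration — an absorbing covert bound on Type-I
    accumulation, partial Type-I/Type-II coupling (shared evidence stream
    plus additional Type-II noise and leak), and no bound on Type-II
    accumulation — is the winning architecture of the model comparison.
    """

    covert_bound: CovertBound = "absorbing"
    type2_coupling: Type2Coupling = "partial"
    type2_bound: Type2Bound = "none"
    type2_noise_mode: Type2NoiseMode = "per_sample"

    def __post_init__(self) -> None:
        if self.covert_bound not in ("none", "absorbing", "reflexive"):
            raise ValueError(f"unknown covert_bound {self.covert_bound!r}")
        if self.type2_coupling not in ("same_z", "independent", "partial"):
            raise ValueError(f"unknown type2_coupling {self.type2_coupling!r}")
        if self.type2_bound not in ("none", "same_as_type1", "independent"):
            raise ValueError(f"unknown type2_bound {self.type2_bound!r}")
        if self.type2_noise_mode not in ("per_sample", "single_sample"):
            raise ValueError(
                f"unknown type2_noise_mode {self.type2_noise_mode!r}"
            )

    @property
    def label(self) -> str:
        return (
            f"cb={self.covert_bound},c={self.type2_coupling},"
            f"b2={self.type2_bound},nm={self.type2_noise_mode}"
        )


def compute_evidence(theta, cat: CategoryParams = CategoryParams()):
    """Log-probability-difference evidence carried by orientation ``theta``.

    Returns ``kappa*cos(2*(theta - mu1)) - kappa*cos(2*(theta - mu2))``:
    positive values favour category 1.  With the default categories this
    equals ``-2*kappa*sin(2*theta)`` and is bounded in ``[-2*kappa, 2*kappa]``.
    Accepts scalars or arrays.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("orientations must be finite")
    out = cat.kappa * (
        np.cos(2.0 * (theta - cat.mu1)) - np.cos(2.0 * (theta - cat.mu2))
    )
    return out if out.ndim else float(out)


def sample_weights(alpha: float, T: int) -> np.ndarray:
    """Weights ``v_n = alpha**(T - n)`` on samples 1..T; the last is 1."""
    if T < 1:
        raise ValueError(f"sequence length must be >= 1, got {T}")
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    return alpha ** (T - np.arange(1, T + 1, dtype=float))


def bound_value(n, a: float, b: float, lam: float):
    """Positive collapsing bound ``n * (a + b*exp(-n/lam))`` at sample ``n``.

    The negative bound is its mirror image.  The per-sample bound
    ``a + b*exp(-n/lam)`` decays from ``a + b`` toward the asymptote ``a``,
    approximating a constant bound on the probability of a correct response.
    """
    if not lam > 0:
        raise ValueError("lam must be > 0")
    n = np.asarray(n, dtype=float)
    out = n * (a + b * np.exp(-n / lam))
    return out if out.ndim else float(out)


def accumulate(stream, alpha: float) -> np.ndarray:
    """Leaky accumulation trajectory of a noisy evidence stream.

    ``stream`` holds the per-sample inputs (evidence plus noise); the
    trajectory follows ``z_N = alpha * z_{N-1} + stream_N``, so the weight on
    sample n at current length N is ``alpha**(N-n)`` — the weighting is
    re-applied as the sequence grows, which is the only form consistent with
    online stopping.
    """
    stream = np.asarray(stream, dtype=float)
    if stream.size == 0:
        raise ValueError("evidence stream must be non-empty")
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    z = np.empty_like(stream)
    acc = 0.0
    for i, x in enumerate(stream):
        acc = alpha * acc + x
        z[i] = acc
    return z


def map_confidence(z_c: float, T: int, crit: Type2Params) -> int:
    """Confidence rating 1-4 from the magnitude of the Type-II evidence.

    The three criteria are evaluated at the trial's final sample index ``T``;
    the rating depends only on ``|z_c|``, never on its sign.
    """
    lam1, lam2, lam3 = crit.criteria(T)
    m = abs(z_c)
    if m < lam1:
        return 1
    if m < lam2:
        return 2
    if m < lam3:
        return 3
    return 4
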