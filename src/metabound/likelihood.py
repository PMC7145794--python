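"""Trial-level likelihoods for the suboptimal accumulation model.

There is no closed form for the first-passage distribution of the bounded
leaky accumulator, so the likelihood of responding with choice ``r`` at
sample ``n`` is estimated by Monte-Carlo simulation: frequencies of first
bound crossings over many draws of the inference noise (1000 by default),
sharing the trial's orientation sequence.  The crossing distribution is then
convolved with a discretised Gaussian non-decision kernel to give the
response-sample distribution.  For fixed-length (replay-style) trials with
no covert bound, the end-of-sequence evidence is exactly Gaussian and the
choice probability has an analytic form used as an internal oracle.

All Monte-Carlo estimators take an explicit seed and draw one frozen noise
matrix, so repeated evaluations at different parameter values share common
random numbers — the negative log-likelihood surface is then a deterministic
function of the parameters, which derivative-free optimisers require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .model_core import (
    CategoryParams,
    ModelVariant,
    Type1Params,
    Type2Params,
    bound_value,
    compute_evidence,
    sample_weights,
)
from .simulator import TrialBank

__all__ = [
    "ResponsePMF",
    "response_pmf_mc",
    "convolve_nondecision",
    "choice_prob_analytic",
    "nll_stopping",
    "nll_replay",
    "epsilon_floor",
]

# Frozen standard-normal matrices keyed by (seed, shape): the same noise is
# reused across optimiser evaluations (common random numbers), and
# regenerating 10^6 draws per evaluation would dominate the fit time.
_NOISE_CACHE: dict[tuple, np.ndarray] = {}
_NOISE_CACHE_MAX = 8


def _frozen_noise(seed: int, shape: tuple[int, ...]) -> np.ndarray:
    key = ("n", int(seed), shape)
    if key not in _NOISE_CACHE:
        if len(_NOISE_CACHE) >= _NOISE_CACHE_MAX:
            _NOISE_CACHE.pop(next(iter(_NOISE_CACHE)))
        _NOISE_CACHE[key] = np.random.default_rng(seed).standard_normal(shape)
    return _NOISE_CACHE[key]


def _frozen_uniform(seed: int, shape: tuple[int, ...]) -> np.ndarray:
    key = ("u", int(seed), shape)
    if key not in _NOISE_CACHE:
        if len(_NOISE_CACHE) >= _NOISE_CACHE_MAX:
            _NOISE_CACHE.pop(next(iter(_NOISE_CACHE)))
        _NOISE_CACHE[key] = np.random.default_rng(seed).random(shape)
    return _NOISE_CACHE[key]


def epsilon_floor(lapse: float = 0.001) -> float:
    """Floor applied to response-cell probabilities before taking logs.

    Scaled from the lapse rate spread over the response space
    (2 choices x 40 samples x 4 ratings), keeping log-likelihoods finite
    with semantics consistent with the lapse mixture.
    """
    return lapse / (2 * 40 * 4)


@dataclass
class ResponsePMF:
    """Per-trial likelihood over (choice, decision sample).

    ``f[c, n]`` is the probability of first crossing toward choice ``c+1``
    at sample ``n+1``; ``censor_mass`` is the probability of no crossing by
    the last sample, with its split by the forced choice's sign in
    ``censor_by_choice``.  ``forced()`` reallocates that mass to a forced
    response at the last sample, mirroring the task rule.
    """

    f: np.ndarray  # (2, T)
    censor_mass: float
    censor_by_choice: np.ndarray  # (2,)

    @property
    def T(self) -> int:
        return self.f.shape[1]

    def total_mass(self) -> float:
        return float(self.f.sum() + self.censor_mass)

    def forced(self) -> "ResponsePMF":
        f = self.f.copy()
        f[:, -1] += self.censor_by_choice
        return ResponsePMF(f, 0.0, np.zeros(2))

    def prob(self, choice: int, n: int) -> float:
        return float(self.f[choice - 1, n - 1])


def _first_passage_counts(ell, alpha, sigma, a, b, lam, eps, bias=0.0):
    """First-crossing (sample, sign) for every noise path of every trial.

    ``ell``: (n_trials, T) evidence; ``eps``: (n_mc, n_trials, T) standard
    normal draws.  Returns (sample, choice) int arrays of shape
    (n_mc, n_trials) — censored paths get sample = T and the forced choice —
    plus the censored mask.
    """
    n_mc, n_trials, T = eps.shape
    stream = ell[None, :, :] + sigma * eps
    lims = bound_value(np.arange(1, T + 1), a, b, lam)
    z = np.zeros((n_mc, n_trials))
    done = np.zeros((n_mc, n_trials), dtype=bool)
    sample = np.full((n_mc, n_trials), T, dtype=np.int64)
    choice = np.zeros((n_mc, n_trials), dtype=np.int64)
    for n in range(T):
        # paths that already crossed keep evolving but are never re-read
        z *= alpha
        z += stream[:, :, n]
        newly = np.abs(z) > lims[n]
        newly &= ~done
        if newly.any():
            sample[newly] = n + 1
            choice[newly] = np.where(z[newly] + bias > 0, 1, 2)
            done |= newly
    censored = ~done
    choice[censored] = np.where(z[censored] + bias > 0, 1, 2)
    return sample, choice, censored


def _first_passage_smooth(ell, alpha, sigma, a, b, lam, u):
    """Rao-Blackwellised first-passage distribution estimate.

    Instead of counting discrete crossings, each Monte-Carlo path carries
    its survival probability: at every step the exact Gaussian probability
    of crossing each bound given the current accumulator state is added to
    the crossing distribution, and the path continues with a draw from the
    truncated (non-crossing) region via the frozen uniforms ``u``.  The
    estimator targets the same first-passage probabilities as path counting
    but is smooth in the parameters and has far lower variance, which the
    derivative-free optimisers rely on.

    Returns ``f`` of shape (n_trials, 2, T) — crossing mass per (choice,
    sample) — and ``censored`` of shape (n_trials, 2): the no-crossing mass
    split by the sign of the final evidence (the forced-response rule).
    """
    n_mc, n_trials, T = u.shape
    lims = bound_value(np.arange(1, T + 1), a, b, lam)
    z = np.zeros((n_mc, n_trials))
    w = np.ones((n_mc, n_trials))
    f = np.zeros((n_trials, 2, T))
    censored = np.zeros((n_trials, 2))
    tiny = 1e-300
    inv_sigma = 1.0 / sigma
    for n in range(T):
        mu = alpha * z + ell[:, n]
        p_lo = ndtr((-lims[n] - mu) * inv_sigma)
        p_hi = ndtr((lims[n] - mu) * inv_sigma)
        f[:, 0, n] = (w * (1.0 - p_hi)).mean(axis=0)
        f[:, 1, n] = (w * p_lo).mean(axis=0)
        if n == T - 1:
            p_mid = ndtr(-mu * inv_sigma)
            censored[:, 0] = (w * np.clip(p_hi - p_mid, 0, None)).mean(axis=0)
            censored[:, 1] = (w * np.clip(p_mid - p_lo, 0, None)).mean(axis=0)
            break
        surv = np.clip(p_hi - p_lo, tiny, None)
        q = p_lo + u[:, :, n] * surv
        z = mu + sigma * ndtri(np.clip(q, tiny, 1 - 1e-16))
        w *= surv
        if w.max() < 1e-12:  # all residual mass is numerically negligible
            break
    return f, censored


def response_pmf_mc(
    params: Type1Params,
    orientations,
    n_mc: int = 1000,
    seed: int = 0,
    condition: str | None = None,
    cat: CategoryParams | None = None,
) -> ResponsePMF:
    """Monte-Carlo first-passage distribution for one trial.

    Estimates ``f(n)``, the probability of the decision terminating at each
    sample with each choice, from ``n_mc`` draws of the inference noise;
    deterministic given ``seed``.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    ell = compute_evidence(np.asarray(orientations), cat or CategoryParams())
    ell = np.atleast_2d(ell)
    T = ell.shape[1]
    try:
        lam = params.lam_for(condition)
    except KeyError:
        lam = _replay_lam_of(params)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n_mc, 1, T))
    sample, choice, censored = _first_passage_counts(
        ell, params.alpha, params.sigma, params.a, params.b, lam, eps,
        params.bias,
    )
    f = np.zeros((2, T))
    cens_by_choice = np.zeros(2)
    crossed = ~censored
    idx = (choice[crossed] - 1) * T + (sample[crossed] - 1)
    f.ravel()[:] = np.bincount(idx, minlength=2 * T) / n_mc
    for c in (1, 2):
        cens_by_choice[c - 1] = np.sum(censored & (choice == c)) / n_mc
    return ResponsePMF(f, float(censored.mean()), cens_by_choice)


def _nondecision_kernel(mu_U: float, sigma_U: float):
    """Discretised Gaussian kernel at integer sample offsets within 4 SD."""
    if sigma_U < 0:
        raise ValueError("sigma_U must be >= 0")
    if sigma_U == 0:
        return np.array([int(round(mu_U))]), np.array([1.0])
    lo = int(np.floor(mu_U - 4 * sigma_U))
    hi = int(np.ceil(mu_U + 4 * sigma_U))
    offsets = np.arange(lo, hi + 1)
    w = np.exp(-0.5 * ((offsets - mu_U) / sigma_U) ** 2)
    total = w.sum()
    if total <= 0:  # SD far below the sample grid: effectively a delta
        return np.array([int(round(mu_U))]), np.array([1.0])
    return offsets, w / total


def _convolve_rows(F: np.ndarray, mu_U: float, sigma_U: float) -> np.ndarray:
    """Convolve the sample axis (last) of ``F`` with the non-decision kernel.

    Mass shifted past the last sample accumulates there; mass shifted before
    the first sample accumulates at the first.  Total mass is preserved.
    """
    offsets, w = _nondecision_kernel(mu_U, sigma_U)
    T = F.shape[-1]
    K = np.zeros((T, T))
    src = np.arange(T)
    for d, wd in zip(offsets, w):
        dest = np.clip(src + d, 0, T - 1)
        np.add.at(K, (src, dest), wd)
    return F @ K


def convolve_nondecision(pmf: ResponsePMF, mu_U: float, sigma_U: float) -> ResponsePMF:
    """Smear the decision-sample distribution with the non-decision lag.

    Each choice-conditional distribution is convolved with a Gaussian kernel
    discretised at integer offsets and renormalised; censored mass is left
    untouched (it is tied to the forced response at the last sample).
    """
    f = _convolve_rows(pmf.f, mu_U, sigma_U)
    return ResponsePMF(f, pmf.censor_mass, pmf.censor_by_choice.copy())


def choice_prob_analytic(
    params: Type1Params,
    orientations,
    T: int | None = None,
    cat: CategoryParams | None = None,
) -> float:
    """Analytic probability of choice 1 for a fixed-length, unbounded trial.

    With no covert bound the end-of-sequence evidence is Gaussian with mean
    ``sum(ell_n * v_n)`` and SD ``sigma * sqrt(sum(v_n^2))``, so the choice
    probability is a normal CDF, mixed with the symmetric lapse.
    """
    ell = compute_evidence(np.asarray(orientations), cat or CategoryParams())
    ell = np.atleast_1d(ell)
    T = len(ell) if T is None else int(T)
    v = sample_weights(params.alpha, T)
    mean = float(np.dot(ell[:T], v)) + params.bias
    sd = params.sigma * float(np.sqrt(np.sum(v**2)))
    if sd == 0:
        core = 1.0 if mean > 0 else 0.0  # mean == 0: deterministic choice 2
    else:
        core = float(norm.cdf(mean / sd))
    return params.lapse / 2 + (1 - params.lapse) * core


def _check_behaviour(behaviour: pd.DataFrame, bank: TrialBank) -> None:
    unknown = set(behaviour["trial_id"]) - set(int(t) for t in bank.trial_id)
    if unknown:
        raise ValueError(f"behaviour references unknown trial ids: {sorted(unknown)[:5]}")


def stopping_pmf_matrix(
    params: Type1Params,
    bank: TrialBank,
    condition: str | None,
    noise: np.ndarray,
) -> np.ndarray:
    """Response-sample likelihood ``f'`` for every bank trial, lapse-mixed.

    ``noise`` is a frozen (n_mc, n_trials, T) matrix of uniforms driving the
    Rao-Blackwellised estimator.  Returns (n_trials, 2, T): probability of
    each (choice, response sample) cell after forcing censored mass to the
    last sample and convolving with the non-decision kernel.
    """
    ell = bank.evidence()
    n_trials, T = ell.shape
    lam = params.lam_for(condition)
    if params.sigma <= 1e-12:
        # noiseless accumulation is deterministic: one path suffices
        eps = np.zeros((1, n_trials, T))
        sample, choice, censored = _first_passage_counts(
            ell, params.alpha, 0.0, params.a, params.b, lam, eps,
            params.bias,
        )
        f = np.zeros((n_trials, 2, T))
        s = np.where(censored[0], T, sample[0])
        f[np.arange(n_trials), choice[0] - 1, s - 1] = 1.0
    else:
        f, cens = _first_passage_smooth(
            ell, params.alpha, params.sigma, params.a, params.b, lam, noise
        )
        f = f.copy()
        f[:, :, -1] += cens  # forced response at the last sample
    f = _convolve_rows(f, params.mu_U, params.sigma_U)
    return (1 - params.lapse) * f + params.lapse / (2 * T)


def nll_stopping(
    params: Type1Params,
    behaviour: pd.DataFrame,
    bank: TrialBank,
    n_mc: int = 1000,
    seed: int = 0,
) -> float:
    """Negative log-likelihood of stopping/free-task responses.

    Sums ``-log f'[choice, response_sample]`` over behaviour rows, with the
    Monte-Carlo crossing distribution recomputed per condition (the bound
    decay may differ across conditions) from one frozen noise matrix.
    """
    _check_behaviour(behaviour, bank)
    ell = bank.evidence()
    n_trials, T = ell.shape
    noise = _frozen_uniform(seed, (n_mc, n_trials, T))
    pos = {int(t): i for i, t in enumerate(bank.trial_id)}
    floor = epsilon_floor(params.lapse if params.lapse > 0 else 0.001)
    nll = 0.0
    for cond, grp in behaviour.groupby("condition", sort=False):
        f = stopping_pmf_matrix(params, bank, cond, noise)
        ti = np.array([pos[int(t)] for t in grp["trial_id"]])
        ci = grp["choice"].to_numpy(dtype=int) - 1
        ni = grp["response_sample"].to_numpy(dtype=int) - 1
        p = np.maximum(f[ti, ci, ni], floor)
        nll -= float(np.log(p).sum())
    return nll


def replay_joint_pmf(
    params: Type1Params,
    type2: Type2Params,
    variant: ModelVariant,
    bank: TrialBank,
    n_shown: np.ndarray,
    n_mc: int,
    seed: int,
    trial_index: np.ndarray | None = None,
) -> np.ndarray:
    """Monte-Carlo joint (choice, rating) distribution for replay trials.

    ``n_shown`` gives the number of samples presented for each row;
    ``trial_index`` maps rows to bank trials (identity by default).  Returns
    (n_rows, 2, 4) frequencies of the eight joint outcomes, lapse-mixed.
    """
    if variant.type2_coupling == "same_z" and type2.sigma_c != 0:
        raise ValueError(
            "same_z coupling is inconsistent with sigma_c != 0"
        )
    ell_all = bank.evidence()
    if trial_index is None:
        trial_index = np.arange(len(n_shown))
    ell = ell_all[trial_index]
    n_rows, T = ell.shape
    n_shown = np.asarray(n_shown, dtype=int)
    lam1 = _replay_lam_of(params)
    eps = _frozen_noise(seed, (n_mc, n_rows, T))
    per_sample_t2 = (
        variant.type2_coupling != "same_z"
        and variant.type2_noise_mode == "per_sample"
    )
    eta = (
        _frozen_noise(seed + 7_000_003, (n_mc, n_rows, T))
        if per_sample_t2 else None
    )

    if variant.type2_bound == "same_as_type1":
        bp2 = (params.a, params.b, lam1)
    elif variant.type2_bound == "independent":
        if None in (type2.a_bound, type2.b_bound, type2.lam_bound):
            raise ValueError(
                "independent type2 bound requires a_bound/b_bound/lam_bound"
            )
        bp2 = (type2.a_bound, type2.b_bound, type2.lam_bound)
    else:
        bp2 = None

    z1 = np.zeros((n_mc, n_rows))
    frozen1 = np.zeros((n_mc, n_rows), dtype=bool)
    z2 = np.zeros((n_mc, n_rows))
    frozen2 = np.zeros((n_mc, n_rows), dtype=bool)
    for n in range(int(n_shown.max())):
        active = n < n_shown  # (n_rows,)
        s1 = ell[:, n] + params.sigma * eps[:, :, n]
        upd1 = active & ~frozen1
        z1 = np.where(upd1, params.alpha * z1 + s1, z1)
        if variant.covert_bound != "none":
            lim = bound_value(n + 1, params.a, params.b, lam1)
            over = upd1 & (np.abs(z1) > lim)
            if variant.covert_bound == "absorbing":
                frozen1 |= over
            else:  # reflexive
                z1 = np.where(over, np.sign(z1) * (2 * lim - np.abs(z1)), z1)
        if variant.type2_coupling == "same_z":
            z2 = z1
            continue
        s2 = s1 if variant.type2_coupling == "partial" else ell[:, n] + 0 * s1
        if variant.type2_coupling == "independent" and per_sample_t2:
            s2 = ell[:, n] + type2.sigma_c * eta[:, :, n]
        elif per_sample_t2:
            s2 = s2 + type2.sigma_c * eta[:, :, n]
        upd2 = active & ~frozen2
        z2 = np.where(upd2, type2.alpha_c * z2 + s2, z2)
        if bp2 is not None:
            frozen2 |= upd2 & (np.abs(z2) > bound_value(n + 1, *bp2))
    if (
        variant.type2_coupling != "same_z"
        and variant.type2_noise_mode == "single_sample"
    ):
        z2 = z2 + type2.sigma_c * _frozen_noise(
            seed + 11_000_017, (n_mc, n_rows)
        )

    choice = np.where(z1 + params.bias > 0, 1, 2)
    crit = np.stack(
        [bound_value(n_shown.astype(float), type2.a_c, type2.b_c, lam)
         for lam in (type2.lam1, type2.lam2, type2.lam3)],
        axis=-1,
    )  # (n_rows, 3)
    if np.any(crit[:, 0] > crit[:, 1]) or np.any(crit[:, 1] > crit[:, 2]):
        raise ValueError("confidence criteria unordered at some trial length")
    rating = 1 + (np.abs(z2)[..., None] >= crit[None, :, :]).sum(axis=-1)
    cell = (choice - 1) * 4 + (rating - 1)  # (n_mc, n_rows) in 0..7
    idx = np.arange(n_rows)[None, :] * 8 + cell
    counts = np.bincount(idx.ravel(), minlength=n_rows * 8)
    freq = counts.reshape(n_rows, 2, 4) / n_mc
    return (1 - params.lapse) * freq + params.lapse / 8


def _replay_lam_of(p: Type1Params) -> float:
    from .simulator import _replay_lam
    return _replay_lam(p)


def nll_replay(
    params: Type1Params,
    type2: Type2Params | None,
    variant: ModelVariant,
    behaviour: pd.DataFrame,
    bank: TrialBank,
    n_mc: int = 1000,
    seed: int = 0,
    type1_only: bool = False,
) -> float:
    """Negative log-likelihood of replay-task responses.

    Jointly scores (choice, confidence) via Monte-Carlo frequencies of the
    eight outcomes under the variant's coupling.  With ``type1_only`` and no
    covert bound the likelihood reduces to the analytic fixed-length choice
    probability.
    """
    _check_behaviour(behaviour, bank)
    pos = {int(t): i for i, t in enumerate(bank.trial_id)}
    trial_index = np.array([pos[int(t)] for t in behaviour["trial_id"]])
    n_shown = behaviour["n_shown"].to_numpy(dtype=int)
    choices = behaviour["choice"].to_numpy(dtype=int)
    floor = epsilon_floor(params.lapse if params.lapse > 0 else 0.001)

    if type1_only and variant.covert_bound == "none":
        ps = np.array([
            choice_prob_analytic(
                params, bank.orientations[ti, :ns], cat=bank.cat_params
            )
            for ti, ns in zip(trial_index, n_shown)
        ])
        p = np.where(choices == 1, ps, 1 - ps)
        return -float(np.log(np.maximum(p, floor)).sum())

    if type2 is None:
        raise ValueError("type2 parameters required unless type1_only "
                         "with no covert bound")
    freq = replay_joint_pmf(
        params, type2, variant, bank, n_shown, n_mc, seed,
        trial_index=trial_index,
    )
    if type1_only:
        p = freq.sum(axis=2)[np.arange(len(choices)), choices - 1]
    else:
        conf = behaviour["confidence"].to_numpy(dtype=int)
        p = freq[np.arange(len(choices)), choices - 1, conf - 1]
    return -float(np.log(np.maximum(p, floor)).sum())
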