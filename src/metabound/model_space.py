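"""Model comparison: BIC knock-out, cross-validation, and group selection.

Model evidence is approximated per subject as -BIC/2 (or as held-out
log-likelihood from five-fold cross-validation), and compared at the group
level with random-effects Bayesian model selection: a variational Dirichlet
posterior over model frequencies in the population, summarised by each
model's exceedance probability (the posterior probability that it is the
most frequent model).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma

from .model_core import ModelVariant, Type1Params, Type2Params
from .simulator import TrialBank
from .likelihood import nll_replay
from .fitting import (
    DEFAULT_HARD_BOUNDS,
    fit_model,
    fit_stopping,
    free_parameters,
)

__all__ = [
    "ModelEvidenceMatrix",
    "bic",
    "crossval_kfold",
    "exceedance_prob",
    "knockout",
    "enumerate_type2_variants",
    "compare_covert_bound_models",
]


@dataclass
class ModelEvidenceMatrix:
    """Subjects x models array of log model evidence."""

    evidence: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.evidence = np.atleast_2d(np.asarray(self.evidence, dtype=float))
        if not self.labels:
            self.labels = [f"m{i}" for i in range(self.evidence.shape[1])]
        if len(self.labels) != self.evidence.shape[1]:
            raise ValueError("labels must match the number of models")
        if not np.all(np.isfinite(self.evidence)):
            raise ValueError("log evidence must be finite")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.evidence, columns=self.labels).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ModelEvidenceMatrix":
        df = pd.read_csv(path)
        return cls(df.to_numpy(), list(df.columns))


def bic(nll: float, k_params: int, n_obs: int) -> float:
    """Bayesian Information Criterion: ``2*nll + k*ln(n)``."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return 2.0 * float(nll) + k_params * np.log(n_obs)


def _make_folds(behaviour: pd.DataFrame, k: int, seed: int,
                stratify_by: str | None) -> np.ndarray:
    """Seeded round-robin fold assignment, stratified by condition."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(behaviour) < k:
        raise ValueError("fewer trials than folds")
    rng = np.random.default_rng(seed)
    fold = np.empty(len(behaviour), dtype=int)
    if stratify_by and stratify_by in behaviour.columns:
        groups = behaviour.groupby(stratify_by, sort=False).indices.values()
    else:
        groups = [np.arange(len(behaviour))]
    for idx in groups:
        idx = np.asarray(idx)
        perm = rng.permutation(len(idx))
        fold[idx[perm]] = np.arange(len(idx)) % k
    return fold


def crossval_kfold(
    fit_fn,
    loglik_fn,
    behaviour: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    stratify_by: str | None = "condition",
) -> tuple[float, np.ndarray]:
    """K-fold cross-validated held-out log-likelihood per trial.

    ``fit_fn(train_df)`` returns an arbitrary fitted model object;
    ``loglik_fn(model, test_df)`` returns its total log-likelihood on the
    held-out rows.  Returns the overall per-trial mean and the per-fold
    per-trial values.
    """
    fold = _make_folds(behaviour, k, seed, stratify_by)
    per_fold = np.empty(k)
    total = 0.0
    for f in range(k):
        train = behaviour[fold != f]
        test = behaviour[fold == f]
        model = fit_fn(train)
        ll = float(loglik_fn(model, test))
        per_fold[f] = ll / len(test)
        total += ll
    return total / len(behaviour), per_fold


def exceedance_prob(
    evidence: ModelEvidenceMatrix | np.ndarray,
    n_mc: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Exceedance probabilities from random-effects group model selection.

    Runs the variational Dirichlet scheme over per-subject log model
    evidence: posterior responsibilities ``u_nk`` proportional to
    ``exp(lme_nk + digamma(alpha_k) - digamma(sum alpha))`` and counts
    ``alpha = alpha0 + sum_n u_n`` are iterated to convergence; exceedance
    probabilities are then the Monte-Carlo frequency with which each model's
    sampled population frequency is the largest.
    """
    if isinstance(evidence, ModelEvidenceMatrix):
        lme = evidence.evidence
    else:
        lme = np.atleast_2d(np.asarray(evidence, dtype=float))
    if not np.all(np.isfinite(lme)):
        raise ValueError("log evidence must be finite")
    n_sub, n_mod = lme.shape
    if n_mod < 2:
        raise ValueError("model selection needs at least two models")
    alpha0 = np.ones(n_mod)
    alpha = alpha0.copy()
    for _ in range(500):
        w = lme + digamma(alpha) - digamma(alpha.sum())
        w = w - w.max(axis=1, keepdims=True)
        u = np.exp(w)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < 1e-8:
            alpha = alpha_new
            break
        alpha = alpha_new
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_mc)
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=n_mod) / n_mc
    return xp


def knockout(
    behaviour_per_subject: list[pd.DataFrame],
    bank: TrialBank,
    neutral_values: dict[str, float],
    free_full: tuple[str, ...] | None = None,
    fit_kwargs: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Knock-out model simplification on stopping-task behaviour.

    Fits the full model and, for each entry of ``neutral_values``, a model
    with that single parameter fixed to its neutral value; per-subject BICs
    become log model evidence (-BIC/2) for group Bayesian model selection.
    Returns one row per candidate model ('full' first) with its exceedance
    probability and mean BIC difference from the full model.
    """
    free_full = free_full or free_parameters("joint_what_when")
    for name, val in neutral_values.items():
        key = "lam" if name.startswith("lam_") else name
        lo, hi = DEFAULT_HARD_BOUNDS[key]
        if not (lo <= val <= hi):
            raise ValueError(
                f"neutral value {val} for {name!r} outside hard bounds"
            )
        if name not in free_full:
            raise ValueError(f"{name!r} is not free in the full model")
    fit_kwargs = dict(fit_kwargs or {})
    caller_base = fit_kwargs.pop("base", Type1Params())
    labels = ["full"] + [f"no_{n}" for n in neutral_values]
    evid = np.empty((len(behaviour_per_subject), len(labels)))
    for i, beh in enumerate(behaviour_per_subject):
        n_obs = len(beh)
        full = fit_stopping(beh, bank, free=free_full, base=caller_base,
                            seed=seed + 17 * i, **fit_kwargs)
        evid[i, 0] = -bic(full.nll, len(free_full), n_obs) / 2
        for j, (name, val) in enumerate(neutral_values.items(), start=1):
            if name.startswith("lam_"):
                raise ValueError(
                    "per-condition bound decays are compared via nested "
                    "fits, not the knock-out procedure"
                )
            free = tuple(n for n in free_full if n != name)
            # start the restricted fit's fixed fields from the caller's
            # base, carrying over the full fit's estimates
            base_kwargs = {
                f: getattr(caller_base, f)
                for f in ("sigma", "alpha", "a", "b", "lam", "mu_U",
                          "sigma_U", "lapse", "bias")
            }
            base_kwargs.update({k: v for k, v in full.params.items()
                                if not k.startswith("lam_")})
            lam_map = {k[4:]: v for k, v in full.params.items()
                       if k.startswith("lam_")}
            if lam_map:
                base_kwargs["lam"] = lam_map
            base_kwargs[name] = val
            fit = fit_stopping(beh, bank, free=free,
                               base=Type1Params(**base_kwargs),
                               seed=seed + 17 * i + j, **fit_kwargs)
            evid[i, j] = -bic(fit.nll, len(free), n_obs) / 2
    xp = exceedance_prob(ModelEvidenceMatrix(evid, labels), seed=seed)
    dbic = (-2 * evid) - (-2 * evid[:, [0]])
    return pd.DataFrame({
        "model": labels,
        "xp": xp,
        "mean_delta_bic": dbic.mean(axis=0),
        "favoured": xp == xp.max(),
    })


def enumerate_type2_variants() -> list[ModelVariant]:
    """The Type-II model-comparison space.

    Couplings: the ideal observer (same evidence for both decisions),
    fully independent accumulators, and partial coupling (shared stream
    plus additional Type-II noise); each crossed with the noise mode
    (per-sample vs one draw per trial) and the Type-II bound
    (none / same as Type-I / independent).  The same-z coupling has no
    Type-II noise, so noise modes collapse to a single entry.
    """
    out = []
    for coupling, noise, b2 in itertools.product(
        ("same_z", "independent", "partial"),
        ("per_sample", "single_sample"),
        ("none", "same_as_type1", "independent"),
    ):
        if coupling == "same_z" and noise == "single_sample":
            continue  # duplicate of per_sample: no Type-II noise exists
        out.append(ModelVariant(
            covert_bound="absorbing", type2_coupling=coupling,
            type2_bound=b2, type2_noise_mode=noise,
        ))
    return out


def compare_covert_bound_models(
    behaviour: pd.DataFrame,
    bank: TrialBank,
    type1: Type1Params,
    type2: Type2Params,
    k: int = 5,
    n_mc: int = 200,
    seed: int = 0,
    maxfev: int = 120,
) -> pd.DataFrame:
    """Cross-validated covert-bound comparison on replay behaviour.

    Rebuilds the three-way comparison on a single observer's replay data:
    (i) a covert bound on Type-I accumulation (bound parameters fitted per
    training fold, suboptimalities fixed) against unbounded accumulation,
    scored on choice likelihood; (ii) a Type-II bound equal to the Type-I
    bound and (iii) an independently parameterised Type-II bound, each
    against unbounded Type-II accumulation, scored on the joint
    choice-confidence likelihood.  Positive ``delta_ll`` (held-out
    log-likelihood per trial, bounded minus unbounded) favours the bound.
    """
    unbounded = ModelVariant(covert_bound="none", type2_bound="none")
    bounded = ModelVariant(covert_bound="absorbing", type2_bound="none")

    def ll_type1(params, variant, df):
        return -nll_replay(params, type2, variant, df, bank,
                           n_mc=n_mc, seed=seed + 1, type1_only=True)

    # (i) Type-I bound: fit (a, b, lam) on training folds
    def fit_t1_bound(train):
        names = ("a", "b", "lam")
        hb = [DEFAULT_HARD_BOUNDS[n] for n in names]
        pb = [(0.05, 2.0), (0.0, 5.0), (0.5, 20.0)]

        def obj(x):
            p = Type1Params(
                sigma=type1.sigma, alpha=type1.alpha,
                a=x[0], b=x[1], lam=x[2],
                mu_U=type1.mu_U, sigma_U=type1.sigma_U,
            )
            return -ll_type1(p, bounded, train)

        x, *_ = fit_model(obj, hb, pb, n_starts=2, seed=seed, maxfev=maxfev)
        return Type1Params(
            sigma=type1.sigma, alpha=type1.alpha, a=x[0], b=x[1], lam=x[2],
            mu_U=type1.mu_U, sigma_U=type1.sigma_U,
        )

    ll_b, _ = crossval_kfold(
        fit_t1_bound, lambda m, df: ll_type1(m, bounded, df),
        behaviour, k=k, seed=seed,
    )
    ll_u, _ = crossval_kfold(
        lambda train: type1, lambda m, df: ll_type1(m, unbounded, df),
        behaviour, k=k, seed=seed,
    )
    rows = [{"model": "type1_bound", "delta_ll": ll_b - ll_u}]

    # (ii)/(iii) Type-II bounds, scored on the joint likelihood with the
    # generating Type-I process held fixed
    def ll_joint(t2, variant, df):
        return -nll_replay(type1, t2, variant, df, bank,
                           n_mc=n_mc, seed=seed + 2)

    base_ll, _ = crossval_kfold(
        lambda train: type2,
        lambda m, df: ll_joint(m, bounded, df),
        behaviour, k=k, seed=seed,
    )
    same = ModelVariant(covert_bound="absorbing", type2_bound="same_as_type1")
    ll_same, _ = crossval_kfold(
        lambda train: type2,
        lambda m, df: ll_joint(m, same, df),
        behaviour, k=k, seed=seed,
    )
    rows.append({"model": "type2_bound_same", "delta_ll": ll_same - base_ll})

    ind = ModelVariant(covert_bound="absorbing", type2_bound="independent")

    def fit_t2_bound(train):
        def obj(x):
            t2 = Type2Params(
                sigma_c=type2.sigma_c, alpha_c=type2.alpha_c,
                a_c=type2.a_c, b_c=type2.b_c,
                lam1=type2.lam1, lam2=type2.lam2, lam3=type2.lam3,
                a_bound=x[0], b_bound=type1.b, lam_bound=x[1],
            )
            return -ll_joint(t2, ind, train)

        x, *_ = fit_model(
            obj, [(0.05, 6.0), (0.5, 40.0)], [(0.1, 3.0), (1.0, 20.0)],
            n_starts=2, seed=seed, maxfev=maxfev,
        )
        return Type2Params(
            sigma_c=type2.sigma_c, alpha_c=type2.alpha_c,
            a_c=type2.a_c, b_c=type2.b_c,
            lam1=type2.lam1, lam2=type2.lam2, lam3=type2.lam3,
            a_bound=x[0], b_bound=type1.b, lam_bound=x[1],
        )

    ll_ind, _ = crossval_kfold(
        fit_t2_bound, lambda m, df: ll_joint(m, ind, df),
        behaviour, k=k, seed=seed,
    )
    rows.append({"model": "type2_bound_independent",
                 "delta_ll": ll_ind - base_ll})
    df = pd.DataFrame(rows)
    df["favoured"] = df["delta_ll"] > 0.01
    return df
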