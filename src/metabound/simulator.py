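"""Synthetic-data generation: trial banks, synthetic observers, three tasks.

Emulates the behavioural protocol of the sequential orientation-
categorisation experiment: a bank of 100 pre-defined trials of 40 samples
(orientations drawn from two von Mises distributions, half the trials from
each category), presented in three task contexts —

* **Stopping task**: samples run until the observer responds; three target-
  performance conditions (70/85/90 % correct), two blocks each.
* **Free task**: as Stopping but with no target; three repetitions.
* **Replay task**: a fixed number of samples is shown and a confidence
  rating (1-4) is collected; the Less/Same/More sample counts are derived
  per trial from the observer's own Free-task response samples.

Synthetic observers replace the study's human participants: each is a
parameter set for the suboptimal accumulation model plus an architecture
variant and a seed, so every behavioural table is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    CategoryParams,
    ModelVariant,
    STOPPING_CONDITIONS,
    Type1Params,
    Type2Params,
    bound_value,
    compute_evidence,
)

__all__ = [
    "TrialBank",
    "SyntheticObserver",
    "generate_trial_bank",
    "simulate_type1_trial",
    "simulate_replay_trial",
    "make_replay_conditions",
    "run_protocol",
    "simulate_stopping_condition",
    "draw_synthetic_observers",
    "DEFAULT_OBSERVER_RANGES",
]

MAX_SAMPLES = 40

BEHAVIOR_COLUMNS = [
    "observer_id", "task", "condition", "trial_id", "repetition",
    "n_shown", "response_sample", "choice", "confidence", "correct",
]


@dataclass(frozen=True)
class TrialBank:
    """Pre-defined trials: category labels and orientation sequences.

    ``orientations`` has shape (n_trials, max_samples), radians;
    ``category`` holds 1 or 2, balanced across the bank.
    """

    trial_id: np.ndarray
    category: np.ndarray
    orientations: np.ndarray
    seed: int | None = None
    cat_params: CategoryParams = field(default_factory=CategoryParams)

    @property
    def n_trials(self) -> int:
        return len(self.trial_id)

    @property
    def max_samples(self) -> int:
        return self.orientations.shape[1]

    def evidence(self) -> np.ndarray:
        """Per-sample evidence for every trial, shape (n_trials, T)."""
        return compute_evidence(self.orientations, self.cat_params)

    def to_csv(self, path) -> None:
        """Long-format CSV: trial_id, category, sample_index, orientation_deg."""
        n, t = self.orientations.shape
        df = pd.DataFrame({
            "trial_id": np.repeat(self.trial_id, t),
            "category": np.repeat(self.category, t),
            "sample_index": np.tile(np.arange(1, t + 1), n),
            "orientation_deg": np.degrees(self.orientations.ravel()),
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cat_params: CategoryParams | None = None) -> "TrialBank":
        df = pd.read_csv(path)
        piv = df.pivot(index="trial_id", columns="sample_index",
                       values="orientation_deg").sort_index()
        cats = df.groupby("trial_id")["category"].first().sort_index()
        return cls(
            trial_id=piv.index.to_numpy(),
            category=cats.to_numpy(),
            orientations=np.radians(piv.to_numpy()),
            cat_params=cat_params or CategoryParams(),
        )


@dataclass(frozen=True)
class SyntheticObserver:
    """A parameterised stand-in for a human participant."""

    type1: Type1Params
    type2: Type2Params
    variant: ModelVariant = field(default_factory=ModelVariant)
    observer_id: int = 0
    seed: int = 0


def generate_trial_bank(
    n_trials: int = 100,
    max_samples: int = MAX_SAMPLES,
    cat: CategoryParams | None = None,
    seed: int = 0,
) -> TrialBank:
    """Draw a balanced bank of pre-defined trials.

    Orientations are i.i.d. von Mises draws on the period-pi orientation
    circle: the doubled angle ``2*theta`` is von Mises distributed around
    ``2*mu_psi`` with concentration ``kappa``.
    """
    if n_trials % 2 != 0:
        raise ValueError("n_trials must be even so categories can balance")
    if max_samples < 1:
        raise ValueError("max_samples must be >= 1")
    cat = cat or CategoryParams()
    rng = np.random.default_rng(seed)
    category = np.repeat([1, 2], n_trials // 2)
    rng.shuffle(category)
    mus = np.where(category == 1, cat.mu1, cat.mu2)
    doubled = rng.vonmises(2.0 * mus[:, None], cat.kappa,
                           size=(n_trials, max_samples))
    theta = doubled / 2.0  # in (-pi/2, pi/2]
    return TrialBank(
        trial_id=np.arange(n_trials),
        category=category,
        orientations=theta,
        seed=seed,
        cat_params=cat,
    )


def _replay_lam(p: Type1Params) -> float:
    """Bound decay used in replay/free contexts when lam is per-condition."""
    for key in ("replay", "free"):
        try:
            return p.lam_for(key)
        except KeyError:
            continue
    if isinstance(p.lam, Mapping):
        return float(np.median(list(p.lam.values())))
    return float(p.lam)


def simulate_type1_trial(
    obs: SyntheticObserver,
    orientations: np.ndarray,
    condition: str,
    rng: np.random.Generator,
    cat: CategoryParams | None = None,
):
    """One Stopping/Free-task trial: accumulate until the bound is crossed.

    Returns ``(choice, decision_sample, response_sample, trajectory)``.
    The decision occurs at the first sample N with ``|z_N| > Lambda_N``; the
    overt response lags it by a rounded Gaussian non-decision time (negative
    lags clipped to zero, responses capped at the last sample).  If the bound
    is never crossed the task forces a response at the last sample with the
    sign rule on the final evidence (z <= 0 -> choice 2).
    """
    p = obs.type1
    T = len(orientations)
    try:
        lam = p.lam_for(condition)
    except KeyError:
        lam = _replay_lam(p)
    ell = compute_evidence(np.asarray(orientations), cat or CategoryParams())
    eps = rng.normal(0.0, p.sigma, size=T)
    stream = ell + eps
    z = np.empty(T)
    acc = 0.0
    decision = None
    for n in range(T):
        acc = p.alpha * acc + stream[n]
        z[n] = acc
        if decision is None and abs(acc) > bound_value(n + 1, p.a, p.b, lam):
            decision = n + 1
            break
    if decision is None:
        decision = T
        final = z[T - 1]
    else:
        final = z[decision - 1]
        z = z[:decision]
    choice = 1 if final + p.bias > 0 else 2
    if p.lapse > 0 and rng.random() < p.lapse:
        choice = int(rng.integers(1, 3))
    lag = int(round(rng.normal(p.mu_U, p.sigma_U)))
    lag = max(lag, 0)
    response_sample = int(min(decision + lag, T))
    return choice, decision, response_sample, z


def simulate_replay_trial(
    obs: SyntheticObserver,
    orientations: np.ndarray,
    n_shown: int,
    rng: np.random.Generator,
    cat: CategoryParams | None = None,
):
    """One Replay-task trial: forced viewing of ``n_shown`` samples.

    Type-I evidence accumulates only until the covert bound is crossed
    (absorbing: frozen thereafter; reflexive: reflected back inside), while
    Type-II evidence accumulates over all shown samples — sharing the
    Type-I per-sample stream under partial coupling, plus additional
    confidence noise and its own leak.  Returns ``(choice, confidence)``.
    """
    p, c, v = obs.type1, obs.type2, obs.variant
    n_shown = int(n_shown)
    if not 1 <= n_shown <= len(orientations):
        raise ValueError(f"n_shown must be in [1, {len(orientations)}]")
    ell = compute_evidence(np.asarray(orientations[:n_shown]),
                           cat or CategoryParams())
    eps = rng.normal(0.0, p.sigma, size=n_shown)
    stream1 = ell + eps
    lam1 = _replay_lam(p)

    # Type-I accumulator, optionally covertly bounded
    z1 = 0.0
    frozen = False
    z1_traj = np.empty(n_shown)
    for n in range(n_shown):
        if not frozen:
            z1 = p.alpha * z1 + stream1[n]
            if v.covert_bound != "none":
                lim = bound_value(n + 1, p.a, p.b, lam1)
                if abs(z1) > lim:
                    if v.covert_bound == "absorbing":
                        frozen = True
                    else:  # reflexive: fold the overshoot back inside
                        z1 = np.sign(z1) * (2.0 * lim - abs(z1))
        z1_traj[n] = z1

    # Type-II accumulator
    if v.type2_coupling == "same_z":
        z2 = z1_traj[-1]
    else:
        if v.type2_coupling == "partial":
            stream2 = stream1.copy()
        else:  # independent: own noise, not sharing the Type-I draws
            stream2 = ell.copy()
        if v.type2_noise_mode == "per_sample":
            stream2 = stream2 + rng.normal(0.0, c.sigma_c, size=n_shown)
        if v.type2_bound == "same_as_type1":
            bp = (p.a, p.b, lam1)
        elif v.type2_bound == "independent":
            if None in (c.a_bound, c.b_bound, c.lam_bound):
                raise ValueError(
                    "independent type2 bound requires a_bound/b_bound/lam_bound"
                )
            bp = (c.a_bound, c.b_bound, c.lam_bound)
        else:
            bp = None
        z2 = 0.0
        frozen2 = False
        for n in range(n_shown):
            if frozen2:
                break
            z2 = c.alpha_c * z2 + stream2[n]
            if bp is not None and abs(z2) > bound_value(n + 1, *bp):
                frozen2 = True
        if v.type2_noise_mode == "single_sample":
            z2 = z2 + rng.normal(0.0, c.sigma_c)

    choice = 1 if z1_traj[-1] + p.bias > 0 else 2
    if p.lapse > 0 and rng.random() < p.lapse:
        choice = int(rng.integers(1, 3))
    from .model_core import map_confidence
    confidence = map_confidence(z2, n_shown, c)
    return choice, confidence


def make_replay_conditions(free_response_samples: Sequence[int]):
    """Less/Same/More sample counts from the three Free-task responses.

    Less shows two fewer than the minimum (floored at 1), Same the median,
    More four more than the maximum (capped at the protocol's 40 samples).
    E.g. responses {4, 5, 10} give (2, 5, 14).
    """
    counts = [int(x) for x in free_response_samples]
    if len(counts) != 3:
        raise ValueError("exactly three Free-task repetitions are required")
    if any(x < 1 for x in counts):
        raise ValueError("response samples must be positive")
    n_less = max(min(counts) - 2, 1)
    n_same = int(np.median(counts))
    n_more = min(max(counts) + 4, MAX_SAMPLES)
    return n_less, n_same, n_more


def simulate_stopping_condition(
    obs: SyntheticObserver,
    bank: TrialBank,
    condition: str,
    n_reps: int,
    rng: np.random.Generator,
    task: str = "stopping",
) -> pd.DataFrame:
    rows = []
    for rep in range(1, n_reps + 1):
        for i in range(bank.n_trials):
            choice, _, resp, _ = simulate_type1_trial(
                obs, bank.orientations[i], condition, rng, cat=bank.cat_params
            )
            rows.append((
                obs.observer_id, task, condition, int(bank.trial_id[i]), rep,
                np.nan, resp, choice, np.nan,
                int(choice == bank.category[i]),
            ))
    return pd.DataFrame(rows, columns=BEHAVIOR_COLUMNS)


def run_protocol(
    obs: SyntheticObserver,
    bank: TrialBank,
    protocol: str,
    free_table: pd.DataFrame | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a full task protocol, returning a behaviour table.

    ``protocol`` is ``"stopping"`` (3 conditions x 2 blocks of the full
    bank), ``"free"`` (3 repetitions), or ``"replay"`` (Less/Same/More
    derived per trial from ``free_table``, which must come from a ``"free"``
    run of the same observer).
    """
    rng = np.random.default_rng(obs.seed if seed is None else seed)
    if protocol == "stopping":
        parts = [
            simulate_stopping_condition(obs, bank, cond, 2, rng)
            for cond in STOPPING_CONDITIONS
        ]
        return pd.concat(parts, ignore_index=True)
    if protocol == "free":
        return simulate_stopping_condition(obs, bank, "free", 3, rng,
                                           task="free")
    if protocol == "replay":
        if free_table is None:
            raise ValueError(
                "replay protocol requires the observer's free-task table"
            )
        rows = []
        for tid in bank.trial_id:
            free_n = free_table.loc[
                free_table["trial_id"] == tid, "response_sample"
            ].to_numpy()
            if len(free_n) != 3:
                raise ValueError(
                    f"trial {tid}: expected 3 free-task repetitions, "
                    f"got {len(free_n)}"
                )
            trip = make_replay_conditions(free_n)
            i = int(np.flatnonzero(bank.trial_id == tid)[0])
            for cond, n_shown in zip(("less", "same", "more"), trip):
                choice, conf = simulate_replay_trial(
                    obs, bank.orientations[i], n_shown, rng,
                    cat=bank.cat_params,
                )
                rows.append((
                    obs.observer_id, "replay", cond, int(tid), 1,
                    n_shown, np.nan, choice, conf,
                    int(choice == bank.category[i]),
                ))
        return pd.DataFrame(rows, columns=BEHAVIOR_COLUMNS)
    raise ValueError(f"unknown protocol {protocol!r}")


# Plausible generating ranges for synthetic observers.  These are the
# fitting module's plausible bounds narrowed to values that produce
# realistic behaviour (above-chance accuracy, responses spread over the
# sequence) in this stimulus regime.
DEFAULT_OBSERVER_RANGES: dict[str, tuple[float, float]] = {
    "sigma": (0.3, 1.2),
    "alpha": (0.8, 1.2),
    "a": (0.05, 0.3),
    "b": (0.3, 1.5),
    "lam": (1.0, 8.0),
    "mu_U": (0.5, 4.0),
    "sigma_U": (0.3, 1.5),
    "sigma_c": (0.2, 1.0),
    "alpha_c": (0.85, 1.15),
    "a_c": (0.05, 0.4),
    "b_c": (0.3, 1.5),
    "lam_c": (1.0, 10.0),
}


def draw_synthetic_observers(
    n: int,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    variant: ModelVariant | None = None,
) -> list[SyntheticObserver]:
    """Draw reproducible synthetic observers with uniformly sampled parameters.

    The three stopping-condition bound decays are drawn jointly and sorted so
    that ``lam_70 <= lam_85 <= lam_90`` (stricter targets require slower
    bound collapse), with the free-task decay set to the middle value; the
    three confidence-criterion decays are likewise sorted.
    """
    if ranges is not None and len(ranges) == 0:
        raise ValueError("ranges must not be empty")
    r = dict(DEFAULT_OBSERVER_RANGES)
    if ranges:
        r.update({k: (float(lo), float(hi)) for k, (lo, hi) in ranges.items()})
    rng = np.random.default_rng(seed)
    variant = variant or ModelVariant()
    out = []
    for i in range(int(n)):
        u = {k: rng.uniform(lo, hi) for k, (lo, hi) in r.items()}
        lams = np.sort(rng.uniform(*r["lam"], size=3))
        lamc = np.sort(rng.uniform(*r["lam_c"], size=3))
        t1 = Type1Params(
            sigma=u["sigma"], alpha=u["alpha"], a=u["a"], b=u["b"],
            lam={"70": lams[0], "85": lams[1], "90": lams[2],
                 "free": lams[1]},
            mu_U=u["mu_U"], sigma_U=u["sigma_U"],
        )
        t2 = Type2Params(
            sigma_c=u["sigma_c"], alpha_c=u["alpha_c"],
            a_c=u["a_c"], b_c=u["b_c"],
            lam1=lamc[0], lam2=lamc[1], lam3=lamc[2],
        )
        out.append(SyntheticObserver(
            type1=t1, type2=t2, variant=variant,
            observer_id=i, seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return out
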