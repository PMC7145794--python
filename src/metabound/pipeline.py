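"""End-to-end orchestration: simulate -> fit -> report, file-based.

Every stage is a plain function over a :class:`RunConfig`; the CLI in
:mod:`metabound.cli` is a thin wrapper.  All randomness derives from the
config seed, so a full run is reproducible from the config file alone; each
stage writes a ``manifest.json`` recording the seed, package version and
stage outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model_core import ModelVariant, Type1Params, Type2Params
from .simulator import (
    SyntheticObserver,
    TrialBank,
    draw_synthetic_observers,
    generate_trial_bank,
    run_protocol,
)
from .fitting import FitResult, fit_stopping_joint, recover_parameters
from .likelihood import nll_replay
from .model_space import compare_covert_bound_models
from . import metrics

__all__ = ["RunConfig", "cmd_simulate", "cmd_fit", "cmd_report",
           "cmd_recover", "cmd_compare"]

VALID_MODELS = ("stopping_joint", "choice_only")


@dataclass
class RunConfig:
    """Configuration for a full synthetic pipeline run."""

    seed: int = 0
    n_mc: int = 300
    bank_size: int = 100
    max_samples: int = 40
    n_observers: int = 4
    ranges: dict = field(default_factory=dict)
    n_starts: int = 2
    maxfev: int = 400
    out_dir: str = "runs/default"

    def __post_init__(self) -> None:
        if self.n_mc < 1:
            raise ValueError("n_mc must be >= 1")
        if self.bank_size % 2:
            raise ValueError("bank_size must be even")
        if self.n_observers < 1:
            raise ValueError("n_observers must be >= 1")
        for name, rng in (self.ranges or {}).items():
            lo, hi = rng
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"invalid range for {name!r}: {rng}")
            if name in ("sigma", "sigma_U", "sigma_c") and lo < 0:
                raise ValueError(f"{name} range must be non-negative")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def _manifest(out: Path, stage: str, config: RunConfig, outputs: list[str]) -> None:
    path = out / "manifest.json"
    man = json.loads(path.read_text()) if path.exists() else {}
    man[stage] = {
        "seed": config.seed,
        "version": __version__,
        "outputs": outputs,
    }
    path.write_text(json.dumps(man, indent=2))


def _observer_to_dict(obs: SyntheticObserver) -> dict:
    d = {
        "observer_id": obs.observer_id,
        "seed": obs.seed,
        "type1": json.loads(obs.type1.to_json()),
        "type2": json.loads(obs.type2.to_json()),
        "variant": asdict(obs.variant),
    }
    return d


def _observer_from_dict(d: dict) -> SyntheticObserver:
    return SyntheticObserver(
        type1=Type1Params(**d["type1"]),
        type2=Type2Params(**d["type2"]),
        variant=ModelVariant(**d["variant"]),
        observer_id=d["observer_id"],
        seed=d["seed"],
    )


def cmd_simulate(config: RunConfig) -> dict[str, str]:
    """Simulate the full three-task protocol for every synthetic observer.

    Writes the trial bank, the observer parameter file, and one behaviour
    CSV per task into ``config.out_dir``; reruns with the same config are
    byte-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bank = generate_trial_bank(config.bank_size, config.max_samples,
                               seed=config.seed)
    bank.to_csv(out / "bank.csv")
    observers = draw_synthetic_observers(
        config.n_observers, ranges=config.ranges or None, seed=config.seed
    )
    (out / "observers.json").write_text(
        json.dumps([_observer_to_dict(o) for o in observers], indent=2)
    )
    tables: dict[str, list[pd.DataFrame]] = {
        "stopping": [], "free": [], "replay": []
    }
    for obs in observers:
        stop = run_protocol(obs, bank, "stopping")
        free = run_protocol(obs, bank, "free", seed=obs.seed + 1)
        replay = run_protocol(obs, bank, "replay", free_table=free,
                              seed=obs.seed + 2)
        tables["stopping"].append(stop)
        tables["free"].append(free)
        tables["replay"].append(replay)
    paths = {"bank": str(out / "bank.csv"),
             "observers": str(out / "observers.json")}
    for task, parts in tables.items():
        p = out / f"behaviour_{task}.csv"
        pd.concat(parts, ignore_index=True).to_csv(p, index=False)
        paths[task] = str(p)
    _manifest(out, "simulate", config, sorted(paths.values()))
    return paths


def _load_run(config: RunConfig):
    out = Path(config.out_dir)
    bank = TrialBank.from_csv(out / "bank.csv")
    observers = [
        _observer_from_dict(d)
        for d in json.loads((out / "observers.json").read_text())
    ]
    return out, bank, observers


def cmd_fit(config: RunConfig, models=("stopping_joint",),
            resume: bool = False) -> dict[str, str]:
    """Fit the requested models to each observer's simulated behaviour.

    Writes one FitResult JSON per observer per model under
    ``<out_dir>/fits/``; with ``resume`` completed fits are skipped.
    """
    for m in models:
        if m not in VALID_MODELS:
            raise ValueError(
                f"unknown model {m!r}; valid models: {VALID_MODELS}"
            )
    out, bank, observers = _load_run(config)
    fits_dir = out / "fits"
    fits_dir.mkdir(exist_ok=True)
    written: dict[str, str] = {}
    for model in models:
        task = "stopping" if model == "stopping_joint" else "replay"
        beh_all = pd.read_csv(out / f"behaviour_{task}.csv")
        for obs in observers:
            path = fits_dir / f"observer_{obs.observer_id}_{model}.json"
            key = f"{model}/{obs.observer_id}"
            if resume and path.exists():
                written[key] = str(path)
                continue
            beh = beh_all[beh_all["observer_id"] == obs.observer_id]
            if model == "stopping_joint":
                fit = fit_stopping_joint(
                    beh, bank, n_mc=config.n_mc,
                    seed=config.seed + 1000 + obs.observer_id,
                    n_starts=config.n_starts, maxfev=config.maxfev,
                )
            else:  # choice_only: analytic replay Type-I fit
                from .fitting import fit_model, DEFAULT_HARD_BOUNDS, \
                    DEFAULT_PLAUSIBLE_BOUNDS
                unbounded = ModelVariant(covert_bound="none")

                def obj(x):
                    p = Type1Params(sigma=x[0], alpha=x[1])
                    return nll_replay(p, None, unbounded, beh, bank,
                                      type1_only=True)

                names = ("sigma", "alpha")
                x, nll, n_evals, conv = fit_model(
                    obj,
                    [DEFAULT_HARD_BOUNDS[n] for n in names],
                    [DEFAULT_PLAUSIBLE_BOUNDS[n] for n in names],
                    n_starts=config.n_starts,
                    seed=config.seed + 2000 + obs.observer_id,
                    maxfev=config.maxfev,
                )
                fit = FitResult(
                    params=dict(zip(names, map(float, x))), nll=nll,
                    n_evals=n_evals, n_mc=0,
                    seed=config.seed + 2000 + obs.observer_id,
                    converged=conv,
                    hard_bounds={n: DEFAULT_HARD_BOUNDS[n] for n in names},
                    plausible_bounds={
                        n: DEFAULT_PLAUSIBLE_BOUNDS[n] for n in names
                    },
                )
            path.write_text(fit.to_json())
            written[key] = str(path)
    _manifest(out, "fit", config, sorted(written.values()))
    return written


def cmd_report(config: RunConfig) -> dict:
    """Measurement report over a completed simulate + fit run.

    Per observer: d', meta-d', Type-II efficiency from replay behaviour;
    optimal bound decays and bound efficiency from the joint stopping fit.
    Across observers: the total-least-squares relation between bound
    efficiency and Type-II efficiency.  Writes ``report.csv``,
    ``report_group.json`` and ``summary.txt``; regeneration is idempotent.
    """
    out, bank, observers = _load_run(config)
    replay_all = pd.read_csv(out / "behaviour_replay.csv")
    rows = []
    for obs in observers:
        fit_path = out / "fits" / f"observer_{obs.observer_id}_stopping_joint.json"
        if not fit_path.exists():
            raise FileNotFoundError(
                f"missing fit for observer {obs.observer_id}: {fit_path}"
            )
        fit = FitResult.from_json(fit_path.read_text())
        beh = replay_all[replay_all["observer_id"] == obs.observer_id]
        counts = metrics.ConfusionCounts.from_behaviour(beh, bank)
        d1 = metrics.dprime(counts)
        md = metrics.meta_dprime(counts)
        t2e = metrics.type2_efficiency(md, d1)
        p = Type1Params(
            sigma=fit.params["sigma"], alpha=fit.params["alpha"],
            a=fit.params["a"], b=fit.params["b"], lam=3.0,
            mu_U=fit.params["mu_U"], sigma_U=fit.params["sigma_U"],
        )
        opt = {}
        reachable = True
        for cond, target in (("70", 0.70), ("85", 0.85)):
            res = metrics.optimal_lambda(
                p, bank, target, n_mc=config.n_mc,
                seed=config.seed + 3000 + obs.observer_id,
            )
            opt[cond] = res.lam_star
            reachable &= res.reachable
        fit_lams = {"70": fit.params["lam_70"], "85": fit.params["lam_85"]}
        try:
            be = metrics.bound_efficiency(fit_lams, opt)
        except ValueError:
            # both targets unreachable for this observer: no defined optimum
            be = float("nan")
        rows.append({
            "observer_id": obs.observer_id, "d_prime": d1,
            "meta_d_prime": md, "type2_efficiency": t2e,
            "lam_fit_70": fit_lams["70"], "lam_fit_85": fit_lams["85"],
            "lam_opt_70": opt["70"], "lam_opt_85": opt["85"],
            "bound_efficiency": be, "targets_reachable": reachable,
        })
    report = pd.DataFrame(rows)
    report.to_csv(out / "report.csv", index=False)
    group: dict = {"n_observers": len(report)}
    usable = report.dropna(subset=["bound_efficiency", "type2_efficiency"])
    if len(usable) >= 3:
        slope, intercept, pval = metrics.orthogonal_fit(
            usable["bound_efficiency"], usable["type2_efficiency"],
            seed=config.seed,
        )
        group.update(slope=slope, intercept=intercept, p_one_sided=pval)
    else:
        warnings.warn("fewer than 3 observers: skipping the group-level "
                      "orthogonal regression")
    (out / "report_group.json").write_text(json.dumps(group, indent=2))
    lines = [
        f"metabound report ({len(report)} observers)",
        f"mean d'            : {report['d_prime'].mean():.3f}",
        f"mean meta-d'       : {report['meta_d_prime'].mean():.3f}",
        f"mean T2 efficiency : {report['type2_efficiency'].mean():.3f}",
        f"mean bound eff.    : {report['bound_efficiency'].mean():.3f}",
    ]
    if "slope" in group:
        lines.append(
            "bound eff. vs T2 eff. (TLS): "
            f"y = {group['slope']:.2f}x + {group['intercept']:.2f} "
            f"(one-sided p = {group['p_one_sided']:.3f})"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    _manifest(out, "report", config,
              [str(out / "report.csv"), str(out / "report_group.json")])
    return {"report": report, "group": group}


def cmd_recover(config: RunConfig, n_observers: int = 20,
                n_trials: int = 300) -> dict[str, str]:
    """Run the parameter-recovery study and write its tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, summary = recover_parameters(
        n_observers=n_observers, n_trials=n_trials,
        fit_settings={"n_mc": config.n_mc, "n_starts": config.n_starts,
                      "maxfev": config.maxfev},
        seed=config.seed,
    )
    table.to_csv(out / "recovery_table.csv", index=False)
    summary.to_csv(out / "recovery_summary.csv", index=False)
    _manifest(out, "recover", config,
              [str(out / "recovery_table.csv"),
               str(out / "recovery_summary.csv")])
    return {"table": str(out / "recovery_table.csv"),
            "summary": str(out / "recovery_summary.csv")}


def cmd_compare(config: RunConfig, k: int = 5) -> str:
    """Covert-bound model comparison on each observer's replay behaviour."""
    out, bank, observers = _load_run(config)
    replay_all = pd.read_csv(out / "behaviour_replay.csv")
    parts = []
    for obs in observers:
        beh = replay_all[replay_all["observer_id"] == obs.observer_id]
        lam = obs.type1.lam_for("free") if hasattr(obs.type1.lam, "items") \
            else obs.type1.lam
        t1 = Type1Params(
            sigma=obs.type1.sigma, alpha=obs.type1.alpha,
            a=obs.type1.a, b=obs.type1.b, lam=lam,
            mu_U=obs.type1.mu_U, sigma_U=obs.type1.sigma_U,
        )
        df = compare_covert_bound_models(
            beh, bank, t1, obs.type2, k=k, n_mc=config.n_mc,
            seed=config.seed + 4000 + obs.observer_id,
        )
        df.insert(0, "observer_id", obs.observer_id)
        parts.append(df)
    result = pd.concat(parts, ignore_index=True)
    path = out / "compare_covert_bound.csv"
    result.to_csv(path, index=False)
    _manifest(out, "compare", config, [str(path)])
    return str(path)
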