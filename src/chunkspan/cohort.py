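"""Generative synthetic cohort for the span-task pipeline.

Each simulated participant carries latent parameters:

``kappa``   baseline capacity, in feature units (> 0);
``gamma``   multiplicative capacity cost of the interleaved processing task,
            in (0, 1] (1 = no cost);
``eta``     compression utilization, in [0, 1]: how far the participant's
            effective code length moves from the verbatim description
            (D x length features) toward the minimal compressed description;
``tau``     recall-noise temperature (> 0);
``p_eq``    accuracy on the interleaved equation judgments, in (0.5, 1].

A trial's *effective load* interpolates between the compressed and verbatim
description lengths, plus one feature unit for serial order whenever the
minimal description leaves order underdetermined (any list of two or more
items).  Recall of the whole list succeeds with probability
``logistic((capacity_eff - load) / tau)`` where ``capacity_eff`` is ``kappa``
in simple span and ``gamma * kappa`` in complex span.  The link and the
feature-unit currency are modeling choices of this package, isolated here so
alternatives can be swapped.

Population parameters are drawn from truncated normals; the defaults below
were set once by the calibration script (``analysis/02_calibrate_cohort.py``)
so that a default 94-participant cohort lands near realistic human cell
means, and are not adjusted elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import optimize
from scipy.special import expit

from .complexity import DEFAULT_SPACE
from .engine import (
    BLOCK_ORDERS,
    BlockResult,
    Equation,
    SessionLog,
    TrialOutcome,
    counterbalance,
    run_block,
)
from .stimuli import TrialSpec, build_block

__all__ = [
    "ParticipantParams",
    "CohortHyperparams",
    "DEFAULT_COHORT",
    "FitResult",
    "effective_load",
    "load_from_counts",
    "recall_probability",
    "SyntheticParticipant",
    "simulate_cohort",
    "expected_cell_spans",
    "fit_params",
]

_N_FEATURES = DEFAULT_SPACE.n_dims  # 3 features per object


@dataclass(frozen=True)
class ParticipantParams:
    kappa: float
    gamma: float
    eta: float
    tau: float
    p_eq: float

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if not 0 <= self.eta <= 1:
            raise ValueError("eta must be in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0.5 < self.p_eq <= 1:
            raise ValueError("p_eq must be in (0.5, 1]")


_BOUNDS = {
    "kappa": (1e-3, np.inf),
    "gamma": (1e-3, 1.0),
    "eta": (0.0, 1.0),
    "tau": (1e-3, np.inf),
    "p_eq": (0.5 + 1e-6, 1.0),
}


@dataclass(frozen=True)
class CohortHyperparams:
    """Population means and between-participant sds for each parameter."""

    kappa_mean: float
    kappa_sd: float
    gamma_mean: float
    gamma_sd: float
    eta_mean: float
    eta_sd: float
    tau_mean: float
    tau_sd: float
    p_eq_mean: float
    p_eq_sd: float
    n_participants: int = 94

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        for name in ("kappa_sd", "gamma_sd", "eta_sd", "tau_sd", "p_eq_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def draw(self, rng: np.random.Generator) -> ParticipantParams:
        vals = {}
        for name in ("kappa", "gamma", "eta", "tau", "p_eq"):
            mean = getattr(self, f"{name}_mean")
            sd = getattr(self, f"{name}_sd")
            vals[name] = _truncated_normal(rng, mean, sd, *_BOUNDS[name])
        return ParticipantParams(**vals)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float) -> float:
    """Rejection-sampled normal truncated to [low, high]."""
    if sd == 0:
        return float(np.clip(mean, low, high))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    return float(np.clip(mean, low, high))


#: calibrated defaults — set once by analysis/02_calibrate_cohort.py so that a
#: default cohort's four cell-mean spans land near 2.49 / 4.05 / 1.45 / 2.2;
#: between-participant sds are a-priori realism choices (capacity varies by
#: about one feature-chunk; equation accuracy mean .87, sd .08).
DEFAULT_COHORT = CohortHyperparams(
    kappa_mean=8.2,
    kappa_sd=1.0,
    gamma_mean=0.70,
    gamma_sd=0.08,
    eta_mean=0.55,
    eta_sd=0.12,
    tau_mean=1.4,
    tau_sd=0.15,
    p_eq_mean=0.87,
    p_eq_sd=0.06,
)


# ---------------------------------------------------------------------------
# recall model
# ---------------------------------------------------------------------------

def load_from_counts(complexity: float, length: float, eta: float,
                     n_features: int = _N_FEATURES) -> float:
    """Effective information load of a list, in feature units.

    ``eta`` interpolates between the verbatim description (``n_features x
    length``) and the minimal compressed description; one extra feature unit
    encodes serial order whenever the list has two or more items (the
    minimal set description underdetermines order).
    """
    verbatim = n_features * np.asarray(length, dtype=float)
    order_unit = (np.asarray(length) >= 2).astype(float)
    return eta * np.asarray(complexity, dtype=float) + (1.0 - eta) * verbatim + order_unit


def effective_load(trial: TrialSpec, params: ParticipantParams) -> float:
    return float(load_from_counts(trial.complexity, trial.length, params.eta))


def recall_probability(trial: TrialSpec, task_type: str,
                       params: ParticipantParams) -> float:
    """Probability of a perfect serial report of the whole list."""
    if params.tau <= 0:
        raise ValueError("tau must be positive")
    capacity = params.kappa * (params.gamma if task_type == "complex" else 1.0)
    return float(expit((capacity - effective_load(trial, params)) / params.tau))


class SyntheticParticipant:
    """Responder whose behavior follows the generative recall model."""

    def __init__(self, params: ParticipantParams, task_type: str,
                 rng: np.random.Generator):
        self.params = params
        self.task_type = task_type
        self.rng = rng

    def recall(self, trial: TrialSpec) -> Tuple[str, ...]:
        p = recall_probability(trial, self.task_type, self.params)
        if self.rng.random() < p:
            return trial.memoranda
        return self._corrupted(trial)

    def _corrupted(self, trial: TrialSpec) -> Tuple[str, ...]:
        seq = list(trial.memoranda)
        if len(seq) == 1:
            return (str(self.rng.choice(trial.lures)),)
        i, j = self.rng.choice(len(seq), size=2, replace=False)
        seq[i], seq[j] = seq[j], seq[i]
        return tuple(seq)

    def judge(self, equation: Equation) -> bool:
        knows = self.rng.random() < self.params.p_eq
        return equation.truth if knows else not equation.truth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(hyper: CohortHyperparams = DEFAULT_COHORT,
                    rng_seed: int = 0) -> List[SessionLog]:
    """Simulate the full within-subject design for a cohort.

    Per participant: draw latent parameters, assign the next counterbalanced
    block order, and run all four blocks through the task engine with
    Bernoulli recall and Bernoulli equation judgments.  Bit-stable for a
    fixed seed.
    """
    root = np.random.SeedSequence(rng_seed)
    order_idx = counterbalance(hyper.n_participants)
    logs: List[SessionLog] = []
    for pid, child in enumerate(root.spawn(hyper.n_participants)):
        seqs = child.spawn(5)
        params = hyper.draw(np.random.default_rng(seqs[0]))
        log = SessionLog(participant_id=pid, block_order=order_idx[pid])
        for position, (task_type, condition) in enumerate(BLOCK_ORDERS[order_idx[pid]]):
            rng = np.random.default_rng(seqs[position + 1])
            trials = build_block(condition, task_type, rng)
            responder = SyntheticParticipant(params, task_type, rng)
            outcomes = run_block(trials, task_type, responder, rng)
            log.blocks.append(
                BlockResult(task_type=task_type, condition=condition,
                            order_position=position, outcomes=outcomes)
            )
        log.validate()
        logs.append(log)
    return logs


def expected_cell_spans(kappa: float, gamma: float, eta: float, tau: float) -> Dict[Tuple[str, str], float]:
    """Analytic expected span per task x condition cell under the model.

    Uses the exact trial schedule (template complexities, most/less
    alternation, stop rule): the block survives length L only if not all
    four trials of some earlier length failed.
    """
    from .stimuli import build_structure_library

    params = ParticipantParams(kappa=kappa, gamma=gamma, eta=eta, tau=tau, p_eq=0.87)
    out: Dict[Tuple[str, str], float] = {}
    for task in ("simple", "complex"):
        capacity = kappa * (gamma if task == "complex" else 1.0)
        for condition in ("chunkable", "nonchunkable"):
            survive = 1.0
            total = 0.0
            for length in range(1, 9):
                lib = build_structure_library(length, condition)
                if condition == "nonchunkable":
                    cx = {r: float(np.mean([t.nominal_complexity for t in lib
                                            if t.incompressibility_rank == r]))
                          for r in ("most", "less")}
                    slot_cx = [cx["most"], cx["less"], cx["most"], cx["less"]]
                else:
                    c = float(np.mean([t.nominal_complexity for t in lib]))
                    slot_cx = [c] * 4
                ps = [float(expit((capacity - load_from_counts(c, length, eta)) / tau))
                      for c in slot_cx]
                total += survive * sum(ps)
                survive *= 1.0 - float(np.prod([1 - p for p in ps]))
            out[(task, condition)] = 0.25 * total
    return out


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    kappa: float
    gamma: float
    eta: float
    tau: float
    kappa_sd: float
    eta_sd: float
    se: Dict[str, float]
    nll: float
    n_trials: int
    converged: bool
    method: str

    def as_dict(self) -> Dict[str, float]:
        return {"kappa": self.kappa, "gamma": self.gamma,
                "eta": self.eta, "tau": self.tau,
                "kappa_sd": self.kappa_sd, "eta_sd": self.eta_sd}


def _get(outcome, name: str):
    # engine TrialOutcome nests trial metadata; io TrialRecord is flat
    if name == "correct":
        return outcome.correct
    if hasattr(outcome, "trial"):
        return getattr(outcome.trial, name)
    return getattr(outcome, name)


def _participant_arrays(logs: Sequence[SessionLog]):
    """Per-participant (complexity, length, is_complex, correct) arrays."""
    out = []
    for log in logs:
        cx, length, cp, y = [], [], [], []
        for block in log.blocks:
            for o in block.outcomes:
                if _get(o, "is_practice"):
                    continue
                cx.append(_get(o, "complexity"))
                length.append(_get(o, "length"))
                cp.append(block.task_type == "complex")
                y.append(_get(o, "correct"))
        out.append((np.asarray(cx, float), np.asarray(length, float),
                    np.asarray(cp, bool), np.asarray(y, float)))
    return out


# probabilists' Gauss-Hermite nodes for the random-effect integrals
_GH_NODES, _GH_W = np.polynomial.hermite_e.hermegauss(9)
_GH2_W = (_GH_W[:, None] * _GH_W[None, :]).ravel()
_GH2_W = _GH2_W / _GH2_W.sum()
_GH2_K = np.repeat(_GH_NODES, _GH_NODES.size)
_GH2_E = np.tile(_GH_NODES, _GH_NODES.size)


def fit_params(logs: Sequence[SessionLog], method: str = "marginal",
               fix_tau: Optional[float] = None,
               compute_se: bool = False,
               x0: Optional[Sequence[float]] = None) -> FitResult:
    """Maximum-likelihood estimates of the population recall parameters.

    ``method="marginal"`` (default) maximizes the marginal Bernoulli
    likelihood of per-trial correctness with participant-level normal random
    effects on capacity and on compression utilization, integrated by 9-point
    Gauss-Hermite quadrature per dimension; it returns the population means
    (kappa, gamma, eta) together with the random-effect sds.
    ``method="pooled"`` fits a single homogeneous parameter vector — faster,
    but between-participant heterogeneity attenuates into the temperature
    and mildly biases eta upward.  ``fix_tau`` pins the temperature instead
    of profiling it.  Standard errors (numerical Hessian at the optimum) are
    computed on request.
    """
    data = _participant_arrays(logs)
    all_y = np.concatenate([d[3] for d in data]) if data else np.array([])
    n = int(all_y.size)
    if n == 0:
        raise ValueError("no scored trials in the logs")
    if all_y.all() or (1 - all_y).all():
        raise ValueError(
            "logs are degenerate (all correct or all incorrect): "
            "recall parameters are not identifiable"
        )
    if method not in ("marginal", "pooled"):
        raise ValueError(f"unknown method {method!r}")

    if method == "pooled":
        names = ["kappa", "gamma", "eta"] + ([] if fix_tau else ["tau"])
        bounds = [(0.5, 40.0), (0.05, 1.0), (0.0, 1.0)]
        start = [6.0, 0.8, 0.5]
        if fix_tau is None:
            bounds.append((0.05, 10.0))
            start.append(1.0)

        cxa = np.concatenate([d[0] for d in data])
        lna = np.concatenate([d[1] for d in data])
        cpa = np.concatenate([d[2] for d in data])
        verbatim = _N_FEATURES * lna
        order_unit = (lna >= 2).astype(float)

        def nll(theta) -> float:
            kappa, gamma, eta = theta[:3]
            tau = fix_tau if fix_tau is not None else theta[3]
            load = eta * cxa + (1 - eta) * verbatim + order_unit
            z = (kappa * np.where(cpa, gamma, 1.0) - load) / tau
            log_p = -np.logaddexp(0.0, -z)
            log_q = -np.logaddexp(0.0, z)
            return float(-(all_y * log_p + (1 - all_y) * log_q).sum())

        def unpack(theta):
            tau = fix_tau if fix_tau is not None else theta[3]
            return (theta[0], theta[1], theta[2], tau, float("nan"), float("nan"))

    else:
        names = ["kappa", "kappa_sd", "gamma", "eta", "eta_sd"] + ([] if fix_tau else ["tau"])
        bounds = [(0.5, 40.0), (0.02, 5.0), (0.05, 1.0), (0.01, 0.99), (0.005, 0.5)]
        start = [7.0, 1.0, 0.8, 0.5, 0.1]
        if fix_tau is None:
            bounds.append((0.05, 10.0))
            start.append(1.2)

        def nll(theta) -> float:
            mk, sk, gamma, me, se_eta = theta[:5]
            tau = fix_tau if fix_tau is not None else theta[5]
            kgrid = mk + sk * _GH2_K
            egrid = np.clip(me + se_eta * _GH2_E, 0.0, 1.0)
            total = 0.0
            for cx, ln, cp, y in data:
                verbatim = _N_FEATURES * ln
                order_unit = (ln >= 2).astype(float)
                load = (egrid[:, None] * cx[None, :]
                        + (1 - egrid)[:, None] * verbatim[None, :]
                        + order_unit[None, :])
                cap = kgrid[:, None] * np.where(cp, gamma, 1.0)[None, :]
                z = (cap - load) / tau
                ll = (y[None, :] * (-np.logaddexp(0.0, -z))
                      + (1 - y)[None, :] * (-np.logaddexp(0.0, z))).sum(axis=1)
                m = ll.max()
                total -= m + np.log((_GH2_W * np.exp(ll - m)).sum())
            return float(total)

        def unpack(theta):
            tau = fix_tau if fix_tau is not None else theta[5]
            return (theta[0], theta[2], theta[3], tau, theta[1], theta[4])

    if x0 is not None:
        start = list(x0)
    res = optimize.minimize(nll, start, method="L-BFGS-B", bounds=bounds)
    kappa, gamma, eta, tau, kappa_sd, eta_sd = unpack(res.x)
    se = _hessian_se(nll, res.x, names) if compute_se else {}
    return FitResult(kappa=float(kappa), gamma=float(gamma), eta=float(eta),
                     tau=float(tau), kappa_sd=float(kappa_sd),
                     eta_sd=float(eta_sd), se=se, nll=float(res.fun),
                     n_trials=n, converged=bool(res.success), method=method)


def _hessian_se(fun, x, names, step: float = 1e-4) -> Dict[str, float]:
    """Standard errors from a central-difference Hessian (best effort)."""
    x = np.asarray(x, float)
    k = x.size
    H = np.zeros((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = step
            ej = np.zeros(k); ej[j] = step
            if i == j:
                H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / step**2
            else:
                H[i, j] = H[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej)
                    - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * step**2)
    try:
        cov = np.linalg.inv(H)
        diag = np.clip(np.diag(cov), 0, None)
        return {name: float(np.sqrt(d)) for name, d in zip(names, diag)}
    except np.linalg.LinAlgError:
        return {name: float("nan") for name in names}
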