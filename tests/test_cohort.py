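"""Generative recall model, cohort simulation, and parameter recovery."""

import dataclasses

import numpy as np
import pytest

from chunkspan.cohort import (
    DEFAULT_COHORT,
    CohortHyperparams,
    ParticipantParams,
    effective_load,
    expected_cell_spans,
    fit_params,
    load_from_counts,
    recall_probability,
    simulate_cohort,
)
from chunkspan.io import logs_to_frame
from chunkspan.scoring import cell_table, concurrent_accuracy, score_sessions
from chunkspan.stimuli import build_block, build_structure_library, instantiate, sample_assignment


def make_trial(length=4, condition="chunkable", seed=0):
    rng = np.random.default_rng(seed)
    template = build_structure_library(length, condition)[0]
    return instantiate(template, sample_assignment(rng), rng)


def params(**kw):
    base = dict(kappa=8.0, gamma=0.7, eta=0.55, tau=1.4, p_eq=0.87)
    base.update(kw)
    return ParticipantParams(**base)


# ---------------------------------------------------------------------------
# load and recall probability
# ---------------------------------------------------------------------------

def test_effective_load_boundaries():
    trial = make_trial(length=4, condition="chunkable")  # complexity 1
    # eta = 0: verbatim description plus the serial-order unit
    assert effective_load(trial, params(eta=0.0)) == 12 + 1
    # eta = 1: compressed description plus the serial-order unit
    assert effective_load(trial, params(eta=1.0)) == 1 + 1
    # a single item needs no order unit
    single = make_trial(length=1)
    assert effective_load(single, params(eta=0.0)) == 3


def test_effective_load_non_increasing_in_eta():
    trial = make_trial(length=5, condition="nonchunkable")
    loads = [effective_load(trial, params(eta=e)) for e in np.linspace(0, 1, 11)]
    assert all(a >= b for a, b in zip(loads, loads[1:]))


def test_recall_probability_midpoint_and_gamma():
    trial = make_trial(length=4, condition="chunkable")
    load = effective_load(trial, params())
    at_capacity = params(kappa=load)
    assert recall_probability(trial, "simple", at_capacity) == pytest.approx(0.5)
    # gamma = 1 removes the complex-span cost entirely
    p = params(gamma=1.0)
    assert recall_probability(trial, "simple", p) == recall_probability(trial, "complex", p)
    # gamma < 1 reduces complex-span recall
    assert recall_probability(trial, "complex", params()) < recall_probability(
        trial, "simple", params()
    )


def test_recall_probability_decreases_with_length():
    """Recall probability falls with list length while structures of the
    class remain available.  Near the full 8-object space complexity is
    forced down (a 7-subset costs 3 literals, the whole space 0), so the
    effective load of compression users flattens at the top lengths:
    strict decrease is asserted through length 7 (chunkable) and 6
    (nonchunkable, whose forced drop comes one length earlier)."""
    p = params()
    for condition, top in (("chunkable", 7), ("nonchunkable", 6)):
        probs = []
        for length in range(1, top + 1):
            t = make_trial(length=length, condition=condition, seed=length)
            probs.append(recall_probability(t, "simple", p))
        assert all(a > b for a, b in zip(probs, probs[1:])), condition


def test_parameter_validation():
    with pytest.raises(ValueError):
        params(tau=0.0)
    with pytest.raises(ValueError):
        params(gamma=1.5)
    with pytest.raises(ValueError):
        params(eta=-0.1)
    with pytest.raises(ValueError):
        params(p_eq=0.4)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def test_same_seed_gives_bitwise_identical_logs():
    hyper = dataclasses.replace(DEFAULT_COHORT, n_participants=6)
    a = logs_to_frame(simulate_cohort(hyper, 42), seed=42)
    b = logs_to_frame(simulate_cohort(hyper, 42), seed=42)
    assert a.equals(b)
    c = logs_to_frame(simulate_cohort(hyper, 43), seed=43)
    assert not a.drop(columns="seed").equals(c.drop(columns="seed"))


def test_default_cohort_cell_means_are_ordered(default_cohort_logs):
    """Chunkable beats nonchunkable within task; simple beats complex within
    condition; the four means are strictly ordered as in human data."""
    table = cell_table(score_sessions(default_cohort_logs))
    cs = table.mean("simple", "chunkable")
    ns = table.mean("simple", "nonchunkable")
    cc = table.mean("complex", "chunkable")
    nc = table.mean("complex", "nonchunkable")
    assert cs > ns > cc > nc


def test_chunking_ratio_similar_across_tasks_with_shared_eta(default_cohort_logs):
    """With a single compression-utilization parameter shared across tasks,
    the global chunkable/nonchunkable ratio is about the same for simple and
    complex span — the multiplicative-effect null the model embodies."""
    table = cell_table(score_sessions(default_cohort_logs))
    r_simple = table.mean("simple", "chunkable") / table.mean("simple", "nonchunkable")
    r_complex = table.mean("complex", "chunkable") / table.mean("complex", "nonchunkable")
    assert abs(r_simple - r_complex) / r_simple < 0.25


def test_equation_accuracy_tracks_p_eq(default_cohort_logs):
    acc = concurrent_accuracy(default_cohort_logs)["by_condition"]
    for cond in ("chunkable", "nonchunkable"):
        stats = acc[cond]
        se = stats["sd"] / np.sqrt(stats["n"])
        assert abs(stats["mean"] - DEFAULT_COHORT.p_eq_mean) < 3 * max(se, 0.01)


def test_expected_cell_spans_match_simulation(default_cohort_logs):
    """The analytic expectation under the population means tracks the
    simulated cohort's cell means to within sampling/heterogeneity slack."""
    expect = expected_cell_spans(
        DEFAULT_COHORT.kappa_mean, DEFAULT_COHORT.gamma_mean,
        DEFAULT_COHORT.eta_mean, DEFAULT_COHORT.tau_mean,
    )
    table = cell_table(score_sessions(default_cohort_logs))
    for cell, value in expect.items():
        assert abs(table.mean(*cell) - value) < 0.45, cell


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def homogeneous(n=40, **overrides):
    base = dict(
        kappa_mean=8.2, kappa_sd=0.0, gamma_mean=0.7, gamma_sd=0.0,
        eta_mean=0.55, eta_sd=0.0, tau_mean=1.4, tau_sd=0.0,
        p_eq_mean=0.87, p_eq_sd=0.0, n_participants=n,
    )
    base.update(overrides)
    return CohortHyperparams(**base)


def test_likelihood_is_maximized_near_truth():
    """On a large homogeneous cohort the Bernoulli log-likelihood at the true
    parameters beats clearly perturbed parameters (computed independently of
    the fitting code, via the model's own recall probabilities)."""
    logs = simulate_cohort(homogeneous(n=60), 11)

    def nll(kappa, gamma, eta, tau):
        total = 0.0
        for log in logs:
            for block in log.blocks:
                for o in block.outcomes:
                    if o.trial.is_practice:
                        continue
                    p = recall_probability(
                        o.trial, block.task_type,
                        ParticipantParams(kappa, gamma, eta, tau, 0.87),
                    )
                    p = min(max(p, 1e-12), 1 - 1e-12)
                    total -= np.log(p) if o.correct else np.log(1 - p)
        return total

    truth = nll(8.2, 0.7, 0.55, 1.4)
    assert truth < nll(10.5, 0.7, 0.55, 1.4)
    assert truth < nll(8.2, 0.45, 0.55, 1.4)
    assert truth < nll(8.2, 0.7, 0.15, 1.4)


def test_pooled_fit_recovers_homogeneous_cohort():
    logs = simulate_cohort(homogeneous(n=60), 21)
    fit = fit_params(logs, method="pooled")
    assert abs(fit.kappa / 8.2 - 1) < 0.10
    assert abs(fit.gamma / 0.7 - 1) < 0.10
    assert abs(fit.eta / 0.55 - 1) < 0.15


def test_null_complex_span_cost_is_recovered():
    """Data simulated with gamma = 1: the estimate's CI must cover 1."""
    logs = simulate_cohort(homogeneous(n=40, gamma_mean=1.0), 31)
    fit = fit_params(logs, method="pooled", compute_se=True)
    se = fit.se.get("gamma", float("nan"))
    slack = 2 * se if np.isfinite(se) and se > 0 else 0.03
    assert fit.gamma + max(slack, 0.02) >= 1.0


def test_fit_rejects_degenerate_logs():
    logs = simulate_cohort(homogeneous(n=4, kappa_mean=39.0, tau_mean=0.05), 5)
    with pytest.raises(ValueError, match="degenerate"):
        fit_params(logs)
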