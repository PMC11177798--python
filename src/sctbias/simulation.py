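"""Accuracy simulation: sensitivity and specificity of the bias test.

Trials are simulated under a controllable selection-bias mechanism and each
is run through the full test, giving Monte-Carlo estimates of sensitivity
(positives among truly biased trials) and specificity (negatives among truly
unbiased ones).

Bias mechanism — directional misallocation.  Patients receive uniform
integer baseline values and a block-randomized allocation, exactly as in a
simulated comparator trial.  A fraction ``bias_fraction`` of patients is
then chosen uniformly at random; among the chosen, patients with discordant
allocations are paired off in random order and each pair is swapped, if
necessary, so that its older member sits in the test arm.  Swapping
preserves both group sizes, so the mechanism distorts only the value
balance, which is what selection bias at baseline does.  ``bias_fraction=0``
reduces exactly to ideal randomization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .bias_test import BiasTestConfig, run_bias_test
from .sct import GROUP_A, GROUP_B, _block_assignments, _summarize
from .trial_data import TrialBaseline, ValueRange

__all__ = [
    "SimulationScenario",
    "AccuracyEstimate",
    "simulate_trial",
    "estimate_accuracy",
]

_SEED_CAP = 2**31


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the simulation design.

    ``bias_fraction`` is the fraction of patients exposed to the directional
    misallocation override; 0 defines the unbiased (true-randomization) arm
    of the study.
    """

    n_total: int = 100
    range: ValueRange = ValueRange(18, 80)
    bias_fraction: float = 0.0
    n_replicates: int = 200
    seed: int = 0
    config: BiasTestConfig = BiasTestConfig()

    def __post_init__(self) -> None:
        if not (0.0 <= self.bias_fraction <= 1.0):
            raise ValueError(f"bias_fraction must be in [0, 1], got {self.bias_fraction}")
        if self.n_total < 4:
            raise ValueError(f"n_total must be >= 4, got {self.n_total}")
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")


@dataclass(frozen=True)
class AccuracyEstimate:
    """Sensitivity/specificity point estimates with Wilson 95% intervals."""

    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    n_biased: int
    n_unbiased: int
    positive_rate_by_scenario: pd.DataFrame
    replicate_log: pd.DataFrame

    def summary(self) -> str:
        lines = [
            "Bias-test accuracy simulation",
            f"  sensitivity: {self.sensitivity:.3f} "
            f"(95% CI {self.sensitivity_ci[0]:.3f}-{self.sensitivity_ci[1]:.3f}, n={self.n_biased})",
            f"  specificity: {self.specificity:.3f} "
            f"(95% CI {self.specificity_ci[0]:.3f}-{self.specificity_ci[1]:.3f}, n={self.n_unbiased})",
            "",
            self.positive_rate_by_scenario.to_string(index=False),
        ]
        return "\n".join(lines)


def simulate_trial(scenario: SimulationScenario, replicate_seed: int) -> TrialBaseline:
    """Simulate one two-arm trial under the scenario's bias mechanism.

    Group A plays the test arm, group B the control arm.  Deterministic for
    a fixed ``replicate_seed``.
    """
    rng = np.random.default_rng(replicate_seed)
    n = scenario.n_total
    assignments = _block_assignments(rng, n, scenario.config.block_size)
    values = rng.integers(scenario.range.low, scenario.range.high + 1, size=n)
    values.sort()

    n_override = int(round(scenario.bias_fraction * n))
    if n_override:
        chosen = rng.choice(n, size=n_override, replace=False)
        chosen_a = [i for i in chosen if assignments[i] == GROUP_A]
        chosen_b = [i for i in chosen if assignments[i] == GROUP_B]
        for i_a, i_b in zip(chosen_a, chosen_b):
            if values[i_b] > values[i_a]:
                assignments[i_a], assignments[i_b] = GROUP_B, GROUP_A

    arm_a, arm_b = _summarize(assignments, values)
    return TrialBaseline(
        trial_id=f"sim(bias={scenario.bias_fraction:g},seed={replicate_seed})",
        test_arm=arm_a,
        control_arm=arm_b,
        range=scenario.range,
    )


def _wilson(successes: int, total: int) -> tuple[float, float]:
    lo, hi = proportion_confint(successes, total, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def estimate_accuracy(scenarios: list[SimulationScenario]) -> AccuracyEstimate:
    """Run the bias test over every scenario replicate and tabulate accuracy.

    Requires at least one scenario with ``bias_fraction = 0`` (ground-truth
    unbiased) and one with ``bias_fraction > 0`` (ground-truth biased).  Each
    replicate draws its trial seed and its test-configuration seed from a
    scenario-level stream, so a longer run reproduces a shorter run's prefix.
    """
    if not any(s.bias_fraction == 0 for s in scenarios):
        raise ValueError("need at least one scenario with bias_fraction = 0")
    if not any(s.bias_fraction > 0 for s in scenarios):
        raise ValueError("need at least one scenario with bias_fraction > 0")

    rows = []
    for scenario in scenarios:
        seed_stream = np.random.default_rng(scenario.seed)
        for replicate in range(scenario.n_replicates):
            trial_seed = int(seed_stream.integers(_SEED_CAP))
            config_seed = int(seed_stream.integers(_SEED_CAP))
            trial = simulate_trial(scenario, trial_seed)
            result = run_bias_test(trial, replace(scenario.config, seed=config_seed))
            rows.append(
                {
                    "bias_fraction": scenario.bias_fraction,
                    "n_total": scenario.n_total,
                    "replicate": replicate,
                    "trial_seed": trial_seed,
                    "config_seed": config_seed,
                    "combined_i_squared": result.combined_i_squared,
                    "positive": result.result,
                    "attempts_used": result.attempts_used,
                }
            )
    log = pd.DataFrame(rows)

    biased = log[log["bias_fraction"] > 0]
    unbiased = log[log["bias_fraction"] == 0]
    n_biased, n_unbiased = len(biased), len(unbiased)
    true_pos = int(biased["positive"].sum())
    true_neg = int((1 - unbiased["positive"]).sum())

    by_scenario = (
        log.groupby(["bias_fraction", "n_total"], as_index=False)
        .agg(n_replicates=("positive", "size"), positive_rate=("positive", "mean"))
        .sort_values(["bias_fraction", "n_total"], ignore_index=True)
    )

    return AccuracyEstimate(
        sensitivity=true_pos / n_biased,
        sensitivity_ci=_wilson(true_pos, n_biased),
        specificity=true_neg / n_unbiased,
        specificity_ci=_wilson(true_neg, n_unbiased),
        n_biased=n_biased,
        n_unbiased=n_unbiased,
        positive_rate_by_scenario=by_scenario,
        replicate_log=log,
    )
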