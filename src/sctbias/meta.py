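"""Fixed-effect inverse-variance meta-analysis of mean differences.

Each study contributes a mean difference MD = mean_1 - mean_2 with variance
sd_1^2/n_1 + sd_2^2/n_2.  Studies are pooled with weights w_i = 1/var_i, and
heterogeneity is quantified by Cochran's Q = sum w_i (MD_i - MD_pooled)^2 and
the I2 point estimate

    I2 = max(0, 100 * (Q - df) / Q),    df = k - 1,

the percentage of between-study variance not attributable to chance.  Only
the fixed-effect model is provided: the bias test interprets any non-zero I2
as a signal, so random-effects machinery has no role here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .trial_data import ArmSummary

__all__ = [
    "StudyEffect",
    "DegenerateStudyError",
    "mean_difference",
    "i_squared",
    "FixedEffectMeta",
    "FixedEffectMetaResults",
    "pool_fixed",
]


class DegenerateStudyError(ValueError):
    """A study has zero effect variance and cannot be inverse-variance weighted."""


@dataclass(frozen=True)
class StudyEffect:
    """One study's mean difference (first arm minus second) and its variance."""

    study_id: str
    md: float
    variance: float

    def __post_init__(self) -> None:
        if not (self.variance > 0):
            raise DegenerateStudyError(
                f"study {self.study_id!r}: effect variance must be positive, got {self.variance!r}"
            )


def mean_difference(first: ArmSummary, second: ArmSummary, study_id: str = "") -> StudyEffect:
    """Mean-difference effect of two arms: MD = first.mean - second.mean.

    The variance is the usual large-sample form sd1^2/n1 + sd2^2/n2.  A pair
    of arms that both report sd = 0 has zero variance and raises
    :class:`DegenerateStudyError` (infinite weight is meaningless).
    """
    variance = first.variance_of_mean + second.variance_of_mean
    return StudyEffect(study_id=study_id, md=first.mean - second.mean, variance=variance)


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (display convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def i_squared(q: float, df: int) -> float:
    """I2 point estimate in percent from Cochran's Q and its degrees of freedom.

    Returns 0 when Q <= df (including Q = 0); otherwise 100*(Q - df)/Q,
    which lies in [0, 100).
    """
    if q < 0:
        raise ValueError(f"Q must be non-negative, got {q}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if q <= df:
        return 0.0
    return 100.0 * (q - df) / q


class FixedEffectMeta:
    """Fixed-effect inverse-variance meta-analysis model.

    Parameters
    ----------
    effects
        Study effects; at least two, all with positive variance.

    Examples
    --------
    >>> from sctbias.meta import FixedEffectMeta, StudyEffect
    >>> res = FixedEffectMeta([StudyEffect("a", 0.0, 1.0),
    ...                        StudyEffect("b", 1.0, 1.0),
    ...                        StudyEffect("c", 2.0, 1.0)]).fit()
    >>> res.pooled_md, res.q, res.i_squared
    (1.0, 2.0, 0.0)
    """

    def __init__(self, effects: Iterable[StudyEffect]):
        self.effects: tuple[StudyEffect, ...] = tuple(effects)
        if len(self.effects) < 2:
            raise ValueError(f"need at least 2 studies to pool, got {len(self.effects)}")

    @classmethod
    def from_arm_summaries(
        cls, pairs: Sequence[tuple[ArmSummary, ArmSummary]], study_ids: Sequence[str] | None = None
    ) -> "FixedEffectMeta":
        """Build the model from (first, second) arm-summary pairs."""
        if study_ids is None:
            study_ids = [f"study_{i + 1}" for i in range(len(pairs))]
        return cls([mean_difference(a, b, study_id=sid) for (a, b), sid in zip(pairs, study_ids)])

    def fit(self) -> "FixedEffectMetaResults":
        md = np.array([e.md for e in self.effects], dtype=float)
        var = np.array([e.variance for e in self.effects], dtype=float)
        w = 1.0 / var
        sw = float(w.sum())
        pooled_md = float((w * md).sum() / sw)
        pooled_se = math.sqrt(1.0 / sw)
        q = float((w * (md - pooled_md) ** 2).sum())
        df = len(self.effects) - 1
        return FixedEffectMetaResults(
            model=self,
            pooled_md=pooled_md,
            pooled_se=pooled_se,
            weights=w,
            q=q,
            df=df,
            i_squared=i_squared(q, df),
        )


@dataclass(frozen=True)
class FixedEffectMetaResults:
    """Results of a fixed-effect pooling: pooled MD, weights, Q and I2."""

    model: FixedEffectMeta
    pooled_md: float
    pooled_se: float
    weights: np.ndarray
    q: float
    df: int
    i_squared: float

    @property
    def i_squared_rounded(self) -> int:
        """I2 rounded to the nearest integer percent (ties away from zero)."""
        return round_half_away(self.i_squared)

    @property
    def pooled_ci(self) -> tuple[float, float]:
        """Normal-approximation 95% interval for the pooled mean difference."""
        half = 1.959963984540054 * self.pooled_se
        return self.pooled_md - half, self.pooled_md + half

    def summary(self) -> str:
        """Forest-style text table of study effects, weights and heterogeneity."""
        lines = [
            "Fixed-effect inverse-variance meta-analysis (mean difference)",
            f"{'study':<16}{'MD':>10}{'95% CI':>22}{'weight %':>10}",
        ]
        rel = 100.0 * self.weights / self.weights.sum()
        for effect, wpct in zip(self.model.effects, rel):
            half = 1.959963984540054 * math.sqrt(effect.variance)
            ci = f"[{effect.md - half:8.2f}, {effect.md + half:8.2f}]"
            lines.append(f"{effect.study_id:<16}{effect.md:>10.2f}{ci:>22}{wpct:>10.1f}")
        lo, hi = self.pooled_ci
        lines.append(f"{'pooled':<16}{self.pooled_md:>10.2f}{f'[{lo:8.2f}, {hi:8.2f}]':>22}{100.0:>10.1f}")
        lines.append(f"Q = {self.q:.4f}, df = {self.df}, I2 = {self.i_squared:.1f}% (rounded {self.i_squared_rounded}%)")
        return "\n".join(lines)

    def plot_forest(self, ax=None):
        """Minimal forest plot of study effects and the pooled diamond."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.6 * len(self.model.effects) + 1.5))
        k = len(self.model.effects)
        for i, effect in enumerate(self.model.effects):
            half = 1.959963984540054 * math.sqrt(effect.variance)
            y = k - i
            ax.plot([effect.md - half, effect.md + half], [y, y], color="k")
            ax.plot(effect.md, y, "ks", markersize=5)
        lo, hi = self.pooled_ci
        ax.fill([lo, self.pooled_md, hi, self.pooled_md], [0, 0.25, 0, -0.25], color="0.3")
        ax.axvline(0.0, color="0.6", linestyle=":")
        ax.set_yticks(list(range(k, 0, -1)) + [0])
        ax.set_yticklabels([e.study_id for e in self.model.effects] + ["pooled"])
        ax.set_xlabel("mean difference")
        ax.set_title(f"I2 = {self.i_squared:.1f}%")
        return ax


def pool_fixed(effects: Iterable[StudyEffect]) -> FixedEffectMetaResults:
    """Pool study effects with fixed-effect inverse-variance weights.

    Convenience wrapper equivalent to ``FixedEffectMeta(effects).fit()``.
    """
    return FixedEffectMeta(effects).fit()
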