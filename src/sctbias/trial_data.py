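"""Trial baseline data model, tabular I/O and summary-statistic converters.

A candidate trial enters the bias test as nothing more than its published
baseline summary: mean, standard deviation and patient count of one baseline
variable (typically age) per arm, plus the variable's plausible range for the
combined study population.  This module holds those records, reads and writes
them as CSV, and provides the two conversions reviewers need in practice when
a report does not print mean/SD directly: the Hozo median/range approximation
and the standard-error-to-SD conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Union

import pandas as pd

__all__ = [
    "ArmSummary",
    "ValueRange",
    "TrialBaseline",
    "SchemaError",
    "TrialValidationError",
    "read_trials",
    "write_trials",
    "median_range_to_mean_sd",
    "se_to_sd",
    "sd_to_se",
]


class SchemaError(ValueError):
    """The input table is missing a required column."""


class TrialValidationError(ValueError):
    """A cell of the input table violates a field constraint."""


@dataclass(frozen=True)
class ArmSummary:
    """Baseline summary of one trial arm: label, mean, SD and patient count.

    Units of ``mean`` and ``sd`` are whatever the baseline variable is
    reported in (years for age, occasionally months); the test is
    unit-invariant so no conversion is attempted.
    """

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if not isinstance(self.n, int) or self.n < 1:
            raise TrialValidationError(f"arm {self.label!r}: n must be a positive integer, got {self.n!r}")
        if not math.isfinite(self.mean):
            raise TrialValidationError(f"arm {self.label!r}: mean must be finite, got {self.mean!r}")
        if not math.isfinite(self.sd) or self.sd < 0:
            raise TrialValidationError(f"arm {self.label!r}: sd must be non-negative, got {self.sd!r}")

    @property
    def variance_of_mean(self) -> float:
        """Sampling variance of the arm mean, sd**2 / n."""
        return self.sd**2 / self.n


@dataclass(frozen=True)
class ValueRange:
    """Inclusive integer range of the baseline variable over both arms.

    ``estimated`` flags that a limit (usually the upper one) was a reviewer's
    estimate rather than a reported value.  A degenerate range with
    ``low == high`` is permitted for programmatic use (it forces constant
    baseline values); the CSV reader rejects it for real trial records.
    """

    low: int
    high: int
    estimated: bool = False

    def __post_init__(self) -> None:
        if not (isinstance(self.low, int) and isinstance(self.high, int)):
            raise TrialValidationError(f"range limits must be integers, got ({self.low!r}, {self.high!r})")
        if self.low > self.high:
            raise TrialValidationError(f"range low must be <= high, got [{self.low}, {self.high}]")

    @property
    def width(self) -> int:
        return self.high - self.low


@dataclass(frozen=True)
class TrialBaseline:
    """One two-arm trial's baseline summary: test arm, control arm, range."""

    trial_id: str
    test_arm: ArmSummary
    control_arm: ArmSummary
    range: ValueRange
    variable_name: str = "age"

    @property
    def n_total(self) -> int:
        """Combined patient number of both arms; sets the comparator-trial size."""
        return self.test_arm.n + self.control_arm.n

    def with_test_mean(self, mean: float) -> "TrialBaseline":
        """Copy of this trial with the test-arm mean replaced (imbalance probes)."""
        return replace(self, test_arm=replace(self.test_arm, mean=mean))


_REQUIRED_COLUMNS = (
    "trial_id",
    "test_mean",
    "test_sd",
    "test_n",
    "control_mean",
    "control_sd",
    "control_n",
    "range_low",
    "range_high",
)

_TableSource = Union[str, "IO[str]"]


def _cell_float(row: dict, row_no: int, column: str) -> float:
    try:
        value = float(row[column])
    except (TypeError, ValueError):
        raise TrialValidationError(f"row {row_no}: field {column!r}: not numeric: {row[column]!r}") from None
    if not math.isfinite(value):
        raise TrialValidationError(f"row {row_no}: field {column!r}: not finite: {value!r}")
    return value


def _cell_int(row: dict, row_no: int, column: str) -> int:
    value = _cell_float(row, row_no, column)
    if value != int(value):
        raise TrialValidationError(f"row {row_no}: field {column!r}: not an integer: {value!r}")
    return int(value)


def _cell_arm(row: dict, row_no: int, prefix: str, label: str) -> ArmSummary:
    mean = _cell_float(row, row_no, f"{prefix}_mean")
    sd = _cell_float(row, row_no, f"{prefix}_sd")
    n = _cell_int(row, row_no, f"{prefix}_n")
    if n < 1:
        raise TrialValidationError(f"row {row_no}: field '{prefix}_n': must be a positive integer, got {n}")
    if sd < 0:
        raise TrialValidationError(f"row {row_no}: field '{prefix}_sd': must be non-negative, got {sd}")
    return ArmSummary(label=label, mean=mean, sd=sd, n=n)


def read_trials(source: _TableSource) -> list[TrialBaseline]:
    """Read trial baseline summaries from a comma-separated table.

    The table must carry a header with the columns ``trial_id``,
    ``test_mean``, ``test_sd``, ``test_n``, ``control_mean``, ``control_sd``,
    ``control_n``, ``range_low``, ``range_high``; ``variable_name`` and
    ``range_estimated`` are optional and extra columns are ignored.  Row order
    is preserved.

    Raises
    ------
    SchemaError
        If a required column is absent.
    TrialValidationError
        If a cell is non-numeric or violates a field constraint
        (``n <= 0``, ``sd < 0``, ``range_low >= range_high``); the message
        names the offending row and field.
    """
    frame = pd.read_csv(source, dtype=str, skipinitialspace=True)
    for column in _REQUIRED_COLUMNS:
        if column not in frame.columns:
            raise SchemaError(f"missing required column {column!r}")

    trials: list[TrialBaseline] = []
    for i, row in enumerate(frame.to_dict("records"), start=1):
        try:
            test = _cell_arm(row, i, "test", "test")
            control = _cell_arm(row, i, "control", "control")
            estimated = str(row.get("range_estimated", "false")).strip().lower() in ("true", "1", "yes")
            low, high = _cell_int(row, i, "range_low"), _cell_int(row, i, "range_high")
            if low >= high:
                raise TrialValidationError(f"row {i}: field 'range_low': range low must be < high, got [{low}, {high}]")
            value_range = ValueRange(low=low, high=high, estimated=estimated)
        except TrialValidationError as err:
            if str(err).startswith("row "):
                raise
            raise TrialValidationError(f"row {i}: {err}") from None
        variable = row.get("variable_name")
        if variable is None or (isinstance(variable, float) and math.isnan(variable)):
            variable = "age"
        trials.append(
            TrialBaseline(
                trial_id=str(row["trial_id"]),
                test_arm=test,
                control_arm=control,
                range=value_range,
                variable_name=str(variable),
            )
        )
    return trials


def write_trials(trials: Iterable[TrialBaseline], dest: _TableSource) -> None:
    """Write trials back to the same CSV schema accepted by :func:`read_trials`."""
    records = [
        {
            "trial_id": t.trial_id,
            "test_mean": t.test_arm.mean,
            "test_sd": t.test_arm.sd,
            "test_n": t.test_arm.n,
            "control_mean": t.control_arm.mean,
            "control_sd": t.control_arm.sd,
            "control_n": t.control_arm.n,
            "range_low": t.range.low,
            "range_high": t.range.high,
            "range_estimated": t.range.estimated,
            "variable_name": t.variable_name,
        }
        for t in trials
    ]
    pd.DataFrame.from_records(records, columns=list(_REQUIRED_COLUMNS) + ["range_estimated", "variable_name"]).to_csv(
        dest, index=False
    )


def median_range_to_mean_sd(median: float, low: float, high: float, n: int) -> tuple[float, float]:
    """Approximate mean and SD from a reported median and range (Hozo method).

    mean = (low + 2*median + high) / 4 for all n.  The SD estimator switches
    with sample size::

        n <= 15      sqrt( ((low - 2*median + high)**2 / 4 + (high - low)**2) / 12 )
        15 < n <= 70 (high - low) / 4
        n > 70       (high - low) / 6

    Raises a ``ValueError`` when the median lies outside [low, high] or n < 1.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (low <= median <= high):
        raise ValueError(f"median {median} outside range [{low}, {high}]")
    mean = (low + 2.0 * median + high) / 4.0
    if n <= 15:
        sd = math.sqrt(((low - 2.0 * median + high) ** 2 / 4.0 + (high - low) ** 2) / 12.0)
    elif n <= 70:
        sd = (high - low) / 4.0
    else:
        sd = (high - low) / 6.0
    return mean, sd


def se_to_sd(se: float, n: int) -> float:
    """Convert a reported standard error of the mean to an SD: sd = se * sqrt(n)."""
    if se < 0:
        raise ValueError(f"standard error must be non-negative, got {se}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return se * math.sqrt(n)


def sd_to_se(sd: float, n: int) -> float:
    """Inverse of :func:`se_to_sd`: se = sd / sqrt(n)."""
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return sd / math.sqrt(n)
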