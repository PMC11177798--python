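"""Bundled reference dataset: 16 published two-arm studies with SCT summaries.

The package ships the baseline age summaries of 16 published prospective
controlled therapy studies — eight randomized controlled trials that serve
as negative controls (each reported a negative patient-level selection-bias
test) and eight prospective controlled cohort studies that serve as positive
controls (no random allocation, so baseline imbalance is expected).  For
each study the arm summaries of the two simulated comparator trials used in
the original application of the test are also included, enabling exact
replay of those 16 test runs via
:func:`sctbias.bias_test.run_bias_test_with_scts`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .trial_data import ArmSummary, TrialBaseline, read_trials

__all__ = [
    "load_trials",
    "load_trials_table",
    "load_sct_summaries",
    "read_sct_summaries",
]

ArmPair = tuple[ArmSummary, ArmSummary]


def _data_path(name: str):
    return resources.files("sctbias") / "data" / name


def load_trials() -> list[TrialBaseline]:
    """The 16 reference studies as validated :class:`TrialBaseline` records."""
    with resources.as_file(_data_path("trials.csv")) as path:
        return read_trials(str(path))


def load_trials_table() -> pd.DataFrame:
    """The raw reference table, including the ``study_type`` column."""
    with resources.as_file(_data_path("trials.csv")) as path:
        return pd.read_csv(path)


def _summaries_from_frame(frame: pd.DataFrame) -> dict[str, tuple[ArmPair, ArmPair]]:
    out: dict[str, tuple[ArmPair, ArmPair]] = {}
    for trial_id, group in frame.groupby("trial_id", sort=False):
        pairs = []
        for _, row in group.sort_values("sct").iterrows():
            pairs.append(
                (
                    ArmSummary("A", float(row["a_mean"]), float(row["a_sd"]), int(row["a_n"])),
                    ArmSummary("B", float(row["b_mean"]), float(row["b_sd"]), int(row["b_n"])),
                )
            )
        if len(pairs) != 2:
            raise ValueError(f"trial {trial_id!r}: expected exactly 2 SCT rows, got {len(pairs)}")
        out[str(trial_id)] = (pairs[0], pairs[1])
    return out


def read_sct_summaries(source) -> dict[str, tuple[ArmPair, ArmPair]]:
    """Read replay SCT arm summaries from a CSV.

    Expected columns: ``trial_id, sct, a_mean, a_sd, a_n, b_mean, b_sd, b_n``
    with exactly two rows (sct = 1 and 2) per trial.
    """
    return _summaries_from_frame(pd.read_csv(source))


def load_sct_summaries() -> dict[str, tuple[ArmPair, ArmPair]]:
    """Per-study SCT arm-summary pairs of the bundled reference dataset."""
    with resources.as_file(_data_path("sct_summaries.csv")) as path:
        return read_sct_summaries(str(path))
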