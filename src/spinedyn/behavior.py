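"""Behavioral indices and qPCR fold change.

Self-contained formula implementations:

* novel-object recognition (NOR) preference index — novel-object
  exploration time as a percentage of total exploration time;
* Y-maze spontaneous alternation — percentage of overlapping entry
  triplets that visit three distinct arms,
  ``100 * successes / (n_entries - 2)``;
* relative gene expression by 2^-ΔΔCt, target Ct normalized to a
  reference gene (e.g. GAPDH) and to the mean control ΔCt.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "preference_index",
    "spontaneous_alternation",
    "fold_change_ddct",
]


def preference_index(t_novel_s: float, t_familiar_s: float) -> float:
    """NOR preference: 100 * novel / (novel + familiar), in percent.

    Returns nan when both exploration times are zero (undefined).
    """
    if t_novel_s < 0 or t_familiar_s < 0:
        raise ValueError("exploration times must be nonnegative")
    total = t_novel_s + t_familiar_s
    if total == 0:
        return float("nan")
    return 100.0 * t_novel_s / total


def spontaneous_alternation(entries) -> float:
    """Y-maze spontaneous alternation percentage.

    ``entries`` is the ordered arm-entry sequence over labels {A, B, C}.
    Every overlapping window of three consecutive entries with three
    distinct arms is a successful triad; the score is
    ``100 * successes / (len(entries) - 2)``. Fewer than three entries is
    undefined (nan).
    """
    entries = list(entries)
    allowed = {"A", "B", "C"}
    if not set(entries) <= allowed:
        raise ValueError(f"arm labels must be drawn from {sorted(allowed)}")
    n = len(entries)
    if n < 3:
        return float("nan")
    successes = sum(
        1 for i in range(n - 2) if len(set(entries[i:i + 3])) == 3
    )
    return 100.0 * successes / (n - 2)


def fold_change_ddct(ct: pd.DataFrame, *,
                     control_label: str = "control") -> pd.DataFrame:
    """Relative expression per sample by the 2^-ΔΔCt method.

    ``ct`` needs columns ``target_ct``, ``reference_ct`` and ``condition``.
    ΔCt = target − reference per sample; ΔΔCt subtracts the mean control
    ΔCt; fold change is 2^−ΔΔCt. Samples with a missing reference Ct are
    excluded with a warning. Returns the input rows plus ``delta_ct``,
    ``delta_delta_ct`` and ``fold_change`` columns.
    """
    required = {"target_ct", "reference_ct", "condition"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    df = ct.copy()
    missing = df["reference_ct"].isna() | df["target_ct"].isna()
    if missing.any():
        warnings.warn(
            f"excluding {int(missing.sum())} sample(s) with missing Ct",
            stacklevel=2,
        )
        df = df[~missing].copy()
    if not np.all((df["target_ct"] > 0) & (df["reference_ct"] > 0)):
        raise ValueError("Ct values must be finite and positive")
    controls = df[df["condition"] == control_label]
    if len(controls) == 0:
        raise ValueError(f"no {control_label!r} samples in the Ct table")
    df["delta_ct"] = df["target_ct"] - df["reference_ct"]
    calibrator = float(
        (controls["target_ct"] - controls["reference_ct"]).mean()
    )
    df["delta_delta_ct"] = df["delta_ct"] - calibrator
    df["fold_change"] = np.power(2.0, -df["delta_delta_ct"])
    return df
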