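"""Trial filtering and derived behavioural measures.

Accuracy is computed on *all* trials of a condition; reaction-time statistics
are computed on correct trials with RTs inside the (100, 1500) ms window
(strict bounds: trials *faster than* 100 ms or *exceeding* 1500 ms are
removed, the boundary values are retained).  The attentional benefit is the
cued-minus-non-specific RT difference (negative = benefit); the distractor
cost is the with-minus-without-distractor difference in accuracy and RT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RT_MIN_MS",
    "RT_MAX_MS",
    "chance_level",
    "filter_trials",
    "condition_summary",
    "attentional_benefit",
    "distractor_cost",
    "read_table",
    "write_table",
]

RT_MIN_MS = 100.0
RT_MAX_MS = 1500.0

REQUIRED_COLUMNS = ("condition", "rt_ms", "correct", "distractor_present")


def chance_level(n_alternatives: int = 3) -> float:
    """Chance accuracy of an n-alternative forced choice (default 3 => ~33%).

    Used as the participant-exclusion criterion: performance must exceed it.
    """
    if n_alternatives < 2:
        raise ValueError("need at least 2 response alternatives")
    return 1.0 / n_alternatives


def _check(table: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"behaviour table missing columns: {sorted(missing)}")


@dataclass
class ExclusionReport:
    """Per-reason counts of trials removed by :func:`filter_trials`."""

    n_input: int
    n_incorrect: int
    n_too_fast: int
    n_too_slow: int

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_incorrect - self.n_too_fast - self.n_too_slow


def filter_trials(table: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove incorrect trials and RTs < 100 ms or > 1500 ms (strict).

    Idempotent: filtering an already-filtered table removes nothing.
    Trials with a missing RT cannot enter RT statistics and are counted
    with the incorrect removals.
    """
    _check(table)
    correct = table["correct"].astype(bool)
    rt = table["rt_ms"].astype(float)
    incorrect = ~correct | rt.isna()
    too_fast = correct & rt.notna() & (rt < RT_MIN_MS)
    too_slow = correct & rt.notna() & (rt > RT_MAX_MS)
    keep = ~(incorrect | too_fast | too_slow)
    report = ExclusionReport(
        n_input=len(table),
        n_incorrect=int(incorrect.sum()),
        n_too_fast=int(too_fast.sum()),
        n_too_slow=int(too_slow.sum()),
    )
    return table[keep].reset_index(drop=True), report


def condition_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition accuracy (%, all trials) and RT mean/SD (filtered trials).

    Conditions with no retained RT trials get NaN RT statistics and are
    flagged in the ``missing_rt`` column.
    """
    _check(table)
    filtered, _ = filter_trials(table)
    rows = []
    for cond, grp in table.groupby("condition", sort=True):
        fgrp = filtered[filtered["condition"] == cond]
        rows.append(
            {
                "condition": cond,
                "n_trials": len(grp),
                "accuracy_pct": 100.0 * grp["correct"].astype(bool).mean(),
                "n_rt_trials": len(fgrp),
                "rt_mean_ms": fgrp["rt_ms"].mean() if len(fgrp) else np.nan,
                "rt_sd_ms": fgrp["rt_ms"].std(ddof=1) if len(fgrp) > 1 else np.nan,
                "missing_rt": len(fgrp) == 0,
            }
        )
    return pd.DataFrame(rows)


_CUED = {"auditory": "auditory_cue", "visual": "visual_cue"}


def attentional_benefit(table: pd.DataFrame, modality: str) -> float:
    """Cued minus non-specific mean filtered RT for one target modality (ms).

    Negative values mean the specific cue speeded responses.  For the
    non-specific condition only trials of the matching target modality would
    ideally enter; the table's non-specific trials are used as they stand.
    """
    if modality not in _CUED:
        raise ValueError(f"modality must be one of {sorted(_CUED)}")
    filtered, _ = filter_trials(table)
    cued = filtered[filtered["condition"] == _CUED[modality]]["rt_ms"]
    nonspec = filtered[filtered["condition"] == "nonspecific_cue"]["rt_ms"]
    if len(nonspec) == 0:
        raise ValueError("no non-specific-cue trials available")
    if len(cued) == 0:
        raise ValueError(f"no {_CUED[modality]} trials available")
    return float(cued.mean() - nonspec.mean())


def distractor_cost(table: pd.DataFrame, modality: str) -> tuple[float, float]:
    """(delta accuracy, delta RT) of cued trials with vs without distractor.

    Accuracy delta is in percentage points on all trials; RT delta (ms) is on
    filtered correct trials.  Positive delta RT = slower with a distractor;
    negative delta accuracy = less accurate with a distractor.
    """
    if modality not in _CUED:
        raise ValueError(f"modality must be one of {sorted(_CUED)}")
    cond = _CUED[modality]
    sub = table[table["condition"] == cond]
    with_d = sub[sub["distractor_present"].astype(bool)]
    without = sub[~sub["distractor_present"].astype(bool)]
    if len(with_d) == 0 or len(without) == 0:
        raise ValueError(f"{cond}: need trials with and without distractors")
    d_acc = 100.0 * (
        with_d["correct"].astype(bool).mean() - without["correct"].astype(bool).mean()
    )
    filtered, _ = filter_trials(sub)
    f_with = filtered[filtered["distractor_present"].astype(bool)]["rt_ms"]
    f_without = filtered[~filtered["distractor_present"].astype(bool)]["rt_ms"]
    if len(f_with) == 0 or len(f_without) == 0:
        raise ValueError(f"{cond}: no retained RT trials in one distractor level")
    return float(d_acc), float(f_with.mean() - f_without.mean())


def write_table(table: pd.DataFrame, path) -> None:
    """Write a behaviour table as TSV with the documented header."""
    _check(table)
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    """Read a behaviour table written by :func:`write_table`."""
    table = pd.read_csv(path, sep="\t")
    _check(table)
    table["correct"] = table["correct"].astype(bool)
    table["distractor_present"] = table["distractor_present"].astype(bool)
    return table
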