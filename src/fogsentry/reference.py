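"""Published reference tables bundled with the package.

Two study cohorts of people with Parkinson's disease walked a
freeze-inducing path wearing pressure-sensing insoles.  The per-participant
characteristics of those cohorts (demographics, clinical scores, trial
counts, FOG episode statistics, total MTD-target-zone durations) and the
published window- and episode-level performance of the models trained on
them are shipped as small CSVs.  They serve two purposes: recomputing the
cohort summary aggregates from the per-participant rows, and fixture checks
of the episode-metric invariants (e.g. max(predicted%, detected%) <=
identified% <= predicted% + detected%).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

_DATA = Path(__file__).parent / "data"

__all__ = ["load_cohort_table", "load_performance_table"]


def load_cohort_table(cohort: int) -> pd.DataFrame:
    """Per-participant table for cohort 1 or 2, indexed by participant id.

    Columns: age_years, years_since_diagnosis, nfogq, updrs3, froze,
    n_trials, total_trial_duration_s, n_fog, total_fog_duration_s,
    total_target_zone_s (blank where no model was evaluated for the
    participant).
    """
    if cohort not in (1, 2):
        raise ValueError("cohort must be 1 or 2")
    df = pd.read_csv(_DATA / f"cohort{cohort}_participants.csv", index_col="participant")
    df["froze"] = df["froze"].astype(bool)
    return df


def load_performance_table() -> pd.DataFrame:
    """Published model performance per training dataset (and modifications)."""
    return pd.read_csv(_DATA / "published_performance.csv", index_col="dataset")
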