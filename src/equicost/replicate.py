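"""Replication driver for the deposited study survey.

Given a local copy of the study's exit-interview table (canonical CSV or
a CSV plus a column-mapping schema), recompute the headline quantities of
the equity analysis: mean travel time, the travel-time concentration
index, the share of patients paying for medical care, and the share
travelling on foot.  The deposited data are not shipped with this
package; point ``path`` at a local download.
"""

from __future__ import annotations

from pathlib import Path

from .pipeline import AnalysisConfig, cost_summary, stratified_equity_table
from .survey_data import load_exit_interviews

STUDY_DATA_PATH = Path("data") / "study_exit_interviews.csv"


def replicate_study(path: str | Path, schema=None) -> dict[str, float]:
    """Headline estimates from a local copy of the study dataset."""
    dataset = load_exit_interviews(path, schema)
    config = AnalysisConfig()
    travel = cost_summary(dataset, "travel_time_min", config)
    travel_eq = stratified_equity_table(dataset, "travel_time_min",
                                        "ses_quintile_extremes", config)
    paid = cost_summary(dataset, "paid_medical_pct", config)
    foot = cost_summary(dataset, "mode_foot_pct", config)
    return {
        "mean_travel_time_min": travel.mean,
        "travel_time_ci": float(travel_eq["ci"].iloc[0]),
        "pct_paying_medical": paid.mean,
        "pct_on_foot": foot.mean,
    }
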