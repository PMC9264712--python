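"""Cost transformations, summaries, share decompositions, equity tables.

The raw survey stores one-way travel time (minutes) and one-way transport
cost (TZS).  This module applies the reporting conventions — currency
conversion at the survey-period rate (1 USD = 1600 TZS by default) and the
optional round-trip doubling of travel components — then computes
per-outcome summaries, component shares of total time / total direct cost,
and the stratified equity analysis across wealth quintiles, residence,
facility ownership and level, and service type.

Every summary recomputes its per-outcome n on the complete-case subset of
the dataset it receives; restrictions (e.g. public facilities only) are
applied to the dataset before analysis and counts are never cached.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .inequality import EquityResult, equity_result, stars
from .survey_data import Dataset, ValidationError, complete_case
from .wealth import ranked_sample, wealth_scores

__all__ = [
    "AnalysisConfig",
    "CostShareBreakdown",
    "convert_currency",
    "apply_convention",
    "cost_summary",
    "share_decomposition",
    "stratified_equity_table",
    "restrict_public",
    "equity_table_ses_residence",
    "group_mean_table",
    "shares_table",
]

ONE_WAY = "one_way"
ROUND_TRIP = "round_trip"

#: Components doubled when the return trip is counted.
TRAVEL_COMPONENTS = ("travel_time", "transport_cost")

TIME_COMPONENTS = ("travel_time", "waiting_time", "consultation_time")
DIRECT_COMPONENTS = ("transport_cost", "medical_cost")


@dataclass
class AnalysisConfig:
    convention: str = ONE_WAY
    currency_rate_tzs_per_usd: float = 1600.0
    restrict_public_only: bool = False
    strata: list[str] = field(default_factory=lambda: [
        "ses_quintile_extremes", "residence", "ownership", "level", "service",
    ])

    def __post_init__(self) -> None:
        if self.convention not in (ONE_WAY, ROUND_TRIP):
            raise ValueError(f"unknown convention {self.convention!r}")
        if self.currency_rate_tzs_per_usd <= 0:
            raise ValueError("currency rate must be positive")


@dataclass
class CostShareBreakdown:
    """Component means and their shares of the total, under one convention."""

    convention: str
    components: dict[str, float]
    total: float
    shares: dict[str, float]


CostSummary = namedtuple("CostSummary", "n mean median pct_nonzero")


def convert_currency(amount_tzs, rate: float = 1600.0):
    """TZS → USD at the survey exchange rate; full precision retained."""
    if rate <= 0:
        raise ValueError("exchange rate must be positive")
    amount = np.asarray(amount_tzs, dtype=float)
    if np.any(amount[~np.isnan(amount)] < 0):
        raise ValueError("negative amount cannot be converted")
    out = amount / rate
    return float(out) if np.isscalar(amount_tzs) else out


def apply_convention(dataset: Dataset, convention: str) -> Dataset:
    """Apply the journey convention to record-level travel components.

    ``round_trip`` doubles travel time and transport cost only (waiting,
    consultation, and medical cost describe the visit, not the journey);
    ``one_way`` is the identity.  A dataset already on the round-trip
    convention cannot be doubled again.
    """
    if convention not in (ONE_WAY, ROUND_TRIP):
        raise ValueError(f"unknown convention {convention!r}")
    if convention == ONE_WAY:
        return dataset
    if dataset.convention == ROUND_TRIP:
        raise ValueError("dataset is already on the round-trip convention")
    df = dataset.df.copy()
    df["travel_time_min"] = df["travel_time_min"] * 2.0
    df["transport_cost_tzs"] = df["transport_cost_tzs"] * 2.0
    return replace(dataset, df=df, convention=ROUND_TRIP)


# ---------------------------------------------------------------------------
# Outcome registry
# ---------------------------------------------------------------------------
# Each analysis outcome maps to (source column for the complete-case subset,
# value extractor).  Binary outcomes are expressed in percent so their means
# print as shares; the concentration index is scale invariant so this does
# not affect equity measures.

def _usd(col: str) -> Callable[[pd.DataFrame, AnalysisConfig], np.ndarray]:
    def extract(df: pd.DataFrame, config: AnalysisConfig) -> np.ndarray:
        return convert_currency(df[col].to_numpy(float),
                                config.currency_rate_tzs_per_usd)
    return extract


def _minutes(col: str) -> Callable[[pd.DataFrame, AnalysisConfig], np.ndarray]:
    return lambda df, config: df[col].to_numpy(float)


def _paid(col: str) -> Callable[[pd.DataFrame, AnalysisConfig], np.ndarray]:
    return lambda df, config: 100.0 * (df[col].to_numpy(float) > 0)


def _mode(mode: str) -> Callable[[pd.DataFrame, AnalysisConfig], np.ndarray]:
    return lambda df, config: 100.0 * (df["travel_mode"] == mode).to_numpy()


OUTCOMES: dict[str, tuple[str | None, Callable]] = {
    "travel_time_min": ("travel_time_min", _minutes("travel_time_min")),
    "waiting_time_min": ("waiting_time_min", _minutes("waiting_time_min")),
    "consultation_time_min": ("consultation_time_min",
                              _minutes("consultation_time_min")),
    "transport_cost_usd": ("transport_cost_tzs", _usd("transport_cost_tzs")),
    "medical_cost_usd": ("medical_cost_tzs", _usd("medical_cost_tzs")),
    "paid_transport_pct": ("transport_cost_tzs", _paid("transport_cost_tzs")),
    "paid_medical_pct": ("medical_cost_tzs", _paid("medical_cost_tzs")),
    "mode_foot_pct": (None, _mode("foot")),
    "mode_car_pct": (None, _mode("car")),
    "mode_motorbike_bicycle_pct": (None, _mode("motorbike_bicycle")),
}

STRATIFIERS = ("ses_quintile_extremes", "residence", "ownership", "level", "service")

#: Reference group for the group-mean stratifiers (Welch t-tests against it).
REFERENCE_GROUP = {"ownership": "public", "level": "hospital", "service": "anc"}
GROUP_ORDER = {
    "ownership": ("public", "fbo", "private"),
    "level": ("hospital", "health_centre", "dispensary"),
    "service": ("anc", "pnc", "vaccination", "checkup"),
}


def _analysis_subset(
    dataset: Dataset,
    outcome: str,
    config: AnalysisConfig,
    *,
    mode_filter: str | None = None,
    payers_only: bool = False,
    scores: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """(subset frame, outcome values, wealth scores) for one outcome.

    Wealth scores are computed on the full dataset passed in, then carried
    into the complete-case / mode-filtered subset, where fractional ranks
    are recomputed so the mean-rank identity holds within the analysis
    sample.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unrecognised outcome {outcome!r}")
    source, extractor = OUTCOMES[outcome]
    if scores is None:
        scores = wealth_scores(dataset)
    df = dataset.df
    mask = np.ones(len(df), dtype=bool)
    if source is not None:
        mask &= df[source].notna().to_numpy()
    if mode_filter is not None:
        mask &= (df["travel_mode"] == mode_filter).to_numpy()
    if payers_only:
        if source is None:
            raise ValueError("payers_only needs a cost outcome")
        mask &= (df[source].to_numpy(float) > 0)
    if not mask.any():
        raise ValidationError(f"no observations for outcome {outcome!r}")
    sub = df.loc[mask]
    values = extractor(sub, config)
    return sub, values, scores[mask]


def cost_summary(
    dataset: Dataset,
    outcome: str,
    config: AnalysisConfig | None = None,
    *,
    mode_filter: str | None = None,
) -> CostSummary:
    """Unweighted n / mean / median / % nonzero on the complete-case subset."""
    config = config or AnalysisConfig()
    _, values, _ = _analysis_subset(dataset, outcome, config,
                                    mode_filter=mode_filter)
    return CostSummary(
        n=int(values.size),
        mean=float(values.mean()),
        median=float(np.median(values)),
        pct_nonzero=float(100.0 * np.mean(values > 0)),
    )


def share_decomposition(
    component_means: Mapping[str, float],
    convention: str = ONE_WAY,
) -> CostShareBreakdown:
    """Component shares of the total, after applying the journey convention.

    ``component_means`` are one-way means keyed by component name (e.g.
    travel_time/waiting_time/consultation_time in minutes, or
    transport_cost/medical_cost in USD).  Under ``round_trip`` the travel
    components are doubled before shares are taken.  Shares sum to one.
    """
    if convention not in (ONE_WAY, ROUND_TRIP):
        raise ValueError(f"unknown convention {convention!r}")
    components: dict[str, float] = {}
    for name, mean in component_means.items():
        mean = float(mean)
        if mean < 0:
            raise ValueError(f"negative component mean for {name!r}")
        if convention == ROUND_TRIP and name in TRAVEL_COMPONENTS:
            mean *= 2.0
        components[name] = mean
    total = sum(components.values())
    if total == 0:
        raise ValueError("zero total: shares undefined")
    shares = {name: mean / total for name, mean in components.items()}
    return CostShareBreakdown(convention=convention, components=components,
                              total=total, shares=shares)


def restrict_public(dataset: Dataset) -> Dataset:
    """Robustness restriction to publicly owned facilities."""
    mask = (dataset.df["ownership"] == "public").to_numpy()
    if not mask.any():
        raise ValidationError("no public-facility records to restrict to")
    return dataset.subset(mask)


def _two_group_result(
    dataset: Dataset,
    outcome: str,
    config: AnalysisConfig,
    contrast: str,
    *,
    mode_filter: str | None = None,
    payers_only: bool = False,
    scores: np.ndarray | None = None,
) -> EquityResult:
    sub, values, sub_scores = _analysis_subset(
        dataset, outcome, config, mode_filter=mode_filter,
        payers_only=payers_only, scores=scores)
    sample = ranked_sample(values, sub_scores)
    if contrast == "ses_quintile_extremes":
        mask_a = sample.quintile == 1  # poorest
        mask_b = sample.quintile == 5  # least poor
        label = "poorest_vs_least_poor"
    elif contrast == "residence":
        mask_a = (sub["residence"] == "rural").to_numpy()
        mask_b = (sub["residence"] == "urban").to_numpy()
        label = "rural_vs_urban"
    else:
        raise ValueError(f"unknown two-group contrast {contrast!r}")
    if not mask_a.any() or not mask_b.any():
        missing = "group a" if not mask_a.any() else "group b"
        raise ValidationError(f"empty cell for {label}: {missing}")
    return equity_result(sample, mask_a, mask_b, outcome=outcome, contrast=label)


def _group_means_row(
    dataset: Dataset,
    outcome: str,
    stratifier: str,
    config: AnalysisConfig,
    *,
    mode_filter: str | None = None,
) -> dict:
    """Group means with Welch tests against the stratifier's reference group."""
    from .inequality import equity_gap

    sub, values, _ = _analysis_subset(dataset, outcome, config,
                                      mode_filter=mode_filter)
    groups = GROUP_ORDER[stratifier]
    ref = REFERENCE_GROUP[stratifier]
    labels = sub[stratifier].to_numpy()
    present = set(labels)
    if len(present) < 2:
        raise ValidationError(
            f"stratifier {stratifier!r} has a single group "
            f"({present.pop()!r}) in the analysis subset")
    ref_values = values[labels == ref]
    if ref_values.size == 0:
        raise ValidationError(f"empty cell: reference group {ref!r}")
    row: dict = {"outcome": outcome, "n": int(values.size),
                 "mean": float(values.mean())}
    for g in groups:
        cell = values[labels == g]
        if cell.size == 0:
            raise ValidationError(f"empty cell: {stratifier}={g!r}")
        row[f"{g}_n"] = int(cell.size)
        row[f"{g}_mean"] = float(cell.mean())
        if g == ref:
            row[f"{g}_stars"] = "(ref)"
        else:
            _, _, p = equity_gap(cell, ref_values)
            row[f"{g}_stars"] = stars(p) if np.isfinite(p) else ""
    return row


def stratified_equity_table(
    dataset: Dataset,
    outcome: str,
    stratifier: str,
    config: AnalysisConfig | None = None,
    *,
    mode_filter: str | None = None,
    payers_only: bool = False,
) -> pd.DataFrame:
    """One-outcome equity table for the requested stratifier.

    For ``ses_quintile_extremes`` and ``residence`` the row carries the
    full equity summary (gap between extreme groups, ratio, concentration
    index with robust inference); for ``ownership`` / ``level`` /
    ``service`` it carries group means with Welch-test stars against the
    reference group (public facility, hospital, ANC respectively).
    """
    if stratifier not in STRATIFIERS:
        raise ValueError(f"unrecognised stratifier {stratifier!r}")
    config = config or AnalysisConfig()
    if stratifier in ("ses_quintile_extremes", "residence"):
        res = _two_group_result(dataset, outcome, config, stratifier,
                                mode_filter=mode_filter, payers_only=payers_only)
        return pd.DataFrame([vars(res)])
    row = _group_means_row(dataset, outcome, stratifier, config,
                           mode_filter=mode_filter)
    return pd.DataFrame([row])


# ---------------------------------------------------------------------------
# Report tables (layouts mirroring the stratified equity reporting)
# ---------------------------------------------------------------------------

#: rows of the SES/residence table: (label, outcome, mode filter, payers only)
_SES_TABLE_ROWS: list[tuple[str, str, str | None, bool]] = [
    ("mode: foot (%)", "mode_foot_pct", None, False),
    ("mode: car (%)", "mode_car_pct", None, False),
    ("mode: motorbike & bicycle (%)", "mode_motorbike_bicycle_pct", None, False),
    ("travel time, all (min)", "travel_time_min", None, False),
    ("travel time, foot (min)", "travel_time_min", "foot", False),
    ("travel time, car (min)", "travel_time_min", "car", False),
    ("travel time, motorbike & bicycle (min)", "travel_time_min",
     "motorbike_bicycle", False),
    ("waiting time (min)", "waiting_time_min", None, False),
    ("consultation time (min)", "consultation_time_min", None, False),
    ("transport cost, all clients (USD)", "transport_cost_usd", None, False),
    ("transport cost, payers only (USD)", "transport_cost_usd", None, True),
    ("transport cost, car (USD)", "transport_cost_usd", "car", False),
    ("transport cost, motorbike & bicycle (USD)", "transport_cost_usd",
     "motorbike_bicycle", False),
    ("prob. of paying for transport (%)", "paid_transport_pct", None, False),
    ("prob. of paying for medical care (%)", "paid_medical_pct", None, False),
    ("medical cost, all clients (USD)", "medical_cost_usd", None, False),
]


def equity_table_ses_residence(
    dataset: Dataset, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Costs by SES extremes and residence: gap, ratio, CI per outcome.

    Mirrors the headline stratified cost table: mode shares, time costs
    (overall and per travel mode), and direct costs, each with the
    poorest−least-poor gap/ratio, the concentration index, and the
    rural−urban gap/ratio.  Transport cost rows are emitted both for all
    clients and conditional on payers, since self-reported zeros conflate
    non-payment with free rides.
    """
    config = config or AnalysisConfig()
    scores = wealth_scores(dataset)
    rows = []
    for label, outcome, mode_filter, payers_only in _SES_TABLE_ROWS:
        try:
            ses = _two_group_result(dataset, outcome, config,
                                    "ses_quintile_extremes",
                                    mode_filter=mode_filter,
                                    payers_only=payers_only, scores=scores)
            res = _two_group_result(dataset, outcome, config, "residence",
                                    mode_filter=mode_filter,
                                    payers_only=payers_only, scores=scores)
        except ValidationError:
            continue  # cell empty under this restriction; row not reportable
        rows.append({
            "row": label,
            "n": ses.n,
            "mean": ses.mean_overall,
            "gap_poorest_least_poor": ses.gap,
            "gap_ses_stars": ses.gap_stars,
            "ratio_poorest_least_poor": ses.ratio,
            "concentration_index": ses.ci,
            "ci_stars": ses.ci_stars,
            "gap_rural_urban": res.gap,
            "gap_residence_stars": res.gap_stars,
            "ratio_rural_urban": res.ratio,
        })
    return pd.DataFrame(rows)


_FACILITY_TABLE_ROWS = [
    ("travel time, all (min)", "travel_time_min"),
    ("waiting time (min)", "waiting_time_min"),
    ("consultation time (min)", "consultation_time_min"),
    ("transport cost, all clients (USD)", "transport_cost_usd"),
    ("prob. of paying for medical care (%)", "paid_medical_pct"),
    ("medical cost, all clients (USD)", "medical_cost_usd"),
]

_SERVICE_TABLE_ROWS = [
    ("waiting time (min)", "waiting_time_min"),
    ("consultation time (min)", "consultation_time_min"),
    ("prob. of paying for medical care (%)", "paid_medical_pct"),
    ("medical cost, all clients (USD)", "medical_cost_usd"),
]


def group_mean_table(
    dataset: Dataset,
    stratifiers: tuple[str, ...],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Group-mean table across one or two stratifiers with reference tests."""
    config = config or AnalysisConfig()
    row_spec = _SERVICE_TABLE_ROWS if stratifiers == ("service",) \
        else _FACILITY_TABLE_ROWS
    rows = []
    for label, outcome in row_spec:
        merged: dict = {"row": label}
        for stratifier in stratifiers:
            r = _group_means_row(dataset, outcome, stratifier, config)
            merged.setdefault("n", r["n"])
            merged.setdefault("mean", r["mean"])
            merged.update({k: v for k, v in r.items()
                           if k not in ("outcome", "n", "mean")})
        rows.append(merged)
    return pd.DataFrame(rows)


def shares_table(dataset: Dataset, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Time and direct-cost share decompositions under both conventions."""
    config = config or AnalysisConfig()
    time_means = {
        "travel_time": cost_summary(dataset, "travel_time_min", config).mean,
        "waiting_time": cost_summary(dataset, "waiting_time_min", config).mean,
        "consultation_time": cost_summary(dataset, "consultation_time_min",
                                          config).mean,
    }
    direct_means = {
        "transport_cost": cost_summary(dataset, "transport_cost_usd", config).mean,
        "medical_cost": cost_summary(dataset, "medical_cost_usd", config).mean,
    }
    rows = []
    for family, means in (("time", time_means), ("direct_cost", direct_means)):
        for convention in (ONE_WAY, ROUND_TRIP):
            bd = share_decomposition(means, convention)
            for name in means:
                rows.append({
                    "family": family,
                    "convention": convention,
                    "component": name,
                    "mean": bd.components[name],
                    "total": bd.total,
                    "share_pct": 100.0 * bd.shares[name],
                })
    return pd.DataFrame(rows)
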