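"""Exit-interview survey records: schema, ingest, validation, complete cases.

The canonical unit of data is one patient interviewed on leaving a primary
health care facility.  Each record carries the patient's travel mode, the
time costs of the visit (travel, waiting, consultation, in minutes, one-way
for travel), the direct costs (transport and medical, in Tanzanian
shillings, one-way for transport), the stratifiers used in the equity
analysis (residence, facility ownership and level, service sought), and the
household asset/housing indicators from which the wealth index is built.

Times and costs are stored exactly as reported: one-way, local currency.
Round-trip doubling and currency conversion are downstream transformations
(see :mod:`equicost.pipeline`), never applied at ingest.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

OWNERSHIP_LEVELS = ("public", "fbo", "private")
FACILITY_LEVELS = ("hospital", "health_centre", "dispensary")
SERVICE_LEVELS = ("anc", "pnc", "vaccination", "checkup")
RESIDENCE_LEVELS = ("rural", "urban")
TRAVEL_MODES = ("foot", "car", "motorbike_bicycle")

#: Outcome variables analysed on their own complete-case subsets.
OUTCOME_COLUMNS = (
    "travel_time_min",
    "waiting_time_min",
    "consultation_time_min",
    "transport_cost_tzs",
    "medical_cost_tzs",
)

ENUM_COLUMNS: dict[str, tuple[str, ...]] = {
    "ownership": OWNERSHIP_LEVELS,
    "level": FACILITY_LEVELS,
    "service": SERVICE_LEVELS,
    "residence": RESIDENCE_LEVELS,
    "travel_mode": TRAVEL_MODES,
}

ID_COLUMNS = ("patient_id", "facility_id")
CANONICAL_COLUMNS = ID_COLUMNS + tuple(ENUM_COLUMNS) + OUTCOME_COLUMNS + ("insurance",)

ASSET_PREFIX = "asset_"


class SchemaError(ValueError):
    """A mapped column is absent from the input file."""


class ValidationError(ValueError):
    """A cell value violates the record invariants (carries the row index)."""


@dataclass(frozen=True)
class ExitInterviewRecord:
    """One patient's costs, times, stratum labels, and asset indicators."""

    patient_id: str
    facility_id: str
    ownership: str
    level: str
    service: str
    residence: str
    travel_mode: str
    travel_time_min: float | None
    waiting_time_min: float | None
    consultation_time_min: float | None
    transport_cost_tzs: float | None
    medical_cost_tzs: float | None
    insurance: bool
    assets: tuple[float, ...]


@dataclass
class Dataset:
    """An ordered collection of exit-interview records.

    Backed by a :class:`pandas.DataFrame` with canonical column names;
    asset indicator columns are prefixed ``asset_``.  ``convention``
    records whether travel time / transport cost are one-way (as surveyed)
    or have been doubled for the return trip.
    """

    df: pd.DataFrame
    asset_names: list[str] = field(default_factory=list)
    currency_rate_tzs_per_usd: float = 1600.0
    convention: str = "one_way"

    def __post_init__(self) -> None:
        if len(self.df) == 0:
            raise ValidationError("dataset must contain at least one record")
        if self.currency_rate_tzs_per_usd <= 0:
            raise ValidationError("currency rate must be positive")
        _validate_frame(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def asset_columns(self) -> list[str]:
        return [ASSET_PREFIX + name for name in self.asset_names]

    def asset_matrix(self) -> np.ndarray:
        """Household indicator matrix, shape (n_records, n_assets)."""
        return self.df[self.asset_columns].to_numpy(dtype=float)

    def records(self) -> Iterator[ExitInterviewRecord]:
        asset_cols = self.asset_columns
        for _, row in self.df.iterrows():
            yield ExitInterviewRecord(
                patient_id=str(row["patient_id"]),
                facility_id=str(row["facility_id"]),
                ownership=row["ownership"],
                level=row["level"],
                service=row["service"],
                residence=row["residence"],
                travel_mode=row["travel_mode"],
                travel_time_min=_opt(row["travel_time_min"]),
                waiting_time_min=_opt(row["waiting_time_min"]),
                consultation_time_min=_opt(row["consultation_time_min"]),
                transport_cost_tzs=_opt(row["transport_cost_tzs"]),
                medical_cost_tzs=_opt(row["medical_cost_tzs"]),
                insurance=bool(row["insurance"]),
                assets=tuple(float(row[c]) for c in asset_cols),
            )

    def subset(self, mask: np.ndarray | pd.Series) -> "Dataset":
        """Row subset preserving order and metadata (errors if empty)."""
        sub = self.df.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        if len(sub) == 0:
            raise ValidationError("subset is empty")
        return replace(self, df=sub)


def _opt(value: object) -> float | None:
    return None if pd.isna(value) else float(value)


def _normalise_label(raw: object) -> str:
    s = str(raw).strip().lower()
    return re.sub(r"[\s/&-]+", "_", s)


# Common survey-export synonyms for the canonical enum labels.
_LABEL_SYNONYMS: dict[str, dict[str, str]] = {
    "ownership": {"government": "public", "faith_based": "fbo", "other": "private"},
    "level": {"health_center": "health_centre", "hc": "health_centre"},
    "service": {"check_up": "checkup", "child_vaccination": "vaccination"},
    "travel_mode": {
        "walking": "foot",
        "on_foot": "foot",
        "motorbike": "motorbike_bicycle",
        "bicycle": "motorbike_bicycle",
        "motorbike_&_bicycle": "motorbike_bicycle",
    },
    "residence": {},
}

_TRUE_SET = {"1", "true", "yes", "y"}
_FALSE_SET = {"0", "false", "no", "n", ""}


def _validate_frame(df: pd.DataFrame) -> None:
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"canonical column {col!r} missing from dataset")
    for col, levels in ENUM_COLUMNS.items():
        bad = ~df[col].isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"unknown {col} label {df[col].iloc[row]!r} at row {row}"
            )
    for col in OUTCOME_COLUMNS:
        vals = df[col].to_numpy(dtype=float)
        neg = vals < 0
        if np.any(neg & ~np.isnan(vals)):
            row = int(np.flatnonzero(neg & ~np.isnan(vals))[0])
            raise ValidationError(f"negative {col} ({vals[row]}) at row {row}")
    asset_cols = [c for c in df.columns if c.startswith(ASSET_PREFIX)]
    if asset_cols and df[asset_cols].isna().to_numpy().any():
        raise ValidationError("missing asset indicator values are not allowed")


def load_schema(path: str | Path) -> dict:
    """Read a column-mapping configuration (YAML key-value text)."""
    with open(path) as fh:
        schema = yaml.safe_load(fh)
    if not isinstance(schema, dict):
        raise SchemaError(f"schema file {path} must be a mapping")
    return schema


def load_exit_interviews(
    path: str | Path,
    schema: Mapping[str, object] | str | Path | None = None,
    *,
    currency_rate_tzs_per_usd: float = 1600.0,
    missing_sentinels: Sequence[str] = ("",),
) -> Dataset:
    """Read an exit-interview CSV into a validated :class:`Dataset`.

    Parameters
    ----------
    path
        CSV file: UTF-8, comma-separated, single header row.
    schema
        Optional column mapping ``{canonical_name: source_column}``; the
        key ``assets`` may map to a list of source columns (their order
        defines the indicator vector).  A path to a YAML file with the
        same structure is also accepted.  When omitted, canonical names
        are expected verbatim and every ``asset_*`` column is an
        indicator.
    missing_sentinels
        Cell values (besides empty) to treat as missing in numeric fields.

    Raises
    ------
    SchemaError
        if a mapped column is absent from the header.
    ValidationError
        for negative times/costs or unknown enum labels (cites the row).
    """
    path = Path(path)
    if schema is not None and not isinstance(schema, Mapping):
        schema = load_schema(schema)
    na_values = [s for s in missing_sentinels if s != ""]
    raw = pd.read_csv(path, dtype=str, keep_default_na=False,
                      na_values=na_values, skipinitialspace=True)
    raw = raw.replace({"": np.nan})

    mapping: dict[str, str] = {c: c for c in CANONICAL_COLUMNS}
    asset_sources: list[str] | None = None
    if schema:
        for canon, src in schema.items():
            if canon == "assets":
                asset_sources = list(src)  # type: ignore[arg-type]
            elif canon in CANONICAL_COLUMNS:
                mapping[canon] = str(src)
            else:
                raise SchemaError(f"schema maps unknown canonical column {canon!r}")

    for canon, src in mapping.items():
        if src not in raw.columns:
            raise SchemaError(f"mapped column {src!r} (for {canon!r}) not in header")

    if asset_sources is None:
        asset_sources = [c for c in raw.columns if c.startswith(ASSET_PREFIX)]
        asset_names = [c[len(ASSET_PREFIX):] for c in asset_sources]
    else:
        for src in asset_sources:
            if src not in raw.columns:
                raise SchemaError(f"mapped asset column {src!r} not in header")
        asset_names = [_normalise_label(c) for c in asset_sources]

    used = set(mapping.values()) | set(asset_sources)
    extra = [c for c in raw.columns if c not in used]
    if extra:
        logger.warning("ignoring %d unmapped column(s): %s", len(extra), extra)

    out = pd.DataFrame(index=raw.index)
    for col in ID_COLUMNS:
        out[col] = raw[mapping[col]].astype(str)
    for col, levels in ENUM_COLUMNS.items():
        decoded = raw[mapping[col]].map(_normalise_label)
        decoded = decoded.replace(_LABEL_SYNONYMS.get(col, {}))
        bad = ~decoded.isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"unknown {col} label {raw[mapping[col]].iloc[row]!r} at row {row}"
            )
        out[col] = decoded
    for col in OUTCOME_COLUMNS:
        try:
            vals = pd.to_numeric(raw[mapping[col]], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric value in column {col}: {exc}") from exc
        out[col] = vals.astype(float)
    ins = raw[mapping["insurance"]].map(
        lambda v: np.nan if pd.isna(v) else _normalise_label(v))
    bad_ins = ~ins.isin(_TRUE_SET | _FALSE_SET) & ins.notna()
    if bad_ins.any():
        row = int(np.flatnonzero(bad_ins.to_numpy())[0])
        raise ValidationError(f"unparseable insurance value at row {row}")
    out["insurance"] = ins.isin(_TRUE_SET)
    for src, name in zip(asset_sources, asset_names):
        out[ASSET_PREFIX + name] = pd.to_numeric(raw[src], errors="raise").astype(float)

    return Dataset(df=out.reset_index(drop=True), asset_names=asset_names,
                   currency_rate_tzs_per_usd=currency_rate_tzs_per_usd)


def write_canonical(dataset: Dataset, path: str | Path) -> None:
    """Write the validated canonical CSV (fixed column names, blank = missing)."""
    cols = list(CANONICAL_COLUMNS) + dataset.asset_columns
    dataset.df[cols].to_csv(path, index=False)


def complete_case(dataset: Dataset, variable: str) -> Dataset:
    """Subset to records where the named outcome is nonmissing.

    Each outcome is analysed on its own nonmissing subset, so per-outcome
    sample sizes differ.  Idempotent; never grows the dataset.
    """
    if variable not in OUTCOME_COLUMNS:
        raise ValueError(
            f"{variable!r} is not a recognised outcome; expected one of {OUTCOME_COLUMNS}"
        )
    mask = dataset.df[variable].notna().to_numpy()
    if not mask.any():
        raise ValidationError(f"no observations for variable {variable!r}")
    kept = dataset.subset(mask)
    logger.info("complete_case(%s): %d of %d records retained",
                variable, len(kept), len(dataset))
    return kept
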