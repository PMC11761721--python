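"""Survey data model, delimited-text I/O, validation and descriptive statistics.

A :class:`SurveyDataset` holds one row per respondent: a stratum label (the
departmental area of discharge), 1–5 Likert responses to the experience items
and the overall-satisfaction item, and optional socio-demographics.  Any field
may be missing — respondents are free to stop the questionnaire at any point —
so every downstream analysis states explicitly which variables it completes on
(:func:`listwise_complete`).

:func:`summarize_by_stratum` produces the descriptive table: per-stratum counts
and column percentages for categorical demographics (Pearson chi-square
comparison when exactly two strata are present), per-stratum means for age and
length of stay (Welch two-sample t-test), and the per-stratum mean, SEM and n
of overall satisfaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codebook import SATISFACTION_ITEM, ItemCodebook, default_codebook
from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

RESERVED_COLUMNS = ("respondent_id", "stratum")

CATEGORICAL_DEMOGRAPHICS: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "age_group": ("<18", "18-44", "45-64", ">=65"),
    "education": ("low", "medium", "high"),
    "perceived_health": ("bad", "sufficient", "good", "very_good", "excellent"),
    "chronic": ("no", "yes", "unknown"),
    "admission": ("urgent", "planned"),
}
CONTINUOUS_DEMOGRAPHICS = ("age", "length_of_stay")
DEMOGRAPHIC_COLUMNS = tuple(CATEGORICAL_DEMOGRAPHICS) + CONTINUOUS_DEMOGRAPHICS


@dataclass(frozen=True)
class RespondentRecord:
    """One respondent's responses; ``None`` marks a skipped question."""

    respondent_id: str
    stratum: str
    item_responses: Mapping[str, int | None]
    satisfaction: int | None
    demographics: Mapping[str, object] = field(default_factory=dict)


@dataclass
class SurveyDataset:
    """Validated respondent-level survey table.

    ``frame`` columns: ``respondent_id``, ``stratum``, one nullable-integer
    column per codebook item, and any recognized demographic columns.
    """

    codebook: ItemCodebook
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        for col in RESERVED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"dataset frame lacks required column {col!r}")
        if df["respondent_id"].duplicated().any():
            dup = df.loc[df["respondent_id"].duplicated(), "respondent_id"].iloc[0]
            raise ValidationError(f"duplicate respondent_id {dup!r}")
        known = set(self.codebook.item_ids) | set(DEMOGRAPHIC_COLUMNS) | set(RESERVED_COLUMNS)
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            raise SchemaError(f"columns not in codebook or demographic schema: {unknown}")
        for item in self.item_columns:
            col = df[item]
            if str(col.dtype) != "Int64":
                self.frame[item] = col = col.astype("Int64")
            bad = col.dropna()
            if len(bad) and ((bad < 1) | (bad > 5)).any():
                raise ValidationError(f"item {item!r} has values outside 1..5")

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def item_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c in self.codebook.item_ids]

    @property
    def strata(self) -> list[str]:
        seen: list[str] = []
        for s in self.frame["stratum"]:
            if s not in seen:
                seen.append(s)
        return seen

    def subset(self, mask) -> "SurveyDataset":
        return SurveyDataset(self.codebook, self.frame.loc[mask].reset_index(drop=True))

    def for_stratum(self, label: str) -> "SurveyDataset":
        return self.subset(self.frame["stratum"] == label)

    @property
    def records(self) -> list[RespondentRecord]:
        items = self.item_columns
        demo = [c for c in self.frame.columns if c in DEMOGRAPHIC_COLUMNS]
        out = []
        for _, row in self.frame.iterrows():
            responses = {
                i: (int(row[i]) if pd.notna(row[i]) else None) for i in items if i != SATISFACTION_ITEM
            }
            sat = row.get(SATISFACTION_ITEM)
            out.append(
                RespondentRecord(
                    respondent_id=str(row["respondent_id"]),
                    stratum=str(row["stratum"]),
                    item_responses=responses,
                    satisfaction=int(sat) if SATISFACTION_ITEM in items and pd.notna(sat) else None,
                    demographics={c: row[c] for c in demo if pd.notna(row[c])},
                )
            )
        return out

    @classmethod
    def from_records(
        cls, records: Iterable[RespondentRecord], codebook: ItemCodebook | None = None
    ) -> "SurveyDataset":
        codebook = codebook or default_codebook()
        rows = []
        for r in records:
            row: dict[str, object] = {"respondent_id": r.respondent_id, "stratum": r.stratum}
            row.update(r.item_responses)
            row[SATISFACTION_ITEM] = r.satisfaction
            row.update(r.demographics)
            rows.append(row)
        df = pd.DataFrame(rows)
        for item in codebook.item_ids:
            if item in df.columns:
                df[item] = df[item].astype("Int64")
        return cls(codebook, df)

    # -- I/O ---------------------------------------------------------------
    def write_csv(self, path: str | Path, delimiter: str = ",") -> None:
        self.frame.to_csv(path, index=False, sep=delimiter)


def _parse_item_cell(text: str, item: str, row_num: int, codebook: ItemCodebook) -> object:
    text = text.strip()
    if text == "":
        return pd.NA
    try:
        value = int(text)
    except ValueError:
        try:
            return codebook.decode_label(item, text)
        except ValidationError:
            raise ValidationError(
                f"row {row_num}, column {item!r}: unrecognized response {text!r}"
            ) from None
    if not 1 <= value <= 5:
        raise ValidationError(f"row {row_num}, column {item!r}: value {value} outside 1..5")
    return value


def load_survey(
    path: str | Path,
    codebook: ItemCodebook | None = None,
    delimiter: str = ",",
    stratum_column: str = "stratum",
) -> SurveyDataset:
    """Read a delimited survey file into a validated :class:`SurveyDataset`.

    Ordinal cells may contain integers 1–5, a recognized scale label (e.g.
    ``excellent`` → 5), or be empty (missing).  Columns that are neither
    reserved, demographic, nor codebook items raise :class:`SchemaError`;
    out-of-range values raise :class:`ValidationError` naming row and column.
    """
    codebook = codebook or default_codebook()
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    raw = raw.rename(columns={stratum_column: "stratum"})
    if "stratum" not in raw.columns:
        raise SchemaError(f"no stratum column {stratum_column!r} in {path}")
    if "respondent_id" not in raw.columns:
        raw.insert(0, "respondent_id", [f"r{i:06d}" for i in range(len(raw))])

    known = set(codebook.item_ids) | set(DEMOGRAPHIC_COLUMNS) | set(RESERVED_COLUMNS)
    unknown = [c for c in raw.columns if c not in known]
    if unknown:
        raise SchemaError(f"unknown columns {unknown}; expected codebook items or demographics")

    out: dict[str, object] = {
        "respondent_id": raw["respondent_id"].astype(str),
        "stratum": raw["stratum"].astype(str),
    }
    for item in (c for c in raw.columns if c in codebook.item_ids):
        parsed = [
            _parse_item_cell(v, item, i + 2, codebook)  # +2: header is line 1
            for i, v in enumerate(raw[item])
        ]
        out[item] = pd.array(parsed, dtype="Int64")
    for col in (c for c in raw.columns if c in CATEGORICAL_DEMOGRAPHICS):
        allowed = CATEGORICAL_DEMOGRAPHICS[col]
        vals = raw[col].str.strip().replace("", pd.NA)
        bad = vals.dropna()[~vals.dropna().isin(allowed)]
        if len(bad):
            raise ValidationError(
                f"column {col!r}: unrecognized level {bad.iloc[0]!r} (allowed: {allowed})"
            )
        out[col] = vals
    for col in (c for c in raw.columns if c in CONTINUOUS_DEMOGRAPHICS):
        vals = pd.to_numeric(raw[col].replace("", np.nan), errors="raise")
        if col == "length_of_stay" and (vals.dropna() < 0).any():
            raise ValidationError("length_of_stay must be >= 0")
        out[col] = vals

    return SurveyDataset(codebook, pd.DataFrame(out))


def listwise_complete(ds: SurveyDataset, variables: Sequence[str]) -> SurveyDataset:
    """Keep only respondents with no missing value among ``variables`` (order preserved)."""
    unknown = [v for v in variables if v not in ds.codebook.item_ids]
    if unknown:
        raise SchemaError(f"variables not in codebook: {unknown}")
    present = [v for v in variables if v in ds.frame.columns]
    if len(present) < len(variables):
        # a codebook item absent from the frame is missing for everyone
        return ds.subset(np.zeros(ds.n, dtype=bool))
    mask = ds.frame[list(present)].notna().all(axis=1)
    return ds.subset(mask)


# -- descriptive statistics ------------------------------------------------


@dataclass
class DescriptiveTable:
    """Per-stratum descriptives with two-stratum comparison tests.

    ``rows`` has one row per (variable, category) for categoricals and one row
    per continuous variable, with per-stratum ``count_*`` / ``percent_*`` or
    ``mean_*`` columns and full-precision plus 3-decimal p-values.
    """

    rows: pd.DataFrame
    satisfaction_summary: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.6g")


def percents_from_counts(counts: Mapping[str, int] | Sequence[int]) -> np.ndarray:
    """Column percentages from category counts (denominator = their sum)."""
    values = np.asarray(list(counts.values()) if isinstance(counts, Mapping) else counts, float)
    total = values.sum()
    if total <= 0:
        raise ValidationError("counts sum to zero")
    return 100.0 * values / total


def chi_square_pvalue(table) -> tuple[float, float]:
    """Pearson chi-square statistic and p-value for an r x c count table."""
    table = np.asarray(table, float)
    if table.sum() == 0:
        raise ValidationError("empty contingency table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def welch_pvalue(a, b) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.pvalue)


def summarize_by_stratum(ds: SurveyDataset) -> DescriptiveTable:
    """Descriptive table per stratum with two-stratum comparison tests."""
    strata = ds.strata
    if not strata:
        raise ValidationError("dataset has no records")
    two = len(strata) == 2
    frames = {s: ds.frame[ds.frame["stratum"] == s] for s in strata}

    rows: list[dict[str, object]] = []
    for var, levels in CATEGORICAL_DEMOGRAPHICS.items():
        if var not in ds.frame.columns:
            continue
        counts = {s: frames[s][var].value_counts() for s in strata}
        observed = [lv for lv in levels if any(counts[s].get(lv, 0) for s in strata)]
        if not observed:
            logger.warning("variable %r has no nonmissing values; skipped", var)
            continue
        p = np.nan
        if two:
            table = np.array([[counts[s].get(lv, 0) for s in strata] for lv in observed], float)
            if table.shape[0] >= 2 and (table.sum(axis=0) > 0).all():
                _, p = chi_square_pvalue(table)
        for lv in observed:
            row: dict[str, object] = {"variable": var, "category": lv}
            for s in strata:
                n_lv = int(counts[s].get(lv, 0))
                denom = int(sum(counts[s].get(l, 0) for l in observed))
                row[f"count_{s}"] = n_lv
                row[f"percent_{s}"] = 100.0 * n_lv / denom if denom else np.nan
            row["p_value"] = p
            row["p_value_3dp"] = round(p, 3) if np.isfinite(p) else np.nan
            rows.append(row)

    for var in CONTINUOUS_DEMOGRAPHICS:
        if var not in ds.frame.columns:
            continue
        samples = {s: frames[s][var].dropna().to_numpy(float) for s in strata}
        if all(len(v) == 0 for v in samples.values()):
            logger.warning("variable %r has no nonmissing values; skipped", var)
            continue
        p = welch_pvalue(*samples.values()) if two and all(len(v) > 1 for v in samples.values()) else np.nan
        row = {"variable": var, "category": "mean"}
        for s in strata:
            row[f"mean_{s}"] = float(samples[s].mean()) if len(samples[s]) else np.nan
            row[f"count_{s}"] = len(samples[s])
        row["p_value"] = p
        row["p_value_3dp"] = round(p, 3) if np.isfinite(p) else np.nan
        rows.append(row)

    sat_rows = []
    sat_samples = {}
    for s in strata:
        if SATISFACTION_ITEM in frames[s].columns:
            y = frames[s][SATISFACTION_ITEM].dropna().to_numpy(float)
        else:
            y = np.array([])
        sat_samples[s] = y
        sat_rows.append(
            {
                "stratum": s,
                "mean": float(y.mean()) if len(y) else np.nan,
                "sem": float(y.std(ddof=1) / np.sqrt(len(y))) if len(y) > 1 else np.nan,
                "n": len(y),
            }
        )
    sat = pd.DataFrame(sat_rows)
    if two and all(len(v) > 1 for v in sat_samples.values()):
        sat["p_value"] = welch_pvalue(*sat_samples.values())
    else:
        sat["p_value"] = np.nan

    return DescriptiveTable(rows=pd.DataFrame(rows), satisfaction_summary=sat)
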