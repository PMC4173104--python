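"""Patient-level registry containers and I/O.

A registry holds one row per patient: a binary outcome Y (e.g. 30-day
death), the treating center C, and a fixed-length vector of numeric baseline
covariates L.  All model-fitting modules consume :class:`Registry`; aggregated
stratum tables (covariate pattern x center x risk/count) can be expanded to
patient level for exact small examples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaSpec",
    "Registry",
    "StratumTable",
    "FilterReport",
    "read_registry",
    "write_registry",
    "registry_from_frame",
    "complete_case_filter",
    "expand_stratum_table",
]


class SchemaError(ValueError):
    """A required column is missing or mis-declared."""


class ValidationError(ValueError):
    """Row-level data violates the registry contract."""


@dataclass
class SchemaSpec:
    """Column-role mapping for a delimited registry file.

    Parameters
    ----------
    outcome : str
        Column holding the binary outcome (values 0/1).
    center : str
        Column holding the center label (treated as an opaque string).
    covariates : list of str
        Covariate columns, in the order they enter the design matrix.
    categorical : dict, optional
        Map ``column -> reference level`` for covariates to dummy-encode.
        If the reference level is ``None`` the most frequent level is used.
    missing_values : list of str, optional
        Sentinel strings (besides the empty field) marking missing entries.
    """

    outcome: str
    center: str
    covariates: list[str] = field(default_factory=list)
    categorical: dict[str, str | None] = field(default_factory=dict)
    missing_values: list[str] = field(default_factory=list)

    @classmethod
    def from_json(cls, path) -> "SchemaSpec":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            outcome=raw["outcome"],
            center=raw["center"],
            covariates=list(raw.get("covariates", [])),
            categorical=dict(raw.get("categorical", {})),
            missing_values=list(raw.get("missing_values", [])),
        )


@dataclass
class Registry:
    """Patient-level multi-center registry.

    ``data`` has one row per patient with an integer outcome column, a string
    center column and numeric covariate columns.  Centers are indexed in
    first-appearance order; ``center_codes`` maps each row to 0..m-1.
    """

    data: pd.DataFrame
    outcome_col: str = "outcome"
    center_col: str = "center"
    covariate_cols: list[str] = field(default_factory=list)

    def __post_init__(self):
        ok = self.data[self.outcome_col].isin([0, 1])
        if not bool(ok.all()):
            bad = self.data.index[~ok][0]
            raise ValidationError(f"outcome outside {{0,1}} at row {bad}")
        # first-appearance order defines the center index
        self.centers: list[str] = list(
            dict.fromkeys(self.data[self.center_col].astype(str))
        )
        code = {c: i for i, c in enumerate(self.centers)}
        self.center_codes: np.ndarray = (
            self.data[self.center_col].astype(str).map(code).to_numpy(dtype=np.int64)
        )

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def m(self) -> int:
        return len(self.centers)

    @property
    def center_sizes(self) -> np.ndarray:
        """Per-center patient counts n_c, in center-index order."""
        return np.bincount(self.center_codes, minlength=self.m)

    @property
    def y(self) -> np.ndarray:
        return self.data[self.outcome_col].to_numpy(dtype=np.float64)

    @property
    def X(self) -> np.ndarray:
        """n x p covariate matrix (may have zero columns)."""
        if not self.covariate_cols:
            return np.empty((self.n, 0))
        return self.data[self.covariate_cols].to_numpy(dtype=np.float64)

    def observed_risks(self) -> np.ndarray:
        """Per-center observed event proportion, in center-index order."""
        return np.bincount(
            self.center_codes, weights=self.y, minlength=self.m
        ) / np.maximum(self.center_sizes, 1)

    def with_covariates(self, cols: list[str]) -> "Registry":
        """Shallow view of the same records with a restricted covariate set."""
        missing = set(cols) - set(self.data.columns)
        if missing:
            raise KeyError(f"unknown covariate columns {sorted(missing)}")
        return Registry(self.data, self.outcome_col, self.center_col, list(cols))

    def validate(self) -> None:
        if self.m < 2:
            warnings.warn("registry has a single center; comparative "
                          "operations require m >= 2")
        assert int(self.center_sizes.sum()) == self.n


@dataclass
class StratumTable:
    """Aggregated covariate-pattern x center table.

    ``data`` is long format with the pattern columns, a ``center`` column and
    either a ``risk`` column (probability in [0,1]) or an ``events`` column
    (nonnegative integer), plus a ``count`` column of patient totals.
    """

    data: pd.DataFrame
    pattern_cols: list[str]
    center_col: str = "center"
    count_col: str = "count"
    risk_col: str | None = "risk"
    events_col: str | None = None

    def __post_init__(self):
        df = self.data
        keys = df[self.pattern_cols + [self.center_col]]
        if keys.duplicated().any():
            raise ValidationError("duplicate (pattern, center) rows in stratum table")
        if self.risk_col and self.risk_col in df:
            r = df[self.risk_col]
            if ((r < 0) | (r > 1)).any():
                raise ValidationError("stratum risk outside [0,1]")
        if self.events_col and self.events_col in df:
            if (df[self.events_col] > df[self.count_col]).any():
                raise ValidationError("event_count exceeds patient_count")

    @property
    def centers(self) -> list[str]:
        return list(dict.fromkeys(self.data[self.center_col].astype(str)))


@dataclass
class FilterReport:
    """Outcome of complete-case filtering."""

    n_input: int
    n_kept: int
    dropped_per_column: dict[str, int]
    dropped_missing_outcome: int
    warnings: list[str]

    @property
    def n_dropped(self) -> int:
        return self.n_input - self.n_kept


def _encode_categoricals(df: pd.DataFrame, schema: SchemaSpec) -> tuple[pd.DataFrame, list[str]]:
    """Reference-cell dummy coding; reference = declared or most frequent level."""
    cov_cols: list[str] = []
    for col in schema.covariates:
        if col in schema.categorical:
            ref = schema.categorical[col]
            levels = df[col].astype(str)
            if ref is None:
                ref = levels.mode().iloc[0]
            other = [lv for lv in dict.fromkeys(levels) if lv != str(ref)]
            for lv in other:
                name = f"{col}__{lv}"
                df[name] = (levels == lv).astype(float)
                cov_cols.append(name)
        else:
            df[col] = pd.to_numeric(df[col], errors="coerce")
            cov_cols.append(col)
    return df, cov_cols


def registry_from_frame(
    df: pd.DataFrame,
    outcome: str = "outcome",
    center: str = "center",
    covariates: list[str] | None = None,
) -> Registry:
    """Build a Registry from an in-memory frame of already-numeric columns."""
    covariates = list(covariates or [])
    out = df[[outcome, center, *covariates]].copy()
    vals = pd.to_numeric(out[outcome], errors="coerce")
    bad = out.index[~vals.isin([0, 1])]
    if len(bad):
        raise ValidationError(
            f"outcome value {out.loc[bad[0], outcome]!r} outside {{0,1}} at row {bad[0]}"
        )
    out[outcome] = vals.astype(np.int8)
    out[center] = out[center].astype(str)
    return Registry(out.reset_index(drop=True), outcome, center, covariates)


def read_registry(path, schema: SchemaSpec | str) -> Registry:
    """Read a delimited patient-level registry file.

    Centers are indexed in first-appearance order; categorical covariates are
    dummy-encoded against the declared (or most frequent) reference level.
    Rows with missing entries are kept -- run :func:`complete_case_filter`
    to drop them.
    """
    if isinstance(schema, (str,)) or hasattr(schema, "__fspath__"):
        schema = SchemaSpec.from_json(schema)
    na = [""] + list(schema.missing_values)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=na)
    for col in [schema.outcome, schema.center, *schema.covariates]:
        if col not in df.columns:
            raise SchemaError(f"column {col!r} declared in schema but absent from file")
    vals = pd.to_numeric(df[schema.outcome], errors="coerce")
    bad = df.index[vals.notna() & ~vals.isin([0, 1])]
    if len(bad):
        raise ValidationError(
            f"outcome value {df.loc[bad[0], schema.outcome]!r} outside {{0,1}} "
            f"at row {bad[0]}"
        )
    df[schema.outcome] = vals.astype("Int64")
    df, cov_cols = _encode_categoricals(df, schema)
    if df[schema.outcome].isna().any() or df[cov_cols].isna().any().any():
        # keep raw missing values; downstream filtering handles them
        out = df[[schema.outcome, schema.center, *cov_cols]].copy()
        out[schema.center] = out[schema.center].astype(str)
        reg = Registry.__new__(Registry)
        reg.data = out.reset_index(drop=True)
        reg.outcome_col = schema.outcome
        reg.center_col = schema.center
        reg.covariate_cols = cov_cols
        reg.centers = list(dict.fromkeys(out[schema.center]))
        code = {c: i for i, c in enumerate(reg.centers)}
        reg.center_codes = out[schema.center].map(code).to_numpy(dtype=np.int64)
        return reg
    out = df[[schema.outcome, schema.center, *cov_cols]].copy()
    out[schema.outcome] = out[schema.outcome].astype(np.int8)
    out[schema.center] = out[schema.center].astype(str)
    for c in cov_cols:
        out[c] = out[c].astype(float)
    return Registry(out.reset_index(drop=True), schema.outcome, schema.center, cov_cols)


def write_registry(registry: Registry, path) -> None:
    """Write a registry to CSV (lossless for finite numeric values)."""
    registry.data.to_csv(path, index=False)


def complete_case_filter(registry: Registry) -> tuple[Registry, FilterReport]:
    """Drop records with any missing model covariate (or missing outcome).

    Complete-case analysis is valid when covariate missingness depends on the
    covariates themselves but not residually on the outcome; the report
    separates outcome-missing drops from covariate-missing drops.
    Idempotent: filtering a complete registry returns it unchanged.
    """
    df = registry.data
    n_in = len(df)
    miss_out = df[registry.outcome_col].isna()
    dropped_per_col = {
        c: int((df[c].isna() & ~miss_out).sum()) for c in registry.covariate_cols
    }
    keep = ~miss_out
    for c in registry.covariate_cols:
        keep &= df[c].notna()
    kept = df[keep].copy()
    msgs: list[str] = []
    lost_centers = set(df[registry.center_col].astype(str)) - set(
        kept[registry.center_col].astype(str)
    )
    for c in sorted(lost_centers):
        msg = f"center {c!r} lost all records in complete-case filtering"
        msgs.append(msg)
        warnings.warn(msg)
    if n_in and len(kept) < 0.5 * n_in:
        msg = f"complete-case filtering removed {n_in - len(kept)}/{n_in} records (>50%)"
        msgs.append(msg)
        warnings.warn(msg)
    kept[registry.outcome_col] = kept[registry.outcome_col].astype(np.int8)
    for c in registry.covariate_cols:
        kept[c] = kept[c].astype(float)
    out = Registry(
        kept.reset_index(drop=True),
        registry.outcome_col,
        registry.center_col,
        list(registry.covariate_cols),
    )
    report = FilterReport(
        n_input=n_in,
        n_kept=out.n,
        dropped_per_column=dropped_per_col,
        dropped_missing_outcome=int(miss_out.sum()),
        warnings=msgs,
    )
    return out, report


def expand_stratum_table(table: StratumTable, mode: str = "expected_counts") -> Registry:
    """Expand an aggregated stratum table into a patient-level registry.

    In ``expected_counts`` mode each (pattern, center) row contributes
    ``risk * count`` events, which must be integral (exact small examples);
    in ``integer`` mode the ``events`` column is used directly.  Records are
    emitted sorted by center-index order, pattern row order, outcome
    descending, so the expansion is deterministic.
    """
    if mode not in ("expected_counts", "integer"):
        raise ValueError(f"unknown mode {mode!r}")
    df = table.data
    rows = []
    for _, row in df.iterrows():
        count = int(row[table.count_col])
        if count == 0:
            continue
        if mode == "expected_counts":
            expected = float(row[table.risk_col]) * count
            events = round(expected)
            if abs(expected - events) > 1e-9:
                raise ValueError(
                    f"expected events {expected} not integral for pattern "
                    f"{tuple(row[c] for c in table.pattern_cols)}, center "
                    f"{row[table.center_col]}; use integer mode with an events column"
                )
            events = int(events)
        else:
            events = int(row[table.events_col])
            if events > count:
                raise ValidationError("events exceed count")
        pat = {c: row[c] for c in table.pattern_cols}
        rows.append((str(row[table.center_col]), pat, events, count))

    centers_order = {c: i for i, c in enumerate(table.centers)}
    rows.sort(key=lambda r: centers_order[r[0]])
    recs = []
    for center, pat, events, count in rows:
        for i in range(count):
            recs.append({"outcome": 1 if i < events else 0, "center": center, **pat})
    out = pd.DataFrame(recs)
    pattern_numeric = []
    for c in table.pattern_cols:
        out[c], uniques = pd.factorize(out[c])  # ordinal code per pattern level
        if pd.api.types.is_numeric_dtype(df[c]):
            out[c] = out[c].map(dict(enumerate(uniques)))
        pattern_numeric.append(c)
    return registry_from_frame(out, covariates=pattern_numeric)
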