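"""Respondent-level survey tables: loading, validation, recoding.

The central object is :class:`SurveyTable`, a thin wrapper around a pandas
DataFrame with canonical column names (``h`` for the binary outcome,
``weight``, ``cluster``, ``stratum``, ``wealth_score``, plus named covariate
columns).  Arbitrary CSV exports are mapped onto this layout through a YAML
configuration whose ``columns:`` section binds file columns to semantic roles
and whose ``covariates:`` section declares each covariate's kind, levels and
reference category.

The binary outcome is a composite knowledge indicator built from five ternary
interview items (two prevention methods affirmed, a healthy-looking person can
be infected, two misconceptions rejected); respondents who never heard of the
disease are coded 0 so the indicator is defined for the full sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CovariateSpec",
    "SurveyTable",
    "build_knowledge_indicator",
    "derive_outcome",
    "complete_case_filter",
    "encode_design",
    "load_survey",
    "write_survey",
]

_TERNARY = {"yes", "no", "dont_know"}
_TERNARY_ALIASES = {
    "yes": "yes",
    "no": "no",
    "dont_know": "dont_know",
    "don't know": "dont_know",
    "dont know": "dont_know",
    "dk": "dont_know",
}


def _normalize_label(value: object) -> str:
    return str(value).strip().lower()


def _normalize_ternary(value: object, *, record: object = None, field_name: str = "") -> str:
    label = _normalize_label(value)
    if label not in _TERNARY_ALIASES:
        where = f" (record {record!r}, field {field_name!r})" if field_name else ""
        raise ValueError(f"malformed response label {value!r}{where}; expected yes/no/dont_know")
    return _TERNARY_ALIASES[label]


@dataclass(frozen=True)
class CovariateSpec:
    """Declaration of one model covariate.

    Parameters
    ----------
    name : column name in the canonical table.
    kind : "binary", "categorical" or "continuous".
    levels : ordered category labels (binary/categorical only).
    reference : reference level, omitted from the design matrix.
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ()
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"binary", "categorical", "continuous"}:
            raise ValueError(f"unknown covariate kind {self.kind!r} for {self.name!r}")
        if self.kind == "continuous":
            return
        levels = tuple(_normalize_label(x) for x in self.levels)
        if len(set(levels)) != len(levels) or not levels:
            raise ValueError(f"levels of {self.name!r} must be non-empty and unique")
        ref = _normalize_label(self.reference if self.reference is not None else levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not among levels of {self.name!r}")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "reference", ref)

    @property
    def design_levels(self) -> tuple[str, ...]:
        """Non-reference levels, in declared order."""
        return tuple(x for x in self.levels if x != self.reference)

    def column_names(self) -> list[str]:
        if self.kind == "continuous":
            return [self.name]
        return [f"{self.name}={lvl}" for lvl in self.design_levels]


@dataclass
class SurveyTable:
    """Canonical respondent-level table plus covariate declarations."""

    data: pd.DataFrame
    covariates: list[CovariateSpec] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        if "weight" in df.columns:
            w = np.asarray(df["weight"], dtype=float)
            bad = ~np.isnan(w) & ~((w > 0) & np.isfinite(w))  # NaN = missing, filtered later
            if bad.any():
                raise ValueError("every observed sampling weight must be positive and finite")
        if "cluster" in df.columns and df["cluster"].nunique() < 2:
            raise ValueError("at least 2 distinct cluster identifiers are required")
        if "h" in df.columns:
            vals = set(pd.unique(df["h"].dropna()))
            if not vals <= {0, 1}:
                raise ValueError(f"derived outcome must be binary, found {sorted(vals)!r}")

    @property
    def n(self) -> int:
        return len(self.data)

    def with_data(self, data: pd.DataFrame) -> "SurveyTable":
        return replace(self, data=data)


def build_knowledge_indicator(items: Sequence[object], heard: object, *, record: object = None) -> int:
    """Composite knowledge indicator from five ternary items.

    ``h = 1`` iff items 1-3 are "yes" and items 4-5 (the misconceptions) are
    "no".  "dont_know" counts as an incorrect answer.  Respondents who never
    heard of the disease get ``h = 0`` regardless of the items.
    """
    heard_label = _normalize_label(heard)
    if heard_label in {"no", "0", "false"}:
        return 0
    if heard_label not in {"yes", "1", "true"}:
        raise ValueError(f"malformed response label {heard!r} (record {record!r}, field 'heard')")
    if len(items) != 5:
        raise ValueError(f"expected 5 knowledge items, got {len(items)} (record {record!r})")
    coded = [
        _normalize_ternary(v, record=record, field_name=f"item{i + 1}")
        for i, v in enumerate(items)
    ]
    correct = all(v == "yes" for v in coded[:3]) and all(v == "no" for v in coded[3:])
    return int(correct)


def derive_outcome(df: pd.DataFrame, item_columns: Sequence[str], heard_column: str) -> pd.Series:
    """Vectorised :func:`build_knowledge_indicator` over a DataFrame."""
    h = np.empty(len(df), dtype=int)
    for pos, (idx, row) in enumerate(df.iterrows()):
        h[pos] = build_knowledge_indicator(
            [row[c] for c in item_columns], row[heard_column], record=idx
        )
    return pd.Series(h, index=df.index, name="h")


def complete_case_filter(table: SurveyTable, required: Iterable[str]) -> tuple[SurveyTable, int]:
    """Listwise deletion over ``required`` columns.

    Returns the filtered table (row order preserved) and the number of rows
    dropped.  Raises if no row survives.
    """
    required = list(required)
    missing_cols = [c for c in required if c not in table.data.columns]
    if missing_cols:
        raise KeyError(f"required columns not in table: {missing_cols}")
    sub = table.data[required]
    keep = ~(sub.isna() | sub.apply(lambda s: s.astype(str).str.strip() == "" if s.dtype == object else False)).any(axis=1)
    dropped = int((~keep).sum())
    if dropped == len(table.data):
        raise ValueError("complete-case filter dropped every row")
    filtered = table.data.loc[keep].copy()
    meta = dict(table.metadata)
    meta["complete_case"] = {
        "rows_before": len(table.data),
        "rows_after": len(filtered),
        "dropped": dropped,
        "required": required,
    }
    return SurveyTable(filtered, covariates=table.covariates, metadata=meta), dropped


def encode_design(
    data: pd.DataFrame | SurveyTable, specs: Sequence[CovariateSpec]
) -> tuple[pd.DataFrame, list[str]]:
    """Dummy-code covariates into a design matrix.

    One 0/1 indicator column per non-reference level, continuous columns
    passed through unchanged; column order is deterministic (spec order, then
    declared level order).  An empty spec list yields an intercept-only design
    (zero columns; the intercept is added by the model fitter).
    """
    df = data.data if isinstance(data, SurveyTable) else data
    cols: dict[str, np.ndarray] = {}
    for spec in specs:
        if spec.name not in df.columns:
            raise KeyError(f"covariate column {spec.name!r} not in table")
        if spec.kind == "continuous":
            cols[spec.name] = np.asarray(df[spec.name], dtype=float)
            continue
        observed = df[spec.name].map(_normalize_label)
        unknown = sorted(set(observed) - set(spec.levels))
        if unknown:
            raise ValueError(
                f"unseen category label(s) {unknown!r} in covariate {spec.name!r}; "
                f"declared levels are {list(spec.levels)!r}"
            )
        for lvl in spec.design_levels:
            cols[f"{spec.name}={lvl}"] = (observed == lvl).to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=df.index)
    return design, list(design.columns)


# ---------------------------------------------------------------------------
# CSV + YAML front end


def _covariate_specs_from_config(cfg: Mapping) -> list[CovariateSpec]:
    specs = []
    for item in cfg.get("covariates", []):
        specs.append(
            CovariateSpec(
                name=item["name"],
                kind=item["kind"],
                levels=tuple(item.get("levels", ())),
                reference=item.get("reference"),
            )
        )
    return specs


def load_survey(csv_path: str | Path, config: str | Path | Mapping) -> SurveyTable:
    """Load a respondent CSV under a column-mapping configuration.

    The configuration's ``columns:`` section maps semantic roles
    (``weight``, ``cluster``, ``stratum``, ``wealth_score``, ``heard``,
    ``items`` — a list of five column names — and optionally ``outcome`` when
    the composite indicator is precomputed) to file column names.
    """
    if not isinstance(config, Mapping):
        config = yaml.safe_load(Path(config).read_text())
    columns: Mapping[str, object] = config.get("columns", {})
    df = pd.read_csv(csv_path)

    out = pd.DataFrame(index=df.index)
    for role in ("weight", "cluster", "stratum", "wealth_score"):
        col = columns.get(role)
        if col is not None:
            if col not in df.columns:
                raise KeyError(f"column {col!r} (role {role!r}) not in {csv_path}")
            out[role] = df[col]
    if "outcome" in columns:
        out["h"] = pd.to_numeric(df[columns["outcome"]])
    elif "items" in columns:
        item_cols = list(columns["items"])
        heard_col = columns["heard"]
        out["h"] = derive_outcome(df, item_cols, heard_col)
    specs = _covariate_specs_from_config(config)
    for spec in specs:
        src = config.get("covariate_columns", {}).get(spec.name, spec.name)
        if src not in df.columns:
            raise KeyError(f"covariate column {src!r} not in {csv_path}")
        out[spec.name] = df[src]
    # carry through any asset indicator columns for the wealth module
    assets = [c for c in df.columns if str(c).startswith("asset_")]
    for c in assets:
        out[c] = df[c]
    metadata = {
        "source": str(csv_path),
        "never_heard_coded_zero": True,
    }
    return SurveyTable(out, covariates=specs, metadata=metadata)


def write_survey(table: SurveyTable, csv_path: str | Path) -> Path:
    """Write the canonical table plus a JSON sidecar with row counts."""
    csv_path = Path(csv_path)
    table.data.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(csv_path.suffix + ".meta.json")
    meta = dict(table.metadata)
    meta.setdefault("rows", len(table.data))
    sidecar.write_text(json.dumps(meta, indent=2, default=str))
    return sidecar
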