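"""Compound catalogs for multi-ingredient herbal prescriptions.

A catalog is a validated table of compounds, each belonging to one declared
ingredient (herb or animal medicine) of the prescription, carrying the six
pharmacology properties used throughout the pipeline: molecular weight (MW,
Da), Moriguchi logP (MLOGP), H-bond donor and acceptor counts (nHDon/nHAcc),
oral bioavailability (OB, percent) and drug-likeness (DL, in [0, 1]).
OB and DL may be missing; missingness is first-class and never encoded as 0.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import InsufficientDataError, SchemaError, ValidationError

__all__ = [
    "Ingredient",
    "CompoundTable",
    "PropertyComparison",
    "load_ingredient_manifest",
    "load_compound_table",
    "save_compound_table",
    "compare_properties",
]

#: canonical column order of a compound table
COLUMNS = ["id", "name", "ingredient", "mw", "mlogp", "nhdon", "nhacc", "ob", "dl", "evidence"]

#: properties that must be numeric when present
NUMERIC_PROPERTIES = ["mw", "mlogp", "nhdon", "nhacc", "ob", "dl"]

#: recognised pharmacological roles of an ingredient
ROLE_CLASSES = {"heat-clearing", "blood-activating", "resuscitation", "animal"}


@dataclass(frozen=True)
class Ingredient:
    """One declared ingredient of the prescription."""

    code: str
    species_name: str
    role_class: str

    def __post_init__(self) -> None:
        if self.role_class not in ROLE_CLASSES:
            raise ValidationError(
                f"ingredient {self.code!r}: unknown role_class {self.role_class!r}; "
                f"expected one of {sorted(ROLE_CLASSES)}"
            )


@dataclass
class CompoundTable:
    """A validated, ordered collection of compounds.

    Thin wrapper around a :class:`pandas.DataFrame` with canonical columns;
    the frame is the in-memory container, this class owns validation and
    provenance.
    """

    df: pd.DataFrame
    provenance: str = "in-memory"
    loaded_at: str = field(default_factory=lambda: _dt.datetime.now().isoformat(timespec="seconds"))

    def __len__(self) -> int:
        return len(self.df)

    def __post_init__(self) -> None:
        self.df = _validate_frame(self.df)

    @property
    def ids(self) -> list[str]:
        return self.df["id"].tolist()

    def counts_by_ingredient(self) -> pd.Series:
        """Number of compounds per ingredient code (descending, then name)."""
        counts = self.df.groupby("ingredient")["id"].count()
        return counts.sort_values(ascending=False).sort_index(kind="stable")

    def summarize(self, by: str = "ingredient") -> pd.DataFrame:
        """Per-group mean/sd/count of each numeric property, missing excluded."""
        agg = self.df.groupby(by)[NUMERIC_PROPERTIES].agg(["count", "mean", "std"])
        agg.columns = [f"{prop}_{stat}" for prop, stat in agg.columns]
        return agg.reset_index()

    def subset(self, ids) -> "CompoundTable":
        keep = self.df[self.df["id"].isin(set(ids))].reset_index(drop=True)
        return CompoundTable(keep, provenance=f"{self.provenance} (subset)")


@dataclass(frozen=True)
class PropertyComparison:
    """Two-sample comparison of one property between two ingredients."""

    property: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    statistic: float
    pvalue: float
    equal_var: bool

    @property
    def mean_difference(self) -> float:
        return self.mean_a - self.mean_b


def load_ingredient_manifest(path) -> dict[str, Ingredient]:
    """Read a YAML prescription manifest into ``{code: Ingredient}``.

    Expected layout: a top-level ``ingredients`` list of mappings with keys
    ``code``, ``species``, ``role_class``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["ingredients"] if isinstance(doc, dict) else doc
    out: dict[str, Ingredient] = {}
    for entry in entries:
        ing = Ingredient(entry["code"], entry.get("species", ""), entry["role_class"])
        if ing.code in out:
            raise ValidationError(f"duplicate ingredient code {ing.code!r} in manifest")
        out[ing.code] = ing
    return out


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("id", "name", "ingredient"):
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing")
    df = df.copy()
    if "evidence" not in df.columns:
        df["evidence"] = False
    df["evidence"] = df["evidence"].fillna(False).astype(bool)
    for col in NUMERIC_PROPERTIES:
        if col not in df.columns:
            df[col] = np.nan
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")]
        # "-" and "" are legitimate missing markers; anything else is malformed
        bad = [i for i in bad if str(df.loc[i, col]).strip() not in {"-", "NA", "nan"}]
        if bad:
            offenders = ", ".join(f"row {i + 1} ({df.loc[i, col]!r})" for i in bad)
            raise ValidationError(f"non-numeric values in column {col!r}: {offenders}")
        df[col] = coerced
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate compound ids: {sorted(set(dup))}")
    if ((df["dl"] < 0) | (df["dl"] > 1)).any():
        raise ValidationError("dl values must lie in [0, 1] when present")
    if (df["ob"] < 0).any():
        raise ValidationError("ob values must be >= 0 when present")
    for col in ("nhdon", "nhacc"):
        vals = df[col].dropna()
        if ((vals < 0) | (vals != vals.round())).any():
            raise ValidationError(f"{col} must be a non-negative integer when present")
    extra = [c for c in df.columns if c not in COLUMNS]
    return df[COLUMNS + extra].reset_index(drop=True)


def load_compound_table(
    path,
    schema: dict[str, str] | None = None,
    ingredients: dict[str, Ingredient] | None = None,
    sep: str = "\t",
) -> CompoundTable:
    """Load and validate a compound table from TSV/CSV.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    schema
        Optional mapping ``{canonical name: column name in file}`` for files
        whose headers differ from the canonical ``id/name/ingredient/mw/...``.
    ingredients
        Optional declared ingredient set; when given, every compound's
        ingredient code must resolve to it.
    """
    raw = pd.read_csv(path, sep=sep, dtype={0: str}, na_values=["-"], keep_default_na=True)
    if schema:
        raw = raw.rename(columns={v: k for k, v in schema.items()})
    raw.columns = [str(c).strip().lower() for c in raw.columns]
    table = CompoundTable(raw, provenance=str(path))
    if ingredients is not None:
        unknown = sorted(set(table.df["ingredient"]) - set(ingredients))
        if unknown:
            raise ValidationError(f"undeclared ingredient codes: {unknown}")
    return table


def save_compound_table(table: CompoundTable, path, sep: str = "\t") -> None:
    """Write a compound table; missing values serialize as empty cells."""
    table.df.to_csv(path, sep=sep, index=False)


def compare_properties(
    table: CompoundTable,
    group_a: str,
    group_b: str,
    property: str,
    equal_var: bool = False,
) -> PropertyComparison:
    """Two-sample t-test of one property between two ingredients.

    Uses the unequal-variance (Welch) form by default; pass
    ``equal_var=True`` for the pooled form. Missing values are excluded.
    Swapping the groups negates the statistic and preserves the p-value.
    """
    if property not in NUMERIC_PROPERTIES:
        raise SchemaError(f"unknown property {property!r}; expected one of {NUMERIC_PROPERTIES}")
    samples = {}
    for code in (group_a, group_b):
        vals = table.df.loc[table.df["ingredient"] == code, property].dropna().to_numpy()
        if len(vals) < 2:
            raise InsufficientDataError(
                f"group {code!r} has {len(vals)} usable values of {property!r}; need >= 2"
            )
        samples[code] = vals
    a, b = samples[group_a], samples[group_b]
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(p):
        # degenerate zero-variance case: identical means are maximally
        # compatible (p = 1), different means with zero spread are not testable
        if np.isclose(a.mean(), b.mean()):
            stat, p = 0.0, 1.0
        else:
            raise InsufficientDataError(
                f"zero within-group variance for {property!r}; t-test undefined"
            )
    return PropertyComparison(
        property=property,
        group_a=group_a,
        group_b=group_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        statistic=stat,
        pvalue=float(min(max(p, np.finfo(float).tiny), 1.0)),
        equal_var=equal_var,
    )
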