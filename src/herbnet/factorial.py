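"""2^k full-factorial analysis of compound-combination bioassays.

The design crosses k compounds at two dose levels each (coded -1/+1). For
every effect term (main effects, first-order i.e. two-way interactions, up
to the single k-way term) the contrast is the signed sum of cell means,

    contrast(T) = sum over cells of  prod(signs in T) * cell mean
    effect(T)   = contrast(T) / 2^(k-1)

so an effect is the change in mean response from low to high level (per
coded unit). With common replicate count n per cell,

    SS(T)     = n * contrast(T)^2 / 2^k            (1 df each)
    SS_within = sum over cells of (n-1) * sd^2     (2^k (n-1) df)

and F(T) = SS(T) / MS_within with p from F(1, 2^k (n-1)). This summary-
statistic reconstruction is algebraically identical to the classical
fixed-effects ANOVA on the raw replicates for any balanced design, which
lets published cell-summary tables (n, mean, sd) be re-analyzed exactly.

The module follows the model/results idiom: build a :class:`FactorialModel`
from cell summaries or long-format replicates, call :meth:`fit`, and read
the ANOVA table, effects and classification off the
:class:`FactorialResults`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IncompleteDesignError, UnbalancedDesignError, ValidationError

__all__ = [
    "FactorialDesign",
    "CellSummary",
    "FactorialModel",
    "FactorialResults",
    "effects_from_means",
    "anova_from_summary",
    "anova_from_replicates",
    "interaction_report",
]


@dataclass(frozen=True)
class FactorialDesign:
    """A full 2^k two-level design over named factors (compounds).

    ``levels`` records the physical doses coded -1/+1 (defaults to the
    coded values themselves); cells enumerate in standard order, last
    factor fastest.
    """

    factors: tuple[str, ...]
    levels: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        if len(self.factors) < 2:
            raise ValidationError("a factorial design needs k >= 2 factors")
        if len(set(self.factors)) != len(self.factors):
            raise ValidationError("factor names must be unique")

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_cells(self) -> int:
        return 2 ** self.k

    def cells(self) -> list[tuple[int, ...]]:
        """All 2^k coded cells in standard order (last factor fastest)."""
        return list(itertools.product((-1, 1), repeat=self.k))

    def terms(self) -> list[tuple[str, ...]]:
        """Effect terms: mains first, then interactions by ascending order."""
        out: list[tuple[str, ...]] = []
        for order in range(1, self.k + 1):
            out.extend(itertools.combinations(self.factors, order))
        return out

    @staticmethod
    def term_label(term: Sequence[str]) -> str:
        return ":".join(term)


@dataclass(frozen=True)
class CellSummary:
    """One cell of the design: coded levels, replicate count, mean, spread."""

    levels: tuple[int, ...]
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(int(v) for v in self.levels))
        if any(v not in (-1, 1) for v in self.levels):
            raise ValidationError(f"cell levels must be coded -1/+1, got {self.levels}")
        if self.n < 2:
            raise ValidationError(f"cell {self.levels}: n = {self.n} < 2, no within-cell variance")
        if self.sd < 0:
            raise ValidationError(f"cell {self.levels}: sd must be >= 0")


def _contrasts(design: FactorialDesign, means: Mapping[tuple[int, ...], float]) -> pd.DataFrame:
    cells = design.cells()
    missing = [c for c in cells if c not in means]
    if missing:
        raise IncompleteDesignError(f"missing cell(s): {missing}")
    idx = {f: i for i, f in enumerate(design.factors)}
    rows = []
    for term in design.terms():
        contrast = sum(
            np.prod([cell[idx[f]] for f in term]) * means[cell] for cell in cells
        )
        rows.append(
            {
                "term": design.term_label(term),
                "order": len(term),
                "contrast": float(contrast),
                "effect": float(contrast) / 2 ** (design.k - 1),
            }
        )
    return pd.DataFrame(rows)


def effects_from_means(
    design: FactorialDesign, means: Mapping[tuple[int, ...], float]
) -> pd.DataFrame:
    """Contrast and effect estimate of every term from the 2^k cell means.

    ``means`` maps coded cells (tuples of -1/+1 in factor order) to the
    cell mean response. The effect is contrast / 2^(k-1), i.e. the mean
    response change from the low to the high level of the term.
    """
    return _contrasts(design, dict(means))


class FactorialModel:
    """A balanced 2^k factorial experiment ready to be fitted.

    Construct with :meth:`from_summary` (per-cell n/mean/sd rows, e.g. a
    published table) or :meth:`from_replicates` (long-format raw
    responses); :meth:`fit` returns a :class:`FactorialResults`.
    """

    def __init__(self, design: FactorialDesign, cells: Sequence[CellSummary]):
        self.design = design
        seen = {}
        for cell in cells:
            if len(cell.levels) != design.k:
                raise ValidationError(
                    f"cell {cell.levels} has {len(cell.levels)} levels for k = {design.k}"
                )
            if cell.levels in seen:
                raise ValidationError(f"duplicate cell {cell.levels}")
            seen[cell.levels] = cell
        missing = [c for c in design.cells() if c not in seen]
        if missing:
            raise IncompleteDesignError(f"missing cell(s): {missing}")
        ns = {c.n for c in cells}
        if len(ns) != 1:
            raise UnbalancedDesignError(
                f"replicate counts differ across cells: {sorted(ns)}; only balanced designs supported"
            )
        self.cells = {c.levels: c for c in cells}
        self.n = ns.pop()

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_summary(
        cls,
        design: FactorialDesign,
        cells: Sequence[CellSummary] | pd.DataFrame,
        dispersion_is: str = "sd",
    ) -> "FactorialModel":
        """Build from per-cell summaries.

        ``cells`` is either CellSummary objects or a data frame with one
        column per factor (coded -1/+1 or the physical low/high doses),
        plus ``n``, ``mean`` and a dispersion column (``sd`` or ``sem``).
        ``dispersion_is`` declares the convention of the +/- column; a
        standard error is converted to sd via sd = sem * sqrt(n).
        """
        if dispersion_is not in ("sd", "sem"):
            raise ValidationError(f"dispersion_is must be 'sd' or 'sem', got {dispersion_is!r}")
        if isinstance(cells, pd.DataFrame):
            cells = _cells_from_frame(design, cells, dispersion_is)
        elif dispersion_is == "sem":
            cells = [
                CellSummary(c.levels, c.n, c.mean, c.sd * np.sqrt(c.n)) for c in cells
            ]
        return cls(design, list(cells))

    @classmethod
    def from_replicates(
        cls,
        design: FactorialDesign,
        data: pd.DataFrame,
        response: str = "response",
    ) -> "FactorialModel":
        """Build from long-format replicates (one row per observation).

        ``data`` needs one column per factor holding coded -1/+1 levels
        (or the declared physical doses) and a response column. Every cell
        must have the same replicate count n >= 2.
        """
        for f in design.factors:
            if f not in data.columns:
                raise ValidationError(f"factor column {f!r} missing from data")
        if response not in data.columns:
            raise ValidationError(f"response column {response!r} missing from data")
        coded = _code_levels(design, data)
        cells = []
        grouped = coded.groupby(list(design.factors), sort=False)[response]
        for levels, vals in grouped:
            if len(vals) < 2:
                raise IncompleteDesignError(
                    f"cell {levels} has {len(vals)} replicate(s); need >= 2"
                )
            cells.append(
                CellSummary(levels, len(vals), float(vals.mean()), float(vals.std(ddof=1)))
            )
        return cls(design, cells)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "FactorialResults":
        """Pooled-error full-factorial ANOVA over all 2^k - 1 terms."""
        design, n = self.design, self.n
        means = {lv: c.mean for lv, c in self.cells.items()}
        table = _contrasts(design, means)
        ss_within = float(sum((c.n - 1) * c.sd**2 for c in self.cells.values()))
        df_within = design.n_cells * (n - 1)
        ms_within = ss_within / df_within
        table["ss"] = n * table["contrast"] ** 2 / design.n_cells
        table["df"] = 1
        if ms_within > 0:
            table["F"] = table["ss"] / ms_within
            table["p"] = stats.f.sf(table["F"], 1, df_within)
        else:
            # zero within-cell variance: any nonzero contrast is infinitely
            # significant, a zero one maximally insignificant
            table["F"] = np.where(table["ss"] > 0, np.inf, 0.0)
            table["p"] = np.where(table["ss"] > 0, 0.0, 1.0)
        table["p"] = table["p"].clip(lower=np.finfo(float).tiny, upper=1.0)
        return FactorialResults(
            model=self,
            anova_table=table,
            ss_within=ss_within,
            df_within=df_within,
            ms_within=ms_within,
        )


@dataclass
class FactorialResults:
    """Fitted 2^k ANOVA: effects, sums of squares, F and p per term."""

    model: FactorialModel
    anova_table: pd.DataFrame
    ss_within: float
    df_within: int
    ms_within: float

    @property
    def design(self) -> FactorialDesign:
        return self.model.design

    @property
    def effects(self) -> pd.Series:
        return self.anova_table.set_index("term")["effect"]

    @property
    def pvalues(self) -> pd.Series:
        return self.anova_table.set_index("term")["p"]

    def term(self, *factors: str) -> pd.Series:
        """Row of the ANOVA table for one term, order-insensitive."""
        want = set(factors)
        for row in self.anova_table.itertuples():
            if set(row.term.split(":")) == want:
                return self.anova_table.loc[row.Index]
        raise KeyError(f"no term {':'.join(factors)!r} in the ANOVA table")

    def interaction_report(self, alpha: float = 0.05) -> pd.DataFrame:
        """Classify interaction terms as present/absent at ``alpha``.

        First-order (two-way) interactions are labeled with the sign of
        their effect; higher-order terms are reported separately via the
        ``order`` column.
        """
        inter = self.anova_table[self.anova_table["order"] >= 2].copy()
        inter["present"] = inter["p"] <= alpha
        inter["direction"] = np.sign(inter["effect"]).astype(int)
        inter["alpha"] = alpha
        return inter[["term", "order", "effect", "F", "p", "present", "direction", "alpha"]].reset_index(
            drop=True
        )

    def summary(self, alpha: float = 0.05) -> str:
        d = self.design
        lines = [
            f"2^{d.k} factorial ANOVA  (factors: {', '.join(d.factors)}; n = {self.model.n} per cell)",
            f"residual: SS = {self.ss_within:.6g}, df = {self.df_within}, MS = {self.ms_within:.6g}",
            "",
            self.anova_table.to_string(
                index=False,
                formatters={"p": "{:.4g}".format, "F": "{:.4g}".format},
            ),
            "",
        ]
        rep = self.interaction_report(alpha)
        first = rep[rep["order"] == 2]
        present = first[first["present"]]["term"].tolist()
        lines.append(
            f"first-order interactions present at alpha={alpha}: "
            + (", ".join(present) if present else "none")
        )
        top = rep[rep["order"] == d.k]
        if len(top):
            row = top.iloc[0]
            lines.append(
                f"{d.k}-way interaction {row.term}: p = {row.p:.4g} "
                f"({'present' if row.present else 'absent'} at alpha={alpha})"
            )
        return "\n".join(lines)


# -- functional wrappers (pipeline surface) ---------------------------------


def anova_from_summary(
    design: FactorialDesign,
    cells: Sequence[CellSummary] | pd.DataFrame,
    dispersion_is: str = "sd",
) -> FactorialResults:
    """ANOVA reconstructed from per-cell summaries (n, mean, sd or sem)."""
    return FactorialModel.from_summary(design, cells, dispersion_is).fit()


def anova_from_replicates(
    design: FactorialDesign, data: pd.DataFrame, response: str = "response"
) -> FactorialResults:
    """Classical full-factorial ANOVA from long-format replicate data.

    For balanced data this coincides exactly with
    :func:`anova_from_summary` on the per-cell summaries.
    """
    return FactorialModel.from_replicates(design, data, response).fit()


def interaction_report(results: FactorialResults, alpha: float = 0.05) -> pd.DataFrame:
    """Module-level alias of :meth:`FactorialResults.interaction_report`."""
    return results.interaction_report(alpha)


# -- helpers ----------------------------------------------------------------


def _code_levels(design: FactorialDesign, data: pd.DataFrame) -> pd.DataFrame:
    """Map physical factor levels to -1/+1 codes (low dose -> -1)."""
    coded = data.copy()
    for f in design.factors:
        vals = sorted(pd.unique(coded[f]))
        if set(vals) <= {-1, 1}:
            coded[f] = coded[f].astype(int)
            continue
        if len(vals) != 2:
            raise ValidationError(f"factor {f!r} has {len(vals)} levels; expected exactly 2")
        if design.levels and f in design.levels:
            low, high = design.levels[f]
            if set(vals) != {low, high}:
                raise ValidationError(
                    f"factor {f!r} levels {vals} do not match declared ({low}, {high})"
                )
        coded[f] = coded[f].map({vals[0]: -1, vals[1]: 1})
    return coded


def _cells_from_frame(
    design: FactorialDesign, frame: pd.DataFrame, dispersion_is: str
) -> list[CellSummary]:
    need = list(design.factors) + ["n", "mean"]
    disp_col = next(
        (c for c in (dispersion_is, "dispersion", "sd") if c in frame.columns), None
    )
    if disp_col is None:
        raise ValidationError(f"summary frame needs a dispersion column {dispersion_is!r}")
    for col in need:
        if col not in frame.columns:
            raise ValidationError(f"summary frame missing column {col!r}")
    coded = _code_levels(design, frame)
    cells = []
    for _, rec in coded.iterrows():
        n = int(rec["n"])
        sd = float(rec[disp_col])
        if dispersion_is == "sem":
            sd = sd * np.sqrt(n)
        cells.append(
            CellSummary(tuple(int(rec[f]) for f in design.factors), n, float(rec["mean"]), sd)
        )
    return cells
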