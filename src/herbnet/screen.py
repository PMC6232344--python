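"""Drug-likeness and oral-bioavailability screening.

Drug-likeness (DL) of a compound is its Tanimoto similarity

    f(a, b) = a.b / (|a|^2 + |b|^2 - a.b)

between the compound's molecular-property vector ``a`` and the average
property vector ``b`` of approved drugs in a reference library. The
screening rule keeps compounds with OB >= ob_min (default 30%) AND
DL >= dl_min (default 0.1), both comparisons inclusive; compounds that
fail can be rescued by literature evidence (an explicit whitelist or a
per-compound evidence flag) rather than by rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import CompoundTable
from .errors import DimensionError, UndefinedSimilarityError

__all__ = [
    "DescriptorVector",
    "DrugLikenessReference",
    "ScreenResult",
    "tanimoto_similarity",
    "screen_compounds",
]

DEFAULT_OB_MIN = 30.0
DEFAULT_DL_MIN = 0.1


@dataclass(frozen=True)
class DescriptorVector:
    """A fixed-length non-negative molecular-property vector."""

    values: tuple[float, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", tuple(float(v) for v in vals))
        if vals.size == 0:
            raise DimensionError("descriptor vector must have length > 0")
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise UndefinedSimilarityError("descriptor values must be finite and >= 0")
        if self.labels and len(self.labels) != vals.size:
            raise DimensionError(
                f"{len(self.labels)} labels for {vals.size} descriptor values"
            )

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class DrugLikenessReference:
    """Average molecular-property profile of a reference drug library."""

    mean_vector: DescriptorVector
    source: str = "synthetic reference"


@dataclass
class ScreenResult:
    """Outcome of OB/DL screening: a partition of the input compound ids."""

    passed: list[str]
    rescued: list[str]
    rejected: list[str]
    ob_min: float = DEFAULT_OB_MIN
    dl_min: float = DEFAULT_DL_MIN
    _table: pd.DataFrame = field(default=None, repr=False)

    @property
    def potential(self) -> list[str]:
        """Compounds retained for downstream analysis: passed + rescued."""
        return self.passed + self.rescued

    def to_frame(self) -> pd.DataFrame:
        """Per-compound id/status/ob/dl table in input order."""
        return self._table.copy()


def tanimoto_similarity(a: DescriptorVector | Sequence[float], b: DescriptorVector | Sequence[float]) -> float:
    """Tanimoto similarity a.b / (|a|^2 + |b|^2 - a.b).

    Symmetric; lies in [0, 1] for non-negative vectors (the denominator
    exceeds the numerator by |a - b|^2 >= 0) and equals 1 iff a == b.
    """
    av = a.as_array() if isinstance(a, DescriptorVector) else np.asarray(a, dtype=float)
    bv = b.as_array() if isinstance(b, DescriptorVector) else np.asarray(b, dtype=float)
    if av.shape != bv.shape or av.ndim != 1:
        raise DimensionError(f"descriptor lengths differ: {av.shape} vs {bv.shape}")
    if np.any(av < 0) or np.any(bv < 0):
        raise UndefinedSimilarityError("tanimoto_similarity requires non-negative vectors")
    dot = float(av @ bv)
    denom = float(av @ av) + float(bv @ bv) - dot
    if denom == 0.0:
        raise UndefinedSimilarityError("similarity undefined: both vectors are zero")
    return dot / denom


def compute_dl(compound: DescriptorVector, reference: DrugLikenessReference) -> float:
    """Drug-likeness of a compound against a reference profile."""
    return tanimoto_similarity(compound, reference.mean_vector)


def screen_compounds(
    table: CompoundTable,
    ob_min: float = DEFAULT_OB_MIN,
    dl_min: float = DEFAULT_DL_MIN,
    whitelist: Iterable[str] = (),
) -> ScreenResult:
    """Apply the OB/DL rule with literature-evidence rescue.

    A compound passes iff both OB and DL are present and ``ob >= ob_min``
    and ``dl >= dl_min`` (inclusive, so DL exactly at the threshold
    passes). A failing compound is *rescued* when its id is whitelisted or
    its evidence flag is set; everything else is rejected. The three lists
    partition the input ids.
    """
    wl = {str(w) for w in whitelist}
    df = table.df
    ob = df["ob"].to_numpy(dtype=float)
    dl = df["dl"].to_numpy(dtype=float)
    # NaN comparisons are False, so missing OB/DL can never satisfy the rule
    meets = (ob >= ob_min) & (dl >= dl_min)
    rescue = (~meets) & (df["evidence"].to_numpy(bool) | df["id"].isin(wl).to_numpy())
    status = np.where(meets, "passed", np.where(rescue, "rescued", "rejected"))
    out = pd.DataFrame({"id": df["id"], "status": status, "ob": df["ob"], "dl": df["dl"]})
    return ScreenResult(
        passed=out.loc[out["status"] == "passed", "id"].tolist(),
        rescued=out.loc[out["status"] == "rescued", "id"].tolist(),
        rejected=out.loc[out["status"] == "rejected", "id"].tolist(),
        ob_min=ob_min,
        dl_min=dl_min,
        _table=out,
    )
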