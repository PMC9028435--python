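"""Agreement statistics between two three-valued predictors.

Cross-classifies paired call lists into a 3x3 table (ordered neg / inc /
pos), with cell percentages, Cohen's kappa, and the two clinically labeled
divergence subsets: "adding information" (baseline inconclusive, fused call
positive) and "increasing safety" (baseline positive, fused call
inconclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .evidence import Call

__all__ = [
    "CALL_ORDER",
    "AgreementTable",
    "DivergenceSubsets",
    "agreement_report",
    "cohens_kappa",
    "cross_tabulate",
    "divergence_subsets",
]

#: Row/column order of the agreement table.
CALL_ORDER: tuple[Call, ...] = (Call.NEG, Call.INC, Call.POS)
_INDEX = {c: i for i, c in enumerate(CALL_ORDER)}


@dataclass(frozen=True)
class AgreementTable:
    """3x3 cross-classification; rows = predictor A, columns = predictor B."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (3, 3) or (counts < 0).any():
            raise ValueError("counts must be a non-negative 3x3 matrix")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def percentages(self) -> np.ndarray:
        """Cell percentages of the grand total (full precision)."""
        return self.counts / self.total * 100.0

    @property
    def observed_agreement(self) -> float:
        return float(np.trace(self.counts)) / self.total


def cross_tabulate(
    calls_a: Sequence[Call], calls_b: Sequence[Call]
) -> AgreementTable:
    """Count paired calls into the 3x3 table (A in rows, B in columns)."""
    if len(calls_a) != len(calls_b):
        raise ValueError(
            f"call lists differ in length: {len(calls_a)} vs {len(calls_b)}"
        )
    if len(calls_a) == 0:
        raise ValueError("cannot tabulate empty call lists")
    counts = np.zeros((3, 3), dtype=np.int64)
    for a, b in zip(calls_a, calls_b):
        counts[_INDEX[Call(a)], _INDEX[Call(b)]] += 1
    return AgreementTable(counts)


def cohens_kappa(table: AgreementTable) -> float:
    """Unweighted Cohen's kappa: (p_o - p_e) / (1 - p_e).

    ``p_o`` is the observed agreement (diagonal fraction) and ``p_e`` the
    chance agreement expected from the marginals.  Undefined when the
    marginals concentrate all mass in a single category (p_e = 1).
    """
    n = table.total
    if n == 0:
        raise ValueError("empty table")
    p_o = table.observed_agreement
    p_e = float(table.row_sums @ table.col_sums) / (n * n)
    if p_e >= 1.0:
        raise ZeroDivisionError("kappa undefined: chance agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


@dataclass(frozen=True)
class DivergenceSubsets:
    """Disjoint off-diagonal sample-id groups (baseline A vs fused B)."""

    adding_information: tuple  # A inc, B pos
    increasing_safety: tuple  # A pos, B inc
    other_divergent: tuple  # remaining off-diagonal


def divergence_subsets(
    ids: Sequence, calls_a: Sequence[Call], calls_b: Sequence[Call]
) -> DivergenceSubsets:
    """Partition all discordant samples into the three labeled subsets."""
    if not (len(ids) == len(calls_a) == len(calls_b)):
        raise ValueError("ids and call lists must be aligned")
    adding, safety, other = [], [], []
    for sid, a, b in zip(ids, calls_a, calls_b):
        a, b = Call(a), Call(b)
        if a is b:
            continue
        if a is Call.INC and b is Call.POS:
            adding.append(sid)
        elif a is Call.POS and b is Call.INC:
            safety.append(sid)
        else:
            other.append(sid)
    return DivergenceSubsets(tuple(adding), tuple(safety), tuple(other))


def agreement_report(
    table: AgreementTable, label_a: str = "A", label_b: str = "B"
) -> pd.DataFrame:
    """Count and percentage matrices with margins, display-rounded to 1 dp."""
    labels = [c.value for c in CALL_ORDER]
    counts = pd.DataFrame(table.counts, index=labels, columns=labels)
    counts["sum"] = table.row_sums
    counts.loc["sum"] = list(table.col_sums) + [table.total]
    pct = pd.DataFrame(table.percentages, index=labels, columns=labels)
    pct["sum"] = table.row_sums / table.total * 100.0
    pct.loc["sum"] = list(table.col_sums / table.total * 100.0) + [100.0]
    pct = pct.round(1)
    counts.index.name = f"{label_a}\\{label_b} (counts)"
    pct.index.name = f"{label_a}\\{label_b} (percent)"
    return pd.concat({"counts": counts, "percent": pct}, names=["block"])
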