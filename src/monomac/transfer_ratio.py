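"""Input-ratio normalization for competitive adoptive-transfer counts.

In a competitive transfer, donor cells (CD45.2 YFP+) are mixed with
competitor cells (CD45.1+) before injection; the input ratio IR =
n_donorA / n_donorB measured pre-transfer normalizes the recovered
donor-to-competitor ratio of each population, so a normalized recovery of 1
means the donor engrafted exactly as well as the competitor.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: explicit marker for ratios undefined because of an empty gate
UNDEFINED = float("nan")


@dataclass
class TransferCounts:
    population: str
    n_donorA: int   # CD45.2 YFP+ analog
    n_donorB: int   # CD45.1+ competitor analog

    def __post_init__(self):
        if self.n_donorA < 0 or self.n_donorB < 0:
            raise ValueError("cell counts must be nonnegative")


def input_ratio(pre_transfer: TransferCounts) -> float:
    """IR = donor / competitor counts in the pre-transfer mix."""
    if pre_transfer.n_donorB == 0:
        raise ValueError("zero competitor count: input ratio undefined")
    return pre_transfer.n_donorA / pre_transfer.n_donorB


def normalized_recovery(recovered: TransferCounts, ir: float) -> float:
    """(recovered donor/competitor ratio) / IR; NaN for an empty competitor gate."""
    if ir <= 0:
        raise ValueError("input ratio must be positive")
    if recovered.n_donorB == 0:
        return UNDEFINED
    return (recovered.n_donorA / recovered.n_donorB) / ir


def normalize_table(table: pd.DataFrame, ir: float) -> pd.DataFrame:
    """Apply normalized_recovery to a TSV-style table (population, n_donorA,
    n_donorB); adds ir and normalized_ratio columns."""
    out = table.copy()
    out["ir"] = ir
    out["normalized_ratio"] = [
        normalized_recovery(TransferCounts(r.population, r.n_donorA, r.n_donorB), ir)
        for r in table.itertuples()
    ]
    return out
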