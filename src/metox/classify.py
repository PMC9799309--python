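"""Threshold rules turning descriptors into oxidation-prone flags.

Four binary predictors are applied independently, one per descriptor:

* sSASA / dSASA: prone when the relative side-chain SASA exceeds 15%.
* WCN: prone when at least 6 water molecules populate the 6 Å shell.
* WCN-OH: prone when WCN > 6 (condition 1), or when WCN > 0.1 and
  #OH > 1.5 (condition 2). Condition 2 captures partially buried
  methionines whose oxidation is mediated by neighbouring Ser/Thr/Tyr
  hydroxyl groups rather than bulk water.

The WCN rule is stated as "at least 6" (≥) while WCN-OH condition 1 uses
a strict ">"; the two behaviours differ only at WCN exactly 6. Both
comparison conventions are kept configurable and the default mirrors the
wording of each rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "Thresholds",
    "PredictionRecord",
    "METHODS",
    "classify_sasa",
    "classify_wcn",
    "classify_wcn_oh",
    "classify_record",
    "classify_table",
    "count_events",
]

METHODS = ("ssasa", "dsasa", "wcn", "wcn_oh")

FLAG_COLUMNS = {
    "ssasa": "flag_ssasa",
    "dsasa": "flag_dsasa",
    "wcn": "flag_wcn",
    "wcn_oh": "flag_wcn_oh",
}


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for the four predictors.

    ``wcn_inclusive`` selects ≥ (default, "at least 6") for the plain WCN
    rule; WCN-OH condition 1 is strict unless ``wcn_oh_cond1_inclusive``.
    """

    sasa_rel_cut: float = 15.0
    wcn_cut: float = 6.0
    wcn_floor: float = 0.1
    oh_cut: float = 1.5
    wcn_inclusive: bool = True
    wcn_oh_cond1_inclusive: bool = False

    def __post_init__(self) -> None:
        if min(self.sasa_rel_cut, self.wcn_cut, self.wcn_floor, self.oh_cut) < 0:
            raise ValueError("thresholds must be non-negative")
        if not self.wcn_floor < self.wcn_cut:
            raise ValueError("wcn_floor must be below wcn_cut")


@dataclass(frozen=True)
class PredictionRecord:
    """Per-site binary oxidation-prone flags, one per method."""

    molecule_id: str
    chain: str
    residue_label: str
    flag_ssasa: int
    flag_dsasa: int
    flag_wcn: int
    flag_wcn_oh: int

    def flag(self, method: str) -> int:
        return getattr(self, _flag_attr(method))


def _flag_attr(method: str) -> str:
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return FLAG_COLUMNS[method]


def classify_sasa(rel_sasa: float, thresholds: Thresholds = Thresholds()) -> int:
    """1 iff the relative side-chain SASA strictly exceeds the cut."""
    return int(rel_sasa > thresholds.sasa_rel_cut)


def classify_wcn(wcn: float, thresholds: Thresholds = Thresholds()) -> int:
    """1 iff the water coordination number reaches the cut ("at least 6"
    by default, hence ≥)."""
    if thresholds.wcn_inclusive:
        return int(wcn >= thresholds.wcn_cut)
    return int(wcn > thresholds.wcn_cut)


def classify_wcn_oh(
    wcn: float, oh: float, thresholds: Thresholds = Thresholds()
) -> int:
    """1 iff WCN > cut, or WCN > floor and #OH > cut (all strict)."""
    if thresholds.wcn_oh_cond1_inclusive:
        cond1 = wcn >= thresholds.wcn_cut
    else:
        cond1 = wcn > thresholds.wcn_cut
    cond2 = wcn > thresholds.wcn_floor and oh > thresholds.oh_cut
    return int(cond1 or cond2)


def classify_record(
    row, thresholds: Thresholds = Thresholds(), molecule_id: str | None = None
) -> PredictionRecord:
    """Classify one descriptor-table row (mapping or pandas Series)."""
    return PredictionRecord(
        molecule_id=str(molecule_id if molecule_id is not None else row["molecule_id"]),
        chain=str(row["chain"]),
        residue_label=str(row["residue_label"]),
        flag_ssasa=classify_sasa(float(row["sSASA_rel"]), thresholds),
        flag_dsasa=classify_sasa(float(row["dSASA_rel"]), thresholds),
        flag_wcn=classify_wcn(float(row["WCN"]), thresholds),
        flag_wcn_oh=classify_wcn_oh(float(row["WCN"]), float(row["OH"]), thresholds),
    )


REQUIRED_COLUMNS = ["molecule_id", "chain", "residue_label", "sSASA_rel", "dSASA_rel", "WCN", "OH"]


def classify_table(
    table: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Append the four flag columns to a descriptor table.

    Raises ``KeyError`` naming the first missing contract column.
    """
    for column in REQUIRED_COLUMNS:
        if column not in table.columns:
            raise KeyError(f"descriptor table is missing required column {column!r}")
    out = table.copy()
    out["flag_ssasa"] = [classify_sasa(v, thresholds) for v in table["sSASA_rel"]]
    out["flag_dsasa"] = [classify_sasa(v, thresholds) for v in table["dSASA_rel"]]
    out["flag_wcn"] = [classify_wcn(v, thresholds) for v in table["WCN"]]
    out["flag_wcn_oh"] = [
        classify_wcn_oh(w, o, thresholds) for w, o in zip(table["WCN"], table["OH"])
    ]
    return out


def count_events(predictions: Iterable, method: str) -> int:
    """Total predicted oxidation events (sum of the chosen flag) over the
    predictions of one molecule."""
    attr = _flag_attr(method)
    total = 0
    for pred in predictions:
        if isinstance(pred, PredictionRecord):
            total += getattr(pred, attr)
        else:  # mapping / pandas Series
            total += int(pred[attr])
    return total
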