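"""Packaged reference datasets for the two evaluation studies.

Three delimited-text tables ship with the package and are verified
against a checksum manifest at load time:

* ``cst_events`` — 14 clinical-stage antibodies with the number of heavy-chain
  Fab (Fd) methionines, the observed segment-level oxidation events, and
  the predicted event counts of five methods (an external baseline plus
  sSASA, dSASA, WCN, WCN-OH); 46 methionines in total.
* ``crystal_example`` — 11 heavy-chain methionines of three antibodies with
  crystal structures, with sSASA/dSASA (Å²), WCN and #OH computed from
  both homology models and the crystal structures.
* ``internal_oxidation`` — 26 methionines of 9 proprietary molecules with measured
  oxidation levels after tert-butyl hydroperoxide stress and the four
  per-residue method predictions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["ReferenceTables", "TableChecksumError", "load_reference_tables"]


class TableChecksumError(RuntimeError):
    """Raised when a packaged table does not match its manifest entry."""


@dataclass(frozen=True)
class ReferenceTables:
    cst_events: pd.DataFrame
    crystal_example: pd.DataFrame
    internal_oxidation: pd.DataFrame

    def validate(self) -> None:
        if int(self.cst_events["n_fd_met"].sum()) != 46:
            raise TableChecksumError("cst_events methionine counts do not sum to 46")
        if len(self.internal_oxidation) != 26:
            raise TableChecksumError("internal_oxidation must have 26 rows")
        if int((self.internal_oxidation["ox_percent"] >= 5.0).sum()) != 6:
            raise TableChecksumError("internal_oxidation must contain 6 oxidation levels >= 5%")
        if len(self.crystal_example) != 11:
            raise TableChecksumError("crystal_example must have 11 rows")


def _manifest() -> dict:
    text = (
        resources.files("metox.data").joinpath("MANIFEST.sha256").read_text()
    )
    entries = {}
    for line in text.strip().splitlines():
        digest, name = line.split()
        entries[name] = digest
    return entries


def _read_checked(name: str, expected: str) -> pd.DataFrame:
    raw = resources.files("metox.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected:
        raise TableChecksumError(
            f"{name}: checksum {digest} does not match manifest {expected}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t")


def load_reference_tables() -> ReferenceTables:
    """Load and checksum-verify the packaged evaluation tables."""
    manifest = _manifest()
    tables = ReferenceTables(
        cst_events=_read_checked("cst_events.tsv", manifest["cst_events.tsv"]),
        crystal_example=_read_checked("crystal_example.tsv", manifest["crystal_example.tsv"]),
        internal_oxidation=_read_checked("internal_oxidation.tsv", manifest["internal_oxidation.tsv"]),
    )
    tables.validate()
    return tables
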