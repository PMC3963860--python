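"""Transcript/protein concordance from spectral and peptide counting.

Spectral counting is a semi-quantitative shotgun-proteomics readout: the
number of MS/MS spectra (and distinct peptides) assigned to a protein
scales, roughly, with its abundance.  This module compares that readout
with transcript levels in two ways: a tie-corrected rank correlation
(Kendall tau-b) between transcript units and spectrum counts across cell
types, and a confusion table between the observed detected/nd states and
the expected-detectability rule of :mod:`gpcrprofile.digest`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcordanceError",
    "DegenerateRankingError",
    "SpectralCountTable",
    "DetectionAgreement",
    "rank_concordance",
    "detection_agreement",
]


class ConcordanceError(ValueError):
    pass


class DegenerateRankingError(ConcordanceError):
    """All values tied on one side; the rank statistic is undefined."""


@dataclass
class SpectralCountTable:
    """Per (accession, cell type) unique-peptide and spectrum counts.

    ``data`` columns: accession, cell_type, peptides, spectra.  A protein not
    detected in a cell type has both counts missing (NaN); the two columns
    are missing together or present together.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"accession", "cell_type", "peptides", "spectra"}
        missing = required - set(self.data.columns)
        if missing:
            raise ConcordanceError(f"spectral table columns missing: {sorted(missing)}")
        pep_na = self.data["peptides"].isna()
        spec_na = self.data["spectra"].isna()
        if (pep_na != spec_na).any():
            raise ConcordanceError("peptide and spectrum counts must be nd together")
        numeric = self.data.loc[~pep_na, ["peptides", "spectra"]]
        if (numeric < 0).any().any():
            raise ConcordanceError("negative counts")

    @property
    def detected(self) -> pd.Series:
        return ~self.data["peptides"].isna()

    def counts_for(self, accession: str, value: str = "spectra") -> pd.Series:
        sub = self.data[self.data["accession"] == accession]
        if sub.empty:
            raise KeyError(accession)
        return sub.set_index("cell_type")[value].astype(float)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SpectralCountTable":
        frame = pd.read_csv(path, sep="\t")
        return cls(data=frame)


def rank_concordance(
    transcript_units: pd.Series,
    counts: pd.Series,
    statistic: str = "kendall_tau_b",
    nd_as: float | None = 0.0,
) -> float:
    """Kendall tau-b between transcript units and spectral counts.

    The two series are aligned on their index (cell types).  Missing counts
    (nd) are replaced by ``nd_as`` (absence treated as zero abundance) or
    dropped when ``nd_as`` is None.  Needs at least three aligned cell types
    and variation on both sides.
    """
    if statistic != "kendall_tau_b":
        raise ConcordanceError(f"unknown statistic {statistic!r}")
    x, y = transcript_units.align(counts, join="inner")
    if nd_as is None:
        keep = ~y.isna() & ~x.isna()
        x, y = x[keep], y[keep]
    else:
        y = y.fillna(nd_as)
        keep = ~x.isna()
        x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ConcordanceError("need at least three aligned cell types")
    if x.nunique() < 2 or y.nunique() < 2:
        raise DegenerateRankingError("all values tied on one side")
    tau = stats.kendalltau(x.to_numpy(float), y.to_numpy(float), variant="b").statistic
    return float(tau)


@dataclass
class DetectionAgreement:
    """Cross-tabulation of observed detection against the predicted rule."""

    tp: int
    fp: int
    fn: int
    tn: int
    mismatches: list[tuple[str, str]]

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")


def detection_agreement(
    table: SpectralCountTable,
    predictions: dict[tuple[str, str], bool],
) -> DetectionAgreement:
    """Compare observed detected/nd cells with predicted detectability.

    ``predictions`` maps (accession, cell type) to the boolean output of the
    detectability rule; its keys must cover exactly the table's cells.
    """
    cells = {(r.accession, r.cell_type) for r in table.data.itertuples(index=False)}
    if cells != set(predictions):
        raise ConcordanceError("prediction keys do not match the spectral table")
    tp = fp = fn = tn = 0
    mismatches: list[tuple[str, str]] = []
    detected = table.detected.to_numpy()
    for row, obs in zip(table.data.itertuples(index=False), detected):
        pred = predictions[(row.accession, row.cell_type)]
        if pred and obs:
            tp += 1
        elif pred and not obs:
            fp += 1
            mismatches.append((row.accession, row.cell_type))
        elif not pred and obs:
            fn += 1
            mismatches.append((row.accession, row.cell_type))
        else:
            tn += 1
    return DetectionAgreement(tp=tp, fp=fp, fn=fn, tn=tn, mismatches=sorted(mismatches))
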