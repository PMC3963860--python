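"""Reference-gene alignment, delta-Ct normalization and cutoff filtering.

All quantities follow the qPCR convention that abundance is proportional to
``2**-Ct``.  Samples (cell types) are aligned by shifting every Ct in a cell
type by the offset of that cell type's reference-gene Ct from the reference
grand mean, so the reference sits at a single study-wide value (21.12 cycles
for RPLP0 in the source study).  From the aligned Ct the module derives

* ``delta_ct``        = Ct_gene - Ct_reference,
* ``fold_below_ref``  = 2**delta_ct   (how many-fold below the reference;
  this is the "fold" convention of the study's top-expressed table),
* ``ratio_over_ref``  = 2**-delta_ct  (the sign-correct abundance ratio),
* ``units``           = 2**-Ct * 1e12 (arbitrary expression units),
* ``above_cutoff``    = Ct <= 31.5    (the expression call, 329 units).

Reference-gene stability is scored with the classical pairwise-ratio M
statistic: for candidate j, M_j is the mean over the other candidates k of
the standard deviation across cell types of the log2 expression ratio j/k.
On the Ct scale that ratio is simply ``Ct_k - Ct_j``.  Lower M = more stable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qpcr_io import MeanCtMatrix
from .reference_data import (
    CUTOFF_CT,
    REFERENCE_CT,
    REFERENCE_GENE,
    ct_from_units,
    expression_units,
)

__all__ = [
    "NormalizationError",
    "UnusableReferenceError",
    "ReferenceModel",
    "ExpressionProfile",
    "FilterResult",
    "compute_stability",
    "build_reference",
    "normalize",
    "filter_expressed",
    "relative_fold_over_cutoff",
    "profile_from_normalized_ct",
    "profile_from_units",
    "expression_units",
]


class NormalizationError(ValueError):
    pass


class UnusableReferenceError(NormalizationError):
    """The reference gene is sentinel or missing in some cell type."""


@dataclass
class ReferenceModel:
    """The reference gene, its per-cell-type Ct and its grand mean."""

    gene: str = REFERENCE_GENE
    grand_mean_ct: float = REFERENCE_CT
    per_cell_ct: dict[str, float] = field(default_factory=dict)
    stability: dict[str, float] = field(default_factory=dict)

    def shift(self, cell_type: str) -> float:
        """Alignment offset subtracted from every Ct of ``cell_type``."""
        if not self.per_cell_ct:
            return 0.0
        return self.per_cell_ct[cell_type] - self.grand_mean_ct


@dataclass
class ExpressionProfile:
    """Normalized per-(gene, cell type) expression quantities.

    ``data`` columns: gene, cell_type, ct, delta_ct, fold_below_ref,
    ratio_over_ref, units, above_cutoff, all_sentinel.
    """

    data: pd.DataFrame
    reference: ReferenceModel
    ct_cutoff: float = CUTOFF_CT

    @property
    def cell_types(self) -> list[str]:
        return list(pd.unique(self.data["cell_type"]))

    def ct_matrix(self) -> pd.DataFrame:
        return self.data.pivot(index="gene", columns="cell_type", values="ct")

    def units_matrix(self) -> pd.DataFrame:
        return self.data.pivot(index="gene", columns="cell_type", values="units")

    def above_cutoff_matrix(self) -> pd.DataFrame:
        return self.data.pivot(index="gene", columns="cell_type", values="above_cutoff")

    def lookup(self, gene: str, cell_type: str) -> pd.Series:
        mask = (self.data["gene"] == gene) & (self.data["cell_type"] == cell_type)
        rows = self.data[mask]
        if rows.empty:
            raise KeyError((gene, cell_type))
        return rows.iloc[0]


@dataclass
class FilterResult:
    """Outcome of the expression-cutoff filter."""

    per_cell_type: dict[str, frozenset[str]]
    union: frozenset[str]
    ct_cutoff: float

    @property
    def counts(self) -> dict[str, int]:
        return {cell: len(genes) for cell, genes in self.per_cell_type.items()}


def compute_stability(
    matrix: MeanCtMatrix, candidates: list[str] | None = None
) -> pd.Series:
    """Pairwise-ratio stability score M per candidate reference gene.

    For candidate ``j`` and every other candidate ``k``, the log2 expression
    ratio across cell types (with quantity ``2**-Ct``) is ``Ct_k - Ct_j``;
    its sample standard deviation over the shared non-sentinel cell types is
    ``V_jk`` and ``M_j = mean_k V_jk``.  Candidates need at least two usable
    cell types; sentinel entries are excluded.
    """
    if candidates is None:
        candidates = matrix.genes("housekeeping")
    if len(candidates) < 2:
        raise NormalizationError("stability scoring needs at least two candidates")
    ct = matrix.ct_matrix()
    sentinel = matrix.sentinel_matrix()
    usable: dict[str, pd.Series] = {}
    for gene in candidates:
        if gene not in ct.index:
            raise NormalizationError(f"candidate {gene!r} not in the Ct matrix")
        vals = ct.loc[gene].where(~sentinel.loc[gene].astype(bool)).dropna()
        if len(vals) < 2:
            raise NormalizationError(f"candidate {gene!r} has fewer than two usable cell types")
        usable[gene] = vals

    scores = {}
    for j in candidates:
        sds = []
        for k in candidates:
            if k == j:
                continue
            shared = usable[j].index.intersection(usable[k].index)
            if len(shared) < 2:
                continue
            log_ratio = usable[k][shared] - usable[j][shared]
            sds.append(float(np.std(log_ratio, ddof=1)))
        if not sds:
            raise NormalizationError(f"candidate {j!r} shares <2 cell types with every other")
        scores[j] = float(np.mean(sds))
    return pd.Series(scores, name="M").loc[candidates]


def build_reference(
    matrix: MeanCtMatrix,
    gene: str = REFERENCE_GENE,
    grand_mean_ct: float | None = None,
    stability_candidates: list[str] | None = None,
) -> ReferenceModel:
    """Extract the reference gene's per-cell-type Ct from a mean-Ct matrix.

    ``grand_mean_ct`` defaults to the mean of the per-cell-type reference Ct;
    passing a value (e.g. the study constant 21.12) pins the aligned scale.
    """
    sub = matrix.data[matrix.data["gene_symbol"] == gene]
    if sub.empty:
        raise UnusableReferenceError(f"reference gene {gene!r} not measured")
    if sub["all_sentinel"].any():
        cells = sub.loc[sub["all_sentinel"], "cell_type"].tolist()
        raise UnusableReferenceError(f"reference {gene!r} sentinel in {cells}")
    per_cell = dict(zip(sub["cell_type"], sub["mean_ct"].astype(float)))
    grand = float(np.mean(list(per_cell.values()))) if grand_mean_ct is None else grand_mean_ct
    stability: dict[str, float] = {}
    if stability_candidates is not None:
        stability = compute_stability(matrix, stability_candidates).to_dict()
    return ReferenceModel(gene=gene, grand_mean_ct=grand, per_cell_ct=per_cell, stability=stability)


def _derive_quantities(
    frame: pd.DataFrame, reference_ct: float, ct_cutoff: float
) -> pd.DataFrame:
    ct = frame["ct"].to_numpy(dtype=float)
    delta = ct - reference_ct
    frame["delta_ct"] = delta
    frame["fold_below_ref"] = 2.0 ** delta
    frame["ratio_over_ref"] = 2.0 ** (-delta)
    frame["units"] = np.array([expression_units(c) for c in ct])
    frame["above_cutoff"] = (ct <= ct_cutoff) & ~frame["all_sentinel"].to_numpy()
    return frame


def normalize(
    matrix: MeanCtMatrix,
    ref: ReferenceModel | None = None,
    ct_cutoff: float = CUTOFF_CT,
    genes: list[str] | None = None,
) -> ExpressionProfile:
    """Align each cell type to the reference and derive expression quantities.

    Aligned Ct = mean Ct - (cell-type reference Ct - reference grand mean).
    Sentinel entries are not shifted: they stay at the sentinel Ct, get the
    units that Ct implies, and are never called above the cutoff.
    """
    if ref is None:
        ref = build_reference(matrix)
    missing = set(matrix.data["cell_type"].unique()) - set(ref.per_cell_ct or {})
    if ref.per_cell_ct and missing:
        raise UnusableReferenceError(f"reference has no Ct for cell types {sorted(missing)}")

    data = matrix.data
    if genes is not None:
        data = data[data["gene_symbol"].isin(genes)]
    shifts = data["cell_type"].map(lambda c: ref.shift(c)).to_numpy(dtype=float)
    sentinel = data["all_sentinel"].to_numpy(dtype=bool)
    ct = data["mean_ct"].to_numpy(dtype=float) - np.where(sentinel, 0.0, shifts)
    frame = pd.DataFrame(
        {
            "gene": data["gene_symbol"].to_numpy(),
            "cell_type": data["cell_type"].to_numpy(),
            "ct": ct,
            "all_sentinel": sentinel,
        }
    )
    frame = _derive_quantities(frame, ref.grand_mean_ct, ct_cutoff)
    return ExpressionProfile(data=frame, reference=ref, ct_cutoff=ct_cutoff)


def filter_expressed(
    profiles: ExpressionProfile, ct_cutoff: float | None = None
) -> FilterResult:
    """Genes retained per cell type (aligned Ct <= cutoff, inclusive) and the
    union retained in at least one cell type."""
    cutoff = profiles.ct_cutoff if ct_cutoff is None else ct_cutoff
    data = profiles.data
    keep = (data["ct"] <= cutoff) & ~data["all_sentinel"]
    per_cell: dict[str, frozenset[str]] = {}
    for cell in profiles.cell_types:
        per_cell[cell] = frozenset(data.loc[keep & (data["cell_type"] == cell), "gene"])
    union = frozenset().union(*per_cell.values()) if per_cell else frozenset()
    return FilterResult(per_cell_type=per_cell, union=union, ct_cutoff=cutoff)


def relative_fold_over_cutoff(ct: float, ct_cutoff: float = CUTOFF_CT) -> float:
    """Fold change of a gene relative to the expression cutoff, 2**(31.5-Ct)."""
    return 2.0 ** (ct_cutoff - ct)


def profile_from_normalized_ct(
    ct_frame: pd.DataFrame,
    reference_ct: float = REFERENCE_CT,
    ct_cutoff: float = CUTOFF_CT,
    sentinel_ct: float = 40.0,
    reference_gene: str = REFERENCE_GENE,
) -> ExpressionProfile:
    """Build an :class:`ExpressionProfile` from already-aligned Ct values.

    ``ct_frame`` is a gene x cell-type matrix of normalized Ct (as printed in
    the study's tables).  Entries equal to ``sentinel_ct`` are treated as
    sentinel (no amplification).
    """
    long = ct_frame.stack().rename("ct").reset_index()
    long.columns = ["gene", "cell_type", "ct"]
    frame = long.assign(all_sentinel=long["ct"] >= sentinel_ct)
    frame = _derive_quantities(frame, reference_ct, ct_cutoff)
    ref = ReferenceModel(
        gene=reference_gene,
        grand_mean_ct=reference_ct,
        per_cell_ct={c: reference_ct for c in ct_frame.columns},
    )
    return ExpressionProfile(data=frame, reference=ref, ct_cutoff=ct_cutoff)


def profile_from_units(
    units_frame: pd.DataFrame,
    reference_ct: float = REFERENCE_CT,
    ct_cutoff: float = CUTOFF_CT,
    sentinel_ct: float = 40.0,
) -> ExpressionProfile:
    """Build a profile from a gene x cell-type matrix of arbitrary units
    (``2**-Ct * 1e12``); zero units map to the sentinel Ct."""
    ct_frame = units_frame.map(lambda u: ct_from_units(u, sentinel_ct=sentinel_ct))
    return profile_from_normalized_ct(
        ct_frame, reference_ct=reference_ct, ct_cutoff=ct_cutoff, sentinel_ct=sentinel_ct
    )
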