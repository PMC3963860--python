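"""Reading, validation and replicate aggregation of TaqMan-array Ct tables.

The input dialect is a UTF-8 tab-separated long format, one observation per
row, with header ``assay_id  gene_symbol  cell_type  replicate  ct``.  Wells
that gave no amplification are exported with an empty or ``Undetermined`` Ct
field and are recorded at a sentinel cycle threshold (40 by convention).  A
companion catalog TSV (``assay_id  gene_symbol  category``) assigns every
assay to one of the panel categories (GPCR, housekeeping, LANCL, other).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CtTableError",
    "CtFormatError",
    "CatalogError",
    "CtParseError",
    "CATEGORIES",
    "SENTINEL_CT",
    "UNDETERMINED_TOKENS",
    "CtDataset",
    "MeanCtMatrix",
    "read_catalog",
    "read_ct_table",
    "write_ct_table",
    "merge_replicates",
]

CATEGORIES = frozenset({"GPCR", "housekeeping", "LANCL", "other"})

#: Default sentinel cycle threshold assigned to wells with no amplification.
SENTINEL_CT = 40.0

#: Ct-field tokens interpreted as "no amplification".
UNDETERMINED_TOKENS = frozenset({"", "Undetermined", "undetermined", "NA"})

_OBS_COLUMNS = ["assay_id", "gene_symbol", "cell_type", "replicate", "ct"]
_CATALOG_COLUMNS = ["assay_id", "gene_symbol", "category"]


class CtTableError(ValueError):
    """Base error for malformed Ct inputs."""


class CtFormatError(CtTableError):
    """Missing columns or duplicated replicate keys."""


class CatalogError(CtTableError):
    """Unknown assay ids, duplicate catalog entries or bad categories."""


class CtParseError(CtTableError):
    """Non-numeric Ct values other than the undetermined token."""


@dataclass
class CtDataset:
    """Replicate-level Ct observations joined with the assay catalog.

    ``observations`` columns: assay_id, gene_symbol, cell_type, replicate,
    ct, is_sentinel.  Sentinel observations carry exactly ``sentinel_ct``.
    """

    observations: pd.DataFrame
    catalog: pd.DataFrame
    sentinel_ct: float = SENTINEL_CT

    def __post_init__(self) -> None:
        obs = self.observations
        missing = [c for c in _OBS_COLUMNS + ["is_sentinel"] if c not in obs.columns]
        if missing:
            raise CtFormatError(f"observation columns missing: {missing}")
        if (obs["ct"] <= 0).any():
            raise CtTableError("Ct values must be positive")
        bad = obs.loc[obs["is_sentinel"], "ct"] != self.sentinel_ct
        if bad.any():
            raise CtTableError("sentinel-flagged observations must equal the sentinel Ct")
        unknown = set(obs["assay_id"]) - set(self.catalog["assay_id"])
        if unknown:
            raise CatalogError(f"assay ids absent from catalog: {sorted(unknown)[:5]}")

    def genes(self, category: str | None = None) -> list[str]:
        cat = self.catalog
        if category is not None:
            cat = cat[cat["category"] == category]
        return sorted(cat["gene_symbol"].unique())

    @property
    def cell_types(self) -> list[str]:
        return list(pd.unique(self.observations["cell_type"]))


@dataclass
class MeanCtMatrix:
    """Per (gene, cell type) replicate summary.

    ``data`` columns: gene_symbol, cell_type, mean_ct, sd_ct, n_replicates,
    all_sentinel, mixed_detection.  Means and sample standard deviations are
    taken on the Ct (log) scale over non-sentinel replicates; all-sentinel
    entries carry the sentinel value itself.
    """

    data: pd.DataFrame
    sentinel_ct: float = SENTINEL_CT
    catalog: pd.DataFrame | None = None

    def ct_matrix(self) -> pd.DataFrame:
        """Mean Ct as a gene x cell-type matrix."""
        return self.data.pivot(index="gene_symbol", columns="cell_type", values="mean_ct")

    def sentinel_matrix(self) -> pd.DataFrame:
        return self.data.pivot(
            index="gene_symbol", columns="cell_type", values="all_sentinel"
        )

    def genes(self, category: str | None = None) -> list[str]:
        if category is None or self.catalog is None:
            return sorted(self.data["gene_symbol"].unique())
        keep = set(self.catalog.loc[self.catalog["category"] == category, "gene_symbol"])
        return sorted(g for g in self.data["gene_symbol"].unique() if g in keep)


def read_catalog(path: str | Path | io.TextIOBase) -> pd.DataFrame:
    catalog = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _CATALOG_COLUMNS if c not in catalog.columns]
    if missing:
        raise CtFormatError(f"catalog columns missing: {missing}")
    if catalog["assay_id"].duplicated().any():
        dupes = catalog.loc[catalog["assay_id"].duplicated(), "assay_id"].tolist()
        raise CatalogError(f"duplicate assay ids in catalog: {dupes[:5]}")
    bad = set(catalog["category"]) - CATEGORIES
    if bad:
        raise CatalogError(f"unknown categories: {sorted(bad)}")
    return catalog[_CATALOG_COLUMNS]


def read_ct_table(
    path: str | Path | io.TextIOBase,
    catalog_path: str | Path | io.TextIOBase,
    sentinel_ct: float = SENTINEL_CT,
) -> CtDataset:
    """Read a long-format Ct TSV and its catalog into a :class:`CtDataset`.

    Empty or ``Undetermined`` Ct fields become sentinel observations at
    ``sentinel_ct``.  Duplicate (assay, cell type, replicate) rows and assay
    ids absent from the catalog are rejected.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _OBS_COLUMNS if c not in raw.columns]
    if missing:
        raise CtFormatError(f"Ct table columns missing: {missing}")
    raw = raw[_OBS_COLUMNS].copy()

    key = ["assay_id", "cell_type", "replicate"]
    if raw.duplicated(subset=key).any():
        dupes = raw.loc[raw.duplicated(subset=key), key].astype(str).agg("/".join, axis=1)
        raise CtFormatError(f"duplicated replicate keys: {dupes.tolist()[:5]}")

    is_sentinel = raw["ct"].str.strip().isin(UNDETERMINED_TOKENS)
    ct = pd.to_numeric(raw["ct"].where(~is_sentinel), errors="coerce")
    unparsable = ct.isna() & ~is_sentinel
    if unparsable.any():
        bad = raw.loc[unparsable, "ct"].tolist()
        raise CtParseError(f"non-numeric Ct values: {bad[:5]}")
    ct = ct.where(~is_sentinel, sentinel_ct)

    obs = raw.drop(columns="ct").assign(
        replicate=pd.to_numeric(raw["replicate"], errors="raise").astype(int),
        ct=ct.astype(float),
        is_sentinel=is_sentinel.to_numpy(),
    )
    catalog = read_catalog(catalog_path)
    return CtDataset(observations=obs, catalog=catalog, sentinel_ct=sentinel_ct)


def write_ct_table(
    dataset: CtDataset,
    path: str | Path | io.TextIOBase,
    catalog_path: str | Path | io.TextIOBase | None = None,
) -> None:
    """Write a dataset back to the long-format TSV dialect read by
    :func:`read_ct_table`; sentinel observations are exported as
    ``Undetermined`` so the round trip is exact."""
    obs = dataset.observations.copy()
    ct_text = obs["ct"].map(lambda v: format(v, ".17g"))  # lossless round trip
    obs["ct"] = np.where(obs["is_sentinel"], "Undetermined", ct_text)
    obs[_OBS_COLUMNS].to_csv(path, sep="\t", index=False)
    if catalog_path is not None:
        dataset.catalog.to_csv(catalog_path, sep="\t", index=False)


def merge_replicates(dataset: CtDataset) -> MeanCtMatrix:
    """Collapse replicates to per-(gene, cell type) mean and sample sd.

    Aggregation is by gene symbol, so genes spotted on several wells (the
    18S rRNA quadruplicate on the array) pool all their observations into a
    single replicate set.  Sentinel replicates are excluded from the mean;
    if every replicate is sentinel the mean is the sentinel value and the
    all-sentinel flag is set; a mix of detected and sentinel replicates is
    flagged as mixed detection.
    """
    obs = dataset.observations
    if obs.empty:
        raise CtTableError("empty dataset")
    gene_map = dict(zip(dataset.catalog["assay_id"], dataset.catalog["gene_symbol"]))
    obs = obs.assign(gene_symbol=obs["assay_id"].map(gene_map))

    rows = []
    for (gene, cell), grp in obs.groupby(["gene_symbol", "cell_type"], sort=True):
        numeric = grp.loc[~grp["is_sentinel"], "ct"]
        n = len(grp)
        if numeric.empty:
            rows.append((gene, cell, dataset.sentinel_ct, 0.0, n, True, False))
        else:
            mean = float(numeric.mean())
            sd = float(numeric.std(ddof=1)) if len(numeric) > 1 else 0.0
            mixed = len(numeric) < n
            rows.append((gene, cell, mean, sd, n, False, mixed))
    data = pd.DataFrame(
        rows,
        columns=[
            "gene_symbol", "cell_type", "mean_ct", "sd_ct",
            "n_replicates", "all_sentinel", "mixed_detection",
        ],
    )
    return MeanCtMatrix(data=data, sentinel_ct=dataset.sentinel_ct, catalog=dataset.catalog)
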