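"""Descriptive repertoire analyses: top-expressed genes, the common core,
cell-type specificity groups and single-cell-type markers.

Specificity groups formalize the study's qualitative subgroup assignments.
A group is a proper, non-empty subset S of the cell types (written with the
one-letter codes T, O, U, N, H for TG1, OB1, U-87 MG, f-NSC and astrocytes)
plus a direction.  A gene belongs to S in the *over* direction when it is
called expressed (Ct at or below the cutoff) in every cell type of S and is
either silent in every cell type outside S, or at least ``f``-fold more
abundant in its weakest in-group cell type than in its strongest out-group
cell type.  The *under* direction is the mirror image.  Each gene receives
at most one maximal code per direction (largest qualifying S; ties broken by
the in/out abundance ratio, then by the canonical code string).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import ExpressionProfile
from .reference_data import CELL_LETTERS, CUTOFF_CT, LETTER_ORDER

__all__ = [
    "SpecificityGroup",
    "letter_map_for",
    "canonical_code",
    "top_expressed",
    "core_set",
    "classify_specificity",
    "cell_markers",
]


@dataclass(frozen=True)
class SpecificityGroup:
    """A cell-type subset with a direction and its member genes."""

    code: str
    direction: str  # "over" | "under"
    members: frozenset[str]
    cell_types: frozenset[str]
    fold_margin: float
    ct_cutoff: float


def letter_map_for(cell_types: list[str]) -> dict[str, str]:
    """One-letter codes for the given cell types.

    Known study labels get their conventional letters (T, O, U, N, H); other
    labels fall back to their first character, which must be unambiguous.
    """
    mapping: dict[str, str] = {}
    for cell in cell_types:
        letter = CELL_LETTERS.get(cell, cell[0].upper())
        if letter in mapping.values():
            raise ValueError(f"ambiguous one-letter code {letter!r} for {cell!r}")
        mapping[cell] = letter
    return mapping


def canonical_code(cells: frozenset[str], letters: dict[str, str]) -> str:
    """Join the subset's letters in the canonical N, T, O, U, H order."""
    chosen = {letters[c] for c in cells}
    known = [l for l in LETTER_ORDER if l in chosen]
    extra = sorted(chosen - set(LETTER_ORDER))
    return "".join(known + extra)


def top_expressed(profiles: ExpressionProfile, ct_max: float = 25.0) -> pd.DataFrame:
    """Per cell type, the genes with aligned Ct at or below ``ct_max``,
    sorted by ascending Ct (the most expressed first)."""
    data = profiles.data
    keep = data[(data["ct"] <= ct_max) & ~data["all_sentinel"]]
    cols = ["cell_type", "gene", "ct", "delta_ct", "fold_below_ref", "units"]
    return (
        keep.sort_values(["cell_type", "ct", "gene"])
        .loc[:, cols]
        .reset_index(drop=True)
    )


def core_set(profiles: ExpressionProfile, ct_cutoff: float | None = None) -> frozenset[str]:
    """Genes expressed above the cutoff in every cell type."""
    cutoff = profiles.ct_cutoff if ct_cutoff is None else ct_cutoff
    ct = profiles.ct_matrix()
    sentinel = profiles.data.pivot(index="gene", columns="cell_type", values="all_sentinel")
    ok = (ct <= cutoff) & ~sentinel.astype(bool)
    return frozenset(ok.index[ok.all(axis=1)])


def classify_specificity(
    profiles: ExpressionProfile,
    f: float = 3.0,
    ct_cutoff: float | None = None,
    letters: dict[str, str] | None = None,
) -> list[SpecificityGroup]:
    """Assign genes to maximal over-/under-expression specificity groups."""
    if f <= 1.0:
        raise ValueError("fold margin f must exceed 1")
    cutoff = profiles.ct_cutoff if ct_cutoff is None else ct_cutoff
    cells = sorted(profiles.cell_types)
    if len(cells) < 2:
        raise ValueError("specificity classification needs at least two cell types")
    letters = letters or letter_map_for(cells)

    units = profiles.units_matrix()[cells]
    expressed = profiles.above_cutoff_matrix()[cells].astype(bool)
    expressed &= profiles.ct_matrix()[cells] <= cutoff

    subsets = [
        frozenset(combo)
        for r in range(1, len(cells))
        for combo in itertools.combinations(cells, r)
    ]
    # Pre-resolve each subset to index arrays and its canonical code so the
    # per-gene loop runs on plain numpy values.
    cell_index = {c: i for i, c in enumerate(cells)}
    prepared = []
    for subset in subsets:
        inside = np.array(sorted(cell_index[c] for c in subset), dtype=int)
        outside = np.array(
            sorted(i for c, i in cell_index.items() if c not in subset), dtype=int
        )
        prepared.append((subset, inside, outside, canonical_code(subset, letters)))

    units_arr = units.to_numpy(dtype=float)
    expr_arr = expressed.to_numpy(dtype=bool)

    def _ratio(u: np.ndarray, e: np.ndarray, ins: np.ndarray, outs: np.ndarray) -> float | None:
        if not e[ins].all():
            return None
        if not e[outs].any():
            return float("inf")
        ratio = float(u[ins].min()) / float(u[outs].max())
        return ratio if ratio >= f else None

    assignments: dict[tuple[str, str], set[str]] = {}
    meta: dict[tuple[str, str], frozenset[str]] = {}
    for gi, gene in enumerate(units.index):
        u = units_arr[gi]
        e = expr_arr[gi]
        chosen: dict[str, frozenset[str]] = {}
        for direction in ("over", "under"):
            best: tuple[int, float, str] | None = None
            best_subset: frozenset[str] | None = None
            for subset, inside, outside, code in prepared:
                if direction == "over":
                    ratio = _ratio(u, e, inside, outside)
                else:
                    ratio = _ratio(u, e, outside, inside)
                if ratio is None:
                    continue
                # maximal size, then higher ratio, then canonical code order
                key = (len(subset), ratio, code)
                if best is None or (key[0], key[1]) > (best[0], best[1]) or (
                    key[0] == best[0] and key[1] == best[1] and code < best[2]
                ):
                    best = key
                    best_subset = subset
            if best_subset is not None:
                chosen[direction] = best_subset
        # A gene may hold an over- and an under-code only when they are
        # disjoint; on overlap the under call is dropped — the over call
        # rests on the cell types where the gene is actually expressed.
        if "over" in chosen and "under" in chosen and chosen["over"] & chosen["under"]:
            del chosen["under"]
        for direction, subset in chosen.items():
            code = canonical_code(subset, letters)
            assignments.setdefault((code, direction), set()).add(gene)
            meta[(code, direction)] = subset

    groups = [
        SpecificityGroup(
            code=code,
            direction=direction,
            members=frozenset(genes),
            cell_types=meta[(code, direction)],
            fold_margin=f,
            ct_cutoff=cutoff,
        )
        for (code, direction), genes in sorted(assignments.items())
    ]
    return groups


def cell_markers(
    profiles: ExpressionProfile,
    f: float = 3.0,
    ct_cutoff: float | None = None,
    letters: dict[str, str] | None = None,
) -> dict[str, frozenset[str]]:
    """Single-cell-type marker genes: the singleton over-direction groups."""
    groups = classify_specificity(profiles, f=f, ct_cutoff=ct_cutoff, letters=letters)
    markers: dict[str, frozenset[str]] = {cell: frozenset() for cell in profiles.cell_types}
    for group in groups:
        if group.direction == "over" and len(group.cell_types) == 1:
            (cell,) = group.cell_types
            markers[cell] = group.members
    return markers
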