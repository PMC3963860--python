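"""Synthetic data with known ground truth for every pipeline stage.

The raw array exports behind the source study were never deposited, so this
module generates datasets that emulate its design: a 384-well TaqMan panel
of 356 GPCR assays plus 14 housekeeping assays measured in five neural cell
types (triplicates for the fetal neural stem cells, duplicates elsewhere),
with additive Gaussian replicate noise on the Ct scale (sd 0.3 cycles, the
replicate spread visible in the study's tables), genes without amplification
emitted at the sentinel Ct of 40 in every replicate, a planted stable
reference gene (RPLP0 at 21.12 cycles), planted cell-type specificity
groups, and a planted cell-type correlation structure in which the two
glioblastoma stem-like lines resemble each other, the astrocytes resemble
the U-87 line, and the fetal neural stem cells sit between the two blocks
but closer to the stem-like lines.

Planted specificity genes are silent (below the expression cutoff) outside
their group, mirroring the dominant pattern in the study ("expressed above
the cutoff only in ..."), and their true in/out abundance ratio is at least
the configured fold separation.

:func:`generate_study_like_dataset` additionally reproduces the study's
expression bookkeeping as ground truth: 138 of 356 GPCRs expressed in at
least one cell type, 26 in all five, and per-cell-type expressed counts of
90 (OB1), 83 (TG1), 77 (f-NSC), 61 (HA) and 57 (U-87).

For the proteomics stages, :func:`generate_protein_set` writes random
topology-annotated protein records together with an independent brute-force
tryptic digest (no code shared with :mod:`gpcrprofile.digest`, masses from
:mod:`pyteomics`), and :func:`generate_spectral_counts` draws Poisson
spectrum counts with mean proportional to transcript units times expected
peptide count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

from .digest import ProteinRecord, predict_detectable
from .concordance import SpectralCountTable
from .normalization import ExpressionProfile
from .qpcr_io import CtDataset, MeanCtMatrix
from .reference_data import CELL_LETTERS, CUTOFF_CT, REFERENCE_CT, REFERENCE_GENE

__all__ = [
    "SimulationError",
    "PlantedGroup",
    "SimConfig",
    "GroundTruth",
    "SyntheticProtein",
    "generate_ct_dataset",
    "generate_study_like_dataset",
    "generate_protein_set",
    "generate_spectral_counts",
    "STUDY_EXPRESSED_PATTERNS",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedGroup:
    """A planted specificity group: genes expressed in ``cells`` only.

    ``fold_separation`` is the minimum true in/out abundance ratio; out-group
    cell types are additionally placed below the expression cutoff.
    ``direction="under"`` plants the mirror image (silent inside, expressed
    outside).
    """

    cells: tuple[str, ...]
    direction: str = "over"
    n_genes: int = 5
    fold_separation: float = 4.0


def _default_groups() -> list[PlantedGroup]:
    # Emulates the study's reported subgroup structure: a GSC group (TO),
    # a stemness group (NTO), a cancer group (TOU), single-cell-type
    # markers for HA / f-NSC / U87, and one under-expressed GSC gene.
    return [
        PlantedGroup(("TG1", "OB1"), "over", 8),
        PlantedGroup(("TG1", "OB1", "NSC"), "over", 16),
        PlantedGroup(("TG1", "OB1", "U87"), "over", 2),
        PlantedGroup(("HA",), "over", 2),
        PlantedGroup(("NSC",), "over", 2),
        PlantedGroup(("U87",), "over", 1),
        PlantedGroup(("TG1", "OB1"), "under", 1),
    ]


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    Counts, noise, replicate design and the sentinel follow the source
    study's assay (356 GPCR assays, 14 housekeeping genes, Ct noise sd 0.3
    cycles, sentinel Ct 40, triplicates for the neural stem cells and
    duplicates elsewhere).
    """

    n_gpcr_assays: int = 356
    n_housekeeping: int = 14
    cell_types: tuple[str, ...] = ("TG1", "OB1", "NSC", "HA", "U87")
    replicates: int | dict[str, int] | None = None
    ct_noise_sd: float = 0.3
    sentinel_ct: float = 40.0
    ct_cutoff: float = CUTOFF_CT
    planted_groups: list[PlantedGroup] = field(default_factory=_default_groups)
    n_core_genes: int = 26
    absent_fraction: float = 0.35
    hk_cell_sd: float = 1.2
    signature_sd: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gpcr_assays <= 0 or self.n_housekeeping <= 0:
            raise SimulationError("counts must be positive")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise SimulationError("duplicate cell-type labels")
        if self.ct_noise_sd < 0:
            raise SimulationError("ct_noise_sd must be >= 0")
        planted: set[str] = set()
        total = 0
        for group in self.planted_groups:
            unknown = set(group.cells) - set(self.cell_types)
            if unknown:
                raise SimulationError(f"planted group uses unknown cells {sorted(unknown)}")
            if group.direction not in {"over", "under"}:
                raise SimulationError(f"bad direction {group.direction!r}")
            total += group.n_genes
        if total + self.n_core_genes > self.n_gpcr_assays:
            raise SimulationError("planted genes exceed the panel size")

    def replicates_for(self, cell: str) -> int:
        if isinstance(self.replicates, int):
            return self.replicates
        if isinstance(self.replicates, dict):
            return self.replicates.get(cell, 2)
        # study default: triplicates for the neural stem cells
        return 3 if CELL_LETTERS.get(cell, "?") == "N" else 2


@dataclass
class GroundTruth:
    """What the generator planted, for checking downstream recovery."""

    true_ct: pd.DataFrame  # genes x cell types, sentinel for absent genes
    expressed: pd.DataFrame  # genes x cell types, boolean (true Ct <= cutoff)
    group_membership: dict[str, tuple[tuple[str, ...], str]]
    reference_gene: str
    absent_genes: frozenset[str]
    housekeeping_genes: tuple[str, ...]
    sentinel_ct: float
    ct_cutoff: float

    def genes_of_group(self, cells: tuple[str, ...], direction: str = "over") -> frozenset[str]:
        want = (tuple(sorted(cells)), direction)
        return frozenset(
            g
            for g, (cs, d) in self.group_membership.items()
            if (tuple(sorted(cs)), d) == want
        )


# ---------------------------------------------------------------------------
# Ct-level generation


def _housekeeping_truth(
    rng: np.random.Generator, n_hk: int, n_cells: int, hk_cell_sd: float
) -> np.ndarray:
    """True Ct of the housekeeping panel (first row = planted reference).

    The reference is perfectly flat across cell types; every other
    housekeeping gene's cell-type effects are centred and rescaled to an
    *exact* between-cell-type standard deviation of ``hk_cell_sd`` cycles,
    so the planted stability ordering (reference strictly most stable) is a
    property of the truth, not of a lucky draw.
    """
    base = rng.uniform(18.0, 26.0, size=n_hk)
    base[0] = REFERENCE_CT
    offsets = rng.standard_normal((n_hk, n_cells))
    if hk_cell_sd > 0 and n_cells > 1:
        offsets -= offsets.mean(axis=1, keepdims=True)
        sd = offsets.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        offsets = offsets / sd * hk_cell_sd
    else:
        offsets[:] = 0.0
    offsets[0, :] = 0.0
    return base[:, None] + offsets


def _cell_loadings(cells: tuple[str, ...]) -> np.ndarray:
    """Factor loadings (GSC factor, differentiated factor, own noise) that
    plant the study's cell-type similarity structure."""
    rows = []
    for cell in cells:
        letter = CELL_LETTERS.get(cell, "?")
        if letter in ("T", "O"):
            rows.append((math.sqrt(0.85), 0.0, math.sqrt(0.15)))
        elif letter in ("H", "U"):
            rows.append((0.0, math.sqrt(0.85), math.sqrt(0.15)))
        elif letter == "N":
            rows.append((0.60, 0.25, math.sqrt(1 - 0.60**2 - 0.25**2)))
        else:
            rows.append((0.0, 0.0, 1.0))
    return np.array(rows)


def _signature_offsets(
    rng: np.random.Generator, cells: tuple[str, ...], n_genes: int, sd: float
) -> np.ndarray:
    """Per-gene cell-type offsets (n_genes x n_cells) with the planted
    correlation structure, clipped so expression calls are never flipped."""
    load = _cell_loadings(cells)
    shared = rng.standard_normal((n_genes, 2))
    own = rng.standard_normal((n_genes, len(cells)))
    z = shared @ load[:, :2].T + own * load[:, 2]
    return np.clip(z * sd, -1.3, 1.3)


def _observations_from_truth(
    true_ct: pd.DataFrame,
    absent: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    catalog: pd.DataFrame,
) -> CtDataset:
    rows = []
    cells = list(true_ct.columns)
    assay_of = dict(zip(catalog["gene_symbol"], catalog["assay_id"]))
    for gene in true_ct.index:
        for cell in cells:
            n_rep = config.replicates_for(cell)
            if n_rep <= 0:
                raise SimulationError("replicate counts must be positive")
            if bool(absent.loc[gene, cell]):
                for r in range(1, n_rep + 1):
                    rows.append((assay_of[gene], gene, cell, r, config.sentinel_ct, True))
            else:
                mu = float(true_ct.loc[gene, cell])
                noise = rng.normal(0.0, config.ct_noise_sd, size=n_rep)
                for r, eps in enumerate(noise, start=1):
                    rows.append((assay_of[gene], gene, cell, r, mu + float(eps), False))
    obs = pd.DataFrame(
        rows,
        columns=["assay_id", "gene_symbol", "cell_type", "replicate", "ct", "is_sentinel"],
    )
    return CtDataset(observations=obs, catalog=catalog, sentinel_ct=config.sentinel_ct)


def _catalog_for(genes_gpcr: list[str], genes_hk: list[str]) -> pd.DataFrame:
    rows = []
    for i, gene in enumerate(genes_gpcr, start=1):
        rows.append((f"A{i:04d}", gene, "GPCR"))
    for i, gene in enumerate(genes_hk, start=1):
        rows.append((f"H{i:04d}", gene, "housekeeping"))
    return pd.DataFrame(rows, columns=["assay_id", "gene_symbol", "category"])


def generate_ct_dataset(config: SimConfig | None = None) -> tuple[CtDataset, GroundTruth]:
    """Generate a replicate-level Ct dataset with planted ground truth.

    Replicate Ct values are the true Ct plus independent Gaussian noise;
    genes planted absent are emitted at the sentinel Ct in all replicates;
    housekeeping genes vary little between cell types and the planted
    reference (RPLP0) not at all.  Deterministic for a fixed ``rng_seed``.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.rng_seed)
    cells = config.cell_types
    n_cells = len(cells)

    hk_genes = [REFERENCE_GENE] + [f"HK{i:02d}" for i in range(1, config.n_housekeeping)]
    n_planted = sum(g.n_genes for g in config.planted_groups)
    n_background = config.n_gpcr_assays - config.n_core_genes - n_planted
    n_absent = int(round(config.absent_fraction * n_background))

    gene_names = [f"GPCR{i:04d}" for i in range(1, config.n_gpcr_assays + 1)]
    true_ct = pd.DataFrame(
        np.full((len(gene_names) + len(hk_genes), n_cells), config.sentinel_ct),
        index=gene_names + hk_genes,
        columns=list(cells),
    )
    absent = pd.DataFrame(False, index=true_ct.index, columns=true_ct.columns)
    membership: dict[str, tuple[tuple[str, ...], str]] = {}

    cursor = 0

    # core genes, expressed everywhere with the planted signature structure
    core = gene_names[cursor : cursor + config.n_core_genes]
    cursor += config.n_core_genes
    base = rng.uniform(24.5, 29.0, size=len(core))
    offs = _signature_offsets(rng, cells, len(core), config.signature_sd)
    true_ct.loc[core, :] = base[:, None] + offs

    # planted specificity groups
    for gi, group in enumerate(config.planted_groups):
        names = gene_names[cursor : cursor + group.n_genes]
        cursor += group.n_genes
        silent_ct = config.ct_cutoff + 1.8  # comfortably below the cutoff call
        for gene in names:
            membership[gene] = (group.cells, group.direction)
            expressed_base = float(rng.uniform(24.5, 28.5))
            silenced = max(expressed_base + math.log2(group.fold_separation), silent_ct)
            for cell in cells:
                inside = cell in group.cells
                hot = inside if group.direction == "over" else not inside
                true_ct.loc[gene, cell] = expressed_base if hot else silenced

    # background genes: absent (sentinel) or expressed below the cutoff
    background = gene_names[cursor:]
    absent_genes = background[:n_absent]
    low_genes = background[n_absent:]
    absent.loc[absent_genes, :] = True
    true_ct.loc[low_genes, :] = rng.uniform(
        config.ct_cutoff + 2.0, config.sentinel_ct - 2.0, size=(len(low_genes), n_cells)
    )

    true_ct.loc[hk_genes, :] = _housekeeping_truth(
        rng, len(hk_genes), n_cells, config.hk_cell_sd
    )

    catalog = _catalog_for(gene_names, hk_genes)
    dataset = _observations_from_truth(true_ct, absent, config, rng, catalog)
    truth = GroundTruth(
        true_ct=true_ct,
        expressed=(true_ct <= config.ct_cutoff) & ~absent,
        group_membership=membership,
        reference_gene=REFERENCE_GENE,
        absent_genes=frozenset(absent_genes),
        housekeeping_genes=tuple(hk_genes),
        sentinel_ct=config.sentinel_ct,
        ct_cutoff=config.ct_cutoff,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# study-like dataset: the published expression bookkeeping as ground truth

#: Expression patterns (cell subsets and gene counts) that reproduce the
#: study's reported per-cell-type expressed-gene counts: column sums give
#: OB1 90, TG1 83, f-NSC 77, HA 61, U87 57; 26 genes in all five; union 138.
STUDY_EXPRESSED_PATTERNS: list[tuple[tuple[str, ...], int]] = [
    (("TG1", "OB1", "f-NSC", "HA", "U87"), 26),
    (("TG1", "OB1", "f-NSC"), 19),
    (("TG1", "OB1"), 24),
    (("TG1", "OB1", "U87"), 6),
    (("TG1", "OB1", "f-NSC", "U87"), 4),
    (("f-NSC",), 12),
    (("OB1", "f-NSC"), 6),
    (("HA", "U87"), 12),
    (("HA",), 9),
    (("U87",), 5),
    (("f-NSC", "HA"), 6),
    (("TG1", "OB1", "HA"), 4),
    (("OB1",), 1),
    (("f-NSC", "HA", "U87"), 4),
]


def generate_study_like_dataset(
    seed: int = 0,
    ct_noise_sd: float = 0.3,
) -> tuple[CtDataset, GroundTruth]:
    """A dataset whose true expression bookkeeping matches the study's.

    The expressed/silent pattern of each gene follows
    :data:`STUDY_EXPRESSED_PATTERNS` (by construction: 138 GPCRs expressed
    in at least one cell type, 26 in all five, per-cell-type counts 90, 83,
    77, 61 and 57), expressed Ct values carry the planted cell-type
    correlation structure, and the remaining 218 GPCRs are silent or absent
    everywhere.  Everything else (noise, replicates, housekeeping panel)
    follows :class:`SimConfig` defaults.
    """
    cells = ("TG1", "OB1", "f-NSC", "HA", "U87")
    config = SimConfig(
        cell_types=cells,
        ct_noise_sd=ct_noise_sd,
        planted_groups=[],
        n_core_genes=0,
        rng_seed=seed,
    )
    rng = np.random.default_rng(seed)

    n_expressed = sum(n for _p, n in STUDY_EXPRESSED_PATTERNS)
    hk_genes = [REFERENCE_GENE] + [f"HK{i:02d}" for i in range(1, config.n_housekeeping)]
    gene_names = [f"GPCR{i:04d}" for i in range(1, config.n_gpcr_assays + 1)]

    true_ct = pd.DataFrame(
        np.full((len(gene_names) + len(hk_genes), len(cells)), config.sentinel_ct),
        index=gene_names + hk_genes,
        columns=list(cells),
    )
    absent = pd.DataFrame(False, index=true_ct.index, columns=true_ct.columns)
    membership: dict[str, tuple[tuple[str, ...], str]] = {}

    base = rng.uniform(25.0, 29.0, size=n_expressed)
    offsets = _signature_offsets(rng, cells, n_expressed, config.signature_sd)
    silent_low, silent_high = config.ct_cutoff + 1.8, config.sentinel_ct - 2.0

    idx = 0
    for pattern, count in STUDY_EXPRESSED_PATTERNS:
        for _ in range(count):
            gene = gene_names[idx]
            if len(pattern) < len(cells):
                membership[gene] = (pattern, "over")
            for j, cell in enumerate(cells):
                if cell in pattern:
                    true_ct.loc[gene, cell] = base[idx] + offsets[idx, j]
                else:
                    true_ct.loc[gene, cell] = float(rng.uniform(silent_low, silent_high))
            idx += 1

    never = gene_names[n_expressed:]
    n_absent = len(never) // 2
    absent.loc[never[:n_absent], :] = True
    true_ct.loc[never[n_absent:], :] = rng.uniform(
        silent_low, silent_high, size=(len(never) - n_absent, len(cells))
    )

    true_ct.loc[hk_genes, :] = _housekeeping_truth(
        rng, len(hk_genes), len(cells), config.hk_cell_sd
    )

    catalog = _catalog_for(gene_names, hk_genes)
    dataset = _observations_from_truth(true_ct, absent, config, rng, catalog)
    truth = GroundTruth(
        true_ct=true_ct,
        expressed=(true_ct <= config.ct_cutoff) & ~absent,
        group_membership=membership,
        reference_gene=REFERENCE_GENE,
        absent_genes=frozenset(never[:n_absent]),
        housekeeping_genes=tuple(hk_genes),
        sentinel_ct=config.sentinel_ct,
        ct_cutoff=config.ct_cutoff,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# protein records with an independent brute-force digest oracle

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_NON_KR = [r for r in _RESIDUES if r not in "KR"]


@dataclass
class SyntheticProtein:
    """A generated record plus the oracle's expected-peptide ground truth."""

    record: ProteinRecord
    oracle_peptides: tuple[str, ...]

    @property
    def oracle_count(self) -> int:
        return len(self.oracle_peptides)


def _oracle_expected_peptides(
    record: ProteinRecord, mass_range: tuple[float, float] = (1000.0, 3000.0)
) -> tuple[str, ...]:
    """Brute-force scan-and-split digest with the four detectability filters.

    Kept deliberately independent of :mod:`gpcrprofile.digest`: fragments are
    found by a character scan and masses come from pyteomics.
    """
    seq = record.sequence
    fragments: list[tuple[int, int, str]] = []  # 1-based start, end
    start = 0
    for i, res in enumerate(seq):
        at_cut = res in "KR" and (i + 1 < len(seq)) and seq[i + 1] != "P"
        if at_cut or i == len(seq) - 1:
            fragments.append((start + 1, i + 1, seq[start : i + 1]))
            start = i + 1

    label_of_pos: dict[int, str] = {}
    for s, e, label in record.topology:
        for p in range(s, e + 1):
            label_of_pos[p] = f"{label}:{s}-{e}"

    seen: dict[str, int] = {}
    for _s, _e, frag in fragments:
        seen[frag] = seen.get(frag, 0) + 1

    survivors = []
    for s, e, frag in fragments:
        m = _ptmass.fast_mass(frag)
        if not mass_range[0] <= m <= mass_range[1]:
            continue
        segments = {label_of_pos.get(p) for p in range(s, e + 1)}
        if len(segments) != 1:
            continue
        (segment,) = segments
        if segment is None or segment.split(":")[0] not in ("EXTRACELLULAR", "CYTOPLASMIC"):
            continue
        if any(p in record.modified_positions for p in range(s, e + 1)):
            continue
        if seen[frag] != 1:
            continue
        survivors.append(frag)
    return tuple(survivors)


def generate_protein_set(
    n: int,
    seed: int = 0,
    length_range: tuple[int, int] = (250, 700),
    kr_density: float = 0.11,
    modification_rate: float = 0.01,
) -> list[SyntheticProtein]:
    """Random topology-annotated protein records with oracle digest truth.

    Sequences are drawn over the 20 standard residues with a controlled
    lysine/arginine density; topology segments tile each sequence in a
    seven-transmembrane-like alternation of extracellular, transmembrane and
    cytoplasmic stretches; a small fraction of residues carries a
    modification annotation.
    """
    if n < 1:
        raise SimulationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    proteins = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        is_kr = rng.random(length) < kr_density
        kr = rng.choice(list("KR"), size=length)
        other = rng.choice(_NON_KR, size=length)
        seq = "".join(np.where(is_kr, kr, other))

        topology: list[tuple[int, int, str]] = []
        pos = 1
        labels = ["EXTRACELLULAR", "TRANSMEMBRANE", "CYTOPLASMIC", "TRANSMEMBRANE"]
        li = 0
        while pos <= length:
            label = labels[li % 4]
            if label == "TRANSMEMBRANE":
                span = int(rng.integers(18, 29))
            else:
                span = int(rng.integers(15, 90))
            end = min(pos + span - 1, length)
            topology.append((pos, end, label))
            pos = end + 1
            li += 1

        modified = frozenset(
            int(p) + 1 for p in np.nonzero(rng.random(length) < modification_rate)[0]
        )
        record = ProteinRecord(
            accession=f"SYN{i:04d}",
            sequence=seq,
            topology=topology,
            modified_positions=modified,
        )
        proteins.append(
            SyntheticProtein(record=record, oracle_peptides=_oracle_expected_peptides(record))
        )
    return proteins


# ---------------------------------------------------------------------------
# spectral counts


def generate_spectral_counts(
    profiles: ExpressionProfile,
    expected_counts: dict[str, int],
    seed: int = 0,
    rate_per_unit_peptide: float = 8.0 / (20000.0 * 5.0),
    leak_probability: float = 0.02,
) -> SpectralCountTable:
    """Draw a spectral-count table from transcript profiles and digests.

    For each (protein, cell type), the spectrum count is Poisson with mean
    ``rate_per_unit_peptide * units * expected peptides``.  Proteins failing
    the joint detectability rule are emitted as not detected except for a
    small leak probability; proteins with no expected peptides are always
    not detected.  Unique-peptide counts are a saturating function of the
    spectrum count, capped at the expected peptide count.
    """
    genes = set(profiles.data["gene"])
    missing = set(expected_counts) - genes
    if missing:
        raise SimulationError(f"expected-count keys not in profiles: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    rows = []
    for accession in sorted(expected_counts):
        expected = expected_counts[accession]
        for cell in profiles.cell_types:
            units = float(profiles.lookup(accession, cell)["units"])
            detected = False
            spectra = 0
            if expected > 0:
                if predict_detectable(expected, units):
                    spectra = int(rng.poisson(rate_per_unit_peptide * units * expected))
                    detected = spectra > 0
                elif rng.random() < leak_probability:
                    spectra = 1 + int(rng.poisson(1.0))
                    detected = True
            if detected:
                peptides = min(expected, 1 + int(rng.binomial(max(spectra - 1, 0), 0.35)))
                rows.append((accession, cell, float(peptides), float(spectra)))
            else:
                rows.append((accession, cell, np.nan, np.nan))
    frame = pd.DataFrame(rows, columns=["accession", "cell_type", "peptides", "spectra"])
    return SpectralCountTable(data=frame)
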