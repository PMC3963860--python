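"""In-silico tryptic digestion and MS-detectability prediction for GPCRs.

A peptide is counted as *expected detectable* when, after a fully specific
tryptic digest (cleavage C-terminal to K or R, suppressed before proline,
no missed cleavage), it

1. has a monoisotopic mass between 1000 and 3000 Da (inclusive),
2. lies entirely within a single extracellular or cytoplasmic topology
   segment (transmembrane and unannotated stretches are assumed shielded
   from the protease and from ionization-friendly behaviour),
3. contains no annotated post-translationally modified residue, and
4. is unique (by default: occurs exactly once among the protein's own
   tryptic fragments; optionally also absent from a background proteome).

The joint transcript/protein rule observed in the source data is exposed as
:func:`predict_detectable`: a receptor is expected in a shotgun membrane
proteomics experiment when it offers strictly more than five such peptides
and its transcript exceeds 20000 arbitrary expression units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
import pandas as pd

__all__ = [
    "DigestError",
    "TopologyError",
    "MONOISOTOPIC_MASSES",
    "AVERAGE_MASSES",
    "WATER_MONO",
    "WATER_AVG",
    "EXTRACELLULAR",
    "TRANSMEMBRANE",
    "CYTOPLASMIC",
    "ACCESSIBLE_LABELS",
    "ProteinRecord",
    "PeptideCandidate",
    "DigestReport",
    "peptide_mass",
    "tryptic_digest",
    "count_expected_peptides",
    "predict_detectable",
    "read_protein_records",
]


class DigestError(ValueError):
    pass


class TopologyError(DigestError):
    pass


EXTRACELLULAR = "EXTRACELLULAR"
TRANSMEMBRANE = "TRANSMEMBRANE"
CYTOPLASMIC = "CYTOPLASMIC"
ACCESSIBLE_LABELS = frozenset({EXTRACELLULAR, CYTOPLASMIC})
_TOPOLOGY_LABELS = frozenset({EXTRACELLULAR, TRANSMEMBRANE, CYTOPLASMIC})

# Monoisotopic residue masses (Da) of the 20 standard amino acids.
MONOISOTOPIC_MASSES = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
AVERAGE_MASSES = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MONO = 18.010565
WATER_AVG = 18.01528

STANDARD_RESIDUES = frozenset(MONOISOTOPIC_MASSES)


@dataclass(frozen=True)
class PeptideCandidate:
    """A tryptic fragment with 1-based inclusive parent coordinates."""

    sequence: str
    start: int
    end: int
    mass: float = 0.0
    compartment: str | None = None
    contains_modified_site: bool = False
    unique: bool = True
    missed_cleavages: int = 0


@dataclass
class ProteinRecord:
    """Sequence plus topology segments and modified-residue annotation.

    ``topology`` holds (start, end, label) with 1-based inclusive
    coordinates; segments must not overlap and need not cover the sequence
    (uncovered residues are treated as unlocalized and fail the compartment
    filter).  ``modified_positions`` are 1-based residue indices.
    """

    accession: str
    sequence: str
    topology: list[tuple[int, int, str]] = field(default_factory=list)
    modified_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise DigestError(f"{self.accession}: non-standard residues {sorted(bad)}")
        n = len(self.sequence)
        covered: set[int] = set()
        for start, end, label in self.topology:
            if label not in _TOPOLOGY_LABELS:
                raise TopologyError(f"{self.accession}: unknown label {label!r}")
            if not (1 <= start <= end <= n):
                raise TopologyError(f"{self.accession}: segment {start}-{end} out of bounds")
            span = set(range(start, end + 1))
            if covered & span:
                raise TopologyError(f"{self.accession}: overlapping segments")
            covered |= span
        out = {p for p in self.modified_positions if not 1 <= p <= n}
        if out:
            raise TopologyError(f"{self.accession}: modified positions out of bounds {sorted(out)}")

    def segment_containing(self, start: int, end: int) -> str | None:
        """Label of the single topology segment containing [start, end], or
        None if the span crosses segments or touches unannotated residues."""
        for s, e, label in self.topology:
            if s <= start and end <= e:
                return label
        return None


def peptide_mass(sequence: str, mode: str = "monoisotopic") -> float:
    """Peptide mass in Da: sum of residue masses plus one water."""
    if mode == "monoisotopic":
        table, water = MONOISOTOPIC_MASSES, WATER_MONO
    elif mode == "average":
        table, water = AVERAGE_MASSES, WATER_AVG
    else:
        raise DigestError(f"unknown mass mode {mode!r}")
    try:
        return sum(table[res] for res in sequence) + water
    except KeyError as exc:
        raise DigestError(f"non-standard residue {exc.args[0]!r}") from None


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices after which trypsin cleaves (K/R not followed by P)."""
    n = len(sequence)
    return [
        i
        for i in range(n - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def tryptic_digest(
    sequence: str,
    missed_cleavages: int = 0,
    mass_mode: str = "monoisotopic",
) -> list[PeptideCandidate]:
    """Fully specific tryptic fragments of a sequence (pre-filter).

    At zero missed cleavages the fragments tile the sequence; with up to
    ``m`` missed cleavages, concatenations of up to ``m+1`` adjacent
    fragments are also emitted.
    """
    if not sequence:
        raise DigestError("empty sequence")
    bad = set(sequence) - STANDARD_RESIDUES
    if bad:
        raise DigestError(f"non-standard residues {sorted(bad)}")
    if missed_cleavages < 0:
        raise DigestError("missed_cleavages must be >= 0")

    bounds = [0] + [i + 1 for i in cleavage_sites(sequence)] + [len(sequence)]
    peptides: list[PeptideCandidate] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for m in range(missed_cleavages + 1):
            if i + m + 1 > n_frag:
                break
            start, end = bounds[i], bounds[i + m + 1]
            peptides.append(
                PeptideCandidate(
                    sequence=sequence[start:end],
                    start=start + 1,
                    end=end,
                    mass=peptide_mass(sequence[start:end], mass_mode),
                    missed_cleavages=m,
                )
            )
    return peptides


@dataclass
class DigestReport:
    """Expected-detectable peptide count and per-filter attrition."""

    accession: str
    candidates: list[PeptideCandidate]
    expected_peptides: list[PeptideCandidate]
    failed_mass: int
    failed_compartment: int
    failed_modification: int
    failed_uniqueness: int

    @property
    def expected_count(self) -> int:
        return len(self.expected_peptides)

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)


def count_expected_peptides(
    record: ProteinRecord,
    mass_range: tuple[float, float] = (1000.0, 3000.0),
    uniqueness_db: Sequence[str] | None = None,
    mass_mode: str = "monoisotopic",
) -> DigestReport:
    """Apply the four detectability criteria to a protein's tryptic digest.

    Filters run in order mass -> compartment -> modification -> uniqueness
    and each rejected candidate is tallied against the first filter it
    fails, so the tallies plus the survivors sum to the candidate count.
    ``uniqueness_db`` optionally lists *other* protein sequences; a peptide
    occurring as a substring of any of them is not unique.
    """
    lo, hi = mass_range
    if lo > hi:
        raise DigestError("invalid mass range")
    raw = tryptic_digest(record.sequence, missed_cleavages=0, mass_mode=mass_mode)

    counts: dict[str, int] = {}
    for pep in raw:
        counts[pep.sequence] = counts.get(pep.sequence, 0) + 1

    candidates: list[PeptideCandidate] = []
    survivors: list[PeptideCandidate] = []
    failed_mass = failed_compartment = failed_modification = failed_uniqueness = 0
    for pep in raw:
        compartment = record.segment_containing(pep.start, pep.end)
        modified = any(
            p in record.modified_positions for p in range(pep.start, pep.end + 1)
        )
        unique = counts[pep.sequence] == 1
        if unique and uniqueness_db is not None:
            unique = not any(pep.sequence in other for other in uniqueness_db)
        annotated = PeptideCandidate(
            sequence=pep.sequence,
            start=pep.start,
            end=pep.end,
            mass=pep.mass,
            compartment=compartment,
            contains_modified_site=modified,
            unique=unique,
        )
        candidates.append(annotated)
        if not lo <= pep.mass <= hi:
            failed_mass += 1
        elif compartment not in ACCESSIBLE_LABELS:
            failed_compartment += 1
        elif modified:
            failed_modification += 1
        elif not unique:
            failed_uniqueness += 1
        else:
            survivors.append(annotated)
    return DigestReport(
        accession=record.accession,
        candidates=candidates,
        expected_peptides=survivors,
        failed_mass=failed_mass,
        failed_compartment=failed_compartment,
        failed_modification=failed_modification,
        failed_uniqueness=failed_uniqueness,
    )


def predict_detectable(
    expected_count: int,
    transcript_units: float,
    min_peptides: int = 5,
    min_units: float = 20000.0,
) -> bool:
    """True when a protein is expected in the shotgun proteomics data:
    strictly more than ``min_peptides`` detectable peptides and strictly
    more than ``min_units`` transcript units."""
    if expected_count < 0 or transcript_units < 0:
        raise DigestError("negative inputs")
    return expected_count > min_peptides and transcript_units > min_units


def read_protein_records(
    fasta_path: str | Path,
    topology_path: str | Path | None = None,
    modifications_path: str | Path | None = None,
) -> list[ProteinRecord]:
    """Load protein records from FASTA plus optional annotation TSVs.

    Topology TSV columns: accession, start, end, label (1-based inclusive).
    Modifications TSV columns: accession, position.
    """
    topo: dict[str, list[tuple[int, int, str]]] = {}
    if topology_path is not None:
        frame = pd.read_csv(topology_path, sep="\t")
        for row in frame.itertuples(index=False):
            topo.setdefault(str(row.accession), []).append(
                (int(row.start), int(row.end), str(row.label))
            )
    mods: dict[str, set[int]] = {}
    if modifications_path is not None:
        frame = pd.read_csv(modifications_path, sep="\t")
        for row in frame.itertuples(index=False):
            mods.setdefault(str(row.accession), set()).add(int(row.position))

    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        acc = rec.id.split("|")[1] if "|" in rec.id else rec.id
        records.append(
            ProteinRecord(
                accession=acc,
                sequence=str(rec.seq).upper(),
                topology=topo.get(acc, []),
                modified_positions=frozenset(mods.get(acc, set())),
            )
        )
    return records
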