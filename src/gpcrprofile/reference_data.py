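"""Published reference values bundled for reanalysis.

Two small tables from the comparative GPCR expression study of five human
neural cell types (the TG1 and OB1 glioblastoma stem-like lines, the U-87 MG
glioblastoma line, fetal neural stem cells and primary astrocytes) are
shipped with the package:

* the top-expressed GPCR table (per cell type, normalized Ct with replicate
  spread, delta-Ct versus the RPLP0 reference, and fold over the reference),
* the proteomics comparison table (per GPCR: UniProt accession, molecular
  weight, in-silico expected proteotypic peptide count, and per cell type the
  transcript level in arbitrary units together with observed unique-peptide
  and spectrum counts, ``None`` meaning not detected at 1% FDR).

These printed values serve as worked-example inputs for the normalization,
specificity, detectability and concordance machinery; the raw array exports
behind them were never deposited, which is why the synthetic generator in
:mod:`gpcrprofile.simulate` exists.
"""

from __future__ import annotations

import math

import pandas as pd

# Canonical cell-type labels and their one-letter specificity codes.
CELL_TYPES = ("TG1", "OB1", "f-NSC", "HA", "U87")

#: One-letter codes used for specificity-group labels.  The canonical code
#: string orders letters as N, T, O, U, H (so e.g. the stem+cancer group of
#: GPR56 prints as "NTOU" and the GSC group of LPHN2 as "TO").
LETTER_ORDER = "NTOUH"
CELL_LETTERS = {
    "TG1": "T",
    "OB1": "O",
    "U87": "U",
    "U-87": "U",
    "U-87 MG": "U",
    "f-NSC": "N",
    "fNSC": "N",
    "NSC": "N",
    "HA": "H",
}

#: Grand-mean cycle threshold of the RPLP0 reference gene in the study.
REFERENCE_GENE = "RPLP0"
REFERENCE_CT = 21.12

#: Expression cutoff: genes with normalized Ct <= 31.5 are called expressed.
CUTOFF_CT = 31.5

#: Arbitrary-unit scale: units = 2**(-Ct) * 1e12 (329 units at the cutoff).
UNITS_SCALE = 1.0e12


def expression_units(ct: float) -> float:
    """Arbitrary expression units for a cycle threshold, ``2**-Ct * 1e12``."""
    return 2.0 ** (-ct) * UNITS_SCALE


def ct_from_units(units: float, sentinel_ct: float = 40.0) -> float:
    """Invert :func:`expression_units`; non-positive units map to the sentinel."""
    if units <= 0:
        return sentinel_ct
    return min(-math.log2(units / UNITS_SCALE), sentinel_ct)


# Top-expressed table: (cell_type, gene, ct, ct_sd, delta_ct, delta_ct_sd,
# fold over reference, fold_sd).  Genes with normalized Ct <= 25.
_TOP_EXPRESSED_ROWS = [
    ("TG1", "LPHN2", 24.0, 0.30, 2.88, 0.58, 7.36, 1.49),
    ("TG1", "GPR56", 24.2, 0.04, 3.08, 0.32, 8.46, 1.25),
    ("OB1", "F2R", 24.3, 0.01, 3.18, 0.28, 9.06, 1.22),
    ("OB1", "GPR56", 24.4, 0.01, 3.28, 0.29, 9.71, 1.22),
    ("OB1", "FZD7", 24.5, 0.03, 3.38, 0.31, 10.41, 1.24),
    ("OB1", "LPHN2", 24.6, 0.04, 3.48, 0.32, 11.16, 1.25),
    ("f-NSC", "GPR56", 22.6, 0.08, 1.48, 0.36, 2.79, 1.28),
    ("f-NSC", "FZD3", 24.7, 0.18, 3.58, 0.46, 12.38, 1.38),
    ("f-NSC", "GPRC5B", 24.8, 0.15, 3.68, 0.43, 13.09, 1.35),
    ("HA", "FZD1", 25.0, 0.08, 3.88, 0.36, 14.72, 1.28),
    ("HA", "FZD7", 25.0, 0.10, 3.88, 0.38, 14.72, 1.30),
    ("U87", "BDKRB2", 24.5, 0.30, 3.38, 0.58, 10.41, 1.49),
    ("U87", "GPR56", 24.9, 0.13, 3.78, 0.41, 13.74, 1.33),
]

# Rows whose printed fold column is inconsistent with 2**delta_ct beyond
# rounding of the delta-Ct column (the fold appears to have been computed
# from an unrounded Ct).  Kept verbatim; flagged for arithmetic checks.
TOP_EXPRESSED_INCONSISTENT = {("f-NSC", "FZD3"), ("f-NSC", "GPRC5B")}


def top_expressed_table() -> pd.DataFrame:
    """The published per-cell-type top-expressed GPCR table as a DataFrame."""
    return pd.DataFrame(
        _TOP_EXPRESSED_ROWS,
        columns=[
            "cell_type", "gene", "ct", "ct_sd",
            "delta_ct", "delta_ct_sd", "fold", "fold_sd",
        ],
    )


# Proteomics comparison table.  Per gene: accession, molecular weight (kDa),
# expected unique proteotypic peptide count; then per cell type a triple
# (transcript units, unique peptides, spectra) with None meaning nd.
# Cell-type order: OB1, TG1, f-NSC, HA, U87.
_PROTEOMICS_ROWS = {
    "GPR56":  ("Q9Y653", 78, 14, [(42820, 4, 8), (52347, 4, 10), (155121, 8, 37), (625, None, None), (32369, 3, 6)]),
    "LPHN2":  ("O95490", 163, 50, [(37915, 9, 15), (62684, 12, 24), (2338, None, None), (5921, None, None), (3495, None, None)]),
    "F2R":    ("P25116", 44, 5, [(48045, 2, 6), (26751, None, None), (18912, None, None), (7701, None, None), (1259, None, None)]),
    "BDKRB2": ("P30411", 44, 0, [(78, None, None), (0, None, None), (1, None, None), (1655, None, None), (42664, None, None)]),
    "FZD7":   ("O75084", 61, 3, [(39613, None, None), (10182, None, None), (14788, None, None), (30943, None, None), (4011, None, None)]),
    "GPRC5B": ("Q9NZH0", 41, 3, [(24853, 1, 3), (24463, 1, 4), (33650, 3, 7), (2888, None, None), (248, None, None)]),
    "TM7SF1": ("O60478", 45, 3, [(15303, None, None), (3322, None, None), (29968, None, None), (2855, None, None), (1743, None, None)]),
    "CXCR4":  ("P61073", 40, 2, [(29644, None, None), (14193, None, None), (11354, None, None), (120, None, None), (19, None, None)]),
    "BAI2":   ("O60241", 173, 40, [(19770, None, None), (15863, None, None), (29243, 1, 1), (5050, None, None), (5478, None, None)]),
    "BDKRB1": ("P46663", 40, 2, [(5, None, None), (0, None, None), (9, None, None), (65, None, None), (27717, None, None)]),
    "GPR153": ("Q6NV75", 65, 1, [(8111, None, None), (26080, None, None), (7762, None, None), (2438, None, None), (342, None, None)]),
    "CD97":   ("P48960", 90, 19, [(14593, 10, 40), (24958, 9, 31), (405, None, None), (1079, None, None), (5233, 6, 21)]),
    "LGR4":   ("Q8N537", 104, 8, [(22726, None, None), (4135, None, None), (19526, None, None), (1804, None, None), (51, None, None)]),
    "CNR1":   ("P21554", 53, 3, [(20381, None, None), (3161, None, None), (14232, None, None), (190, None, None), (1, None, None)]),
    "CELSR2": ("Q9HCU4", 317, 79, [(7543, 2, 2), (1769, 2, 2), (3501, 8, 12), (601, None, None), (118, None, None)]),
}

_PROTEOMICS_CELL_ORDER = ("OB1", "TG1", "f-NSC", "HA", "U87")

#: (gene, cell_type) cells of the proteomics grid where the observed
#: detected/nd state contradicts the simple detectability rule (more than
#: five expected peptides and more than 20000 transcript units) and which
#: the study's text itself discusses: low-transcript or few-peptide proteins
#: nevertheless identified (GPRC5B, CELSR2, F2R in OB1, CD97 in OB1/U87) and
#: one well-qualified receptor that still escaped detection (LGR4 in OB1).
DETECTION_RULE_EXCEPTIONS = frozenset(
    {
        ("GPRC5B", "OB1"), ("GPRC5B", "TG1"), ("GPRC5B", "f-NSC"),
        ("CELSR2", "OB1"), ("CELSR2", "TG1"), ("CELSR2", "f-NSC"),
        ("F2R", "OB1"),
        ("CD97", "OB1"), ("CD97", "U87"),
        ("LGR4", "OB1"),
    }
)


def proteomics_table() -> pd.DataFrame:
    """Long-format proteomics comparison table.

    Columns: gene, accession, mw_kda, expected_peptides, cell_type, units,
    peptides, spectra.  ``peptides``/``spectra`` are NaN when the protein was
    not detected in that cell type.
    """
    rows = []
    for gene, (acc, mw, expected, cells) in _PROTEOMICS_ROWS.items():
        for cell, (units, pep, spec) in zip(_PROTEOMICS_CELL_ORDER, cells):
            rows.append((gene, acc, mw, expected, cell, units, pep, spec))
    frame = pd.DataFrame(
        rows,
        columns=[
            "gene", "accession", "mw_kda", "expected_peptides",
            "cell_type", "units", "peptides", "spectra",
        ],
    )
    frame["peptides"] = frame["peptides"].astype("Float64")
    frame["spectra"] = frame["spectra"].astype("Float64")
    return frame


def transcript_units_matrix() -> pd.DataFrame:
    """Transcript units of the proteomics table as a gene x cell-type matrix."""
    frame = proteomics_table()
    return frame.pivot(index="gene", columns="cell_type", values="units")
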