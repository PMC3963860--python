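# Methods

## Scope and model

The package analyses a relative-quantification qPCR experiment on a fixed
assay panel (here: 356 endo-GPCR assays plus 14 housekeeping assays on a
384-well TaqMan array) measured across a small panel of cell types, and
couples it to a membrane-proteomics detectability model. Abundance is
treated throughout as proportional to 2^−Ct; all averaging happens on the
Ct (log) scale, matching how the source tables report mean ± sd.

### Replicate merging

Observations are aggregated per (gene, cell type) over every well of that
gene, so multi-well assays (the 18S quadruplicate) pool into one replicate
set. Wells without amplification carry a sentinel Ct of 40 and an explicit
flag. Sentinel replicates are excluded from the mean — the sentinel is an
arbitrary floor, not a measurement — and a mixed detected/sentinel set is
flagged rather than silently averaged. A single replicate reports sd 0.

### Reference normalization

Each cell type is aligned by subtracting (reference Ct in that cell type −
reference grand mean), pinning the reference gene (default RPLP0) to one
study-wide value, 21.12 cycles by default. The study's tables fix a single
reference Ct and do not describe per-plate calibration, so this single
shift is the whole cross-sample model. Sentinel entries are not shifted.

Derived quantities per (gene, cell type), with Ct the aligned value:

* ΔCt = Ct − Ct_ref
* fold-below-reference = 2^ΔCt — the "fold" convention of the published
  top-expressed table (its footnote formula reads 2^(Ct_ref − Ct_gene),
  but the printed numbers equal 2^(+ΔCt); both directions are exposed as
  distinct named quantities rather than guessing one)
* ratio-over-reference = 2^−ΔCt — the sign-correct abundance ratio
* units = 2^−Ct · 10¹² (arbitrary); the expression call Ct ≤ 31.5 is
  inclusive and corresponds to 329 units

Two caveats inherited from the source and verified here rather than
patched: (i) the published claim that Ct ≤ 31.5 equals 1.33·10⁻³ of the
reference level does not follow from the formulas (2^(21.12−31.5) ≈
7.5·10⁻⁴); the package implements the Ct/units definition. (ii) In the
published top-expressed table, the FZD3 and GPRC5B rows print folds
(12.38, 13.09) inconsistent with their own printed ΔCt (2^3.58 = 11.96,
2^3.68 = 12.82) beyond any rounding of either column — the folds appear to
have been computed from unrounded Ct. The two corresponding cases of the
arithmetic-reproduction test fail and are left failing on purpose.

### Reference stability (M)

For candidate j, over every other candidate k, the log2 expression ratio
across cell types is Ct_k − Ct_j; its sample sd (shared non-sentinel cell
types, ddof 1) is V_jk, and M_j = mean_k V_jk. Lower M = more stable. This
is the classical pairwise-ratio stability score used to justify
single-reference normalization; the package reports it but normalizes
against one gene (the study found multi-reference geometric averaging gave
similar results).

### Specificity groups

The published subgroup assignments are qualitative; they are formalized
as: gene g belongs to cell-type subset S (direction "over") iff g is
expressed (Ct ≤ cutoff) in every member of S, and either every non-member
is below the cutoff, or min units over S ≥ f · max units over the
complement (default f = 3, cutoff 31.5). "Under" is the mirror image. For
f > 1 any two qualifying subsets are nested (two non-nested subsets would
require mutually contradictory f-fold dominance), so the maximal code is
unique; ties in the formal comparison are still broken deterministically
by in/out ratio and then code order. A gene may hold one over- and one
under-code only if they are disjoint; on overlap the under call is
dropped, since the over call rests on cell types where the gene is
actually expressed. Single-cell-type markers are the singleton
over-direction groups. With f = 3 the rule reproduces the published
exemplar assignments from the printed unit values (LPHN2 → TO,
GPR56 → NTOU, CD97 → TOU, BDKRB1 → U). Letters follow the study
convention (T, O, U, N, H) and codes print in the canonical order
N, T, O, U, H.

Note that a gene expressed everywhere but very strongly enriched in one
cell type can satisfy both the core ("expressed in all five") and a
singleton marker code through the ratio branch; the two result sets are
disjoint on realistic data but not by logical necessity.

### Clustering

The original analysis names only closed-source software, so the chain is
re-implemented from first principles and kept configurable. Features are
−Ct per cell type over the expression-filter union set, silent genes
contributing −40: shared absence is informative for cell-type
separation, and the log scale keeps a few very high expressors from
dominating. Dissimilarity defaults to 1 − Pearson; trees are built by
average linkage (UPGMA: candidate merge score = mean of all cross-cluster
leaf-pair distances), which is monotone, with deterministic
lexicographic tie-breaks and internally sorted leaves so results are
independent of input order. Cutting keeps the last k clusters. Agreement
with an independent hierarchical-clustering implementation is asserted in
the tests for random matrices up to n = 6. The published three-cluster
structure ({TG1, OB1}, {HA, U87}, {f-NSC}) is a cut at k = 3, with the
stem-cell branch joining the GSC side first.

### MS detectability

Fully specific tryptic digest: cleave C-terminal to K/R except before
proline, zero missed cleavages (the study's expected-peptide calculation
uses none even though its database search tolerated one). A peptide is
expected-detectable when its monoisotopic mass is in [1000, 3000] Da
(inclusive; mass scale unstated in the source, monoisotopic is the
LC-MS/MS convention), it lies entirely within a single extracellular or
cytoplasmic topology segment (a peptide spanning a membrane boundary or
touching unannotated residues fails — accessibility of the whole peptide
is what trypsin and ionization require), it contains no annotated modified
residue, and it is unique. Uniqueness defaults to "occurs exactly once
among the parent's tryptic fragments"; an optional background-proteome
check (substring absence) is exposed because the source does not define
the background. Filters are applied in the order mass → compartment →
modification → uniqueness and each rejected peptide is tallied against the
first filter it fails, so tallies plus survivors equal the candidate
count. Residue masses are authored from the standard monoisotopic table
and cross-checked against an independent proteomics library in the tests.

The joint transcript/protein rule observed in the source data — detected
iff strictly more than 5 expected peptides and strictly more than 20000
transcript units — is exposed as `predict_detectable`. On the published
15 × 5 proteomics grid it reproduces 65 of 75 detected/nd cells; the ten
mismatches are exactly the cases the source text itself discusses
(GPRC5B, CELSR2, F2R-in-OB1 and CD97 detected at low transcript or few
peptides; LGR4 undetected despite qualifying) and are frozen as a named
exception set.

### Concordance

Kendall τ-b (tie-corrected) between transcript units and spectral counts
across cell types, computed with scipy and checked against exhaustive pair
counting in the tests. Not-detected cells default to count 0 (absence is
informative); an exclusion policy is available. At least three aligned
cell types and variation on both sides are required; an all-tied side
raises a dedicated error rather than returning NaN.

## Synthetic data

The raw array exports behind the study were never deposited, so the
generator emulates the study conditions and carries exact ground truth:

* Panel and design: 356 GPCR + 14 housekeeping assays, five cell types,
  triplicates for the neural stem cells and duplicates elsewhere,
  additive Gaussian Ct noise (sd 0.3 cycles — the replicate spread visible
  in the published table), sentinel 40 in all replicates for absent genes
  (never partially).
* Housekeeping panel: the reference is planted perfectly flat at 21.12;
  every other housekeeping gene's cell-type effects are centred and
  rescaled to an exact between-cell-type sd (default 1.2 cycles,
  consistent with the multi-cycle spread of the study's housekeeping
  boxplots). The rescaling makes "the reference is strictly most stable"
  a property of the truth rather than of a lucky draw — with independent
  Gaussian effects a competitor occasionally lands a near-constant vector
  and genuinely rivals the reference, which would make ranking recovery a
  coin toss on those realizations.
* Specificity groups: planted genes are expressed (Ct ≈ 24.5–28.5) inside
  their subset and silent outside — the dominant pattern the study
  reports ("expressed above the cutoff only in …") — with true in/out
  abundance ratio at least the configured fold separation (default 4).
  Out-group true Ct sits ≥ 1.8 cycles below the cutoff call, so
  classification margins are set by the cutoff, not by the f-ratio race;
  planting out-groups exactly at the f-fold boundary would make ≥95%
  recovery statistically impossible under the stated noise.
* Cell-type structure: expressed values share a two-factor signature
  (a GSC factor loading TG1/OB1, a differentiated factor loading HA/U87,
  the stem cells loading 0.60/0.25 on the two) so that correlation-based
  clustering recovers the published three-cluster topology.
* `generate_study_like_dataset` plants the study's full expression
  bookkeeping: a fixed pattern table whose column sums equal the
  published per-cell-type expressed counts (OB1 90, TG1 83, f-NSC 77,
  HA 61, U87 57), 26 ubiquitous genes, 138 in the union and 218 silent
  or absent. Expressed true Ct stays ≥ 1.2 cycles above the cutoff
  boundary and silent true Ct ≥ 1.8 below, so the noisy pipeline
  recovers the counts exactly for essentially every seed.
* Proteins: random sequences (250–700 residues, K/R density 0.11) with
  seven-transmembrane-like alternating topology tiling the sequence and
  ~1% modified residues; an independent scan-and-split digest (no shared
  code with the digest module, masses from an independent library)
  records the oracle peptide set per record.
* Spectral counts: Poisson with mean proportional to units × expected
  peptides (8 expected spectra at the 20000-unit / 5-peptide rule point);
  proteins failing the detectability rule are emitted not-detected except
  for a 2% leak, and proteins with no expected peptides never appear.
  Unique-peptide counts saturate at the expected-peptide count.

What the generator does **not** emulate: plate/batch effects, amplification
efficiency differences, fluorescence-curve artefacts, heavy-tailed or
Ct-dependent noise, correlated replicate failures, protein inference
ambiguity and FDR filtering on the MS side. Passing recovery tests
therefore demonstrates correctness of the pipeline's logic under the
study's nominal noise model, not robustness to those real-data pathologies.

## Numerical choices

* Means/sds on Ct with ddof 1; single replicates report sd 0.
* Cutoff comparisons inclusive (≤), per the study's wording.
* Folds compared to published values after rounding to 2 decimals; full
  precision retained internally.
* Distance matrices are validated (symmetry, zero diagonal, finiteness);
  the correlation metric clips to [0, 2] and rejects zero-variance
  feature vectors.
* Average-linkage heights are asserted non-decreasing during merging.
* Mass window inclusive at both ends.
* Deterministic seeds everywhere; fixed seed ⇒ bit-identical outputs.

## Problem sizes

The test suite and acceptance script run the full 356-assay × 5-cell-type
panel; parameter-recovery statements use 20 seeds, digest-oracle
equivalence 100 random proteins, the tiling invariant 1000 random
sequences, and the spectral-count rate check 500 cells × 2 proteins —
sizes chosen so each statistical assertion has comfortable margins while
the whole suite stays interactive.

## Known limitations

* The published peptide counts for the five detected receptors depend on
  the (unstated) sequence/topology annotation release; the digest engine
  is validated against a brute-force oracle and pinned synthetic stand-in
  records instead, and agreement with the published counts is reported,
  not asserted.
* The specificity rule is a formalization of qualitative published
  groupings; membership near the f-fold margin is sensitive to f.
* Uniqueness against a background proteome uses substring containment,
  not a tryptic digest of the background.
* The CLI covers the pipeline stages but not every library option.
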