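# Methods

## The detection problem

A MazF-family toxin is a ribosome-independent, sequence-specific
endoribonuclease: it cleaves single-stranded RNA wherever a short recognition
motif (3–7 nt) occurs. When a pool of substrate RNAs is digested by such an
enzyme, the products are 5'-phosphorylated fragments whose 5' ends coincide
with cleavage positions. After library preparation and single-end sequencing,
reads anchor at fragment 5' ends, so per-position coverage of the substrate
steps **up** at the first nucleotide downstream of every cut.

The relative coverage increase turns that step into a position statistic:

    RCI(n) = cov(n) / cov(n-1),   n ≥ 2,

computed after replacing zero coverage with a pseudocount of 1 (replacement,
not addition: positive values are untouched, so the operation is idempotent).
A position n is called a cleavage site when

1. `cov(n) ≥ median` of the substrate's (pseudocounted) coverage
   distribution over all L positions — rejects step-like noise in
   low-coverage regions; and
2. `RCI(n) ≥ 3` (inclusive; `--rci-threshold`).

The 11-nt window `n-5 … n+5` around each passing position is extracted (the
step-up base is window position 6; the cut lies between window positions 5
and 6, i.e. U^ACAAA for the UACAAA motif). Windows that would run off either
end of the substrate are dropped, not padded: the downstream motif model
needs equal-width windows and no principled padding exists. The ten windows
with the highest RCI, pooled **across** substrates, feed the motif model;
ties are broken by substrate id then position, both ascending.

Two deliberate interpretation choices, exposed as parameters:

- the median is computed on the **pseudocounted** track (the pseudocount
  step precedes the exclusion step in the procedure this follows);
- the median test applies to `cov(n)` only — the filter excludes
  *positions*, and the position of interest is the step-up base n;
- the threshold is **inclusive** (≥ 3): the criterion is stated both ways in
  the literature this implements; the inclusive form is the formal rule and
  the flag covers the other reading.

## Motif model

The top-k windows are tallied into a 4×W count matrix (rows A, C, G, U),
column probabilities p, and per-column information content

    info_j = 2 + Σ_b p_bj log2 p_bj   (bits, 0·log 0 = 0),

2 bits for a unanimous column, 0 for a uniform one. No small-sample
correction is applied by default — with N≈10 windows the logo is read
qualitatively and the correction (e_N = 3 / (2 ln2 · N)) would subtract a
constant ≈0.22 bits from every column; it is available behind a flag.

The IUPAC consensus is called per column: the smallest degenerate code
covering every base with frequency ≥ 0.5 (`min_fraction`); if no base
reaches it, the smallest code covering bases taken in descending frequency
(alphabetical ties) until the cumulative frequency reaches 0.75. The
consensus rule is a package convention — the original analysis reads the
consensus off the logo by eye — so both constants are exposed and reported.

## The simulator

`synthetic_data` emulates the digestion→library→coverage process so the
pipeline is testable without any deposited data:

- **Substrates.** Eight artificial RNAs with the study panel's geometry
  (533, 5×1033, 1533, 2033 nt), i.i.d. background at a given GC fraction,
  with recognition-site variants planted at known step-base positions.
  Accidental occurrences of any variant in the efficiency table are
  rejection-resampled away, so the planted roster is exact ground truth.
- **Digestion.** Each of `n_molecules` copies is cut independently at each
  planted site with the variant's per-molecule efficiency, and at every
  other bond with a background rate (default 1e-4 per bond per molecule) —
  i.i.d. background gives the median filter something to reject.
- **Sequencing.** Every fragment is sequenced exactly once by a single-end,
  5'-anchored read of `min(read_length, fragment_length)` nt. Depth is
  controlled by `n_molecules` alone; there is no second sampling layer —
  the simplest model that produces the step signature RCI measures.

Default efficiencies (UACAAA 0.9; UACUAA 0.4; UACGAA 0.3; UACCAA 0.1;
UACAAC/G/U 0.02) are configuration values encoding the enzyme's qualitative
preference ordering, not measurements. Defaults `n_molecules=5000`,
`read_length=150` are realistic desk-scale stand-ins for a MiSeq-class run;
the depth per substrate and mapped read-length distribution of the original
libraries are not published.

**Detectability constraint.** A planted step base n is only detectable when
the 5'-fragment's read no longer covers n−1, i.e. when n lies more than
`read_length` positions downstream of the previous fragment start. A site at
exactly n = read_length produces *no* step (uncut reads reach n, upstream
fragment reads reach n−1). The default roster places all sites well clear of
this geometry; users planting their own sites should too.

What the simulator does **not** model: phosphorylation/ligation efficiency,
RT dropout, PCR duplicates, sequencing error, paired-end reads, mapping
ambiguity. Passing recovery tests therefore demonstrate the *statistical
pipeline's* correctness and its behaviour under Poisson-like background
noise — not robustness to library-preparation artefacts in real data.

## CDS motif scanning

The in-vivo target survey counts coding sequences containing ≥ 1 occurrence
of the recognition motif. Scanning is exact-match over IUPAC-expanded
positions, case- and T/U-insensitive, counting overlapping occurrences at
every start. Only the sense (mRNA) strand is scanned by default — the
enzyme attacks single-stranded mRNA — with `--both-strands` available. `N`
in a CDS matches nothing unless `--n-matches-any` (conservative default).

## Conservation utilities

Pairwise alignment is global Needleman–Wunsch with affine gaps via
Biopython's `PairwiseAligner` (BLOSUM62, gap open 10, gap extend 0.5; a
length-k gap costs `open + (k−1)·extend`, end gaps included). Percent
identity = identical columns / alignment length; percent similarity
additionally admits columns whose pair scores > 0 in the matrix. Among
co-optimal alignments the aligner's first traceback is reported —
deterministic for a fixed Biopython version; the optimal score is unique.
Published identity/similarity figures for these protein pairs came from an
unnamed tool, so these defaults make the numbers approximately checkable
without claiming exact reproduction.

MSA annotation consumes an existing alignment (construction is out of
scope): `*` where all rows share one residue with no gaps; `.` where ≥ 80%
of the non-gap residues fall into one conventional strong similarity group
({STA, NEQK, NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW}); gap rows are excluded
from the denominator and at least two non-gap rows are required. Conserved
columns are mapped to reference-sequence positions, skipping columns where
the reference is gapped.

## Numerical and design notes

- Coordinates are 1-based inclusive throughout; 0-based half-open appears
  only at the BED/bedGraph boundary.
- All randomness flows from explicit integer seeds; panel generation spawns
  per-substrate child streams from one master seed
  (`numpy.random.SeedSequence`), so fixtures regenerate byte-identically.
- The simulator groups molecules by cut pattern, so a full 8-substrate panel
  at default depth simulates in well under a second; the recovery and
  specificity studies run 100 independent panels each.
- Reports are JSON with sorted keys and no timestamps: identical inputs and
  parameters give byte-identical reports.
- Degenerate inputs: a track of all-equal coverage keeps every position
  under the median filter (inclusive boundary); an empty site list yields a
  null consensus and an empty BED, with success exit.

## Known limitations

- RCI has no significance model; thresholds are fixed, as in the procedure
  this reimplements. No FDR control.
- The consensus rule (min_fraction / cumulative-0.75) is a convention; very
  heterogeneous top-window sets can produce highly degenerate codes.
- Recovery/specificity results are properties of the synthetic generative
  model at its default settings; they transfer to real libraries only to the
  extent the step-signal model holds there.
- The pairwise-alignment tie-break differs between Biopython versions in
  principle; only score, identity and similarity are contractual.
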