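# cleavemap

Mapping the recognition sequence of a sequence-specific endoribonuclease —
such as a MazF-family toxin of a bacterial toxin–antitoxin system — from
positional sequencing coverage of digested substrate RNAs.

When a single-strand-specific ribonuclease digests a pool of substrate RNAs
and the products are sequenced with 5'-anchored reads, read starts pile up
at the first base downstream of every cut, so coverage steps up there. The
**relative coverage increase**

    RCI(n) = cov(n) / cov(n−1),  n ≥ 2   (zero coverage replaced by a pseudocount of 1)

turns that step into a per-position statistic. `cleavemap` implements the
full detection pipeline — pseudocount → RCI → per-substrate median-coverage
filter → RCI ≥ 3 threshold → 11-nt window extraction (step-up base at window
position 6, cut between positions 5 and 6) → top-10 ranking across
substrates → position weight matrix, per-column information content, sequence
logo and IUPAC consensus — together with:

- a **seeded simulator** of the cleavage → fragment → read → coverage
  process (eight-substrate panel of 533/1033×5/1533/2033 nt with planted
  motif variants and exact ground truth), so every stage is testable with no
  external data;
- an **IUPAC motif scanner** counting coding sequences that carry the
  recognition motif on the mRNA strand (the in-vivo target survey);
- **conservation utilities**: affine-gap global protein alignment with
  percent identity/similarity, and MSA column annotation (`*` full identity,
  `.` ≥ 80% similarity-group conservation) mapped to reference positions —
  the displays used to shortlist mutagenesis candidates.

It is aimed at microbiologists characterising ribonuclease specificity from
massively parallel sequencing of digested substrate libraries, and at anyone
who needs a tested, reproducible RCI implementation.

## Worked example

```bash
cleavemap demo --out-dir demo_out --master-seed 0
```

prints

```
cleavemap demo (master seed 0)
substrates: 8; sites called: 14
recovered recognition sequence: U^ACAAA
consensus window: VVVAUACAAAV
toy CDS scan: 24/60 CDSs carry UACAAA (planted: 24)
```

Reading this: the simulator planted UACAAA (cut efficiency 0.9) plus weaker
variants across an eight-substrate panel; the pipeline called 14 step-up
sites passing both criteria, ranked the top ten by RCI, and the consensus of
their aligned 11-nt windows spells `UACAAA` at window positions 5–10, with
the cut before the first A — `U^ACAAA`, exactly the planted truth. Flanking
window columns (the `V`s) are background and carry no information. The toy
CDS scan recovers all 24 coding sequences that contain the motif. The demo
exits non-zero if the recovered sequence differs from the planted one.

The same stages are available as separate subcommands
(`simulate`, `detect`, `logo`, `scan`, `align`, `annotate`), e.g.

```bash
cleavemap simulate --length 800 --plant 300:UACAAA --seed 4 --out-prefix sim
cleavemap detect --fasta sim.fasta --coverage sim.coverage.tsv \
    --out report.json --bed sites.bed
cleavemap logo --report report.json --out logo.png
cleavemap scan --cds cds.fasta --motif UACAAA --out scan.tsv
```

and as library functions (`cleavemap.detect_recognition_sequence`, etc.).
Every flag can come from a YAML config (`--config`), with command-line
values taking precedence; identical inputs and seeds give byte-identical
reports.

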