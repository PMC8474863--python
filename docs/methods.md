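# Methods

## The assay and its analysis problem

Fetal *RHD* genotyping from maternal plasma cell-free DNA (cfDNA)
decides whether an RhD-negative pregnant woman carries an RhD-positive
fetus, which determines whether anti-D prophylaxis is needed. In East
Asian populations the common European strategy (detect any *RHD*
sequence) fails, because *RHD*-positive but D-antigen-negative alleles
(*RHD\*01EL.01*, *RHD\*01N.04*) are frequent. The assay this package
analyzes therefore interrogates four genomic regions with two primer
pairs:

- the **upstream and downstream Rhesus boxes** (105-bp amplicons,
  co-amplified, differing at a single base). The *RHD* deletion allele
  (*RHD\*01N.01*) carries one hybrid box; intact alleles carry both.
- the **exon-9 regions of *RHD* and *RHCE*** (148-bp amplicons,
  co-amplified, differing at two paralog-diagnostic bases). The
  amplicon also covers the c.1227G>A variant that defines
  *RHD\*01EL.01*.

Each allele contributes a fixed integer number of copies of five
amplicon units (upstream box, downstream box, wild-type *RHD* exon 9,
c.1227A *RHD* exon 9, *RHCE* exon 9):

| allele | up box | down box | RHD wt | RHD var | RHCE |
|---|---|---|---|---|---|
| RHD\*01 | 1 | 1 | 1 | 0 | 1 |
| RHD\*01N.01 | 0 | 1 | 0 | 0 | 1 |
| RHD\*01EL.01 | 1 | 1 | 0 | 1 | 1 |
| RHD\*01N.04 | 1 | 1 | 0 | 0 | 2 |

The table ships as JSON data (`rhdamp/data/allele_units.json`) so new
alleles can be added without code changes. Two entries deserve comment:

- The *RHD\*01N.01* hybrid box is modeled as one **down-type** box
  unit. If the deletion allele contributed no box amplicon at all, a
  deletion-homozygous mother carrying a heterozygous RhD-positive fetus
  would show ~50% upstream reads, contradicting the ~2–4% observed in
  real del/del pregnancies; a down-type hybrid box reproduces the
  observed ~98% downstream share. Which discriminating base the hybrid
  box actually carries is not documented, so the down-type assignment is
  an inference.
- *RHD\*01N.04* (exons 3–9 of *RHD* replaced by *RHCE*) keeps both
  boxes and contributes two *RHCE*-type exon-9 units.

For a mixture of a maternal genotype (weight `mw` per genome) and a
fetal genotype (weight `fw`), expected read fractions are obtained by
summing unit vectors weighted by genotype copy and mixture weight and
normalizing within each co-amplified group. All of this is exact
rational arithmetic (`fractions.Fraction`); no floats enter until
rendering. The fetal fraction is f = fw/(mw+fw); a 10:1 genomic DNA
mixture of two diploid individuals corresponds to f = 1/11, since
weights act per genome copy.

When the mother contributes zero upstream-box units, the observed
upstream fraction u inverts analytically to a mixture-fraction proxy:

    u = f·Uf / ((1−f)·Dm + f·(Uf+Df))   ⇒   f = u·Dm / (Uf + u·(Dm−Uf−Df))

with Dm the maternal downstream units and Uf/Df the fetal genotype's
box units per genome. For mother del/del and fetus RHD\*01/del this is
f = 2u/(1−u). This is a proxy under an assumed fetal genotype, not a
measured fetal fraction: the assay by itself cannot determine the
fetal fraction, which is the method's acknowledged limitation.

## Read processing

Input is paired-end 151 × 2 FASTQ. Because both amplicons are shorter
than the read length, the two mates overlap across the entire insert,
which drives several design choices:

- **Adaptor trimming** removes 3′ read-through adaptor by
  exact-prefix matching with up to 1 mismatch per 10 matched bases,
  minimum overlap 3 (the 148-bp insert leaves only a 3-base adaptor
  remnant in a 151-bp read). A spurious 3-base trim is harmless: the
  mate restores the lost bases during merging.
- **Merging** finds the maximal overlap (≥ 10 bases, FLASH's default
  minimum) between read 1 and the reverse complement of read 2 with a
  mismatch density of 0 by default: only perfect overlaps merge. The
  merged quality at overlapped positions is the per-position maximum.
  A consequence worth stating explicitly: any pair whose two reads
  disagree anywhere — i.e. any pair carrying an independent per-read
  sequencing error in the overlap — is rejected, so the reads that
  survive carry almost exclusively *template-level* substitutions
  (PCR errors, which both mates share). This mirrors the observation
  that stringent filtering leaves amplicon data nearly free of
  erroneous reads, and it is why error-rate calibration tests inject
  template-level errors.
- **Size filter**: merged length must equal an amplicon length
  (105/148) exactly; primer dimers and artefacts fail here.
- **Quality filter**: mean Phred over the merged read ≥ 25, boundary
  inclusive. The published filter ("base quality scores, cutoff 25")
  does not specify per-base vs aggregate semantics; a read-level mean
  matches its stated purpose of removing low-quality reads.
- **UMI handling**: in UMI mode the first 12 bases of the merged read
  (the molecular tag attached to read 1 before amplification) are
  split off *before* size filtering, otherwise expected sizes would
  shift to 117/160. PCR duplicates are then collapsed by exact
  (UMI, length-class) grouping with plurality consensus,
  lexicographic tie-break. No Hamming-1 UMI error network is built:
  plain duplicate removal is the behavior being reproduced, and UMI
  sequencing errors only fragment a molecule into two (slightly
  inflating molecule counts) rather than corrupting consensus.

Every stage is deterministic given input order and keeps an exact
ledger (inputs = kept + rejected); rejections are data, not exceptions.

## Classification and counting

After size filtering, every read is a full-length, ungapped amplicon,
so alignment reduces to Hamming distance against the two co-amplified
references of the read's length class. A read is assigned iff the best
reference is within 3 mismatches AND strictly beats the second best
(margin ≥ 1); ties are "ambiguous", distant reads "unassigned". This
replaces genome-wide alignment with mapping-quality cutoffs: the
uniqueness margin enforces the same intent (discard reads that cannot
be attributed to one paralog) without a genome build. An `N` at the
single discriminating base produces a tie and is discarded — `N` never
counts toward any allele.

Assigned reads are tallied into per-region position × {A,C,G,T,other}
count matrices (serializable as wiggle-style text). The five diagnostic
counts are read off the matrices: each box's own base at the
box-discriminating offset; G-equivalent and A-equivalent counts at the
c.1227 offset of the RHD exon-9 matrix (wild-type vs c.1227A — the
variant allele is *not* a separate reference); and the RHCE-expected
base at the same declared offset in the RHCE matrix.

## Ratio statistics

Allele ratios are exact rationals rendered Table-style: minor fractions
at 2 decimals (extended until nonzero when a positive fraction would
render as 0.00, e.g. one read in ~61,000 renders as 0.002), and the
majority fraction as 100 minus the rendered minor fractions, so each
rendered group sums to 100%.

The **error ratio** at position p pools the two regions of a group:
errors(p)/total(p), where a read is erroneous at p if its base differs
from *its own region's* reference base (so paralog-diagnostic positions
contribute correctly). The c.1227 offset is excluded for the exon-9
group (the RHD pool legitimately mixes G and A there). Ratios are
computed at every non-excluded position, but summary statistics (max,
median) are taken over the non-primer interior — nt 21–80 for the
boxes (60 positions) and nt 23–119 for exon 9 (97 positions) — because
primer-footprint positions show inflated artefactual error rates.

The run report carries a QC contamination flag: any diagnostic-class
fraction that exceeds the run's own interior maximum error ratio while
staying below the positive-signal floor (default 0.5%) looks like
carry-over contamination rather than a genuine minor allele, and is
flagged rather than silently reported.

## Genotype calling

The maternal genotype is matched at fetal fraction 0 by minimizing the
L1 distance between observed and expected (upstream, RHD-wt, RHD-var)
fractions over the three common RhD-negative genotypes
(del/del, del/EL, del/hybrid). The fetal call is:

- **RhD-positive** iff the wild-type exon-9 fraction ≥ 0.5% with ≥ 50
  supporting reads (unique molecules when UMI dedup ran) and, for
  del/del mothers, a corroborating upstream-box signal ≥ 0.5%;
- **RhD-negative (del/del)** iff the wild-type fraction ≤ 0.1% and the
  upstream signal matches the maternal-only expectation;
- **inconclusive** otherwise — in particular when the signal is
  compatible with a fetal fraction too low to detect, or when the two
  independent amplicon groups disagree (QC-noted).

No decision thresholds are published for this assay; the defaults are
anchored to the observed background error ceiling (~0.1%) and sit well
below genuine fetal signals (1.3–3.6% at ordinary fetal fractions).
All are configurable, and `rhdamp call` re-calls an existing report
under new thresholds without recomputation. The maternal-match
tolerance (default 0.15) must admit the fetal displacement of the
maternal pattern, which equals ≈ f for a del/del mother with a
positive fetus: 0.15 accepts fetal fractions up to ~15% while the
nearest wrong pattern (an RhD-positive mother) sits at distance ~0.66.
A positive call reports the RhD status plus the compatible allele
(*RHD\*01*), never a two-allele fetal genotype: the assay cannot phase
fetal alleles. A single-read variant signal (e.g. RHD-var 0.002%) falls
below the negative ceiling and is treated as below-background noise.

## The simulator

`make_synthetic_references` builds four **synthetic** reference
amplicons — the true genomic sequences of the amplified intervals are
not reproduced, only their discriminating structure: lengths 105/148,
primer footprints nt 1–20/81–105 and 1–22/120–148, one
box-discriminating base, two exon-9 paralog bases plus the c.1227
offset at interior positions (23/57/119) whose 34/62-base spacings and
hg19 anchors match the published diagnostic coordinates (the *RHCE*
amplicon runs on the minus strand, where coordinates descend). Any
user-supplied real reference satisfying the same structural invariants
is accepted via the FASTA + JSON interchange format.

`simulate_reads` draws template molecules per group from the
closed-form expected class fractions (multinomial), optionally
reweighted by a per-class amplification bias (to emulate the observed
bias towards *RHCE* exon 9 under linear+PCR protocols). Each molecule
gets a uniform random 12-base UMI (collisions permitted and recorded —
negligible below 10^5 molecules), a geometric number of PCR duplicates
(support ≥ 1; the true duplicate distribution under 30–35 cycles is
unknown, geometric is a pragmatic stand-in), template-level PCR
substitutions per duplicate, and independent per-read sequencing
substitutions within the amplicon-derived bases of each mate. Reads are
padded to 151 bases with read-through adaptor and G fill; qualities are
sampled around Q35 so clean reads pass the quality filter. All
randomness flows from the single seed; identical configurations give
byte-identical FASTQ.

Defaults are the study conditions: 10:1 maternal:fetal genome weights,
20,000 template molecules per amplicon group, duplication mean 3,
sequencing error 1e-3 per base per read, PCR error 1e-4 per base per
duplication event. `simulate_twelve_panel` enumerates the 3 × 4
validation design (three RhD-negative "mothers" × one RhD-positive +
three RhD-negative "fetuses") with per-run seeds derived from the base
seed.

What the simulator does **not** emulate — and hence what passing tests
do not show about real data: fragment-size distributions and
electropherogram artefacts, index hopping, primer-dimer formation
(size-filter rejections in real data come from chemistry, here only
from degenerate reads), context-dependent error spectra (errors are
uniform substitutions), quality-score correlation with errors, and
real PCR amplification kinetics (bias is a static multiplier).
Passing the panel shows the *analysis* is correct under the assay's
statistical model, not that the wet-lab assay works.

## Numerical and degenerate-input choices

- Exact rational arithmetic for all ratio/threshold comparisons;
  floats only at rendering and reporting boundaries.
- 1-based closed coordinate intervals throughout, matching the
  published coordinate convention; genomic position = start + offset − 1
  on '+', start − offset + 1 on '−'.
- Zero-read groups yield "no data" results (None), never exceptions;
  zero-coverage positions are excluded from error-ratio summaries.
- Classification ties break to "ambiguous" (discard), dedup ties to
  the lexicographically smallest sequence (deterministic).
- Empty FASTQ input or an empty post-filter read set are distinct
  pipeline errors with distinct CLI exit codes (4), as are unreadable
  inputs (2) and invalid reference specs (3).

## Problem sizes used in tests and the acceptance script

The panel and calibration computations use 20,000 template molecules
per amplicon group (duplication mean 3 → ~120,000 read pairs per run,
~1.4 M pairs over the twelve-run panel), matching the depth of the
published cfDNA runs (~20,000–60,000 reads per group). Property and
unit tests use a few hundred molecules, which is ample for their exact
(non-statistical) assertions.
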