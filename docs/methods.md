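# Methods

## The screen

The package operationalizes a three-arm screen for coding circRNAs in a
two-condition (vehicle vs. treated), two-timepoint (day 10, day 20) bulk
circRNA-seq design. A candidate passes iff

1. it is *sustained down*: called significantly downregulated
   (p < 0.05 and log₂FC < −1, treated vs. vehicle) at **both** timepoints;
2. it carries an ORF that crosses the back-splice junction at least once;
3. an RRACH m6A consensus pentamer lies wholly within the window
   (default 100 nt) immediately 5' of that ORF's start codon.

Passing candidates are ranked by most negative mean log₂FC, then smallest
day-20 p-value, then circ_id — fixed tie-breaks so runs are reproducible.
Whether sustained suppression should additionally require a monotone
decrease from day 10 to day 20 is an open design point; both-timepoints-
down is implemented.

The ORF and motif arms are paired per start codon: the candidate ORF is
the longest junction-crossing ORF that has an in-window upstream RRACH,
falling back to the longest crossing ORF when none has one. Pairing per
start matters because random circles frequently carry several
junction-crossing ORFs, and the motif criterion is meaningful only
relative to the start that would actually initiate translation.

## Circular coordinates

Position +1 is the first nucleotide 3' of the back-splice junction (the
acceptor exon's first transcript-orientation base); positions run 1..L
with the junction between L and 1. `circ_pos(o, L) = ((o − 1) mod L) + 1`
reduces any absolute offset, and is bijective from any window of L
consecutive offsets onto 1..L. All circle-level work happens in transcript
orientation; minus-strand genes are reverse-complemented on assembly.

## Circular ORFs

From each ATG on the circle (junction-spanning occurrences included),
codons are read forward circularly until the first in-frame stop
(TAA/TAG/TGA). After lcm(L, 3) nt the reading frame revisits its initial
(position, phase) state, so absence of a stop within that bound proves a
rolling-circle ORF that never terminates (`is_infinite`); the longest
finite peptide is therefore lcm(L, 3)/3 − 1 residues. Peptides include
the initiator Met and exclude the stop; for infinite ORFs the reported
peptide is one frame cycle, which repeats indefinitely.

A junction crossing is the frame reading past position L into position 1:
counting multiples of L among the read nt offsets excluding the final
base, an ORF whose stop codon ends exactly at position L crosses zero
times. The reference geometry is analytically forced: on a 373-nt circle
with the start at +366, a 130-residue product reads 393 nt, crosses the
junction twice, and puts its stop codon at +10..+12.

Start codons are ATG only; near-cognate starts are out of scope. The
screen's reference circle (and its translation-dead control, ATG→ACC at
the same position via `mutate_start`) uses this machinery directly.

Peptide masses use standard average (not monoisotopic) residue masses
plus one water; the table is embedded and unit-tested against
hand-computed peptides.

## RRACH scanning

The m6A consensus RRACH (R = G/A, H = A/C/U) is matched as
`[GA][GA]AC[ACT]` on the DNA alphabet (T≡U — one alphabet end to end).
Scanning the doubled sequence with starts restricted to 1..L finds all
pentamers including junction-spanning ones. The upstream gap to a start
codon is `(orf_start − motif_end − 1) mod L`; a hit is in-window when
gap + 5 ≤ window, i.e. the whole pentamer lies in the window and does not
overlap the start codon (consistent with a motif at +357..+361 against a
start at +366: gap 4).

## Differential testing

Expression is RPM = junction reads / total mapped reads × 10⁶.
Group comparison uses a conditional exact binomial rate test on pooled
counts: with pooled counts kA (vehicle), kB (treated) and summed library
sizes LA, LB, under equal per-read rates kA ~ Binomial(kA+kB, LA/(LA+LB)).
The two-sided p doubles the smaller tail, capped at 1 (stated because
conventions differ; scipy's `binomtest` uses the minimum-likelihood
convention instead). Fold changes are log₂(((kB+0.5)/LB)/((kA+0.5)/LA)) —
0.5 pseudocounts keep zeros finite; positive means higher in treated.
Both groups all-zero is the defined degenerate case (log₂FC 0, p 1).

This is a fully specified, oracle-checkable substitute for a
negative-binomial GLM, not a reproduction of one: it conditions away
library-size differences but does not model biological overdispersion, so
its type-I error under an overdispersed null exceeds the nominal level
(under a Poisson null it is conservative — measured ≈ 0.04–0.05 at
α = 0.05 with n = 3 per group and mean 50). Raw p-values drive the calls,
matching the screen's stated thresholds; a Benjamini–Hochberg column is
emitted for reference only. The ΔΔCt helper (2^−ΔΔCt) supports simulated
qPCR validation.

## BSJ detection

The detector targets error-free toy-scale data: anchors are exact
matches, and both read segments must terminate exactly at annotated exon
boundaries of one gene, with the prefix mapping strictly downstream
(transcript orientation) of the suffix — the inverted-order hallmark.
Reads are deduplicated by sequence per sample before counting, so
"unique" support means distinct read sequences; reads fitting more than
one junction are dropped and tallied. Junctions with ≥ 1 unique junction
read in ≥ 1 sample are reported. Gapped or mismatch alignment,
unannotated junctions and paired-end logic are out of scope. Production
circRNA callers integrate two independent algorithms; whether their
results are combined by union or intersection is typically unstated —
this detector produces a single call set.

## Synthetic data

The generator emulates a fixed experimental design: two conditions × two
timepoints × 3 replicates (replicate count configurable; 3 is the
default in the absence of a stated design), library size 10⁶, baseline
mean 50 junction reads per circle, and a planted coding circle suppressed
with log₂FC −2 at both timepoints among null circles.

Counts are negative binomial with mean m = baseline × 2^log₂FC ×
(library size / reference library size) and variance m + αm²; α = 0
degenerates to Poisson. The default dispersion α = 0.05 reflects the
moderate replicate-to-replicate variability expected of junction-read
counts at this depth; the Poisson limit is used where a calibration
explicitly assumes it. One global seed drives every stage through fixed
substream labels, making all outputs byte-identical per seed.

Planting works backwards from the desired geometry: fixed bases (ATG at
the start, TAA at the stop, an RRACH pentamer at the motif position) are
written onto a random circle, conflicts between fixed positions raise a
planting error, and premature in-frame stops are repaired by writing C at
a free position — C occurs in no stop codon, so a repair can never create
a new stop elsewhere in the wrapped frame. The circle is then written
back into the host gene's exons (strand-aware), so genome, annotation and
truth stay consistent. The default planted geometry is a 373-nt circle
from four exons (100+90+93+90 nt) with the start at +366, motif gap 4 and
a 130-residue product.

Simulated reads are error-free, single-end, uniform quality; junction
reads overlap the BSJ by at least the detector's minimum anchor on both
sides and stay within the junction-flanking exons; linear background
reads (10× the junction reads) are sampled from random genomic positions
and strands. No sequencing-error model, paired ends or rRNA contamination
— passing detection here shows the junction logic is correct, not that
the detector tolerates real-data noise.

## Oligo design

Junction probes take the sense window centered on the junction (the
5'-of-junction arm gets the extra base for even lengths) and return its
reverse complement; by construction the probe straddles the BSJ and is
absent from the linear spliced transcript. Divergent primers place the
forward primer sense upstream of the junction and the reverse antisense
downstream; the circular amplicon is the distance from forward 5' end to
reverse 5' end plus 1, and on the linear transcript the pair points apart
and yields no product. Primer 3' ends must be unique on the circle
(12-mer check); melting temperatures use the Wallace rule
(2(A+T) + 4(G+C)) — nearest-neighbor thermodynamics is out of scope since
only relative feasibility matters at toy scale. A gRNA checker verifies a
provided guide is reverse-complementary to a circle window overlapping
the m6A motif; guide design itself is out of scope.

## Problem sizes

The test and acceptance workloads use: 500 random circles (L 6..90) per
oracle-equivalence check; 1000 circles for rate-test calibration; 20
seeds × 50 circles for end-to-end recovery; 100 random circles for oligo
checks; 20 seeds × 3 circles for detector recovery. These sizes give
stable pass/fail behavior while keeping a full run to a few seconds.

## Known limitations

* The rate test pools replicates; it does not estimate per-circle
  dispersion and will be anti-conservative on strongly overdispersed real
  data.
* The detector requires exact matches and annotated boundaries; it is a
  reference implementation of the junction logic, not a production
  aligner.
* IRES prediction, m6A site prediction beyond the RRACH consensus, Kozak
  scoring and protein structure are all out of scope.
* Whether a reported peptide length counts the initiator Met is
  convention-dependent; the inclusive convention is used throughout.
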