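# circorf

A toolkit for screening circular RNAs (circRNAs) for protein-coding
potential, built around the kind of evidence that identifies a coding
circle in a differential sequencing experiment:

* **back-splice junction (BSJ) detection** from reads whose two segments
  map in inverted genomic order (a minimal exact-match, two-anchor
  detector for annotated exon boundaries);
* **junction-read quantification** as RPM = junction reads / total mapped
  reads × 10⁶, and a **differential screen** with an exact two-group rate
  test plus the standard thresholds p < 0.05 and |log₂FC| > 1, with a
  *sustained suppression* flag (down at both timepoints);
* **circular ORF enumeration**: on a circle of length L, an ORF may cross
  the BSJ, wrap the circle several times (rolling-circle reading), or —
  when the frame cycle of lcm(L, 3) nt contains no stop — never terminate;
* **RRACH m6A motif scanning** ([G/A][G/A]AC[A/C/U]) in the window
  immediately 5' of a start codon, junction-spanning pentamers included;
* **junction oligo design**: antisense probes centered on the BSJ and
  divergent qPCR primer pairs that amplify only across the junction, with
  circle-vs-linear specificity checks;
* a **synthetic data generator** that plants circles with fully known
  geometry (BSJ coordinates, ORF start/stop, motif position, per-sample
  expected counts) so the whole pipeline is testable end to end without
  any external data.

Coordinates on a circle follow the convention that +1 is the first
nucleotide 3' of the back-splice junction; positions run 1..L with the
junction between L and 1.

## Worked example

Run the full synthetic screen — 10 circles, one planted coding circle
(373 nt, start codon at +366..+368, RRACH motif at +357..+361, a
130-residue cross-junction product) suppressed 4-fold by treatment at
both timepoints:

```python
from circorf.pipeline import ScreenConfig, run_screen
from circorf.report import report_table

res = run_screen(ScreenConfig(n_circ=10), seed=1)
print(report_table(res.records).head(4).to_string(index=False))
```

```
 rank  circ_id  screen_pass  log2fc_d10  log2fc_d20        p_d20  orf_aa_length  orf_crossings  motif_upstream_gap  peptide_mass_da
    1  circ_g1         True   -1.744871   -1.860024 4.430292e-14          130.0            2.0                 4.0         14473.04
    2  circ_g5        False   -0.668549   -0.120714 5.154769e-01            NaN            NaN                 NaN              NaN
    3  circ_g4        False   -0.315614   -0.096215 6.257959e-01            NaN            NaN                 NaN              NaN
    4 circ_g10        False   -0.383495   -0.020392 9.525288e-01            NaN            NaN                 NaN              NaN
```

The planted circle ranks first and is the only screen pass: it is
suppressed at both timepoints (estimated log₂ fold changes ≈ −1.7/−1.9
against a planted −2), carries a 130-amino-acid ORF that crosses the
junction twice (start at +366, stop codon at +10..+12 after wrapping), and
has an RRACH motif ending 5 nt upstream of the start (gap 4 nt). The
predicted peptide mass is ≈ 14.5 kDa. Null circles fail on the
differential arm.

Validation oligos for the top candidate:

```python
from circorf import design_junction_probe, design_divergent_primers

circ = res.truth[res.planted_id].transcript()
probe = design_junction_probe(circ)            # 22-nt antisense, 11|11 arms
fwd, rev, amp = design_divergent_primers(circ, max_amplicon=134)
```

yields probe `TAGAGGGAGTACCGGCCATTCC` (hits the circle, absent from the
linear spliced transcript) and a divergent pair whose 134-nt amplicon
exists only on the circle — on the linear transcript the primers point
apart and give no product.

The same stages are available from the shell:

```bash
circorf simulate --out sim/ --seed 5 --n-circ 4 --depth 10
circorf detect --genome sim/genome.fa --gtf sim/annotation.gtf --reads sim/reads.fq --out bsj.tsv
circorf de --counts sim/counts.tsv --samples sim/samples.tsv --out de.tsv
circorf run --out run/ --seed 2 --n-circ 50
```

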