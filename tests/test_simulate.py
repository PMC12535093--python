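"""Synthetic-data generator: determinism, planted geometry, count model."""

import numpy as np
import pytest

from circorf import (
    SimDesign,
    TruthTable,
    find_circular_orfs,
    make_toy_genome,
    plant_coding_circ,
    scan_rrach,
    simulate_junction_counts,
    simulate_reads,
)
from circorf.simulate import PlantingError, SizingError, null_circle_truth
from conftest import orf_oracle, rrach_oracle


def test_genome_is_deterministic_per_seed():
    a = make_toy_genome(1, 10000, 3, 4, seed=7)
    b = make_toy_genome(1, 10000, 3, 4, seed=7)
    assert a[0].chroms == b[0].chroms
    assert a[1] == b[1]
    assert sum(len(g.exons) for g in a[1]) == 12


def test_genome_seeds_differ():
    a, _ = make_toy_genome(2, 10000, 2, 4, seed=1)
    b, _ = make_toy_genome(2, 10000, 2, 4, seed=2)
    assert a.chroms != b.chroms


def test_genome_sizing_error_names_bound():
    with pytest.raises(SizingError, match="60"):
        make_toy_genome(1, 100, 3, 4, seed=7)


def test_genes_fit_with_spacers():
    genome, genes = make_toy_genome(2, 15000, 6, 3, seed=5)
    for gene in genes:
        assert gene.exons[-1][1] <= len(genome.chroms[gene.chrom])
    # intergenic spacing >= 20 within each chromosome
    for chrom in genome.chroms:
        spans = sorted(
            (g.exons[0][0], g.exons[-1][1]) for g in genes if g.chrom == chrom
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 - e1 > 20


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_planted_geometry_is_sound(seed):
    """Brute-force translation of the concatenated circle from the planted
    start yields a junction-crossing ORF, and the upstream window holds the
    planted RRACH motif."""
    genome, genes = make_toy_genome(
        1, 5000, 1, 4, seed=seed, exon_lengths={0: [100, 90, 93, 90]}
    )
    genome, entry = plant_coding_circ(genes[0], genome, 373, 366, 4, seed=seed, aa_length=130)
    orfs = orf_oracle(entry.sequence)
    match = [o for o in orfs if o[0] == entry.orf_start]
    assert match, "no junction-crossing ORF at the planted start"
    start, aa, peptide, stop_start, crossings, infinite = match[0]
    assert aa == 130 and crossings >= 1 and not infinite
    assert stop_start == entry.stop_start
    gaps = [g for (_, end, _, g) in rrach_oracle(entry.sequence, entry.orf_start) if end == entry.motif_end]
    assert entry.motif_offset in gaps


def test_plant_small_wrap_once_geometry():
    genome, genes = make_toy_genome(1, 5000, 1, 1, seed=3, exon_lengths={0: [30]})
    genome, entry = plant_coding_circ(genes[0], genome, 30, 28, 4, seed=3)
    orfs = find_circular_orfs(entry.transcript())
    best = [o for o in orfs if o.start == 28][0]
    assert best.junction_crossings == 1
    # oracle agreement on the triple/quad concatenation
    assert (best.start, best.aa_length, best.peptide, best.stop_start, best.junction_crossings, best.is_infinite) in orf_oracle(entry.sequence)


def test_plant_contradictory_geometry_raises():
    genome, genes = make_toy_genome(1, 5000, 1, 1, seed=1, exon_lengths={0: [9]})
    with pytest.raises(PlantingError):
        plant_coding_circ(genes[0], genome, 9, 1, 4, seed=1)


def test_plant_rejects_stop_inside_first_copy():
    genome, genes = make_toy_genome(1, 5000, 1, 4, seed=0, exon_lengths={0: [100, 90, 93, 90]})
    with pytest.raises(PlantingError, match="crossing"):
        plant_coding_circ(genes[0], genome, 373, 100, 4, seed=0, aa_length=2)


def _truth_one(seed=0):
    genome, genes = make_toy_genome(1, 5000, 2, 3, seed=seed)
    truth = TruthTable()
    for g in genes:
        truth.add(null_circle_truth(g, genome))
    return genome, genes, truth


def test_counts_deterministic_and_calibrated():
    """With dispersion 0 and 10,000 replicate draws the empirical mean is
    within 1% of the specified mean."""
    genome, genes, truth = _truth_one()
    design = SimDesign(replicates=2, dispersion=0.0, baseline_mean=80.0, seed=9)
    m1 = simulate_junction_counts(truth, design)
    m2 = simulate_junction_counts(truth, design)
    assert (m1.counts.values == m2.counts.values).all()

    big = SimDesign(replicates=5000, dispersion=0.0, baseline_mean=80.0, seed=9)
    m = simulate_junction_counts(truth, big)
    cid = m.circ_ids[0]
    emp = m.counts.loc[cid].mean()
    assert abs(emp - 80.0) / 80.0 < 0.01
    assert truth[cid].expected_counts[m.sample_ids[0]] == pytest.approx(80.0)


def test_counts_apply_planted_fold_change_to_treated_only():
    genome, genes, truth = _truth_one()
    cid = sorted(truth)[0]
    design = SimDesign(
        replicates=2000,
        dispersion=0.0,
        baseline_mean=64.0,
        planted_log2fc={cid: {"d10": -2.0}},
        seed=4,
    )
    m = simulate_junction_counts(truth, design)
    veh = m.counts.loc[cid, m.samples_for("vehicle", "d10")].mean()
    trt = m.counts.loc[cid, m.samples_for("treated", "d10")].mean()
    trt_d20 = m.counts.loc[cid, m.samples_for("treated", "d20")].mean()
    assert veh == pytest.approx(64.0, rel=0.05)
    assert trt == pytest.approx(16.0, rel=0.05)
    assert trt_d20 == pytest.approx(64.0, rel=0.05)


def test_negative_binomial_is_overdispersed():
    genome, genes, truth = _truth_one()
    design = SimDesign(replicates=3000, dispersion=0.5, baseline_mean=50.0, seed=2)
    m = simulate_junction_counts(truth, design)
    var = m.counts.loc[m.circ_ids[0]].var()
    # variance m + alpha m^2 = 50 + 0.5*2500 = 1300 >> Poisson's 50
    assert var > 500


def test_reads_depth_zero_yields_only_linear(small_screen):
    genome, genes, truth = small_screen
    reads, rt = simulate_reads(genome, truth, depth=0, read_len=60, seed=1)
    assert reads and all(v["origin"] == "linear" for v in rt.values())


def test_reads_cover_every_junction_with_anchors(small_screen):
    genome, genes, truth = small_screen
    reads, rt = simulate_reads(genome, truth, depth=50, read_len=60, seed=1, min_anchor=19)
    by_seq = dict(reads)
    for cid, entry in truth.items():
        junc = [rid for rid, v in rt.items() if v["origin"] == cid and v["crosses_bsj"]]
        assert len(junc) >= 1
        L = entry.length
        circ = entry.transcript()
        for rid in junc:
            seq = by_seq[rid]
            # read overlaps the BSJ by >= min_anchor on both sides
            found = False
            for arm5 in range(19, len(seq) - 19 + 1):
                if circ.window(L - arm5 + 1, len(seq)) == seq:
                    found = True
            assert found, rid


def test_reads_deterministic_and_validate_length(small_screen):
    genome, genes, truth = small_screen
    a, _ = simulate_reads(genome, truth, depth=5, read_len=60, seed=7)
    b, _ = simulate_reads(genome, truth, depth=5, read_len=60, seed=7)
    assert a == b
    with pytest.raises(ValueError, match="min_anchor"):
        simulate_reads(genome, truth, depth=5, read_len=30, seed=7, min_anchor=19)
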