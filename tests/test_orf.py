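"""Circular ORF finder, RRACH scanner, peptide mass."""

import math

import numpy as np
import pytest

from circorf import (
    CircularTranscript,
    find_circular_orfs,
    mutate_start,
    peptide_mass,
    scan_rrach,
)
from conftest import orf_oracle, random_circle, rrach_oracle


def _circ(seq, cid="c"):
    return CircularTranscript(circ_id=cid, gene_id="g", sequence=seq)


def _as_tuples(orfs):
    return [
        (o.start, o.aa_length, o.peptide, o.stop_start, o.junction_crossings, o.is_infinite)
        for o in orfs
    ]


def test_orf_crosses_junction_simple():
    orfs = find_circular_orfs(_circ("AAATAAAATG"))
    assert _as_tuples(orfs) == [(8, 2, "MK", 4, 1, False)]


def test_orf_wholly_linear_excluded_by_crossing_filter():
    circ = _circ("ATGAAATAG")
    assert find_circular_orfs(circ, require_crossing=True) == []
    orfs = find_circular_orfs(circ, require_crossing=False)
    assert _as_tuples(orfs) == [(1, 2, "MK", 7, 0, False)]


def test_orf_infinite_rolling_circle():
    orfs = find_circular_orfs(_circ("ATGGGGGGG"))
    assert len(orfs) == 1
    o = orfs[0]
    assert o.is_infinite and o.stop_start is None
    assert o.aa_length == 3 and o.peptide == "MGG"
    assert o.junction_crossings == 1


def test_orf_reference_geometry(planted_circle, planted_entry):
    """The 373-nt circle with its start at +366 and a 130-residue product
    puts the stop codon at +10..+12, crossing the junction twice."""
    orfs = [o for o in find_circular_orfs(planted_circle) if o.start == 366]
    assert len(orfs) == 1
    o = orfs[0]
    assert o.aa_length == 130
    assert o.stop_start == 10
    assert o.junction_crossings == 2
    assert o.wraps == pytest.approx(393 / 373)
    assert o.peptide.startswith("M") and len(o.peptide) == 130


@pytest.mark.parametrize("require_crossing", [True, False])
def test_orf_matches_bruteforce_on_random_circles(require_crossing):
    """Finder output equals brute-force enumeration on the 4-fold
    concatenation (starts, peptides, stops, crossings) for random circles."""
    rng = np.random.default_rng(99)
    for _ in range(60):
        L = int(rng.integers(6, 91))
        circ = random_circle(rng, L)
        got = _as_tuples(find_circular_orfs(circ, require_crossing=require_crossing))
        assert got == orf_oracle(circ.sequence, require_crossing=require_crossing)


def test_orf_infinite_iff_frame_cycle_stopless():
    """For every L in 3..30: is_infinite exactly when no in-frame stop lies
    within lcm(L,3) nt of the start."""
    rng = np.random.default_rng(5)
    for L in range(3, 31):
        for _ in range(5):
            circ = random_circle(rng, L)
            cycle = 3 * L // math.gcd(L, 3)
            quad = circ.sequence * 4
            for o in find_circular_orfs(circ, require_crossing=False):
                s0 = o.start - 1
                has_stop = any(
                    quad[s0 + j : s0 + j + 3] in {"TAA", "TAG", "TGA"}
                    for j in range(0, cycle, 3)
                )
                assert o.is_infinite == (not has_stop)


def test_orf_rejects_bad_inputs():
    with pytest.raises(ValueError):
        find_circular_orfs(_circ("AT"))
    with pytest.raises(ValueError, match="position 3"):
        find_circular_orfs(_circ("ATNGGG"))


def test_mutate_start_removes_only_that_orf(planted_circle):
    before = find_circular_orfs(planted_circle, require_crossing=False)
    mutant = mutate_start(planted_circle, 366, "ACC")
    after = find_circular_orfs(mutant, require_crossing=False)
    lost = {o.start for o in before} - {o.start for o in after}
    assert 366 in lost
    # no ORF at other starts is lost unless its frame ran through 366's codon
    assert all(o.start != 366 for o in after)


def test_mutate_start_identity_and_precondition(planted_circle):
    same = mutate_start(planted_circle, 366, "ATG")
    assert same.sequence == planted_circle.sequence
    with pytest.raises(ValueError, match="not a start codon"):
        mutate_start(planted_circle, 100, "ACC")


def test_rrach_reference_coordinates(planted_circle):
    """Motif at +357..+361 with the start at +366: upstream gap of 4 nt,
    inside the 100-nt window."""
    hits = scan_rrach(planted_circle, 366, window=100)
    top = hits[0]
    assert (top.start, top.end) == (357, 361)
    assert top.upstream_gap == 4
    assert top.within_window is True


def test_rrach_no_motif():
    assert scan_rrach(_circ("TTTTTTTTTT"), 1) == []


def test_rrach_junction_spanning_hit():
    # motif GGACT ends exactly at position L; start codon at 3 → gap 2
    circ = _circ("TTTTTGGACT")
    hits = scan_rrach(circ, 3)
    assert [(h.start, h.end, h.upstream_gap) for h in hits] == [(6, 10, 2)]

    # motif wrapping across the junction itself
    circ2 = _circ("ACTTTTTTGG")  # pentamer GGACT spans positions 9,10,1,2,3
    hits2 = scan_rrach(circ2, 6)
    assert [(h.start, h.end) for h in hits2] == [(9, 3)]
    assert hits2[0].upstream_gap == 2


def test_rrach_matches_doubled_sequence_oracle():
    rng = np.random.default_rng(17)
    for _ in range(50):
        L = int(rng.integers(6, 91))
        circ = random_circle(rng, L)
        orf_start = int(rng.integers(1, L + 1))
        got = [(h.start, h.end, h.motif_seq, h.upstream_gap) for h in scan_rrach(circ, orf_start)]
        assert got == rrach_oracle(circ.sequence, orf_start)


def test_rrach_window_semantics(planted_circle):
    hits = scan_rrach(planted_circle, 366, window=9)
    top = hits[0]
    assert top.upstream_gap == 4 and top.within_window is True  # 4+5 <= 9
    hits8 = scan_rrach(planted_circle, 366, window=8)
    assert hits8[0].within_window is False  # pentamer no longer fully inside
    with pytest.raises(ValueError):
        scan_rrach(planted_circle, 366, window=4)


@pytest.mark.parametrize(
    "peptide, expected",
    [("G", 75.07), ("MK", 277.38), ("GAS", 233.22)],
)
def test_peptide_mass_average_scale(peptide, expected):
    assert peptide_mass(peptide) == pytest.approx(expected, abs=0.02)


def test_peptide_mass_rejects_invalid():
    with pytest.raises(ValueError):
        peptide_mass("")
    with pytest.raises(ValueError, match="position 2"):
        peptide_mass("GXS")
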