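"""Circular ORF enumeration, RRACH m6A motif scanning and peptide properties.

Translation on a circle differs from the linear case in three ways this
module models explicitly:

* an ORF may **cross the back-splice junction** (the reading frame passes
  the L→1 boundary) — the hallmark the screen selects for;
* an ORF may **wrap** the circle more than once (rolling-circle reading)
  before meeting an in-frame stop;
* when the circle length is such that the frame cycle contains no stop at
  all, translation never terminates: an **infinite ORF**.  After
  lcm(L, 3) nt the frame revisits its initial (position, phase) state, so
  scanning that many nucleotides decides finiteness exactly.

The m6A scanner looks for the RRACH consensus (R = G/A, H = A/C/U, matched
as A/C/T on the DNA alphabet) anywhere on the circle, including pentamers
spanning the junction, and reports each hit's circular distance upstream of
a given start codon.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from Bio.Seq import Seq

from .assembly import CircularTranscript, circ_pos

__all__ = [
    "CircOrf",
    "MotifHit",
    "RRACH_PATTERN",
    "find_circular_orfs",
    "mutate_start",
    "peptide_mass",
    "scan_rrach",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
RRACH_PATTERN = re.compile(r"(?=([GA][GA]AC[ACT]))")

# average (not monoisotopic) residue masses, Da
_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
_WATER = 18.0153


@dataclass(frozen=True)
class CircOrf:
    """An open reading frame on a circular transcript.

    ``start`` and ``stop_start`` are circle coordinates (1..L) of the first
    nucleotide of the start and stop codons; ``junction_crossings`` counts
    how many times the frame passes the L→1 boundary from the start codon
    through the stop codon inclusive; ``wraps`` is total nucleotides read
    divided by L.  Infinite (rolling-circle) ORFs have no stop; their
    peptide is one full frame cycle of lcm(L,3)/3 residues, which repeats
    indefinitely.
    """

    circ_id: str
    start: int
    aa_length: int
    peptide: str
    stop_start: int | None
    junction_crossings: int
    wraps: float
    is_infinite: bool


def _validate_circle(circ: CircularTranscript) -> None:
    if circ.length < 3:
        raise ValueError(f"{circ.circ_id}: circle length {circ.length} < 3")
    for i, b in enumerate(circ.sequence):
        if b not in "ACGT":
            raise ValueError(
                f"{circ.circ_id}: non-ACGT base {b!r} at circle position {i + 1}"
            )


def find_circular_orfs(
    circ: CircularTranscript,
    start_codon: str = "ATG",
    require_crossing: bool = True,
) -> list:
    """Enumerate ORFs starting at every occurrence of ``start_codon`` on the
    circle (junction-spanning occurrences included).

    From each start, codons are read forward circularly until the first
    in-frame stop, or until lcm(L, 3) nt have been read without one, in
    which case the ORF is infinite.  With ``require_crossing`` (the screen's
    criterion) ORFs that never pass the back-splice junction are dropped.
    Results are sorted by peptide length descending, then start ascending.
    """
    _validate_circle(circ)
    L = circ.length
    seq = circ.sequence
    cycle = 3 * L // math.gcd(L, 3)  # lcm(L, 3)
    extended = seq * (cycle // L + 2)  # long enough for any start in 1..L
    orfs = []
    doubled = seq * 2
    for s0 in range(L):
        if doubled[s0 : s0 + 3] != start_codon:
            continue
        stop_at = None  # nt offset (from start) of the stop codon's first nt
        for j in range(0, cycle, 3):
            if extended[s0 + j : s0 + j + 3] in STOP_CODONS:
                stop_at = j
                break
        start = s0 + 1
        if stop_at is None:
            n_aa = cycle // 3
            total_nt = cycle
            stop_start = None
            infinite = True
            peptide = str(Seq(extended[s0 : s0 + cycle]).translate())
        else:
            n_aa = stop_at // 3
            total_nt = stop_at + 3
            stop_start = circ_pos(start + stop_at, L)
            infinite = False
            peptide = str(Seq(extended[s0 : s0 + stop_at]).translate())
        # A crossing happens when the frame reads past position L into
        # position 1, i.e. between nt offsets t and t+1 with t a multiple of
        # L and both offsets inside the read span [start, start+total_nt-1].
        # An ORF whose stop ends exactly at position L therefore crosses 0
        # times.  Infinite ORFs wrap forever; report crossings per frame
        # cycle (cycle/L, always >= 1).
        if infinite:
            crossings = cycle // L
        else:
            crossings = (start + total_nt - 2) // L - (start - 1) // L
        if require_crossing and crossings == 0:
            continue
        orfs.append(
            CircOrf(
                circ_id=circ.circ_id,
                start=start,
                aa_length=n_aa,
                peptide=peptide,
                stop_start=stop_start,
                junction_crossings=crossings,
                wraps=total_nt / L,
                is_infinite=infinite,
            )
        )
    orfs.sort(key=lambda o: (-o.aa_length, o.start))
    return orfs


def mutate_start(
    circ: CircularTranscript, pos: int, replacement: str = "ACC"
) -> CircularTranscript:
    """Copy of the circle with the start codon at ``pos`` replaced.

    The canonical translation-incompetent mutant replaces ATG with ACC.
    Raises if ``pos`` does not hold an ATG.
    """
    if len(replacement) != 3 or set(replacement) - set("ACGT"):
        raise ValueError(f"replacement must be an ACGT codon, got {replacement!r}")
    L = circ.length
    codon = circ.window(pos, 3)
    if codon != "ATG":
        raise ValueError(
            f"{circ.circ_id}: position {pos} holds {codon!r}, not a start codon"
        )
    seq = list(circ.sequence)
    for k, b in enumerate(replacement):
        seq[circ_pos(pos + k, L) - 1] = b
    return CircularTranscript(
        circ_id=circ.circ_id,
        gene_id=circ.gene_id,
        sequence="".join(seq),
        exon_blocks=circ.exon_blocks,
    )


@dataclass(frozen=True)
class MotifHit:
    """One RRACH occurrence on the circle.

    ``start``/``end`` are circle coordinates of the pentamer (``end`` wraps
    below ``start`` when the motif spans the junction); ``upstream_gap`` is
    the circular distance in nt between the motif's last base and the start
    codon's first base; ``within_window`` marks pentamers lying entirely
    within the window immediately 5' of the start codon.
    """

    start: int
    end: int
    motif_seq: str
    upstream_gap: int
    within_window: bool


def scan_rrach(circ: CircularTranscript, orf_start: int, window: int = 100) -> list:
    """Find all RRACH pentamers on the circle, junction-spanning included,
    and their circular distances upstream of ``orf_start``.

    ``within_window`` requires the whole pentamer inside the ``window`` nt
    immediately 5' of the start codon (upstream_gap + 5 <= window), i.e. the
    motif does not overlap the start codon itself.  Hits are sorted by
    upstream gap ascending.
    """
    _validate_circle(circ)
    if window < 5:
        raise ValueError(f"window must be >= 5 nt, got {window}")
    L = circ.length
    if not 1 <= orf_start <= L:
        raise ValueError(f"orf_start {orf_start} outside 1..{L}")
    doubled = circ.sequence * 2
    hits = []
    for m in RRACH_PATTERN.finditer(doubled):
        s0 = m.start()
        if s0 >= L:
            break  # every circular position already covered
        start = s0 + 1
        end = circ_pos(start + 4, L)
        gap = (orf_start - end - 1) % L
        hits.append(
            MotifHit(
                start=start,
                end=end,
                motif_seq=m.group(1),
                upstream_gap=gap,
                within_window=gap + 5 <= window,
            )
        )
    hits.sort(key=lambda h: (h.upstream_gap, h.start))
    return hits


def peptide_mass(peptide: str) -> float:
    """Average molecular mass of a peptide in Da (residue masses + water)."""
    if not peptide:
        raise ValueError("empty peptide")
    mass = _WATER
    for i, aa in enumerate(peptide):
        try:
            mass += _RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"invalid residue {aa!r} at position {i + 1}") from None
    return mass
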