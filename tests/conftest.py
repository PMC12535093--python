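"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's own circular-index
arithmetic: they operate on explicit tandem concatenations of the circle
sequence and count junction crossings by walking base transitions.
"""

from __future__ import annotations

import math

import pytest

from circorf import CircularTranscript
from circorf.pipeline import ScreenConfig, build_truth

STOPS = {"TAA", "TAG", "TGA"}

_CODON = {}


def _codon_table() -> dict:
    global _CODON
    if not _CODON:
        from Bio.Data.CodonTable import unambiguous_dna_by_id

        _CODON = dict(unambiguous_dna_by_id[1].forward_table)
    return _CODON


def orf_oracle(seq: str, require_crossing: bool = True) -> list:
    """Brute-force ORF enumeration over the 4-fold concatenation.

    Returns tuples (start, aa_length, peptide, stop_start, crossings,
    is_infinite) sorted like the finder's output.  Crossings are counted by
    walking every read base and tallying transitions off position L.
    """
    table = _codon_table()
    L = len(seq)
    cycle = 3 * L // math.gcd(L, 3)
    quad = seq * 4
    out = []
    for s0 in range(L):
        if quad[s0 : s0 + 3] != "ATG":
            continue
        peptide = []
        stop_j = None
        for j in range(s0, s0 + cycle, 3):
            codon = quad[j : j + 3]
            if codon in STOPS:
                stop_j = j
                break
            peptide.append(table[codon])
        if stop_j is None:
            total_nt = cycle
            stop_start = None
            infinite = True
        else:
            total_nt = stop_j - s0 + 3
            stop_start = (stop_j % L) + 1
            infinite = False
        crossings = 0
        for i in range(total_nt if infinite else total_nt - 1):
            if (s0 + i) % L == L - 1:
                crossings += 1
        if require_crossing and crossings == 0:
            continue
        out.append(
            (s0 + 1, len(peptide), "".join(peptide), stop_start, crossings, infinite)
        )
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def rrach_oracle(seq: str, orf_start: int) -> list:
    """Pattern search on the doubled sequence with step-walked upstream gaps.

    Returns (start, end, motif, gap) tuples sorted by gap then start.
    """
    L = len(seq)
    doubled = seq * 2
    hits = []
    for i in range(L):
        penta = doubled[i : i + 5]
        if (
            penta[0] in "GA"
            and penta[1] in "GA"
            and penta[2] == "A"
            and penta[3] == "C"
            and penta[4] in "ACT"
        ):
            end0 = (i + 4) % L  # 0-based position of the motif's last base
            # walk forward from the base after the motif until the start codon
            gap = 0
            p = (end0 + 1) % L
            while p != orf_start - 1:
                gap += 1
                p = (p + 1) % L
            hits.append((i + 1, end0 + 1, penta, gap))
    hits.sort(key=lambda t: (t[3], t[0]))
    return hits


def random_circle(rng, length: int) -> CircularTranscript:
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return CircularTranscript(circ_id=f"rand{length}", gene_id="rand", sequence=seq)


@pytest.fixture(scope="session")
def small_screen():
    """Toy genome with one planted coding circle among four nulls."""
    genome, genes, truth = build_truth(ScreenConfig(n_circ=5), seed=42)
    return genome, genes, truth


@pytest.fixture(scope="session")
def planted_entry(small_screen):
    _, _, truth = small_screen
    return next(e for e in truth.values() if e.coding)


@pytest.fixture(scope="session")
def planted_circle(planted_entry):
    return planted_entry.transcript()
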