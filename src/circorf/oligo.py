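"""Junction-spanning validation oligos.

A circle's only sequence absent from its linear host transcript is the
back-splice junction itself, so circle-specific reagents must straddle it:
an antisense FISH probe whose window is centered on the junction, and a
divergent qPCR primer pair that points outward on the linear gene but
amplifies across the junction on the circle.  Melting temperatures use the
Wallace rule — only relative feasibility matters at this scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .assembly import CircularTranscript, circ_pos, revcomp

__all__ = [
    "Oligo",
    "OligoDesignError",
    "check_grna",
    "check_specificity",
    "design_divergent_primers",
    "design_junction_probe",
    "linear_amplicon",
    "wallace_tm",
]


class OligoDesignError(ValueError):
    """No oligo satisfies the requested constraints."""


@dataclass(frozen=True)
class Oligo:
    """A designed oligonucleotide.

    ``span`` records the circle coordinates the oligo covers (start, end;
    end wraps below start for junction-spanning oligos).  ``arm5``/``arm3``
    are the nt on the 5'- and 3'-of-junction side (probes and junction
    oligos only).
    """

    kind: str       # divergent_fwd / divergent_rev / probe / grna
    sequence: str
    span: tuple
    tm: float
    arm5: int = 0
    arm3: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise OligoDesignError(f"{self.kind}: empty oligo")


def wallace_tm(oligo_seq: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C) °C."""
    if not oligo_seq:
        raise ValueError("empty oligo")
    bad = set(oligo_seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid bases {sorted(bad)} in oligo")
    at = oligo_seq.count("A") + oligo_seq.count("T")
    return 2.0 * at + 4.0 * (len(oligo_seq) - at)


def _tm_lenient(seq: str) -> float:
    return wallace_tm(seq) if len(seq) >= 1 else 0.0


def design_junction_probe(
    circ: CircularTranscript, length: int = 22, min_arm: int = 8
) -> Oligo:
    """Antisense probe against the sense window centered on the junction.

    The sense window takes ceil(length/2) nt ending at position L (the
    5'-of-junction arm gets the extra base for even lengths) and the rest
    from position 1; the probe is its reverse complement.
    """
    L = circ.length
    if length > L:
        raise OligoDesignError(f"probe length {length} exceeds circle length {L}")
    if 2 * min_arm > length:
        raise OligoDesignError(
            f"2×min_arm = {2 * min_arm} exceeds probe length {length}"
        )
    arm5 = math.ceil(length / 2)
    arm3 = length - arm5
    if arm5 < min_arm or arm3 < min_arm:
        raise OligoDesignError(
            f"arm split {arm5}/{arm3} violates min_arm {min_arm}"
        )
    start = L - arm5 + 1
    sense = circ.window(start, length)
    probe = revcomp(sense)
    return Oligo(
        kind="probe",
        sequence=probe,
        span=(start, circ_pos(start + length - 1, L)),
        tm=wallace_tm(probe),
        arm5=arm5,
        arm3=arm3,
    )


def design_divergent_primers(
    circ: CircularTranscript,
    primer_len: int = 20,
    max_amplicon: int | None = None,
) -> tuple:
    """Divergent primer pair whose circular amplicon crosses the junction.

    The forward primer is sense with its 5' end upstream of the junction;
    the reverse primer is antisense with its 5' end downstream of it.  On
    the linear transcript the pair points apart and yields no product; on
    the circle the amplicon runs from the forward 5' end across the
    junction to the reverse 5' end (circular distance + 1 nt).

    Returns ``(forward, reverse, amplicon_length)``.
    """
    L = circ.length
    if L < 2 * primer_len + 10:
        raise OligoDesignError(
            f"circle length {L} < 2×primer_len+10 = {2 * primer_len + 10}"
        )
    amp = max_amplicon if max_amplicon is not None else min(L, 150)
    if amp > L:
        raise OligoDesignError(f"max_amplicon {amp} exceeds circle length {L}")
    if amp < 2 * primer_len + 2:
        raise OligoDesignError(
            f"max_amplicon {amp} cannot hold two {primer_len}-nt primers"
        )

    for shrink in range(0, min(11, amp - 2 * primer_len - 1)):
        a = amp - shrink
        left = max(primer_len, a // 2)     # nt of amplicon before the junction
        right = a - left                   # nt after the junction
        if right < primer_len:
            continue
        f5 = L - left + 1                  # forward primer 5' end
        r5 = right                         # reverse primer 5' end
        fwd_seq = circ.window(f5, primer_len)
        rev_seq = revcomp(circ.window(r5 - primer_len + 1, primer_len))
        if _unique_three_prime(circ, fwd_seq, sense=True) and _unique_three_prime(
            circ, rev_seq, sense=False
        ):
            fwd = Oligo(
                kind="divergent_fwd",
                sequence=fwd_seq,
                span=(f5, circ_pos(f5 + primer_len - 1, L)),
                tm=wallace_tm(fwd_seq),
            )
            rev = Oligo(
                kind="divergent_rev",
                sequence=rev_seq,
                span=(circ_pos(r5 - primer_len + 1, L), r5),
                tm=wallace_tm(rev_seq),
            )
            return fwd, rev, a
    raise OligoDesignError(
        f"{circ.circ_id}: no divergent placement with unique 3' ends "
        f"within amplicon {amp}"
    )


def _unique_three_prime(circ: CircularTranscript, primer: str, sense: bool, k: int = 12) -> bool:
    """The primer's 3'-terminal k-mer occurs exactly once on its template
    strand of the circle."""
    kmer = primer[-k:]
    target = kmer if sense else revcomp(kmer)
    doubled = circ.sequence * 2
    n = 0
    i = doubled.find(target)
    while i != -1 and i < circ.length:
        n += 1
        i = doubled.find(target, i + 1)
    return n == 1


def linear_amplicon(fwd: Oligo, rev: Oligo, template: str) -> int | None:
    """PCR product length of the pair on a linear template, or None.

    A product requires the forward primer on the sense strand upstream of
    the reverse primer's (antisense) binding site.  Divergent junction
    primers yield None on the linear spliced transcript.
    """
    f = template.find(fwd.sequence)
    rc = revcomp(rev.sequence)
    best = None
    while f != -1:
        j = template.find(rc, f + len(fwd.sequence))
        if j != -1:
            length = j + len(rc) - f
            best = length if best is None else min(best, length)
        f = template.find(fwd.sequence, f + 1)
    return best


def circular_amplicon(fwd: Oligo, rev: Oligo, L: int) -> int:
    """Amplicon length on the circle: circular distance from the forward 5'
    end to the reverse 5' end, + 1."""
    f5 = fwd.span[0]
    r5 = rev.span[1]
    return (r5 - f5) % L + 1


def check_specificity(oligo: Oligo, circ: CircularTranscript, linear_mrna: str) -> tuple:
    """(hits_circle, hits_linear): exact occurrence of the oligo or its
    reverse complement on the (pseudo-circularized) circle and on the
    linear spliced transcript."""
    doubled = circ.sequence * 2
    fwd, rc = oligo.sequence, revcomp(oligo.sequence)
    hits_circle = fwd in doubled or rc in doubled
    hits_linear = fwd in linear_mrna or rc in linear_mrna
    return hits_circle, hits_linear


def check_grna(grna: str, circ: CircularTranscript, motif_start: int, motif_end: int) -> bool:
    """Verify a guide RNA is reverse-complementary to a circle window that
    overlaps the m6A motif at ``motif_start``..``motif_end``.

    Supports guides targeting windows that span the back-splice junction.
    """
    if set(grna.upper()) - set("ACGTU"):
        raise ValueError("gRNA must be a nucleotide sequence")
    target = revcomp(grna.upper().replace("U", "T"))
    L = circ.length
    doubled = circ.sequence * 2
    motif = {circ_pos(p, L) for p in range(motif_start, motif_start + ((motif_end - motif_start) % L) + 1)}
    i = doubled.find(target)
    while i != -1 and i < L:
        covered = {circ_pos(i + 1 + k, L) for k in range(len(target))}
        if covered & motif:
            return True
        i = doubled.find(target, i + 1)
    return False
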