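"""Spliced circular transcript assembly and circular coordinate arithmetic.

A back-splice junction (BSJ) joins the 3' end of a downstream exon (the
donor) to the 5' end of an upstream exon (the acceptor), producing a
covalently closed circle.  All circle-level work in this package uses the
convention that position +1 is the first nucleotide immediately 3' of the
junction (the acceptor exon's first transcript-orientation base), positions
run 1..L, and the junction lies between positions L and 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "AssemblyError",
    "CircularTranscript",
    "circ_pos",
    "linearize",
    "revcomp",
    "splice_circle",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class AssemblyError(ValueError):
    """Raised when a BSJ cannot be assembled onto annotated exon boundaries."""


@dataclass(frozen=True)
class CircularTranscript:
    """A spliced circular RNA in transcript orientation (DNA alphabet).

    Parameters
    ----------
    circ_id : str
        Identifier of the circle (conventionally ``chrom:acceptor|donor``).
    gene_id : str
        Host gene.
    sequence : str
        Spliced sequence, position 1 first; the back-splice junction lies
        between the last and first base.
    exon_blocks : tuple of (int, int)
        Genomic 1-based closed intervals of the exons included, in genomic
        order, recorded for provenance.
    """

    circ_id: str
    gene_id: str
    sequence: str
    exon_blocks: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise AssemblyError(f"{self.circ_id}: empty circle sequence")
        if self.exon_blocks:
            total = sum(e - s + 1 for s, e in self.exon_blocks)
            if total != len(self.sequence):
                raise AssemblyError(
                    f"{self.circ_id}: exon blocks sum to {total}, "
                    f"sequence length is {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at circle position ``pos`` (any integer offset, wrapped)."""
        return self.sequence[circ_pos(pos, self.length) - 1]

    def window(self, start: int, length: int) -> str:
        """``length`` bases starting at circle position ``start``, wrapping
        past the junction as needed."""
        L = self.length
        s0 = circ_pos(start, L) - 1
        doubled = self.sequence * (2 + length // L)
        return doubled[s0 : s0 + length]


def circ_pos(absolute_offset: int, L: int) -> int:
    """Reduce an absolute 1-based offset to a circle coordinate in 1..L.

    ``circ_pos(374, 373) == 1``: one step past the junction wraps to +1.
    """
    if L < 1:
        raise ValueError(f"circle length must be >= 1, got {L}")
    return (absolute_offset - 1) % L + 1


def linearize(circ: CircularTranscript, copies: int) -> str:
    """Concatenate ``copies`` tandem copies of the circle sequence.

    Pseudo-circularization: scanning a linearized repeat finds features that
    span the back-splice junction.
    """
    if copies < 1:
        raise ValueError(f"copies must be >= 1, got {copies}")
    return circ.sequence * copies


def splice_circle(genome, gene, bsj) -> CircularTranscript:
    """Assemble the spliced circular transcript for a back-splice junction.

    Parameters
    ----------
    genome : mapping of chrom -> sequence
        Reference sequences (a :class:`~circorf.simulate.ToyGenome` or any
        ``dict``-like of uppercase DNA strings).
    gene : GeneModel
        Host gene; the BSJ acceptor and donor must coincide with exon
        boundaries of this gene.
    bsj : BackSpliceJunction
        ``acceptor_pos`` is the genomic coordinate of the first circle
        nucleotide and ``donor_pos`` that of the last (1-based closed,
        acceptor <= donor on the genome).

    Returns
    -------
    CircularTranscript
        Sequence in transcript orientation; position 1 is the acceptor
        exon's first transcript-orientation base.
    """
    chrom_seq = genome[gene.chrom] if not hasattr(genome, "chroms") else genome.chroms[gene.chrom]
    starts = {s for s, _ in gene.exons}
    ends = {e for _, e in gene.exons}
    # On the + strand the acceptor is the 5'-most included exon start and
    # the donor the 3'-most included exon end; on the - strand transcript
    # orientation is reversed, so the roles of genomic start/end swap.
    if gene.strand == "+":
        first_coord, last_coord = bsj.acceptor_pos, bsj.donor_pos
        if first_coord not in starts:
            raise AssemblyError(
                f"BSJ acceptor {gene.chrom}:{bsj.acceptor_pos} is not an exon start of {gene.gene_id}"
            )
        if last_coord not in ends:
            raise AssemblyError(
                f"BSJ donor {gene.chrom}:{bsj.donor_pos} is not an exon end of {gene.gene_id}"
            )
    else:
        # acceptor (first circle base, transcript orientation) sits at a
        # genomic exon END; donor at a genomic exon START
        if bsj.acceptor_pos not in ends:
            raise AssemblyError(
                f"BSJ acceptor {gene.chrom}:{bsj.acceptor_pos} is not an exon end of {gene.gene_id} (- strand)"
            )
        if bsj.donor_pos not in starts:
            raise AssemblyError(
                f"BSJ donor {gene.chrom}:{bsj.donor_pos} is not an exon start of {gene.gene_id} (- strand)"
            )

    lo = min(bsj.acceptor_pos, bsj.donor_pos)
    hi = max(bsj.acceptor_pos, bsj.donor_pos)
    blocks = [(s, e) for s, e in gene.exons if s >= lo and e <= hi]
    if not blocks:
        raise AssemblyError(
            f"no exons of {gene.gene_id} between {lo} and {hi}"
        )
    parts = [chrom_seq[s - 1 : e] for s, e in blocks]
    seq = "".join(parts)
    if gene.strand == "-":
        seq = revcomp(seq)
    circ_id = getattr(bsj, "circ_id", None) or f"{gene.chrom}:{lo}|{hi}"
    return CircularTranscript(
        circ_id=circ_id,
        gene_id=gene.gene_id,
        sequence=seq,
        exon_blocks=tuple(blocks),
    )
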