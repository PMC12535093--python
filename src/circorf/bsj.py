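"""Minimal two-anchor back-splice junction detector.

A junction read is a read whose two segments map in inverted genomic
order: the read's prefix matches the 3' end of a downstream exon (the
donor) and its suffix matches the 5' start of an upstream exon (the
acceptor) of the same gene, both segments ending/starting exactly at
annotated exon boundaries.  Anchors are exact matches only — the toy-scale
genomes this detector targets make mismatch tolerance unnecessary.

"Unique" junction-read support counts distinct read sequences: duplicated
reads contribute once.  Reads whose segments fit more than one junction
are ambiguous and dropped (tallied in :class:`DetectionStats`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .assembly import revcomp

__all__ = [
    "AnchorHit",
    "BackSpliceJunction",
    "DetectionStats",
    "anchor_map",
    "detect_bsj",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_ANCHOR = 19


@dataclass(frozen=True)
class AnchorHit:
    """One exact genomic placement of a read's prefix or suffix segment."""

    read_id: str
    segment: str          # "prefix" or "suffix"
    chrom: str
    strand: str           # orientation of the read relative to the genome
    start: int            # 1-based closed genomic interval of the match
    end: int
    read_offset: int      # 0-based offset of the segment in the oriented read
    length: int


@dataclass
class BackSpliceJunction:
    """A called back-splice junction with per-sample unique-read support.

    ``acceptor_pos`` is the genomic coordinate of the first circle
    nucleotide and ``donor_pos`` that of the last.  On the + strand
    acceptor_pos <= donor_pos — the inverted-order hallmark; on the -
    strand the genomic order is reversed.
    """

    chrom: str
    strand: str
    acceptor_pos: int
    donor_pos: int
    gene_id: str
    counts: dict = field(default_factory=dict)  # sample -> unique junction reads

    @property
    def circ_id(self) -> str:
        lo, hi = sorted((self.acceptor_pos, self.donor_pos))
        return f"{self.chrom}:{lo}|{hi}"

    @property
    def total_support(self) -> int:
        return sum(self.counts.values())


@dataclass
class DetectionStats:
    """Log counters from one detector run."""

    n_reads: int = 0
    n_unique_sequences: int = 0
    n_linear: int = 0
    n_junction: int = 0
    n_ambiguous: int = 0
    n_too_short: int = 0
    n_unmapped: int = 0


def _occurrences(genome, segment: str) -> list:
    """All (chrom, start0) exact occurrences of ``segment`` on the forward
    genome."""
    hits = []
    for chrom in sorted(genome.chroms):
        seq = genome.chroms[chrom]
        i = seq.find(segment)
        while i != -1:
            hits.append((chrom, i))
            i = seq.find(segment, i + 1)
    return hits


def _max_prefix(genome, read: str, min_anchor: int) -> tuple:
    """(k, occurrences) for the longest prefix of length >= min_anchor with
    at least one exact genomic occurrence; (0, []) if none."""
    if not _occurrences(genome, read[:min_anchor]):
        return 0, []
    lo, hi = min_anchor, len(read)  # invariant: prefix of length lo occurs
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _occurrences(genome, read[:mid]):
            lo = mid
        else:
            hi = mid - 1
    return lo, _occurrences(genome, read[:lo])


def _max_suffix(genome, read: str, min_anchor: int) -> tuple:
    if not _occurrences(genome, read[-min_anchor:]):
        return 0, []
    lo, hi = min_anchor, len(read)
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _occurrences(genome, read[-mid:]):
            lo = mid
        else:
            hi = mid - 1
    return lo, _occurrences(genome, read[-lo:])


def anchor_map(read, genome, min_anchor: int = DEFAULT_MIN_ANCHOR) -> list:
    """Exact placements of a read's maximal prefix and suffix segments.

    The read is tried in both orientations (as given, and reverse
    complemented — minus-strand transcripts are thereby handled in
    transcript orientation).  If the maximal prefix covers the whole read
    the read maps contiguously and a single prefix hit spanning it is
    returned per placement.  Reads shorter than 2×min_anchor are skipped
    with a warning (empty result), not an error.
    """
    if min_anchor < 15:
        raise ValueError(f"min_anchor must be >= 15, got {min_anchor}")
    read_id, seq = read if isinstance(read, tuple) else ("read", read)
    if len(seq) < 2 * min_anchor:
        logger.warning("read %s shorter than 2×min_anchor (%d nt); skipped", read_id, len(seq))
        return []
    hits = []
    for strand in "+-":
        oriented = seq if strand == "+" else revcomp(seq)
        pk, p_occ = _max_prefix(genome, oriented, min_anchor)
        for chrom, s0 in p_occ:
            hits.append(
                AnchorHit(read_id, "prefix", chrom, strand, s0 + 1, s0 + pk, 0, pk)
            )
        if pk == len(oriented):
            continue  # contiguous placement; no split to report
        sk, s_occ = _max_suffix(genome, oriented, min_anchor)
        for chrom, s0 in s_occ:
            hits.append(
                AnchorHit(
                    read_id, "suffix", chrom, strand, s0 + 1, s0 + sk,
                    len(oriented) - sk, sk,
                )
            )
    return hits


def _gene_junction_solutions(read: str, genome, gene, min_anchor: int) -> set:
    """All BSJs of one gene explaining ``read`` as a junction read.

    In transcript orientation the read must split as
    [last i nt of donor exon][first len-i nt of acceptor exon] with the
    acceptor at or upstream of the donor and both arms >= min_anchor.
    Both read orientations are tried.
    """
    t_exons = gene.transcript_exons
    t_seqs = [gene.exon_sequence(genome, ex) for ex in t_exons]
    n = len(read)
    solutions = set()
    for oriented in (read, revcomp(read)):
        for d in range(len(t_exons)):          # donor index, transcript order
            for a in range(d + 1):             # acceptor at or upstream
                for i in range(min_anchor, n - min_anchor + 1):
                    if i > len(t_seqs[d]) or n - i > len(t_seqs[a]):
                        continue
                    if oriented[:i] != t_seqs[d][-i:]:
                        continue
                    if oriented[i:] != t_seqs[a][: n - i]:
                        continue
                    if gene.strand == "+":
                        acc = t_exons[a][0]    # acceptor exon genomic start
                        don = t_exons[d][1]    # donor exon genomic end
                    else:
                        acc = t_exons[a][1]
                        don = t_exons[d][0]
                    solutions.add((gene.chrom, gene.strand, acc, don, gene.gene_id))
    return solutions


def detect_bsj(
    reads,
    genome,
    genes,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    sample_of=None,
    stats: DetectionStats | None = None,
) -> list:
    """Call back-splice junctions from reads against an annotated genome.

    Parameters
    ----------
    reads : iterable of (read_id, sequence)
        Error-free reads; identical sequences count once per sample toward
        unique support.
    genome : ToyGenome
    genes : list of GeneModel
    min_anchor : int
        Minimum exact-match length of each read segment (>= 15).
    sample_of : callable, optional
        read_id → sample_id; defaults to a single sample ``"sample1"``.
    stats : DetectionStats, optional
        Filled with run counters when given.

    Returns
    -------
    list of BackSpliceJunction
        Junctions with >= 1 unique junction read in >= 1 sample, sorted by
        (chrom, coordinates).
    """
    if min_anchor < 15:
        raise ValueError(f"min_anchor must be >= 15, got {min_anchor}")
    stats = stats if stats is not None else DetectionStats()
    sample_of = sample_of or (lambda rid: "sample1")

    # unique sequences per sample (duplicates count once)
    seen: dict = {}  # (sample, seq) -> representative read_id
    for rid, seq in reads:
        stats.n_reads += 1
        seen.setdefault((sample_of(rid), seq.upper()), rid)
    stats.n_unique_sequences = len(seen)

    junctions: dict = {}  # (chrom, strand, acc, don, gene) -> {sample: support}
    for (sample, seq), rid in seen.items():
        if len(seq) < 2 * min_anchor:
            stats.n_too_short += 1
            logger.warning("read %s shorter than 2×min_anchor; skipped", rid)
            continue
        # contiguous genomic placement in either orientation → linear read
        if _occurrences(genome, seq) or _occurrences(genome, revcomp(seq)):
            stats.n_linear += 1
            continue
        solutions = set()
        for gene in genes:
            solutions |= _gene_junction_solutions(seq, genome, gene, min_anchor)
        if not solutions:
            stats.n_unmapped += 1
            continue
        if len(solutions) > 1:
            stats.n_ambiguous += 1
            logger.warning("read %s fits %d junctions; dropped", rid, len(solutions))
            continue
        key = solutions.pop()
        stats.n_junction += 1
        junctions.setdefault(key, {})
        junctions[key][sample] = junctions[key].get(sample, 0) + 1

    out = []
    for (chrom, strand, acc, don, gene_id), counts in junctions.items():
        out.append(
            BackSpliceJunction(
                chrom=chrom,
                strand=strand,
                acceptor_pos=acc,
                donor_pos=don,
                gene_id=gene_id,
                counts=dict(sorted(counts.items())),
            )
        )
    out.sort(key=lambda b: (b.chrom, min(b.acceptor_pos, b.donor_pos), max(b.acceptor_pos, b.donor_pos)))
    return out
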