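"""Synthetic data generator for the circRNA coding screen.

Produces a toy genome with annotated multi-exon genes, plants circRNAs with
known back-splice junctions — including a coding circle whose cross-junction
ORF and upstream RRACH motif geometry are fully controlled — and simulates
junction-read count matrices and junction-spanning sequencing reads, all
with recorded ground truth.

The emulated design is a two-condition (vehicle vs. treated)
two-timepoint (day 10, day 20) bulk circRNA-seq experiment with a few
replicates per cell, where treatment suppresses the planted coding circle
at both timepoints.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .assembly import CircularTranscript, circ_pos, revcomp

__all__ = [
    "GeneModel",
    "PlantingError",
    "SimDesign",
    "SizingError",
    "ToyGenome",
    "TruthEntry",
    "TruthTable",
    "make_toy_genome",
    "null_circle_truth",
    "plant_coding_circ",
    "simulate_junction_counts",
    "simulate_reads",
]

_BASES = np.array(list("ACGT"))
STOP_CODONS = ("TAA", "TAG", "TGA")


def _rng(seed: int, label: str) -> np.random.Generator:
    """Derive a reproducible substream from one global seed and a fixed label."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(label.encode())]))


class SizingError(ValueError):
    """Genome too small to pack the requested genes."""


class PlantingError(ValueError):
    """The requested circle geometry is self-contradictory."""


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered list of exons on one chromosome.

    Exons are 1-based closed genomic intervals, sorted by start and
    non-overlapping.  Transcript orientation follows ``strand``.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: exon list empty")
        prev_end = 0
        for s, e in self.exons:
            if e < s:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) has length < 1")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted at ({s},{e})")
            prev_end = e

    @property
    def transcript_exons(self) -> tuple:
        """Exons in transcript (5'→3') order."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def exon_sequence(self, genome: "ToyGenome", exon: tuple) -> str:
        """Transcript-orientation sequence of one exon."""
        s, e = exon
        raw = genome.chroms[self.chrom][s - 1 : e]
        return raw if self.strand == "+" else revcomp(raw)

    def spliced_sequence(self, genome: "ToyGenome") -> str:
        return "".join(self.exon_sequence(genome, ex) for ex in self.transcript_exons)


@dataclass
class ToyGenome:
    """Chromosome name → uppercase DNA sequence."""

    chroms: dict

    def __post_init__(self) -> None:
        for name, seq in self.chroms.items():
            if not seq:
                raise ValueError(f"chromosome {name} is empty")
            if set(seq) - set("ACGT"):
                raise ValueError(f"chromosome {name} contains non-ACGT bases")

    def __getitem__(self, name: str) -> str:
        return self.chroms[name]

    def with_edit(self, chrom: str, pos0: int, bases: str) -> "ToyGenome":
        """Copy with ``bases`` written at 0-based offset ``pos0`` of ``chrom``."""
        seq = self.chroms[chrom]
        new = seq[:pos0] + bases + seq[pos0 + len(bases):]
        chroms = dict(self.chroms)
        chroms[chrom] = new
        return ToyGenome(chroms)


@dataclass
class TruthEntry:
    """Ground truth for one planted circRNA."""

    circ_id: str
    gene_id: str
    chrom: str
    strand: str
    acceptor_pos: int  # genomic coordinate of the first circle nucleotide
    donor_pos: int     # genomic coordinate of the last circle nucleotide
    exon_blocks: tuple
    sequence: str      # spliced circle, position 1 first
    coding: bool = False
    orf_start: int | None = None
    aa_length: int | None = None
    stop_start: int | None = None
    motif_start: int | None = None
    motif_end: int | None = None
    motif_offset: int | None = None
    expected_counts: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def transcript(self) -> CircularTranscript:
        return CircularTranscript(
            circ_id=self.circ_id,
            gene_id=self.gene_id,
            sequence=self.sequence,
            exon_blocks=self.exon_blocks,
        )


class TruthTable(dict):
    """circ_id → :class:`TruthEntry`; JSON-serializable."""

    def add(self, entry: TruthEntry) -> None:
        self[entry.circ_id] = entry

    def to_json(self, path) -> None:
        payload = {
            cid: {**dataclasses.asdict(e), "exon_blocks": [list(b) for b in e.exon_blocks]}
            for cid, e in self.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        table = cls()
        for cid, d in payload.items():
            d["exon_blocks"] = tuple(tuple(b) for b in d["exon_blocks"])
            table[cid] = TruthEntry(**d)
        return table


@dataclass(frozen=True)
class SimDesign:
    """Two-condition × two-timepoint junction-count design.

    Negative-binomial counts with mean m and variance m + dispersion·m²;
    dispersion 0 degenerates to Poisson.  ``planted_log2fc`` maps
    circ_id → {timepoint → log2 fold change of treated vs. vehicle}.
    """

    conditions: tuple = ("vehicle", "treated")
    timepoints: tuple = ("d10", "d20")
    replicates: int = 3
    library_size: int = 1_000_000
    baseline_mean: float = 50.0
    dispersion: float = 0.05
    planted_log2fc: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")

    @property
    def samples(self) -> list:
        """(sample_id, condition, timepoint) triples, fixed order."""
        out = []
        for cond in self.conditions:
            for tp in self.timepoints:
                for r in range(1, self.replicates + 1):
                    out.append((f"{cond}_{tp}_r{r}", cond, tp))
        return out


def make_toy_genome(
    n_chrom: int,
    chrom_len: int,
    n_genes: int,
    exons_per_gene: int,
    seed: int,
    *,
    exon_lengths: dict | None = None,
    exon_len_range: tuple = (60, 120),
    intron_len_range: tuple = (20, 60),
    spacer_len_range: tuple = (30, 100),
) -> tuple:
    """Generate a random genome with packed multi-exon genes.

    Genes are distributed round-robin over chromosomes and packed left to
    right with introns and intergenic spacers (all spacing >= 20 nt).
    ``exon_lengths`` optionally fixes the exon lengths of individual genes
    (gene index → list of lengths) so a planted circle can span exons whose
    lengths sum to an exact target.

    Returns ``(ToyGenome, [GeneModel, ...])``; byte-identical for a fixed
    seed.
    """
    required = n_genes * exons_per_gene * 60
    if n_chrom * chrom_len < required:
        raise SizingError(
            f"genome capacity {n_chrom}×{chrom_len}={n_chrom * chrom_len} nt < "
            f"n_genes×exons_per_gene×60 = {required} nt"
        )
    rng = _rng(seed, "toy-genome")
    exon_lengths = exon_lengths or {}

    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    chrom_seqs = {
        name: "".join(rng.choice(_BASES, size=chrom_len)) for name in chrom_names
    }
    cursors = {name: 0 for name in chrom_names}
    genes = []
    for g in range(n_genes):
        chrom = chrom_names[g % n_chrom]
        lens = list(exon_lengths.get(g, [])) or [
            int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
            for _ in range(exons_per_gene)
        ]
        cur = cursors[chrom] + int(rng.integers(*spacer_len_range))
        exons = []
        for i, ln in enumerate(lens):
            if i > 0:
                cur += int(rng.integers(*intron_len_range))
            exons.append((cur + 1, cur + ln))
            cur += ln
        if cur > chrom_len:
            raise SizingError(
                f"gene g{g + 1} would end at {cur} > chrom_len {chrom_len} on {chrom}; "
                f"increase chrom_len or reduce gene/exon counts"
            )
        cursors[chrom] = cur
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(gene_id=f"g{g + 1}", chrom=chrom, strand=strand, exons=tuple(exons))
        )
    return ToyGenome(chrom_seqs), genes


def _bsj_coords(gene: GeneModel, blocks: tuple) -> tuple:
    """Genomic (acceptor_pos, donor_pos) of a circle over ``blocks``.

    Acceptor = first circle base, donor = last, in transcript orientation.
    """
    if gene.strand == "+":
        return blocks[0][0], blocks[-1][1]
    return blocks[-1][1], blocks[0][0]


def null_circle_truth(gene: GeneModel, genome: ToyGenome, circ_id: str | None = None) -> TruthEntry:
    """Truth entry for a non-coding circle spanning all exons of a gene."""
    blocks = gene.exons
    acc, don = _bsj_coords(gene, blocks)
    seq = gene.spliced_sequence(genome)
    return TruthEntry(
        circ_id=circ_id or f"circ_{gene.gene_id}",
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        acceptor_pos=acc,
        donor_pos=don,
        exon_blocks=blocks,
        sequence=seq,
        coding=False,
    )


def plant_coding_circ(
    gene: GeneModel,
    genome: ToyGenome,
    circle_len: int,
    start_pos: int,
    motif_offset: int,
    seed: int,
    *,
    aa_length: int | None = None,
    motif_seq: str = "GGACT",
    circ_id: str | None = None,
) -> tuple:
    """Edit exon bases so the gene hosts a coding circle with known geometry.

    On the spliced circle of length ``circle_len`` (a contiguous run of
    exons summing exactly to that length):

    * an ATG occupies ``start_pos``..``start_pos+2``;
    * the first in-frame stop (TAA) lies past the back-splice junction, so
      the ORF crosses it at least once; ``aa_length`` picks the peptide
      length (default: the shortest that forces the crossing);
    * an RRACH pentamer ends ``motif_offset`` nt upstream of the start
      codon, measured circularly;
    * no other in-frame stop intervenes before the planted one.

    Returns ``(edited ToyGenome, TruthEntry)``.  Contradictory geometry
    (overlapping fixed bases wanting different letters, or a stop that
    cannot clear the junction) raises :class:`PlantingError`.
    """
    L = circle_len
    if not 1 <= start_pos <= L:
        raise PlantingError(f"start_pos {start_pos} outside 1..{L}")
    if not 0 <= motif_offset <= 100:
        raise PlantingError(f"motif_offset {motif_offset} outside 0..100")
    import re
    if not re.fullmatch(r"[GA][GA]AC[ACT]", motif_seq):
        raise PlantingError(f"motif_seq {motif_seq!r} does not match RRACH")

    # contiguous exon run (transcript orientation) summing exactly to L
    t_exons = gene.transcript_exons
    lens = [e - s + 1 for s, e in t_exons]
    run = None
    for i in range(len(lens)):
        total = 0
        for j in range(i, len(lens)):
            total += lens[j]
            if total == L:
                run = (i, j)
                break
            if total > L:
                break
        if run:
            break
    if run is None:
        raise PlantingError(
            f"{gene.gene_id}: no contiguous exon run sums to circle_len={L} "
            f"(exon lengths {lens})"
        )
    run_exons = t_exons[run[0] : run[1] + 1]

    # smallest peptide pushing the stop past the junction: the stop codon's
    # last base must have absolute offset > L
    n_min = max(1, math.ceil((L - start_pos - 1) / 3))
    n_aa = aa_length if aa_length is not None else n_min
    cycle = 3 * L // math.gcd(L, 3)
    if n_aa < n_min:
        raise PlantingError(
            f"aa_length={n_aa} leaves the stop codon inside the first copy "
            f"(crossing constraint needs >= {n_min} for start {start_pos}, L={L})"
        )
    if 3 * (n_aa + 1) > cycle:
        raise PlantingError(
            f"aa_length={n_aa} exceeds the frame cycle lcm(L,3)={cycle}; "
            f"max finite length is {cycle // 3 - 1}"
        )

    fixed: dict = {}

    def fix(pos: int, base: str, what: str) -> None:
        p = circ_pos(pos, L)
        if fixed.get(p, base) != base:
            raise PlantingError(
                f"contradictory geometry: position {p} needed for {what} ({base}) "
                f"already fixed to {fixed[p]}"
            )
        fixed[p] = base

    for k, b in enumerate("ATG"):
        fix(start_pos + k, b, "start codon")
    stop_off = start_pos + 3 * n_aa  # absolute offset of the stop codon's first nt
    for k, b in enumerate("TAA"):
        fix(stop_off + k, b, "stop codon")
    motif_end = circ_pos(start_pos - motif_offset - 1, L)
    for k, b in enumerate(motif_seq):
        fix(motif_end - 4 + k, b, "RRACH motif")

    rng = _rng(seed, f"plant:{gene.gene_id}")
    seq = list("".join(rng.choice(_BASES, size=L)))
    for p, b in fixed.items():
        seq[p - 1] = b

    # remove premature in-frame stops; 'C' never occurs in a stop codon, so
    # writing C at a free position can only destroy stops, never create one
    for i in range(n_aa):
        off = start_pos + 3 * i
        pos3 = [circ_pos(off + k, L) for k in range(3)]
        codon = "".join(seq[p - 1] for p in pos3)
        if codon in STOP_CODONS:
            free = [p for p in pos3 if p not in fixed]
            if not free:
                raise PlantingError(
                    f"premature in-frame stop at circle position {pos3[0]} is fully "
                    f"pinned by other planted features"
                )
            seq[free[-1] - 1] = "C"
    circle_seq = "".join(seq)

    # write the circle back into the genome across the selected exons
    genomic_blocks = tuple(sorted(run_exons))
    genomic_concat = circle_seq if gene.strand == "+" else revcomp(circle_seq)
    edited = genome
    offset = 0
    for s, e in genomic_blocks:
        ln = e - s + 1
        edited = edited.with_edit(gene.chrom, s - 1, genomic_concat[offset : offset + ln])
        offset += ln

    acc, don = _bsj_coords(gene, genomic_blocks)
    entry = TruthEntry(
        circ_id=circ_id or f"circ_{gene.gene_id}",
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        acceptor_pos=acc,
        donor_pos=don,
        exon_blocks=genomic_blocks,
        sequence=circle_seq,
        coding=True,
        orf_start=start_pos,
        aa_length=n_aa,
        stop_start=circ_pos(stop_off, L),
        motif_start=circ_pos(motif_end - 4, L),
        motif_end=motif_end,
        motif_offset=motif_offset,
    )
    return edited, entry


def simulate_junction_counts(truth: TruthTable, design: SimDesign, seed: int | None = None):
    """Draw a junction-read count matrix under the stated design.

    Per-sample mean for a circle = baseline_mean × 2^log2fc (treated
    samples only) × library_size / reference library size (first sample).
    Counts are negative binomial (variance m + α·m²); α = 0 gives Poisson.
    Expected counts are recorded in each truth entry.
    """
    from .de import JunctionCountMatrix  # deferred: quantify module owns the type
    import pandas as pd

    rng = _rng(design.seed if seed is None else seed, "junction-counts")
    samples = design.samples
    lib = design.library_size
    libs = {sid: (lib[sid] if isinstance(lib, dict) else lib) for sid, _, _ in samples}
    ref_lib = libs[samples[0][0]]
    circ_ids = sorted(truth)
    rows = []
    for cid in circ_ids:
        lfc_by_tp = design.planted_log2fc.get(cid, {})
        means = []
        for sid, cond, tp in samples:
            m = design.baseline_mean * libs[sid] / ref_lib
            if cond != design.conditions[0]:
                m *= 2.0 ** lfc_by_tp.get(tp, 0.0)
            means.append(m)
        means = np.asarray(means)
        if design.dispersion == 0:
            counts = rng.poisson(means)
        else:
            n = 1.0 / design.dispersion
            p = n / (n + means)
            counts = rng.negative_binomial(n, p)
        truth[cid].expected_counts = {
            sid: float(m) for (sid, _, _), m in zip(samples, means)
        }
        rows.append(counts)
    counts_df = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(samples)), int),
        index=circ_ids,
        columns=[sid for sid, _, _ in samples],
        dtype=int,
    )
    return JunctionCountMatrix(
        counts=counts_df,
        library_sizes=pd.Series(libs),
        conditions=pd.Series({sid: cond for sid, cond, _ in samples}),
        timepoints=pd.Series({sid: tp for sid, _, tp in samples}),
    )


def simulate_reads(
    genome: ToyGenome,
    truth: TruthTable,
    depth: int,
    read_len: int,
    seed: int,
    *,
    min_anchor: int = 19,
    background_factor: int = 10,
) -> tuple:
    """Simulate error-free reads: junction reads over each planted BSJ plus
    linear genomic background reads (``background_factor`` × as many).

    Returns ``(reads, read_truth)`` where ``reads`` is a list of
    ``(read_id, sequence)`` pairs and ``read_truth`` maps read_id →
    ``{"origin": circ_id or "linear", "crosses_bsj": bool}``.  Junction
    reads overlap the back-splice point by at least ``min_anchor`` nt on
    each side and stay within the junction-flanking exons so both segments
    map contiguously.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if read_len < 2 * min_anchor:
        raise ValueError(
            f"read_len {read_len} < 2×min_anchor {2 * min_anchor}: junction reads "
            f"could not anchor on both sides"
        )
    rng = _rng(seed, "reads")
    reads = []
    read_truth = {}
    n_junction = 0
    for cid in sorted(truth):
        entry = truth[cid]
        L = entry.length
        t_exons = (
            entry.exon_blocks
            if entry.strand == "+"
            else tuple(reversed(entry.exon_blocks))
        )
        donor_len = t_exons[-1][1] - t_exons[-1][0] + 1
        acceptor_len = t_exons[0][1] - t_exons[0][0] + 1
        lo = max(min_anchor, read_len - acceptor_len)
        hi = min(read_len - min_anchor, donor_len, L - 1)
        if lo > hi:
            raise ValueError(
                f"{cid}: cannot place a {read_len} nt junction read within the "
                f"junction-flanking exons (donor {donor_len} nt, acceptor {acceptor_len} nt)"
            )
        circ = entry.transcript()
        for i in range(depth):
            arm5 = int(rng.integers(lo, hi + 1))
            seq = circ.window(L - arm5 + 1, read_len)
            rid = f"junc|{cid}|{i + 1}"
            reads.append((rid, seq))
            read_truth[rid] = {"origin": cid, "crosses_bsj": True}
            n_junction += 1
    chrom_names = sorted(genome.chroms)
    n_background = background_factor * max(n_junction, len(truth))
    for i in range(n_background):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        cseq = genome.chroms[chrom]
        start = int(rng.integers(0, len(cseq) - read_len + 1))
        seq = cseq[start : start + read_len]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        rid = f"lin|{i + 1}"
        reads.append((rid, seq))
        read_truth[rid] = {"origin": "linear", "crosses_bsj": False}
    return reads, read_truth
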