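"""Readers and writers for the pipeline's on-disk formats.

FASTA (60-column wrap) and FASTQ (Phred+33, uniform quality 'I') go
through Biopython; GTF is written 1-based closed with gene_id /
transcript_id / exon_number attributes and read back with gffutils;
count matrices and sample sheets are plain TSV via pandas.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import GeneModel, ToyGenome

__all__ = [
    "read_counts_tsv",
    "read_fasta",
    "read_fastq",
    "read_gtf",
    "write_bsj_tsv",
    "write_counts_tsv",
    "write_fasta",
    "write_fastq",
    "write_gtf",
]


def write_fasta(path, sequences: dict) -> None:
    """Write name → sequence as 60-column-wrapped FASTA."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_gtf(path, genes: list) -> None:
    """1-based closed GTF with exon features."""
    with open(path, "w") as fh:
        for gene in genes:
            for i, (s, e) in enumerate(gene.transcript_exons, start=1):
                attrs = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t1"; '
                    f'exon_number "{i}";'
                )
                fh.write(
                    f"{gene.chrom}\tcircorf\texon\t{s}\t{e}\t.\t{gene.strand}\t.\t{attrs}\n"
                )


def read_gtf(path) -> list:
    """Parse exon features back into GeneModels."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: dict = {}
    for feat in db.features_of_type("exon"):
        gid = feat.attributes["gene_id"][0]
        by_gene.setdefault(gid, {"chrom": feat.seqid, "strand": feat.strand, "exons": []})
        by_gene[gid]["exons"].append((feat.start, feat.end))
    genes = []
    for gid in sorted(by_gene):
        info = by_gene[gid]
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=info["chrom"],
                strand=info["strand"],
                exons=tuple(sorted(info["exons"])),
            )
        )
    return genes


def write_fastq(path, reads: list) -> None:
    """Write (read_id, sequence) pairs with uniform quality 'I' (Q40)."""
    records = []
    for rid, seq in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, path, "fastq")


def read_fastq(path) -> list:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fastq")]


def write_counts_tsv(matrix, counts_path, samples_path) -> None:
    """Counts TSV (rows circ_id) plus companion sample sheet."""
    matrix.counts.to_csv(counts_path, sep="\t", index_label="circ_id")
    sheet = pd.DataFrame(
        {
            "sample": matrix.sample_ids,
            "condition": [matrix.conditions[s] for s in matrix.sample_ids],
            "timepoint": [matrix.timepoints[s] for s in matrix.sample_ids],
            "library_size": [int(matrix.library_sizes[s]) for s in matrix.sample_ids],
        }
    )
    sheet.to_csv(samples_path, sep="\t", index=False)


def read_counts_tsv(counts_path, samples_path):
    from .de import JunctionCountMatrix

    counts = pd.read_csv(counts_path, sep="\t", index_col="circ_id")
    sheet = pd.read_csv(samples_path, sep="\t").set_index("sample")
    return JunctionCountMatrix(
        counts=counts.astype(int),
        library_sizes=sheet["library_size"],
        conditions=sheet["condition"],
        timepoints=sheet["timepoint"],
    )


def write_bsj_tsv(path, junctions: list, samples: list | None = None) -> None:
    """BSJ table: genomic 1-based closed coordinates, one support column per
    sample (header documents the convention since circRNA callers vary)."""
    all_samples = samples or sorted({s for j in junctions for s in j.counts})
    with open(path, "w") as fh:
        fh.write("# coordinates are genomic, 1-based, closed; acceptor = first circle nt, donor = last\n")
        cols = ["chrom", "acceptor_pos", "donor_pos", "strand", "gene_id"] + [
            f"n_unique_junction_reads.{s}" for s in all_samples
        ]
        fh.write("\t".join(cols) + "\n")
        for j in junctions:
            row = [j.chrom, str(j.acceptor_pos), str(j.donor_pos), j.strand, j.gene_id]
            row += [str(j.counts.get(s, 0)) for s in all_samples]
            fh.write("\t".join(row) + "\n")
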