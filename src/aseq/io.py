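"""Plain-text readers/writers for the pipeline's tabular and sequence formats.

FASTQ/FASTA parsing goes through Biopython; tables are tab-separated and read
with pandas.  Template tables state both coordinate conventions explicitly:
``snp_offset`` is 0-based within the amplicon, ``genomic_pos`` is 1-based as
printed in variant tables.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO

from .amplicon import AlleleCount, SampleMeta
from .simulate import GeneTemplate

TEMPLATE_COLUMNS = ["gene_id", "snp_offset", "allele_a", "allele_b", "genomic_pos", "anchor_len"]


def read_fastq(path) -> list:
    return list(SeqIO.parse(str(path), "fastq"))


def read_templates(tsv_path, fasta_path) -> list[GeneTemplate]:
    """Load gene templates from a TSV (SNP bookkeeping) plus a FASTA
    (amplicon sequences keyed by gene_id)."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    df = pd.read_csv(tsv_path, sep="\t")
    templates = []
    for _, row in df.iterrows():
        gid = str(row["gene_id"])
        if gid not in seqs:
            raise ValueError(f"template {gid} missing from FASTA")
        templates.append(
            GeneTemplate(
                gene_id=gid,
                amplicon_seq=seqs[gid],
                snp_offset=int(row["snp_offset"]),
                allele_a=str(row["allele_a"]),
                allele_b=str(row["allele_b"]),
                anchor_len=int(row.get("anchor_len", 20) or 20),
                genomic_pos=int(row["genomic_pos"]) if "genomic_pos" in row and pd.notna(row["genomic_pos"]) else None,
            )
        )
    anchors = [t.anchor for t in templates]
    if len(set(anchors)) != len(anchors):
        raise ValueError("templates must have mutually distinct anchors")
    return templates


def write_templates(templates: list[GeneTemplate], tsv_path, fasta_path) -> None:
    with open(fasta_path, "w") as fh:
        for t in templates:
            fh.write(f">{t.gene_id}\n{t.amplicon_seq}\n")
    pd.DataFrame(
        [
            (t.gene_id, t.snp_offset, t.allele_a, t.allele_b, t.genomic_pos, t.anchor_len)
            for t in templates
        ],
        columns=TEMPLATE_COLUMNS,
    ).to_csv(tsv_path, sep="\t", index=False)


def read_sample_meta(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    metas = []
    for _, row in df.iterrows():
        metas.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                cross_type=str(row["cross_type"]),
                pair_id=str(row["pair_id"]),
                material=str(row.get("material", "cDNA") or "cDNA"),
                excluded=bool(row.get("excluded", False)),
                exclusion_reason=str(row.get("exclusion_reason", "") or ""),
            )
        )
    return metas


def write_counts(counts: list[AlleleCount], path) -> None:
    from .amplicon import counts_to_frame

    counts_to_frame(counts).to_csv(path, sep="\t", index=False)


def read_counts(path) -> list[AlleleCount]:
    df = pd.read_csv(path, sep="\t")
    return [
        AlleleCount(
            sample_id=str(r["sample_id"]),
            gene_id=str(r["gene_id"]),
            n_allele_a=int(r["n_allele_a"]),
            n_allele_b=int(r["n_allele_b"]),
            n_other=int(r["n_other"]),
            depth=int(r["depth"]),
        )
        for _, r in df.iterrows()
    ]
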