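"""Reading and writing the pipeline's file formats.

GTF is 1-based with inclusive ends; junction tables carry the 1-based first
and last intron base.  Both are converted to the package's internal 0-based
half-open coordinates here and nowhere else.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import Junction, TranscriptModel

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(path: str | Path, chroms: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in chroms.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gtf(path: str | Path, stage: str | None = None) -> list[TranscriptModel]:
    """Parse exon features of a GTF into TranscriptModel objects."""
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            attrs = dict(_ATTR_RE.findall(f[8]))
            tid = attrs["transcript_id"]
            exons.setdefault(tid, []).append((int(f[3]) - 1, int(f[4])))
            meta[tid] = (attrs.get("gene_id", tid), f[0], f[6])
    out = []
    for tid in sorted(exons):
        gene, chrom, strand = meta[tid]
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(exons[tid])),
                stage=stage,
            )
        )
    return out


def write_gtf(
    path: str | Path,
    transcripts: Iterable[TranscriptModel],
    source: str = "fruitsplice",
) -> None:
    lines = []
    for t in sorted(transcripts, key=lambda t: (t.chrom, t.span, t.transcript_id)):
        attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
        s, e = t.span
        lines.append(
            f"{t.chrom}\t{source}\ttranscript\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
        )
        for xs, xe in t.exons:
            lines.append(
                f"{t.chrom}\t{source}\texon\t{xs + 1}\t{xe}\t.\t{t.strand}\t.\t{attrs}\n"
            )
    with open(path, "w") as fh:
        fh.writelines(lines)


def read_junction_counts(path: str | Path) -> dict[Junction, tuple[int, int]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[Junction, tuple[int, int]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.chrom), int(row.start) - 1, int(row.end), str(row.strand))
        out[key] = (int(row.count_rep1), int(row.count_rep2))
    return out


def write_junction_counts(
    path: str | Path, counts: Mapping[Junction, tuple[int, int]]
) -> None:
    rows = [
        {
            "chrom": chrom,
            "start": s + 1,
            "end": e,
            "strand": strand,
            "count_rep1": c1,
            "count_rep2": c2,
        }
        for (chrom, s, e, strand), (c1, c2) in sorted(counts.items())
    ]
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "count_rep1", "count_rep2"]
    ).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """TPM table: index transcript_id, one column per sample."""
    return pd.read_csv(path, sep="\t", index_col="transcript_id")


def write_expression(path: str | Path, expr: pd.DataFrame) -> None:
    expr.to_csv(path, sep="\t", index_label="transcript_id", float_format="%.12g")
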