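"""Format readers/writers shared across the pipeline.

FASTA goes through Bio.SeqIO.  GFF3 handling is a deliberately narrow
subset: single-exon CDS features only (prokaryotic genomes), 1-based
inclusive coordinates converted to the internal 0-based half-open
convention, round-trip stable.  TSV outputs are tab-separated with a
mandatory header, no quoting, and floats at 6 significant digits so golden
files are bit-stable.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .proteogenomics import AnomalyCall, MatchReport, PeptideDB, RetentionFit
from .types import AnomalyRecord, CdsFeature, CdsSet, Contig, ContigSet, ObservedPeptide, Read, ReadSet

FLOAT_FMT = "%.6g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> ContigSet:
    """Read contigs; sequences uppercased, duplicate ids rejected."""
    contigs = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        contigs.append(Contig(id=rec.id, seq=str(rec.seq).upper()))
    return ContigSet(contigs)


def write_fasta(contigs: ContigSet | ReadSet, path) -> None:
    records = [
        SeqRecord(Seq(c.seq), id=c.id, description="") for c in contigs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reads(path, fmt: str | None = None) -> ReadSet:
    """Read sequencing reads from FASTA or FASTQ (qualities ignored)."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix in (".fq", ".fastq") else "fasta"
    reads = [Read(id=r.id, seq=str(r.seq).upper()) for r in SeqIO.parse(str(path), fmt)]
    return ReadSet(reads)


# ---------------------------------------------------------------------------
# GFF3 (CDS-only, single-exon)

_GFF_COLUMNS = 9


def read_gff3(path) -> CdsSet:
    """Read CDS features; 1-based inclusive -> 0-based half-open.

    Strand must be '+' or '-'; phase is ignored (single-exon CDS only);
    a repeated feature ID (multi-exon CDS) is rejected loudly.
    """
    features: list[CdsFeature] = []
    seen_ids = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _GFF_COLUMNS:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "CDS":
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"{path}:{lineno}: end < start")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            fid = attr_map.get("ID")
            if fid is None:
                raise ValueError(f"{path}:{lineno}: CDS without ID attribute")
            if fid in seen_ids:
                raise ValueError(
                    f"{path}:{lineno}: repeated feature ID {fid!r} "
                    "(multi-exon CDS are not supported)"
                )
            seen_ids.add(fid)
            features.append(
                CdsFeature(
                    id=fid,
                    contig=seqid,
                    start=start_i - 1,
                    end=end_i,
                    strand=strand,
                    anomaly_id=attr_map.get("anomaly") or None,
                )
            )
    return CdsSet(features)


def write_gff3(cds_set: CdsSet, path, source: str = "thermoclades") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in cds_set:
            attrs = f"ID={f.id}"
            if f.anomaly_id:
                attrs += f";anomaly={f.anomaly_id}"
            fh.write(
                "\t".join(
                    [
                        f.contig, source, "CDS", str(f.start + 1), str(f.end),
                        ".", f.strand, "0", attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# TSV outputs (fixed column orders)


def _write_tsv(path, header: list[str], rows: list[list[str]]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        writer.writerow(header)
        writer.writerows(rows)


def write_anomaly_ledger(ledger: list[AnomalyRecord], path) -> None:
    _write_tsv(
        path,
        ["anomaly_id", "category", "contig", "start", "end", "strand"],
        [
            [a.anomaly_id, a.category, a.contig, str(a.start), str(a.end), a.strand]
            for a in ledger
        ],
    )


def read_anomaly_ledger(path) -> list[AnomalyRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        AnomalyRecord(
            anomaly_id=r.anomaly_id, category=r.category, contig=r.contig,
            start=int(r.start), end=int(r.end), strand=r.strand,
        )
        for r in df.itertuples()
    ]


def write_observed_peptides(peptides: list[ObservedPeptide], path) -> None:
    _write_tsv(
        path,
        ["peptide_id", "sequence", "rt_minutes", "is_outlier"],
        [
            [p.id, p.sequence, _fmt(p.retention_time),
             "" if p.is_outlier is None else str(int(p.is_outlier))]
            for p in peptides
        ],
    )


def read_observed_peptides(path) -> list[ObservedPeptide]:
    df = pd.read_csv(path, sep="\t", dtype={"is_outlier": "string"})
    out = []
    for r in df.itertuples():
        flag = r.is_outlier if hasattr(r, "is_outlier") else None
        out.append(
            ObservedPeptide(
                id=r.peptide_id,
                sequence=r.sequence,
                retention_time=float(r.rt_minutes),
                is_outlier=None if flag is None or pd.isna(flag) else bool(int(flag)),
            )
        )
    return out


def write_peptide_db(db: PeptideDB, path) -> None:
    _write_tsv(
        path,
        ["normalized_sequence", "n_provenance"],
        [[seq, str(len(prov))] for seq, prov in sorted(db.entries.items())],
    )


def write_match_report(report: MatchReport, path) -> None:
    _write_tsv(
        path,
        ["peptide_id", "label"],
        [[pid, label] for pid, label in sorted(report.labels.items())],
    )


def write_retention_summary(fit: RetentionFit, path) -> None:
    _write_tsv(
        path,
        ["slope", "intercept", "correlation", "n_outliers"],
        [[_fmt(fit.slope), _fmt(fit.intercept), _fmt(fit.correlation),
          str(fit.n_outliers)]],
    )


def write_anomaly_calls(calls: list[AnomalyCall], path) -> None:
    _write_tsv(
        path,
        ["anomaly_id", "verdict", "n_support", "supporting_peptides"],
        [
            [c.anomaly_id, c.verdict, str(len(c.supporting_peptides)),
             ",".join(c.supporting_peptides)]
            for c in calls
        ],
    )


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "genome") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FMT)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
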