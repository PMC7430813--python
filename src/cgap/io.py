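"""Readers and writers for the on-disk formats used by the protocol.

FASTA and EMBL flat files go through Biopython; Newick through dendropy;
statistics tables through pandas.  GFF3 CDS features are read and written
directly (nine-column TSV), converting between the file format's 1-based
closed intervals and the package's 0-based half-open spans.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .records import CodingSequenceRecord, CoverageTrack, ExonSpan, GenomicContig, UNKNOWN

log = logging.getLogger("cgap")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_contigs(contigs: Iterable[GenomicContig], path) -> None:
    write_fasta({c.id: c.sequence for c in contigs}, path)


# ---------------------------------------------------------------------------
# GFF3 gene models

_GFF_COLS = (
    "seqid source type start end score strand phase attributes".split()
)


def _fmt_attrs(record: CodingSequenceRecord) -> str:
    parts = [f"ID=cds-{record.id}", f"Parent={record.id}"]
    parts.append(f"taxon={record.taxon.replace(' ', '_')}")
    if record.cluster_label != UNKNOWN:
        parts.append(f"cluster={record.cluster_label}")
    if record.supercluster_label != UNKNOWN:
        parts.append(f"supercluster={record.supercluster_label}")
    if record.gene_label != UNKNOWN:
        parts.append(f"gene={record.gene_label}")
    parts.append(f"status={record.status}")
    return ";".join(parts)


def write_gff3(records: Iterable[CodingSequenceRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            attrs = _fmt_attrs(rec)
            for exon in rec.exon_model:
                fh.write(
                    "\t".join(
                        [
                            exon.contig_id,
                            "cgap",
                            "CDS",
                            str(exon.start + 1),  # 1-based closed at the boundary
                            str(exon.end),
                            ".",
                            exon.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_dataset(fasta_path, gff3_path) -> list[CodingSequenceRecord]:
    """Assemble coding-sequence records from a contig FASTA and a GFF3 file.

    CDS features sharing a ``Parent`` attribute form one record; minus-strand
    features are reverse-complemented into the spliced CDS.  Records whose
    spliced length is not a multiple of 3 are rejected with a logged reason;
    a feature referencing a missing contig is a hard error.
    """
    contigs = read_fasta(fasta_path)
    features: dict[str, list[tuple[ExonSpan, dict]]] = {}
    with open(gff3_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9 or fields[2] != "CDS":
                continue
            seqid, _, _, start, end, _, strand, _, attr_text = fields
            attrs = _parse_attrs(attr_text)
            parent = attrs.get("Parent") or attrs.get("ID") or seqid
            span = ExonSpan(seqid, int(start) - 1, int(end), strand)
            features.setdefault(parent, []).append((span, attrs))

    records: list[CodingSequenceRecord] = []
    for parent, feats in features.items():
        attrs = feats[0][1]
        strand = feats[0][0].strand
        # genomic order, then transcript order (reversed on minus strand)
        spans = sorted((f[0] for f in feats), key=lambda e: (e.contig_id, e.start))
        pieces = []
        for span in spans:
            if span.contig_id not in contigs:
                raise KeyError(
                    f"GFF3 feature of {parent} references missing contig {span.contig_id}"
                )
            seq = contigs[span.contig_id][span.start : span.end]
            if len(seq) != span.length:
                raise ValueError(f"{parent}: exon {span} exceeds contig bounds")
            pieces.append(seq)
        if strand == "-":
            cds = str(Seq("".join(pieces)).reverse_complement())
            model = tuple(reversed(spans))
        else:
            cds = "".join(pieces)
            model = tuple(spans)
        taxon = attrs.get("taxon", UNKNOWN).replace("_", " ")
        try:
            records.append(
                CodingSequenceRecord(
                    id=parent,
                    taxon=taxon,
                    cds_sequence=cds,
                    exon_model=model,
                    cluster_label=attrs.get("cluster", UNKNOWN),
                    supercluster_label=attrs.get("supercluster", UNKNOWN),
                    gene_label=attrs.get("gene", UNKNOWN),
                    status=attrs.get("status", "potential"),
                )
            )
        except ValueError as exc:
            log.warning("rejected record %s: %s", parent, exc)
    return records


# ---------------------------------------------------------------------------
# EMBL flat files (third-party-data deposits use CDS join() features)

def read_dataset_embl(paths: Sequence) -> list[CodingSequenceRecord]:
    """Best-effort reader for EMBL flat files carrying CDS join() features.

    Each CDS feature becomes one record; the entry sequence is treated as the
    record's contig.  Organism is taken from the source feature, the record
    id from ``locus_tag``/``gene`` qualifiers or the entry name.
    """
    records: list[CodingSequenceRecord] = []
    for path in paths:
        for entry in SeqIO.parse(str(path), "embl"):
            organism = UNKNOWN
            for feat in entry.features:
                if feat.type == "source":
                    organism = feat.qualifiers.get("organism", [UNKNOWN])[0]
            for feat in entry.features:
                if feat.type != "CDS":
                    continue
                name = feat.qualifiers.get(
                    "locus_tag", feat.qualifiers.get("gene", [entry.id])
                )[0]
                strand = "-" if feat.location.strand == -1 else "+"
                parts = sorted(feat.location.parts, key=lambda p: int(p.start))
                spans = tuple(
                    ExonSpan(entry.id, int(p.start), int(p.end), strand) for p in parts
                )
                if strand == "-":
                    spans = tuple(reversed(spans))
                cds = str(feat.extract(entry.seq)).upper()
                try:
                    records.append(
                        CodingSequenceRecord(
                            id=name,
                            taxon=organism,
                            cds_sequence=cds,
                            exon_model=spans,
                            gene_label=feat.qualifiers.get("gene", [UNKNOWN])[0],
                        )
                    )
                except ValueError as exc:
                    log.warning("rejected EMBL record %s: %s", name, exc)
    return records


# ---------------------------------------------------------------------------
# Coverage tracks (bedGraph: record_id, start, end, depth; run-length encoded)

def write_coverage(tracks: Iterable[CoverageTrack], path) -> None:
    with open(path, "w") as fh:
        for track in tracks:
            cov = track.coverage
            i = 0
            while i < len(cov):
                j = i
                while j < len(cov) and cov[j] == cov[i]:
                    j += 1
                fh.write(f"{track.record_id}\t{i}\t{j}\t{cov[i]}\n")
                i = j


def read_coverage(path) -> dict[str, CoverageTrack]:
    runs: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            rid, start, end, depth = line.split()[:4]
            runs.setdefault(rid, []).append((int(start), int(end), int(depth)))
    tracks = {}
    for rid, items in runs.items():
        items.sort()
        cov: list[int] = []
        for start, end, depth in items:
            if start != len(cov):
                raise ValueError(f"coverage for {rid} has a gap/overlap at {start}")
            cov.extend([depth] * (end - start))
        tracks[rid] = CoverageTrack(rid, tuple(cov))
    return tracks


# ---------------------------------------------------------------------------
# Alignments, trees, tables

def write_alignment(rows: Mapping[str, str], path) -> None:
    write_fasta(rows, path)


def read_alignment(path) -> dict[str, str]:
    rows = read_fasta(path)
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ValueError(f"alignment rows differ in length: {sorted(lengths)}")
    return rows


def write_tree(newick: str, path) -> None:
    text = newick.strip()
    if not text.endswith(";"):
        text += ";"
    Path(path).write_text(text + "\n")


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
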