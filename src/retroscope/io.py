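"""Standard-format input/output: FASTA, FASTQ, GFF3, TSV, PAF.

All in-memory coordinates are 0-based half-open; GFF3 output converts to
1-based closed intervals here and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import ElementCall, LtrElement
from .origin import OriginCall
from .simkit import TruthElement
from .transcript import TranscriptModel


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def write_fasta(path: str | Path, records: dict[str, str], width: int = 60) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fastq(path: str | Path, reads: list[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    out = []
    for r in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in r.letter_annotations["phred_quality"])
        out.append((r.id, str(r.seq).upper(), quals))
    return out


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_HEADER = "##gff-version 3\n"


def _gff_line(seqid: str, source: str, ftype: str, span: tuple[int, int],
              strand: str, attrs: dict[str, str], score: str = ".") -> str:
    attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
    return (f"{seqid}\t{source}\t{ftype}\t{span[0] + 1}\t{span[1]}\t{score}\t"
            f"{strand}\t.\t{attr_s}\n")


def write_truth_gff3(path: str | Path, truth: list[TruthElement],
                     seqid: str = "chr_sim") -> None:
    """Planted-element ground truth: category in the type column, domain
    layout and exon structure in the attributes."""
    with open(path, "w") as fh:
        fh.write(_GFF_HEADER)
        for te in truth:
            attrs = {
                "ID": te.element_id,
                "domain_layout": ",".join(te.domain_layout),
                "exons": ",".join(f"{s + 1}-{e}" for s, e in te.exon_spans),
            }
            if te.tsd:
                attrs["tsd"] = te.tsd
            if te.ltr5_span:
                attrs["ltr5"] = f"{te.ltr5_span[0] + 1}-{te.ltr5_span[1]}"
                attrs["ltr3"] = f"{te.ltr3_span[0] + 1}-{te.ltr3_span[1]}"
            fh.write(_gff_line(seqid, "simkit", te.category, te.span, te.strand, attrs))


def write_elements_gff3(path: str | Path,
                        elements: list[LtrElement],
                        calls: dict[str, ElementCall] | None = None,
                        seqid: str = "chr_sim") -> None:
    with open(path, "w") as fh:
        fh.write(_GFF_HEADER)
        for el in elements:
            attrs = {"ID": el.element_id, "ltr_identity": f"{el.ltr_identity:.4f}",
                     "motif_ok": str(el.motif_ok).lower()}
            if el.tsd:
                attrs["tsd"] = el.tsd
            if calls and el.element_id in calls:
                call = calls[el.element_id]
                attrs["superfamily"] = call.superfamily
                attrs["completeness"] = call.completeness
                attrs["domains"] = ",".join(h.domain for h in call.domains)
            fh.write(_gff_line(seqid, "retroscope", "LTR_retrotransposon",
                               el.span, el.strand, attrs))
            for tag, span in (("five_prime", el.ltr5_span), ("three_prime", el.ltr3_span)):
                fh.write(_gff_line(seqid, "retroscope", "long_terminal_repeat", span,
                                   el.strand, {"Parent": el.element_id, "end": tag}))


def write_models_gff3(path: str | Path, models: list[TranscriptModel],
                      seqid: str = "chr_sim") -> None:
    with open(path, "w") as fh:
        fh.write(_GFF_HEADER)
        for m in models:
            fh.write(_gff_line(seqid, "retroscope", "mRNA", m.locus, m.strand,
                               {"ID": m.cluster_id, "mq": str(m.mq)}))
            for i, exon in enumerate(m.exons):
                fh.write(_gff_line(seqid, "retroscope", "exon", exon, m.strand,
                                   {"Parent": m.cluster_id, "exon_number": str(i + 1)}))


def write_origin_calls(path: str | Path, calls: list[OriginCall]) -> None:
    rows = [{
        "cluster_id": c.cluster_id,
        "category": c.category,
        "completeness": c.completeness,
        "subtype": c.subtype,
        "matched_element_id": c.matched_element_id or "",
        "encoded_domains": ",".join(c.encoded_domains),
        "exon_count": c.exon_count,
        "overlap_fraction": round(c.overlap_fraction, 4),
    } for c in calls]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PAF ingestion (optional external spliced alignments)
# ---------------------------------------------------------------------------


@dataclass
class PafRecord:
    query_name: str
    query_len: int
    query_span: tuple[int, int]
    strand: str
    target_name: str
    target_span: tuple[int, int]
    mq: int
    exons: list[tuple[int, int]]  # inferred from cs/cigar when present


def _exons_from_cigar(cigar: str, tstart: int, min_intron: int = 50) -> list[tuple[int, int]]:
    exons = [[tstart, tstart]]
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "M=XD":
            exons[-1][1] += n
        elif ch == "N" or (ch == "D" and n > min_intron):
            exons.append([exons[-1][1] + n, exons[-1][1] + n])
    return [(s, e) for s, e in exons if e > s]


def read_paf(path: str | Path, min_intron: int = 50) -> list[PafRecord]:
    """Parse standard 12+-column PAF; exon chains are inferred from a
    ``cg:Z`` CIGAR tag (N operations; long deletions count as introns)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            tstart = int(f[7])
            exons = [(tstart, int(f[8]))]
            for tag in f[12:]:
                if tag.startswith("cg:Z:"):
                    exons = _exons_from_cigar(tag[5:], tstart, min_intron)
            out.append(PafRecord(
                query_name=f[0], query_len=int(f[1]),
                query_span=(int(f[2]), int(f[3])), strand=f[4],
                target_name=f[5], target_span=(tstart, int(f[8])),
                mq=int(f[11]), exons=exons,
            ))
    return out


def paf_to_models(records: list[PafRecord],
                  consensi: dict[str, str]) -> list[TranscriptModel]:
    """Transcript models from externally produced spliced alignments."""
    return [TranscriptModel(
        cluster_id=r.query_name,
        consensus=consensi.get(r.query_name, ""),
        locus=r.target_span,
        exons=r.exons,
        strand=r.strand,
        mq=r.mq,
    ) for r in records]
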