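"""Readers and writers for the external formats the pipeline touches.

Formats: multi-record FASTA, 12-column BLAST tabular (outfmt 6), the NUPT
TSV table with its BED6 companion, and the ground-truth TSV written by the
simulator. BLAST tabular is 1-based inclusive with ``sstart > send``
encoding minus-strand subjects; everything is normalized to 0-based
half-open forward intervals on the way in and converted back on the way
out.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .records import AlignmentHit, NuptRecord, SequenceRecord

logger = logging.getLogger(__name__)

_VALID = re.compile(r"[^ACGTN]")

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

NUPT_COLUMNS = [
    "id", "s_chrom", "s_start", "s_end", "q_start", "q_end", "strand",
    "pident", "aln_length", "evalue", "is_ir_redundant", "episode",
    "posterior", "cluster_id",
]


def _clean_sequence(seq_id: str, raw: str) -> str:
    seq = raw.upper().replace("U", "T")
    if _VALID.search(seq):
        n_bad = len(_VALID.findall(seq))
        logger.warning(
            "sequence %s: %d non-ACGTN characters mapped to N", seq_id, n_bad
        )
        seq = _VALID.sub("N", seq)
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Sequences are uppercased, U mapped to T, and any residue outside
    {A,C,G,T,N} mapped to N with a logged warning. Empty files and
    duplicate ids are hard errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, _clean_sequence(rec.id, str(rec.seq))))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_blast_tab(path: str | Path) -> list[AlignmentHit]:
    """Parse 12-column BLAST tabular output (outfmt 6).

    Coordinates are converted to 0-based half-open forward-strand
    intervals; ``sstart > send`` rows become minus-strand hits. Row order
    is preserved. Malformed rows raise with their line number.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                length = int(fields[3])
                mismatch = int(fields[4])
                gapopen = int(fields[5])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if sstart <= send:
                s0, s1, strand = sstart - 1, send, "+"
            else:
                s0, s1, strand = send - 1, sstart, "-"
            hits.append(
                AlignmentHit(
                    query_id=fields[0], subject_id=fields[1], pident=pident,
                    aln_length=length, mismatches=mismatch, gap_opens=gapopen,
                    q_start=qstart - 1, q_end=qend, s_start=s0, s_end=s1,
                    strand=strand, evalue=evalue, bitscore=bitscore,
                )
            )
    return hits


def write_blast_tab(hits: list[AlignmentHit], path: str | Path) -> None:
    """Write hits back to the 1-based inclusive 12-column dialect.

    Inverse of :func:`read_blast_tab` on all fields.
    """
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                sstart, send = h.s_start + 1, h.s_end
            else:
                sstart, send = h.s_end, h.s_start + 1
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, f"{h.pident:.2f}",
                        str(h.aln_length), str(h.mismatches), str(h.gap_opens),
                        str(h.q_start + 1), str(h.q_end), str(sstart), str(send),
                        f"{h.evalue:.2e}", f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


def nupts_to_frame(records: list[NuptRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id, "s_chrom": r.s_chrom, "s_start": r.s_start,
                "s_end": r.s_end, "q_start": r.q_start, "q_end": r.q_end,
                "strand": r.strand, "pident": r.pident,
                "aln_length": r.aln_length, "evalue": r.evalue,
                "is_ir_redundant": r.is_ir_redundant, "episode": r.episode,
                "posterior": ",".join(f"{p:.6g}" for p in r.posterior),
                "cluster_id": r.cluster_id if r.cluster_id is not None else ".",
            }
        )
    return pd.DataFrame(rows, columns=NUPT_COLUMNS)


def write_nupt_table(records: list[NuptRecord], path: str | Path) -> Path:
    """Write the NUPT TSV plus a BED6 companion (``<path>.bed``).

    BED scores are pident × 10 rounded; coordinates stay 0-based
    half-open. Returns the BED path.
    """
    path = Path(path)
    nupts_to_frame(records).to_csv(path, sep="\t", index=False)
    bed_path = path.with_suffix(path.suffix + ".bed")
    with open(bed_path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.s_chrom}\t{r.s_start}\t{r.s_end}\t{r.id}\t"
                f"{round(r.pident * 10)}\t{r.strand}\n"
            )
    return bed_path


def read_nupt_table(path: str | Path) -> list[NuptRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"posterior": str, "cluster_id": str})
    records: list[NuptRecord] = []
    for row in df.itertuples(index=False):
        post = (
            [float(p) for p in str(row.posterior).split(",")]
            if isinstance(row.posterior, str) and row.posterior not in ("", "nan")
            else []
        )
        cid = None if row.cluster_id in (".", "nan", None) or pd.isna(row.cluster_id) else str(row.cluster_id)
        records.append(
            NuptRecord(
                id=str(row.id), s_chrom=str(row.s_chrom),
                s_start=int(row.s_start), s_end=int(row.s_end),
                q_start=int(row.q_start), q_end=int(row.q_end),
                strand=str(row.strand), pident=float(row.pident),
                aln_length=int(row.aln_length), evalue=float(row.evalue),
                is_ir_redundant=bool(row.is_ir_redundant),
                episode=str(row.episode), posterior=post, cluster_id=cid,
            )
        )
    return records
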