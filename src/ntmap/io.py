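"""Reading and writing the external formats the tool touches.

Formats
-------
* multi-FASTA (reference genomes, contig sets, transposons, query lists)
* headerless RAW sequence files (one file per contig, sequence bytes only)
* plain-text coordinate lists (one integer per line)
* the mapping/annotation result table as RFC-4180 CSV
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .dna import normalize
from .errors import CoordinateError, DuplicateIdError, FormatError, HeaderConventionError

log = logging.getLogger(__name__)

_CONTIG_RE = re.compile(r"^contig_(\d+)$")


@dataclass
class SequenceRecord:
    """A named DNA sequence (reference, contig or query).

    ``seq`` is upper-case over {A,C,G,T,N}; anything else is normalized to N
    at construction time (and counted in the log).
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"sequence record {self.id!r} with empty sequence")
        clean, replaced = normalize(self.seq)
        if replaced:
            log.warning("record %s: %d non-ACGTN characters normalized to N", self.id, replaced)
        self.seq = clean

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ResultRow:
    """One line of the exported mapping/annotation table."""

    query_id: str
    transposon: str = ""
    reference_id: str = ""
    tgn_coordinate: Optional[int] = None  # 1-based; None for non-junction rows
    orientation: str = "unknown"  # "1", "2" or "unknown"
    score: int = 0
    hit_gene: str = ""
    upstream_gene: str = ""
    downstream_gene: str = ""
    tsd: str = ""
    classification: str = "genomic"  # genomic | junction | transposon_internal

    def validate(self, tsd_length: Optional[int] = None) -> None:
        if self.classification == "junction":
            if self.tgn_coordinate is None or self.tgn_coordinate < 1:
                raise FormatError(
                    f"junction row {self.query_id!r} needs a 1-based TGN coordinate"
                )
        if self.tsd and tsd_length is not None and len(self.tsd) != tsd_length:
            raise FormatError(
                f"row {self.query_id!r}: TSD length {len(self.tsd)} != configured {tsd_length}"
            )


RESULT_COLUMNS = [
    "query_id",
    "transposon",
    "reference_id",
    "tgn_coordinate",
    "orientation",
    "score",
    "hit_gene",
    "upstream_gene",
    "downstream_gene",
    "tsd",
    "classification",
]


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into :class:`SequenceRecord` objects.

    Order is preserved, sequences are upper-cased, duplicate ids are an error.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), description=desc))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    bio = [
        _BioRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def write_plain_fasta(entries: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    """Write (id, sequence) pairs verbatim -- no alphabet normalization.

    Used for IUPAC consensus strings, which legitimately contain ambiguity
    codes outside the plain {A,C,G,T,N} alphabet.
    """
    with open(path, "w") as fh:
        for rid, seq in entries:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def fasta_to_raw(path, outdir) -> list[Path]:
    """Convert a multi-FASTA of contigs to one headerless RAW file per record.

    Every header must follow the ``contig_<number>`` convention; the output
    file is named after it and contains the bare sequence with no line breaks.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for rec in read_fasta(path):
        if not _CONTIG_RE.match(rec.id):
            raise HeaderConventionError(
                f"header {rec.id!r} does not match the required '>contig_number' convention"
            )
        out = outdir / f"{rec.id}.raw"
        out.write_text(rec.seq)
        written.append(out)
    return written


def export_results_csv(rows: Iterable[ResultRow], path, tsd_length: Optional[int] = None) -> None:
    """Write the result table (header + one line per row, RFC-4180)."""
    rows = list(rows)
    for r in rows:
        r.validate(tsd_length)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RESULT_COLUMNS)
        for r in rows:
            w.writerow([
                r.query_id,
                r.transposon,
                r.reference_id,
                "" if r.tgn_coordinate is None else r.tgn_coordinate,
                r.orientation,
                r.score,
                r.hit_gene,
                r.upstream_gene,
                r.downstream_gene,
                r.tsd,
                r.classification,
            ])


def read_results_csv(path) -> list[ResultRow]:
    out = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            out.append(ResultRow(
                query_id=rec["query_id"],
                transposon=rec["transposon"],
                reference_id=rec["reference_id"],
                tgn_coordinate=int(rec["tgn_coordinate"]) if rec["tgn_coordinate"] else None,
                orientation=rec["orientation"],
                score=int(rec["score"]),
                hit_gene=rec["hit_gene"],
                upstream_gene=rec["upstream_gene"],
                downstream_gene=rec["downstream_gene"],
                tsd=rec["tsd"],
                classification=rec["classification"],
            ))
    return out


def read_coordinate_list(path, reference_id: str) -> list[tuple[str, int]]:
    """Parse a one-coordinate-per-line text file.

    The target reference is supplied separately (it is chosen from a drop-down
    in the original GUI).  Blank lines are skipped; any non-integer token is a
    parse error naming the line.
    """
    out: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            try:
                coord = int(token)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: not an integer coordinate: {token!r}")
            if coord < 1:
                raise CoordinateError(f"{path}:{lineno}: coordinates are 1-based, got {coord}")
            out.append((reference_id, coord))
    return out
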