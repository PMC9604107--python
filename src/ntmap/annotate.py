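"""Genomic features and the association of insertion calls with them.

Two input conventions coexist and are converted to a single internal one
(0-based, end-exclusive):

* GFF3 files are 1-based with inclusive ends, as usual.
* The transposon-annotation TSV follows the tool's own rule that the line
  referring to the first nucleotide of a sequence starts at coordinate zero:
  columns are already 0-based with an exclusive end.  Note that coordinates
  copied from 1-based sources must be shifted down by one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

from .errors import CoordinateError, FormatError
from .io import SequenceRecord

log = logging.getLogger(__name__)

CATEGORIES = ("gene", "transposon", "TIR5", "TIR3", "exon", "UTR", "other")
#: search radius (nt) for nearest upstream/downstream genes
VICINITY = 100_000


@dataclass(frozen=True)
class Feature:
    """An annotated interval on a reference sequence (0-based, end-exclusive)."""

    reference_id: str
    name: str
    category: str
    interval: tuple[int, int]
    strand: str = "+"

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise FormatError(f"unknown feature category {self.category!r}")
        start, end = self.interval
        if not 0 <= start < end:
            raise CoordinateError(
                f"feature {self.name!r}: bad interval {self.interval} (0-based, end-exclusive)"
            )

    @property
    def start(self) -> int:
        return self.interval[0]

    @property
    def end(self) -> int:
        return self.interval[1]


class AnnotationContext(NamedTuple):
    hit_gene: str
    upstream_gene: str
    downstream_gene: str
    overlapping_nts: tuple[str, ...]


def annotate_call(call, features: Sequence[Feature]) -> AnnotationContext:
    """Gene context of an insertion call.

    hit_gene: every gene whose interval contains the TGN, joined with "/"
    (overlapping genes yield a joined label); upstream/downstream: nearest
    non-overlapping genes within the vicinity radius; overlapping_nts:
    transposon-category features containing the TGN (the nested-insertion
    landscape).
    """
    pos = call.tgn - 1  # 1-based -> 0-based
    rid = call.reference_id
    genes = [f for f in features if f.reference_id == rid and f.category == "gene"]
    nts = [f for f in features if f.reference_id == rid and f.category == "transposon"]
    hit = sorted(f.name for f in genes if f.start <= pos < f.end)
    up = down = ""
    up_d = down_d = VICINITY + 1
    for f in genes:
        if f.end <= pos and pos - f.end + 1 < up_d:
            up, up_d = f.name, pos - f.end + 1
        if f.start > pos and f.start - pos < down_d:
            down, down_d = f.name, f.start - pos
    overlapping = tuple(sorted(f.name for f in nts if f.start <= pos < f.end))
    return AnnotationContext("/".join(hit), up, down, overlapping)


def annotate_transposon(
    nt: SequenceRecord,
    tir5: tuple[int, int],
    tir3: tuple[int, int],
    extra: Iterable[Feature] = (),
) -> list[Feature]:
    """Attach TIR5/TIR3 (0-based intervals) plus extra features to a transposon.

    The returned TIR features are what the insertion-candidate bonus consumes.
    """
    out = []
    for cat, interval in (("TIR5", tir5), ("TIR3", tir3)):
        start, end = interval
        if not 0 <= start < end <= len(nt):
            raise CoordinateError(
                f"{cat} interval {interval} outside transposon {nt.id!r} (length {len(nt)})"
            )
        out.append(Feature(nt.id, f"{nt.id}_{cat}", cat, (start, end)))
    for f in extra:
        if f.reference_id != nt.id:
            raise FormatError(f"extra feature {f.name!r} refers to {f.reference_id!r}, not {nt.id!r}")
        if f.end > len(nt):
            raise CoordinateError(f"feature {f.name!r} extends past transposon end")
        out.append(f)
    return out


def read_feature_tsv(path) -> list[Feature]:
    """Minimal 5/6-column annotation TSV.

    Columns: reference_id, name, category, start, end[, strand], where start
    and end are 0-based with an exclusive end (the zero-coordinate rule).
    Lines starting with '#' are skipped.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: expected >= 5 tab-separated columns")
            rid, name, cat, start, end = fields[:5]
            strand = fields[5] if len(fields) > 5 and fields[5] else "+"
            try:
                interval = (int(start), int(end))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates")
            out.append(Feature(rid, name, cat, interval, strand))
    return out


def write_feature_tsv(features: Iterable[Feature], path) -> None:
    with open(path, "w") as fh:
        fh.write("# reference_id\tname\tcategory\tstart\tend\tstrand (0-based, end-exclusive)\n")
        for f in features:
            fh.write(f"{f.reference_id}\t{f.name}\t{f.category}\t{f.start}\t{f.end}\t{f.strand}\n")


_GFF_CATEGORY = {
    "gene": "gene",
    "mRNA": "other",
    "exon": "exon",
    "three_prime_UTR": "UTR",
    "five_prime_UTR": "UTR",
    "transposable_element": "transposon",
    "transposable_element_insertion_site": "transposon",
    "mobile_genetic_element": "transposon",
    "terminal_inverted_repeat": "other",
    "repeat_region": "other",
}


def read_gff3(path, keep_categories: Optional[set[str]] = None) -> list[Feature]:
    """Read GFF3 (1-based, inclusive) into internal 0-based features.

    Feature types without a mapping are imported as category "other"; the
    Name/ID attribute provides the feature name.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out = []
    for f in db.all_features():
        cat = _GFF_CATEGORY.get(f.featuretype, "other")
        if keep_categories is not None and cat not in keep_categories:
            continue
        name = (f.attributes.get("Name") or f.attributes.get("ID") or [f.id])[0]
        out.append(Feature(
            reference_id=f.seqid,
            name=name,
            category=cat,
            interval=(f.start - 1, f.end),
            strand=f.strand if f.strand in "+-" else "+",
        ))
    return out
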