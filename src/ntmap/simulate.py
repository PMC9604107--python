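"""Synthetic genomes, transposons and planted insertions with truth tables.

The generator emulates the study design the mapping workflows target: a
canonical reference genome (CRG), an alternative genome (ARG) of contigs
carrying class-II transposon insertions with target site duplications (TSDs),
in both orientations, plus truncated single-TIR remnants and one nested
(transposon-in-transposon) pair.  Every fixture is byte-reproducible from
(parameters, seed).

Insertion mechanics: inserting after 1-based coordinate ``c`` duplicates the
``tsd_len`` genomic nucleotides ending at ``c``, so the contig reads
``genome[:c] + NT + motif + genome[c:]`` -- the first motif copy is the
pre-existing genomic sequence at the site, hence the contig grows by
len(NT) + tsd_len.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .dna import revcomp
from .errors import CoordinateError
from .io import SequenceRecord, write_fasta
from .annotate import Feature

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

REMNANT_TYPES = ("full", "single_tir_5", "single_tir_3", "nested")
#: fraction of the transposon kept when one TIR has been lost
TRUNCATION_KEEP = 0.6


@dataclass
class TruthRecord:
    """Ground truth for one planted insertion, in CRG coordinate space.

    ``insertion_coordinate`` is the 1-based coordinate of the last genomic
    nucleotide before the insertion point, i.e. the high-coordinate end of the
    duplicated motif; ``tsd_start``/``tsd_end`` delimit the motif (1-based,
    inclusive).  The expected TGN of a junction call depends on which
    transposon end forms the junction and on the orientation:
    """

    contig_id: str
    transposon: str
    insertion_coordinate: int
    orientation: int  # 1 plus, 2 minus
    tsd: str
    remnant_type: str = "full"
    shared: bool = False  # also present in the CRG (no junction expected)
    tsd_start: int = 0  # 1-based first base of the duplicated motif
    tsd_end: int = 0  # 1-based last base

    def expected_tgn(self, side: str) -> int:
        """TGN a junction call on the given transposon side should report."""
        at_high = (side == "5'") == (self.orientation == 1)
        return self.tsd_end if at_high else self.tsd_start


def generate_genome(length: int, gc: float = 0.42, seed: int = 0,
                    id: str = "chr_sim") -> SequenceRecord:
    """Random genome with the given GC content; reproducible for a seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")
    return SequenceRecord(id=id, seq=seq)


def make_transposon(length: int, tir_len: int, seed: int = 0,
                    id: str = "NT_sim") -> tuple[SequenceRecord, list[Feature]]:
    """Random class-II transposon: TIR + internal sequence + inverted TIR.

    Returns the record and its TIR5/TIR3 features (0-based intervals).
    """
    if length < 2 * tir_len + 1:
        raise ValueError("transposon too short for its TIRs")
    rng = np.random.default_rng(seed)
    tir = rng.choice(_BASES, size=tir_len).tobytes().decode("ascii")
    body = rng.choice(_BASES, size=length - 2 * tir_len).tobytes().decode("ascii")
    seq = tir + body + revcomp(tir)
    rec = SequenceRecord(id=id, seq=seq)
    feats = [
        Feature(id, f"{id}_TIR5", "TIR5", (0, tir_len)),
        Feature(id, f"{id}_TIR3", "TIR3", (length - tir_len, length)),
    ]
    return rec, feats


def _remnant(nt_seq: str, remnant_type: str) -> str:
    keep = max(1, int(round(TRUNCATION_KEEP * len(nt_seq))))
    if remnant_type in ("full", "nested"):
        return nt_seq
    if remnant_type == "single_tir_5":
        return nt_seq[:keep]
    if remnant_type == "single_tir_3":
        return nt_seq[-keep:]
    raise ValueError(f"unknown remnant type {remnant_type!r}")


def plant_insertion(
    genome: SequenceRecord,
    nt: SequenceRecord,
    coordinate: int,
    tsd_len: int = 8,
    orientation: int = 1,
    remnant_type: str = "full",
    contig_id: Optional[str] = None,
) -> tuple[SequenceRecord, TruthRecord]:
    """Plant one (possibly truncated, possibly reversed) insertion.

    ``coordinate`` is 1-based: the transposon lands after that genomic
    position, duplicating the ``tsd_len`` nucleotides that end there.
    """
    c = coordinate
    if not tsd_len < c <= len(genome) - 1:
        raise CoordinateError(
            f"coordinate {c} (with {tsd_len} nt TSD) outside genome of length {len(genome)}"
        )
    if orientation not in (1, 2):
        raise ValueError("orientation must be 1 or 2")
    if remnant_type not in REMNANT_TYPES:
        raise ValueError(f"unknown remnant type {remnant_type!r}")
    g = genome.seq
    motif = g[c - tsd_len:c]
    insert = _remnant(nt.seq, remnant_type)
    if orientation == 2:
        insert = revcomp(insert)
    contig_seq = g[:c] + insert + motif + g[c:]
    contig = SequenceRecord(id=contig_id or f"contig_{genome.id}_{c}", seq=contig_seq)
    truth = TruthRecord(
        contig_id=contig.id,
        transposon=nt.id,
        insertion_coordinate=c,
        orientation=orientation,
        tsd=motif,
        remnant_type=remnant_type,
        tsd_start=c - tsd_len + 1,
        tsd_end=c,
    )
    return contig, truth


@dataclass
class Fixture:
    """One simulated mapping scenario: CRG + ARG contig(s) + TD + truth."""

    crg: list[SequenceRecord]
    contigs: list[SequenceRecord]
    transposons: list[SequenceRecord]
    tir_features: list[Feature]
    gene_features: list[Feature]
    truth: list[TruthRecord]
    seed: int
    params: dict = field(default_factory=dict)


def make_fixture(
    seed: int,
    genome_length: Optional[int] = None,
    nt_length: int = 2000,
    tir_len: int = 31,
    tsd_len: int = 8,
    orientation: Optional[int] = None,
    shared: bool = False,
    remnant_type: str = "full",
    gc: float = 0.42,
) -> Fixture:
    """A single-insertion fixture: one CRG chromosome, one ARG contig.

    ``shared=True`` plants the insertion in the CRG as well (the contig then
    matches the reference over the whole junction region and mapping must
    classify it as genomic-only).  Unset values are drawn from the seed:
    genome length uniform in 50-200 kb, orientation fair coin.
    """
    rng = np.random.default_rng(seed)
    if genome_length is None:
        genome_length = int(rng.integers(50_000, 200_001))
    if orientation is None:
        orientation = int(rng.integers(1, 3))
    genome = generate_genome(genome_length, gc=gc, seed=int(rng.integers(2**31)),
                             id=f"chr_{seed}")
    nt, tirs = make_transposon(nt_length, tir_len, seed=int(rng.integers(2**31)),
                               id=f"NT_{seed}")
    margin = max(5_000, tsd_len + 1)
    coord = int(rng.integers(margin, genome_length - margin))
    contig, truth = plant_insertion(
        genome, nt, coord, tsd_len=tsd_len, orientation=orientation,
        remnant_type=remnant_type, contig_id=f"contig_{seed}",
    )
    truth.shared = shared
    crg = [contig if shared else genome]
    if shared:
        crg = [SequenceRecord(id=genome.id, seq=contig.seq)]
    return Fixture(
        crg=crg, contigs=[SequenceRecord(id=contig.id, seq=contig.seq)],
        transposons=[nt], tir_features=tirs, gene_features=[],
        truth=[truth], seed=seed,
        params=dict(genome_length=genome_length, nt_length=nt_length,
                    tir_len=tir_len, tsd_len=tsd_len, orientation=orientation,
                    shared=shared, remnant_type=remnant_type, gc=gc),
    )


def make_case_study(
    seed: int,
    n_private: int = 4,
    n_shared: int = 2,
    n_single_tir: int = 1,
    nested: bool = True,
    genome_length: int = 60_000,
    nt_length: int = 2000,
    tir_len: int = 31,
    tsd_len: int = 8,
    gc: float = 0.42,
) -> Fixture:
    """A multi-contig scenario mixing every event class on one CRG.

    Each event lives on its own contig (a copy of the CRG chromosome region
    with the insertion planted), which mirrors how assembly contigs tile a
    genome.  The nested pair plants transposon A inside a transposon-B copy
    that is shared with the CRG, so mapping the inner junction lands inside
    the annotated B interval of the reference.
    """
    rng = np.random.default_rng(seed)
    genome = generate_genome(genome_length, gc=gc, seed=int(rng.integers(2**31)),
                             id=f"chr_cs{seed}")
    nt_a, tirs_a = make_transposon(nt_length, tir_len, seed=int(rng.integers(2**31)),
                                   id=f"NTA_{seed}")
    nt_b, tirs_b = make_transposon(nt_length, tir_len, seed=int(rng.integers(2**31)),
                                   id=f"NTB_{seed}")
    margin = 6_000
    contigs: list[SequenceRecord] = []
    truth: list[TruthRecord] = []
    gene_features: list[Feature] = []
    crg_seq = genome.seq

    def draw_coord(lo=margin, hi=None):
        hi = hi if hi is not None else genome_length - margin
        return int(rng.integers(lo, hi))

    idx = 0
    events = (
        [("full", False)] * n_private
        + [("full", True)] * n_shared
        + [("single_tir_5", False)] * n_single_tir
    )
    for remnant_type, shared in events:
        idx += 1
        orientation = int(rng.integers(1, 3))
        coord = draw_coord()
        contig, t = plant_insertion(
            genome, nt_a, coord, tsd_len=tsd_len, orientation=orientation,
            remnant_type=remnant_type, contig_id=f"contig_{idx}",
        )
        t.shared = shared
        contigs.append(contig)
        truth.append(t)

    crg_records = [genome]
    # shared events get their own CRG chromosome copy carrying the insertion,
    # so both ARG and CRG contain it while the plain chromosome keeps the
    # private coordinates valid
    for t, c in zip(truth, contigs):
        if t.shared:
            crg_records.append(SequenceRecord(id=f"chr_shared_{t.contig_id}", seq=c.seq))

    if nested:
        idx += 1
        coord_b = draw_coord()
        with_b, t_b = plant_insertion(
            genome, nt_b, coord_b, tsd_len=tsd_len, orientation=1,
            contig_id=f"contig_{idx}",
        )
        # transposon B is shared with the CRG (annotated in it); A lands inside B
        crg_b = SequenceRecord(id=f"chr_nested_{seed}", seq=with_b.seq)
        crg_records.append(crg_b)
        gene_features.append(Feature(
            crg_b.id, nt_b.id, "transposon", (coord_b, coord_b + nt_length),
        ))
        inner = coord_b + nt_length // 2
        nested_contig, t_a = plant_insertion(
            SequenceRecord(id=crg_b.id, seq=with_b.seq), nt_a, inner,
            tsd_len=tsd_len, orientation=1, remnant_type="nested",
            contig_id=f"contig_{idx}",
        )
        t_b.shared = True
        t_b.contig_id = nested_contig.id
        t_a.contig_id = nested_contig.id
        contigs.append(nested_contig)
        truth.extend([t_b, t_a])

    return Fixture(
        crg=crg_records, contigs=contigs, transposons=[nt_a, nt_b],
        tir_features=tirs_a + tirs_b, gene_features=gene_features,
        truth=truth, seed=seed,
        params=dict(n_private=n_private, n_shared=n_shared,
                    n_single_tir=n_single_tir, nested=nested,
                    genome_length=genome_length, nt_length=nt_length,
                    tir_len=tir_len, tsd_len=tsd_len, gc=gc),
    )


def write_fixture(fx: Fixture, outdir) -> dict[str, str]:
    """Write a fixture as FASTA + truth CSV + a seed/parameter manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "crg": outdir / "crg.fasta",
        "contigs": outdir / "contigs.fasta",
        "transposons": outdir / "transposons.fasta",
        "truth": outdir / "truth.csv",
        "manifest": outdir / "manifest.json",
    }
    write_fasta(fx.crg, paths["crg"])
    write_fasta(fx.contigs, paths["contigs"])
    write_fasta(fx.transposons, paths["transposons"])
    with open(paths["truth"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["contig_id", "transposon", "insertion_coordinate", "orientation",
                    "tsd", "remnant_type", "shared", "tsd_start", "tsd_end"])
        for t in fx.truth:
            w.writerow([t.contig_id, t.transposon, t.insertion_coordinate,
                        t.orientation, t.tsd, t.remnant_type, t.shared,
                        t.tsd_start, t.tsd_end])
    with open(paths["manifest"], "w") as fh:
        json.dump({"seed": fx.seed, "params": fx.params}, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}
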