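"""Genome and transcript-model ingestion, spliced mRNA coordinate maps.

Coordinates are 0-based, half-open everywhere internally; GTF input is
converted from 1-based inclusive on read. Minus-strand exon lists are kept in
transcript 5'->3' order (descending genomic coordinate).
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: biotypes retained by :func:`filter_biotypes`
CODING_BIOTYPES = frozenset({"protein_coding"})


class GenomeError(ValueError):
    """Malformed genome FASTA or out-of-bounds access."""


class AnnotationError(ValueError):
    """Malformed or inconsistent transcript annotation."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Genome:
    """Chromosome name -> uppercase nucleotide string (A/C/G/T/N)."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise GenomeError(f"chromosome {name!r} has empty sequence")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise GenomeError(
                    f"chromosome {name!r} contains invalid bases: {sorted(bad)}"
                )

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


@dataclass(frozen=True)
class TranscriptModel:
    """Spliced exon structure of one transcript on a genome.

    ``exons`` are genomic ``(start, end)`` intervals (0-based half-open),
    sorted in transcript 5'->3' order: ascending genomic start on the plus
    strand, descending on the minus strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript has no exons")
        for start, end in self.exons:
            if not (0 <= start < end):
                raise AnnotationError(
                    f"{self.transcript_id}: invalid exon interval ({start}, {end})"
                )
        by_start = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(by_start, by_start[1:]):
            if s2 < e1:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        expected = by_start if self.strand == "+" else by_start[::-1]
        if tuple(expected) != self.exons:
            raise AnnotationError(
                f"{self.transcript_id}: exons not in transcript 5'->3' order "
                f"for strand {self.strand}"
            )

    @property
    def spliced_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class MrnaMap:
    """Bijection between mRNA coordinates and genomic coordinates.

    ``junctions[i]`` is the mRNA coordinate of the first base *after* the
    i-th exon-exon junction (= cumulative length of the first i+1 exons), so
    "distance upstream of the final junction" is a plain subtraction.
    """

    transcript_id: str
    mrna_length: int
    junctions: tuple[int, ...]
    genomic_positions: np.ndarray = field(repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.genomic_positions) != self.mrna_length:
            raise AnnotationError(
                f"{self.transcript_id}: coordinate array length mismatch"
            )
        for j in self.junctions:
            if not 0 < j < self.mrna_length:
                raise AnnotationError(
                    f"{self.transcript_id}: junction {j} outside (0, {self.mrna_length})"
                )
        if any(b <= a for a, b in zip(self.junctions, self.junctions[1:])):
            raise AnnotationError(
                f"{self.transcript_id}: junctions not strictly increasing"
            )

    def to_genomic(self, pos: int) -> int:
        """Genomic coordinate of mRNA position ``pos``."""
        if not 0 <= pos < self.mrna_length:
            raise IndexError(f"mRNA position {pos} out of [0, {self.mrna_length})")
        return int(self.genomic_positions[pos])

    def to_mrna(self, gpos: int) -> int:
        """mRNA coordinate of genomic position ``gpos`` (must be exonic)."""
        hits = np.flatnonzero(self.genomic_positions == gpos)
        if hits.size == 0:
            raise KeyError(f"genomic position {gpos} not in transcript")
        return int(hits[0])


def read_genome_fasta(path: str | os.PathLike) -> Genome:
    """Read a genome FASTA into memory; sequences are uppercased."""
    records = {}
    with open(path) as handle:
        first = handle.read(1)
        if not first:
            raise GenomeError(f"{path}: empty FASTA file")
        if first != ">":
            raise GenomeError(f"{path}: line 1: expected FASTA header starting with '>'")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in records:
                raise GenomeError(f"{path}: duplicate chromosome name {rec.id!r}")
            records[rec.id] = str(rec.seq).upper()
    if not records:
        raise GenomeError(f"{path}: no FASTA records found")
    return Genome(records)


def read_gtf(
    path: str | os.PathLike,
    biotype_keys: Sequence[str] = ("transcript_biotype", "gene_biotype"),
) -> list[TranscriptModel]:
    """Read exon features from a GTF into :class:`TranscriptModel` objects.

    Exons are grouped by ``transcript_id``; 1-based inclusive GTF intervals
    become 0-based half-open. The biotype is taken from the first matching
    attribute key; absent -> ``"unknown"``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    groups: dict[str, dict] = {}
    order: list[str] = []
    for feat in db.features_of_type("exon"):
        if "transcript_id" not in feat.attributes:
            raise AnnotationError(
                f"{path}: exon at {feat.seqid}:{feat.start}-{feat.end} "
                "missing transcript_id attribute"
            )
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        biotype = "unknown"
        for key in biotype_keys:
            if key in feat.attributes:
                biotype = feat.attributes[key][0]
                break
        entry = groups.setdefault(
            tid,
            {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand, "exons": [],
             "biotype": biotype},
        )
        if biotype != "unknown":
            entry["biotype"] = biotype
        entry["exons"].append((feat.start - 1, feat.end))
        if tid not in order:
            order.append(tid)

    transcripts = []
    for tid in order:
        info = groups[tid]
        exons = sorted(info["exons"])
        if info["strand"] == "-":
            exons = exons[::-1]
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene_id"],
                chrom=info["chrom"],
                strand=info["strand"],
                exons=tuple(exons),
                biotype=info["biotype"],
            )
        )
    return transcripts


def build_mrna_map(t: TranscriptModel, g: Genome) -> tuple[str, MrnaMap]:
    """Splice a transcript to its mRNA sequence and coordinate map."""
    if t.chrom not in g:
        raise GenomeError(f"{t.transcript_id}: chromosome {t.chrom!r} not in genome")
    chrom_len = g.length(t.chrom)
    parts: list[str] = []
    gpos_parts: list[np.ndarray] = []
    for start, end in t.exons:
        if end > chrom_len:
            raise GenomeError(
                f"{t.transcript_id}: exon ({start},{end}) exceeds "
                f"{t.chrom} length {chrom_len}"
            )
        exon_seq = g[t.chrom][start:end]
        if t.strand == "+":
            parts.append(exon_seq)
            gpos_parts.append(np.arange(start, end, dtype=np.int64))
        else:
            parts.append(reverse_complement(exon_seq))
            gpos_parts.append(np.arange(end - 1, start - 1, -1, dtype=np.int64))
    seq = "".join(parts)
    lengths = [end - start for start, end in t.exons]
    junctions = tuple(np.cumsum(lengths)[:-1].tolist())
    mmap = MrnaMap(
        transcript_id=t.transcript_id,
        mrna_length=len(seq),
        junctions=junctions,
        genomic_positions=np.concatenate(gpos_parts),
    )
    return seq, mmap


def filter_biotypes(
    transcripts: Iterable[TranscriptModel],
    keep: frozenset[str] | set[str] = CODING_BIOTYPES,
) -> list[TranscriptModel]:
    """Retain protein-coding transcripts; removals are logged per biotype.

    Unknown/absent biotypes are removed (and logged), matching the policy of
    filtering by annotation class rather than by sequence.
    """
    kept: list[TranscriptModel] = []
    removed: Counter[str] = Counter()
    for t in transcripts:
        if t.biotype in keep:
            kept.append(t)
        else:
            removed[t.biotype] += 1
    for biotype, n in sorted(removed.items()):
        logger.info("filter_biotypes: removed %d transcript(s) with biotype %r", n, biotype)
    return kept
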