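"""Per-transcript NMD-feature classification.

Three features are annotated from the spliced mRNA:

- PTC status by the 50-nt junction rule: the stop codon lies *more than*
  50 nt upstream of the final (3'-most) exon-exon junction. The boundary is
  strict — a distance of exactly 50 nt is PTC-negative. Single-exon
  transcripts are always PTC-negative.
- uORF presence: complete ORFs that start and terminate within the 5' UTR.
- 3' UTR length category: short (<= 350 nt), medium, long (>= 1500 nt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Optional

import pandas as pd

from .orf_annotation import (
    CdsAnnotation,
    Orf,
    find_complete_orfs,
    select_cds,
)
from .transcript_models import Genome, MrnaMap, TranscriptModel, build_mrna_map

logger = logging.getLogger(__name__)

#: stop-to-final-junction distance must exceed this many nt to call a PTC
PTC_DISTANCE_NT = 50

#: 3' UTR length class boundaries (nt)
UTR3_SHORT_MAX = 350
UTR3_LONG_MIN = 1500


@dataclass(frozen=True)
class NmdFeatureRecord:
    transcript_id: str
    has_ptc: bool
    stop_to_last_junction: Optional[int]  # None for single-exon transcripts
    uorf_count: int
    has_uorf: bool
    longest_uorf_len: int
    uorf_in_cds_frame: bool
    utr3_len: int
    utr3_category: str


def annotate_ptc(
    cds: CdsAnnotation,
    mmap: MrnaMap,
    distance_threshold: int = PTC_DISTANCE_NT,
) -> tuple[bool, Optional[int]]:
    """Apply the 50-nt rule against the final exon-exon junction.

    Distance is measured in mRNA coordinates from the first base after the
    stop codon (``cds.end``) to the first base after the final junction;
    "more than 50 nt" is strict. Single-exon transcripts return
    ``(False, None)``.
    """
    if cds.cds.end > mmap.mrna_length:
        raise ValueError(
            f"{mmap.transcript_id}: CDS end {cds.cds.end} exceeds mRNA length "
            f"{mmap.mrna_length}"
        )
    if not mmap.junctions:
        return False, None
    distance = mmap.junctions[-1] - cds.cds.end
    return distance > distance_threshold, distance


def detect_uorfs(
    utr5_seq: str,
    cds_frame_offset: int,
    min_len: int = 3,
    frame_match_required: bool = False,
    all_starts: bool = False,
) -> tuple[list[Orf], bool, int, bool]:
    """Find complete uORFs fully contained in the 5' UTR.

    An ORF qualifies only when both its start codon and stop codon lie within
    the UTR (scanning the UTR sequence alone enforces this). uORF coordinates
    equal mRNA coordinates because the 5' UTR starts at mRNA position 0.

    Returns ``(uorfs, has_uorf, longest_uorf_len, uorf_in_cds_frame)`` where
    the frame flag reports whether the longest uORF shares the reading frame
    of the main CDS (start positions congruent mod 3). ``has_uorf`` requires
    the frame match only when ``frame_match_required`` is set.
    """
    if cds_frame_offset not in (0, 1, 2):
        raise ValueError(f"cds_frame_offset must be 0..2, got {cds_frame_offset}")
    if not utr5_seq:
        return [], False, 0, False
    uorfs = find_complete_orfs(utr5_seq, min_len=min_len, all_starts=all_starts)
    if not uorfs:
        return [], False, 0, False
    longest = min(uorfs, key=lambda o: (-o.length, o.start))
    in_frame = longest.start % 3 == cds_frame_offset
    has = in_frame if frame_match_required else True
    return uorfs, has, longest.length, in_frame


def utr3_category(
    utr3_len: int,
    short_max: int = UTR3_SHORT_MAX,
    long_min: int = UTR3_LONG_MIN,
) -> str:
    """Length class of a 3' UTR: short (<=350), long (>=1500), else medium."""
    if utr3_len < 0:
        raise ValueError(f"negative 3' UTR length: {utr3_len}")
    if utr3_len <= short_max:
        return "short"
    if utr3_len >= long_min:
        return "long"
    return "medium"


def annotate_transcript(
    seq: str,
    mmap: MrnaMap,
    min_orf_len: int = 3,
    distance_threshold: int = PTC_DISTANCE_NT,
    frame_match_required: bool = False,
) -> Optional[NmdFeatureRecord]:
    """Annotate one spliced mRNA; ``None`` when no complete ORF exists."""
    orfs = find_complete_orfs(seq, min_len=min_orf_len)
    cds = select_cds(orfs, mmap.mrna_length, transcript_id=mmap.transcript_id)
    if cds is None:
        return None
    has_ptc, distance = annotate_ptc(cds, mmap, distance_threshold=distance_threshold)
    utr5_seq = seq[: cds.cds.start]
    uorfs, has_uorf, longest_len, in_frame = detect_uorfs(
        utr5_seq,
        cds.cds.start % 3,
        min_len=min_orf_len,
        frame_match_required=frame_match_required,
    )
    utr3_len = cds.utr3_len
    return NmdFeatureRecord(
        transcript_id=mmap.transcript_id,
        has_ptc=has_ptc,
        stop_to_last_junction=distance,
        uorf_count=len(uorfs),
        has_uorf=has_uorf,
        longest_uorf_len=longest_len,
        uorf_in_cds_frame=in_frame,
        utr3_len=utr3_len,
        utr3_category=utr3_category(utr3_len),
    )


def annotate_all(
    transcripts: Iterable[TranscriptModel],
    genome: Genome,
    min_orf_len: int = 3,
    distance_threshold: int = PTC_DISTANCE_NT,
    frame_match_required: bool = False,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Annotate every transcript with a selectable CDS.

    Returns ``(table, skipped)`` where ``table`` has one row per annotated
    transcript (NmdFeatureRecord fields) and ``skipped`` lists
    ``(transcript_id, reason)`` for transcripts without a complete ORF.
    """
    rows = []
    skipped: list[tuple[str, str]] = []
    for t in transcripts:
        seq, mmap = build_mrna_map(t, genome)
        rec = annotate_transcript(
            seq,
            mmap,
            min_orf_len=min_orf_len,
            distance_threshold=distance_threshold,
            frame_match_required=frame_match_required,
        )
        if rec is None:
            skipped.append((t.transcript_id, "no complete ORF"))
            continue
        rows.append(asdict(rec))
    if skipped:
        logger.info("annotate_all: skipped %d transcript(s) without a complete ORF",
                    len(skipped))
    columns = [f.name for f in NmdFeatureRecord.__dataclass_fields__.values()]
    table = pd.DataFrame(rows, columns=columns)
    return table, skipped
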