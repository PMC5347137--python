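"""Complete-ORF scanning on spliced mRNA, CDS selection, UTR derivation.

Only "complete" ORFs (intact ATG start and in-frame stop) are reported; the
main CDS is the longest complete ORF with ties broken toward the 5'-most
start. Codons containing N never act as start or stop codons.
"""

from __future__ import annotations

from dataclasses import dataclass

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: getorf-style default: report regions of at least this many nucleotides
DEFAULT_MIN_ORF_LEN = 3


@dataclass(frozen=True, order=True)
class Orf:
    """A complete open reading frame in mRNA coordinates.

    ``start`` is the position of the A of ATG; ``end`` is one past the last
    base of the stop codon (0-based half-open), so ``length == end - start``
    includes the stop codon.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError(f"ORF [{self.start},{self.end}) length not divisible by 3")
        if self.end - self.start < 6:
            raise ValueError("complete ORF must span at least ATG + stop (6 nt)")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def frame(self) -> int:
        return self.start % 3

    @property
    def complete(self) -> bool:
        return True


@dataclass(frozen=True)
class CdsAnnotation:
    """Selected main CDS of one transcript plus the derived UTR intervals."""

    transcript_id: str
    cds: Orf
    utr5: tuple[int, int]
    utr3: tuple[int, int]

    @property
    def utr5_len(self) -> int:
        return self.utr5[1] - self.utr5[0]

    @property
    def utr3_len(self) -> int:
        return self.utr3[1] - self.utr3[0]


def find_complete_orfs(
    seq: str,
    min_len: int = DEFAULT_MIN_ORF_LEN,
    all_starts: bool = False,
) -> list[Orf]:
    """Enumerate complete ATG->stop ORFs in the three forward frames.

    By default one ORF is reported per (frame, stop codon) pair, anchored at
    the 5'-most ATG preceding that stop; ``all_starts=True`` additionally
    reports every internal ATG sharing the stop. Returned sorted by
    (start, end).

    Parameters
    ----------
    seq
        mRNA sequence over A/C/G/T/N (case-insensitive).
    min_len
        Minimum ORF length in nucleotides (complete ORFs are always >= 6).
    """
    if min_len < 3:
        raise ValueError("min_len must be >= 3")
    seq = seq.upper()
    orfs: list[Orf] = []
    n = len(seq)
    for frame in range(3):
        pending_starts: list[int] = []
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if pending_starts:
                    end = pos + 3
                    candidates = pending_starts if all_starts else pending_starts[:1]
                    for start in candidates:
                        if end - start >= max(min_len, 6):
                            orfs.append(Orf(start=start, end=end))
                    pending_starts = []
            elif codon == START_CODON:
                pending_starts.append(pos)
        # ORFs without an in-frame stop before the sequence end are incomplete
        # and dropped.
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def select_cds(
    orfs: list[Orf], mrna_length: int, transcript_id: str = ""
) -> CdsAnnotation | None:
    """Pick the main CDS: longest complete ORF, ties to the 5'-most start.

    Returns ``None`` when no complete ORF exists (transcript then excluded
    from downstream feature annotation).
    """
    if not orfs:
        return None
    best = min(orfs, key=lambda o: (-o.length, o.start))
    if best.end > mrna_length:
        raise ValueError(
            f"{transcript_id}: CDS end {best.end} exceeds mRNA length {mrna_length}"
        )
    utr5, utr3 = extract_utrs(best, mrna_length)
    return CdsAnnotation(transcript_id=transcript_id, cds=best, utr5=utr5, utr3=utr3)


def extract_utrs(cds: Orf, mrna_length: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """UTR intervals flanking a CDS: ``[0, cds.start)`` and ``[cds.end, length)``."""
    if cds.end > mrna_length:
        raise ValueError(f"CDS end {cds.end} exceeds mRNA length {mrna_length}")
    return (0, cds.start), (cds.end, mrna_length)
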