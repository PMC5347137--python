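"""Synthetic inputs with planted ground truth for every pipeline stage.

Transcripts are constructed feature-first: the CDS, uORF, stop-to-junction
distance and 3' UTR class are planted, then the built mRNA is verified with
the real annotator and regenerated on the rare occasions a random sequence
creates a competing ORF. This guarantees 100% recoverable truth, including
the exact 50/51-nt boundary cases, in every fixture set.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .nmd_features import annotate_transcript
from .orf_annotation import STOP_CODONS
from .transcript_models import Genome, MrnaMap, TranscriptModel, reverse_complement

_BASES = np.array(list("ACGT"))
_SAFE_CODONS = [
    c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if c not in STOP_CODONS and c != "ATG"
]


@dataclass(frozen=True)
class SurvivalGroupSpec:
    n: int = 100
    dist: str = "weibull"  # or "exponential"
    scale: float = 18.0  # days
    shape: float = 3.0  # weibull only
    censor_frac: float = 0.1


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    n_transcripts: int = 200
    frac_ptc: float = 0.2
    frac_uorf: float = 0.25
    frac_long_utr3: float = 0.15
    frac_noncoding: float = 0.05
    n_nmd_targets: int = 30
    effect_down_log2fc: float = -2.0
    effect_up_log2fc: float = 1.0
    effect_restore_log2fc: float = 1.5
    noise_sd: float = 0.25
    n_replicates: int = 2
    frac_bad_status: float = 0.05
    frac_zero_fpkm: float = 0.02
    decay: tuple[tuple[str, str, float], ...] = (
        ("rpl-12ptc", "wt", 60.0),
        ("rpl-12ptc", "daf2", 30.0),
    )
    decay_timepoints: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0)
    decay_replicates: int = 3
    decay_noise_sd: float = 0.1
    survival_groups: Mapping[str, SurvivalGroupSpec] = field(
        default_factory=lambda: {
            "wt": SurvivalGroupSpec(scale=18.0),
            "daf2": SurvivalGroupSpec(scale=32.0),
        }
    )

    def __post_init__(self) -> None:
        for name in ("frac_ptc", "frac_uorf", "frac_long_utr3", "frac_noncoding",
                     "frac_bad_status", "frac_zero_fpkm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for g, gs in self.survival_groups.items():
            if gs.censor_frac >= 1.0:
                raise ValueError(f"survival group {g!r}: censor_frac must be < 1")


@dataclass
class SyntheticAnnotation:
    genome: Genome
    transcripts: list[TranscriptModel]
    truth: pd.DataFrame


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _scrubbed_seq(rng: np.random.Generator, n: int) -> str:
    """Random sequence with every ATG occurrence broken (-> ACG)."""
    seq = _random_seq(rng, n)
    while "ATG" in seq:
        seq = seq.replace("ATG", "ACG")
    return seq


def _safe_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_SAFE_CODONS), size=n)
    return "".join(_SAFE_CODONS[i] for i in idx)


def _stop_codon(rng: np.random.Generator) -> str:
    return sorted(STOP_CODONS)[rng.integers(0, 3)]


def _build_mrna(
    rng: np.random.Generator,
    want_uorf: bool,
    utr3_len: int,
) -> tuple[str, int, int, Optional[int]]:
    """Assemble one mRNA; returns (seq, cds_start, cds_end, uorf_len)."""
    utr5_len = int(rng.integers(40, 150))
    utr5 = _scrubbed_seq(rng, utr5_len)
    uorf_len: Optional[int] = None
    if want_uorf:
        n_codons = int(rng.integers(1, 8))  # ATG + 1..7 codons + stop
        uorf = "ATG" + _safe_codons(rng, n_codons) + _stop_codon(rng)
        uorf_len = len(uorf)
        offset = int(rng.integers(0, utr5_len - uorf_len + 1))
        utr5 = utr5[:offset] + uorf + utr5[offset + uorf_len:]
    n_cds_codons = int(rng.integers(100, 250))
    cds = "ATG" + _safe_codons(rng, n_cds_codons) + _stop_codon(rng)
    utr3 = _scrubbed_seq(rng, utr3_len)
    seq = utr5 + cds + utr3
    return seq, utr5_len, utr5_len + len(cds), uorf_len


def _place_junctions(
    rng: np.random.Generator,
    cds_end: int,
    mrna_length: int,
    ptc: bool,
    forced_distance: Optional[int],
) -> tuple[int, ...]:
    """Junction positions (first base after each junction) satisfying PTC truth."""
    utr3_len = mrna_length - cds_end
    if ptc:
        if forced_distance is not None:
            d = forced_distance
        else:
            d = int(rng.integers(51, min(200, utr3_len - 1) + 1))
        if d <= 50 or cds_end + d >= mrna_length:
            raise ValueError("infeasible PTC+ junction placement")
    else:
        if forced_distance is not None:
            d = forced_distance
        else:
            # junction at most 50 nt past the stop, possibly inside the CDS
            hi = min(50, utr3_len - 1)
            d = int(rng.integers(-min(100, cds_end - 20), hi + 1))
        if d > 50:
            raise ValueError("infeasible PTC- junction placement")
    last = cds_end + d
    if not 0 < last < mrna_length:
        raise ValueError("junction outside mRNA")
    junctions = {last}
    for _ in range(int(rng.integers(0, 3))):  # up to 2 extra upstream junctions
        pos = int(rng.integers(20, max(21, last - 20)))
        if all(abs(pos - j) >= 20 for j in junctions):
            junctions.add(pos)
    return tuple(sorted(junctions))


def _layout_on_genome(
    rng: np.random.Generator,
    cursor: int,
    mrna: str,
    junctions: tuple[int, ...],
    strand: str,
) -> tuple[list[str], int, tuple[tuple[int, int], ...]]:
    """Lay out exons/introns starting at ``cursor``; returns the sequence
    parts to append plus exon intervals in transcript 5'->3' order."""
    bounds = [0, *junctions, len(mrna)]
    pieces = [mrna[a:b] for a, b in zip(bounds, bounds[1:])]
    parts: list[str] = []
    gap = int(rng.integers(80, 200))
    parts.append(_random_seq(rng, gap))
    cursor += gap
    order = pieces if strand == "+" else pieces[::-1]
    intervals: list[tuple[int, int]] = []
    for i, piece in enumerate(order):
        if i > 0:
            intron = int(rng.integers(50, 300))
            parts.append(_random_seq(rng, intron))
            cursor += intron
        seq = piece if strand == "+" else reverse_complement(piece)
        intervals.append((cursor, cursor + len(piece)))
        parts.append(seq)
        cursor += len(piece)
    if strand == "-":
        intervals = intervals[::-1]  # transcript order = descending genomic
    return parts, cursor, tuple(intervals)


def _mrna_map_from_plan(
    tid: str, mrna_length: int, junctions: tuple[int, ...],
    exons: tuple[tuple[int, int], ...], strand: str,
) -> MrnaMap:
    gpos = []
    for start, end in exons:
        if strand == "+":
            gpos.append(np.arange(start, end, dtype=np.int64))
        else:
            gpos.append(np.arange(end - 1, start - 1, -1, dtype=np.int64))
    return MrnaMap(
        transcript_id=tid, mrna_length=mrna_length, junctions=junctions,
        genomic_positions=np.concatenate(gpos),
    )


def gen_genome_and_transcripts(spec: SyntheticSpec) -> SyntheticAnnotation:
    """Generate a genome, transcript models and a planted-feature truth table.

    The first PTC+ transcript is pinned to a stop-to-junction distance of
    exactly 51 nt and the first multi-exon PTC- transcript to exactly 50 nt,
    so the strict boundary of the rule is always represented.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_transcripts
    ptc_flags = np.zeros(n, dtype=bool)
    ptc_flags[: int(round(spec.frac_ptc * n))] = True
    rng.shuffle(ptc_flags)
    uorf_flags = np.zeros(n, dtype=bool)
    uorf_flags[: int(round(spec.frac_uorf * n))] = True
    rng.shuffle(uorf_flags)
    n_long = int(round(spec.frac_long_utr3 * n))
    categories = np.array(
        ["long"] * n_long
        + ["short"] * ((n - n_long + 1) // 2)
        + ["medium"] * ((n - n_long) // 2)
    )
    rng.shuffle(categories)

    chrom_parts: list[str] = []
    cursor = 0
    transcripts: list[TranscriptModel] = []
    truth_rows: list[dict] = []
    first_ptc_pos = True
    first_ptc_neg_multi = True

    for i in range(n):
        ptc = bool(ptc_flags[i])
        want_uorf = bool(uorf_flags[i])
        cat = str(categories[i])
        if cat == "short":
            # PTC+ needs room for a junction >51 nt into the 3' UTR
            lo = 80 if ptc else 20
            utr3_len = int(rng.integers(lo, 351))
        elif cat == "medium":
            utr3_len = int(rng.integers(351, 1500))
        else:
            utr3_len = int(rng.integers(1500, 2500))
        single_exon = (not ptc) and rng.random() < 0.4
        strand = "+" if rng.random() < 0.5 else "-"

        for _attempt in range(50):
            seq, cds_start, cds_end, uorf_len = _build_mrna(rng, want_uorf, utr3_len)
            forced = None
            if ptc and first_ptc_pos and utr3_len > 52:
                forced = 51
            elif (not ptc) and (not single_exon) and first_ptc_neg_multi \
                    and utr3_len > 51:
                forced = 50
            junctions = () if single_exon else _place_junctions(
                rng, cds_end, len(seq), ptc, forced
            )
            tid = f"T{i:05d}"
            parts, cursor_try, exons = _layout_on_genome(
                rng, cursor, seq, junctions, strand
            )
            model = TranscriptModel(
                transcript_id=tid,
                gene_id=f"G{i:05d}",
                chrom="chrS",
                strand=strand,
                exons=exons,
                biotype="protein_coding",
            )
            # verify against the real annotator on the built mRNA
            mmap = _mrna_map_from_plan(tid, len(seq), junctions, exons, strand)
            rec = annotate_transcript(seq, mmap)
            expected_distance = None if single_exon else junctions[-1] - cds_end
            ok = (
                rec is not None
                and rec.has_ptc == ptc
                and rec.stop_to_last_junction == expected_distance
                and rec.has_uorf == want_uorf
                and rec.uorf_count == (1 if want_uorf else 0)
                and rec.utr3_len == len(seq) - cds_end
                and rec.utr3_category == cat
                and (uorf_len is None or rec.longest_uorf_len == uorf_len)
            )
            if ok:
                chrom_parts.extend(parts)
                cursor = cursor_try
                if forced == 51:
                    first_ptc_pos = False
                elif forced == 50:
                    first_ptc_neg_multi = False
                transcripts.append(model)
                truth_rows.append(
                    {
                        "transcript_id": tid,
                        "gene_id": f"G{i:05d}",
                        "biotype": "protein_coding",
                        "strand": strand,
                        "n_exons": len(exons),
                        "has_ptc": ptc,
                        "stop_to_last_junction": expected_distance,
                        "has_uorf": want_uorf,
                        "uorf_count": 1 if want_uorf else 0,
                        "longest_uorf_len": uorf_len or 0,
                        "utr5_len": cds_start,
                        "cds_start": cds_start,
                        "cds_end": cds_end,
                        "utr3_len": len(seq) - cds_end,
                        "utr3_category": cat,
                    }
                )
                break
            # otherwise a competing ORF slipped in; retry with fresh sequence
        else:
            raise RuntimeError(f"could not build transcript {i} in 50 attempts")

    # non-coding decoys exercising the biotype filter
    n_nc = int(round(spec.frac_noncoding * n))
    nc_biotypes = ["rRNA", "tRNA", "snoRNA", "ncRNA", "pseudogene"]
    for j in range(n_nc):
        gap = int(rng.integers(80, 200))
        chrom_parts.append(_random_seq(rng, gap))
        cursor += gap
        length = int(rng.integers(100, 400))
        chrom_parts.append(_random_seq(rng, length))
        tid = f"NC{j:04d}"
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=f"GNC{j:04d}",
                chrom="chrS",
                strand="+",
                exons=((cursor, cursor + length),),
                biotype=nc_biotypes[j % len(nc_biotypes)],
            )
        )
        truth_rows.append(
            {"transcript_id": tid, "gene_id": f"GNC{j:04d}",
             "biotype": nc_biotypes[j % len(nc_biotypes)], "strand": "+",
             "n_exons": 1, "has_ptc": False, "stop_to_last_junction": None,
             "has_uorf": False, "uorf_count": 0, "longest_uorf_len": 0,
             "utr5_len": 0, "cds_start": 0, "cds_end": 0, "utr3_len": 0,
             "utr3_category": "short"}
        )
        cursor += length

    genome = Genome({"chrS": "".join(chrom_parts)})
    truth = pd.DataFrame(truth_rows)

    # plant NMD targets among feature-bearing coding transcripts
    coding = truth["biotype"] == "protein_coding"
    eligible = truth.index[
        coding & (truth["has_ptc"] | truth["has_uorf"] | (truth["utr3_category"] == "long"))
    ].to_numpy()
    n_targets = min(spec.n_nmd_targets, eligible.size)
    target_idx = rng.choice(eligible, size=n_targets, replace=False)
    truth["is_nmd_target"] = False
    truth.loc[target_idx, "is_nmd_target"] = True
    return SyntheticAnnotation(genome=genome, transcripts=transcripts, truth=truth)


def write_fasta(genome: Genome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.sequences:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(transcripts: Sequence[TranscriptModel], path: str) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            for start, end in sorted(t.exons):
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'transcript_biotype "{t.biotype}";'
                )
                fh.write(
                    "\t".join(
                        [t.chrom, "nmdpipe", "exon", str(start + 1), str(end),
                         ".", t.strand, ".", attrs]
                    )
                    + "\n"
                )


def gen_expression(
    spec: SyntheticSpec,
    truth: pd.DataFrame,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Expression table for the 4-genotype design with planted effects.

    Conditions: wt, daf2, smg2, double. Contrasts: daf2_vs_wt, smg2_vs_wt,
    double_vs_daf2. Planted NMD targets are shifted by ``effect_down`` in
    daf2, ``effect_up`` in smg2, and ``effect_down + effect_restore`` in the
    double mutant. Per-contrast log2fc and p come from small-replicate
    t-tests on the simulated replicates (default 2 replicates per condition).
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    coding = truth[truth["biotype"] == "protein_coding"].reset_index(drop=True)
    n = len(coding)
    is_target = coding["is_nmd_target"].to_numpy(dtype=bool)
    baseline = rng.normal(5.0, 1.5, size=n)
    shifts = {
        "wt": np.zeros(n),
        "daf2": np.where(is_target, spec.effect_down_log2fc, 0.0),
        "smg2": np.where(is_target, spec.effect_up_log2fc, 0.0),
        "double": np.where(
            is_target, spec.effect_down_log2fc + spec.effect_restore_log2fc, 0.0
        ),
    }
    reps = {
        cond: baseline[:, None]
        + shift[:, None]
        + rng.normal(0.0, spec.noise_sd, size=(n, spec.n_replicates))
        for cond, shift in shifts.items()
    }

    out = coding[["transcript_id", "gene_id"]].copy()
    out["status"] = "OK"
    for cond in shifts:
        out[f"fpkm_{cond}"] = 2.0 ** reps[cond].mean(axis=1)
    for contrast, (c2, c1) in {
        "daf2_vs_wt": ("daf2", "wt"),
        "smg2_vs_wt": ("smg2", "wt"),
        "double_vs_daf2": ("double", "daf2"),
    }.items():
        a, b = reps[c2], reps[c1]
        lfc = a.mean(axis=1) - b.mean(axis=1)
        if spec.noise_sd == 0.0:
            p = np.where(np.abs(lfc) > 0, 0.0, 1.0)
        else:
            from scipy import stats

            p = stats.ttest_ind(a, b, axis=1).pvalue
            p = np.where(np.isfinite(p), p, np.where(np.abs(lfc) > 0, 0.0, 1.0))
        out[f"log2fc_{contrast}"] = lfc
        out[f"p_{contrast}"] = p

    # plant filterable rows: bad status and zero FPKMs (never on targets, so
    # planted effects survive filtering)
    nontargets = np.flatnonzero(~is_target)
    n_bad = int(round(spec.frac_bad_status * n))
    n_zero = int(round(spec.frac_zero_fpkm * n))
    picked = rng.choice(nontargets, size=min(n_bad + n_zero, nontargets.size),
                        replace=False)
    bad, zero = picked[:n_bad], picked[n_bad:]
    out.loc[out.index[bad], "status"] = [
        ("NOTEST", "HIDATA", "FAIL")[int(x)] for x in rng.integers(0, 3, size=len(bad))
    ]
    if len(zero):
        out.loc[out.index[zero], "fpkm_daf2"] = 0.0
    return out


def gen_decay(spec: SyntheticSpec, seed: Optional[int] = None,
              emit_ct: bool = False) -> pd.DataFrame:
    """Exponential decay time courses: abundance(t) = 2^(-t/t_half) x noise.

    Abundance is emitted already normalized (t=0 exactly 1 per replicate);
    multiplicative lognormal noise (sd on the ln scale) applies to t > 0.
    With ``emit_ct`` the table instead carries ct_target/ct_reference columns
    (constant reference Ct) encoding the same abundances.
    """
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    rows = []
    for gene, genotype, t_half in spec.decay:
        for rep in range(1, spec.decay_replicates + 1):
            for t in spec.decay_timepoints:
                level = 2.0 ** (-t / t_half)
                if t > 0 and spec.decay_noise_sd > 0:
                    level *= math.exp(rng.normal(0.0, spec.decay_noise_sd))
                rows.append(
                    {"gene": gene, "genotype": genotype, "replicate": rep,
                     "time_min": t, "abundance": level}
                )
    df = pd.DataFrame(rows)
    if emit_ct:
        ct_ref = 15.0
        df["ct_reference"] = ct_ref
        df["ct_target"] = ct_ref - np.log2(df["abundance"]) + 8.0
        df = df.drop(columns=["abundance"])
    return df


def gen_survival(spec: SyntheticSpec, seed: Optional[int] = None) -> pd.DataFrame:
    """Censored survival tables with per-group hazard models.

    Death days are Weibull or exponential draws; a ``censor_frac`` fraction
    of animals is right-censored uniformly before their death day. Days are
    rounded up to integers (animals scored on transfer days).
    """
    rng = np.random.default_rng(spec.seed + 3 if seed is None else seed)
    rows = []
    for group, gs in spec.survival_groups.items():
        if gs.dist == "weibull":
            deaths = gs.scale * rng.weibull(gs.shape, size=gs.n)
        elif gs.dist == "exponential":
            deaths = rng.exponential(gs.scale, size=gs.n)
        else:
            raise ValueError(f"unknown survival distribution {gs.dist!r}")
        censored = rng.random(gs.n) < gs.censor_frac
        days = np.where(censored, rng.uniform(0, deaths), deaths)
        days = np.maximum(np.ceil(days), 1.0)
        for i in range(gs.n):
            rows.append(
                {"animal_id": f"{group}-{i:04d}", "group": group,
                 "day": int(days[i]),
                 "event": "censored" if censored[i] else "death"}
            )
    return pd.DataFrame(rows)
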