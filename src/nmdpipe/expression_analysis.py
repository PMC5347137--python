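"""Expression filtering, differential classes and enrichment statistics.

Expression tables are pandas DataFrames with columns::

    transcript_id, gene_id, status,
    fpkm_<condition> ...,
    log2fc_<contrast>, p_<contrast> ...

Statuses follow the upstream differential-testing convention: ``OK`` rows are
testable; ``NOTEST``/``HIDATA``/``FAIL`` rows (and rows with a zero FPKM in
any condition) are excluded before analysis.

Default thresholds: down-regulated means log2 fold change <= -1 and
p <= 0.1 (both boundaries inclusive); the gene-set input variant relaxes the
fold-change cut to -0.4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_FC_THRESHOLD = 1.0
DEFAULT_P_THRESHOLD = 0.1
GO_INPUT_FC_THRESHOLD = 0.4

VALID_STATUSES = frozenset({"OK", "NOTEST", "HIDATA", "FAIL"})


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 feature-vs-downregulation association test."""

    feature: str
    contrast: str
    table: tuple[tuple[int, int], tuple[int, int]]  # [[feat&down, feat&not], [nofeat&down, nofeat&not]]
    chi2: Optional[float]
    p: Optional[float]
    fraction_down: Optional[float]  # feature fraction among down
    fraction_other: Optional[float]  # feature fraction among not-down
    testable: bool


@dataclass(frozen=True)
class RestorationSummary:
    n_down: int
    n_restored: int

    @property
    def fraction_restored(self) -> Optional[float]:
        return self.n_restored / self.n_down if self.n_down else None


def compute_fpkm(
    fragment_count: float | np.ndarray,
    transcript_length: float | np.ndarray,
    total_mapped_fragments: float | np.ndarray,
) -> float | np.ndarray:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if np.any(np.asarray(transcript_length) <= 0):
        raise ValueError("transcript_length must be positive")
    if np.any(np.asarray(total_mapped_fragments) <= 0):
        raise ValueError("total_mapped_fragments must be positive")
    return fragment_count / (
        (transcript_length / 1000.0) * (total_mapped_fragments / 1e6)
    )


def fpkm_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("fpkm_")]


def filter_expression(df: pd.DataFrame) -> pd.DataFrame:
    """Keep rows with status OK and strictly positive FPKM in all conditions.

    Removal counts are logged per reason.
    """
    if "status" not in df.columns:
        raise ValueError("expression table lacks a 'status' column")
    cols = fpkm_columns(df)
    ok = df["status"] == "OK"
    nonzero = (df[cols] > 0).all(axis=1) if cols else pd.Series(True, index=df.index)
    n_status = int((~ok).sum())
    n_zero = int((ok & ~nonzero).sum())
    if n_status:
        logger.info("filter_expression: removed %d row(s) with non-OK status", n_status)
    if n_zero:
        logger.info("filter_expression: removed %d row(s) with a zero FPKM", n_zero)
    return df[ok & nonzero].copy()


def classify_de(
    df: pd.DataFrame,
    contrast: str,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Three-way down / up / unchanged partition for one contrast.

    Boundaries are inclusive: log2fc <= -fc_threshold and p <= p_threshold
    call "down"; "up" is symmetric.
    """
    fc_col, p_col = f"log2fc_{contrast}", f"p_{contrast}"
    for col in (fc_col, p_col):
        if col not in df.columns:
            raise KeyError(f"contrast {contrast!r}: missing column {col!r}")
    fc = df[fc_col].to_numpy(dtype=float)
    p = df[p_col].to_numpy(dtype=float)
    cls = np.where(
        (fc <= -fc_threshold) & (p <= p_threshold),
        "down",
        np.where((fc >= fc_threshold) & (p <= p_threshold), "up", "unchanged"),
    )
    out = df[["transcript_id"]].copy()
    out["contrast"] = contrast
    out["de_class"] = cls
    return out


def chi2_fraction_test(table: Sequence[Sequence[int]]) -> tuple[Optional[float], Optional[float]]:
    """Pearson chi-square on a 2x2 table, no continuity correction, df=1.

    Returns ``(chi2, two_sided_p)``; ``(None, None)`` when any margin is zero
    (the test is then undefined).
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(arr < 0):
        raise ValueError("table entries must be nonnegative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        return None, None
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


def feature_fraction_test(
    de: pd.DataFrame,
    features: pd.DataFrame,
    feature: str,
    contrast: Optional[str] = None,
) -> EnrichmentResult:
    """Association between a binary NMD feature and down-regulation.

    Builds the 2x2 table (feature+/- x down/not-down) over the shared
    transcript universe; "not-down" means every other tested transcript, so
    the columns partition the universe.

    Parameters
    ----------
    de
        Output of :func:`classify_de` (columns transcript_id, de_class).
    features
        Feature table with transcript_id and a boolean column named
        ``has_ptc`` / ``has_uorf`` (``feature`` may be given as "PTC",
        "uORF", or the literal column name).
    """
    col = {"ptc": "has_ptc", "uorf": "has_uorf"}.get(feature.lower(), feature)
    if col not in features.columns:
        raise KeyError(f"feature column {col!r} not in feature table")
    merged = de.merge(features[["transcript_id", col]], on="transcript_id", how="inner")
    down = merged["de_class"] == "down"
    feat = merged[col].astype(bool)
    table = (
        (int((feat & down).sum()), int((feat & ~down).sum())),
        (int((~feat & down).sum()), int((~feat & ~down).sum())),
    )
    chi2, p = chi2_fraction_test(table)
    n_down = table[0][0] + table[1][0]
    n_other = table[0][1] + table[1][1]
    return EnrichmentResult(
        feature=feature,
        contrast=contrast or (de["contrast"].iloc[0] if "contrast" in de and len(de) else ""),
        table=table,
        chi2=chi2,
        p=p,
        fraction_down=table[0][0] / n_down if n_down else None,
        fraction_other=table[0][1] / n_other if n_other else None,
        testable=chi2 is not None,
    )


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses the exact Mann-Whitney distribution when both samples have n <= 10
    and no ties (equivalent to exhaustive permutation over ranks); otherwise
    the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    small = len(x) <= 10 and len(y) <= 10
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.pvalue)


def utr3_foldchange_test(
    df: pd.DataFrame,
    features: pd.DataFrame,
    contrast: str,
) -> dict:
    """Fold-change distributions by 3' UTR length class, pairwise rank-sum tests.

    Returns a dict with per-category medians/sizes and p-values for
    long-vs-short, long-vs-medium and medium-vs-short. Comparisons where a
    category has fewer than 2 members are skipped with a warning.
    """
    fc_col = f"log2fc_{contrast}"
    if fc_col not in df.columns:
        raise KeyError(f"missing column {fc_col!r}")
    merged = df.merge(
        features[["transcript_id", "utr3_category"]], on="transcript_id", how="inner"
    )
    groups = {
        cat: merged.loc[merged["utr3_category"] == cat, fc_col].to_numpy(dtype=float)
        for cat in ("short", "medium", "long")
    }
    result: dict = {
        "contrast": contrast,
        "median_log2fc": {c: (float(np.median(v)) if v.size else None)
                          for c, v in groups.items()},
        "n": {c: int(v.size) for c, v in groups.items()},
        "p_values": {},
    }
    for a, b in (("long", "short"), ("long", "medium"), ("medium", "short")):
        if groups[a].size < 2 or groups[b].size < 2:
            logger.warning("utr3_foldchange_test: skipping %s vs %s (category too small)",
                           a, b)
            result["p_values"][f"{a}_vs_{b}"] = None
            continue
        result["p_values"][f"{a}_vs_{b}"] = rank_sum_test(groups[a], groups[b])
    return result


def restoration_analysis(
    df: pd.DataFrame,
    contrast_down: str,
    contrast_restore: str,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    restore_threshold: float = 0.0,
) -> pd.DataFrame:
    """Flag down-regulated transcripts whose levels rise again in the double mutant.

    A transcript enters the analysis when classified down in
    ``contrast_down`` (mutant A vs WT); it is called restored when its log2
    fold change in ``contrast_restore`` (double vs mutant A) is >=
    ``restore_threshold`` (default 0: any increase).

    Returns a DataFrame with transcript_id, down_in_mutA, restored (restored
    is pd.NA for transcripts not down in mutant A).
    """
    de = classify_de(df, contrast_down, fc_threshold, p_threshold)
    rest_col = f"log2fc_{contrast_restore}"
    if rest_col not in df.columns:
        raise KeyError(f"missing column {rest_col!r}")
    out = df[["transcript_id"]].copy()
    out["down_in_mutA"] = (de["de_class"] == "down").to_numpy()
    restored = df[rest_col].to_numpy(dtype=float) >= restore_threshold
    out["restored"] = pd.array(
        np.where(out["down_in_mutA"], restored, None), dtype="boolean"
    )
    return out


def summarize_restoration(calls: pd.DataFrame) -> RestorationSummary:
    down = calls[calls["down_in_mutA"]]
    return RestorationSummary(
        n_down=int(len(down)), n_restored=int(down["restored"].sum())
    )


def hypergeom_tail(k: int, universe_size: int, term_size: int, target_size: int) -> float:
    """One-sided enrichment p: P(X >= k) under hypergeometric sampling."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, universe_size, term_size, target_size))


def overrepresentation_test(
    target_set: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-term gene-set overrepresentation (Fisher tail and EASE variant).

    ``p_fisher`` is the exact one-sided hypergeometric tail P(X >= k);
    ``p_ease`` is the same tail computed after decrementing the observed
    overlap by one (conservative). Terms with zero overlap are skipped.
    Term gene lists are intersected with the universe first.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    target = set(target_set) & universe
    n = len(target)
    N = len(universe)
    rows = []
    for term, genes in term_map.items():
        term_genes = set(genes) & universe
        k = len(term_genes & target)
        if k == 0:
            continue
        K = len(term_genes)
        rows.append(
            {
                "term": term,
                "overlap": k,
                "term_size": K,
                "expected": n * K / N,
                "p_fisher": hypergeom_tail(k, N, K, n),
                "p_ease": hypergeom_tail(k - 1, N, K, n),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term", "overlap", "term_size", "expected", "p_fisher", "p_ease"]
    ).sort_values("p_ease", kind="stable").reset_index(drop=True)
    if bh_correct and len(out):
        from statsmodels.stats.multitest import multipletests

        out["q_ease"] = multipletests(out["p_ease"], method="fdr_bh")[1]
    return out


def set_overlap_test(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> tuple[int, Optional[float], float]:
    """Overlap of two gene sets vs hypergeometric expectation.

    Returns ``(overlap, fold, p)`` with fold = observed/expected (None when
    either set is empty) and a one-sided enrichment p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(set_a) & universe
    b = set(set_b) & universe
    k = len(a & b)
    if not a or not b:
        return k, None, 1.0
    expected = len(a) * len(b) / len(universe)
    fold = k / expected
    p = hypergeom_tail(k, len(universe), len(a), len(b))
    return k, fold, p
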