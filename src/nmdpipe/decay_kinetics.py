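"""qPCR quantification (comparative C_T) and first-order mRNA decay fitting.

Half-lives come from transcription-shutoff time courses: abundance is
reference-normalized per replicate, divided by that replicate's t=0 value,
and ln(abundance) is regressed on time. The default fit fixes the intercept
at 0 (t=0 is normalized to 1); a free-intercept variant is available for
robustness checks.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)


@dataclass(frozen=True)
class QpcrMeasurement:
    sample: str
    gene: str
    ct_target: float
    ct_reference: float
    reference_gene: str = ""

    def __post_init__(self) -> None:
        for name, value in (("ct_target", self.ct_target),
                            ("ct_reference", self.ct_reference)):
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{self.sample}/{self.gene}: {name}={value!r} "
                                 "must be positive and finite")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass
class DecayTimeCourse:
    """Normalized abundance vs time after transcription shutoff.

    ``data`` columns: time_min, replicate, abundance. Abundance is relative
    to the reference gene and to each replicate's t=0 value (so every
    replicate has abundance 1 at t=0).
    """

    gene: str
    genotype: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"time_min", "replicate", "abundance"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"decay time course missing columns: {sorted(missing)}")
        if 0 not in set(self.data["time_min"]):
            raise ValueError(f"{self.gene}/{self.genotype}: t=0 timepoint required")

    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(self.data["time_min"].unique())


@dataclass(frozen=True)
class HalfLifeEstimate:
    gene: str
    genotype: str
    k: float  # per-minute decay rate; <= 0 flags "no decay"
    t_half: Optional[float]  # minutes; None when no decay
    se_k: float
    r2: float
    no_decay: bool


def ddct_relative_level(m: QpcrMeasurement, calibrator: QpcrMeasurement) -> float:
    """Relative abundance by the comparative C_T method: 2^-(ddCt)."""
    if m.gene != calibrator.gene or m.reference_gene != calibrator.reference_gene:
        raise ValueError("sample and calibrator must share gene and reference gene")
    ddct = m.delta_ct - calibrator.delta_ct
    return 2.0 ** (-ddct)


def normalize_timecourse(
    df: pd.DataFrame,
    gene: str,
    genotype: str,
) -> DecayTimeCourse:
    """Build a normalized time course from raw Ct (or abundance) rows.

    Input columns: time_min, replicate and either ``abundance`` or the pair
    ``ct_target``/``ct_reference``. Normalization order: per-replicate
    reference normalization (2^-(dCt)) first, then division by that
    replicate's t=0 value.
    """
    df = df.copy()
    if "abundance" not in df.columns:
        if not {"ct_target", "ct_reference"} <= set(df.columns):
            raise ValueError("need 'abundance' or 'ct_target'+'ct_reference' columns")
        df["abundance"] = 2.0 ** -(df["ct_target"] - df["ct_reference"])
    parts = []
    for rep, sub in df.groupby("replicate"):
        t0 = sub.loc[sub["time_min"] == 0, "abundance"]
        if t0.empty:
            raise ValueError(f"replicate {rep!r}: no t=0 measurement")
        sub = sub.copy()
        sub["abundance"] = sub["abundance"] / float(t0.mean())
        parts.append(sub)
    out = pd.concat(parts, ignore_index=True)[["time_min", "replicate", "abundance"]]
    return DecayTimeCourse(gene=gene, genotype=genotype, data=out)


def fit_decay(
    tc: DecayTimeCourse,
    through_origin: bool = True,
    floor_policy: str = "half_min",
) -> HalfLifeEstimate:
    """Least-squares fit of ln(abundance) = -k*t.

    Non-positive abundances cannot be log-transformed; under the default
    ``floor_policy="half_min"`` they are replaced by half the smallest
    positive observed abundance (count logged), under ``"drop"`` the points
    are discarded.

    A non-positive fitted k is flagged ``no_decay`` with ``t_half=None``;
    otherwise ``t_half = ln2 / k``.
    """
    df = tc.data
    if df["time_min"].nunique() < 3:
        raise ValueError(f"{tc.gene}/{tc.genotype}: need >=3 timepoints")
    t = df["time_min"].to_numpy(dtype=float)
    a = df["abundance"].to_numpy(dtype=float)
    nonpos = a <= 0
    if nonpos.any():
        if floor_policy == "drop":
            t, a = t[~nonpos], a[~nonpos]
            logger.info("fit_decay %s/%s: dropped %d non-positive point(s)",
                        tc.gene, tc.genotype, int(nonpos.sum()))
        elif floor_policy == "half_min":
            floor = a[a > 0].min() / 2.0
            a = np.where(nonpos, floor, a)
            logger.info("fit_decay %s/%s: floored %d non-positive point(s) to %g",
                        tc.gene, tc.genotype, int(nonpos.sum()), floor)
        else:
            raise ValueError(f"unknown floor_policy {floor_policy!r}")
    y = np.log(a)
    if through_origin:
        mask = t > 0  # t=0 points carry no information about the slope
        tt, yy = t[mask], y[mask]
        sxx = float(np.sum(tt * tt))
        slope = float(np.sum(tt * yy)) / sxx
        resid = yy - slope * tt
        dof = max(len(tt) - 1, 1)
        se = math.sqrt(float(np.sum(resid**2)) / dof / sxx)
        ss_tot = float(np.sum(yy**2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    else:
        from scipy import stats as _st

        res = _st.linregress(t, y)
        slope, se = float(res.slope), float(res.stderr)
        r2 = float(res.rvalue**2)
    k = -slope
    no_decay = k <= 0
    return HalfLifeEstimate(
        gene=tc.gene,
        genotype=tc.genotype,
        k=k,
        t_half=None if no_decay else LN2 / k,
        se_k=se,
        r2=r2,
        no_decay=no_decay,
    )


def compare_decay(tc_a: DecayTimeCourse, tc_b: DecayTimeCourse) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA (genotype x time) on abundance.

    Requires shared timepoints and >=2 replicates per genotype-time cell
    (balanced design; type II sums of squares, equivalent to type I there).
    Returns the ANOVA table with F and p per effect.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    ta, tb = set(tc_a.timepoints), set(tc_b.timepoints)
    if ta != tb:
        raise ValueError(f"timepoints differ between genotypes: {sorted(ta ^ tb)}")
    frames = []
    for tc in (tc_a, tc_b):
        sub = tc.data.copy()
        sub["genotype"] = tc.genotype
        frames.append(sub)
    df = pd.concat(frames, ignore_index=True)
    counts = df.groupby(["genotype", "time_min"]).size()
    bad = counts[counts < 2]
    if len(bad):
        geno, tm = bad.index[0]
        raise ValueError(f"cell genotype={geno!r}, time={tm}: fewer than 2 replicates")
    model = smf.ols("abundance ~ C(genotype) * C(time_min)", data=df).fit()
    with warnings.catch_warnings():
        # a zero genotype effect (identical inputs) yields F=0 with a harmless
        # divide-by-zero warning in the p-value
        warnings.simplefilter("ignore", RuntimeWarning)
        table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(genotype)": "genotype",
            "C(time_min)": "time",
            "C(genotype):C(time_min)": "interaction",
            "Residual": "residual",
        }
    )
    return table


def reporter_ratio(
    intensity_ptc: np.ndarray,
    intensity_wt: np.ndarray,
    auto_ptc: float,
    auto_wt: float,
) -> dict:
    """Background-subtracted reporter intensity ratio (PTC reporter / WT reporter).

    Backgrounds are autofluorescence means from matched non-transgenic
    controls. Negative per-animal numerators (reporter dimmer than
    background) pass through with a warning.
    """
    ptc = np.asarray(intensity_ptc, dtype=float) - auto_ptc
    wt = np.asarray(intensity_wt, dtype=float) - auto_wt
    if np.any(ptc < 0):
        logger.warning("reporter_ratio: %d PTC-reporter animal(s) dimmer than background",
                       int((ptc < 0).sum()))
    denom = float(wt.mean())
    if denom <= 0:
        raise ValueError("WT reporter mean does not exceed background")
    numer = float(ptc.mean())
    ratio = numer / denom
    sem = float(ptc.std(ddof=1) / math.sqrt(len(ptc))) if len(ptc) > 1 else float("nan")
    return {
        "ratio": ratio,
        "per_animal_ptc": ptc.tolist(),
        "per_animal_wt": wt.tolist(),
        "sem_ptc": sem,
    }
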