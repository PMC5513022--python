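"""Efficiency-corrected relative quantification of high-throughput RT-qPCR.

Implements the multi-reference-gene scheme popularised by qBase: per assay
*g* and sample *s*,

    RQ_{g,s}  = E_g ^ (meanCq_g − Cq_{g,s})          (calibrated relative quantity)
    NF_s      = geometric mean over references r of RQ_{r,s}
    NRQ_{g,s} = RQ_{g,s} / NF_s                      (normalized relative quantity)

with E_g the amplification efficiency (fold amplification per cycle,
estimated from a standard dilution series as E = 10^(−1/slope)) and
meanCq_g the across-sample arithmetic mean Cq of the assay.  By
construction the geometric mean of the reference-assay NRQs is 1 in every
sample, and a constant Cq shift applied to a whole sample (a global
pipetting effect) cancels in NRQ.

Differential calls between conditions use an exact Mann-Whitney (Wilcoxon
rank-sum) permutation test on the per-sample NRQs, with mid-ranks for ties;
significance defaults to P < 0.01.  Undetected observations (Cq = "ND") are
treated as missing, never as zero; an assay without observations in a
condition is reported as not testable rather than imputed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CqMatrix",
    "NRQMatrix",
    "DiffCall",
    "MannWhitneyResult",
    "estimate_efficiency",
    "normalize",
    "mann_whitney_exact",
    "condition_ratios",
]

EFFICIENCY_QC_RANGE = (1.6, 2.2)
EXACT_MAX_GROUP = 12


@dataclass
class CqMatrix:
    """Raw quantification cycles plus per-assay efficiencies and the
    reference-assay set.

    ``observations`` is a long table with columns assay, sample, condition,
    replicate, cq (NaN = undetected).  ``replicate`` indexes technical
    replicates within a biological sample.
    """

    observations: pd.DataFrame
    efficiencies: dict[str, float] = field(default_factory=dict)
    reference_assays: frozenset[str] = frozenset()

    def detectable(self, assay: str) -> bool:
        sub = self.observations[self.observations["assay"] == assay]
        return bool(sub["cq"].notna().any())


@dataclass
class NRQMatrix:
    """Normalized relative quantities, one row per (assay, unit).

    A *unit* is the statistical replicate the test sees: each technical
    replicate when replicates are pooled (the default), or the averaged
    biological sample otherwise.
    """

    values: pd.DataFrame  # columns: assay, unit, sample, condition, nrq

    def log2(self) -> pd.DataFrame:
        out = self.values.copy()
        out["log2_nrq"] = np.log2(out["nrq"])
        return out

    def pivot(self) -> pd.DataFrame:
        return self.values.pivot_table(
            index="assay", columns="unit", values="nrq", aggfunc="first"
        )


@dataclass
class DiffCall:
    assay: str
    condition: str
    control: str
    log2_ratio: float
    p_value: float
    significant: bool
    testable: bool = True


@dataclass
class MannWhitneyResult:
    u: float
    p: float
    exact: bool


def estimate_efficiency(dilution_table: pd.DataFrame) -> dict[str, float]:
    """Per-assay amplification efficiency from a standard dilution series.

    ``dilution_table`` columns: assay, dilution (relative input amount),
    cq.  E = 10^(−1/slope) with slope the least-squares slope of Cq on
    log10(dilution); a perfect duplication gives slope −3.32 and E = 2.
    Fewer than 3 points or a positive slope (corrupt series) is an error;
    E outside (1.6, 2.2) only warns.
    """
    out: dict[str, float] = {}
    for assay, sub in dilution_table.groupby("assay"):
        sub = sub.dropna(subset=["cq"])
        if len(sub) < 3:
            raise ValueError(f"assay {assay}: need >=3 dilution points, got {len(sub)}")
        x = np.log10(sub["dilution"].astype(float).to_numpy())
        if x.max() - x.min() < 2.0 - 1e-9:
            warnings.warn(f"assay {assay}: dilution series spans <2 log10 units")
        y = sub["cq"].astype(float).to_numpy()
        slope = np.polyfit(x, y, 1)[0]
        if slope >= 0:
            raise ValueError(f"assay {assay}: non-negative dilution slope {slope:.3f}")
        e = 10.0 ** (-1.0 / slope)
        if not (EFFICIENCY_QC_RANGE[0] < e < EFFICIENCY_QC_RANGE[1]):
            warnings.warn(f"assay {assay}: efficiency {e:.3f} outside QC range")
        out[str(assay)] = float(e)
    return out


def _units(obs: pd.DataFrame, average_technical: bool) -> pd.DataFrame:
    """Collapse observations to one Cq per (assay, unit).

    Pooled mode (default): every (sample, replicate) is its own unit, so a
    3 biological × 3 technical design yields n = 9 units per condition.
    Averaged mode: technical replicates are averaged first and the
    biological sample is the unit (n = 3).
    """
    df = obs.dropna(subset=["cq"]).copy()
    if average_technical:
        g = (
            df.groupby(["assay", "sample", "condition"], as_index=False)["cq"]
            .mean()
        )
        g["unit"] = g["sample"]
        return g[["assay", "unit", "sample", "condition", "cq"]]
    df["unit"] = df["sample"].astype(str) + ":" + df["replicate"].astype(str)
    return df[["assay", "unit", "sample", "condition", "cq"]]


def normalize(cq: CqMatrix, average_technical: bool = False) -> NRQMatrix:
    """Cq table -> normalized relative quantities (see module docstring).

    Every unit must be covered by all reference assays; a missing reference
    observation is an error naming the unit.
    """
    if not cq.reference_assays:
        raise ValueError("no reference assays declared")
    for a in cq.reference_assays:
        if a not in cq.efficiencies:
            raise ValueError(f"reference assay {a} has no efficiency")
    units = _units(cq.observations, average_technical)

    for assay in units["assay"].unique():
        e = cq.efficiencies.get(assay)
        if e is None:
            raise ValueError(f"assay {assay}: no efficiency")
        if e <= 1:
            raise ValueError(f"assay {assay}: efficiency {e} must exceed 1")

    # RQ relative to the across-unit mean Cq of the assay (qBase calibrator)
    units = units.copy()
    mean_cq = units.groupby("assay")["cq"].transform("mean")
    eff = units["assay"].map(cq.efficiencies).astype(float)
    units["rq"] = eff ** (mean_cq - units["cq"])

    ref = units[units["assay"].isin(cq.reference_assays)]
    all_units = units["unit"].unique()
    nf: dict[str, float] = {}
    for unit in all_units:
        sub = ref[ref["unit"] == unit]
        missing = cq.reference_assays - set(sub["assay"])
        if missing:
            raise ValueError(
                f"sample unit {unit}: missing reference observations {sorted(missing)}"
            )
        nf[unit] = float(np.exp(np.mean(np.log(sub["rq"].to_numpy()))))

    units["nrq"] = units["rq"] / units["unit"].map(nf)
    return NRQMatrix(
        units[["assay", "unit", "sample", "condition", "nrq"]].reset_index(drop=True)
    )


def _rank_sum_distribution(ranks2: np.ndarray, n1: int) -> np.ndarray:
    """Exact null distribution of the group-1 rank sum (doubled ranks).

    ``dist[s]`` counts the C(n, n1) equally likely label assignments whose
    doubled rank sum is s.  Classic subset-sum dynamic program; equivalent
    to enumerating every assignment.
    """
    total = int(ranks2.sum())
    dp = np.zeros((n1 + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:  # dp[j, s] += dp[j-1, s-r], items added one at a time
        r = int(r)
        dp[1:, r:] += dp[:-1, : total + 1 - r].copy()
    return dp[n1]


def mann_whitney_exact(
    x, y, alternative: str = "two-sided"
) -> MannWhitneyResult:
    """Mann-Whitney U test by exact label-permutation enumeration.

    Mid-ranks are assigned to ties; the two-sided p counts permutations whose
    U is at least as far from the null mean n1·n2/2 as observed.  The exact
    null is computed by a subset-sum dynamic program over doubled mid-ranks
    (integers), equivalent to full enumeration of all C(n1+n2, n1) label
    assignments.  Groups larger than 12 fall back to the normal
    approximation with tie correction (flagged via ``exact=False``).  Empty
    groups are an error.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("empty group in Mann-Whitney test")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0

    if max(n1, n2) > EXACT_MAX_GROUP:
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
        return MannWhitneyResult(u=float(u_obs), p=float(res.pvalue), exact=False)

    ranks2 = np.rint(2 * ranks).astype(int)  # doubled mid-ranks are integers
    dist = _rank_sum_distribution(ranks2, n1)
    # doubled rank sum s  ->  U = s/2 - n1(n1+1)/2
    s = np.arange(len(dist))
    u_all = s / 2.0 - n1 * (n1 + 1) / 2.0
    eps = 1e-9
    if alternative == "two-sided":
        mask = np.abs(u_all - mu) >= abs(u_obs - mu) - eps
    elif alternative == "greater":
        mask = u_all >= u_obs - eps
    elif alternative == "less":
        mask = u_all <= u_obs + eps
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = float(dist[mask].sum() / dist.sum())
    return MannWhitneyResult(u=u_obs, p=p, exact=True)


def condition_ratios(
    nrq: NRQMatrix,
    design: list[tuple[str, str]],
    alpha: float = 0.01,
) -> tuple[list[DiffCall], pd.DataFrame]:
    """log2 condition/control ratios with Mann-Whitney calls per assay.

    ``design`` lists (condition, control) comparisons; the control must be
    present in the data.  The returned table has assays as rows and
    "condition_vs_control" log2 ratios as columns (not-testable cells NaN).
    """
    df = nrq.values
    conditions = set(df["condition"])
    calls: list[DiffCall] = []
    for condition, control in design:
        if control not in conditions:
            raise ValueError(f"control condition {control!r} absent from data")
        for assay, sub in df.groupby("assay"):
            a = sub.loc[sub["condition"] == condition, "nrq"].to_numpy()
            b = sub.loc[sub["condition"] == control, "nrq"].to_numpy()
            if len(a) == 0 or len(b) == 0:
                calls.append(
                    DiffCall(assay, condition, control, math.nan, math.nan,
                             False, testable=False)
                )
                continue
            ratio = float(np.log2(a.mean() / b.mean()))
            p = mann_whitney_exact(a, b).p
            calls.append(
                DiffCall(assay, condition, control, ratio, p, p < alpha)
            )
    rows = [
        {
            "assay": c.assay,
            "comparison": f"{c.condition}_vs_{c.control}",
            "log2_ratio": c.log2_ratio,
        }
        for c in calls
        if c.testable
    ]
    heatmap = (
        pd.DataFrame(rows)
        .pivot_table(index="assay", columns="comparison", values="log2_ratio")
        if rows
        else pd.DataFrame()
    )
    return calls, heatmap
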