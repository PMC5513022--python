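import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lignoreg import qpcr_quant as q
from lignoreg.synthetic_data import make_cq_dataset

REFS = ["R1", "R2", "R3"]


def _dataset(fold, noise_sd, seed, e_target=1.9, conditions=("ctrl", "treat")):
    design = {
        "conditions": list(conditions),
        "control": conditions[0],
        "assays": ["T1"] + REFS,
        "reference_assays": REFS,
    }
    eff = {"T1": e_target, **{r: 1.95 for r in REFS}}
    folds = {("T1", c): fold for c in conditions[1:]}
    return make_cq_dataset(design, folds, eff, noise_sd=noise_sd, seed=seed)


def _normalize(cq_df, eff):
    cq = q.CqMatrix(cq_df, eff, frozenset(REFS))
    return q.normalize(cq)


# --- efficiency --------------------------------------------------------------

def test_efficiency_textbook_perfect_duplication():
    df = pd.DataFrame(
        {"assay": ["a"] * 3, "dilution": [1, 0.1, 0.01], "cq": [20, 23.32, 26.64]}
    )
    e = q.estimate_efficiency(df)["a"]
    assert e == pytest.approx(2.00, abs=0.01)


def test_efficiency_slope_3_80():
    # slope exactly -3.80 -> E = 10^(1/3.80)
    df = pd.DataFrame(
        {"assay": ["a"] * 3, "dilution": [1, 0.1, 0.01], "cq": [20, 23.8, 27.6]}
    )
    assert q.estimate_efficiency(df)["a"] == pytest.approx(10 ** (1 / 3.80), rel=1e-9)


def test_efficiency_two_points_error():
    df = pd.DataFrame({"assay": ["a"] * 2, "dilution": [1, 0.1], "cq": [20, 23.3]})
    with pytest.raises(ValueError, match=">=3"):
        q.estimate_efficiency(df)


def test_efficiency_positive_slope_error():
    df = pd.DataFrame(
        {"assay": ["a"] * 3, "dilution": [1, 0.1, 0.01], "cq": [26, 23, 20]}
    )
    with pytest.raises(ValueError, match="slope"):
        q.estimate_efficiency(df)


def test_efficiency_outside_qc_range_warns_not_errors():
    df = pd.DataFrame(
        {"assay": ["a"] * 3, "dilution": [1, 0.1, 0.01], "cq": [20, 25, 30]}
    )
    with pytest.warns(UserWarning, match="QC range"):
        e = q.estimate_efficiency(df)["a"]
    assert 1 < e < 1.6


# --- normalization -----------------------------------------------------------

def test_all_equal_cq_gives_unit_nrq():
    rows = [
        {"assay": a, "sample": s, "condition": "c", "replicate": 1, "cq": 20.0}
        for a in ["T1"] + REFS
        for s in ["s1", "s2", "s3"]
    ]
    nrq = _normalize(pd.DataFrame(rows), {a: 2.0 for a in ["T1"] + REFS})
    assert np.allclose(nrq.values["nrq"], 1.0)


def test_three_cycles_is_eightfold():
    rows = []
    for s, cq_t in [("s1", 20.0), ("s2", 23.0)]:
        rows.append(
            {"assay": "T1", "sample": s, "condition": s, "replicate": 1, "cq": cq_t}
        )
        for r in REFS:
            rows.append(
                {"assay": r, "sample": s, "condition": s, "replicate": 1, "cq": 21.0}
            )
    nrq = _normalize(pd.DataFrame(rows), {a: 2.0 for a in ["T1"] + REFS})
    v = nrq.values.set_index(["assay", "sample"])["nrq"]
    assert v["T1", "s1"] / v["T1", "s2"] == pytest.approx(8.0, rel=1e-12)


def test_noise_free_planted_fold_recovered_exactly():
    cq_df, dil_df, man = _dataset(fold=6.0, noise_sd=0.0, seed=0)
    eff = q.estimate_efficiency(dil_df)
    # efficiencies themselves recovered exactly from the noise-free series
    for a, e in man["efficiencies"].items():
        assert eff[a] == pytest.approx(e, rel=1e-9)
    nrq = _normalize(cq_df, eff)
    calls, _ = q.condition_ratios(nrq, [("treat", "ctrl")])
    (call,) = [c for c in calls if c.assay == "T1"]
    assert call.log2_ratio == pytest.approx(math.log2(6.0), abs=1e-9)


def test_reference_geometric_mean_is_one_per_sample():
    cq_df, dil_df, _ = _dataset(fold=4.0, noise_sd=0.2, seed=3)
    nrq = _normalize(cq_df, q.estimate_efficiency(dil_df))
    ref = nrq.values[nrq.values["assay"].isin(REFS)]
    for _, sub in ref.groupby("unit"):
        assert np.exp(np.mean(np.log(sub["nrq"]))) == pytest.approx(1.0, rel=1e-9)


def test_global_per_sample_cq_shift_leaves_nrq_invariant():
    # equal efficiencies: a pipetting shift is a constant per-sample Cq
    # offset, and reference normalization absorbs it exactly
    cq_df, _, _ = _dataset(fold=5.0, noise_sd=0.1, seed=7, e_target=1.95)
    eff = {a: 1.95 for a in ["T1"] + REFS}
    base = _normalize(cq_df, eff).values.sort_values(["assay", "unit"])
    rng = np.random.default_rng(0)
    shifts = {s: rng.uniform(-2, 2) for s in cq_df["sample"].unique()}
    shifted = cq_df.copy()
    shifted["cq"] = shifted["cq"] + shifted["sample"].map(shifts)
    after = _normalize(shifted, eff).values.sort_values(["assay", "unit"])
    assert np.allclose(base["nrq"].to_numpy(), after["nrq"].to_numpy(), rtol=1e-9)


def test_missing_reference_observation_names_sample():
    rows = [
        {"assay": a, "sample": "s1", "condition": "c", "replicate": 1, "cq": 20.0}
        for a in ["T1", "R1", "R2"]  # R3 missing
    ]
    cq = q.CqMatrix(pd.DataFrame(rows), {a: 2.0 for a in ["T1"] + REFS}, frozenset(REFS))
    with pytest.raises(ValueError, match="s1"):
        q.normalize(cq)


def test_technical_averaging_collapses_to_biological_units():
    cq_df, dil_df, _ = _dataset(fold=4.0, noise_sd=0.1, seed=5)
    cq = q.CqMatrix(cq_df, q.estimate_efficiency(dil_df), frozenset(REFS))
    pooled = q.normalize(cq, average_technical=False)
    averaged = q.normalize(cq, average_technical=True)
    n_units = lambda m: m.values.groupby("condition")["unit"].nunique()
    assert (n_units(pooled) == 9).all() and (n_units(averaged) == 3).all()


# --- Mann-Whitney ------------------------------------------------------------

def _brute_force_p(x, y):
    """Independent oracle: literal enumeration of all label assignments."""
    pooled = np.asarray(list(x) + list(y), float)
    ranks = stats.rankdata(pooled)
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    cnt = tot = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        tot += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            cnt += 1
    return cnt / tot


def test_identical_groups_give_p_one():
    assert q.mann_whitney_exact([1, 2, 3], [1, 2, 3]).p == 1.0


def test_fully_separated_3v3_gives_p_point_one():
    assert q.mann_whitney_exact([1, 2, 3], [4, 5, 6]).p == pytest.approx(0.1)


def test_empty_group_errors():
    with pytest.raises(ValueError):
        q.mann_whitney_exact([], [1.0])


def test_exact_matches_brute_force_with_and_without_ties():
    rng = np.random.default_rng(0)
    for _ in range(250):
        n1, n2 = rng.integers(1, 6), rng.integers(1, 6)
        if rng.random() < 0.5:  # heavy ties
            x = rng.integers(0, 4, n1).astype(float)
            y = rng.integers(0, 4, n2).astype(float)
        else:
            x, y = rng.normal(size=n1), rng.normal(size=n2)
        res = q.mann_whitney_exact(x, y)
        assert res.exact
        assert res.p == pytest.approx(_brute_force_p(x, y), abs=1e-12)


def test_exact_matches_scipy_on_tie_free_data():
    rng = np.random.default_rng(1)
    for _ in range(100):
        x, y = rng.normal(size=9), rng.normal(size=9)
        ours = q.mann_whitney_exact(x, y).p
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)


def test_large_groups_fall_back_to_flagged_approximation():
    rng = np.random.default_rng(2)
    res = q.mann_whitney_exact(rng.normal(size=15), rng.normal(size=15))
    assert not res.exact and 0 <= res.p <= 1


# --- condition ratios --------------------------------------------------------

def test_eightfold_mean_gives_log2_three():
    rows = []
    for cond, nrq_val in [("treat", 8.0), ("ctrl", 1.0)]:
        for i in range(3):
            rows.append(
                {"assay": "T1", "unit": f"{cond}{i}", "sample": f"{cond}{i}",
                 "condition": cond, "nrq": nrq_val}
            )
    calls, heat = q.condition_ratios(q.NRQMatrix(pd.DataFrame(rows)), [("treat", "ctrl")])
    assert calls[0].log2_ratio == pytest.approx(3.0)
    assert heat.loc["T1", "treat_vs_ctrl"] == pytest.approx(3.0)


def test_absent_control_condition_errors():
    df = pd.DataFrame(
        [{"assay": "a", "unit": "u", "sample": "s", "condition": "treat", "nrq": 1.0}]
    )
    with pytest.raises(ValueError, match="ctrl"):
        q.condition_ratios(q.NRQMatrix(df), [("treat", "ctrl")])


def test_all_nd_assay_reported_not_testable_and_off_heatmap():
    cq_df, dil_df, _ = _dataset(fold=2.0, noise_sd=0.0, seed=0)
    cq_df.loc[
        (cq_df["assay"] == "T1") & (cq_df["condition"] == "treat"), "cq"
    ] = np.nan  # undetected in one condition
    nrq = _normalize(cq_df, q.estimate_efficiency(dil_df))
    calls, heat = q.condition_ratios(nrq, [("treat", "ctrl")])
    t1 = [c for c in calls if c.assay == "T1"][0]
    assert not t1.testable and not t1.significant
    assert "T1" not in heat.index


def test_null_fold_rarely_called_significant():
    """Type-I behaviour: planted fold 1 at noise_sd 0.15 stays quiet."""
    n_sig = 0
    for seed in range(100):
        cq_df, dil_df, _ = _dataset(fold=1.0, noise_sd=0.15, seed=seed)
        nrq = _normalize(cq_df, q.estimate_efficiency(dil_df))
        calls, _ = q.condition_ratios(nrq, [("treat", "ctrl")], alpha=0.01)
        (c,) = [c for c in calls if c.assay == "T1"]
        assert abs(c.log2_ratio) < 0.5
        n_sig += c.significant
    assert n_sig <= 5  # >=95% of seeds give no call
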