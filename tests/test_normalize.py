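import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exodecomp import normalize as norm
from exodecomp.normalize import NormalizationError
from exodecomp.types import ExpressionMatrix


# ---------------------------------------------------------------- size factors


def test_size_factors_hand_example():
    k = pd.DataFrame([[100, 200], [50, 100], [10, 20]], columns=["a", "b"])
    f = norm.spikein_size_factors(k)
    assert f["a"] == pytest.approx(1 / np.sqrt(2), abs=1e-4)
    assert f["b"] == pytest.approx(np.sqrt(2), abs=1e-4)


def test_size_factors_identical_columns_are_one():
    k = pd.DataFrame({"a": [5, 9, 100], "b": [5, 9, 100], "c": [5, 9, 100]})
    assert np.allclose(norm.spikein_size_factors(k), 1.0)


def test_size_factors_scale_equivariance():
    rng = np.random.default_rng(0)
    k = pd.DataFrame(rng.poisson(200, (30, 4)).astype(float),
                     columns=list("abcd"))
    f0 = norm.spikein_size_factors(k)
    k2 = k.copy()
    k2["b"] *= 3.0
    f1 = norm.spikein_size_factors(k2)
    # geometric means change too; the RATIO of sample b's factor to the others
    # must scale by exactly 3
    assert np.allclose((f1["b"] / f1["a"]) / (f0["b"] / f0["a"]), 3.0)


def test_size_factors_zero_handling():
    k = pd.DataFrame({"a": [0, 10, 20], "b": [5, 10, 20]})
    f = norm.spikein_size_factors(k)  # first spike excluded, still works
    assert (f > 0).all()
    with pytest.raises(NormalizationError):
        norm.spikein_size_factors(pd.DataFrame({"a": [0, 0], "b": [1, 2]}))


# ---------------------------------------------------------------- apply factors


def test_apply_size_factors_divides_and_drops_spikes():
    counts = pd.DataFrame({"s1": [100, 10], "s2": [100, 10]},
                          index=["G1", "SPIKE_001"])
    f = pd.Series({"s1": 2.0, "s2": 1.0})
    em = norm.apply_size_factors(counts, f, spike_ids=["SPIKE_001"])
    assert em.stage == "size_normalized"
    assert list(em.values.index) == ["G1"]
    assert em.values.loc["G1", "s1"] == 50
    assert em.values.loc["G1", "s2"] == 100
    with pytest.raises(NormalizationError):
        norm.apply_size_factors(counts, pd.Series({"s1": 2.0}))


def test_exact_factors_undo_depth(toy_design):
    rng = np.random.default_rng(1)
    base = rng.poisson(100, (50, 12)).astype(float)
    depths = rng.uniform(0.5, 2.0, 12)
    counts = pd.DataFrame(base * depths, columns=toy_design["sample_id"])
    em = norm.apply_size_factors(counts, pd.Series(depths, index=counts.columns))
    assert np.allclose(em.values.to_numpy(), base)


# ------------------------------------------------------------------------- TPM


def test_cage_tpm_bounds_and_conservation():
    counts = pd.DataFrame({"s1": [10, 0], "s2": [3, 1]}, index=["c1", "c2"])
    em = norm.cage_tpm(counts)
    assert em.values["s1"]["c1"] == pytest.approx(1e6)
    assert np.allclose(em.values.sum(axis=0), 1e6)
    # doubling all counts of a sample leaves its TPM unchanged
    doubled = counts.copy()
    doubled["s2"] *= 2
    assert np.allclose(norm.cage_tpm(doubled).values["s2"], em.values["s2"])
    with pytest.raises(NormalizationError):
        norm.cage_tpm(pd.DataFrame({"s1": [0, 0]}))


# ------------------------------------------------------------ expressed filter


def test_expressed_filter_rules(toy_design):
    cols = list(toy_design["sample_id"])
    values = pd.DataFrame(0.0, index=["dead", "ctrl_only", "patchy"], columns=cols)
    # expressed in all three ESC control replicates only
    for c in cols:
        if "ESC_control" in c:
            values.loc["ctrl_only", c] = 5.0
    # nonzero in one replicate of every condition
    for cell in ("ESC_control", "ESC_RRP40_KD", "EBd3_control", "EBd3_RRP40_KD"):
        values.loc["patchy", f"RNAseq_{cell}_r1"] = 5.0
    kept = norm.expressed_filter(values, toy_design)
    assert list(kept) == ["ctrl_only"]


# -------------------------------------------------------- quantile normalization


def test_quantile_normalization_hand_example():
    m = pd.DataFrame({"a": [1.0, 3.0, 5.0], "b": [2.0, 4.0, 100.0]})
    out = norm.quantile_normalize_to_reference(m, ["a", "b"])
    expected = np.array([1.5, 3.5, 52.5])
    assert np.allclose(out.values["a"], expected)
    assert np.allclose(out.values["b"], expected)


def test_quantile_normalization_fixed_point_and_idempotent():
    rng = np.random.default_rng(2)
    ref = np.sort(rng.lognormal(3, 1, 200))
    m = pd.DataFrame({c: rng.permutation(ref) for c in "abcd"})
    out = norm.quantile_normalize_to_reference(m, ["a"])
    # every column already a permutation of the single reference: unchanged
    pd.testing.assert_frame_equal(out.values, m)
    # idempotency on noisy data (no ties)
    noisy = pd.DataFrame(rng.lognormal(3, 1, (300, 4)), columns=list("abcd"))
    once = norm.quantile_normalize_to_reference(noisy, ["a", "b"]).values
    twice = norm.quantile_normalize_to_reference(once, ["a", "b"]).values
    pd.testing.assert_frame_equal(once, twice)
    # identical sorted values in every column
    sorted_cols = np.sort(once.to_numpy(), axis=0)
    assert np.allclose(sorted_cols, sorted_cols[:, [0]])


def test_quantile_normalization_tie_handling():
    m = pd.DataFrame({"ref": [1.0, 2.0, 9.0], "x": [5.0, 5.0, 7.0]})
    out = norm.quantile_normalize_to_reference(m, ["ref"])
    # the two tied values span reference ranks 1-2 -> mean(1, 2) = 1.5
    assert np.allclose(sorted(out.values["x"]), [1.5, 1.5, 9.0])


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_quantile_normalization_permutation_equivariant(seed):
    rng = np.random.default_rng(seed)
    m = pd.DataFrame(rng.lognormal(2, 1, (40, 3)), columns=list("abc"),
                     index=[f"f{i}" for i in range(40)])
    perm = rng.permutation(40)
    out1 = norm.quantile_normalize_to_reference(m, ["a"]).values.iloc[perm]
    out2 = norm.quantile_normalize_to_reference(m.iloc[perm], ["a"]).values
    pd.testing.assert_frame_equal(out1, out2)


# -------------------------------------------------------------- batch adjust


def _batch_design(batches):
    rows = []
    for state in ("ESC", "EBd3"):
        for condition in ("control", "RRP40_KD"):
            for rep, batch in enumerate(batches, start=1):
                rows.append(
                    {
                        "sample_id": f"P_{state}_{condition}_r{rep}",
                        "assay": "PROseq", "state": state, "condition": condition,
                        "replicate": rep, "batch": batch, "library_factor": 1.0,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def test_batch_adjust_single_batch_identity():
    design = _batch_design(["b1", "b1"])
    values = pd.DataFrame(
        np.random.default_rng(3).poisson(100, (20, len(design))).astype(float),
        columns=design["sample_id"],
    )
    out = norm.batch_adjust(values, design)
    pd.testing.assert_frame_equal(out.values, values)
    assert out.stage == "batch_adjusted"


def test_batch_adjust_removes_planted_batch_effect():
    design = _batch_design(["early", "late"])
    rng = np.random.default_rng(4)
    base = rng.lognormal(5, 1, 200)
    cols = {}
    for sid, row in design.iterrows():
        factor = 2.0 if row["batch"] == "late" else 1.0
        cols[sid] = rng.poisson(base * factor)
    values = pd.DataFrame(cols, columns=design["sample_id"]).astype(float)
    out = norm.batch_adjust(values, design).values
    log = np.log2(out + 1)
    early = log[[s for s, r in design.iterrows() if r["batch"] == "early"]].mean(axis=1)
    late = log[[s for s, r in design.iterrows() if r["batch"] == "late"]].mean(axis=1)
    # residual per-feature batch difference below 5% of the planted 1 log2 unit
    assert (late - early).abs().median() < 0.05
    # grand mean preserved per feature on the log scale
    before = np.log2(values + 1).mean(axis=1)
    assert np.allclose(log.mean(axis=1), before, atol=1e-9)


def test_batch_adjust_label_swap_invariance():
    design = _batch_design(["x", "y"])
    values = pd.DataFrame(
        np.random.default_rng(5).poisson(50, (30, len(design))).astype(float),
        columns=design["sample_id"],
    )
    out1 = norm.batch_adjust(values, design).values
    swapped = design.copy()
    swapped["batch"] = swapped["batch"].map({"x": "y", "y": "x"})
    out2 = norm.batch_adjust(values, swapped).values
    pd.testing.assert_frame_equal(out1, out2)


def test_batch_adjust_confounded_cell_errors():
    design = _batch_design(["b1", "b1"])
    # make one cell's samples an entire batch of their own
    design.loc[design["sample_id"].str.contains("ESC_control"), "batch"] = "solo"
    values = pd.DataFrame(
        np.ones((5, len(design))), columns=design["sample_id"]
    )
    with pytest.raises(NormalizationError, match="confounded"):
        norm.batch_adjust(values, design)


# ------------------------------------------------------- percentile exclusion


def test_exclude_lowest_percentile_counting():
    rng = np.random.default_rng(6)
    values = pd.DataFrame({"s1": np.arange(100.0), "s2": np.arange(100.0)})
    kept = norm.exclude_lowest_percentile(values, 1.0)
    assert len(kept) == 99 and 0 not in kept
    assert len(norm.exclude_lowest_percentile(values, 0.0)) == 100
    with pytest.raises(NormalizationError):
        norm.exclude_lowest_percentile(values, 100.0)


def test_exclude_lowest_percentile_matches_sort_oracle():
    rng = np.random.default_rng(7)
    values = pd.DataFrame(rng.lognormal(2, 1, (173, 4)))
    pct = 5.0
    kept = set(norm.exclude_lowest_percentile(values, pct))
    means = values.mean(axis=1)
    cut = np.percentile(means, pct)
    oracle = set(means.index[means >= cut])
    assert kept == oracle


def test_filters_do_not_alter_surviving_values(small_dataset):
    ds = small_dataset
    raw = ExpressionMatrix(ds.counts["RNAseq"].astype(float), "raw", "RNAseq")
    kept = norm.expressed_filter(raw, ds.design)
    sub = raw.subset(kept)
    pd.testing.assert_frame_equal(sub.values, raw.values.loc[kept])
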