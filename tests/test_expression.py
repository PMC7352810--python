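import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xenomir.expression import (
    CountMatrix,
    ExpressionMatrix,
    SampleMeta,
    accumulation_test,
    average_replicates,
    columns_for,
    cpm_normalize,
    growth_trend_filter,
    remove_excluded_mirnas,
)


def _cm(values: dict, meta=None, category="human_specific"):
    df = pd.DataFrame(values)
    return CountMatrix(category=category, values=df, meta=meta or {})


def test_mir451_rows_removed_case_insensitively():
    m = _cm({"s1": {"mmu-miR-451a": 5, "hsa-miR-451b": 3, "hsa-let-7a": 2}})
    out = remove_excluded_mirnas(m)
    assert list(out.values.index) == ["hsa-let-7a"]
    assert out.exclusions_applied
    # empty pattern list is the identity (but still marks the gate)
    out2 = remove_excluded_mirnas(m, patterns=())
    assert list(out2.values.index) == list(m.values.index)


def test_cpm_requires_exclusion_first():
    m = _cm({"s1": {"hsa-miR-21-5p": 3}})
    with pytest.raises(ValueError, match="remove_excluded_mirnas first"):
        cpm_normalize(m)


def test_cpm_arithmetic_and_column_conservation():
    m = remove_excluded_mirnas(_cm({"s1": {"a": 3, "b": 1}, "s2": {"a": 7, "b": 0}}))
    e = cpm_normalize(m)
    assert e.values.loc["a", "s1"] == pytest.approx(750_000)
    assert e.values.loc["b", "s1"] == pytest.approx(250_000)
    assert e.values.loc["a", "s2"] == pytest.approx(1_000_000)
    rng = np.random.default_rng(3)
    big = remove_excluded_mirnas(
        _cm(pd.DataFrame(rng.integers(1, 100, size=(50, 4)),
                         index=[f"m{i}" for i in range(50)],
                         columns=list("abcd")).to_dict())
    )
    sums = cpm_normalize(big).values.sum(axis=0)
    assert np.allclose(sums, 1e6, rtol=1e-6)


def test_zero_library_column_becomes_zero_with_warning(caplog):
    m = remove_excluded_mirnas(_cm({"s1": {"a": 0, "b": 0}}))
    e = cpm_normalize(m)
    assert (e.values["s1"] == 0).all()


def test_exclusion_changes_cpm_of_remaining_mirnas():
    # removal-first semantics: miR-451 reads must not inflate library size
    counts = {"s1": {"hsa-miR-451a": 90, "hsa-let-7a": 10}}
    first = cpm_normalize(remove_excluded_mirnas(_cm(counts)))
    assert first.values.loc["hsa-let-7a", "s1"] == pytest.approx(1_000_000)


def _meta4():
    return {
        "c1": SampleMeta("c1", "total_plasma", "control", 1),
        "c2": SampleMeta("c2", "total_plasma", "control", 2),
        "d1": SampleMeta("d1", "total_plasma", "day23", 1),
        "d2": SampleMeta("d2", "total_plasma", "day23", 2),
    }


def test_average_replicates_means_cpm_per_condition():
    e = ExpressionMatrix(
        "human_specific",
        pd.DataFrame({"c1": {"a": 100.0}, "c2": {"a": 300.0},
                      "d1": {"a": 50.0}, "d2": {"a": 50.0}}),
        meta=_meta4(),
    )
    out = average_replicates(e)
    assert out.values.loc["a", "total_plasma_control"] == pytest.approx(200.0)
    assert out.values.loc["a", "total_plasma_day23"] == pytest.approx(50.0)


def test_accumulation_test_identical_groups_is_half():
    e = ExpressionMatrix(
        "human_specific",
        pd.DataFrame({"c1": {"a": 1.0}, "c2": {"a": 1.0},
                      "d1": {"a": 1.0}, "d2": {"a": 1.0}}),
        meta=_meta4(),
    )
    p = accumulation_test(e, ["d1", "d2"], ["c1", "c2"], statistic="total")
    assert p == pytest.approx(0.5)


def test_accumulation_test_matches_textbook_t_formula():
    # control totals (1, 2), day-23 totals (5, 6); independent closed form
    e = ExpressionMatrix(
        "human_specific",
        pd.DataFrame({"c1": {"a": 1.0}, "c2": {"a": 2.0},
                      "d1": {"a": 5.0}, "d2": {"a": 6.0}}),
        meta=_meta4(),
    )
    p = accumulation_test(e, ["d1", "d2"], ["c1", "c2"], statistic="total")
    # pooled-variance t by hand: means 5.5 vs 1.5, s_p^2 = 0.5, se = sqrt(0.5)
    t = (5.5 - 1.5) / math.sqrt(0.5 * (1 / 2 + 1 / 2))
    expected = float(stats.t.sf(t, df=2))
    assert p == pytest.approx(expected, rel=1e-12)


def test_accumulation_test_detects_large_effect_in_simulation():
    rng = np.random.default_rng(42)
    meta = _meta4()
    rejections = 0
    n_sim = 300
    for _ in range(n_sim):
        ctrl = rng.normal(10, 2, size=2)
        day = rng.normal(25, 2, size=2)  # large effect
        e = ExpressionMatrix(
            "human_specific",
            pd.DataFrame(
                {"c1": {"a": ctrl[0]}, "c2": {"a": ctrl[1]},
                 "d1": {"a": day[0]}, "d2": {"a": day[1]}}
            ),
            meta=meta,
        )
        if accumulation_test(e, ["d1", "d2"], ["c1", "c2"], statistic="total") < 0.05:
            rejections += 1
    assert rejections / n_sim > 0.9


def test_n_detected_statistic_counts_nonzero_mirnas():
    meta = _meta4()
    vals = pd.DataFrame(
        {"c1": {"a": 0.0, "b": 0.0, "c": 1.0}, "c2": {"a": 0.0, "b": 1.0, "c": 0.0},
         "d1": {"a": 5.0, "b": 5.0, "c": 5.0}, "d2": {"a": 5.0, "b": 5.0, "c": 0.0}}
    )
    e = ExpressionMatrix("human_specific", vals, meta=meta)
    # detected counts: day (3, 2) vs control (1, 1) -> one-sided p < 0.5
    p = accumulation_test(e, ["d1", "d2"], ["c1", "c2"], statistic="n_detected")
    assert 0 < p < 0.5


def test_growth_trend_strict_inequality_and_monotonicity():
    meta = _meta4()
    vals = pd.DataFrame(
        {"c1": {"up": 100.0, "flat": 100.0}, "c2": {"up": 100.0, "flat": 100.0},
         "d1": {"up": 150.0, "flat": 100.0}, "d2": {"up": 150.0, "flat": 100.0}}
    )
    e = ExpressionMatrix("conserved", vals, meta=meta)
    kept = growth_trend_filter(e, ["c1", "c2"], ["d1", "d2"])
    assert kept == {"up"}
    # raising any day-23 value never removes a kept miRNA
    vals2 = vals.copy()
    vals2.loc["up", "d1"] = 500.0
    e2 = ExpressionMatrix("conserved", vals2, meta=meta)
    assert "up" in growth_trend_filter(e2, ["c1", "c2"], ["d1", "d2"])


def test_columns_for_selects_by_condition():
    e = ExpressionMatrix("x", pd.DataFrame({k: {"a": 1.0} for k in _meta4()}), _meta4())
    assert columns_for(e, "total_plasma", "control") == ["c1", "c2"]
    assert columns_for(e, "sev", "day23") == []


def test_sample_meta_validates_vocabulary():
    with pytest.raises(ValueError):
        SampleMeta("s", "total_plasma", "day99", 1)
    with pytest.raises(ValueError):
        SampleMeta("s", "serum", "day7", 1)
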