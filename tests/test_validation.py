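import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from xenomir.simulate import simulate_external_profiles
from xenomir.validation import (
    ExternalProfileSet,
    ValidationConfig,
    canonical_name,
    differential_expression,
    expressed_filter,
    load_profiles,
    overlap_validation,
    progression_trend,
)


def reference_bh(pvals):
    """Independent Benjamini-Hochberg step-up (textbook definition)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        k = m - rank_from_top  # 1-based rank of this p-value
        running_min = min(running_min, p[idx] * m / k)
        adj[idx] = running_min
    return adj


def _profiles(rows: dict, groups: dict) -> ExternalProfileSet:
    return ExternalProfileSet(intensities=pd.DataFrame(rows).T, groups=groups)


def test_load_profiles_aligns_matrix_and_groups(tmp_path):
    mat = tmp_path / "matrix.tsv"
    mat.write_text("mirna\ts1\ts2\ts3\ts4\nmiR-a\t6\t6\t4\t4\nmiR-b\t1\t2\t3\t4\n")
    grp = tmp_path / "groups.tsv"
    grp.write_text("sample_id\tgroup\ns1\thealthy\ns2\thealthy\ns3\tmetastatic\ns4\tmetastatic\n")
    p = load_profiles(mat, grp)
    assert p.intensities.shape == (2, 4)
    assert p.samples_in("metastatic") == ["s3", "s4"]
    # a sample missing from the labels is a hard error
    grp2 = tmp_path / "bad.tsv"
    grp2.write_text("sample_id\tgroup\ns1\thealthy\ns2\thealthy\ns3\tmetastatic\n")
    with pytest.raises(ValueError, match="without group labels"):
        load_profiles(mat, grp2)


@pytest.mark.parametrize(
    "values,expected",
    [
        ([6, 6, 4, 4], True),   # 2 of 4 above -> expressed at fraction 0.5
        ([4, 4, 4, 6], False),  # 1 of 4 below the ceil(0.5*4)=2 requirement
        ([5, 5, 5, 5], False),  # strictly greater than the cutoff required
    ],
)
def test_expressed_filter_boundaries(values, expected):
    groups = {f"s{i}": "metastatic" for i in range(4)}
    p = _profiles({"miR-x": dict(zip(groups, values))}, groups)
    got = "miR-x" in expressed_filter(p, "metastatic")
    assert got is expected


def test_expressed_filter_monotone_in_cutoff_and_fraction():
    rng = np.random.default_rng(9)
    groups = {f"s{i}": "metastatic" for i in range(8)}
    rows = {
        f"miR-{j}": dict(zip(groups, rng.normal(6, 2, 8))) for j in range(50)
    }
    p = _profiles(rows, groups)
    prev = None
    for cutoff in (3, 5, 7, 9):
        s = expressed_filter(p, "metastatic", ValidationConfig(intensity_cutoff=cutoff))
        if prev is not None:
            assert s <= prev
        prev = s
    prev = None
    for frac in (0.25, 0.5, 0.75, 1.0):
        s = expressed_filter(p, "metastatic", ValidationConfig(sample_fraction=frac))
        if prev is not None:
            assert s <= prev
        prev = s


def test_overlap_canonicalizes_species_prefix():
    count, fraction, table = overlap_validation(
        ["hsa-miR-21-5p", "hsa-miR-224-5p", "hsa-miR-999-3p", "hsa-miR-1246"],
        {"miR-21-5p", "MIR-224-5P", "miR-1246"},
    )
    assert count == 3
    assert fraction == pytest.approx(0.75)
    assert not table.set_index("query").loc["hsa-miR-999-3p", "expressed"]
    assert overlap_validation([], set())[0] == 0
    assert overlap_validation(["hsa-miR-1"], set())[0] == 0


def test_canonical_name_rules():
    assert canonical_name("hsa-miR-21-5p") == canonical_name("miR-21-5p")
    assert canonical_name("miR-21-5p") != canonical_name("miR-21-3p")  # arm kept


def test_de_identical_groups_all_p_one():
    groups = {"a1": "metastatic", "a2": "metastatic", "b1": "primary", "b2": "primary"}
    p = _profiles({"miR-x": {"a1": 5.0, "a2": 5.0, "b1": 5.0, "b2": 5.0}}, groups)
    out = differential_expression(p, "metastatic", "primary")
    assert (out.p == 1).all() and (out.p_adj == 1).all()


def test_bh_step_up_arithmetic_example():
    # raw (0.01, 0.02, 0.03), m = 3 -> all adjusted to 0.03
    adj = reference_bh([0.01, 0.02, 0.03])
    assert np.allclose(adj, [0.03, 0.03, 0.03])
    _, sm_adj, _, _ = multipletests([0.01, 0.02, 0.03], method="fdr_bh")
    assert np.allclose(sm_adj, adj)


def test_bh_matches_reference_on_many_random_vectors():
    rng = np.random.default_rng(77)
    for _ in range(1000):
        m = rng.integers(1, 60)
        p = rng.random(m)
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(adj, reference_bh(p), atol=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
def test_bh_properties(pvals):
    adj = reference_bh(pvals)
    p = np.asarray(pvals)
    assert (adj >= p - 1e-12).all()
    assert (adj <= 1 + 1e-12).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(adj[order]) >= -1e-12).all()  # monotone in the raw-p order


def test_null_simulation_uniform_p_and_no_rejections():
    rng = np.random.default_rng(5)
    n_mirna, n = 1000, 8
    groups = {f"a{i}": "metastatic" for i in range(n)}
    groups.update({f"b{i}": "primary" for i in range(n)})
    mat = pd.DataFrame(
        rng.normal(7, 1, size=(n_mirna, 2 * n)),
        index=[f"miR-{i}" for i in range(n_mirna)],
        columns=list(groups),
    )
    p = ExternalProfileSet(intensities=mat, groups=groups)
    out = differential_expression(p, "metastatic", "primary")
    assert (out.p_adj < 0.05).mean() < 0.01
    # raw p approximately uniform: compare deciles to 0.1
    hist, _ = np.histogram(out.p, bins=10, range=(0, 1))
    assert np.abs(hist / n_mirna - 0.1).max() < 0.05


def test_progression_trend_strict_median_increase():
    groups = {
        "h1": "healthy", "h2": "healthy",
        "p1": "primary", "p2": "primary",
        "m1": "metastatic", "m2": "metastatic",
    }
    rows = {
        "miR-up": {"h1": 1, "h2": 1, "p1": 2, "p2": 2, "m1": 3, "m2": 3},
        "miR-flat": {"h1": 2, "h2": 2, "p1": 2, "p2": 2, "m1": 3, "m2": 3},
        "miR-down": {"h1": 3, "h2": 3, "p1": 2, "p2": 2, "m1": 1, "m2": 1},
    }
    p = _profiles(rows, groups)
    assert progression_trend(p) == {"miR-up"}


def test_planted_trend_recovery_with_large_shift():
    profiles, truth = simulate_external_profiles(
        n_mirna=103, trend_mirnas=None, shift=3.0, seed=123
    )
    recovered = progression_trend(profiles)
    planted = set(truth["trend_mirnas"])
    assert planted <= recovered
    # a purely ordinal screen lets a null miRNA through with prob ~1/6
    # (three near-independent group medians landing in increasing order),
    # so chance hits among the 100 nulls are expected but bounded
    assert len(recovered - planted) < 30


def test_zero_shift_recovers_only_chance_level():
    profiles, truth = simulate_external_profiles(n_mirna=100, shift=0.0, seed=9)
    recovered = progression_trend(profiles)
    # each null miRNA is strictly increasing with prob ~1/4; allow slack
    assert len(recovered) < 50
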