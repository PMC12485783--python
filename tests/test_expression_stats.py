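import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allergome.expression_stats import (bh_adjust, call_degs, de_test,
                                        filter_low_counts, log2_tpm_plus1,
                                        size_factors_median_of_ratios, tmm_factors,
                                        tmm_log2_cpm, tpm)


def _matrix(rows, samples=("s1", "s2", "s3", "s4")):
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                        columns=samples[:len(rows[0])])


# ---------------------------------------------------------------------------
# low-count filter
# ---------------------------------------------------------------------------

def test_filter_low_counts_threshold():
    m = _matrix([[3, 3, 3], [4, 3, 3]], samples=("a", "b", "c"))
    out = filter_low_counts(m, min_row_sum=10)
    assert list(out.index) == ["g1"]  # row sum 9 removed, 10 kept


def test_filter_low_counts_zero_is_identity():
    m = _matrix([[0, 0], [1, 0]], samples=("a", "b"))
    pd.testing.assert_frame_equal(filter_low_counts(m, 0), m)


def test_filter_low_counts_matches_bruteforce(rng):
    m = pd.DataFrame(rng.integers(0, 8, size=(100, 4)),
                     index=[f"g{i}" for i in range(100)],
                     columns=list("abcd"))
    out = filter_low_counts(m, 10)
    expected = [g for g in m.index if sum(m.loc[g]) >= 10]
    assert list(out.index) == expected


def test_filter_low_counts_empty_errors():
    m = _matrix([[1, 1]], samples=("a", "b"))
    with pytest.raises(ValueError):
        filter_low_counts(m, 1000)


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def test_size_factors_doubled_column():
    m = _matrix([[10, 20], [4, 8], [100, 200]], samples=("a", "b"))
    sf = size_factors_median_of_ratios(m)
    assert sf["a"] == pytest.approx(1 / np.sqrt(2), abs=1e-12)
    assert sf["b"] == pytest.approx(np.sqrt(2), abs=1e-12)


def test_size_factors_identical_columns():
    m = _matrix([[10, 10, 10], [4, 4, 4]], samples=("a", "b", "c"))
    assert np.allclose(size_factors_median_of_ratios(m).values, 1.0)


def test_size_factors_match_bruteforce(rng):
    m = pd.DataFrame(rng.integers(1, 500, size=(100, 4)),
                     columns=list("abcd"))
    sf = size_factors_median_of_ratios(m)
    # brute force: per-gene geometric means, then medians of ratios
    expected = []
    for j in range(4):
        ratios = []
        for i in range(100):
            row = m.iloc[i].values.astype(float)
            gm = np.exp(np.mean(np.log(row)))
            ratios.append(m.iloc[i, j] / gm)
        expected.append(np.median(ratios))
    np.testing.assert_allclose(sf.values, expected, rtol=1e-12)


def test_size_factors_scaling_invariance(rng):
    # factors are defined up to overall scale: tripling one column triples
    # its factor relative to the others
    m = pd.DataFrame(rng.integers(1, 500, size=(50, 3)), columns=list("abc"))
    sf = size_factors_median_of_ratios(m)
    m2 = m.copy()
    m2["b"] = m2["b"] * 3
    sf2 = size_factors_median_of_ratios(m2)
    assert (sf2["b"] / sf2["a"]) == pytest.approx(3 * sf["b"] / sf["a"],
                                                  rel=1e-9)


def test_size_factors_degenerate_error():
    m = _matrix([[0, 5], [5, 0]], samples=("a", "b"))
    with pytest.raises(ValueError, match="no gene positive"):
        size_factors_median_of_ratios(m)


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def test_tpm_single_gene():
    m = _matrix([[7, 3]], samples=("a", "b"))
    lengths = pd.Series([1000.0], index=["g0"])
    out = tpm(m, lengths)
    assert np.allclose(out.values, 1e6)


def test_tpm_length_normalization():
    m = _matrix([[100, 100], [100, 100]], samples=("a", "b"))
    lengths = pd.Series([1000.0, 2000.0], index=["g0", "g1"])
    out = tpm(m, lengths)
    assert out.loc["g0", "a"] == pytest.approx(2e6 / 3)
    assert out.loc["g1", "a"] == pytest.approx(1e6 / 3)


def test_tpm_columns_sum_to_million(rng):
    m = pd.DataFrame(rng.integers(0, 300, size=(60, 3)), columns=list("abc"))
    m.iloc[0] += 1
    lengths = pd.Series(rng.integers(200, 3000, size=60).astype(float),
                        index=m.index)
    out = tpm(m, lengths)
    assert np.allclose(out.sum(axis=0).values, 1e6, rtol=1e-9)
    logged = log2_tpm_plus1(out)
    assert np.allclose(logged.values, np.log2(out.values + 1))


def test_tpm_column_invariance(rng):
    m = pd.DataFrame(rng.integers(1, 300, size=(30, 2)), columns=list("ab"))
    lengths = pd.Series(np.full(30, 1000.0), index=m.index)
    scaled = m.copy()
    scaled["a"] = scaled["a"] * 5
    pd.testing.assert_series_equal(tpm(m, lengths)["a"],
                                   tpm(scaled, lengths)["a"])


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def test_tmm_identical_columns():
    m = pd.DataFrame({"a": [10, 50, 200], "b": [10, 50, 200]})
    assert np.allclose(tmm_factors(m).values, 1.0)


def test_tmm_doubled_column_composition_unchanged():
    rng = np.random.default_rng(5)
    base = rng.integers(10, 1000, size=300)
    m = pd.DataFrame({"a": base, "b": base * 2})
    assert np.allclose(tmm_factors(m).values, 1.0, atol=1e-9)


def _tmm_oracle(m, trim_m=0.30, trim_a=0.05):
    """Step-by-step reimplementation with explicit loops."""
    counts = m.values.astype(float)
    lib = counts.sum(axis=0)
    uq = []
    for j in range(counts.shape[1]):
        col = counts[:, j]
        uq.append(np.quantile(col[col > 0] / lib[j], 0.75))
    ref = int(np.argmin([abs(x - np.mean(uq)) for x in uq]))
    factors = []
    for j in range(counts.shape[1]):
        if j == ref:
            factors.append(1.0)
            continue
        ms, as_, ws = [], [], []
        for i in range(counts.shape[0]):
            o, r = counts[i, j], counts[i, ref]
            if o <= 0 or r <= 0:
                continue
            po, pr = o / lib[j], r / lib[ref]
            ms.append(np.log2(po / pr))
            as_.append(0.5 * np.log2(po * pr))
            ws.append((lib[j] - o) / (lib[j] * o)
                      + (lib[ref] - r) / (lib[ref] * r))
        ms, as_, ws = map(np.asarray, (ms, as_, ws))
        n = len(ms)
        rm = stats.rankdata(ms)
        ra = stats.rankdata(as_)
        keep = ((rm >= np.floor(n * trim_m) + 1) & (rm <= n - np.floor(n * trim_m))
                & (ra >= np.floor(n * trim_a) + 1)
                & (ra <= n - np.floor(n * trim_a)))
        f = np.sum(ms[keep] / ws[keep]) / np.sum(1.0 / ws[keep])
        factors.append(2.0 ** f)
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def test_tmm_matches_independent_reimplementation(rng):
    m = pd.DataFrame(rng.integers(0, 2000, size=(400, 5)),
                     columns=list("abcde"))
    np.testing.assert_allclose(tmm_factors(m).values, _tmm_oracle(m),
                               rtol=1e-9)


def test_tmm_log2_cpm_shape_and_scale():
    rng = np.random.default_rng(8)
    m = pd.DataFrame(rng.integers(0, 1000, size=(200, 4)),
                     columns=list("abcd"))
    out = tmm_log2_cpm(m)
    assert out.shape == m.shape
    assert np.isfinite(out.values).all()


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def test_bh_worked_example():
    q = bh_adjust([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_single_p():
    assert bh_adjust([0.37])[0] == pytest.approx(0.37)


def test_bh_matches_bruteforce(rng):
    p = rng.uniform(size=57)
    q = bh_adjust(p)
    m = len(p)
    brute = np.empty(m)
    order = np.argsort(p)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [p[j] * m / (list(order).index(j) + 1)
                      for j in order[rank_pos - 1:]]
        brute[idx] = min(1.0, min(candidates))
    np.testing.assert_allclose(q, brute, rtol=1e-12)
    # order preserving, >= p after rank adjustment
    assert np.all(q[np.argsort(p)] == np.sort(q))
    assert np.all(q >= p - 1e-15)


def test_bh_rejects_bad_p():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


def test_bh_permutation_equivariance(rng):
    p = rng.uniform(size=31)
    perm = rng.permutation(31)
    np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


# ---------------------------------------------------------------------------
# DE test
# ---------------------------------------------------------------------------

def _null_counts(rng, genes=800, mu=150.0, disp=0.1):
    r = 1 / disp
    base = rng.lognormal(np.log(mu), 1.0, genes)
    counts = rng.negative_binomial(r, r / (r + base[:, None]),
                                   size=(genes, 6))
    return pd.DataFrame(counts, index=[f"g{i}" for i in range(genes)],
                        columns=[f"HDM_{i}" for i in range(3)]
                        + [f"VEH_{i}" for i in range(3)])


GROUPS = ["HDM"] * 3 + ["VEH"] * 3


def test_de_identical_groups_zero_lfc(rng):
    m = _null_counts(rng, genes=50)
    m.iloc[:, 3:] = m.iloc[:, :3].values  # group B mirrors group A
    res = de_test(m, GROUPS, "HDM", "VEH")
    assert np.allclose(res["log2fc"].values, 0.0)


def test_de_label_swap_negates_lfc(rng):
    m = _null_counts(rng, genes=100)
    a = de_test(m, GROUPS, "HDM", "VEH")
    b = de_test(m, GROUPS, "VEH", "HDM")
    np.testing.assert_allclose(a["log2fc"].values, -b["log2fc"].values,
                               atol=1e-12)
    np.testing.assert_allclose(a["p_value"].values, b["p_value"].values,
                               atol=1e-12)


def test_de_lfc_estimation_accuracy(rng):
    # planted log2FC 2, dispersion 0.1: |estimate - 2| <= 0.5 for >= 80%
    genes, planted = 2000, 100
    r = 1 / 0.1
    base = np.full(genes, 500.0)
    mu_a = base.copy()
    mu_a[:planted] *= 4.0
    xa = rng.negative_binomial(r, r / (r + mu_a[:, None]), size=(genes, 3))
    xb = rng.negative_binomial(r, r / (r + base[:, None]), size=(genes, 3))
    m = pd.DataFrame(np.hstack([xa, xb]), columns=GROUPS)
    m.columns = [f"s{i}" for i in range(6)]
    res = de_test(m, GROUPS, "HDM", "VEH")
    est = res["log2fc"].values[:planted]
    assert np.mean(np.abs(est - 2.0) <= 0.5) >= 0.80


def test_de_requires_two_per_group(rng):
    m = _null_counts(rng, genes=20).iloc[:, [0, 3, 4]]
    with pytest.raises(ValueError):
        de_test(m, ["HDM", "VEH", "VEH"], "HDM", "VEH")


def test_call_degs_thresholds():
    rec = pd.DataFrame({
        "log2fc": [1.5, 0.9, -3.0],
        "q_value": [0.01, 0.001, 0.049],
        "p_value": [0.001, 0.0001, 0.01],
        "base_mean": [10, 10, 10],
    }, index=["a", "b", "c"])
    out = call_degs(rec)
    assert out.loc["a", "is_deg"] and out.loc["a", "direction"] == "up"
    assert not out.loc["b", "is_deg"]
    assert out.loc["c", "is_deg"] and out.loc["c", "direction"] == "down"
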