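"""Instrument selection, clumping, harmonization, and strength diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from mrscreen import (HarmonizationError, LDInfo, clump, confounder_filter,
                      drop_palindromic, f_statistic, harmonize,
                      read_confounder_table, read_ld_matrix, read_ld_pairs,
                      select_by_pvalue, simulate_confounder_table,
                      variance_explained, write_ld_matrix)

from conftest import make_hset, make_sumstats


# ---------------------------------------------------------------- selection
def test_select_strict_inequality_at_boundary():
    stats = make_sumstats([{"SNP": "a", "P": 1e-6}, {"SNP": "b", "P": 1e-5},
                           {"SNP": "c", "P": 1e-4}])
    kept = select_by_pvalue(stats, 1e-5)
    assert list(kept.snp_ids) == ["a"]


def test_select_threshold_one_keeps_all():
    stats = make_sumstats([{"P": 0.5}, {"P": 1.0}, {"P": 1e-9}])
    assert len(select_by_pvalue(stats, 1.0)) == 2  # p == 1.0 is not < 1.0
    assert len(select_by_pvalue(stats, 0.9999999)) == 2


def test_select_count_matches_binomial_oracle():
    # under the null, p-values are U(0,1); the kept count over many seeds
    # is Binomial(n_total, threshold)
    rng = np.random.default_rng(7)
    n, thr, seeds = 10_000, 1e-5, 200
    total = 0
    for _ in range(seeds):
        p = rng.uniform(size=n)
        df = pd.DataFrame({
            "SNP": [f"rs{i}" for i in range(n)], "CHR": "1",
            "POS": np.arange(1, n + 1), "EA": "A", "OA": "G", "EAF": 0.3,
            "BETA": 0.0, "SE": 1.0, "P": p, "N": 1000.0,
        })
        from mrscreen import SummaryStats
        total += len(select_by_pvalue(SummaryStats("null", df), thr))
    lo = sps.binom.ppf(0.0005, n * seeds, thr)
    hi = sps.binom.ppf(0.9995, n * seeds, thr)
    assert lo <= total <= hi


# ---------------------------------------------------------------- clumping
def _ld(ids, r2):
    return LDInfo(snp_ids=list(ids), r2=np.asarray(r2, float))


def test_clump_keeps_smaller_p_of_correlated_pair():
    stats = make_sumstats([
        {"SNP": "a", "CHR": "1", "POS": 100_000, "P": 1e-6},
        {"SNP": "b", "CHR": "1", "POS": 110_000, "P": 1e-8},
    ])
    ld = _ld(["a", "b"], [[1, 0.5], [0.5, 1]])
    kept = clump(stats, ld)
    assert list(kept.snp_ids) == ["b"]


def test_clump_window_semantics():
    # 600 kb apart: outside the 500 kb window, both kept despite r2 = 0.5
    stats = make_sumstats([
        {"SNP": "a", "CHR": "1", "POS": 100_000, "P": 1e-8},
        {"SNP": "b", "CHR": "1", "POS": 700_000, "P": 1e-6},
    ])
    ld = _ld(["a", "b"], [[1, 0.5], [0.5, 1]])
    assert len(clump(stats, ld)) == 2
    # exactly at the window edge the r2 check applies
    stats2 = make_sumstats([
        {"SNP": "a", "CHR": "1", "POS": 100_000, "P": 1e-8},
        {"SNP": "b", "CHR": "1", "POS": 600_000, "P": 1e-6},
    ])
    assert list(clump(stats2, ld).snp_ids) == ["a"]


def test_clump_different_chromosomes_independent():
    stats = make_sumstats([
        {"SNP": "a", "CHR": "1", "POS": 100, "P": 1e-8},
        {"SNP": "b", "CHR": "2", "POS": 100, "P": 1e-6},
    ])
    ld = _ld(["a", "b"], [[1, 0.99], [0.99, 1]])
    assert len(clump(stats, ld)) == 2


def test_clump_missing_from_ld_kept_unless_strict():
    stats = make_sumstats([
        {"SNP": "a", "CHR": "1", "POS": 100, "P": 1e-8},
        {"SNP": "zz", "CHR": "1", "POS": 200, "P": 1e-6},
    ])
    ld = _ld(["a"], [[1.0]])
    assert len(clump(stats, ld)) == 2
    assert list(clump(stats, ld, strict_missing=True).snp_ids) == ["a"]


def brute_force_check(kept, discarded, stats, ld, r2_max=0.1, window=500_000):
    """Exhaustive verification of the greedy clumping solution."""
    df = stats.data.set_index("SNP")
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            if df.loc[a, "CHR"] != df.loc[b, "CHR"]:
                continue
            if abs(int(df.loc[a, "POS"]) - int(df.loc[b, "POS"])) > window:
                continue
            r2 = ld.lookup(a, b)
            assert r2 is None or r2 < r2_max, (a, b, r2)
    for d in discarded:
        conflict = any(
            df.loc[d, "CHR"] == df.loc[kpt, "CHR"]
            and abs(int(df.loc[d, "POS"]) - int(df.loc[kpt, "POS"])) <= window
            and (ld.lookup(d, kpt) or 0) >= r2_max
            and df.loc[kpt, "P"] <= df.loc[d, "P"]
            for kpt in kept
        )
        assert conflict, f"{d} discarded without a retained conflicting SNP"


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_clump_ar1_block_matches_pairwise_oracle(seed):
    from mrscreen import SimScenario, simulate_pair

    sc = SimScenario(n_snps_total=50, n_instruments=10, ld_block_size=50,
                     ld_rho=0.8, seed=seed)
    exp, _, ld, _ = simulate_pair(sc)
    kept = clump(exp, ld)
    kept_ids = list(kept.snp_ids)
    discarded = [s for s in exp.snp_ids if s not in kept_ids]
    assert kept_ids  # never empty on nonempty input
    brute_force_check(kept_ids, discarded, exp, ld)


# ------------------------------------------------------------- palindromes
@pytest.mark.parametrize("ea,oa,dropped", [
    ("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
    ("A", "G", False), ("C", "T", False), ("A", "C", False),
])
def test_drop_palindromic_pairs(ea, oa, dropped):
    stats = make_sumstats([{"SNP": "x", "EA": ea, "OA": oa}])
    assert (len(drop_palindromic(stats)) == 0) is dropped


def test_drop_palindromic_identity_when_absent():
    stats = make_sumstats([{"EA": "A", "OA": "G"}, {"EA": "C", "OA": "T"}])
    assert drop_palindromic(stats).equals(stats)


# ------------------------------------------------------------ harmonization
def test_harmonize_allele_swap_negates_beta():
    exp = make_sumstats([{"SNP": "rs1", "EA": "A", "OA": "G", "BETA": 0.5,
                          "EAF": 0.3}])
    out = make_sumstats([{"SNP": "rs1", "EA": "G", "OA": "A", "BETA": 0.2,
                          "EAF": 0.7}])
    h = harmonize(exp, out)
    assert h.beta_out[0] == pytest.approx(-0.2)
    assert h.eaf_out[0] == pytest.approx(0.3)


def test_harmonize_strand_flip_keeps_sign():
    exp = make_sumstats([{"SNP": "rs1", "EA": "A", "OA": "G", "BETA": 0.5}])
    out = make_sumstats([{"SNP": "rs1", "EA": "T", "OA": "C", "BETA": 0.2}])
    h = harmonize(exp, out)
    assert h.beta_out[0] == pytest.approx(0.2)


def test_harmonize_flip_then_swap():
    exp = make_sumstats([{"SNP": "rs1", "EA": "A", "OA": "G", "BETA": 0.5,
                          "EAF": 0.3}])
    out = make_sumstats([{"SNP": "rs1", "EA": "C", "OA": "T", "BETA": 0.2,
                          "EAF": 0.6}])
    h = harmonize(exp, out)
    assert h.beta_out[0] == pytest.approx(-0.2)
    assert h.eaf_out[0] == pytest.approx(0.4)


def test_harmonize_ambiguous_dropped():
    exp = make_sumstats([{"SNP": "rs1", "EA": "A", "OA": "G"},
                         {"SNP": "rs2", "EA": "A", "OA": "G"}])
    out = make_sumstats([{"SNP": "rs1", "EA": "A", "OA": "C"},
                         {"SNP": "rs2", "EA": "A", "OA": "G"}])
    h = harmonize(exp, out)
    assert list(h.snp_ids) == ["rs2"]


def test_harmonize_duplicates_all_copies_dropped():
    exp = make_sumstats([{"SNP": "rs1"}, {"SNP": "rs1"}, {"SNP": "rs2"}])
    out = make_sumstats([{"SNP": "rs1"}, {"SNP": "rs2"}])
    h = harmonize(exp, out)
    assert list(h.snp_ids) == ["rs2"]


def test_harmonize_no_overlap_raises():
    exp = make_sumstats([{"SNP": "rs1"}])
    out = make_sumstats([{"SNP": "rs2"}])
    with pytest.raises(HarmonizationError):
        harmonize(exp, out)


def test_harmonize_self_is_identity(rng):
    rows = [{"SNP": f"rs{i}", "BETA": float(b), "EA": "A", "OA": "G"}
            for i, b in enumerate(rng.normal(size=8))]
    stats = make_sumstats(rows)
    h = harmonize(stats, stats)
    np.testing.assert_array_equal(h.beta_out, h.beta_exp)


# -------------------------------------------------------------- diagnostics
def test_variance_explained_closed_form():
    assert variance_explained(1.0, 0.5) == pytest.approx(0.5)
    assert variance_explained(0.0, 0.3) == 0.0
    assert variance_explained(0.1, 0.2) == pytest.approx(0.0032)


@given(st.floats(0.01, 0.49))
def test_variance_explained_maximized_at_half(f):
    beta = 0.7
    assert variance_explained(beta, f) < variance_explained(beta, 0.5)
    assert variance_explained(beta, f) == pytest.approx(
        variance_explained(beta, 1 - f))


def test_variance_explained_domain_error():
    with pytest.raises(ValueError):
        variance_explained(0.1, 0.0)
    with pytest.raises(ValueError):
        variance_explained(0.1, 1.0)


def test_f_statistic_closed_form():
    assert f_statistic(0.5, 103, 1) == pytest.approx(101.0)
    assert f_statistic(0.0, 100, 1) == 0.0


def test_f_statistic_monotonicity():
    base = f_statistic(0.02, 10_000, 5)
    assert f_statistic(0.03, 10_000, 5) > base
    assert f_statistic(0.02, 20_000, 5) > base


def test_f_statistic_domain_errors():
    with pytest.raises(ValueError):
        f_statistic(0.02, 6, 5)
    with pytest.raises(ValueError):
        f_statistic(1.0, 100, 5)


# ---------------------------------------------------------------- LD files
def test_ld_matrix_round_trip(tmp_path, rng):
    ids = [f"rs{i}" for i in range(5)]
    a = rng.uniform(0, 0.5, size=(5, 5))
    r2 = (a + a.T) / 2
    np.fill_diagonal(r2, 1.0)
    ld = LDInfo(ids, r2)
    path = tmp_path / "ld.tsv"
    write_ld_matrix(ld, path)
    back = read_ld_matrix(path)
    assert back.snp_ids == ids
    np.testing.assert_allclose(back.r2, r2)


def test_ld_pairs_reader(tmp_path):
    path = tmp_path / "pairs.tsv"
    path.write_text("snp_a\tsnp_b\tr2\nrs1\trs2\t0.4\nrs2\trs3\t0.2\n")
    ld = read_ld_pairs(path)
    assert ld.lookup("rs1", "rs2") == pytest.approx(0.4)
    assert ld.lookup("rs1", "rs3") == 0.0
    assert ld.lookup("rs1", "rs1") == 1.0


def test_ld_validation():
    with pytest.raises(ValueError):
        LDInfo(["a", "b"], np.array([[1.0, 0.5], [0.4, 1.0]]))  # asymmetric
    with pytest.raises(ValueError):
        LDInfo(["a", "b"], np.array([[1.0, 1.5], [1.5, 1.0]]))  # r2 > 1


# -------------------------------------------------------- confounder filter
def test_confounder_filter_removes_planted_set(tmp_path):
    h = make_hset(beta_exp=np.full(6, 0.1), beta_out=np.full(6, 0.02))
    planted = {"rs2", "rs5"}
    table = simulate_confounder_table(h.snp_ids, n_traits=7, planted=planted,
                                      seed=11)
    # round-trips through the on-disk reader
    path = tmp_path / "conf.tsv"
    table.to_csv(path, sep="\t")
    table2 = read_confounder_table(path)
    filtered = confounder_filter(h, table2)
    assert set(h.snp_ids) - set(filtered.snp_ids) == planted


def test_confounder_filter_identity_when_clean():
    h = make_hset(beta_exp=np.full(4, 0.1), beta_out=np.full(4, 0.02))
    table = simulate_confounder_table(h.snp_ids, n_traits=3, seed=1)
    filtered = confounder_filter(h, table)
    assert list(filtered.snp_ids) == list(h.snp_ids)


def test_confounder_filter_absent_snps_retained():
    h = make_hset(beta_exp=np.full(3, 0.1), beta_out=np.full(3, 0.02))
    table = pd.DataFrame({"trait_1": [0.001]}, index=pd.Index(["other"]))
    filtered = confounder_filter(h, table)
    assert filtered.k == 3
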