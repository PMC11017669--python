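"""Instrument selection: filters, clumping, strength metrics."""

import itertools

import numpy as np
import pytest

from mrscreen.instruments import (
    LDMatrix,
    apply_blacklist,
    f_statistic,
    filter_maf,
    filter_pvalue,
    greedy_clump,
    read_blacklist,
    read_ld_matrix,
    select_instruments,
    variance_explained,
    write_ld_matrix,
)

from conftest import make_record, make_table


class TestFilters:
    def test_pvalue_strict_threshold(self):
        t = make_table(
            [make_record("rs1", pval=1e-6), make_record("rs2", pval=1e-4),
             make_record("rs3", pval=1e-5)]
        )
        kept = filter_pvalue(t, 1e-5)
        assert kept.variant_ids == ["rs1"]  # boundary p == threshold excluded

    def test_pvalue_vacuous_threshold_keeps_all(self):
        t = make_table([make_record(f"rs{i}", pval=0.9) for i in range(3)])
        assert len(filter_pvalue(t, 1.0)) == 3

    @pytest.mark.parametrize(
        "eaf,kept",
        [(0.005, False), (0.995, False), (0.01, True), (0.5, True),
         (float("nan"), True)],
    )
    def test_maf_filter_boundaries(self, eaf, kept):
        t = make_table([make_record("rs1", eaf=eaf)])
        assert (len(filter_maf(t, 0.01)) == 1) is kept

    def test_blacklist_removal_and_identity(self):
        t = make_table([make_record(f"rs{i}") for i in range(20)])
        log = []
        assert len(apply_blacklist(t, {"rs1", "rs2"}, drop_log=log)) == 18
        assert sorted(v for v, _ in log) == ["rs1", "rs2"]
        assert len(apply_blacklist(t, set())) == 20
        assert len(apply_blacklist(t, {"rs999"})) == 20

    def test_filters_commute(self, rng):
        recs = [
            make_record(
                f"rs{i}",
                eaf=float(rng.uniform(0.001, 0.999)),
                pval=float(rng.uniform(1e-9, 1e-2)),
            )
            for i in range(40)
        ]
        t = make_table(recs)
        bl = {"rs3", "rs17", "rs25"}
        orders = [
            apply_blacklist(filter_maf(filter_pvalue(t, 1e-4), 0.01), bl),
            filter_maf(apply_blacklist(filter_pvalue(t, 1e-4), bl), 0.01),
            filter_pvalue(filter_maf(apply_blacklist(t, bl), 0.01), 1e-4),
        ]
        ids = {tuple(o.variant_ids) for o in orders}
        assert len(ids) == 1


def _ld(snp_ids, r, pos):
    return LDMatrix(snp_ids, r, pos)


class TestClump:
    def test_correlated_pair_keeps_more_significant(self):
        t = make_table(
            [make_record("rsA", pos=100_000, pval=1e-6),
             make_record("rsB", pos=110_000, pval=1e-8)]
        )
        ld = _ld(["rsA", "rsB"], np.array([[1, 0.8], [0.8, 1]]),
                 {"rsA": ("1", 100_000), "rsB": ("1", 110_000)})
        out = greedy_clump(t, ld, r2_max=0.1, window_kb=500)
        assert out.variant_ids == ["rsB"]

    def test_outside_window_both_kept(self):
        t = make_table(
            [make_record("rsA", pos=100_000, pval=1e-8),
             make_record("rsB", pos=700_000, pval=1e-6)]
        )
        ld = _ld(["rsA", "rsB"], np.array([[1, 0.8], [0.8, 1]]),
                 {"rsA": ("1", 100_000), "rsB": ("1", 700_000)})
        assert len(greedy_clump(t, ld, 0.1, 500)) == 2

    def test_cross_chromosome_never_clumps(self):
        t = make_table(
            [make_record("rsA", pos=100_000, pval=1e-8),
             make_record("rsB", pos=100_000, pval=1e-6)]
        )
        ld = _ld(["rsA", "rsB"], np.array([[1, 0.9], [0.9, 1]]),
                 {"rsA": ("1", 100_000), "rsB": ("2", 100_000)})
        assert len(greedy_clump(t, ld, 0.1, 500)) == 2

    def test_single_snp_identity(self):
        t = make_table([make_record("rsA", pos=5000)])
        ld = _ld(["rsA"], np.eye(1), {"rsA": ("1", 5000)})
        assert greedy_clump(t, ld, 0.1, 500).variant_ids == ["rsA"]

    def test_absent_from_panel_removed_and_logged(self):
        t = make_table([make_record("rsA", pos=5000), make_record("rsZ", pos=6000)])
        ld = _ld(["rsA"], np.eye(1), {"rsA": ("1", 5000)})
        log = []
        out = greedy_clump(t, ld, 0.1, 500, drop_log=log)
        assert out.variant_ids == ["rsA"]
        assert log == [("rsZ", "absent_from_ld_panel")]

    def test_survivors_pairwise_below_threshold(self, rng):
        for _ in range(20):
            t, ld = _random_instance(rng)
            out = greedy_clump(t, ld, 0.1, 500)
            for a, b in itertools.combinations(out.variant_ids, 2):
                ca, pa = ld.pos[a]
                cb, pb = ld.pos[b]
                if ca == cb and abs(pa - pb) <= 500_000:
                    assert ld.r2(a, b) < 0.1

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            t, ld = _random_instance(rng)
            got = greedy_clump(t, ld, 0.1, 500).variant_ids
            assert got == brute_force_clump(t, ld, 0.1, 500)


def _random_instance(rng, max_snps=15):
    """Random clumping instance: clustered positions, factor-model LD."""
    k = int(rng.integers(2, max_snps + 1))
    ids = [f"rs{i:02d}" for i in range(k)]
    chroms = rng.choice(["1", "2"], size=k)
    pos = rng.integers(1, 2_000_000, size=k)
    loadings = rng.uniform(-1, 1, size=(k, 2))
    cov = loadings @ loadings.T + np.diag(rng.uniform(0.1, 1.0, size=k))
    d = np.sqrt(np.diag(cov))
    r = cov / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    recs = [
        make_record(ids[i], chrom=str(chroms[i]), pos=int(pos[i]),
                    pval=float(rng.uniform(1e-9, 1e-3)))
        for i in range(k)
    ]
    ld = LDMatrix(ids, r, {ids[i]: (str(chroms[i]), int(pos[i])) for i in range(k)})
    return make_table(recs), ld


def brute_force_clump(table, ld, r2_max, window_kb):
    """Independent reference: exhaustive rule application on plain lists."""
    rows = [
        (row.variant_id, row.pval, *ld.pos[row.variant_id])
        for row in table.df.itertuples()
        if row.variant_id in ld
    ]
    selected = []
    while rows:
        best = sorted(rows, key=lambda r: (r[1], r[3], r[0]))[0]
        selected.append(best[0])
        survivors = []
        for r in rows:
            if r[0] == best[0]:
                continue
            same_chrom = r[2] == best[2]
            in_window = abs(r[3] - best[3]) <= window_kb * 1000
            high_ld = ld.r2(r[0], best[0]) >= r2_max
            if not (same_chrom and in_window and high_ld):
                survivors.append(r)
        rows = survivors
    return selected


class TestStrengthMetrics:
    @pytest.mark.parametrize(
        "beta,se,expected",
        [(0.1, 0.05, 4.0), (0.0, 0.3, 0.0), (0.0431, 0.0100, 18.5761)],
    )
    def test_f_statistic_values(self, beta, se, expected):
        assert f_statistic(beta, se) == pytest.approx(expected, abs=1e-12)

    def test_f_statistic_rejects_nonpositive_se(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)

    @pytest.mark.parametrize(
        "beta,se,n,expected",
        [
            (0.02, 0.02, 102, 1 / 101),  # t = 1
            (0.0, 0.01, 1000, 0.0),
            (10.0, 1.0, 102, 0.5),  # t^2 = n - 2
        ],
    )
    def test_variance_explained_values(self, beta, se, n, expected):
        assert variance_explained(beta, se, n) == pytest.approx(expected, rel=1e-12)

    def test_variance_explained_monotonic_in_t_and_n(self):
        base = variance_explained(0.1, 0.02, 1000)
        assert variance_explained(0.12, 0.02, 1000) > base
        assert variance_explained(0.1, 0.02, 2000) < base

    def test_variance_explained_requires_n_above_2(self):
        with pytest.raises(ValueError):
            variance_explained(0.1, 0.02, 2)


def test_ld_matrix_round_trip(tmp_path, rng):
    _, ld = _random_instance(rng)
    write_ld_matrix(ld, tmp_path / "ld.tsv", tmp_path / "pos.tsv")
    back = read_ld_matrix(tmp_path / "ld.tsv", tmp_path / "pos.tsv")
    assert back.snp_ids == ld.snp_ids
    np.testing.assert_allclose(back.r, ld.r)
    assert back.pos == ld.pos


def test_blacklist_file_parsing(tmp_path):
    (tmp_path / "bl.txt").write_text("# confounder-associated\nrs1\n\nrs2\n")
    assert read_blacklist(tmp_path / "bl.txt") == {"rs1", "rs2"}


def test_select_instruments_cascade(rng):
    t, ld = _random_instance(rng, max_snps=12)
    selected, inst = select_instruments(t, ld, blacklist={t.variant_ids[0]})
    assert t.variant_ids[0] not in selected.variant_ids
    assert len(inst.snp_ids) == len(selected)
    assert 0 <= inst.total_r2 < 1
    assert np.all(inst.f_stats >= 0)
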