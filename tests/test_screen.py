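"""Target-list handling and the relapse-vs-control down-regulation screen."""

import numpy as np
import pytest
from scipy import stats

from mirascore.screen import (
    CONTROL,
    RELAPSE,
    ExpressionMatrix,
    TargetListSet,
    de_screen,
    intersect_targets,
    read_target_list,
)
from mirascore.synth import ScreenSimConfig, generate_screen_matrix


class TestTargetLists:
    def test_dedup_and_case_fold(self, tmp_path):
        p = tmp_path / "db.txt"
        p.write_text("RASD1\nrasd1\nSEC23A\n")
        tl = read_target_list(p, "db")
        assert tl.genes == frozenset({"RASD1", "SEC23A"})

    def test_comments_and_blanks_ignored(self, tmp_path):
        p = tmp_path / "db.txt"
        p.write_text("# header\nRASD1  # validated\n\n\n")
        assert read_target_list(p, "db").genes == frozenset({"RASD1"})

    def test_comments_only_is_error(self, tmp_path):
        p = tmp_path / "db.txt"
        p.write_text("# nothing\n# here\n")
        with pytest.raises(ValueError):
            read_target_list(p, "db")

    @pytest.mark.parametrize(
        "min_db,expected",
        [(2, {"G2"}), (1, {"G1", "G2", "G3"})],
    )
    def test_intersection_and_union(self, min_db, expected):
        a = TargetListSet("A", frozenset({"G1", "G2"}))
        b = TargetListSet("B", frozenset({"G2", "G3"}))
        selected, counts = intersect_targets([a, b], min_db)
        assert selected == expected
        assert counts["G2"] == 2

    def test_single_list_identity(self):
        a = TargetListSet("A", frozenset({"G1", "G2"}))
        selected, _ = intersect_targets([a], 1)
        assert selected == set(a.genes)


def _matrix(values, n_rel, n_ctl, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(n_rel + n_ctl)]
    return ExpressionMatrix(genes, samples, values, [RELAPSE] * n_rel + [CONTROL] * n_ctl)


class TestDeScreen:
    def test_flat_gene_has_no_signal(self):
        em = _matrix(np.ones((1, 8)), 4, 4)
        row = de_screen(em, ["G0"]).iloc[0]
        assert row.log_fc == 0
        assert row.p_value == 1.0
        assert not row.down_in_relapse_pass

    def test_welch_matches_scipy(self, rng):
        vals = rng.normal(size=(50, 20))
        em = _matrix(vals, 10, 10)
        rows = de_screen(em, []).set_index("gene")
        ref = stats.ttest_ind(vals[:, :10], vals[:, 10:], axis=1, equal_var=False)
        for i in range(50):
            assert rows.loc[f"g{i}", "p_value"] == pytest.approx(ref.pvalue[i], rel=1e-9)
            assert rows.loc[f"g{i}", "t_stat"] == pytest.approx(ref.statistic[i], rel=1e-9)

    def test_group_swap_preserves_pvalues_and_negates_logfc(self, rng):
        vals = rng.normal(size=(30, 12))
        em = _matrix(vals, 6, 6)
        swapped = ExpressionMatrix(
            em.genes, em.samples, em.values,
            [CONTROL if g == RELAPSE else RELAPSE for g in em.group],
        )
        a = de_screen(em, []).set_index("gene")
        b = de_screen(swapped, []).set_index("gene")
        assert np.allclose(a.p_value, b.loc[a.index].p_value)
        assert np.allclose(a.log_fc, -b.loc[a.index].log_fc)

    def test_pass_flag_requires_target_direction_and_alpha(self, rng):
        vals = rng.normal(size=(3, 28))
        vals[0, :14] -= 5.0  # strongly down in relapse
        vals[1, :14] += 5.0  # strongly up in relapse
        em = _matrix(vals, 14, 14)
        rows = de_screen(em, ["G0", "G1"], alpha=0.2).set_index("gene")
        assert bool(rows.loc["g0", "down_in_relapse_pass"])
        assert not bool(rows.loc["g1", "down_in_relapse_pass"])  # wrong direction
        # g2 not a predicted target, can never pass
        assert not bool(rows.loc["g2", "down_in_relapse_pass"])

    def test_pass_count_monotone_in_alpha(self, rng):
        expr, targets, _ = generate_screen_matrix(ScreenSimConfig(n_genes=400, seed=4))
        counts = [
            de_screen(expr, targets.genes, alpha=a)["down_in_relapse_pass"].sum()
            for a in (0.01, 0.05, 0.2, 0.5, 0.9)
        ]
        assert counts == sorted(counts)

    def test_sorted_by_pvalue_with_gene_tiebreak(self, rng):
        vals = rng.normal(size=(40, 10))
        rows = de_screen(_matrix(vals, 5, 5), [])
        p = rows.p_value.to_numpy()
        assert np.all(np.diff(p) >= 0)

    def test_null_pvalues_uniform(self):
        # a calibrated test gives KS p-values spread over (0,1); a biased one
        # collapses them toward 0, so the median over seeds is the stable check
        ks = []
        for seed in range(10):
            expr, targets, _ = generate_screen_matrix(
                ScreenSimConfig(n_genes=1000, n_planted_down=0, seed=seed)
            )
            rows = de_screen(expr, targets.genes)
            ks.append(stats.kstest(rows.p_value, "uniform").pvalue)
        assert np.median(ks) > 0.1

    def test_bh_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        vals = rng.normal(size=(100, 12))
        rows = de_screen(_matrix(vals, 6, 6), [])
        ref = multipletests(rows.p_value, method="fdr_bh")[1]
        assert np.allclose(rows.p_bh, ref)

    def test_moderated_agrees_with_welch_at_large_n(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(500, 400))
        em = _matrix(vals, 200, 200)
        pw = de_screen(em, [], method="welch").set_index("gene").p_value
        pm = de_screen(em, [], method="moderated").set_index("gene").p_value
        rho = stats.spearmanr(pw, pm.loc[pw.index]).statistic
        assert rho > 0.99

    def test_moderated_shrinks_small_sample_outliers(self, rng):
        # a gene with accidentally tiny variance should not dominate under shrinkage
        vals = rng.normal(size=(200, 8))
        vals[0] = [0.0, 0.001, 0.0, 0.001, 0.01, 0.011, 0.01, 0.011]
        em = _matrix(vals, 4, 4)
        pw = de_screen(em, [], method="welch").set_index("gene").loc["g0", "p_value"]
        pm = de_screen(em, [], method="moderated").set_index("gene").loc["g0", "p_value"]
        assert pm > pw
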