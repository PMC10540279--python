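"""Feature tables: assembly, normalisation, ranking, PCA, Sammon mapping."""

import numpy as np
import pandas as pd
import pytest

from stereonn.features import (
    AssemblyError,
    FeatureTable,
    SammonState,
    _sammon_stress_grad,
    assemble,
    correlation_rank,
    minmax_apply,
    minmax_fit,
    pca_reduce,
    sammon_map,
    select_manual,
)
from stereonn.selectivity import SelectivityRecord

GEOM_CSV = (
    "ligand_id,descriptor,role,value,units\n"
    "L1,planarity,proR,0.1,A\nL1,planarity,proS,0.2,A\n"
    "L2,planarity,proR,0.3,A\nL2,planarity,proS,0.4,A\n"
    "L3,planarity,proR,0.5,A\nL3,planarity,proS,0.6,A\n"
)
AUX_CSV = (
    "#provenance: c2_pop=electronic,disp_e=dispersion\n"
    "ligand_id,c2_pop,disp_e\nL1,1.0,-2.0\nL2,1.5,-2.5\nL3,2.0,-3.0\n"
)
LABELS_CSV = "ligand_id,er\nL1,20:80\nL2,40:60\nL3,60:40\n"


def make_table(values, labels_s=None, names=None):
    values = np.asarray(values, dtype=float)
    ids = [f"L{i+1}" for i in range(len(values))]
    names = names or [f"f{j+1}" for j in range(values.shape[1])]
    labels = None
    if labels_s is not None:
        labels = {i: SelectivityRecord(float(s), float(100 - s))
                  for i, s in zip(ids, labels_s)}
    return FeatureTable(pd.DataFrame(values, index=ids, columns=names), {}, labels)


class TestAssemble:
    def test_join_shape_and_order(self):
        t = assemble(GEOM_CSV, AUX_CSV, LABELS_CSV)
        assert t.n_ligands == 3
        assert t.feature_names == ["planarity_proR", "planarity_proS",
                                   "c2_pop", "disp_e"]
        assert t.provenance["planarity_proR"] == "geometric"
        assert t.provenance["disp_e"] == "dispersion"
        assert t.labels["L1"].s_percent == pytest.approx(80)

    def test_missing_ligand_named(self):
        aux_missing = AUX_CSV.replace("L3,2.0,-3.0\n", "")
        with pytest.raises(AssemblyError, match="L3"):
            assemble(GEOM_CSV, aux_missing, LABELS_CSV)

    def test_duplicate_feature_rejected(self):
        dup = AUX_CSV.replace("c2_pop", "planarity_proR")
        with pytest.raises(AssemblyError, match="duplicate"):
            assemble(GEOM_CSV, dup, None)

    def test_row_order_independent(self):
        shuffled = (
            "ligand_id,descriptor,role,value,units\n"
            "L3,planarity,proS,0.6,A\nL1,planarity,proR,0.1,A\n"
            "L2,planarity,proR,0.3,A\nL3,planarity,proR,0.5,A\n"
            "L1,planarity,proS,0.2,A\nL2,planarity,proS,0.4,A\n"
        )
        a = assemble(GEOM_CSV, AUX_CSV, LABELS_CSV)
        b = assemble(shuffled, AUX_CSV, LABELS_CSV)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_csv_roundtrip(self):
        t = assemble(GEOM_CSV, AUX_CSV, LABELS_CSV)
        back = FeatureTable.from_csv(t.to_csv())
        pd.testing.assert_frame_equal(back.df, t.df)
        assert back.provenance == {k: t.provenance[k] for k in back.feature_names}
        assert back.labels["L2"].s_percent == pytest.approx(60)


class TestMinMax:
    def test_fit_apply_basic(self):
        t = make_table([[2], [4], [6]])
        p = minmax_fit(t)
        np.testing.assert_allclose(
            minmax_apply(t, p).df["f1"].to_numpy(), [0, 0.5, 1])

    def test_constant_column_excluded(self):
        t = make_table([[2, 5], [4, 5], [6, 5]])
        p = minmax_fit(t)
        assert p.excluded == ("f2",)
        assert minmax_apply(t, p).feature_names == ["f1"]

    def test_out_of_fit_not_clipped(self):
        t = make_table([[2], [4], [6], [8]])
        p = minmax_fit(t, rows=["L1", "L2", "L3"])
        scaled = minmax_apply(t, p)
        assert scaled.df.loc["L4", "f1"] == pytest.approx(1.5)

    def test_no_leakage_from_outside_rows(self):
        t = make_table([[2], [4], [6], [8]])
        t_corrupt = make_table([[2], [4], [6], [1e9]])
        rows = ["L1", "L2", "L3"]
        p1, p2 = minmax_fit(t, rows), minmax_fit(t_corrupt, rows)
        np.testing.assert_array_equal(p1.mins, p2.mins)
        np.testing.assert_array_equal(p1.maxs, p2.maxs)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            minmax_fit(make_table([[1], [2]]), rows=[])


class TestCorrelationRank:
    def test_perfect_and_anti_correlation(self):
        s = [20, 40, 60, 80]
        t = make_table(np.column_stack([s, [-v for v in s], [1, 5, 2, 4]]),
                       labels_s=s)
        ranking = correlation_rank(t, "s_select")
        by_name = {f: r for f, r, _ in ranking}
        assert by_name["f1"] == pytest.approx(1.0)
        assert by_name["f2"] == pytest.approx(-1.0)
        assert abs(ranking[-1][1]) < 1.0  # weakest last

    def test_hand_computed_pearson(self):
        # 4-point table: r = cov / (sx sy) computed by hand
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([10.0, 20.0, 25.0, 60.0])
        t = make_table(x[:, None], labels_s=y)
        r = correlation_rank(t, "s_select")[0][1]
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged(self):
        t = make_table([[1, 7], [2, 7], [3, 7]], labels_s=[10, 20, 30])
        ranking = correlation_rank(t)
        flagged = {f: flag for f, _, flag in ranking}
        assert flagged["f2"] and not flagged["f1"]

    def test_affine_rescaling_invariant(self):
        s = [15, 35, 55, 75, 95]
        x = np.array([[0.2], [0.1], [0.5], [0.4], [0.9]])
        t1 = make_table(x, labels_s=s)
        t2 = make_table(13.0 * x + 7.0, labels_s=s)
        r1 = correlation_rank(t1)[0][1]
        r2 = correlation_rank(t2)[0][1]
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestSelectManual:
    def test_identity_and_top1(self):
        s = [20, 40, 60, 80]
        t = make_table(np.column_stack([s, [3, 1, 4, 1], [5, 9, 2, 6]]),
                       labels_s=s)
        ranking = correlation_rank(t)
        assert select_manual(t, 3, ranking).feature_names == t.feature_names
        assert select_manual(t, 1, ranking).feature_names == ["f1"]
        with pytest.raises(ValueError):
            select_manual(t, 0, ranking)

    def test_planted_signal_retained(self, rng):
        n, p, k = 30, 40, 15
        x = rng.uniform(size=(n, p))
        s = np.clip(50 + 40 * (x[:, 0] - 0.5) - 30 * (x[:, 1] - 0.5), 1, 99)
        t = make_table(x, labels_s=s)
        kept = select_manual(t, k, correlation_rank(t)).feature_names
        assert "f1" in kept and "f2" in kept


class TestPCA:
    def test_exact_two_dim_embedding(self, rng):
        basis = rng.normal(size=(2, 6))
        scores = rng.normal(size=(8, 2))
        t = make_table(scores @ basis)
        res = pca_reduce(t, 2)
        recon = res.reconstruct()
        np.testing.assert_allclose(recon, t.values, atol=1e-9)

    def test_variance_conserved_at_full_rank(self, rng):
        t = make_table(rng.normal(size=(6, 3)))
        res = pca_reduce(t, 3)
        total = t.values.var(axis=0, ddof=1).sum()
        assert res.explained_variance.sum() == pytest.approx(total, abs=1e-9)

    def test_matches_eigen_oracle_and_orthogonal(self, rng):
        x = rng.normal(size=(5, 3))
        t = make_table(x)
        res = pca_reduce(t, 2)
        xc = x - x.mean(axis=0)
        w, v = np.linalg.eigh(xc.T @ xc / 4)
        for j, comp in enumerate(res.components):
            oracle = v[:, -1 - j]
            assert abs(np.dot(comp, oracle)) == pytest.approx(1.0, abs=1e-9)
        g = res.table.values.T @ res.table.values
        assert abs(g[0, 1]) < 1e-9

    def test_sign_convention(self, rng):
        t = make_table(rng.normal(size=(6, 4)))
        res = pca_reduce(t, 2)
        for comp in res.components:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_k_too_large(self, rng):
        t = make_table(rng.normal(size=(4, 3)))
        with pytest.raises(ValueError):
            pca_reduce(t, 4)


class TestSammon:
    def test_identity_embedding_reaches_zero_stress(self, rng):
        t = make_table(rng.normal(size=(6, 2)))
        y, state = sammon_map(t, SammonState(target_dim=2))
        assert state.stress_trace[-1] < 1e-6

    def test_stress_trace_non_increasing(self, rng):
        t = make_table(rng.normal(size=(8, 5)))
        _, state = sammon_map(t, SammonState(target_dim=2))
        trace = state.stress_trace
        assert all(b <= a for a, b in zip(trace, trace[1:]))

    def test_gradient_matches_finite_differences(self, rng):
        from scipy.spatial.distance import pdist, squareform
        x = rng.normal(size=(4, 3))
        d = squareform(pdist(x))
        c = d[np.triu_indices(4, 1)].sum()
        y = rng.normal(size=(4, 2))
        stress, grad = _sammon_stress_grad(y, d, c)
        h = 1e-6
        for i in range(4):
            for j in range(2):
                yp, ym = y.copy(), y.copy()
                yp[i, j] += h
                ym[i, j] -= h
                fd = (_sammon_stress_grad(yp, d, c)[0]
                      - _sammon_stress_grad(ym, d, c)[0]) / (2 * h)
                assert grad[i, j] == pytest.approx(fd, rel=1e-5, abs=1e-9)

    def test_scale_consistency(self, rng):
        x = rng.normal(size=(7, 4))
        t1 = make_table(x)
        t2 = make_table(3.0 * x)
        _, s1 = sammon_map(t1, SammonState(target_dim=2))
        _, s2 = sammon_map(t2, SammonState(target_dim=2))
        assert s2.stress_trace[-1] == pytest.approx(s1.stress_trace[-1],
                                                    rel=0.1, abs=1e-8)

    def test_duplicate_rows_jittered(self):
        x = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [2.0, 0.5]])
        t = make_table(x)
        _, state = sammon_map(t, SammonState(target_dim=2, seed=3))
        assert state.jittered
        assert np.isfinite(state.stress_trace[-1])
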