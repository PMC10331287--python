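"""Differential statistics: preprocessing, Welch/FC, PCA, PLS-DA VIP, selection."""

import numpy as np
import pandas as pd
import pytest

from oddlipid.diff_stats import (
    pca_scores,
    plsda_vip,
    preprocess,
    select_differential,
    splot,
    sus_plot,
    venn_sets,
    volcano,
    welch_fc,
)


def _matrix(data, samples=None):
    df = pd.DataFrame(data)
    if samples:
        df.columns = samples
    return df


def _design(groups):
    return pd.Series(groups)


class TestPreprocess:
    def test_pareto_scaling_worked_example(self):
        # row (1,2,3) in log space: mean 2, sd 1, sqrt(sd)=1 -> (-1,0,1)
        matrix = pd.DataFrame([[10.0, 100.0, 1000.0]], index=["sp"],
                              columns=["a", "b", "c"])
        out = preprocess(matrix, iqr_drop_fraction=0.0)
        assert list(out.matrix.loc["sp"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_rows_are_mean_zero(self):
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame(np.exp(rng.normal(0, 1, (30, 12))))
        out = preprocess(matrix)
        assert out.matrix.mean(axis=1).abs().max() < 1e-12

    def test_constant_species_dropped(self):
        matrix = pd.DataFrame(
            [[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], index=["const", "var"]
        )
        out = preprocess(matrix, iqr_drop_fraction=0.0)
        assert "const" not in out.matrix.index
        assert (out.dropped["reason"] == "zero variance").any()

    def test_zero_iqr_fraction_keeps_all(self):
        rng = np.random.default_rng(1)
        matrix = pd.DataFrame(np.exp(rng.normal(0, 1, (20, 8))))
        out = preprocess(matrix, iqr_drop_fraction=0.0)
        assert len(out.matrix) == 20

    def test_iqr_filter_drops_lowest_fraction(self):
        rng = np.random.default_rng(2)
        matrix = pd.DataFrame(np.exp(rng.normal(0, 1, (20, 8))))
        out = preprocess(matrix, iqr_drop_fraction=0.10)
        assert len(out.matrix) == 18
        assert (out.dropped["reason"] == "low IQR").sum() == 2

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            preprocess(pd.DataFrame([[1.0, 0.0, 2.0]]))


def manual_welch(x1, x2):
    """Independent Welch t-test: hand-coded statistic and Satterthwaite df."""
    from scipy.stats import t as tdist

    n1, n2 = len(x1), len(x2)
    v1, v2 = np.var(x1, ddof=1), np.var(x2, ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (np.mean(x1) - np.mean(x2)) / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return 2 * tdist.sf(abs(t), df)


class TestWelchFc:
    def _run(self, raw, design, g1="A", g2="B"):
        processed = np.log10(raw)
        processed = processed.sub(processed.mean(axis=1), axis=0)
        return welch_fc(raw, processed, design, g1, g2)

    def test_identical_groups(self):
        raw = pd.DataFrame([[10.0] * 6], index=["sp"],
                           columns=[f"s{i}" for i in range(6)])
        design = _design({f"s{i}": "A" if i < 3 else "B" for i in range(6)})
        out = self._run(raw, design)
        assert out.loc["sp", "p"] == 1.0
        assert out.loc["sp", "t"] == 0.0
        assert out.loc["sp", "fc"] == pytest.approx(1.0)

    def test_exact_fold_change_on_raw_scale(self):
        raw = pd.DataFrame([[10.0, 10.0, 10.0, 20.0, 20.0, 20.0]], index=["sp"],
                           columns=[f"s{i}" for i in range(6)])
        design = _design({f"s{i}": "A" if i < 3 else "B" for i in range(6)})
        out = self._run(raw, design)
        assert out.loc["sp", "fc"] == pytest.approx(2.0)

    def test_bonferroni_arithmetic_and_monotonicity(self):
        rng = np.random.default_rng(3)
        raw = pd.DataFrame(
            np.exp(rng.normal(0, 0.3, (5, 12))),
            index=[f"sp{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(12)],
        )
        design = _design({f"s{i}": "A" if i < 6 else "B" for i in range(12)})
        out = self._run(raw, design)
        assert np.allclose(out["p_adj"], np.minimum(1.0, out["p"] * 5))
        assert (out["p_adj"] >= out["p"]).all()

    def test_matches_manual_welch_reference(self):
        """Implementation agrees with a hand-coded Welch test to 1e-10."""
        rng = np.random.default_rng(4)
        raw = pd.DataFrame(
            np.exp(rng.normal(0, 0.5, (40, 14))),
            index=[f"sp{i}" for i in range(40)],
            columns=[f"s{i}" for i in range(14)],
        )
        design = _design({f"s{i}": "A" if i < 7 else "B" for i in range(14)})
        processed = np.log10(raw)
        out = welch_fc(raw, processed, design, "A", "B")
        g1 = [f"s{i}" for i in range(7)]
        g2 = [f"s{i}" for i in range(7, 14)]
        for sp in raw.index:
            expected = manual_welch(
                processed.loc[sp, g1].to_numpy(), processed.loc[sp, g2].to_numpy()
            )
            assert out.loc[sp, "p"] == pytest.approx(expected, abs=1e-10)

    def test_small_groups_rejected(self):
        raw = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["sp"],
                           columns=list("abcd"))
        with pytest.raises(ValueError):
            welch_fc(raw, raw, _design({"a": "A", "b": "A", "c": "B", "d": "B"}),
                     "A", "B")


class TestPca:
    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(0, 1, (20, 5)),
                         columns=["s1", "s2", "s3", "s4", "s5"])
        m["s5"] = m["s4"]
        res = pca_scores(m, 2)
        assert res.scores.loc["s4"].to_numpy() == pytest.approx(
            res.scores.loc["s5"].to_numpy()
        )

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(0, 1, (30, 10)))
        res = pca_scores(m, 5)
        evr = res.explained_variance_ratio
        assert all(b <= a + 1e-12 for a, b in zip(evr, evr[1:]))
        assert evr.sum() <= 1.0 + 1e-12

    def test_rank_one_matrix_single_component(self):
        u = np.arange(1.0, 11.0)
        v = np.array([1.0, -2.0, 3.0, 0.5])
        m = pd.DataFrame(np.outer(u, v))
        with pytest.warns(UserWarning, match="capped"):
            res = pca_scores(m, 3)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(0, 1, (15, 8)))
        res = pca_scores(m, 2)
        for comp in res.loadings.columns:
            col = res.loadings[comp]
            assert col.iloc[int(np.argmax(np.abs(col)))] > 0


def _planted_matrix(seed=8, n_per_group=12, n_species=60, n_informative=6,
                    effect=1.5):
    """Two-group log-normal matrix with a block of informative species.

    Noise sd 0.11 on the log10 scale ~ 25% multiplicative biological
    variation, the regime the pipeline targets.
    """
    rng = np.random.default_rng(seed)
    samples = [f"A{i}" for i in range(n_per_group)] + [
        f"B{i}" for i in range(n_per_group)
    ]
    design = _design({s: s[0] for s in samples})
    base = rng.normal(0, 0.11, (n_species, 2 * n_per_group))
    base[:n_informative, n_per_group:] += np.log10(effect)
    raw = pd.DataFrame(
        np.power(10.0, base), index=[f"sp{i}" for i in range(n_species)],
        columns=samples,
    )
    return raw, design


class TestPlsdaVip:
    def test_vip_identity_sums_to_p(self):
        raw, design = _planted_matrix()
        prep = preprocess(raw, iqr_drop_fraction=0.0)
        model, vip = plsda_vip(prep.matrix, design, "A", "B")
        assert float((vip ** 2).sum()) == pytest.approx(len(prep.matrix), abs=1e-6)

    def test_weights_unit_norm_scores_orthogonal(self):
        raw, design = _planted_matrix(seed=9)
        prep = preprocess(raw, iqr_drop_fraction=0.0)
        model, _ = plsda_vip(prep.matrix, design, "A", "B", n_components=2)
        W = model.weights.to_numpy()
        assert np.linalg.norm(W, axis=0) == pytest.approx(np.ones(W.shape[1]))
        T = model.scores.to_numpy()
        assert abs(T[:, 0] @ T[:, 1]) < 1e-8

    def test_informative_species_top_ranked(self):
        raw, design = _planted_matrix(effect=2.0)
        prep = preprocess(raw, iqr_drop_fraction=0.0)
        _, vip = plsda_vip(prep.matrix, design, "A", "B")
        top = set(vip.nlargest(6).index)
        assert top == {f"sp{i}" for i in range(6)}
        assert vip.loc["sp0"] > 1.0

    def test_permuted_labels_mean_q2_nonpositive(self):
        """Label permutation destroys predictivity: mean Q2 <= ~0 over 50 runs."""
        raw, design = _planted_matrix(seed=10)
        prep = preprocess(raw, iqr_drop_fraction=0.0)
        rng = np.random.default_rng(11)
        q2s = []
        labels = design.to_numpy()
        for i in range(50):
            perm = pd.Series(rng.permutation(labels), index=design.index)
            model, _ = plsda_vip(prep.matrix, perm, "A", "B", cv_seed=i)
            q2s.append(model.q2)
        assert float(np.mean(q2s)) <= 0.1

    def test_true_labels_beat_permutations(self):
        raw, design = _planted_matrix(effect=2.0)
        prep = preprocess(raw, iqr_drop_fraction=0.0)
        model, _ = plsda_vip(prep.matrix, design, "A", "B")
        assert model.q2 > 0.5
        assert 0 < model.r2y <= 1.0

    def test_matches_sklearn_pls_cross_check(self):
        """First-component scores/weights agree with an independent PLS fit."""
        from sklearn.cross_decomposition import PLSRegression

        raw, design = _planted_matrix(seed=12)
        prep = preprocess(raw, iqr_drop_fraction=0.0)
        model, _ = plsda_vip(prep.matrix, design, "A", "B", n_components=2)
        X = prep.matrix[list(model.samples)].to_numpy().T
        y = np.array([-1.0] * 12 + [1.0] * 12)
        ref = PLSRegression(n_components=2, scale=False).fit(X, y)
        for a in range(2):
            w_mine = model.weights.to_numpy()[:, a]
            w_ref = ref.x_weights_[:, a]
            sign = np.sign(w_mine @ w_ref)
            assert w_mine == pytest.approx(sign * w_ref, abs=1e-8)
            t_mine = model.scores.to_numpy()[:, a]
            assert t_mine == pytest.approx(sign * ref.x_scores_[:, a], abs=1e-6)


class TestSplotSus:
    def test_self_correlated_species(self):
        raw, design = _planted_matrix(effect=2.5)
        prep = preprocess(raw, iqr_drop_fraction=0.0)
        model, _ = plsda_vip(prep.matrix, design, "A", "B")
        # inject a species equal to t1 itself
        m = prep.matrix.copy()
        m.loc["t1-clone"] = model.t1.reindex(m.columns).to_numpy()
        coords = splot(model, m)
        assert coords.loc["t1-clone", "corr"] == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_species_near_zero(self):
        raw, design = _planted_matrix(seed=13)
        prep = preprocess(raw, iqr_drop_fraction=0.0)
        model, _ = plsda_vip(prep.matrix, design, "A", "B")
        m = prep.matrix.copy()
        t1 = model.t1.reindex(m.columns).to_numpy()
        rng = np.random.default_rng(14)
        noise = rng.normal(0, 1, len(t1))
        ortho = noise - (noise @ t1) / (t1 @ t1) * t1
        m.loc["ortho"] = ortho
        coords = splot(model, m)
        assert coords.loc["ortho", "cov"] == pytest.approx(0.0, abs=1e-9)
        assert abs(coords.loc["ortho", "corr"]) < 1e-9

    def test_opposite_regulation_lands_off_diagonal(self):
        """A species up in comparison 1 and down in comparison 2 falls in the
        second/fourth SUS-plot quadrant."""
        rng = np.random.default_rng(15)
        samples = (
            [f"A{i}" for i in range(8)] + [f"B{i}" for i in range(8)]
            + [f"C{i}" for i in range(8)]
        )
        design = _design({s: s[0] for s in samples})
        base = rng.normal(0, 0.2, (30, 24))
        base[0, 8:16] += 1.0  # up in B only -> up in A-vs-B, down in B-vs-C
        raw = pd.DataFrame(np.power(10.0, base),
                           index=[f"sp{i}" for i in range(30)], columns=samples)
        prep = preprocess(raw, iqr_drop_fraction=0.0)
        m1, _ = plsda_vip(prep.matrix, design, "A", "B")
        m2, _ = plsda_vip(prep.matrix, design, "B", "C")
        coords = sus_plot(m1, m2, prep.matrix)
        assert coords.loc["sp0", "corr_1"] > 0.5
        assert coords.loc["sp0", "corr_2"] < -0.5
        assert coords["corr_1"].between(-1, 1).all()
        assert coords["corr_2"].between(-1, 1).all()


class TestSelection:
    def _results(self, p, vip, fc):
        return pd.DataFrame(
            {"p": [p], "p_adj": [min(1.0, p * 10)], "fc": [fc], "vip": [vip]},
            index=["sp"],
        )

    @pytest.mark.parametrize(
        "p,vip,fc,expected",
        [
            (0.04, 1.5, 1.3, True),
            (0.04, 0.9, 1.3, False),   # VIP fails
            (0.06, 1.5, 1.3, False),   # P fails
            (0.04, 1.5, 1.1, False),   # FC fails
            (0.04, 1.5, 1 / 1.3, True),  # direction-agnostic FC
        ],
    )
    def test_differential_rule(self, p, vip, fc, expected):
        out = select_differential(self._results(p, vip, fc))
        assert bool(out.loc["sp"]) is expected

    def test_volcano_rule_up_down(self):
        res = pd.DataFrame(
            {"p": [0.05, 0.05, 0.5, 0.05], "fc": [2.5, 0.4, 3.0, 1.5]},
            index=["up", "down", "ns_p", "ns_fc"],
        )
        out = volcano(res)
        assert out.to_dict() == {
            "up": "up", "down": "down", "ns_p": "ns", "ns_fc": "ns"
        }

    def test_venn_intersection(self):
        out = venn_sets({"m1": ["a", "b", "c"], "m2": ["b", "c", "d"]})
        assert out["intersection"] == {"b", "c"}
        assert out["unique:m1"] == {"a"}
        assert out["unique:m2"] == {"d"}
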