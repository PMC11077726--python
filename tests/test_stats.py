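"""ANOVA battery: Type III SS, repeated measures, sphericity, post hocs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gapassr import stats as gs
from gapassr.stimulus import InvalidParameterError


def _two_way_table(rng, ns=None, effects=(0.0, 0.0, 0.0)):
    a_eff, b_eff, ab_eff = effects
    rows = []
    for i, a in enumerate(["a1", "a2"]):
        for j, b in enumerate(["b1", "b2", "b3"]):
            n = ns[i][j] if ns is not None else 4
            mu = a_eff * i + b_eff * j + ab_eff * i * j
            for v in rng.normal(mu, 1.0, n):
                rows.append(dict(A=a, B=b, y=v))
    return pd.DataFrame(rows)


def _rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return r @ r


def _type3_oracle(df, response, factors):
    """Projection oracle: Type III SS = RSS(model minus effect) - RSS(full),
    built with an independent design-matrix construction."""
    levels = {f: sorted(df[f].unique()) for f in factors}
    blocks = {}
    coded = {}
    for f in factors:
        lv = levels[f]
        m = np.zeros((len(df), len(lv) - 1))
        for j, l in enumerate(lv[:-1]):
            m[(df[f] == l).to_numpy(), j] = 1
        m[(df[f] == lv[-1]).to_numpy(), :] = -1
        coded[f] = m
    names = []
    for r in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, r):
            m = coded[combo[0]]
            for f in combo[1:]:
                m = np.concatenate(
                    [m[:, [i]] * coded[f] for i in range(m.shape[1])], axis=1
                )
            blocks[":".join(combo)] = m
            names.append(":".join(combo))
    y = df[response].to_numpy(dtype=float)
    intercept = np.ones((len(df), 1))
    X_full = np.hstack([intercept] + [blocks[n] for n in names])
    out = {}
    for n in names:
        X_red = np.hstack([intercept] + [blocks[m] for m in names if m != n])
        out[n] = _rss(X_red, y) - _rss(X_full, y)
    out["residual"] = _rss(X_full, y)
    return out


class TestTwoWayAnova:
    def test_ss_match_projection_oracle(self, rng):
        df = _two_way_table(rng, effects=(0.8, 0.3, 0.5))
        res = gs.anova_twoway(df, "y", "A", "B")
        oracle = _type3_oracle(df, "y", ["A", "B"])
        for effect in ("A", "B", "A:B", "residual"):
            assert res.effect(effect)["ss"] == pytest.approx(
                oracle[effect], abs=1e-10
            )

    def test_unbalanced_ss_match_statsmodels_type3(self, rng):
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        df = _two_way_table(rng, ns=[[4, 7, 5], [6, 4, 8]], effects=(1.0, 0.2, 0.4))
        res = gs.anova_twoway(df, "y", "A", "B")
        fit = smf.ols("y ~ C(A, Sum)*C(B, Sum)", df).fit()
        ref = anova_lm(fit, typ=3)
        assert res.effect("A")["ss"] == pytest.approx(ref.loc["C(A, Sum)", "sum_sq"])
        assert res.effect("B")["F"] == pytest.approx(ref.loc["C(B, Sum)", "F"])
        assert res.effect("A:B")["p"] == pytest.approx(
            ref.loc["C(A, Sum):C(B, Sum)", "PR(>F)"]
        )

    def test_zero_within_cell_variance_gives_inf_f(self):
        means = {("x", "p"): 1.0, ("x", "q"): 2.0, ("x", "r"): 3.0,
                 ("y", "p"): 5.0, ("y", "q"): 4.0, ("y", "r"): 6.0}
        rows = [dict(A=a, B=b, y=means[(a, b)])
                for a in "xy" for b in "pqr" for _ in range(3)]
        res = gs.anova_twoway(pd.DataFrame(rows), "y", "A", "B")
        assert np.isinf(res.effect("A")["F"])
        assert res.effect("A")["p"] == 0.0

    def test_identical_cell_data_gives_zero_effect_ss(self, rng):
        cell = rng.normal(size=5)
        rows = [dict(A=a, B=b, y=v) for a in "xy" for b in "pqr" for v in cell]
        res = gs.anova_twoway(pd.DataFrame(rows), "y", "A", "B")
        for effect in ("A", "B", "A:B"):
            assert res.effect(effect)["ss"] == pytest.approx(0.0, abs=1e-18)
            assert res.effect(effect)["F"] == pytest.approx(0.0, abs=1e-9)

    def test_empty_cell_unestimable(self, rng):
        df = _two_way_table(rng)
        df = df[~((df.A == "a1") & (df.B == "b2"))]
        with pytest.raises(gs.UnestimableEffectError):
            gs.anova_twoway(df, "y", "A", "B")


def _rm_table(rng, n_subj=12, k=4, groups=None, subj_sd=1.0, noise_sd=1.0,
              within_eff=0.0):
    rows = []
    for s in range(n_subj):
        grp = groups[s] if groups is not None else "g"
        base = rng.normal(scale=subj_sd)
        for j in range(k):
            rows.append(dict(subject=f"s{s:02d}", grp=grp, w=f"w{j}",
                             y=base + within_eff * j + rng.normal(scale=noise_sd)))
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_matches_pingouin_one_way_rm(self, rng):
        pg = pytest.importorskip("pingouin")
        df = _rm_table(rng, within_eff=0.3)
        res = gs.rm_anova(df, "y", "w", "subject")
        ref = pg.rm_anova(df, dv="y", within="w", subject="subject",
                          correction=True, detailed=True)
        row = res.effect("w")
        assert row["F"] == pytest.approx(ref.loc[0, "F"])
        assert row["p"] == pytest.approx(ref.loc[0, "p_unc"])
        assert res.epsilon_gg == pytest.approx(ref.loc[0, "eps"], abs=1e-6)
        sph = pg.sphericity(df, dv="y", within="w", subject="subject")
        assert res.mauchly_w == pytest.approx(sph.W)
        # chi-square approximations use slightly different small-sample
        # correction factors; W itself matches exactly
        assert res.mauchly_p == pytest.approx(sph.pval, abs=1e-3)

    def test_mixed_design_strata_match_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        groups = ["WT"] * 8 + ["KO"] * 8
        df = _rm_table(rng, n_subj=16, groups=groups, within_eff=0.4)
        res = gs.rm_anova(df, "y", "w", "subject", between=["grp"])
        ref = pg.mixed_anova(df, dv="y", within="w", subject="subject",
                             between="grp")
        assert res.effect("grp")["F"] == pytest.approx(ref.loc[0, "F"])
        assert res.effect("w")["F"] == pytest.approx(ref.loc[1, "F"])
        assert res.effect("grp:w")["F"] == pytest.approx(ref.loc[2, "F"])

    def test_zero_between_subject_variance_equals_direct_formula(self, rng):
        """With no subject offsets the within F matches the classical
        one-way repeated-measures formula computed directly."""
        df = _rm_table(rng, subj_sd=0.0, within_eff=0.5)
        res = gs.rm_anova(df, "y", "w", "subject")
        wide = df.pivot(index="subject", columns="w", values="y").to_numpy()
        n, k = wide.shape
        grand = wide.mean()
        ss_w = n * ((wide.mean(0) - grand) ** 2).sum()
        ss_subj = k * ((wide.mean(1) - grand) ** 2).sum()
        ss_err = ((wide - wide.mean(0) - wide.mean(1)[:, None] + grand) ** 2).sum()
        f_direct = (ss_w / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
        assert res.effect("w")["F"] == pytest.approx(f_direct)
        assert res.effect("w")["ss"] == pytest.approx(ss_w)

    def test_compound_symmetry_epsilon_near_one(self):
        """Monte Carlo: compound-symmetric covariance keeps eps ~ 1 and
        Mauchly mostly non-significant at n=20."""
        rng = np.random.default_rng(42)
        eps_vals, mauchly_sig = [], 0
        for _ in range(30):
            df = _rm_table(rng, n_subj=20, k=4, subj_sd=1.0, noise_sd=1.0)
            res = gs.rm_anova(df, "y", "w", "subject")
            eps_vals.append(res.epsilon_gg)
            mauchly_sig += res.mauchly_p < 0.05
        assert np.mean(eps_vals) > 0.85
        assert mauchly_sig <= 5  # ~5 % nominal rate, 30 draws

    def test_epsilon_lower_bound_k6(self, rng):
        for _ in range(10):
            df = _rm_table(rng, n_subj=8, k=6, noise_sd=2.0)
            res = gs.rm_anova(df, "y", "w", "subject")
            assert 1.0 / 5 <= res.epsilon_gg <= 1.0

    def test_gg_correction_never_lowers_p(self, rng):
        for seed in range(5):
            df = _rm_table(np.random.default_rng(seed), n_subj=10, k=5,
                           within_eff=0.3)
            res = gs.rm_anova(df, "y", "w", "subject", gg_policy="always")
            for _, row in res.table.iterrows():
                if row["stratum"] == "within" and np.isfinite(row["F"]):
                    assert row["p_gg"] >= row["p"] - 1e-12

    def test_incomplete_design_rejected(self, rng):
        df = _rm_table(rng)
        df = df[~((df.subject == "s03") & (df.w == "w2"))]
        with pytest.raises(gs.IncompleteDesignError):
            gs.rm_anova(df, "y", "w", "subject")

    def test_two_between_factors_supported(self, rng):
        rows = []
        for s in range(24):
            geno = "WT" if s % 2 else "KO"
            age = ("p21", "p30", "p60")[s % 3]
            base = rng.normal()
            for j in range(6):
                rows.append(dict(subject=f"s{s}", genotype=geno, age=age,
                                 gap=f"g{j}", y=base + 0.1 * j + rng.normal()))
        df = pd.DataFrame(rows)
        res = gs.rm_anova(df, "y", "gap", "subject", between=["genotype", "age"])
        effects = set(res.table["effect"])
        assert {"genotype", "age", "genotype:age", "gap", "genotype:gap",
                "age:gap", "genotype:age:gap"} <= effects
        assert res.effect("genotype:age:gap")["df1"] == 2 * 5


class TestPosthoc:
    def test_single_comparison_unadjusted(self, rng):
        df = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5, "y": rng.normal(size=10)})
        for method in ("tukey", "bonferroni", "sidak"):
            (res,) = gs.posthoc(df, "y", "g", method)
            if method != "tukey":
                assert res.p_adjusted == pytest.approx(res.p_raw)
            else:  # studentized range with k=2 equals the t test
                assert res.p_adjusted == pytest.approx(res.p_raw, rel=1e-6)

    def test_sidak_closed_form(self):
        assert gs._adjust(0.01, 6, "sidak") == pytest.approx(1 - 0.99**6)
        assert gs._adjust(0.2, 3, "bonferroni") == pytest.approx(0.6)
        assert gs._adjust(0.5, 10, "bonferroni") == 1.0

    def test_adjustment_ordering_property(self, rng):
        df = pd.DataFrame({
            "g": np.repeat(list("abcd"), 6),
            "y": rng.normal(size=24) + np.repeat([0, 0.5, 1.0, 0.2], 6),
        })
        by = {m: gs.posthoc(df, "y", "g", m) for m in ("tukey", "bonferroni",
                                                       "sidak")}
        for bon, sid in zip(by["bonferroni"], by["sidak"]):
            assert bon.p_adjusted >= sid.p_adjusted >= sid.p_raw
        for tuk in by["tukey"]:
            assert tuk.p_adjusted >= tuk.p_raw - 1e-12

    def test_tukey_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        df = pd.DataFrame({
            "g": np.repeat(list("abc"), 8),
            "y": rng.normal(size=24) + np.repeat([0, 0.7, 0.1], 8),
        })
        mine = {c.comparison: c.p_adjusted for c in gs.posthoc(df, "y", "g",
                                                               "tukey")}
        ref = sm.pairwise_tukeyhsd(df.y, df.g)
        for (a, b), p_ref in zip(
            itertools.combinations(ref.groupsunique, 2), ref.pvalues
        ):
            assert mine[f"{a} - {b}"] == pytest.approx(p_ref, abs=1e-6)

    def test_unknown_method_rejected(self, rng):
        df = pd.DataFrame({"g": ["a", "a", "b", "b"], "y": rng.normal(size=4)})
        with pytest.raises(InvalidParameterError):
            gs.posthoc(df, "y", "g", "holm")


class TestDiagnostics:
    def test_normal_sample_moments(self):
        rng = np.random.default_rng(7)
        d = gs.diagnostics(rng.standard_normal(5000))
        assert abs(d.skewness) < 0.1
        assert abs(d.kurtosis) < 0.2  # excess kurtosis convention
        assert d.within_plus_minus_two
        assert np.all(np.diff(d.qq_theoretical) >= 0)

    def test_exponential_sample_flagged(self):
        rng = np.random.default_rng(8)
        d = gs.diagnostics(rng.exponential(size=2000))
        assert d.skewness > 1.5
        assert not gs.diagnostics(rng.exponential(size=2000) ** 2).within_plus_minus_two

    def test_shapiro_calibration(self):
        rng = np.random.default_rng(9)
        rej = sum(
            gs.diagnostics(rng.standard_normal(50)).shapiro_p < 0.05
            for _ in range(2000)
        )
        assert 0.04 <= rej / 2000 <= 0.06

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(gs.DegenerateInputError):
            gs.diagnostics([1.0, 1.0])
        with pytest.raises(gs.DegenerateInputError):
            gs.diagnostics(np.ones(10))


def _synthetic_tables(rng, female_only=False, null=True):
    """Cohort tables with every factor cell populated."""
    erp_rows, itpc_rows = [], []
    sexes = ["F"] if female_only else ["F", "M"]
    sid = 0
    for geno in ("WT", "KO"):
        for sex in sexes:
            for age in ("p21", "p30", "p60"):
                for _ in range(5):
                    sub = f"s{sid:03d}"
                    sid += 1
                    for ch in ("AC", "FC"):
                        for wave in ("P1", "N1", "P2"):
                            erp_rows.append(dict(
                                subject=sub, genotype=geno, sex=sex, age=age,
                                channel=ch, wave=wave,
                                amplitude_uv=rng.normal(10, 2),
                                latency_ms=rng.normal(60, 5),
                            ))
                        for depth in (75.0, 100.0):
                            for gap in (2.0, 4.0, 6.0, 8.0, 10.0, 12.0):
                                itpc_rows.append(dict(
                                    subject=sub, genotype=geno, sex=sex,
                                    age=age, channel=ch, gap_width_ms=gap,
                                    mod_depth_pct=depth,
                                    itpc=rng.uniform(0.1, 0.8),
                                ))
    return pd.DataFrame(erp_rows), pd.DataFrame(itpc_rows)


class TestRunPaperContrasts:
    def test_block_grid_cardinality(self, rng):
        erp_t, itpc_t = _synthetic_tables(rng)
        report = gs.run_paper_contrasts(erp_t, itpc_t)
        # ERP: 2 ch x 3 waves x 2 measures x (female dev + WT sex + KO sex)
        n_erp = 2 * 3 * 2 * 3
        # ITPC: 2 ch x 2 depths x (female dev + 2 genotypes x 3 ages)
        n_itpc = 2 * 2 * (1 + 6)
        assert len(report.blocks) == n_erp + n_itpc
        frame = report.anova_frame()
        assert {"erp", "itpc"} == set(frame["analysis"].unique())

    def test_contrast_calibration_under_null(self):
        """Raw genotype-at-age contrast p-values are uniform under the null
        (~5 % below 0.05)."""
        rng = np.random.default_rng(11)
        hits = total = 0
        for _ in range(150):
            rows = []
            for geno in ("WT", "KO"):
                for age in ("p21", "p30", "p60"):
                    for i in range(8):
                        rows.append(dict(subject=f"{geno}{age}{i}",
                                         genotype=geno, age=age,
                                         itpc=rng.normal()))
            contrasts = gs._contrasts_at(pd.DataFrame(rows), "itpc",
                                         "genotype", "age", "sidak")
            hits += sum(c.p_raw < 0.05 for c in contrasts)
            total += len(contrasts)
        assert 0.03 <= hits / total <= 0.07

    def test_report_serialization(self, rng, tmp_path):
        erp_t, itpc_t = _synthetic_tables(rng, female_only=True)
        report = gs.run_paper_contrasts(erp_t, itpc_t)
        report.to_json(tmp_path / "r.json")
        report.to_csv(tmp_path / "a.csv", tmp_path / "c.csv")
        import json

        blocks = json.loads((tmp_path / "r.json").read_text())
        assert len(blocks) == len(report.blocks)
        assert (tmp_path / "a.csv").stat().st_size > 0
        back = pd.read_csv(tmp_path / "c.csv")
        assert {"comparison", "estimate", "p_adjusted"} <= set(back.columns)
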