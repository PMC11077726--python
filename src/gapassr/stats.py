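"""Factorial and repeated-measures ANOVA battery with assumption diagnostics.

Implements, in plain linear algebra, the statistics the analysis pipeline
needs: Type III sums of squares for (possibly unbalanced) factorial
designs via general-linear-hypothesis tests under sum-to-zero coding;
split-plot (repeated-measures) ANOVA with between-subject factors and one
within-subject factor; Mauchly's sphericity test; the Greenhouse-Geisser
epsilon correction (applied when Mauchly rejects, or always, by policy);
Tukey/Bonferroni/Sidak pairwise procedures; and residual normality
diagnostics (Shapiro-Wilk, skewness/kurtosis against the +-2 rule, QQ
points).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps

from .stimulus import InvalidParameterError

__all__ = [
    "UnestimableEffectError",
    "IncompleteDesignError",
    "DegenerateInputError",
    "AnovaResult",
    "ContrastResult",
    "ResidualDiagnostics",
    "anova_twoway",
    "type_iii_anova",
    "rm_anova",
    "posthoc",
    "diagnostics",
    "run_paper_contrasts",
    "StatsReport",
]

logger = logging.getLogger(__name__)


class UnestimableEffectError(ValueError):
    """The design matrix is rank deficient (e.g. an empty cell)."""


class IncompleteDesignError(ValueError):
    """A subject is missing one or more within-factor levels."""


class DegenerateInputError(ValueError):
    """Input carries no usable variation (e.g. constant residuals)."""


# --------------------------------------------------------------------------
# design-matrix machinery (sum-to-zero coding, Type III GLH)


def _sum_code(values: np.ndarray, levels: list) -> np.ndarray:
    """Sum-to-zero (deviation) coding: len(levels)-1 columns."""
    out = np.zeros((len(values), len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        out[values == lev, j] = 1.0
    out[values == levels[-1], :] = -1.0
    return out


def _factorial_design(
    df: pd.DataFrame, factors: list[str]
) -> tuple[np.ndarray, dict[str, slice]]:
    """Full-factorial sum-coded design matrix with all interactions.

    Returns (X, spans) where spans maps effect name ("A", "A:B", ...) to
    the slice of its columns; column 0 is the intercept.
    """
    coded = {
        f: _sum_code(df[f].to_numpy(), sorted(df[f].unique())) for f in factors
    }
    cols = [np.ones((len(df), 1))]
    spans: dict[str, slice] = {}
    start = 1
    for order in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, order):
            block = coded[combo[0]]
            for f in combo[1:]:
                # column-wise Khatri-Rao product -> interaction columns
                block = (block[:, :, None] * coded[f][:, None, :]).reshape(
                    len(df), -1
                )
            cols.append(block)
            spans[":".join(combo)] = slice(start, start + block.shape[1])
            start += block.shape[1]
    X = np.hstack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise UnestimableEffectError(
            "design matrix is rank deficient (empty or confounded cells)"
        )
    return X, spans


def _glh_ss(X: np.ndarray, y: np.ndarray, idx) -> float:
    """SS for H0: beta[idx] = 0 in the full model (Type III under sum coding)."""
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    lb = beta[idx]
    m = xtx_inv[np.ix_(idx, idx)]
    return float(lb @ np.linalg.solve(m, lb))


def _fit_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _f_and_p(ss: float, df1: float, sse: float, df2: float,
             scale: float = 1.0) -> tuple[float, float]:
    if df2 <= 0:
        return np.nan, np.nan
    if sse <= max(scale, 1.0e-300) * 1e-12:
        # zero residual variance: the documented F -> inf / p -> 0 sentinel
        if ss <= max(scale, 1.0e-300) * 1e-12:
            return 0.0, 1.0
        return np.inf, 0.0
    f = (ss / df1) / (sse / df2)
    return f, float(sps.f.sf(f, df1, df2))


@dataclass
class AnovaResult:
    """ANOVA table plus sphericity metadata.

    ``table`` has one row per effect (and error strata) with columns:
    effect, stratum, ss, df1, df2, F, p, and — for within-subject effects —
    eps_gg, p_gg, and the reported p under the sphericity policy.
    """

    table: pd.DataFrame
    mauchly_w: float | None = None
    mauchly_p: float | None = None
    epsilon_gg: float | None = None
    gg_applied: bool = False

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(f"no effect named {name!r}")
        return rows.iloc[0]

    def p(self, name: str) -> float:
        row = self.effect(name)
        return float(row.get("p_reported", row["p"]))


def type_iii_anova(df: pd.DataFrame, response: str, factors: list[str]) -> AnovaResult:
    """Between-subjects factorial ANOVA, Type III sums of squares."""
    df = df.dropna(subset=[response, *factors])
    for f in factors:
        if df[f].nunique() < 2:
            raise UnestimableEffectError(f"factor {f!r} needs >= 2 observed levels")
    y = df[response].to_numpy(dtype=float)
    X, spans = _factorial_design(df, factors)
    sse = _fit_rss(X, y)
    df_e = len(df) - X.shape[1]
    scale = float(np.sum((y - y.mean()) ** 2))
    rows = []
    for effect, span in spans.items():
        idx = list(range(span.start, span.stop))
        ss = _glh_ss(X, y, idx)
        df1 = len(idx)
        f, p = _f_and_p(ss, df1, sse, df_e, scale)
        rows.append(dict(effect=effect, stratum="between", ss=ss, df1=df1,
                         df2=df_e, F=f, p=p))
    rows.append(dict(effect="residual", stratum="between", ss=sse, df1=df_e,
                     df2=np.nan, F=np.nan, p=np.nan))
    return AnovaResult(table=pd.DataFrame(rows))


def anova_twoway(
    df: pd.DataFrame, response: str, factor_a: str, factor_b: str
) -> AnovaResult:
    """Two-way between-subjects ANOVA (main effects + interaction, Type III)."""
    return type_iii_anova(df, response, [factor_a, factor_b])


# --------------------------------------------------------------------------
# repeated measures


def _sphericity_stats(Y: np.ndarray, Xb: np.ndarray) -> tuple[float, float, float]:
    """Mauchly's W (with its chi-square p) and Greenhouse-Geisser epsilon.

    Computed from the pooled within-cell covariance of the k within-level
    responses, projected through orthonormal contrasts.
    """
    n, k = Y.shape
    beta, *_ = np.linalg.lstsq(Xb, Y, rcond=None)
    E = Y - Xb @ beta
    df_e = n - Xb.shape[1]
    if df_e < k:
        logger.warning("too few error df (%d) for a stable Mauchly test at k=%d",
                       df_e, k)
    S = E.T @ E / max(df_e, 1)
    C = linalg.helmert(k, full=False)  # (k-1, k), orthonormal rows
    T = C @ S @ C.T
    k1 = k - 1
    tr = np.trace(T)
    eps = tr**2 / (k1 * np.sum(T * T)) if tr > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / k1, 1.0))
    det = np.linalg.det(T)
    denom = (tr / k1) ** k1
    if det <= 0 or denom <= 0:
        return 0.0, 0.0, eps
    w = float(det / denom)
    d = 1.0 - (2.0 * k1**2 + k1 + 2.0) / (6.0 * k1 * df_e)
    chi2 = -df_e * d * np.log(w)
    df_chi = k * k1 / 2.0 - 1.0
    p = float(sps.chi2.sf(chi2, df_chi)) if df_chi > 0 else 1.0
    return w, p, eps


def rm_anova(
    df: pd.DataFrame,
    response: str,
    within: str,
    subject: str,
    between: list[str] | None = None,
    gg_policy: str = "auto",  # "auto" | "always" | "never"
) -> AnovaResult:
    """Split-plot ANOVA: between-subject factors x one within-subject factor.

    Every subject must be measured at all ``within`` levels (long format).
    Between effects are tested against the subject stratum, within effects
    (the within main effect and its interactions with the between factors)
    against the within-subject residual.  Mauchly's test is run on the
    pooled within-cell covariance; under the default ``auto`` policy the
    Greenhouse-Geisser correction multiplies the within dfs whenever
    Mauchly rejects at 0.05 ("always"/"never" override).
    """
    between = list(between or [])
    if gg_policy not in ("auto", "always", "never"):
        raise InvalidParameterError("gg_policy must be auto, always or never")
    wide = df.pivot_table(index=subject, columns=within, values=response)
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise IncompleteDesignError(
            f"subjects missing within-factor levels: {missing}"
        )
    wide = wide.sort_index()
    k = wide.shape[1]
    if k < 2:
        raise InvalidParameterError("within factor needs >= 2 levels")
    Y = wide.to_numpy(dtype=float)
    n = Y.shape[0]

    meta = df.drop_duplicates(subject).set_index(subject).loc[wide.index]
    if between:
        Xb, spans_b = _factorial_design(meta.reset_index(), between)
    else:
        Xb, spans_b = np.ones((n, 1)), {}
    p_b = Xb.shape[1]

    rows = []
    # --- between stratum: subject means, scaled by k to stay on the y scale
    m = Y.mean(axis=1)
    scale = float(np.sum((Y - Y.mean()) ** 2))
    sse_b = _fit_rss(Xb, m) * k
    df_eb = n - p_b
    for effect, span in spans_b.items():
        idx = list(range(span.start, span.stop))
        ss = _glh_ss(Xb, m, idx) * k
        f, p = _f_and_p(ss, len(idx), sse_b, df_eb, scale)
        rows.append(dict(effect=effect, stratum="between", ss=ss, df1=len(idx),
                         df2=df_eb, F=f, p=p, eps_gg=np.nan, p_gg=np.nan,
                         p_reported=p))
    rows.append(dict(effect="subjects(error)", stratum="between", ss=sse_b,
                     df1=df_eb, df2=np.nan, F=np.nan, p=np.nan,
                     eps_gg=np.nan, p_gg=np.nan, p_reported=np.nan))

    # --- within stratum: orthonormal contrast scores
    C = linalg.helmert(k, full=False)
    Z = Y @ C.T  # (n, k-1)
    sse_w = sum(_fit_rss(Xb, Z[:, j]) for j in range(k - 1))
    df_ew = (n - p_b) * (k - 1)

    mauchly_w, mauchly_p, eps = _sphericity_stats(Y, Xb)
    apply_gg = gg_policy == "always" or (gg_policy == "auto" and mauchly_p < 0.05)

    within_effects: list[tuple[str, list[int], int]] = [(within, [0], 1)]
    for effect, span in spans_b.items():
        within_effects.append(
            (f"{effect}:{within}", list(range(span.start, span.stop)),
             span.stop - span.start)
        )
    for name, idx, df_b1 in within_effects:
        ss = sum(_glh_ss(Xb, Z[:, j], idx) for j in range(k - 1))
        df1 = df_b1 * (k - 1)
        f, p = _f_and_p(ss, df1, sse_w, df_ew, scale)
        if np.isfinite(f):
            p_gg = float(sps.f.sf(f, eps * df1, eps * df_ew))
        else:
            p_gg = p
        rows.append(dict(effect=name, stratum="within", ss=ss, df1=df1,
                         df2=df_ew, F=f, p=p, eps_gg=eps, p_gg=p_gg,
                         p_reported=p_gg if apply_gg else p))
    rows.append(dict(effect=f"{within}:subjects(error)", stratum="within",
                     ss=sse_w, df1=df_ew, df2=np.nan, F=np.nan, p=np.nan,
                     eps_gg=np.nan, p_gg=np.nan, p_reported=np.nan))

    return AnovaResult(
        table=pd.DataFrame(rows),
        mauchly_w=mauchly_w,
        mauchly_p=mauchly_p,
        epsilon_gg=eps,
        gg_applied=apply_gg,
    )


# --------------------------------------------------------------------------
# post hoc procedures


@dataclass
class ContrastResult:
    comparison: str
    estimate: float
    p_raw: float
    p_adjusted: float
    method: str


def _adjust(p_raw: float, m: int, method: str, q: float | None = None,
            k: int = 2, df: float = np.inf) -> float:
    if method == "bonferroni":
        return min(1.0, m * p_raw)
    if method == "sidak":
        return 1.0 - (1.0 - p_raw) ** m
    if method == "tukey":
        return float(sps.studentized_range.sf(q, k, df))
    raise InvalidParameterError(f"unknown post hoc method {method!r}")


def posthoc(
    df: pd.DataFrame,
    response: str,
    factor: str,
    method: str = "tukey",
    mse: float | None = None,
    df_error: float | None = None,
) -> list[ContrastResult]:
    """All pairwise contrasts between the levels of ``factor``.

    Raw p-values come from two-sided t tests on the pooled error variance
    (the within-cell MSE of a one-way fit unless ``mse``/``df_error`` are
    passed from a richer model).  Adjustment: Bonferroni min(1, m*p),
    Sidak 1-(1-p)^m, or Tukey HSD via the studentized range with the
    Tukey-Kramer (pairwise harmonic-mean cell size) standard error.
    """
    if method not in ("tukey", "bonferroni", "sidak"):
        raise InvalidParameterError(f"unknown post hoc method {method!r}")
    groups = df.groupby(factor)[response]
    levels = sorted(groups.groups)
    if len(levels) < 2:
        raise UnestimableEffectError("post hoc needs >= 2 levels")
    means = groups.mean()
    ns = groups.size()
    if mse is None:
        sse = float(((df[response] - df[factor].map(means)) ** 2).sum())
        df_error = len(df) - len(levels)
        if df_error <= 0:
            raise UnestimableEffectError("no error degrees of freedom")
        mse = sse / df_error
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        est = float(means[a] - means[b])
        n_h = 2.0 / (1.0 / ns[a] + 1.0 / ns[b])  # pairwise harmonic mean n
        se = np.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
        if se == 0:
            p_raw, q = (0.0 if est != 0 else 1.0), np.inf
        else:
            p_raw = float(2 * sps.t.sf(abs(est) / se, df_error))
            q = abs(est) / np.sqrt(mse / n_h)
        p_adj = _adjust(p_raw, m, method, q=q, k=len(levels), df=df_error)
        out.append(ContrastResult(f"{a} - {b}", est, p_raw, float(p_adj), method))
    return out


# --------------------------------------------------------------------------
# diagnostics


@dataclass
class ResidualDiagnostics:
    shapiro_w: float
    shapiro_p: float
    skewness: float
    kurtosis: float  # excess kurtosis; the +-2 rule applies to this value
    qq_theoretical: np.ndarray
    qq_empirical: np.ndarray

    @property
    def within_plus_minus_two(self) -> bool:
        return abs(self.skewness) <= 2.0 and abs(self.kurtosis) <= 2.0


def diagnostics(residuals) -> ResidualDiagnostics:
    """Shapiro-Wilk, sample skewness/excess kurtosis, and QQ points."""
    x = np.asarray(residuals, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise DegenerateInputError("diagnostics need n >= 3 residuals")
    if np.ptp(x) == 0:
        raise DegenerateInputError("residuals are constant")
    w, p = sps.shapiro(x)
    (osm, osr), _ = sps.probplot(x, dist="norm")
    return ResidualDiagnostics(
        shapiro_w=float(w),
        shapiro_p=float(p),
        skewness=float(sps.skew(x, bias=False)),
        kurtosis=float(sps.kurtosis(x, fisher=True, bias=False)),
        qq_theoretical=osm,
        qq_empirical=osr,
    )


# --------------------------------------------------------------------------
# the full analysis grid


def _contrasts_at(
    df: pd.DataFrame,
    response: str,
    group_factor: str,
    at_factor: str,
    method: str,
) -> list[ContrastResult]:
    """Two-level group contrast at each level of ``at_factor``.

    Error variance is pooled within the group x at cells; p-values are
    adjusted across the ``at_factor`` levels.
    """
    cells = df.groupby([group_factor, at_factor])[response]
    cell_means = cells.mean()
    sse = float(
        (
            (df[response] - df.set_index([group_factor, at_factor]).index.map(cell_means))
            ** 2
        ).sum()
    )
    df_error = len(df) - len(cell_means)
    if df_error <= 0:
        raise UnestimableEffectError("no error degrees of freedom")
    mse = sse / df_error
    levels = sorted(df[group_factor].unique())
    ats = sorted(df[at_factor].unique())
    m = len(ats)
    out = []
    for at in ats:
        sub = df[df[at_factor] == at]
        ns = sub.groupby(group_factor)[response].size()
        if len(ns) < 2:
            continue
        a, b = levels[0], levels[1]
        est = float(cell_means[(a, at)] - cell_means[(b, at)])
        se = np.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
        p_raw = float(2 * sps.t.sf(abs(est) / se, df_error)) if se > 0 else 0.0
        p_adj = _adjust(p_raw, m, method if method != "tukey" else "bonferroni")
        out.append(
            ContrastResult(f"{a} - {b} @ {at_factor}={at}", est, p_raw, p_adj, method)
        )
    return out


@dataclass
class StatsReport:
    """One results block per (channel x depth/wave x comparison)."""

    blocks: list[dict] = field(default_factory=list)

    def anova_frame(self) -> pd.DataFrame:
        frames = []
        for blk in self.blocks:
            t = pd.DataFrame(blk["anova"])
            for key in ("analysis", "comparison", "channel", "wave", "measure",
                        "mod_depth_pct", "age"):
                if key in blk:
                    t[key] = blk[key]
            frames.append(t)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def contrast_frame(self) -> pd.DataFrame:
        rows = []
        for blk in self.blocks:
            for c in blk["contrasts"]:
                row = dict(c)
                for key in ("analysis", "comparison", "channel", "wave", "measure",
                            "mod_depth_pct", "age"):
                    if key in blk:
                        row[key] = blk[key]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.blocks, fh, indent=1, default=_jsonable)

    def to_csv(self, anova_path, contrast_path) -> None:
        self.anova_frame().to_csv(anova_path, index=False)
        self.contrast_frame().to_csv(contrast_path, index=False)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _block(analysis, comparison, anova: AnovaResult,
           contrasts: list[ContrastResult], **meta) -> dict:
    return dict(
        analysis=analysis,
        comparison=comparison,
        anova=anova.table.to_dict("records"),
        mauchly_w=anova.mauchly_w,
        mauchly_p=anova.mauchly_p,
        epsilon_gg=anova.epsilon_gg,
        gg_applied=anova.gg_applied,
        contrasts=[c.__dict__ for c in contrasts],
        **meta,
    )


def run_paper_contrasts(
    erp_table: pd.DataFrame | None,
    itpc_table: pd.DataFrame | None,
    gg_policy: str = "auto",
) -> StatsReport:
    """Execute the full analysis grid on cohort tables.

    ERP (per channel x wave x measure): two-way genotype x age ANOVA on the
    female cohort with Tukey age contrasts per genotype and Bonferroni
    genotype-at-age contrasts; sex x age variants within each genotype when
    both sexes are present.  Gap-ASSR ITPC (per channel x depth, analyzed
    separately): genotype x age x gap-duration repeated-measures ANOVA on
    females with Sidak genotype-at-age contrasts on gap-collapsed means;
    per-age sex x gap repeated-measures ANOVAs within each genotype.
    """
    report = StatsReport()

    def _has_levels(d, col, n=2):
        return col in d and d[col].nunique() >= n

    if erp_table is not None and len(erp_table):
        for channel in sorted(erp_table["channel"].unique()):
            ch_t = erp_table[erp_table["channel"] == channel]
            for wave in ("P1", "N1", "P2"):
                wv = ch_t[ch_t["wave"] == wave]
                if wv.empty:
                    continue
                for measure in ("amplitude_uv", "latency_ms"):
                    fem = wv[wv["sex"] == "F"]
                    if _has_levels(fem, "genotype") and _has_levels(fem, "age"):
                        res = anova_twoway(fem, measure, "genotype", "age")
                        contrasts = _contrasts_at(
                            fem, measure, "genotype", "age", "bonferroni"
                        )
                        for geno in sorted(fem["genotype"].unique()):
                            sub = fem[fem["genotype"] == geno]
                            for c in posthoc(sub, measure, "age", "tukey"):
                                c.comparison = f"{geno}: {c.comparison}"
                                contrasts.append(c)
                        report.blocks.append(_block(
                            "erp", "female_development", res, contrasts,
                            channel=channel, wave=wave, measure=measure,
                        ))
                    for geno in ("WT", "KO"):
                        gsub = wv[wv["genotype"] == geno]
                        if _has_levels(gsub, "sex") and _has_levels(gsub, "age"):
                            res = anova_twoway(gsub, measure, "sex", "age")
                            contrasts = _contrasts_at(
                                gsub, measure, "sex", "age", "bonferroni"
                            )
                            report.blocks.append(_block(
                                "erp", f"{geno.lower()}_sex_development", res,
                                contrasts, channel=channel, wave=wave,
                                measure=measure,
                            ))

    if itpc_table is not None and len(itpc_table):
        itpc_table = itpc_table.copy()
        itpc_table["gap"] = itpc_table["gap_width_ms"]
        for channel in sorted(itpc_table["channel"].unique()):
            for depth in sorted(itpc_table["mod_depth_pct"].unique()):
                sub = itpc_table[
                    (itpc_table["channel"] == channel)
                    & (itpc_table["mod_depth_pct"] == depth)
                ]
                fem = sub[sub["sex"] == "F"]
                if _has_levels(fem, "genotype") and _has_levels(fem, "age", 2):
                    res = rm_anova(fem, "itpc", "gap", "subject",
                                   between=["genotype", "age"], gg_policy=gg_policy)
                    collapsed = fem.groupby(
                        ["subject", "genotype", "age"], as_index=False
                    )["itpc"].mean()
                    contrasts = _contrasts_at(
                        collapsed, "itpc", "genotype", "age", "sidak"
                    )
                    report.blocks.append(_block(
                        "itpc", "female_development", res, contrasts,
                        channel=channel, mod_depth_pct=depth,
                    ))
                for geno in ("WT", "KO"):
                    gsub = sub[sub["genotype"] == geno]
                    if not _has_levels(gsub, "sex"):
                        continue
                    # sex-at-age contrasts on gap-collapsed means, Sidak
                    # adjusted across the three ages (one family per
                    # channel x depth x genotype)
                    collapsed = gsub.groupby(
                        ["subject", "sex", "age"], as_index=False
                    )["itpc"].mean()
                    sex_contrasts = _contrasts_at(
                        collapsed, "itpc", "sex", "age", "sidak"
                    )
                    for age in sorted(gsub["age"].unique()):
                        asub = gsub[gsub["age"] == age]
                        if not _has_levels(asub, "sex"):
                            continue
                        res = rm_anova(asub, "itpc", "gap", "subject",
                                       between=["sex"], gg_policy=gg_policy)
                        contrasts = [
                            c for c in sex_contrasts
                            if c.comparison.endswith(f"age={age}")
                        ]
                        report.blocks.append(_block(
                            "itpc", f"{geno.lower()}_sex_by_age", res, contrasts,
                            channel=channel, mod_depth_pct=depth, age=age,
                        ))
    return report
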