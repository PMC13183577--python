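"""Factorial analyses for the behavioural and histological designs.

The behavioural design is a 2 (strain: SHR vs WKY) x 2 (sex) x 3 (strategy
category: L-P, L-NN, Global) split-plot: strain and sex vary between
subjects, strategy within subjects (each rat contributes a mean per
category, averaging its two configurations of that category).  The
univariate repeated-measures ANOVA partitions error into a between-subjects
term (subjects within strain x sex) for the between effects and the
subject x strategy residual for the within effects; Greenhouse-Geisser
corrected p-values are reported alongside uncorrected ones because the
three-level within factor can violate sphericity.

When trials are missing (typically velocity, when some trials lack
tracks), a linear mixed
model with a random intercept per rat replaces the ANOVA; on complete
balanced data its F tests coincide with the repeated-measures ANOVA.

The histological design is a plain 2 x 2 between-subjects ANOVA per brain
region on percent hypertrophic microglia, with Type III sums of squares
because the per-region animal counts are unequal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import ArenaConfig, Strategy

__all__ = [
    "TermResult",
    "AnovaResult",
    "aggregate_by_strategy",
    "rm_anova_2x2x3",
    "mixed_model_anova",
    "between_anova_2x2",
]

MEASURE_COLUMNS = [
    "latency",
    "revisits",
    "revisits_per_target",
    "skips",
    "span",
    "travel_distance",
    "pao_diff",
    "pao_pct",
    "rate",
    "prop_opt",
    "prop_dist_opt",
    "velocity",
]


@dataclass(frozen=True)
class TermResult:
    term: str
    df_num: int
    df_den: float
    F: float
    p: float
    p_gg: float | None = None  # Greenhouse-Geisser corrected (within terms)


@dataclass(frozen=True)
class AnovaResult:
    method: str
    terms: tuple[TermResult, ...]
    cell_means: dict[str, float] = field(default_factory=dict)
    gg_epsilon: float | None = None

    def __getitem__(self, term: str) -> TermResult:
        for t in self.terms:
            if t.term == term:
                return t
        raise KeyError(term)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": t.term,
                    "df_num": t.df_num,
                    "df_den": t.df_den,
                    "F": t.F,
                    "p": t.p,
                    "p_gg": t.p_gg,
                }
                for t in self.terms
            ]
        )


class DesignError(ValueError):
    """Unusable design: empty cells, zero variance, or incomplete data."""


def aggregate_by_strategy(
    measures: pd.DataFrame, configs: dict[int, ArenaConfig]
) -> pd.DataFrame:
    """Per-rat means of each measure within each strategy category.

    Baseline configurations are excluded (too few targets to dissociate
    strategies); the remaining configurations are averaged pairwise within
    their category.  Returns a long table with one row per rat x category
    and one column per measure; a rat with no trials in a category is
    simply absent from that category (missingness is propagated, never
    imputed).
    """
    strategy_of = {
        cid: cfg.strategy.value for cid, cfg in configs.items()
    }
    unknown = set(measures["config_id"].unique()) - set(strategy_of)
    if unknown:
        raise DesignError(f"no strategy mapping for config ids {sorted(unknown)}")
    df = measures.copy()
    df["strategy"] = df["config_id"].map(strategy_of)
    df = df[df["strategy"] != Strategy.BASELINE.value]
    value_cols = [c for c in MEASURE_COLUMNS if c in df.columns]
    out = (
        df.groupby(["rat_id", "strain", "sex", "strategy"], sort=True)[value_cols]
        .mean()
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# design-matrix helpers (sum-to-zero coding; Type III partial tests)


def _sum_code(values: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero contrast columns for a categorical series."""
    levels = sorted(values.unique())
    k = len(levels)
    cols = np.zeros((len(values), k - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = np.where(values == lev, 1.0, 0.0)
    cols -= np.where(values.to_numpy()[:, None] == levels[-1], 1.0, 0.0)
    return cols, levels


def _interaction(*blocks: np.ndarray) -> np.ndarray:
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ij,ik->ijk", out, b).reshape(len(out), -1)
    return out


def _type3_ss(X: np.ndarray, y: np.ndarray, slices: dict[str, slice]) -> dict:
    """Type III sum of squares for each term of a full linear model."""
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    beta = XtX_inv @ (X.T @ y)
    ss = {}
    for term, sl in slices.items():
        b = beta[sl]
        V = XtX_inv[sl, sl]
        ss[term] = float(b @ np.linalg.solve(V, b))
    resid = y - X @ beta
    ss["__resid__"] = float(resid @ resid)
    return ss


def _gg_epsilon(wide: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity estimate from subject x level data
    (group-centred)."""
    k = wide.shape[1]
    S = np.cov(wide, rowvar=False)
    P = np.eye(k) - np.ones((k, k)) / k
    Sd = P @ S @ P
    num = np.trace(Sd) ** 2
    den = (k - 1) * np.trace(Sd @ Sd)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


def _check_groups(df: pd.DataFrame, factors: list[str]) -> None:
    counts = df.groupby(factors, sort=True).size()
    for combo in itertools.product(*(sorted(df[f].unique()) for f in factors)):
        if combo not in counts.index or counts.loc[combo] == 0:
            raise DesignError(f"empty design cell {dict(zip(factors, combo))}")


def rm_anova_2x2x3(
    table: pd.DataFrame, value: str = "prop_opt"
) -> AnovaResult:
    """Split-plot repeated-measures ANOVA: strain x sex between, strategy
    within.

    ``table`` is the long output of :func:`aggregate_by_strategy` (columns
    ``rat_id, strain, sex, strategy`` and the measure column).  Requires a
    complete within-subject table — every rat observed in every strategy
    category; use :func:`mixed_model_anova` otherwise.  Degenerate factors
    with a single level are dropped from the term list, so the same routine
    covers collapsed designs.
    """
    df = table.dropna(subset=[value]).copy()
    if df.empty:
        raise DesignError("no data")
    strategies = sorted(df["strategy"].unique())
    k = len(strategies)
    per_rat = df.groupby("rat_id")["strategy"].nunique()
    if (per_rat != k).any():
        missing = per_rat.index[per_rat != k].tolist()
        raise DesignError(
            f"incomplete within-subject data for rats {missing}; use "
            f"mixed_model_anova"
        )
    dup = df.groupby(["rat_id", "strategy"]).size()
    if (dup > 1).any():
        raise DesignError("multiple values per rat x strategy cell")

    subj = (
        df.groupby(["rat_id", "strain", "sex"], sort=True)[value]
        .mean()
        .reset_index()
    )
    n_subj = len(subj)

    between_factors = [f for f in ("strain", "sex") if subj[f].nunique() > 1]
    # between-subjects part: ANOVA on subject means
    Xb_blocks: dict[str, np.ndarray] = {}
    coded = {f: _sum_code(subj[f])[0] for f in between_factors}
    for r in range(1, len(between_factors) + 1):
        for combo in itertools.combinations(between_factors, r):
            Xb_blocks["*".join(combo)] = _interaction(*(coded[f] for f in combo))
    Xb_cols = [np.ones((n_subj, 1))] + list(Xb_blocks.values())
    Xb = np.hstack(Xb_cols)
    slices: dict[str, slice] = {}
    pos = 1
    for term, blk in Xb_blocks.items():
        slices[term] = slice(pos, pos + blk.shape[1])
        pos += blk.shape[1]
    yb = subj[value].to_numpy(float)
    ssb = _type3_ss(Xb, yb, slices)
    df_err_b = n_subj - Xb.shape[1]
    if df_err_b <= 0:
        raise DesignError("not enough subjects for the between-subjects test")
    ms_err_b = ssb["__resid__"] / df_err_b
    if ms_err_b <= 0:
        raise DesignError("zero between-subjects variance (singular design)")

    terms: list[TermResult] = []
    cell_means: dict[str, float] = {}
    for f in between_factors:
        for lev, m in df.groupby(f)[value].mean().items():
            cell_means[f"{f}={lev}"] = float(m)
    for term, sl in slices.items():
        df_num = sl.stop - sl.start
        F = (ssb[term] / df_num) / ms_err_b
        p = float(sps.f.sf(F, df_num, df_err_b))
        terms.append(TermResult(term, df_num, df_err_b, float(F), p))

    gg_eps = None
    if k > 1:
        # within part: subject-centred responses against strategy terms
        df = df.merge(
            subj.rename(columns={value: "_subj_mean"})[["rat_id", "_subj_mean"]],
            on="rat_id",
        )
        w = (df[value] - df["_subj_mean"]).to_numpy(float)
        strat_cols, _ = _sum_code(df["strategy"])
        coded_full = {f: _sum_code(df[f])[0] for f in between_factors}
        Xw_blocks: dict[str, np.ndarray] = {"strategy": strat_cols}
        for r in range(1, len(between_factors) + 1):
            for combo in itertools.combinations(between_factors, r):
                name = "*".join(combo) + "*strategy"
                Xw_blocks[name] = _interaction(
                    *(coded_full[f] for f in combo), strat_cols
                )
        Xw_cols = [np.ones((len(df), 1))] + [
            _interaction(*(coded_full[f] for f in combo))
            for r in range(1, len(between_factors) + 1)
            for combo in itertools.combinations(between_factors, r)
        ] + list(Xw_blocks.values())
        Xw = np.hstack(Xw_cols)
        wpos = Xw.shape[1] - sum(b.shape[1] for b in Xw_blocks.values())
        wslices: dict[str, slice] = {}
        for term, blk in Xw_blocks.items():
            wslices[term] = slice(wpos, wpos + blk.shape[1])
            wpos += blk.shape[1]
        ssw = _type3_ss(Xw, w, wslices)
        n_groups = int(
            subj.groupby(between_factors).ngroups if between_factors else 1
        )
        df_err_w = (n_subj - n_groups) * (k - 1)
        if df_err_w <= 0:
            raise DesignError("not enough subjects for the within-subject test")
        ms_err_w = ssw["__resid__"] / df_err_w
        if ms_err_w <= 0:
            raise DesignError("zero within-cell variance (singular design)")

        # sphericity estimate from group-centred subject x strategy matrix
        wide = df.pivot_table(index="rat_id", columns="strategy", values=value)
        wide = wide[strategies]
        group_of = subj.set_index("rat_id")[between_factors] if between_factors else None
        centred = wide.copy()
        if between_factors:
            key = subj.set_index("rat_id")[between_factors].apply(tuple, axis=1)
            centred = wide.sub(wide.groupby(key).transform("mean"))
        else:
            centred = wide - wide.mean()
        gg_eps = _gg_epsilon(centred.to_numpy(float)) if k > 2 else 1.0

        for term, sl in wslices.items():
            df_num = sl.stop - sl.start
            F = (ssw[term] / df_num) / ms_err_w
            p = float(sps.f.sf(F, df_num, df_err_w))
            p_gg = float(sps.f.sf(F, df_num * gg_eps, df_err_w * gg_eps))
            terms.append(TermResult(term, df_num, df_err_w, float(F), p, p_gg))
        for lev, m in df.groupby("strategy")[value].mean().items():
            cell_means[f"strategy={lev}"] = float(m)

    return AnovaResult(
        method="rm_anova_2x2x3",
        terms=tuple(terms),
        cell_means=cell_means,
        gg_epsilon=gg_eps,
    )


def mixed_model_anova(
    table: pd.DataFrame, value: str = "prop_opt"
) -> AnovaResult:
    """Mixed-model analysis with a random intercept per rat.

    Handles missing rat x strategy cells (e.g. velocity without tracks).  Fixed
    effects are the full strain x sex x strategy factorial; each term is
    tested with a Wald F against containment denominator degrees of freedom
    (between terms: subjects minus between-cell parameters; within terms:
    residual observations minus strategy-involving parameters), which
    reproduces the split-plot ANOVA df on complete balanced data.
    """
    import statsmodels.api as sm

    df = table.dropna(subset=[value]).copy()
    if df.empty:
        raise DesignError("no data")
    _check_groups(df, ["strain", "sex"])

    factors = [f for f in ("strain", "sex", "strategy") if df[f].nunique() > 1]
    coded = {f: _sum_code(df[f])[0] for f in factors}
    blocks: dict[str, np.ndarray] = {}
    for r in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, r):
            blocks["*".join(combo)] = _interaction(*(coded[f] for f in combo))
    X = np.hstack([np.ones((len(df), 1))] + list(blocks.values()))
    slices: dict[str, slice] = {}
    pos = 1
    for term, blk in blocks.items():
        slices[term] = slice(pos, pos + blk.shape[1])
        pos += blk.shape[1]

    y = df[value].to_numpy(float)
    groups = df["rat_id"].to_numpy()
    model = sm.MixedLM(y, X, groups=groups)
    fit = None
    err: Exception | None = None
    # the likelihood is flat when the random-intercept variance collapses
    # to zero; fall through a few optimisers before giving up
    for method in ("lbfgs", "powell", "nm"):
        try:
            fit = model.fit(reml=True, method=method)
            break
        except Exception as exc:  # singular fit or non-identifiable design
            err = exc
    if fit is None:
        raise DesignError(f"mixed model failed to fit: {err}") from err

    n_subj = df["rat_id"].nunique()
    n_obs = len(df)
    q_between = 1 + sum(
        blocks[t].shape[1] for t in blocks if "strategy" not in t
    )
    q_within = sum(blocks[t].shape[1] for t in blocks if "strategy" in t)

    k_fe = X.shape[1]
    beta = fit.fe_params
    cov = np.asarray(fit.cov_params())[:k_fe, :k_fe]

    terms: list[TermResult] = []
    for term, sl in slices.items():
        b = np.asarray(beta)[sl]
        V = cov[sl, sl]
        df_num = sl.stop - sl.start
        chi2 = float(b @ np.linalg.solve(V, b))
        F = chi2 / df_num
        if "strategy" in term:
            df_den = float(n_obs - n_subj - q_within)
        else:
            df_den = float(n_subj - q_between)
        if df_den <= 0:
            raise DesignError(f"no denominator df for term {term}")
        p = float(sps.f.sf(F, df_num, df_den))
        terms.append(TermResult(term, df_num, df_den, F, p))

    cell_means = {
        f"{f}={lev}": float(m)
        for f in factors
        for lev, m in df.groupby(f)[value].mean().items()
    }
    return AnovaResult(
        method="mixed_model_anova", terms=tuple(terms), cell_means=cell_means
    )


def between_anova_2x2(
    table: pd.DataFrame, value: str = "pct_hypertrophic"
) -> AnovaResult:
    """Two-way between-subjects ANOVA (strain, sex, strain x sex).

    One value per rat; Type III sums of squares so unequal cell counts
    (typical of per-region animal counts after tissue exclusions) are handled.
    """
    df = table.dropna(subset=[value]).copy()
    if df.empty:
        raise DesignError("no data")
    _check_groups(df, ["strain", "sex"])

    a, _ = _sum_code(df["strain"])
    b, _ = _sum_code(df["sex"])
    blocks = {"strain": a, "sex": b, "strain*sex": _interaction(a, b)}
    X = np.hstack([np.ones((len(df), 1))] + list(blocks.values()))
    slices = {}
    pos = 1
    for term, blk in blocks.items():
        slices[term] = slice(pos, pos + blk.shape[1])
        pos += blk.shape[1]
    y = df[value].to_numpy(float)
    ss = _type3_ss(X, y, slices)
    df_err = len(df) - X.shape[1]
    if df_err <= 0:
        raise DesignError("not enough rats for the between-subjects ANOVA")
    ms_err = ss["__resid__"] / df_err
    if ms_err <= 0:
        raise DesignError("zero residual variance")

    terms = []
    for term, sl in slices.items():
        df_num = sl.stop - sl.start
        F = (ss[term] / df_num) / ms_err
        p = float(sps.f.sf(F, df_num, df_err))
        terms.append(TermResult(term, df_num, df_err, float(F), p))
    cell_means = {
        f"strain={s},sex={x}": float(m)
        for (s, x), m in df.groupby(["strain", "sex"])[value].mean().items()
    }
    return AnovaResult(
        method="between_anova_2x2", terms=tuple(terms), cell_means=cell_means
    )
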