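"""Trial statistics: treatment ANOVA, grouped Pearson tables, forward
stepwise yield regression with variance portions, and the isotope
delta-notation utility.

The analysis layer mirrors a standard fertilization-trial workflow: a
one-way treatment ANOVA per trait with group means ± standard errors;
Pearson correlations of every remote-sensing index against grain yield (or
leaf phosphorus) within each treatment arm and with both arms pooled
("Combined"); and a forward stepwise multiple regression of yield on a
candidate index set with partial-F entry (p-to-enter, default alpha 0.05,
no removal step).  "Portion of variance" per selected term is the
LMG decomposition — incremental R² averaged over all entry orderings —
normalized to sum to one; a simpler normalized squared standardized
coefficient option is available.  Two-sided p-values throughout; no
multiple-testing correction.  Missing values are dropped pairwise per
correlation cell and listwise per regression.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .records import PlotRecord, TREATMENTS

__all__ = [
    "AnovaResult", "GroupStats", "StepwiseResult",
    "treatment_anova", "pearson_table", "forward_stepwise",
    "variance_portions", "delta_notation", "significance_stars",
]


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.to_row() if isinstance(r, PlotRecord) else dict(r)
                         for r in records])


def significance_stars(p: float) -> str:
    """Footnote stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# ANOVA


@dataclass(frozen=True)
class GroupStats:
    mean: float
    se: float
    n: int


@dataclass(frozen=True)
class AnovaResult:
    trait: str
    f_stat: float
    p_value: float
    groups: dict[str, GroupStats]


def treatment_anova(records, trait: str, group_col: str = "treatment") -> AnovaResult:
    """One-way (treatment) ANOVA of a trait, with group means ± SE.

    Requires at least two complete observations per level.  F and p come
    from the classical between/within mean-square ratio.
    """
    df = _as_frame(records)
    if trait not in df.columns:
        raise KeyError(f"trait {trait!r} not in table")
    groups = []
    stats: dict[str, GroupStats] = {}
    for level, sub in df.groupby(group_col, sort=True):
        vals = pd.to_numeric(sub[trait], errors="coerce").dropna().to_numpy(float)
        if len(vals) < 2:
            raise ValueError(f"level {level!r} has fewer than 2 observations of {trait!r}")
        stats[str(level)] = GroupStats(mean=float(vals.mean()),
                                       se=float(vals.std(ddof=1) / math.sqrt(len(vals))),
                                       n=len(vals))
        groups.append(vals)
    if len(groups) < 2:
        raise ValueError("need at least two levels")
    f, p = sps.f_oneway(*groups)
    return AnovaResult(trait=trait, f_stat=float(f), p_value=float(p), groups=stats)


# ---------------------------------------------------------------------------
# Pearson correlation tables


def pearson_table(records, index_columns, target_column: str,
                  group_col: str = "treatment",
                  groups=(*TREATMENTS, "Combined")) -> pd.DataFrame:
    """Pearson r/p/n of each index against a target, per group.

    ``"Combined"`` pools all rows without adjustment.  Pairs with a missing
    value are dropped pairwise; a cell with fewer than 3 complete pairs is
    reported as NaN (flagged unavailable, never fabricated), with its n
    recorded.  Returns a DataFrame indexed by the index columns with a
    (group, statistic) column MultiIndex.
    """
    df = _as_frame(records)
    if target_column not in df.columns:
        raise KeyError(f"target {target_column!r} not in table")
    out: dict[tuple[str, str], list[float]] = {}
    for group in groups:
        sub = df if group == "Combined" else df[df[group_col] == group]
        y_all = pd.to_numeric(sub[target_column], errors="coerce")
        rs, ps, ns = [], [], []
        for col in index_columns:
            x_all = pd.to_numeric(sub[col], errors="coerce") if col in sub.columns \
                else pd.Series(np.nan, index=sub.index)
            ok = x_all.notna() & y_all.notna()
            n = int(ok.sum())
            if n < 3 or x_all[ok].nunique() < 2 or y_all[ok].nunique() < 2:
                rs.append(math.nan)
                ps.append(math.nan)
            else:
                r, p = sps.pearsonr(x_all[ok], y_all[ok])
                rs.append(float(r))
                ps.append(float(p))
            ns.append(n)
        out[(group, "r")] = rs
        out[(group, "p")] = ps
        out[(group, "n")] = ns
    table = pd.DataFrame(out, index=list(index_columns))
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["group", "stat"])
    table.index.name = "index"
    return table


# ---------------------------------------------------------------------------
# forward stepwise regression


def _ols(X: np.ndarray, y: np.ndarray):
    """Least squares with intercept; returns (coefs, residual SS, rank)."""
    n = len(y)
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    coefs, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coefs
    return coefs, float(resid @ resid), rank


def _r_squared(X: np.ndarray, y: np.ndarray) -> float:
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 0.0
    _, rss, _ = _ols(X, y)
    return 1.0 - rss / tss


@dataclass(frozen=True)
class StepwiseResult:
    """Fitted forward-stepwise model."""

    response: str
    terms: tuple[str, ...]
    coefficients: dict[str, float]   # per-term slopes
    intercept: float
    r_squared: float
    rse: float                       # residual standard error
    model_p_value: float
    portions: dict[str, float]       # per-term portion of variance, sums to 1
    coefficient_se: dict[str, float] = field(default_factory=dict)
    entry_p_values: dict[str, float] = field(default_factory=dict)
    n_obs: int = 0

    @property
    def intercept_only(self) -> bool:
        return not self.terms

    def equation(self, precision: int = 2) -> str:
        parts = []
        for t in self.terms:
            c = self.coefficients[t]
            parts.append(f"{'- ' if c < 0 and parts else ('-' if c < 0 else ('+ ' if parts else ''))}"
                         f"{abs(c):.{precision}f}*{t} ")
        sign = "+ " if self.intercept >= 0 and parts else ("- " if parts else "")
        const = f"{sign}{abs(self.intercept):.{precision}f}" if parts \
            else f"{self.intercept:.{precision}f}"
        return f"{self.response} = " + "".join(parts) + const


def forward_stepwise(records, response: str, candidates,
                     alpha_enter: float = 0.05) -> StepwiseResult:
    """Forward stepwise multiple regression with partial-F entry.

    At each step the candidate with the smallest partial-F p-value (the
    two-sided t-test of its coefficient in the augmented model) enters if
    that p-value is below ``alpha_enter``; the model is refit after every
    entry and there is no removal step.  If no candidate qualifies, the
    result is the intercept-only model (flagged via ``intercept_only``).
    Rows with any missing value among response and candidates are dropped
    listwise.
    """
    df = _as_frame(records)
    cols = [response, *candidates]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    data = df[cols].apply(pd.to_numeric, errors="coerce").dropna()
    n = len(data)
    if n < 3:
        raise ValueError(f"need at least 3 complete records, got {n}")
    y = data[response].to_numpy(float)

    terms: list[str] = []
    entry_p: dict[str, float] = {}
    remaining = [c for c in candidates if data[c].nunique() > 1]
    tss = float(((y - y.mean()) ** 2).sum())
    while remaining and n >= len(terms) + 3:
        if terms:
            # stop once the current model is numerically saturated: partial-F
            # tests on residual rounding noise would admit arbitrary terms
            _, rss_now, _ = _ols(data[terms].to_numpy(float), y)
            if tss == 0 or rss_now <= 1e-10 * tss:
                break
        best_p, best_cand = math.inf, None
        for cand in remaining:
            X = data[[*terms, cand]].to_numpy(float)
            design = np.column_stack([np.ones(n), X])
            coefs, rss, rank = _ols(X, y)
            dof = n - design.shape[1]
            if rank < design.shape[1] or dof <= 0 or rss <= 0:
                continue  # collinear with current model or saturated fit
            xtx_inv = np.linalg.inv(design.T @ design)
            se = math.sqrt(rss / dof * xtx_inv[-1, -1])
            if se == 0:
                continue
            t = coefs[-1] / se
            p = 2.0 * sps.t.sf(abs(t), dof)
            if p < best_p:
                best_p, best_cand = p, cand
        if best_cand is None or not (best_p < alpha_enter):
            break
        terms.append(best_cand)
        entry_p[best_cand] = best_p
        remaining.remove(best_cand)

    if terms:
        design = sm.add_constant(data[terms].to_numpy(float))
        fit = sm.OLS(y, design).fit()
        dof = n - len(terms) - 1
        rse = math.sqrt(fit.ssr / dof) if dof > 0 else math.nan
        model_p = 0.0 if fit.ssr <= 0 else float(fit.f_pvalue)
        portions = variance_portions(data, response, terms)
        return StepwiseResult(
            response=response, terms=tuple(terms),
            coefficients={t_: float(fit.params[i + 1]) for i, t_ in enumerate(terms)},
            intercept=float(fit.params[0]), r_squared=float(fit.rsquared),
            rse=float(rse), model_p_value=model_p, portions=portions,
            coefficient_se={t_: float(fit.bse[i + 1]) for i, t_ in enumerate(terms)},
            entry_p_values=entry_p, n_obs=n,
        )
    return StepwiseResult(
        response=response, terms=(), coefficients={}, intercept=float(y.mean()),
        r_squared=0.0, rse=float(y.std(ddof=1)) if n > 1 else math.nan,
        model_p_value=math.nan, portions={}, entry_p_values={}, n_obs=n,
    )


def variance_portions(records, response: str, terms,
                      method: str = "lmg") -> dict[str, float]:
    """Per-term share of a fitted model's explained variance (sums to 1).

    ``method="lmg"`` (default): each term's incremental R² averaged over all
    orderings of entry, normalized by the total R².  For orthogonal
    standardized predictors with equal coefficients this gives equal shares;
    for a single term it gives 1.0.  ``method="beta_sq"``: normalized squared
    standardized coefficients.  A design collinear to machine precision
    raises ``ValueError`` naming the terms.
    """
    terms = list(terms)
    if not terms:
        raise ValueError("variance portions need at least one term")
    if len(terms) > 10:
        raise ValueError("LMG over >10 terms is factorial; reduce the term set")
    df = _as_frame(records)
    data = df[[response, *terms]].apply(pd.to_numeric, errors="coerce").dropna()
    y = data[response].to_numpy(float)
    X = data[terms].to_numpy(float)
    n = len(y)
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"design collinear to machine precision for terms {terms}")

    if method == "beta_sq":
        sx = X.std(axis=0, ddof=1)
        sy = y.std(ddof=1)
        coefs, _, _ = _ols(X, y)
        beta2 = (coefs[1:] * sx / sy) ** 2
        total = beta2.sum()
        if total == 0:
            raise ValueError("all standardized coefficients are zero")
        return {t: float(b / total) for t, b in zip(terms, beta2)}
    if method != "lmg":
        raise ValueError("method must be 'lmg' or 'beta_sq'")

    k = len(terms)
    r2_cache: dict[frozenset, float] = {frozenset(): 0.0}

    def r2_of(subset: frozenset) -> float:
        if subset not in r2_cache:
            idx = [terms.index(t) for t in subset]
            r2_cache[subset] = _r_squared(X[:, idx], y)
        return r2_cache[subset]

    raw = {t: 0.0 for t in terms}
    perms = list(itertools.permutations(range(k)))
    for perm in perms:
        seen: frozenset = frozenset()
        for i in perm:
            t = terms[i]
            with_t = seen | {t}
            raw[t] += r2_of(with_t) - r2_of(seen)
            seen = with_t
    total = sum(raw.values())  # equals k! * R2_full
    if total <= 0:
        raise ValueError("model explains no variance; portions undefined")
    return {t: float(v / total) for t, v in raw.items()}


# ---------------------------------------------------------------------------
# isotope delta notation


def delta_notation(r_sample: float, r_standard: float) -> float:
    """Per-mil deviation of a sample isotope ratio from a standard:
    ``delta = (R_sample/R_standard - 1) * 1000``."""
    if r_standard <= 0:
        raise ValueError("standard isotope ratio must be positive")
    return (r_sample / r_standard - 1.0) * 1000.0
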