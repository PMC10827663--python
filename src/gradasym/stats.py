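"""Parcel- and network-wise inference on asymmetry indices.

The primary contrast is multivariate: the joint (G1, G2, G3) asymmetry
vector of each homolog pair is compared between groups with Hotelling's
T^2, turned into an exact F statistic. General designs (age group, group
x age-group interaction) are tested per term with the Hotelling-Lawley
trace and its standard F approximation, which reduces exactly to the
two-sample T^2 for a single two-level factor. Multiplicity: BH-FDR over
units (180 pairs, or 12 networks); post-hoc per-gradient t tests on units
surviving the multivariate gate, Bonferroni-corrected by the number of
gradients (p < alpha/3).

Sign convention for group t values: positive t = lower leftward asymmetry
in autism relative to NAI (t is computed on NAI minus autism).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .errors import DegenerateDataError, DesignError, DimensionError, ParameterError
from .io_core import CohortTable, ParcellationScheme

AGE_ORDER = ("child", "adolescent", "adult")


# ---------------------------------------------------------------------------
# Hotelling's T^2
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HotellingResult:
    T2: float
    F: float
    df1: int
    df2: int
    p: float
    ridged: bool = False


def hotelling_two_sample(
    Xa: np.ndarray, Xb: np.ndarray, ridge_fallback: bool = True
) -> HotellingResult:
    """Two-sample Hotelling T^2 with its exact F transform.

    T^2 = (n1 n2 / n) d' S_pooled^-1 d;  F = T^2 (n - p - 1) / ((n - 2) p)
    on (p, n - p - 1) df. A singular pooled covariance falls back to a
    ridge (lambda = 1e-6 tr(S)/p), flagged in the result, unless
    ``ridge_fallback`` is False, in which case it raises.
    """
    Xa = np.atleast_2d(np.asarray(Xa, dtype=float))
    Xb = np.atleast_2d(np.asarray(Xb, dtype=float))
    if Xa.shape[1] != Xb.shape[1]:
        raise DimensionError("groups must share the feature dimension")
    n1, n2, p = Xa.shape[0], Xb.shape[0], Xa.shape[1]
    n = n1 + n2
    if n <= p + 1:
        raise ParameterError(f"need n1+n2 > p+1 (got n={n}, p={p})")
    d = Xa.mean(axis=0) - Xb.mean(axis=0)
    S = ((Xa - Xa.mean(axis=0)).T @ (Xa - Xa.mean(axis=0))
         + (Xb - Xb.mean(axis=0)).T @ (Xb - Xb.mean(axis=0))) / (n - 2)
    ridged = False
    try:
        sol = np.linalg.solve(S, d)
    except np.linalg.LinAlgError:
        if not ridge_fallback:
            raise DegenerateDataError(
                "singular pooled covariance; enable the ridge fallback"
            ) from None
        lam = 1e-6 * np.trace(S) / p
        sol = np.linalg.solve(S + lam * np.eye(p), d)
        ridged = True
    T2 = float(n1 * n2 / n * d @ sol)
    df1, df2 = p, n - p - 1
    F = T2 * df2 / ((n - 2) * p)
    pval = float(sps.f.sf(F, df1, df2))
    return HotellingResult(T2=T2, F=float(F), df1=df1, df2=df2, p=pval, ridged=ridged)


def hotelling_permutation_p(
    Xa: np.ndarray, Xb: np.ndarray, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Permutation p value for the two-sample T^2 (group labels shuffled).

    Batched: per-permutation means suffice because the pooled SSCP equals
    the total SSCP minus both group-mean outer products.
    """
    Xa, Xb = np.atleast_2d(Xa), np.atleast_2d(Xb)
    X = np.vstack([Xa, Xb]).astype(float)
    n1, n = Xa.shape[0], Xa.shape[0] + Xb.shape[0]
    n2, p = n - n1, X.shape[1]
    rng = np.random.default_rng(seed)
    obs = hotelling_two_sample(Xa, Xb).T2
    total = X.sum(axis=0)
    gram = X.T @ X
    count = 0
    chunk = 2000
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        sel = np.stack([rng.permutation(n)[:n1] for _ in range(m)])
        MA = X[sel].sum(axis=1) / n1  # (m, p)
        MB = (total[None, :] - n1 * MA) / n2
        D = MA - MB
        S = (gram[None] - n1 * np.einsum("ij,ik->ijk", MA, MA)
             - n2 * np.einsum("ij,ik->ijk", MB, MB)) / (n - 2)
        sol = np.linalg.solve(S, D[..., None])[..., 0]
        t2 = n1 * n2 / n * np.einsum("ij,ij->i", D, sol)
        count += int(np.sum(t2 >= obs))
        done += m
    return (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# multivariate linear model, Hotelling-Lawley trace
# ---------------------------------------------------------------------------

def _encode_design(
    table: pd.DataFrame,
    terms: list[str],
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, list[int]]]:
    """Treatment-coded design with intercept; returns matrix and term -> columns."""
    cols = [np.ones(len(table))]
    spans: dict[str, list[int]] = {}
    idx = 1
    parts: dict[str, np.ndarray] = {}
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            block = np.stack(
                [ca * cb for ca in parts[a].T for cb in parts[b].T], axis=1
            )
        else:
            vals = table[term]
            if vals.dtype.kind in "OUSb" or str(vals.dtype) == "category":
                levels = AGE_ORDER if term == "age_group" else sorted(pd.unique(vals))
                levels = [lv for lv in levels if lv in set(vals)]
                block = np.stack(
                    [(vals == lv).to_numpy(float) for lv in levels[1:]], axis=1
                )
            else:
                block = vals.to_numpy(float)[:, None]
        parts[term] = block
        cols.append(block)
        spans[term] = list(range(idx, idx + block.shape[1]))
        idx += block.shape[1]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(table):
            cov = cov.T
        cols.append(cov)
        spans["covariates"] = list(range(idx, idx + cov.shape[1]))
    X = np.column_stack(cols)
    return X, spans


def hotelling_lawley_test(
    Y: np.ndarray, X: np.ndarray, term_cols: list[int]
) -> tuple[float, float, float, float, float]:
    """Hotelling-Lawley trace for H0: the term's coefficients are zero.

    Returns (HLT, F, df1, df2, p). Exact for s = min(p, q) = 1, otherwise
    the standard F approximation.
    """
    n, p = Y.shape
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DesignError("rank-deficient design matrix")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    E = resid.T @ resid
    df_e = n - rank
    L = np.zeros((len(term_cols), X.shape[1]))
    for i, c in enumerate(term_cols):
        L[i, c] = 1.0
    LB = L @ B
    M = L @ XtX_inv @ L.T
    H = LB.T @ np.linalg.solve(M, LB)
    q = len(term_cols)
    try:
        U = float(np.trace(np.linalg.solve(E, H)))
    except np.linalg.LinAlgError:
        lam = 1e-6 * np.trace(E) / p
        U = float(np.trace(np.linalg.solve(E + lam * np.eye(p), H)))
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (df_e - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = 2 * (s * nn + 1)
    if df2 <= 0:
        raise ParameterError("insufficient error degrees of freedom")
    F = df2 * U / (s * df1)
    pval = float(sps.f.sf(F, df1, df2))
    return U, float(F), float(df1), float(df2), pval


def mglm_terms(
    Y: np.ndarray,
    table: pd.DataFrame,
    terms: list[str],
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-term Hotelling-Lawley tests in a multivariate linear model."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != len(table):
        raise DimensionError("Y must be subjects x p matching the table")
    X, spans = _encode_design(table, terms, covariates)
    rows = []
    for term in terms:
        U, F, df1, df2, p = hotelling_lawley_test(Y, X, spans[term])
        rows.append({"term": term, "HLT": U, "F": F, "df1": df1, "df2": df2, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# univariate post-hoc and multiplicity
# ---------------------------------------------------------------------------

def posthoc_t(ya: np.ndarray, yb: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample t (first group minus second) and its p."""
    res = sps.ttest_ind(np.asarray(ya, float), np.asarray(yb, float), equal_var=True)
    return float(res.statistic), float(res.pvalue)


def p_adjust(
    pvals: np.ndarray, method: str = "bh_fdr", q_or_alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicity flags and adjusted p values over the supplied family.

    'bh_fdr' is the Benjamini-Hochberg step-up; 'bonferroni' multiplies by
    the family size (capped at 1).
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p values must lie in [0, 1]")
    mm = {"bh_fdr": "fdr_bh", "bonferroni": "bonferroni"}
    if method not in mm:
        raise ParameterError(f"unknown method {method!r}")
    reject, p_adj, *_ = multipletests(p, alpha=q_or_alpha, method=mm[method])
    return reject, p_adj


# ---------------------------------------------------------------------------
# pipeline-level group statistics
# ---------------------------------------------------------------------------

def _unit_tables(
    ai: np.ndarray, scheme: ParcellationScheme, level: str
) -> tuple[np.ndarray, list]:
    """AI per unit: (subjects, units, g). Units are pairs or networks."""
    if level == "pair":
        return ai, list(range(ai.shape[1]))
    nets = scheme.pair_networks
    units, mats = [], []
    for net in scheme.networks:
        members = nets == net
        if members.any():
            units.append(net)
            mats.append(ai[:, members, :].mean(axis=1))
    return np.stack(mats, axis=1), units


def group_contrast_table(
    ai: np.ndarray,
    cohort: CohortTable,
    scheme: ParcellationScheme,
    config: PipelineConfig,
    level: str = "pair",
    pattern: str = "intra",
) -> pd.DataFrame:
    """Group (NAI vs autism) multivariate test per unit with gated post-hoc.

    BH-FDR over the units; per-gradient pooled t (NAI minus autism, so
    positive t = lower leftward asymmetry in autism) evaluated at
    p < alpha / k only on units passing the multivariate gate.
    """
    t = cohort.table
    groups = np.asarray(t["group"])
    Y, units = _unit_tables(ai, scheme, level)
    a_rows = groups == "NAI"
    b_rows = groups == "autism"
    k = Y.shape[2]
    recs = []
    for u in range(Y.shape[1]):
        hr = hotelling_two_sample(Y[a_rows, u, :], Y[b_rows, u, :])
        rec = {
            "unit": units[u], "pattern": pattern, "level": level,
            "T2": hr.T2, "F": hr.F, "df1": hr.df1, "df2": hr.df2, "p": hr.p,
        }
        for g in range(k):
            tg, pg = posthoc_t(Y[a_rows, u, g], Y[b_rows, u, g])
            rec[f"t_G{g+1}"] = tg
            rec[f"p_G{g+1}"] = pg
        recs.append(rec)
    out = pd.DataFrame(recs)
    q = config.multiple_testing.fdr_q
    kb = config.multiple_testing.posthoc_bonferroni_k
    out["sig_fdr"], out["p_fdr"] = p_adjust(out["p"].to_numpy(), "bh_fdr", q)
    for g in range(k):
        out[f"sig_G{g+1}"] = out["sig_fdr"] & (out[f"p_G{g+1}"] < q / kb)
    return out


def interaction_table(
    ai: np.ndarray,
    cohort: CohortTable,
    scheme: ParcellationScheme,
    config: PipelineConfig,
    level: str = "pair",
    pattern: str = "intra",
) -> pd.DataFrame:
    """Group x age-group interaction per unit (Hotelling-Lawley), FDR over units.

    If the factorial design is rank deficient (an empty group x age-group
    cell, possible in small cohorts), the tests are undefined: the table is
    returned with NaN statistics and no significance flags, rather than
    failing the whole run.
    """
    t = cohort.table
    Y, units = _unit_tables(ai, scheme, level)
    X, _ = _encode_design(t, ["group", "age_group", "group:age_group"])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        out = pd.DataFrame(
            {
                "unit": units, "pattern": pattern, "level": level,
                "HLT": np.nan, "F": np.nan, "df1": np.nan, "df2": np.nan,
                "p": np.nan, "sig_fdr": False, "p_fdr": np.nan,
            }
        )
        return out
    recs = []
    for u in range(Y.shape[1]):
        res = mglm_terms(Y[:, u, :], t, ["group", "age_group", "group:age_group"])
        inter = res[res["term"] == "group:age_group"].iloc[0]
        recs.append(
            {
                "unit": units[u], "pattern": pattern, "level": level,
                "HLT": inter["HLT"], "F": inter["F"],
                "df1": inter["df1"], "df2": inter["df2"], "p": inter["p"],
            }
        )
    out = pd.DataFrame(recs)
    out["sig_fdr"], out["p_fdr"] = p_adjust(
        out["p"].to_numpy(), "bh_fdr", config.multiple_testing.fdr_q
    )
    return out


def age_contrast_table(
    ai: np.ndarray,
    cohort: CohortTable,
    scheme: ParcellationScheme,
    config: PipelineConfig,
    within_group: str,
    level: str = "network",
    pattern: str = "intra",
) -> pd.DataFrame:
    """Pairwise age-group comparisons within one diagnostic group.

    Bonferroni over the three age-group pairs (p < alpha / 3), following
    the multivariate test per unit.
    """
    t = cohort.table
    rows = np.asarray(t["group"]) == within_group
    Y, units = _unit_tables(ai[rows], scheme, level)
    ages = np.asarray(t["age_group"])[rows]
    pairs = [("child", "adolescent"), ("child", "adult"), ("adolescent", "adult")]
    alpha = config.multiple_testing.fdr_q
    recs = []
    for u in range(Y.shape[1]):
        for ga, gb in pairs:
            a_rows, b_rows = ages == ga, ages == gb
            if a_rows.sum() < 4 or b_rows.sum() < 4:
                continue
            hr = hotelling_two_sample(Y[a_rows, u, :], Y[b_rows, u, :])
            recs.append(
                {
                    "unit": units[u], "pattern": pattern, "level": level,
                    "group": within_group, "contrast": f"{ga}_vs_{gb}",
                    "T2": hr.T2, "F": hr.F, "p": hr.p,
                    "sig_bonf": hr.p < alpha / len(pairs),
                }
            )
    return pd.DataFrame(recs)


def group_pipeline(
    ai_by_pattern: dict[str, np.ndarray],
    cohort: CohortTable,
    scheme: ParcellationScheme,
    config: PipelineConfig,
) -> dict[str, pd.DataFrame]:
    """All contrasts for both patterns at parcel and network level."""
    out: dict[str, pd.DataFrame] = {}
    for pattern, ai in ai_by_pattern.items():
        for level in ("pair", "network"):
            out[f"group_{pattern}_{level}"] = group_contrast_table(
                ai, cohort, scheme, config, level=level, pattern=pattern
            )
            out[f"interaction_{pattern}_{level}"] = interaction_table(
                ai, cohort, scheme, config, level=level, pattern=pattern
            )
        for grp in ("autism", "NAI"):
            out[f"age_{grp}_{pattern}_network"] = age_contrast_table(
                ai, cohort, scheme, config, within_group=grp,
                level="network", pattern=pattern,
            )
    return out
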