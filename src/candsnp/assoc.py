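"""Fixed-effects litter-size model and compact letter displays.

The litter-size phenotype ``Y`` of ewe ``n`` with parity ``i`` and genotype
``j`` is decomposed as

    Y_ijn = mu + P_i + G_j + I_ij + e_ijn,     e ~ N(0, sigma^2)

with parity (1-3) and genotype as fixed effects plus their interaction,
fitted by ordinary least squares.  Litter size in this breed is essentially
binary (1 or 2 lambs), so the Gaussian error model is an approximation; the
linear model is nevertheless the standard analysis for this design and a
logistic alternative on the twin indicator is available.

Term tests are Type III F tests: with sum-to-zero (effects) coding, each
term's sum of squares is the SSE increase from deleting that term's columns
from the full design.  Empty parity x genotype cells simply drop unestimable
interaction columns (pinv-based fitting), which is logged.

Group comparisons are reported as compact letter displays: all pairwise
two-sided t tests on a pooled residual variance, letters built greedily from
the sorted means so that groups differing at ``p < alpha`` never share a
letter ('a' marks the highest mean, as in printed association tables).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GLMFit:
    """Least-squares decomposition with Type III F tests."""

    anova: pd.DataFrame        # index: term; columns: ss, df, F, p
    n: int
    rank: int
    residual_df: int
    sigma2: float
    cell_means: pd.DataFrame   # parity x genotype means (NaN for empty cells)
    genotype_means: pd.DataFrame  # marginal per-genotype n / mean / sd / sem
    dropped_columns: int       # unestimable design columns removed


def _effects_columns(labels: pd.Series, levels: list) -> np.ndarray:
    """Sum-to-zero (effects) coding: k-1 columns, last level coded -1."""
    n, k = len(labels), len(levels)
    X = np.zeros((n, k - 1))
    idx = {lev: i for i, lev in enumerate(levels)}
    codes = labels.map(idx).to_numpy()
    for col in range(k - 1):
        X[codes == col, col] = 1.0
    X[codes == k - 1, :] = -1.0
    return X


def _sse(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and design rank via pinv-based least squares."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def fit_litter_model(
    table: pd.DataFrame,
    response: str = "litter_size",
    include_interaction: bool = True,
) -> GLMFit:
    """Fit the parity + genotype (+ interaction) model to a joined table.

    ``table`` must carry ``genotype``, ``parity`` and the response column
    (the output of :func:`candsnp.io.join_genotypes_phenotypes`).
    """
    table = table.copy()
    g_levels = sorted(table["genotype"].unique())
    p_levels = sorted(table["parity"].unique())
    if len(g_levels) < 2:
        raise ValueError(
            "only one genotype level present; use genotype_means for a "
            "descriptive summary instead of the fixed-effects model"
        )
    y = table[response].to_numpy(dtype=float)
    n = len(y)
    ones = np.ones((n, 1))
    P = _effects_columns(table["parity"], p_levels) if len(p_levels) > 1 else np.zeros((n, 0))
    G = _effects_columns(table["genotype"], g_levels)
    if include_interaction and P.shape[1] and G.shape[1]:
        PG = np.column_stack([P[:, i] * G[:, j] for i in range(P.shape[1])
                              for j in range(G.shape[1])])
    else:
        PG = np.zeros((n, 0))

    blocks = {"parity": P, "genotype": G, "interaction": PG}
    X_full = np.column_stack([ones, P, G, PG])

    # drop unestimable columns (empty cells make interaction columns collinear)
    full_rank = np.linalg.matrix_rank(X_full)
    dropped = X_full.shape[1] - full_rank
    if dropped:
        logger.info("design rank deficient: %d unestimable columns (empty cells)", dropped)

    model = sm.OLS(y, X_full).fit()
    sse_full = float(model.ssr)
    residual_df = n - full_rank
    sigma2 = sse_full / residual_df if residual_df > 0 else 0.0

    rows = {}
    for term, B in blocks.items():
        if B.shape[1] == 0:
            continue
        keep = [b for t, b in blocks.items() if t != term]
        X_red = np.column_stack([ones] + keep)
        sse_red, rank_red = _sse(y, X_red)
        df_term = full_rank - rank_red
        ss_term = max(sse_red - sse_full, 0.0)
        if df_term <= 0:
            rows[term] = dict(ss=ss_term, df=0, F=np.nan, p=np.nan)
            continue
        if sse_full <= 1e-12 * max(1.0, float(y @ y)):
            # degenerate: zero residual variance (e.g. all responses equal)
            F = 0.0 if ss_term <= 1e-12 else np.inf
            p = 1.0 if F == 0.0 else 0.0
        else:
            F = (ss_term / df_term) / sigma2
            p = float(stats.f.sf(F, df_term, residual_df))
        rows[term] = dict(ss=ss_term, df=df_term, F=float(F), p=p)
    anova = pd.DataFrame(rows).T[["ss", "df", "F", "p"]]

    cell = table.pivot_table(index="parity", columns="genotype", values=response,
                             aggfunc="mean")
    gm = _group_summary(table, "genotype", response)
    return GLMFit(
        anova=anova, n=n, rank=full_rank, residual_df=residual_df, sigma2=sigma2,
        cell_means=cell, genotype_means=gm, dropped_columns=dropped,
    )


def _group_summary(table: pd.DataFrame, by: str, response: str) -> pd.DataFrame:
    grp = table.groupby(by)[response]
    out = pd.DataFrame(
        {
            "n": grp.size(),
            "mean": grp.mean(),
            "sd": grp.std(ddof=1).fillna(0.0),
        }
    )
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out


def pairwise_letters(
    groups: list[tuple[str, np.ndarray]],
    alpha: float = 0.05,
    variance: str = "pooled",
) -> dict[str, str]:
    """Compact letter display from all pairwise two-sided t tests.

    ``variance="pooled"`` uses the one-way residual variance with N - k
    degrees of freedom (matching the fitted linear model); ``"welch"`` uses
    per-pair Welch tests and falls back to pooled (with a warning) when any
    group has fewer than 2 observations.  Letters are assigned greedily over
    means sorted in descending order; groups significantly different at
    ``alpha`` never share a letter.
    """
    labels = [lab for lab, _ in groups]
    values = [np.asarray(v, dtype=float) for _, v in groups]
    if len(groups) < 2 or any(len(v) < 1 for v in values):
        raise ValueError("need >=2 groups with >=1 value each")
    if variance == "welch" and any(len(v) < 2 for v in values):
        warnings.warn("group with n < 2: Welch unavailable, falling back to pooled variance")
        variance = "pooled"
    means = np.array([v.mean() for v in values])
    ns = np.array([len(v) for v in values])
    k = len(groups)
    pmat = np.ones((k, k))
    if variance == "pooled":
        N = int(ns.sum())
        df = N - k
        ss_within = sum(float(((v - v.mean()) ** 2).sum()) for v in values)
        s2 = ss_within / df if df > 0 else 0.0
        for i in range(k):
            for j in range(i + 1, k):
                if s2 <= 0:
                    p = 1.0 if np.isclose(means[i], means[j]) else 0.0
                else:
                    se = np.sqrt(s2 * (1 / ns[i] + 1 / ns[j]))
                    t = (means[i] - means[j]) / se
                    p = 2 * float(stats.t.sf(abs(t), df))
                pmat[i, j] = pmat[j, i] = p
    else:
        for i in range(k):
            for j in range(i + 1, k):
                p = float(stats.ttest_ind(values[i], values[j], equal_var=False).pvalue)
                pmat[i, j] = pmat[j, i] = p
    return letters_from_pmatrix(labels, means, pmat, alpha)


def letters_from_pmatrix(
    labels: list[str], means: np.ndarray, pmat: np.ndarray, alpha: float = 0.05
) -> dict[str, str]:
    """Greedy insert-absorb letter assignment from a pairwise p-value matrix.

    Maximal windows of mean-sorted groups that are pairwise non-significant
    each receive one letter; a group's display is the sorted concatenation of
    the letters of the windows containing it.
    """
    order = np.argsort(-np.asarray(means), kind="stable")
    k = len(labels)
    sig = pmat < alpha
    windows: list[tuple[int, int]] = []  # [start, end] inclusive, in sorted order
    for i in range(k):
        j = i
        while j + 1 < k and not any(
            sig[order[a], order[b]] for a in range(i, j + 2) for b in range(a + 1, j + 2)
        ):
            j += 1
        if not windows or j > windows[-1][1]:  # keep maximal windows only
            windows.append((i, j))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assigned: dict[str, list[str]] = {lab: [] for lab in labels}
    for w, (start, end) in enumerate(windows):
        letter = alphabet[w % len(alphabet)]
        for pos in range(start, end + 1):
            assigned[labels[order[pos]]].append(letter)
    return {lab: "".join(sorted(set(ls))) for lab, ls in assigned.items()}


def genotype_means(
    table: pd.DataFrame,
    alpha: float = 0.05,
    all_genotypes: list[str] | None = None,
    variance: str = "pooled",
    response: str = "litter_size",
) -> pd.DataFrame:
    """Per-genotype n / mean / SD / SEM with significance letters.

    ``all_genotypes`` adds zero rows ("0.00 +/- 0.00", no letter) for
    genotype classes absent from the data, matching report conventions for
    unobserved homozygotes.  Both SD and SEM are carried; report writers
    choose (and label) their dispersion column.
    """
    if table.empty:
        raise ValueError("empty association table")
    summary = _group_summary(table, "genotype", response)
    observed = list(summary.index)
    if len(observed) >= 2:
        groups = [(g, table.loc[table["genotype"] == g, response].to_numpy())
                  for g in observed]
        letters = pairwise_letters(groups, alpha=alpha, variance=variance)
    else:
        letters = {observed[0]: "a"}
    summary["letters"] = [letters[g] for g in summary.index]
    if all_genotypes:
        for g in all_genotypes:
            if g not in summary.index:
                summary.loc[g] = {"n": 0, "mean": 0.0, "sd": 0.0, "sem": 0.0, "letters": ""}
        summary = summary.loc[[g for g in all_genotypes]]
    summary["n"] = summary["n"].astype(int)
    summary.index.name = "genotype"
    return summary


def fit_twin_logit(table: pd.DataFrame, response: str = "litter_size"):
    """Optional logistic alternative: P(litter >= 2) ~ parity + genotype.

    Returns the fitted statsmodels results object.  Off the default path;
    the linear model above is the standard analysis for this design.
    """
    y = (table[response] >= 2).astype(float)
    X = pd.get_dummies(table[["parity", "genotype"]].astype(str), drop_first=True)
    X = sm.add_constant(X.astype(float))
    return sm.Logit(y, X).fit(disp=False)
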