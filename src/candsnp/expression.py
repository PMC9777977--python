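"""Relative qPCR quantification by the 2^-ddCt method.

Per animal and tissue, technical replicates are averaged first, then

    dCt   = Ct_target - Ct_reference            (per animal, per tissue)
    ddCt  = dCt - mean dCt of the calibrator tissue
    fold  = 2^-ddCt                             (per animal)

assuming perfect doubling per cycle (no efficiency correction).  Unless a
calibrator is named, the tissue with the highest mean dCt (lowest relative
expression) is used, which only rescales the fold axis.

Two tissue summaries are reported: ``fold_point = 2^(-mean ddCt)`` (exactly 1
at the calibrator by construction) and the arithmetic mean +/- SEM of the
per-animal folds (the conventional bar-plot summary; >= 1 at the calibrator
by Jensen's inequality).  Tissue-level comparison is a one-way ANOVA on the
per-animal folds followed by a compact letter display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import pairwise_letters
from .io import validate_ct


@dataclass
class RelativeExpression:
    """Per-tissue fold changes for one target gene vs a reference gene."""

    target: str
    reference: str
    calibrator: str
    per_animal: pd.DataFrame  # columns: animal, tissue, dct, ddct, fold
    summary: pd.DataFrame     # index tissue: dct_mean, ddct, fold_point, fold_mean, fold_sem, n


def relative_expression(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    calibrator: str | None = None,
    replicate_agg: str = "mean",
) -> RelativeExpression:
    """2^-ddCt fold changes of ``target`` normalised to ``reference``.

    ``replicate_agg`` is ``"mean"`` (default) or ``"median"`` over technical
    replicates.  Cells lacking the reference gene are dropped with a warning;
    a missing calibrator tissue is an error.
    """
    ct = validate_ct(ct)
    agg = {"mean": "mean", "median": "median"}[replicate_agg]
    cell = (
        ct[ct["gene"].isin([target, reference])]
        .groupby(["animal", "tissue", "gene"])["ct"]
        .agg(agg)
        .unstack("gene")
    )
    if target not in cell.columns:
        raise ValueError(f"target gene {target!r} absent from Ct table")
    if reference not in cell.columns:
        raise ValueError(f"reference gene {reference!r} absent from Ct table")
    incomplete = cell[target].isna() | cell[reference].isna()
    if incomplete.any():
        warnings.warn(
            f"dropping {int(incomplete.sum())} (animal, tissue) cells lacking "
            f"{target!r} or {reference!r} measurements"
        )
        cell = cell[~incomplete]
    per = cell.reset_index()
    per["dct"] = per[target] - per[reference]
    tissue_dct = per.groupby("tissue")["dct"].mean()
    if calibrator is None:
        calibrator = tissue_dct.idxmax()  # lowest-expressed tissue
    elif calibrator not in tissue_dct.index:
        raise ValueError(f"calibrator tissue {calibrator!r} absent from Ct table")
    per["ddct"] = per["dct"] - tissue_dct[calibrator]
    per["fold"] = 2.0 ** (-per["ddct"])
    grp = per.groupby("tissue")
    summary = pd.DataFrame(
        {
            "n": grp["fold"].size(),
            "dct_mean": grp["dct"].mean(),
            "ddct": grp["ddct"].mean(),
            "fold_mean": grp["fold"].mean(),
            "fold_sem": grp["fold"].sem(ddof=1),
        }
    )
    summary["fold_point"] = 2.0 ** (-summary["ddct"])
    summary = summary[["n", "dct_mean", "ddct", "fold_point", "fold_mean", "fold_sem"]]
    per_animal = per[["animal", "tissue", "dct", "ddct", "fold"]]
    return RelativeExpression(
        target=target, reference=reference, calibrator=str(calibrator),
        per_animal=per_animal, summary=summary,
    )


def tissue_comparison(rel: RelativeExpression, alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA across tissues on per-animal folds, plus letters.

    Returns the summary table with a ``letters`` column; the overall ANOVA F
    and p are attached as DataFrame attrs (``anova_F``, ``anova_p``).
    """
    groups = [
        (tissue, sub["fold"].to_numpy())
        for tissue, sub in rel.per_animal.groupby("tissue")
    ]
    if len(groups) < 2:
        raise ValueError("need >=2 tissues for a tissue comparison")
    if any(len(v) < 2 for _, v in groups):
        raise ValueError("every tissue needs >=2 animals (no within-group variance otherwise)")
    F, p = stats.f_oneway(*[v for _, v in groups])
    letters = pairwise_letters(groups, alpha=alpha, variance="pooled")
    out = rel.summary.copy()
    out["letters"] = [letters[t] for t in out.index]
    out.attrs["anova_F"] = float(F)
    out.attrs["anova_p"] = float(p)
    return out
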