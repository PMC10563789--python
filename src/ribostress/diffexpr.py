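"""Differential expression on count matrices.

The stage follows the selection rules of the stress/depression contrasts it
re-creates: low-count genes are removed before testing, nuisance covariates
(age, RNA integrity, ...) are regressed out of log-CPM values, a Welch
two-sample t test compares stress vs control per gene, p-values are
Benjamini-Hochberg corrected, and significance is thresholded either on raw
p (human MDD-style contrasts) or on q (mouse chronic-stress-style
contrasts).

The Welch-on-adjusted-log-CPM test is a documented stand-in for a full NB
GLM fit; externally computed DE tables (TSV with gene, log2FC, p, q) are
accepted anywhere a DETable is, so real DESeq2 output can be dropped in.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts import CountMatrix

logger = logging.getLogger(__name__)

P_MODE, Q_MODE = "p_threshold", "q_threshold"
DE_COLUMNS = ["log2FC", "p", "q", "direction"]


def filter_low_counts(cm: CountMatrix, threshold: float = 5.0, mode: str = "mean") -> CountMatrix:
    """Drop genes with mean count across all samples <= threshold (inclusive).

    ``mode="row_sum"`` instead drops genes whose total count is <= threshold;
    both readings of the low-count rule are provided, mean being the default.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if mode == "mean":
        stat = cm.counts.mean(axis=1)
    elif mode == "row_sum":
        stat = cm.counts.sum(axis=1)
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    keep = stat > threshold
    if not keep.any():
        warnings.warn("low-count filter removed every gene")
    return CountMatrix(counts=cm.counts.loc[keep], meta=cm.meta)


def normalize_log_cpm(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(counts-per-million + pseudocount); library sizes are column sums."""
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return np.log2(1e6 * counts / lib + pseudocount)


def covariate_adjust(X: pd.DataFrame, covariates: pd.DataFrame | None) -> pd.DataFrame:
    """Replace each gene's profile by OLS residuals on [intercept | covariates].

    The group label must NOT be among the covariates: this stage removes
    nuisance variation only.  With no covariates, X is returned unchanged.
    Residuals are mean-centred per gene (the intercept is in the design).
    """
    if covariates is None or covariates.shape[1] == 0:
        return X
    if not covariates.index.equals(X.columns):
        covariates = covariates.loc[X.columns]
    design = np.column_stack([np.ones(len(covariates)), covariates.to_numpy(float)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        collinear = _collinear_columns(design, ["intercept", *covariates.columns])
        raise ValueError(f"rank-deficient covariate design; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(design, X.to_numpy(float).T, rcond=None)
    resid = X.to_numpy(float).T - design @ beta
    return pd.DataFrame(resid.T, index=X.index, columns=X.columns)


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    bad, rank = [], 0
    kept = np.empty((design.shape[0], 0))
    for j, name in enumerate(names):
        trial = np.column_stack([kept, design[:, j]])
        r = np.linalg.matrix_rank(trial)
        if r == rank:
            bad.append(name)
        else:
            kept, rank = trial, r
    return bad


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotonised, clipped to [0, 1])."""
    arr = np.asarray(p, dtype=float)
    if arr.size and ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def de_test(
    X: pd.DataFrame,
    groups: pd.Series,
    case: str = "stress",
    control: str = "control",
    mode: str = Q_MODE,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch two-sample t per gene on (covariate-adjusted) log-CPM values.

    Returns a DETable-shaped DataFrame indexed by gene with columns log2FC
    (case minus control means on the log2 scale), p (two-sided), q (BH) and
    direction under the requested threshold rule.

    Degenerate zero-variance genes get p equal to the smallest positive
    float when the means differ (a warning is logged) and p = 1 otherwise.
    """
    groups = groups.loc[X.columns]
    case_X = X.loc[:, (groups == case).to_numpy()].to_numpy(float)
    ctrl_X = X.loc[:, (groups == control).to_numpy()].to_numpy(float)
    if case_X.shape[1] < 2 or ctrl_X.shape[1] < 2:
        raise ValueError(
            f"need >= 2 samples per group, got case={case_X.shape[1]} control={ctrl_X.shape[1]}"
        )
    lfc = case_X.mean(axis=1) - ctrl_X.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(case_X, ctrl_X, axis=1, equal_var=False)
    degenerate = (case_X.var(axis=1, ddof=1) + ctrl_X.var(axis=1, ddof=1)) == 0
    if degenerate.any():
        logger.warning("%d gene(s) with zero within-group variance", int(degenerate.sum()))
        p = np.where(degenerate & (lfc != 0), np.finfo(float).tiny, p)
        p = np.where(degenerate & (lfc == 0), 1.0, p)
    p = np.nan_to_num(p, nan=1.0)
    de = pd.DataFrame({"log2FC": lfc, "p": p, "q": bh_adjust(p)}, index=X.index)
    de["direction"] = _directions(de, mode, alpha)
    return de


def _directions(de: pd.DataFrame, mode: str, alpha: float) -> pd.Series:
    stat = de["p"] if mode == P_MODE else de["q"]
    if mode not in (P_MODE, Q_MODE):
        raise ValueError(f"unknown selection mode {mode!r}")
    sig = (stat < alpha) & (de["log2FC"] != 0)
    return pd.Series(
        np.where(sig & (de["log2FC"] > 0), "up", np.where(sig, "down", "ns")),
        index=de.index,
    )


def select_significant(
    de: pd.DataFrame, mode: str = Q_MODE, alpha: float = 0.05
) -> tuple[set[str], set[str]]:
    """Split significant genes into (up, down) sets under the threshold rule."""
    direction = _directions(de, mode, alpha)
    return set(de.index[direction == "up"]), set(de.index[direction == "down"])


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index_label="gene")


def read_de_table(path: str | Path) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t", index_col="gene")
    missing = [c for c in ("log2FC", "p", "q") if c not in de.columns]
    if missing:
        raise ValueError(f"DE table {path} missing columns {missing}")
    return de
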