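"""Seeded signed Spearman co-expression networks per condition stratum.

Selected seed genes (in the motivating analysis, the down-regulated RPGs
common to mouse chronic stress and human MDD) are correlated against every
other gene within each (species, sex, group) stratum of a normalised
expression matrix.  Genes passing a raw p < 0.05 threshold are split by
correlation sign into positive and negative lists; no multiple-testing
correction is applied at this stage (FDR control happens in the downstream
pathway enrichment).

rho uses average ranks (tie-corrected).  The two-sided p mirrors R's
``cor.test``: for tie-free vectors with n <= 9 it comes from the exact
permutation null distribution of rho (enumerated once per n and cached);
otherwise from the t approximation t = rho * sqrt((n - 2) / (1 - rho^2)).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MIN_SAMPLES = 4
EXACT_MAX_N = 9


@lru_cache(maxsize=None)
def _exact_null_abs_rho(n: int) -> np.ndarray:
    """Sorted |rho| over all n! rank permutations (tie-free null)."""
    base = np.arange(1, n + 1, dtype=float)
    scale = n * (n * n - 1)
    d2 = np.array(
        [np.sum((base - np.array(perm)) ** 2) for perm in itertools.permutations(base)]
    )
    return np.sort(np.abs(1.0 - 6.0 * d2 / scale))


def _exact_two_sided_p(abs_rho: float, n: int) -> float:
    null = _exact_null_abs_rho(n)
    # P[|rho_perm| >= |rho_obs|] with a tolerance for float round-off
    idx = np.searchsorted(null, abs_rho - 1e-12, side="left")
    return float((len(null) - idx) / len(null))


def _t_approx_two_sided_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rho and two-sided p.

    Tie-free vectors with n <= 9 get the exact permutation-null p; larger n
    (or ties) use the t approximation.  Requires length >= 4 and
    non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    tie_free = len(set(rx)) == n and len(set(ry)) == n
    if tie_free and n <= EXACT_MAX_N:
        return rho, _exact_two_sided_p(abs(rho), n)
    return rho, _t_approx_two_sided_p(rho, n)


@dataclass
class SeedNetwork:
    """Signed correlate lists for one seed in one stratum."""

    stratum: tuple[str, ...]  # (species, sex, group)
    seed: str
    positive: pd.DataFrame  # columns gene, rho, p  (rho > 0, p < threshold)
    negative: pd.DataFrame  # columns gene, rho, p  (rho < 0, p < threshold)
    p_threshold: float = 0.05

    def __post_init__(self) -> None:
        for sign, frame in (("positive", self.positive), ("negative", self.negative)):
            if len(frame) == 0:
                continue
            assert (frame["p"] < self.p_threshold).all()
            assert (frame["rho"] > 0).all() if sign == "positive" else (frame["rho"] < 0).all()
            assert self.seed not in set(frame["gene"])


def _rank_standardize(X: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, centred and scaled to unit norm."""
    ranks = stats.rankdata(X, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    norms[norms == 0] = np.nan  # constant rows: correlation undefined
    return ranks / norms


def seeded_correlations(
    X: pd.DataFrame,
    seeds,
    stratum: tuple[str, ...] = ("all", "all", "all"),
    p_threshold: float = 0.05,
) -> list[SeedNetwork]:
    """Correlate each seed against every other gene of a normalised matrix.

    ``X`` is genes x samples for a single stratum.  Seeds absent from the
    matrix are logged and skipped; if none remain an error is raised.
    Computation is vectorised: Pearson correlation of tie-corrected ranks
    equals Spearman rho, and p comes from the t approximation.
    """
    present = [s for s in seeds if s in X.index]
    missing = [s for s in seeds if s not in X.index]
    if missing:
        logger.warning("seeds absent from matrix, skipped: %s", missing)
    if not present:
        raise ValueError("no seed genes present in the expression matrix")
    n = X.shape[1]
    if n < MIN_SAMPLES:
        raise ValueError(f"stratum has {n} samples; need >= {MIN_SAMPLES}")

    R = _rank_standardize(X.to_numpy(float))
    seed_idx = [X.index.get_loc(s) for s in present]
    rho = np.clip(R[seed_idx] @ R.T, -1.0, 1.0)  # seeds x genes
    if n <= EXACT_MAX_N:
        # small strata: exact permutation-null p per pair, matching spearman()
        ranks = stats.rankdata(X.to_numpy(float), axis=1)
        tie_free_row = (np.sort(ranks, axis=1) == np.arange(1, n + 1)).all(axis=1)
        p = np.empty_like(rho)
        for i, si in enumerate(seed_idx):
            for j in range(rho.shape[1]):
                r = rho[i, j]
                if np.isnan(r):
                    p[i, j] = np.nan
                elif tie_free_row[si] and tie_free_row[j]:
                    p[i, j] = _exact_two_sided_p(abs(r), n)
                else:
                    p[i, j] = _t_approx_two_sided_p(r, n)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.where(np.isnan(t) & ~np.isnan(rho), 0.0, p)  # |rho| = 1 -> t = inf

    networks = []
    genes = X.index.to_numpy()
    for i, seed in enumerate(present):
        row_rho, row_p = rho[i], p[i]
        ok = (row_p < p_threshold) & (genes != seed) & ~np.isnan(row_rho)
        table = pd.DataFrame({"gene": genes[ok], "rho": row_rho[ok], "p": row_p[ok]})
        networks.append(
            SeedNetwork(
                stratum=stratum,
                seed=seed,
                positive=table[table["rho"] > 0].reset_index(drop=True),
                negative=table[table["rho"] < 0].reset_index(drop=True),
                p_threshold=p_threshold,
            )
        )
    return networks


def stratify(
    X: pd.DataFrame,
    meta: pd.DataFrame,
    by: tuple[str, ...] = ("species", "sex", "group"),
    min_samples: int = MIN_SAMPLES,
):
    """Yield ((level, ...), sample id list) per stratum; small strata skipped.

    Yielded strata are pairwise disjoint and cover every sample belonging to
    a stratum of at least ``min_samples``.
    """
    meta = meta.loc[X.columns]
    for levels, sub in meta.groupby(list(by), sort=True):
        if len(sub) < min_samples:
            logger.warning("stratum %s has %d samples; skipped", levels, len(sub))
            continue
        yield tuple(levels), list(sub.index)


def networks_to_frame(networks: list[SeedNetwork]) -> pd.DataFrame:
    """Long-format table: stratum fields, seed, gene, rho, p, sign."""
    rows = []
    for net in networks:
        species, sex, group = net.stratum
        for sign, frame in (("positive", net.positive), ("negative", net.negative)):
            for rec in frame.itertuples(index=False):
                rows.append((species, sex, group, net.seed, rec.gene, rec.rho, rec.p, sign))
    return pd.DataFrame(
        rows, columns=["species", "sex", "group", "seed", "gene", "rho", "p", "sign"]
    )
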