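"""Cross-species symbol harmonisation and gene-family overlap enrichment.

Gene sets from each species' contrasts are brought into one namespace (an
explicit 1:1 ortholog map takes precedence; remaining symbols follow the
mouse title-case vs human upper-case convention), RP pseudogene suffixes
(``-ps<digits>`` mouse, ``AS<digits>`` human) can be stripped back to parent
symbols, and each gene family is tested for over-representation in a DE set
with the hypergeometric upper tail — equivalent to the one-sided Fisher
exact test — against a fixed gene universe (default 21,196 genes, the
conventional genomic background; synthetic runs override it with the
simulated universe size).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_UNIVERSE = 21196

_MOUSE_PS = re.compile(r"-ps\d*$")
_HUMAN_PS = re.compile(r"AS\d*$")


def strip_pseudogene_suffix(symbol: str, species: str) -> tuple[str, bool]:
    """Strip the RP pseudogene suffix, returning (parent symbol, was stripped).

    Mouse pseudogenes end in ``-ps`` plus optional digits, human pseudogenes
    in ``AS`` plus optional digits.  Symbols without the suffix are returned
    unchanged with ``is_pseudogene=False``.  Pattern-only stripping can
    collide with genuine symbols ending in "AS"; callers holding a pseudogene
    annotation table should pre-filter to annotated symbols.
    """
    if not symbol:
        raise ValueError("empty symbol")
    pattern = {"mouse": _MOUSE_PS, "human": _HUMAN_PS}.get(species)
    if pattern is None:
        raise ValueError(f"unknown species {species!r}")
    parent = pattern.sub("", symbol)
    if parent and parent != symbol:
        return parent, True
    return symbol, False


def harmonize_symbols(
    symbols,
    ortholog_map: pd.DataFrame | None = None,
    from_species: str = "mouse",
    target_universe=None,
) -> set[str]:
    """Map symbols from one species' namespace into the other's.

    Explicit ortholog-map rows (columns ``mouse_symbol``, ``human_symbol``,
    enforced 1:1) take precedence; anything else follows the case
    convention (mouse ``Rps29`` <-> human ``RPS29``).  If ``target_universe``
    is given, symbols that fail to land in it are dropped with a logged count.
    """
    if from_species not in ("mouse", "human"):
        raise ValueError(f"unknown species {from_species!r}")
    explicit: dict[str, str] = {}
    if ortholog_map is not None and len(ortholog_map):
        src, dst = (
            ("mouse_symbol", "human_symbol")
            if from_species == "mouse"
            else ("human_symbol", "mouse_symbol")
        )
        for col in ("mouse_symbol", "human_symbol"):
            dup = ortholog_map[col][ortholog_map[col].duplicated()]
            if len(dup):
                raise ValueError(
                    f"ortholog map is not 1:1; duplicated {col}: {sorted(set(dup))[:5]}"
                )
        explicit = dict(zip(ortholog_map[src], ortholog_map[dst]))

    out: set[str] = set()
    dropped = 0
    for sym in symbols:
        mapped = explicit.get(sym)
        if mapped is None:
            mapped = sym.upper() if from_species == "mouse" else sym.capitalize()
        if target_universe is not None and mapped not in target_universe:
            dropped += 1
            continue
        out.add(mapped)
    if dropped:
        logger.warning("harmonize_symbols: dropped %d unmapped symbol(s)", dropped)
        if not out:
            warnings.warn("no symbols could be harmonized into the target universe")
    return out


@dataclass(frozen=True)
class OverlapResult:
    k: int  # overlap size
    K: int  # family size within the universe
    n: int  # DE set size
    N: int  # universe size
    p: float  # hypergeometric upper tail P[X >= k]
    odds_ratio: float

    def __post_init__(self) -> None:
        assert self.k <= min(self.K, self.n)
        assert self.N >= max(self.K, self.n)


def family_overlap_test(de_set, family_members, universe_size: int = DEFAULT_UNIVERSE) -> OverlapResult:
    """Hypergeometric over-representation of a family in a DE set.

    p = P[X >= k] for X ~ Hypergeom(N, K, n) with N the universe size, K the
    family size, n the DE set size and k the overlap — identical to the
    one-sided Fisher exact test on the 2x2 table.  Only over-representation
    is tested.
    """
    de_set, family_members = set(de_set), set(family_members)
    k = len(de_set & family_members)
    K, n, N = len(family_members), len(de_set), int(universe_size)
    if N < max(K, n):
        raise ValueError(f"universe size {N} smaller than a tested set (K={K}, n={n})")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    num = k * (N - K - n + k)
    den = (K - k) * (n - k)
    odds = float("inf") if den == 0 and num > 0 else (num / den if den else 0.0)
    return OverlapResult(k=k, K=K, n=n, N=N, p=p, odds_ratio=odds)


def enrich_families(
    de_sets: dict[tuple[str, str], set[str]],
    families: dict[str, set[str]],
    universe_size: int = DEFAULT_UNIVERSE,
) -> pd.DataFrame:
    """Test every family against every (contrast, direction) DE set.

    BH correction is applied across the families tested for the same DE set.
    Returns a long DataFrame: contrast, direction, family, k, K, n, N, p, q,
    odds_ratio.
    """
    rows = []
    for (contrast, direction), de_set in de_sets.items():
        block = []
        for fid, members in families.items():
            r = family_overlap_test(de_set, members, universe_size)
            block.append((contrast, direction, fid, r.k, r.K, r.n, r.N, r.p, r.odds_ratio))
        df = pd.DataFrame(
            block,
            columns=["contrast", "direction", "family", "k", "K", "n", "N", "p", "odds_ratio"],
        )
        df["q"] = bh_adjust(df["p"].to_numpy())
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    cols = ["contrast", "direction", "family", "k", "K", "n", "N", "p", "q", "odds_ratio"]
    return out[cols]


def enrichment_score_matrix(enrichment: pd.DataFrame, cap: float = 16.0) -> pd.DataFrame:
    """Wide matrix of -log10(q): rows (contrast, direction), columns families.

    q-values of 0 (impossible from the hypergeometric but possible in
    external tables) are capped with a warning; all entries are clipped to
    ``cap`` for display.
    """
    q = enrichment["q"].to_numpy(float)
    if (q == 0).any():
        warnings.warn("q = 0 encountered; capping -log10(q)")
    with np.errstate(divide="ignore"):
        score = np.minimum(-np.log10(q), cap)
    df = enrichment.assign(score=score)
    return df.pivot_table(
        index=["contrast", "direction"], columns="family", values="score", aggfunc="first"
    )


def cross_species_common(
    set_mouse,
    set_human,
    ortholog_map: pd.DataFrame | None = None,
) -> list[str]:
    """Orthologous genes present in both species' sets, in the human namespace.

    The mouse set is harmonized first; output order is sorted for stability.
    """
    mouse_h = harmonize_symbols(set_mouse, ortholog_map, from_species="mouse")
    return sorted(mouse_h & set(set_human))


# ---- file IO ----------------------------------------------------------------

def read_family_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"family_id", "species", "symbol"} - set(df.columns)
    if missing:
        raise ValueError(f"family table missing columns {sorted(missing)}")
    return df


def family_sets(families: pd.DataFrame, species: str) -> dict[str, set[str]]:
    sub = families[families["species"] == species]
    return {fid: set(g["symbol"]) for fid, g in sub.groupby("family_id")}


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"mouse_symbol", "human_symbol"} - set(df.columns)
    if missing:
        raise ValueError(f"ortholog map missing columns {sorted(missing)}")
    return df
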