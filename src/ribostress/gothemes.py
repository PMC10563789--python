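"""GO over-representation, theme clustering and signed condition matrices.

Gene lists (seeded-network correlates or DE sets) are tested for GO term
over-representation with annotations propagated to all is_a ancestors;
Benjamini-Hochberg q < 0.05 rows are retained.  Each significant term is
assigned to interpretive themes by two routes: a case-insensitive keyword
substring match on the term name, or descent from hand-picked anchor terms
in the DAG.  Terms matching no theme are labelled "unclassified"; a term may
carry several themes (no priority between the two routes is imposed).

Two figure-shaped outputs are produced: a signed condition x pathway matrix
(-log10(q), sign encoding whether the term came from positively or
negatively correlated gene lists, with per-term contributing-seed counts)
and a pathway-set overlap between two enrichment tables (e.g. down-regulated
RPG pathways vs up-regulated RP pseudogene pathways).
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd
import numpy as np

from .diffexpr import bh_adjust
from .families import family_overlap_test
from .network import SeedNetwork

logger = logging.getLogger(__name__)


@dataclass
class GODag:
    """Minimal GO DAG: id -> name plus child -> parents (is_a) edges."""

    names: dict[str, str]
    parents: dict[str, set[str]]

    def __post_init__(self) -> None:
        g = nx.DiGraph((c, p) for c, ps in self.parents.items() for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("GO graph contains a cycle")
        unknown = {p for ps in self.parents.values() for p in ps} - set(self.names)
        if unknown:
            raise ValueError(f"is_a references unknown terms: {sorted(unknown)}")

    @classmethod
    def from_obo(cls, source: str | Path) -> "GODag":
        """Parse an OBO document (path, or the document text itself)."""
        text = Path(source).read_text() if Path(str(source)[:200]).is_file() else str(source)
        graph = obonet.read_obo(io.StringIO(text))
        names = {n: data.get("name", n) for n, data in graph.nodes(data=True)}
        parents: dict[str, set[str]] = {n: set() for n in names}
        for child, parent, key in graph.edges(keys=True):
            if key == "is_a":
                parents[child].add(parent)
        return cls(names=names, parents=parents)


def ancestors(term: str, dag: GODag) -> set[str]:
    """Transitive is_a closure above ``term``, excluding the term itself."""
    if term not in dag.names:
        raise KeyError(f"unknown GO term {term}")
    out: set[str] = set()
    frontier = list(dag.parents.get(term, ()))
    while frontier:
        t = frontier.pop()
        if t not in out:
            out.add(t)
            frontier.extend(dag.parents.get(t, ()))
    return out


def descendants(term: str, dag: GODag) -> set[str]:
    """All terms whose ancestor closure contains ``term`` (term excluded)."""
    if term not in dag.names:
        raise KeyError(f"unknown GO term {term}")
    children: dict[str, set[str]] = {t: set() for t in dag.names}
    for c, ps in dag.parents.items():
        for p in ps:
            children[p].add(c)
    out: set[str] = set()
    frontier = list(children[term])
    while frontier:
        t = frontier.pop()
        if t not in out:
            out.add(t)
            frontier.extend(children[t])
    return out


def propagate_annotations(annotations: pd.DataFrame, dag: GODag) -> dict[str, set[str]]:
    """term -> annotated gene set, with genes propagated to all ancestors."""
    unknown = set(annotations["term"]) - set(dag.names)
    if unknown:
        raise ValueError(f"annotations reference unknown terms: {sorted(unknown)}")
    term_genes: dict[str, set[str]] = {}
    for gene, term in annotations[["gene", "term"]].itertuples(index=False):
        for t in {term, *ancestors(term, dag)}:
            term_genes.setdefault(t, set()).add(gene)
    return term_genes


def go_enrichment(
    gene_list,
    dag: GODag,
    annotations: pd.DataFrame,
    universe=None,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric GO over-representation with ancestor propagation.

    The universe defaults to every annotated gene.  Terms with at least one
    list gene are tested; BH-corrected rows with q < ``q_max`` are returned
    (pass ``q_max=1.0`` to keep everything).
    """
    gene_list = set(gene_list)
    if not gene_list:
        warnings.warn("empty gene list; no enrichment computed")
        return pd.DataFrame(columns=["term", "name", "k", "K", "n", "N", "p", "q"])
    term_genes = propagate_annotations(annotations, dag)
    universe = set(universe) if universe is not None else set(annotations["gene"])
    gene_list &= universe
    rows = []
    for term, genes in sorted(term_genes.items()):
        K_set = genes & universe
        k = len(gene_list & K_set)
        if k == 0 or not K_set:
            continue
        r = family_overlap_test(gene_list, K_set, universe_size=len(universe))
        rows.append((term, dag.names[term], r.k, r.K, r.n, r.N, r.p))
    df = pd.DataFrame(rows, columns=["term", "name", "k", "K", "n", "N", "p"])
    if df.empty:
        return df.assign(q=pd.Series(dtype=float))
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df[df["q"] < q_max].reset_index(drop=True)


# ---- themes -----------------------------------------------------------------

def load_theme_map(source: str | Path | dict) -> dict[str, dict]:
    if isinstance(source, dict):
        themes = source
    else:
        themes = json.loads(Path(source).read_text())
    out = {}
    for theme, spec in themes.items():
        keywords = [k.lower() for k in spec.get("keywords", []) if k]
        out[theme] = {"keywords": keywords, "anchor_terms": list(spec.get("anchor_terms", []))}
    return out


def validate_theme_map(theme_map: dict[str, dict], dag: GODag) -> None:
    for theme, spec in theme_map.items():
        missing = [t for t in spec["anchor_terms"] if t not in dag.names]
        if missing:
            raise ValueError(f"theme {theme!r} anchors missing from DAG: {missing}")


def assign_themes(term: str, dag: GODag, theme_map: dict[str, dict]) -> set[str]:
    """Themes whose keywords match the term name or whose anchors dominate it.

    A term matches a theme if any keyword is a case-insensitive substring of
    its name, or if the term equals or descends from any anchor term.  All
    matching themes are recorded; no match yields {"unclassified"}.
    """
    if term not in dag.names:
        raise KeyError(f"unknown GO term {term}")
    name = dag.names[term].lower()
    anc = ancestors(term, dag)
    matched = {
        theme
        for theme, spec in theme_map.items()
        if any(kw in name for kw in spec["keywords"])
        or any(a == term or a in anc for a in spec["anchor_terms"])
    }
    return matched or {"unclassified"}


# ---- figure-shaped outputs ---------------------------------------------------

def signed_theme_matrix(
    seed_networks: list[SeedNetwork],
    dag: GODag,
    annotations: pd.DataFrame,
    theme_map: dict[str, dict],
    universe=None,
    q_max: float = 0.05,
    symbol_mapper=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signed condition x pathway enrichment from seeded networks.

    Per stratum and sign, enrichment runs on the union of the per-seed
    correlate lists; a term's ``contributing_seeds`` counts the seeds whose
    own list independently yields q < ``q_max`` for that term.  Returns
    (long ThemedEnrichment table, wide matrix of signed -log10(q) with rows
    = terms grouped by theme and columns = (stratum, sign)).

    ``symbol_mapper`` (optional) converts gene symbols into the annotation
    namespace, e.g. mouse -> human harmonisation.
    """
    mapper = symbol_mapper or (lambda genes: set(genes))
    validate_theme_map(theme_map, dag)
    by_stratum: dict[tuple, list[SeedNetwork]] = {}
    for net in seed_networks:
        by_stratum.setdefault(net.stratum, []).append(net)

    long_rows = []
    for stratum, nets in sorted(by_stratum.items()):
        for sign in ("positive", "negative"):
            per_seed_lists = {
                net.seed: mapper(set(getattr(net, sign)["gene"])) for net in nets
            }
            union = set().union(*per_seed_lists.values()) if per_seed_lists else set()
            if not union:
                continue
            enr = go_enrichment(union, dag, annotations, universe=universe, q_max=q_max)
            if enr.empty:
                continue
            seed_hits: dict[str, int] = {}
            for genes in per_seed_lists.values():
                if not genes:
                    continue
                per = go_enrichment(genes, dag, annotations, universe=universe, q_max=q_max)
                for term in per["term"]:
                    seed_hits[term] = seed_hits.get(term, 0) + 1
            for rec in enr.itertuples(index=False):
                themes = sorted(assign_themes(rec.term, dag, theme_map))
                long_rows.append(
                    ("|".join(stratum), sign, rec.term, rec.name, rec.p, rec.q,
                     ";".join(themes), max(seed_hits.get(rec.term, 0), 1))
                )

    long = pd.DataFrame(
        long_rows,
        columns=["stratum", "sign", "term", "name", "p", "q", "themes", "contributing_seeds"],
    )
    if long.empty:
        return long, pd.DataFrame()
    signed = np.where(long["sign"] == "positive", 1.0, -1.0) * (-np.log10(long["q"]))
    wide = (
        long.assign(score=signed, column=long["stratum"] + "|" + long["sign"])
        .pivot_table(index=["themes", "term", "name"], columns="column", values="score",
                     aggfunc="first")
        .sort_index()
    )
    return long, wide


def pathway_overlap(enrich_a: pd.DataFrame, enrich_b: pd.DataFrame) -> dict:
    """Term-set overlap between two q-filtered enrichment tables.

    Returns shared / only_a / only_b term-id sets plus a per-term table of
    -log10(q) on each side (NaN where absent).
    """
    a = enrich_a.set_index("term") if len(enrich_a) else pd.DataFrame(columns=["q"])
    b = enrich_b.set_index("term") if len(enrich_b) else pd.DataFrame(columns=["q"])
    terms_a, terms_b = set(a.index), set(b.index)
    table = pd.DataFrame(index=sorted(terms_a | terms_b))
    table["minus_log10_q_a"] = -np.log10(a["q"].reindex(table.index))
    table["minus_log10_q_b"] = -np.log10(b["q"].reindex(table.index))
    return {
        "shared": terms_a & terms_b,
        "only_a": terms_a - terms_b,
        "only_b": terms_b - terms_a,
        "table": table,
    }
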