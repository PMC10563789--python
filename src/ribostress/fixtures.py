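"""Toy-scale gene universe, family tables, ortholog map, GO DAG and themes.

These fixtures emulate, at desk scale, the configuration inputs of the real
analysis: HGNC-style gene-family membership tables (including a large- and a
small-subunit ribosomal protein family plus decoy families), a mouse/human
ortholog symbol map, a small rooted acyclic GO graph with gene annotations,
and a theme map (keywords + anchor terms) for pathway clustering.

Symbol conventions follow the field: mouse title-case (``Rpl3``), human
upper-case (``RPL3``); RP pseudogenes carry suffix ``-ps<digit>`` in mouse
and ``AS<digit>`` in human.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class GeneUniverse:
    """Parallel mouse/human symbol universes with known structure."""

    rpl: list[str]  # human-namespace large-subunit RPG symbols
    rps: list[str]  # human-namespace small-subunit RPG symbols
    pseudogenes: dict[str, str]  # human pseudogene symbol -> parent symbol
    background: list[str]  # human-namespace background symbols
    synapse_genes: list[str]
    immune_genes: list[str]
    autophagy_genes: list[str]

    @property
    def rpg(self) -> list[str]:
        return self.rpl + self.rps

    @property
    def human_symbols(self) -> list[str]:
        return self.rpg + list(self.pseudogenes) + self.background

    @property
    def mouse_symbols(self) -> list[str]:
        return [human_to_mouse(s) for s in self.human_symbols]


def mouse_to_human(symbol: str) -> str:
    """Default case-convention map: mouse title-case -> human upper-case."""
    return symbol.upper()


def human_to_mouse(symbol: str) -> str:
    """Inverse case convention, with the pseudogene suffix translated.

    Human ``RPL3AS1`` corresponds to mouse ``Rpl3-ps1`` in this toy universe;
    plain symbols just switch case convention.
    """
    import re

    m = re.match(r"^(.*?)AS(\d+)$", symbol)
    if m:
        return f"{m.group(1).capitalize()}-ps{m.group(2)}"
    return symbol.capitalize()


def build_gene_universe(
    n_rpl: int = 50,
    n_rps: int = 30,
    n_pseudo: int = 10,
    n_synapse: int = 40,
    n_immune: int = 40,
    n_autophagy: int = 40,
    n_background: int = 360,
) -> GeneUniverse:
    rpl = [f"RPL{i}" for i in range(1, n_rpl + 1)]
    rps = [f"RPS{i}" for i in range(1, n_rps + 1)]
    pseudogenes = {f"RPL{i}AS1": f"RPL{i}" for i in range(1, n_pseudo + 1)}
    synapse = [f"SYN{i:03d}" for i in range(1, n_synapse + 1)]
    immune = [f"IMM{i:03d}" for i in range(1, n_immune + 1)]
    autophagy = [f"ATG{i:03d}" for i in range(1, n_autophagy + 1)]
    background = synapse + immune + autophagy + [
        f"GENE{i:04d}" for i in range(1, n_background - n_synapse - n_immune - n_autophagy + 1)
    ]
    return GeneUniverse(
        rpl=rpl, rps=rps, pseudogenes=pseudogenes, background=background,
        synapse_genes=synapse, immune_genes=immune, autophagy_genes=autophagy,
    )


# ---- GO DAG ---------------------------------------------------------------

# (term id, name, parents)
_TOY_TERMS: list[tuple[str, str, list[str]]] = [
    ("GO:0000001", "biological_process", []),
    ("GO:0000002", "metabolic process", ["GO:0000001"]),
    ("GO:0000003", "translation", ["GO:0000002"]),
    ("GO:0000004", "cytoplasmic translation", ["GO:0000003"]),
    ("GO:0000015", "cellular component organization", ["GO:0000001"]),
    ("GO:0000016", "organelle organization", ["GO:0000015"]),
    # diamond: ribosome assembly sits under both organelle organization and
    # translation machinery metabolism
    ("GO:0000005", "ribosome assembly", ["GO:0000016", "GO:0000002"]),
    ("GO:0000006", "RNA processing", ["GO:0000002"]),
    ("GO:0000007", "mRNA stabilization", ["GO:0000006"]),
    ("GO:0000014", "signaling", ["GO:0000001"]),
    ("GO:0000008", "synapse organization", ["GO:0000015"]),
    ("GO:0000009", "chemical synaptic transmission", ["GO:0000014"]),
    ("GO:0000010", "immune system process", ["GO:0000001"]),
    ("GO:0000011", "inflammatory response", ["GO:0000010"]),
    ("GO:0000012", "autophagy", ["GO:0000002"]),
    ("GO:0000013", "protein folding", ["GO:0000002"]),
]

_TOY_THEMES: dict[str, dict] = {
    "translation": {"keywords": ["translation", "ribosom"], "anchor_terms": ["GO:0000003"]},
    "rna": {"keywords": ["rna"], "anchor_terms": ["GO:0000006"]},
    "synapse": {"keywords": ["synap"], "anchor_terms": ["GO:0000008"]},
    "immune response": {"keywords": ["immune", "inflamm"], "anchor_terms": ["GO:0000010"]},
    "autophagy": {"keywords": ["autophagy"], "anchor_terms": ["GO:0000012"]},
    "organelle": {"keywords": ["organelle"], "anchor_terms": ["GO:0000016"]},
}


def toy_obo_text(terms: list[tuple[str, str, list[str]]] | None = None) -> str:
    """Render a minimal OBO document (id/name/is_a stanzas)."""
    out = io.StringIO()
    out.write("format-version: 1.2\nontology: toy\n")
    for tid, name, parents in terms or _TOY_TERMS:
        out.write(f"\n[Term]\nid: {tid}\nname: {name}\nnamespace: biological_process\n")
        for p in parents:
            out.write(f"is_a: {p}\n")
    return out.getvalue()


@dataclass
class Fixtures:
    universe: GeneUniverse
    families: pd.DataFrame  # columns family_id, species, symbol
    ortholog_map: pd.DataFrame  # columns mouse_symbol, human_symbol
    obo_text: str
    annotations: pd.DataFrame  # columns gene, term (human namespace)
    theme_map: dict[str, dict] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "families": outdir / "gene_families.tsv",
            "ortholog_map": outdir / "ortholog_map.tsv",
            "obo": outdir / "toy_go.obo",
            "annotations": outdir / "go_annotations.tsv",
            "themes": outdir / "themes.json",
        }
        self.families.to_csv(paths["families"], sep="\t", index=False)
        self.ortholog_map.to_csv(paths["ortholog_map"], sep="\t", index=False)
        paths["obo"].write_text(self.obo_text)
        self.annotations.to_csv(paths["annotations"], sep="\t", index=False)
        paths["themes"].write_text(json.dumps(self.theme_map, indent=2))
        return paths


def generate_fixtures(seed: int = 0, universe: GeneUniverse | None = None) -> Fixtures:
    """Build all configuration fixtures for the demo gene universe.

    Deterministic given ``seed``; the seed only randomises decoy-family
    membership draws.
    """
    rng = np.random.default_rng(seed)
    uni = universe or build_gene_universe()

    fam_rows: list[tuple[str, str, str]] = []

    def add_family(fid: str, human_members: list[str]) -> None:
        for sym in human_members:
            fam_rows.append((fid, "human", sym))
            fam_rows.append((fid, "mouse", human_to_mouse(sym)))

    add_family("RPG", uni.rpg)
    add_family("RPG_L", uni.rpl)  # large-subunit ribosomal proteins
    add_family("RPG_S", uni.rps)  # small-subunit ribosomal proteins
    add_family("RP_PSEUDO", list(uni.pseudogenes))
    pool = np.array(uni.background)
    for d in range(1, 7):
        members = rng.choice(pool, size=30, replace=False)
        add_family(f"DECOY{d}", sorted(members))
    families = pd.DataFrame(fam_rows, columns=["family_id", "species", "symbol"])

    ortholog_map = pd.DataFrame(
        {
            "mouse_symbol": [human_to_mouse(s) for s in uni.human_symbols],
            "human_symbol": uni.human_symbols,
        }
    )

    ann_rows: list[tuple[str, str]] = []
    for g in uni.rpg:
        ann_rows.append((g, "GO:0000004"))  # cytoplasmic translation
    for g in uni.rpl[:20]:
        ann_rows.append((g, "GO:0000005"))  # ribosome assembly
    for g in uni.pseudogenes:
        ann_rows.append((g, "GO:0000007"))  # mRNA stabilization
    half = len(uni.synapse_genes) // 2
    for g in uni.synapse_genes[:half]:
        ann_rows.append((g, "GO:0000008"))
    for g in uni.synapse_genes[half:]:
        ann_rows.append((g, "GO:0000009"))
    for g in uni.immune_genes:
        ann_rows.append((g, "GO:0000011"))
    for g in uni.autophagy_genes:
        ann_rows.append((g, "GO:0000012"))
    # a slab of generically annotated background widens the GO universe
    generic = [g for g in uni.background if g.startswith("GENE")]
    for g in generic[:120]:
        ann_rows.append((g, "GO:0000013"))
    annotations = pd.DataFrame(ann_rows, columns=["gene", "term"])

    return Fixtures(
        universe=uni,
        families=families,
        ortholog_map=ortholog_map,
        obo_text=toy_obo_text(),
        annotations=annotations,
        theme_map={k: dict(v) for k, v in _TOY_THEMES.items()},
    )
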