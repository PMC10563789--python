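"""End-to-end orchestration: reads -> counts -> DE -> families -> networks -> themes.

Stages hand data to each other exclusively through files, so any stage's
input can be replaced by real data (e.g. externally computed DE tables).
A run is a pure function of (config, seed, inputs); the manifest records the
seed, thresholds, per-stage timings and SHA-256 checksums of every output.

``make_demo`` generates the all-synthetic demonstration: a composite
reference with pseudogene copies, error-free reads, and two-species count
matrices with 15 RPGs planted down (log2FC -1) inside an 80-member RPG
family, an anti-correlated 10-gene RP pseudogene block planted up, a
correlated synapse-gene module, and nuisance covariates.  Differential
expression pools the two sexes of a species into one contrast (sex carried
as an adjustment covariate); seeded networks are computed per
(species, sex, group) stratum.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import align as al
from . import diffexpr as de
from . import families as fam
from . import gothemes as got
from . import network as net
from .counts import CountMatrix, ModuleSpec, SimDesign, simulate_counts
from .fixtures import Fixtures, GeneUniverse, generate_fixtures, human_to_mouse
from .reads import read_fastq, simulate_reads, write_fastq
from .reference import CompositeReference, generate_composite_reference

logger = logging.getLogger(__name__)

SPECIES = ("mouse", "human")
# threshold rule per species contrast: raw p for the human (MDD-style)
# contrast, BH q for the mouse (chronic-stress-style) contrast
DE_MODE = {"mouse": de.Q_MODE, "human": de.P_MODE}


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    run_align: bool = True
    filter_threshold: float = 5.0
    filter_mode: str = "mean"
    p_threshold: float = 0.05
    q_threshold: float = 0.05
    universe_size: int | None = None  # None -> size of the simulated universe
    covariates: tuple[str, ...] = ("age", "rin", "sex_code")
    index_k: int = 16
    # input paths, filled by make_demo or by the caller
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["covariates"] = tuple(data.get("covariates", ("age", "rin", "sex_code")))
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        return d


def _stage_seed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k) % 2**31)


# ---------------------------------------------------------------------------
# demo design
# ---------------------------------------------------------------------------

N_PLANTED_RPL, N_PLANTED_RPS = 10, 5  # 15 planted RPGs in the 80-member family
PLANTED_LFC = -1.0
PSEUDO_LFC = 1.0
MODULE_LOADING = 0.8
N_PER_GROUP = 24  # per (species, sex, group)


def planted_rpgs(universe: GeneUniverse) -> list[str]:
    return universe.rpl[:N_PLANTED_RPL] + universe.rps[:N_PLANTED_RPS]


def build_demo_design(
    universe: GeneUniverse,
    species: str,
    seed: int,
    n_per_group: int = N_PER_GROUP,
    dispersion: float = 0.1,
    null: bool = False,
) -> SimDesign:
    """Per-species simulation design with the planted demo effects.

    ``null=True`` strips all planted effects and modules (used for false
    positive calibration).
    """
    planted_h = {}
    loadings_h: dict[str, float] = {}
    if not null:
        for g in planted_rpgs(universe):
            planted_h[g] = PLANTED_LFC
            loadings_h[g] = MODULE_LOADING
        for g in universe.pseudogenes:
            planted_h[g] = PSEUDO_LFC
            loadings_h[g] = -MODULE_LOADING
        for g in universe.synapse_genes[:25]:
            loadings_h[g] = MODULE_LOADING

    def sym(s: str) -> str:
        return human_to_mouse(s) if species == "mouse" else s

    genes = [sym(s) for s in universe.human_symbols]
    modules = []
    if loadings_h:
        modules.append(
            ModuleSpec(
                name="rpg_module",
                seed_gene=sym(planted_rpgs(universe)[0]),
                loadings={sym(g): v for g, v in loadings_h.items()},
            )
        )
    return SimDesign(
        genes=genes,
        n_per_group=n_per_group,
        strata=[(species, "F"), (species, "M")],
        planted={sym(g): v for g, v in planted_h.items()},
        modules=modules,
        dispersion=dispersion,
        covariate_spec=[("age", 0.2), ("rin", 0.2)],
        seed=_stage_seed(seed, 11 if species == "mouse" else 13),
    )


# ---------------------------------------------------------------------------
# file-based stages
# ---------------------------------------------------------------------------

def stage_align(cfg: RunConfig, outdir: Path) -> dict:
    ref = CompositeReference.read(cfg.paths["ref_fasta"], cfg.paths["loci_tsv"])
    reads = read_fastq(cfg.paths["reads_fastq"])
    index = al.build_index(ref, k=cfg.index_k)
    assignments = al.assign_reads(reads, index)
    counts, summary = al.quantify(assignments, ref)
    counts.to_frame().to_csv(outdir / "alignment_counts.tsv", sep="\t", index_label="locus_id")
    al.write_assignments(assignments, outdir / "assignments.tsv")
    (outdir / "align_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def stage_de(cfg: RunConfig, outdir: Path) -> dict:
    info = {}
    for species in SPECIES:
        cm = CountMatrix.read_tsv(
            cfg.paths[f"counts_{species}"], cfg.paths[f"meta_{species}"]
        )
        cm = de.filter_low_counts(cm, cfg.filter_threshold, mode=cfg.filter_mode)
        X = de.normalize_log_cpm(cm.counts)
        meta = cm.meta.copy()
        meta["sex_code"] = (meta["sex"] == "M").astype(float)
        covs = meta[[c for c in cfg.covariates if c in meta.columns]].astype(float)
        X_adj = de.covariate_adjust(X, covs)
        mode = DE_MODE[species]
        alpha = cfg.q_threshold if mode == de.Q_MODE else cfg.p_threshold
        table = de.de_test(X_adj, meta["group"], mode=mode, alpha=alpha)
        de.write_de_table(table, outdir / f"de_{species}.tsv")
        up, down = de.select_significant(table, mode=mode, alpha=alpha)
        info[species] = {"mode": mode, "n_genes": len(table), "n_up": len(up), "n_down": len(down)}
    return info


def stage_families(cfg: RunConfig, outdir: Path) -> dict:
    families = fam.read_family_table(cfg.paths["families"])
    orthologs = fam.read_ortholog_map(cfg.paths["ortholog_map"])
    de_sets: dict[tuple[str, str], set[str]] = {}
    down_by_species: dict[str, set[str]] = {}
    universe_n = {}
    for species in SPECIES:
        table = de.read_de_table(outdir / f"de_{species}.tsv")
        mode = DE_MODE[species]
        alpha = cfg.q_threshold if mode == de.Q_MODE else cfg.p_threshold
        up, down = de.select_significant(table, mode=mode, alpha=alpha)
        de_sets[(species, "up")] = up
        de_sets[(species, "down")] = down
        down_by_species[species] = down
        universe_n[species] = len(table)

    N = cfg.universe_size or max(universe_n.values())
    enrichment_blocks = []
    for species in SPECIES:
        fsets = fam.family_sets(families, species)
        block = fam.enrich_families(
            {k: v for k, v in de_sets.items() if k[0] == species}, fsets, universe_size=N
        )
        enrichment_blocks.append(block)
    enrichment = pd.concat(enrichment_blocks, ignore_index=True)
    enrichment.to_csv(outdir / "family_enrichment.tsv", sep="\t", index=False)
    fam.enrichment_score_matrix(enrichment).to_csv(outdir / "family_score_matrix.tsv", sep="\t")

    common = fam.cross_species_common(
        down_by_species["mouse"], down_by_species["human"], orthologs
    )
    pd.Series(common, name="gene").to_csv(outdir / "common_down.tsv", sep="\t", index=False)
    sig_down = enrichment[
        (enrichment["direction"] == "down") & (enrichment["q"] < cfg.q_threshold)
    ]
    return {
        "n_common_down": len(common),
        "universe_size": N,
        "significant_down_families": sorted(set(sig_down["family"])),
    }


def stage_seednet(cfg: RunConfig, outdir: Path) -> dict:
    seeds_h = list(pd.read_csv(outdir / "common_down.tsv", sep="\t")["gene"])
    if not seeds_h:
        raise RuntimeError("seeded network stage: no common down-regulated seeds found")
    orthologs = fam.read_ortholog_map(cfg.paths["ortholog_map"])
    h2m = dict(zip(orthologs["human_symbol"], orthologs["mouse_symbol"]))
    frames = []
    n_strata = 0
    for species in SPECIES:
        cm = CountMatrix.read_tsv(cfg.paths[f"counts_{species}"], cfg.paths[f"meta_{species}"])
        cm = de.filter_low_counts(cm, cfg.filter_threshold, mode=cfg.filter_mode)
        X = de.normalize_log_cpm(cm.counts)
        seeds = seeds_h if species == "human" else [h2m.get(s, s.capitalize()) for s in seeds_h]
        for stratum, samples in net.stratify(X, cm.meta):
            networks = net.seeded_correlations(
                X[samples], seeds, stratum=stratum, p_threshold=cfg.p_threshold
            )
            frames.append(net.networks_to_frame(networks))
            n_strata += 1
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(outdir / "seed_networks.tsv", sep="\t", index=False)
    return {"n_strata": n_strata, "n_edges": len(table)}


def _rebuild_networks(table: pd.DataFrame, p_threshold: float) -> list[net.SeedNetwork]:
    networks = []
    for (species, sex, group, seed), sub in table.groupby(
        ["species", "sex", "group", "seed"], sort=True
    ):
        pos = sub[sub["sign"] == "positive"][["gene", "rho", "p"]].reset_index(drop=True)
        neg = sub[sub["sign"] == "negative"][["gene", "rho", "p"]].reset_index(drop=True)
        networks.append(
            net.SeedNetwork((species, sex, group), seed, pos, neg, p_threshold=p_threshold)
        )
    return networks


def stage_themes(cfg: RunConfig, outdir: Path) -> dict:
    dag = got.GODag.from_obo(cfg.paths["obo"])
    annotations = pd.read_csv(cfg.paths["annotations"], sep="\t")
    theme_map = got.load_theme_map(cfg.paths["themes"])
    orthologs = fam.read_ortholog_map(cfg.paths["ortholog_map"])

    table = pd.read_csv(outdir / "seed_networks.tsv", sep="\t")
    networks = _rebuild_networks(table, cfg.p_threshold)

    def to_human(genes: set[str]) -> set[str]:
        return fam.harmonize_symbols(genes, orthologs, from_species="mouse")

    mouse_nets = [n for n in networks if n.stratum[0] == "mouse"]
    human_nets = [n for n in networks if n.stratum[0] == "human"]
    longs, wides = [], []
    for nets, mapper in ((mouse_nets, to_human), (human_nets, None)):
        if not nets:
            continue
        long, wide = got.signed_theme_matrix(
            nets, dag, annotations, theme_map, q_max=cfg.q_threshold, symbol_mapper=mapper
        )
        longs.append(long)
        if not wide.empty:
            wides.append(wide)
    long = pd.concat(longs, ignore_index=True)
    long.to_csv(outdir / "themed_enrichment.tsv", sep="\t", index=False)
    if wides:
        wide = pd.concat(wides, axis=1).sort_index()
        wide.to_csv(outdir / "theme_matrix.tsv", sep="\t")

    # RPG-vs-pseudogene pathway overlap on the DE gene sets
    overlap_info = {}
    de_h = de.read_de_table(outdir / "de_human.tsv")
    up, down = de.select_significant(de_h, mode=DE_MODE["human"], alpha=cfg.p_threshold)
    pseudo_parents = set()
    for g in up:
        parent, is_ps = fam.strip_pseudogene_suffix(g, "human")
        if is_ps:
            pseudo_parents.add(parent)
    enr_down = got.go_enrichment(down, dag, annotations, q_max=cfg.q_threshold)
    enr_pseudo = got.go_enrichment(pseudo_parents, dag, annotations, q_max=cfg.q_threshold)
    ov = got.pathway_overlap(enr_down, enr_pseudo)
    ov["table"].to_csv(outdir / "pathway_overlap.tsv", sep="\t", index_label="term")
    overlap_info = {
        "shared": len(ov["shared"]), "only_down_rpg": len(ov["only_a"]),
        "only_up_pseudogene": len(ov["only_b"]),
    }
    neg = long[(long["sign"] == "negative")]
    return {
        "n_themed_rows": len(long),
        "negative_terms": sorted(set(neg["term"])),
        "pathway_overlap": overlap_info,
    }


STAGES = (
    ("align", stage_align),
    ("de", stage_de),
    ("families", stage_families),
    ("seednet", stage_seednet),
    ("themes", stage_themes),
)


def run(cfg: RunConfig) -> dict:
    """Execute all enabled stages in dependency order; return the manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    required = ["counts_mouse", "meta_mouse", "counts_human", "meta_human",
                "families", "ortholog_map", "obo", "annotations", "themes"]
    if cfg.run_align:
        required += ["ref_fasta", "loci_tsv", "reads_fastq"]
    for key in required:
        path = cfg.paths.get(key)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"missing input for stage pipeline: {key} -> {path}")

    manifest: dict = {"config": cfg.to_dict(), "stages": {}}
    for name, fn in STAGES:
        if name == "align" and not cfg.run_align:
            continue
        t0 = time.perf_counter()
        try:
            info = fn(cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "info": info, "seconds": round(time.perf_counter() - t0, 3),
        }
        logger.info("stage %s done in %.2fs", name, manifest["stages"][name]["seconds"])

    manifest["checksums"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.json"))
        if p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def make_demo(
    seed: int = 0,
    outdir: str | Path = "results/demo",
    run_align: bool = True,
    n_per_group: int = N_PER_GROUP,
) -> dict:
    """Generate all synthetic inputs, then run the full pipeline on them."""
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    fixtures = generate_fixtures(seed=_stage_seed(seed, 1))
    fixture_paths = fixtures.write(inputs)

    paths = {k: str(v) for k, v in fixture_paths.items()}
    if run_align:
        ref = generate_composite_reference(seed=_stage_seed(seed, 2))
        ref.write_fasta(inputs / "reference.fa")
        ref.write_loci_tsv(inputs / "loci.tsv")
        reads, _ = simulate_reads(ref, seed=_stage_seed(seed, 3))
        write_fastq(reads, inputs / "reads.fq")
        paths |= {
            "ref_fasta": str(inputs / "reference.fa"),
            "loci_tsv": str(inputs / "loci.tsv"),
            "reads_fastq": str(inputs / "reads.fq"),
        }

    truths = {}
    for species in SPECIES:
        design = build_demo_design(fixtures.universe, species, seed, n_per_group=n_per_group)
        cm, truth = simulate_counts(design)
        cm.write_tsv(inputs / f"counts_{species}.tsv", inputs / f"meta_{species}.tsv")
        paths |= {
            f"counts_{species}": str(inputs / f"counts_{species}.tsv"),
            f"meta_{species}": str(inputs / f"meta_{species}.tsv"),
        }
        truths[species] = truth

    simulate_seconds = round(time.perf_counter() - t0, 3)
    cfg = RunConfig(outdir=str(outdir), seed=seed, run_align=run_align, paths=paths)
    manifest = run(cfg)
    manifest["stages"]["simulate"] = {
        "info": {"species": list(SPECIES), "n_per_group": n_per_group,
                 "n_genes": len(fixtures.universe.human_symbols)},
        "seconds": simulate_seconds,
    }
    manifest["planted"] = {
        "common_rpgs": planted_rpgs(fixtures.universe),
        "pseudogenes": sorted(fixtures.universe.pseudogenes),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
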