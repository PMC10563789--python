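"""Negative-binomial count simulation with planted effects.

The generator emulates the structure the downstream analysis assumes in bulk
stress/depression transcriptomes:

* two-group (control vs stress) NB counts for each (species, sex) stratum,
* planted log2 fold changes on chosen genes (RPG down-regulation and
  anti-correlated pseudogene up-regulation in the demo design),
* correlated gene modules induced by a shared per-sample Gaussian latent
  factor added on the log2-mean scale, with signed per-gene loadings, so that
  member genes correlate with their seed gene with controllable sign and
  strength,
* nuisance covariates (e.g. age, RNA integrity) with per-gene Gaussian
  coefficients, and log-uniform library sizes to exercise normalisation.

With dispersion 0 the NB degenerates to Poisson.  All output is a pure
function of (design, design.seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .truth import ModuleTruth, TruthTable

CONTROL, STRESS = "control", "stress"


@dataclass
class ModuleSpec:
    """A correlated gene module driven by one latent factor.

    ``loadings`` maps each member gene (the seed included) to a signed
    loading in log2-scale standard deviations: the gene's log2 mean receives
    ``loading * z_s`` for a per-sample standard normal ``z_s`` shared by the
    whole module.  Opposite signs yield anti-correlated blocks, e.g. an RP
    pseudogene block loading with sign opposite to its parent RPG module.
    """

    name: str
    seed_gene: str
    loadings: dict[str, float]

    def __post_init__(self) -> None:
        if self.seed_gene not in self.loadings:
            raise ValueError(f"module {self.name}: seed gene must carry a loading")


@dataclass
class SimDesign:
    genes: list[str]
    n_per_group: int = 24
    strata: list[tuple[str, str]] = field(default_factory=lambda: [("mouse", "F"), ("mouse", "M")])
    planted: dict[str, float] = field(default_factory=dict)  # gene -> log2FC (stress vs control)
    modules: list[ModuleSpec] = field(default_factory=list)
    dispersion: float = 0.1  # NB dispersion phi: var = mu + phi mu^2
    lib_size_range: tuple[float, float] = (1.5e5, 4.5e5)
    covariate_spec: list[tuple[str, float]] = field(default_factory=list)  # (name, effect sd)
    base_mean_range: tuple[float, float] = (30.0, 300.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols in design")
        universe = set(self.genes)
        missing = set(self.planted) - universe
        if missing:
            raise ValueError(f"planted genes outside gene universe: {sorted(missing)[:5]}")
        for mod in self.modules:
            if set(mod.loadings) - universe:
                raise ValueError(f"module {mod.name} has genes outside the universe")


@dataclass
class CountMatrix:
    """Integer gene x sample counts with per-sample metadata."""

    counts: pd.DataFrame  # index genes, columns sample ids
    meta: pd.DataFrame  # index sample ids; columns species, sex, group, covariates

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene symbols")
        if not self.counts.columns.equals(self.meta.index):
            raise ValueError("counts columns and metadata rows disagree")
        if "group" not in self.meta.columns or self.meta["group"].isna().any():
            raise ValueError("every sample needs a group label")
        arr = self.counts.to_numpy()
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    def write_tsv(self, counts_path: str | Path, meta_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene")
        self.meta.to_csv(meta_path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, counts_path: str | Path, meta_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
        return cls(counts=counts.astype(np.int64), meta=meta.loc[counts.columns])


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0.0:
        return rng.poisson(mu)
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_counts(design: SimDesign) -> tuple[CountMatrix, TruthTable]:
    """Simulate an NB count matrix for every (species, sex) stratum of the design.

    Within each stratum, ``n_per_group`` control and ``n_per_group`` stress
    samples are drawn.  Gene base means are log-uniform over
    ``base_mean_range`` and shared across strata; library sizes are
    log-uniform over ``lib_size_range`` per sample.
    """
    rng = np.random.default_rng(design.seed)
    genes = list(design.genes)
    g_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    log2_base = rng.uniform(np.log2(design.base_mean_range[0]),
                            np.log2(design.base_mean_range[1]), size=n_genes)
    lfc = np.zeros(n_genes)
    for gene, value in design.planted.items():
        lfc[g_index[gene]] = value

    # per-gene covariate coefficients, fixed across strata
    cov_coef = {
        name: rng.normal(0.0, sd, size=n_genes) for name, sd in design.covariate_spec
    }

    blocks: list[pd.DataFrame] = []
    meta_rows: list[dict] = []
    for species, sex in design.strata:
        sample_ids, groups = [], []
        for group in (CONTROL, STRESS):
            for i in range(design.n_per_group):
                sample_ids.append(f"{species}_{sex}_{group}_{i:02d}")
                groups.append(group)
        n_samples = len(sample_ids)
        is_stress = np.array([g == STRESS for g in groups], dtype=float)

        log2_mu = np.tile(log2_base[:, None], (1, n_samples))
        log2_mu += np.outer(lfc, is_stress)

        for mod in design.modules:
            z = rng.normal(size=n_samples)
            for gene, loading in mod.loadings.items():
                log2_mu[g_index[gene]] += loading * z

        cov_values = {name: rng.normal(size=n_samples) for name, _ in design.covariate_spec}
        for name, coef in cov_coef.items():
            log2_mu += np.outer(coef, cov_values[name])

        mu = np.exp2(log2_mu)
        # scale each column so its expected total equals the drawn library size
        lo, hi = design.lib_size_range
        lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
        mu *= lib / mu.sum(axis=0)

        counts = _nb_draw(rng, mu, design.dispersion)
        blocks.append(pd.DataFrame(counts, index=genes, columns=sample_ids))
        for sid, group in zip(sample_ids, groups):
            row = {"sample_id": sid, "species": species, "sex": sex, "group": group}
            for name in cov_values:
                row[name] = cov_values[name][sample_ids.index(sid)]
            meta_rows.append(row)

    counts = pd.concat(blocks, axis=1)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    if counts.empty:
        warnings.warn("simulated count matrix is empty")

    truth = TruthTable(
        true_log2fc={g: design.planted.get(g, 0.0) for g in genes},
        modules=[ModuleTruth(m.name, m.seed_gene, dict(m.loadings)) for m in design.modules],
    )
    return CountMatrix(counts=counts.astype(np.int64), meta=meta), truth
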