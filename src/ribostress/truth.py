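"""Ground-truth bookkeeping for the synthetic generators.

A single ``TruthTable`` accompanies each simulated artefact: the read
simulator fills the per-read fields, the count simulator fills the per-gene
and per-module fields.  Downstream tests compare pipeline output against this
table, never against the pipeline itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ModuleTruth:
    name: str
    seed: str
    # gene -> signed latent loading (log2-scale standard deviations)
    loadings: dict[str, float]


@dataclass
class TruthTable:
    # read_id -> origin locus_id
    read_origin: dict[str, str] = field(default_factory=dict)
    # read_id -> strand the read was drawn from ("+" forward, "-" revcomp)
    read_strand: dict[str, str] = field(default_factory=dict)
    # gene -> planted log2 fold change (case vs control); 0 if unplanted
    true_log2fc: dict[str, float] = field(default_factory=dict)
    modules: list[ModuleTruth] = field(default_factory=list)

    def merge(self, other: "TruthTable") -> "TruthTable":
        merged = TruthTable(
            read_origin={**self.read_origin, **other.read_origin},
            read_strand={**self.read_strand, **other.read_strand},
            true_log2fc={**self.true_log2fc, **other.true_log2fc},
            modules=self.modules + other.modules,
        )
        return merged
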