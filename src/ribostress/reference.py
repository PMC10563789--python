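"""Composite reference with parent mRNAs and homologous pseudogene copies.

A *composite reference* holds the spliced mRNA sequence of each parent
ribosomal protein gene (RPG) as a standalone contig, plus decoy genomic
contigs in which mutated pseudogene copies of the parent mRNAs are embedded.
Reads can then be disambiguated between a parent and its pseudogenes by exact
matching: a read overlapping a diverged base matches exactly one locus.

Parent mRNAs are deliberately NOT also embedded in genomic contigs; a read
matching both a parent mRNA contig and a genomic exonic copy would always be
multi-locus, which would make simulated ground truth ambiguous.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = np.array(list("ACGT"))
_VALID_SEQ = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class Locus:
    """One annotated locus on a contig, 0-based half-open coordinates."""

    locus_id: str
    contig: str
    start: int
    end: int
    strand: str
    locus_class: str  # "parent" | "pseudogene" | "decoy"
    parent_of: str | None = None  # set iff locus_class == "pseudogene"


@dataclass
class CompositeReference:
    """Contigs, locus annotations and the ground-truth divergence map."""

    contigs: dict[str, str]
    loci: list[Locus]
    # pseudogene locus_id -> sorted positions (within the locus) where the
    # pseudogene differs from its parent mRNA
    truth_divergence: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, seq in self.contigs.items():
            if not _VALID_SEQ.match(seq):
                raise ValueError(f"contig {name!r} contains non-ACGT characters")
        ids = [loc.locus_id for loc in self.loci]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate locus ids")
        for loc in self.loci:
            if loc.contig not in self.contigs:
                raise ValueError(f"locus {loc.locus_id} references unknown contig {loc.contig}")
            if not (0 <= loc.start < loc.end <= len(self.contigs[loc.contig])):
                raise ValueError(f"locus {loc.locus_id} out of contig bounds")
            if (loc.locus_class == "pseudogene") != (loc.parent_of is not None):
                raise ValueError(f"locus {loc.locus_id}: parent_of set iff pseudogene")

    @property
    def locus_map(self) -> dict[str, Locus]:
        return {loc.locus_id: loc for loc in self.loci}

    def locus_seq(self, locus_id: str) -> str:
        loc = self.locus_map[locus_id]
        seq = self.contigs[loc.contig][loc.start : loc.end]
        if loc.strand == "-":
            seq = revcomp(seq)
        return seq

    # ---- file IO -----------------------------------------------------------

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self.contigs.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_loci_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tstart\tend\tstrand\tlocus_id\tclass\tparent_of\n")
            for loc in self.loci:
                fh.write(
                    f"{loc.contig}\t{loc.start}\t{loc.end}\t{loc.strand}\t"
                    f"{loc.locus_id}\t{loc.locus_class}\t{loc.parent_of or '.'}\n"
                )

    @classmethod
    def read(cls, fasta: str | Path, loci_tsv: str | Path) -> "CompositeReference":
        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
        loci = []
        with open(loci_tsv) as fh:
            header = fh.readline()
            assert header.startswith("contig")
            for line in fh:
                contig, start, end, strand, lid, cls_, parent = line.rstrip("\n").split("\t")
                loci.append(
                    Locus(lid, contig, int(start), int(end), strand, cls_,
                          None if parent == "." else parent)
                )
        return cls(contigs=contigs, loci=loci)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def generate_composite_reference(
    n_parents: int = 8,
    pseudos_per_parent: int = 2,
    mrna_len: int = 400,
    divergence_rate: float = 0.05,
    seed: int = 0,
    flank_len: int = 150,
    n_decoys: int = 2,
    decoy_len: int = 400,
) -> CompositeReference:
    """Generate a toy composite reference with known pseudogene divergence.

    Each parent mRNA is a random sequence stored as its own contig.  Each
    pseudogene is a copy of its parent with i.i.d. per-base substitutions at
    ``divergence_rate``, embedded between random flanks in a decoy genomic
    contig; every substituted position is recorded in ``truth_divergence``.

    Parameters
    ----------
    divergence_rate
        Per-base substitution probability in [0, 1]; 0 yields pseudogenes
        identical to their parents (every read from either becomes
        multi-locus under exact matching).
    """
    if not 0.0 <= divergence_rate <= 1.0:
        raise ValueError(f"divergence_rate must be in [0, 1], got {divergence_rate}")
    if n_parents < 1 or mrna_len < 1 or pseudos_per_parent < 0:
        raise ValueError("n_parents, mrna_len must be >= 1; pseudos_per_parent >= 0")

    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    loci: list[Locus] = []
    truth: dict[str, list[int]] = {}

    for i in range(1, n_parents + 1):
        parent_id = f"Rpl{i}"
        mrna = random_seq(rng, mrna_len)
        contig_name = f"{parent_id}_mrna"
        contigs[contig_name] = mrna
        loci.append(Locus(parent_id, contig_name, 0, mrna_len, "+", "parent"))

        for j in range(1, pseudos_per_parent + 1):
            ps_id = f"{parent_id}-ps{j}"
            pos = np.flatnonzero(rng.random(mrna_len) < divergence_rate)
            ps = list(mrna)
            for p in pos:
                choices = [b for b in "ACGT" if b != ps[p]]
                ps[p] = choices[rng.integers(len(choices))]
            region = random_seq(rng, flank_len) + "".join(ps) + random_seq(rng, flank_len)
            contig_name = f"{ps_id}_region"
            contigs[contig_name] = region
            loci.append(
                Locus(ps_id, contig_name, flank_len, flank_len + mrna_len, "+",
                      "pseudogene", parent_of=parent_id)
            )
            truth[ps_id] = [int(p) for p in pos]

    for k in range(1, n_decoys + 1):
        name = f"Decoy{k}"
        contigs[f"{name}_contig"] = random_seq(rng, decoy_len)
        loci.append(Locus(name, f"{name}_contig", 0, decoy_len, "+", "decoy"))

    return CompositeReference(contigs=contigs, loci=loci, truth_divergence=truth)
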