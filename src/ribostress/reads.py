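"""Error-free read simulation from a composite reference.

Reads are exact substrings of their origin locus (forward or reverse
complement), with constant maximum base quality.  Sequencing errors are
deliberately absent: the downstream assigner forbids mismatches, so an
erroneous read could only fall into the unmapped class and would not
exercise the parent/pseudogene disambiguation logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import CompositeReference, revcomp
from .truth import TruthTable

MAX_QUAL = 40  # Phred; written as "I" in Phred+33


@dataclass(frozen=True)
class Read:
    read_id: str
    seq: str


def simulate_reads(
    ref: CompositeReference,
    read_len: int = 60,
    depth_per_locus: int = 40,
    seed: int = 0,
) -> tuple[list[Read], TruthTable]:
    """Draw ``depth_per_locus`` error-free reads from every locus.

    Offsets are uniform over valid positions; each read is taken from the
    forward or reverse-complement strand with equal probability.  The
    returned truth table records origin locus and strand per read.
    """
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    truth = TruthTable()
    for loc in ref.loci:
        seq = ref.locus_seq(loc.locus_id)
        if read_len > len(seq):
            raise ValueError(
                f"read_len {read_len} exceeds length of locus {loc.locus_id} ({len(seq)})"
            )
        if depth_per_locus == 0:
            continue
        offsets = rng.integers(0, len(seq) - read_len + 1, size=depth_per_locus)
        rev = rng.random(depth_per_locus) < 0.5
        for i, (off, r) in enumerate(zip(offsets, rev)):
            rid = f"{loc.locus_id}:{i}"
            fragment = seq[off : off + read_len]
            reads.append(Read(rid, revcomp(fragment) if r else fragment))
            truth.read_origin[rid] = loc.locus_id
            truth.read_strand[rid] = "-" if r else "+"
    return reads, truth


def write_fastq(reads: list[Read], path: str | Path) -> None:
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.seq), id=read.read_id, description="")
        rec.letter_annotations["phred_quality"] = [MAX_QUAL] * len(read.seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[Read]:
    return [Read(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]
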