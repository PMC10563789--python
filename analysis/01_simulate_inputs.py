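#!/usr/bin/env python
"""Generate every synthetic input the analysis consumes, with known truth.

Writes to results/analysis/inputs: a composite reference (parent RPG mRNAs +
diverged pseudogene copies in decoy contigs) with error-free reads, and for
each species a two-sex NB count matrix in which 15 RPGs of the 80-member RPG
family are planted down (log2FC -1), the 10 RP pseudogenes are planted up
(log2FC +1) loading on the shared latent factor with opposite sign, and 25
synapse genes co-vary with the RPG module.  Also writes the run config used
by the later steps.
"""

from pathlib import Path

import yaml

from ribostress.counts import simulate_counts
from ribostress.fixtures import generate_fixtures
from ribostress.pipeline import RunConfig, build_demo_design, planted_rpgs
from ribostress.reads import simulate_reads, write_fastq
from ribostress.reference import generate_composite_reference

SEED = 42
OUTDIR = Path("results/analysis")
INPUTS = OUTDIR / "inputs"


def main() -> None:
    INPUTS.mkdir(parents=True, exist_ok=True)
    fixtures = generate_fixtures(seed=SEED)
    paths = {k: str(v) for k, v in fixtures.write(INPUTS).items()}

    ref = generate_composite_reference(seed=SEED)
    ref.write_fasta(INPUTS / "reference.fa")
    ref.write_loci_tsv(INPUTS / "loci.tsv")
    reads, truth = simulate_reads(ref, seed=SEED)
    write_fastq(reads, INPUTS / "reads.fq")
    paths |= {"ref_fasta": str(INPUTS / "reference.fa"),
              "loci_tsv": str(INPUTS / "loci.tsv"),
              "reads_fastq": str(INPUTS / "reads.fq")}

    for species in ("mouse", "human"):
        design = build_demo_design(fixtures.universe, species, SEED)
        cm, _ = simulate_counts(design)
        cm.write_tsv(INPUTS / f"counts_{species}.tsv", INPUTS / f"meta_{species}.tsv")
        paths |= {f"counts_{species}": str(INPUTS / f"counts_{species}.tsv"),
                  f"meta_{species}": str(INPUTS / f"meta_{species}.tsv")}
        print(f"{species}: {cm.counts.shape[0]} genes x {cm.counts.shape[1]} samples")

    cfg = RunConfig(outdir=str(OUTDIR), seed=SEED, paths=paths)
    (OUTDIR / "run_config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    print(f"reference: {len(ref.loci)} loci, {len(reads)} reads")
    print(f"planted down-regulated RPGs: {len(planted_rpgs(fixtures.universe))}")
    print(f"config -> {OUTDIR / 'run_config.yaml'}")


if __name__ == "__main__":
    main()
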