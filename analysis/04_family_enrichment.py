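#!/usr/bin/env python
"""Gene-family enrichment and the cross-species common down-regulated set.

Each family is tested for over-representation in every (species, direction)
DE set with the hypergeometric upper tail (one-sided Fisher), BH-corrected
across families.  Mouse symbols are harmonised into the human namespace and
the down-regulated sets intersected — the resulting common RPGs become the
seeds for the co-expression step.
"""

from pathlib import Path

import pandas as pd

from ribostress.pipeline import RunConfig, stage_families

OUTDIR = Path("results/analysis")


def main() -> None:
    cfg = RunConfig.from_file(OUTDIR / "run_config.yaml")
    info = stage_families(cfg, OUTDIR)
    enr = pd.read_csv(OUTDIR / "family_enrichment.tsv", sep="\t")
    rpg = enr[(enr["family"] == "RPG") & (enr["direction"] == "down")]
    print(f"universe size: {info['universe_size']}")
    print("RPG family, down direction:")
    print(rpg[["contrast", "k", "K", "n", "q"]].to_string(index=False))
    print(f"families q<0.05 (down): {info['significant_down_families']}")
    print(f"common down-regulated orthologs: {info['n_common_down']} "
          f"-> {OUTDIR / 'common_down.tsv'}")


if __name__ == "__main__":
    main()
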