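#!/usr/bin/env python
"""Seeded co-expression networks per (species, sex, group) stratum.

The common down-regulated RPGs act as network seeds: within each stratum,
every other gene is Spearman-correlated with each seed and genes passing
raw p < 0.05 are split into positively and negatively correlated lists.
The anti-correlated pseudogene block should surface in the negative lists.
"""

from pathlib import Path

import pandas as pd

from ribostress.pipeline import RunConfig, stage_seednet

OUTDIR = Path("results/analysis")


def main() -> None:
    cfg = RunConfig.from_file(OUTDIR / "run_config.yaml")
    info = stage_seednet(cfg, OUTDIR)
    table = pd.read_csv(OUTDIR / "seed_networks.tsv", sep="\t")
    print(f"{info['n_strata']} strata, {info['n_edges']} seed-gene correlations at p<0.05")
    by_sign = table.groupby("sign").size()
    print(by_sign.to_string())
    pseudo = table[table["gene"].str.contains("AS1$|-ps1$", regex=True)]
    print(f"pseudogene correlate entries: {len(pseudo)} "
          f"({(pseudo['sign'] == 'negative').mean():.0%} negative)")


if __name__ == "__main__":
    main()
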