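#!/usr/bin/env python
"""GO theme clustering and the signed condition x pathway matrices.

Per stratum and correlation sign, GO over-representation runs on the
seed-correlate lists (q < 0.05, annotations propagated to ancestors); each
significant term is clustered into themes by keyword or anchor descent.  The
signed matrix mirrors a condition x pathway heatmap with per-term
contributing-seed counts; the final overlap maps pathways of down-regulated
RPGs against those of up-regulated pseudogenes (suffix-stripped to parents).
"""

from pathlib import Path

import pandas as pd

from ribostress.pipeline import RunConfig, stage_themes

OUTDIR = Path("results/analysis")


def main() -> None:
    cfg = RunConfig.from_file(OUTDIR / "run_config.yaml")
    info = stage_themes(cfg, OUTDIR)
    themed = pd.read_csv(OUTDIR / "themed_enrichment.tsv", sep="\t")
    print(f"{info['n_themed_rows']} (stratum, sign, term) rows at q<0.05")
    print("themes by sign:")
    print(themed.groupby(["sign"])["themes"].value_counts().to_string())
    print(f"negative-sign terms: {info['negative_terms']}")
    ov = info["pathway_overlap"]
    print(f"RPG-vs-pseudogene pathway overlap: {ov['shared']} shared, "
          f"{ov['only_down_rpg']} RPG-only, {ov['only_up_pseudogene']} pseudogene-only")
    print(f"matrix -> {OUTDIR / 'theme_matrix.tsv'}")


if __name__ == "__main__":
    main()
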