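#!/usr/bin/env python
"""Two-group differential expression per species.

Low-count genes (mean count <= 5 across samples) are removed, log-CPM values
are residualised on the nuisance covariates (age, RNA integrity, sex), and a
Welch t test compares stress vs control.  The mouse contrast is thresholded
on BH q < 0.05, the human contrast on raw p < 0.05, mirroring the different
selection rules conventionally used for chronic-stress and MDD cohorts.
"""

from pathlib import Path

from ribostress.pipeline import RunConfig, stage_de

OUTDIR = Path("results/analysis")


def main() -> None:
    cfg = RunConfig.from_file(OUTDIR / "run_config.yaml")
    info = stage_de(cfg, OUTDIR)
    for species, stats in info.items():
        print(f"{species}: {stats['n_genes']} genes tested ({stats['mode']}); "
              f"{stats['n_up']} up, {stats['n_down']} down")
    print(f"DE tables -> {OUTDIR}/de_mouse.tsv, {OUTDIR}/de_human.tsv")


if __name__ == "__main__":
    main()
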