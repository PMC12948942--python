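"""Score the SCL-5 items: prorated raw scores (5-20), log-transform and
z-score within each (role, wave) stratum, plus the lockdown day covariate.
"""

import importlib.util
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location("config", Path(__file__).parent / "00_config.py")
cfg = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg)

from triofx import scoring


def main():
    out = cfg.RUN_DIR
    pheno = pd.read_csv(out / "phenotypes.tsv", sep="\t")
    scored = scoring.score_phenotype_table(pheno, cutoff_flag=True)
    scored.to_csv(out / "scored_phenotypes.tsv", sep="\t", index=False, float_format="%.10g")
    n_scored = scored["raw_score"].notna().sum()
    above = scored["above_cutoff"].mean()
    print(f"scored {n_scored}/{len(scored)} person-waves (>=2 items answered)")
    print(f"  mean raw score {scored['raw_score'].mean():.2f} (scale 5-20), "
          f"{above:.1%} above the 2.0 mean-item cutoff")


if __name__ == "__main__":
    main()
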