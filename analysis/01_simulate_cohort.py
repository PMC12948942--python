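"""Simulate the synthetic trio cohort and write its on-disk tables.

Writes genotypes.tsv (dosages for all three roles), phenotypes.tsv
(item-level distress per wave with covariates), pgs.tsv (five-trait
polygenic scores), and a manifest echoing the full configuration.
"""

import importlib.util
import sys
from pathlib import Path

spec = importlib.util.spec_from_file_location("config", Path(__file__).parent / "00_config.py")
cfg = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg)

from triofx import simulate as sim


def main():
    out = cfg.RUN_DIR
    out.mkdir(parents=True, exist_ok=True)
    config = cfg.COHORT
    geno = sim.simulate_trio_genotypes(config)
    effects = sim.draw_effect_vectors(config)
    pheno = sim.render_item_responses(
        sim.simulate_latent_phenotypes(geno, effects, config), config
    )
    scores = sim.simulate_pgs(geno, effects, config)
    sim.write_dosage_tsv(geno, out / "genotypes.tsv")
    sim.write_phenotype_tsv(pheno, out / "phenotypes.tsv")
    sim.write_pgs_tsv(scores, out / "pgs.tsv")
    sim.write_manifest(config, out / "manifest.json")
    n_consistent = sim.mendelian_consistent(geno).all()
    print(f"cohort: {config.n_families} families x {config.n_snps} SNPs -> {out}")
    print(f"  Mendelian-consistent offspring genotypes: {bool(n_consistent)}")
    print(f"  records: {len(pheno)} person-waves, {scores['trait'].nunique()} PGS traits")


if __name__ == "__main__":
    main()
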