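"""Pipeline orchestration: simulate -> score -> GRM -> Trio-GCTA -> Trio-PGS.

A run is declared by one YAML config, executes stage by stage through the
on-disk TSV formats (so stages can be re-run independently), and leaves a
manifest with the full echoed configuration, seed, input hashes and row
counts.  All result tables carry the config hash and seed as comment
headers and are byte-identical across reruns with the same seed; the
manifest additionally records wall-clock timings and is therefore the one
non-deterministic file.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gcta, grm as grmmod, pgs as pgsmod, scoring, simulate as sim

__all__ = ["RunConfig", "run_all", "render_report", "StageError"]

DEFAULT_TRAITS = ("anxiety", "depression", "neuroticism", "ADHD", "AN")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    simulate: sim.SimConfig | None = None
    geno_path: str | None = None
    pheno_path: str | None = None
    pgs_path: str | None = None
    min_maf: float = 0.01
    unrelated_threshold: float = 0.05
    gcta_focal_roles: tuple[str, ...] = ("offspring",)
    gcta_waves: tuple[int, ...] = (1,)
    gcta_covariates: tuple[str, ...] = ("sex",)
    gcta_restarts: int = 2
    pgs_focal_roles: tuple[str, ...] = ()
    pgs_traits: tuple[str, ...] = DEFAULT_TRAITS
    pgs_interactions: bool = False
    restrict_to_shared_household: bool = False

    def __post_init__(self):
        if self.simulate is None and not (self.geno_path and self.pheno_path):
            raise ValueError("either a simulate block or input paths must be given")
        if isinstance(self.simulate, dict):
            self.simulate = sim.SimConfig(**self.simulate)
        if self.simulate is not None:
            self.simulate.seed = self.seed
        if not (self.gcta_focal_roles or self.pgs_focal_roles):
            raise ValueError("analysis grid is empty")
        for p in ("geno_path", "pheno_path", "pgs_path"):
            v = getattr(self, p)
            if self.simulate is None and v is not None and not Path(v).exists():
                raise FileNotFoundError(f"{p}: {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)

    def to_jsonable(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_jsonable()
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def config_hash(self) -> str:
        """Hash of the analysis-defining fields (where outputs land is not
        part of the analysis identity)."""
        doc = {k: v for k, v in self.to_jsonable().items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash()}\tseed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def run_all(config: RunConfig) -> Path:
    """Execute the declared grid; returns the run directory.

    Any stage failure writes a ``failed/<stage>.txt`` marker (partial
    outputs persist) and re-raises as :class:`StageError`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_jsonable(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    stage = "simulate"
    try:
        t0 = time.time()
        if config.simulate is not None:
            sc = config.simulate
            geno = sim.simulate_trio_genotypes(sc)
            effects = sim.draw_effect_vectors(sc)
            pheno = sim.simulate_latent_phenotypes(geno, effects, sc)
            pheno = sim.render_item_responses(pheno, sc)
            scores = sim.simulate_pgs(geno, effects, sc)
            sim.write_dosage_tsv(geno, out / "genotypes.tsv")
            sim.write_phenotype_tsv(pheno, out / "phenotypes.tsv")
            sim.write_pgs_tsv(scores, out / "pgs.tsv")
            geno_path, pheno_path, pgs_path = (
                out / "genotypes.tsv",
                out / "phenotypes.tsv",
                out / "pgs.tsv",
            )
        else:
            geno_path = Path(config.geno_path)
            pheno_path = Path(config.pheno_path)
            pgs_path = Path(config.pgs_path) if config.pgs_path else None
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "inputs": {
                name: _file_hash(p)
                for name, p in (("geno", geno_path), ("pheno", pheno_path))
            },
        }

        stage = "score"
        t0 = time.time()
        pheno = pd.read_csv(pheno_path, sep="\t")
        if config.restrict_to_shared_household and "same_household" in pheno.columns:
            pheno = pheno[pheno["same_household"] == 1]
        scored = scoring.score_phenotype_table(pheno)
        _write_table(scored, out / "scored_phenotypes.tsv", config)
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "rows": int(len(scored)),
            "scored": int(scored["raw_score"].notna().sum()),
        }

        stage = "grm"
        t0 = time.time()
        geno = sim.read_dosage_tsv(geno_path)
        grms = grmmod.build_grm_set(geno, min_maf=config.min_maf)
        kept = grmmod.filter_unrelated(grms, config.unrelated_threshold)
        grms_u = grms.subset(kept)
        grmmod.write_grm_set(grms_u, out / "grm")
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "families": int(grms.n_families),
            "families_unrelated": int(len(kept)),
            "n_snps_used": grms.n_snps_used,
        }

        stage = "gcta"
        t0 = time.time()
        grms_u = grmmod.read_grm_set(out / "grm")
        scored = _read_table(out / "scored_phenotypes.tsv")
        comp_rows = []
        for focal_role in config.gcta_focal_roles:
            for wave in config.gcta_waves:
                comp = gcta.run_model_comparison(
                    grms_u,
                    scored,
                    focal_role,
                    wave,
                    covariates=list(config.gcta_covariates),
                    options=gcta.FitOptions(restarts=config.gcta_restarts, seed=config.seed),
                )
                frame = comp.to_frame()
                frame.insert(0, "wave", wave)
                frame.insert(0, "focal_role", focal_role)
                comp_rows.append(frame)
        if comp_rows:
            _write_table(pd.concat(comp_rows, ignore_index=True),
                         out / "gcta_model_comparison.tsv", config)
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "grid": len(comp_rows),
        }

        stage = "pgs"
        t0 = time.time()
        if config.pgs_focal_roles and pgs_path is not None:
            scores = pd.read_csv(pgs_path, sep="\t")
            table = pgsmod.fit_pgs_grid(
                scored,
                scores,
                config.pgs_focal_roles,
                config.pgs_traits,
                interactions=config.pgs_interactions,
            )
            _write_table(table, out / "pgs_coefficients.tsv", config)
            manifest["stages"][stage] = {
                "seconds": round(time.time() - t0, 3),
                "models": len(config.pgs_focal_roles) * len(config.pgs_traits),
            }
        else:
            manifest["stages"][stage] = {"skipped": True}
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        (failed / f"{stage}.txt").write_text(f"{type(exc).__name__}: {exc}\n")
        raise StageError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def render_report(run_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Summary tables for a completed run.

    Returns (and writes under ``<run_dir>/report/``) a stacked
    variance-share table across the five models with the selected-model
    marker, and, when present, a PGS coefficient table with FDR stars.
    Shares are copied from the fit output, never recomputed.
    """
    run = Path(run_dir)
    missing = [p for p in ("gcta_model_comparison.tsv",) if not (run / p).exists()]
    if missing:
        raise FileNotFoundError(f"run is missing stage outputs: {missing}")
    report_dir = run / "report"
    report_dir.mkdir(exist_ok=True)
    out: dict[str, pd.DataFrame] = {}

    comp = _read_table(run / "gcta_model_comparison.tsv")
    share_cols = [c for c in comp.columns if c.startswith("share_")]
    shares = comp[
        ["focal_role", "wave", "model", "selected", "aic", "bic", "loglik"] + share_cols
    ].copy()
    shares["selected_marker"] = np.where(shares["selected"], "*", "")
    shares.to_csv(report_dir / "variance_shares.tsv", sep="\t", index=False,
                  float_format="%.10g")
    out["variance_shares"] = shares

    pgs_path = run / "pgs_coefficients.tsv"
    if pgs_path.exists():
        pgs_tab = _read_table(pgs_path)
        main = pgs_tab[pgs_tab["role"].notna()].copy()
        main["sig_fdr"] = np.where(main["q"] < 0.05, "*", "")
        main.to_csv(report_dir / "pgs_forest.tsv", sep="\t", index=False,
                    float_format="%.10g")
        out["pgs_forest"] = main
    return out
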