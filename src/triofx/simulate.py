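"""Synthetic trio-cohort generator.

Emulates a Norwegian-registry-style family cohort: mother/father/offspring
trios genotyped at M biallelic SNPs, role-specific SNP effects drawn from a
3x3 genetic covariance, longitudinal 5-item ordinal distress responses over
up to three lockdown waves, sibling clusters sharing a mother, polygenic
scores as noisy proxies of true genetic values, and item/wave missingness.

Everything is deterministic given ``SimConfig.seed``; each stage draws from
its own seeded stream so stages can be re-run independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .params import VCParams

__all__ = [
    "SimConfig",
    "TrioGenotypes",
    "EffectVectors",
    "ROLES",
    "ROLE_CODES",
    "focal_slot_roles",
    "simulate_trio_genotypes",
    "draw_effect_vectors",
    "simulate_latent_phenotypes",
    "render_item_responses",
    "simulate_pgs",
    "simulate_pgs_outcome",
    "mendelian_consistent",
    "standardize_by_freqs",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_plink_raw",
    "write_phenotype_tsv",
    "write_pgs_tsv",
    "write_manifest",
]

ROLES = ("offspring", "mother", "father")
ROLE_CODES = {"offspring": "o", "mother": "m", "father": "f"}

#: ages (mean, sd) in years for a lockdown trio sample
DEFAULT_AGES = {"offspring": (16.9, 0.6), "mother": (47.1, 4.5), "father": (49.4, 5.1)}

#: proxy-quality (squared correlation with the true genetic value) per trait
DEFAULT_PGS_R2 = {
    "anxiety": 0.10,
    "depression": 0.20,
    "neuroticism": 0.20,
    "ADHD": 0.15,
    "AN": 0.10,
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def focal_slot_roles(focal_role: str) -> tuple[str, str, str]:
    """Map a focal role to the (direct, indirect-1, indirect-2) role slots.

    The focal person's own genotype always carries the direct component.
    For a focal offspring the indirect slots are (mother, father); for a
    focal parent they are (partner, child).
    """
    if focal_role == "offspring":
        return ("offspring", "mother", "father")
    if focal_role == "mother":
        return ("mother", "father", "offspring")
    if focal_role == "father":
        return ("father", "mother", "offspring")
    raise ConfigError(f"unknown focal role {focal_role!r}")


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_families: int = 1000
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    focal_role: str = "offspring"
    truth: VCParams = field(
        default_factory=lambda: VCParams(
            sigma2_o=0.088, sigma2_m=0.104, sigma_om=-0.013, sigma2_e=0.82
        )
    )
    fixed_effects: dict[str, float] = field(default_factory=lambda: {"sex": 0.2})
    n_timepoints: int = 3
    wave_autocorrelation: float = 0.5
    sibling_fraction: float = 0.1
    pgs_r2: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PGS_R2))
    #: correlation of each trait's true SNP weights with the direct-effect
    #: vector; 0 keeps polygenic scores orthogonal to the distress genetics
    pgs_loading: dict[str, float] = field(default_factory=dict)
    missing_item_rate: float = 0.02
    missing_wave_rate: float = 0.15
    item_cutpoints: tuple[float, float, float] = (0.8, 1.6, 2.4)
    item_noise_sd: float = 0.3
    #: demonstration knob only: rank-based assortment of parental genetic
    #: scores; 0 = random mating (the default and the assumed regime)
    mating_correlation: float = 0.0
    household_rate: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_families < 1 or self.n_snps < 1:
            raise ConfigError("n_families and n_snps must be >= 1")
        if not (1 <= self.n_timepoints <= 3):
            raise ConfigError("n_timepoints must be 1-3")
        if not (0 <= self.wave_autocorrelation < 1):
            raise ConfigError("wave_autocorrelation must be in [0, 1)")
        for name in ("sibling_fraction", "missing_item_rate", "missing_wave_rate", "household_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be a probability, got {v}")
        for trait, r2 in self.pgs_r2.items():
            if not (0 < r2 <= 1):
                raise ConfigError(f"pgs_r2[{trait!r}] must be in (0, 1], got {r2}")
        if self.focal_role not in ROLES:
            raise ConfigError(f"focal_role must be one of {ROLES}")
        if isinstance(self.truth, dict):
            self.truth = VCParams.from_dict(self.truth)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["truth"] = self.truth.as_dict()
        return d

    def rng(self, stream: int) -> np.random.Generator:
        """A deterministic per-stage random stream."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class TrioGenotypes:
    """Minor-allele dosage matrices for each trio role, one row per family."""

    family_ids: np.ndarray
    mother_dosages: np.ndarray
    father_dosages: np.ndarray
    offspring_dosages: np.ndarray
    allele_freqs: np.ndarray
    maternal_cluster_ids: np.ndarray

    def __post_init__(self) -> None:
        shapes = {
            self.mother_dosages.shape,
            self.father_dosages.shape,
            self.offspring_dosages.shape,
        }
        if len(shapes) != 1:
            raise ValueError(f"role dosage matrices differ in shape: {shapes}")
        if self.allele_freqs.shape[0] != self.mother_dosages.shape[1]:
            raise ValueError("allele_freqs length does not match SNP dimension")

    @property
    def n_families(self) -> int:
        return self.mother_dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.mother_dosages.shape[1]

    def dosages(self, role: str) -> np.ndarray:
        return {
            "mother": self.mother_dosages,
            "father": self.father_dosages,
            "offspring": self.offspring_dosages,
        }[role]

    def person_ids(self, role: str) -> np.ndarray:
        code = ROLE_CODES[role]
        return np.array([f"{fid}_{code}" for fid in self.family_ids])


@dataclass
class EffectVectors:
    """Per-SNP effect triplets on the standardized-genotype scale.

    Column order is (direct, indirect-1, indirect-2) matching
    :func:`focal_slot_roles`; per-SNP triplets have covariance ``Sigma_g/M``
    so total genetic variance contributions equal the configured block.
    """

    beta: np.ndarray  # M x 3

    @property
    def b_direct(self) -> np.ndarray:
        return self.beta[:, 0]


# ---------------------------------------------------------------------------
# genotypes


def simulate_trio_genotypes(config: SimConfig) -> TrioGenotypes:
    """Draw founder parents under Hardy-Weinberg and Mendelian offspring.

    Parents are independent founders at SNP-specific minor-allele
    frequencies sampled uniformly in ``maf_range``; each offspring receives
    one allele per parent per SNP with transmission probability dosage/2.
    A ``sibling_fraction`` share of families is reassigned an existing
    maternal cluster (sharing that cluster's simulated mother genotype).
    """
    n, m = config.n_families, config.n_snps
    rng = config.rng(1)
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    mother = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)
    father = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)

    if config.mating_correlation > 0:
        mother, father = _assort_parents(mother, father, mafs, config.mating_correlation, rng)

    family_ids = np.array([f"F{i:05d}" for i in range(n)])
    cluster_ids = np.array([f"M{i:05d}" for i in range(n)])

    n_sib = int(round(config.sibling_fraction * n))
    if n_sib > 0 and n >= 2:
        sibs = rng.choice(n, size=n_sib, replace=False)
        donors_pool = np.setdiff1d(np.arange(n), sibs)
        if donors_pool.size == 0:  # everything a sibling: chain to family 0
            donors_pool = np.array([0])
            sibs = sibs[sibs != 0]
        donors = rng.choice(donors_pool, size=sibs.size, replace=True)
        mother[sibs] = mother[donors]
        cluster_ids[sibs] = cluster_ids[donors]

    offspring = (
        rng.binomial(1, mother / 2.0).astype(np.int8)
        + rng.binomial(1, father / 2.0).astype(np.int8)
    )
    return TrioGenotypes(
        family_ids=family_ids,
        mother_dosages=mother,
        father_dosages=father,
        offspring_dosages=offspring,
        allele_freqs=mafs,
        maternal_cluster_ids=cluster_ids,
    )


def _assort_parents(mother, father, mafs, rho, rng):
    """Re-pair couples by noisy rank-matching of genotypic scores.

    A deliberately crude device to demonstrate the bias assortative mating
    induces in indirect-effect estimates; not an equilibrium model.
    """
    z_m = standardize_by_freqs(mother, mafs).mean(axis=1)
    z_f = standardize_by_freqs(father, mafs).mean(axis=1)
    noise = np.sqrt(max(1.0 / max(rho, 1e-6) ** 2 - 1.0, 0.0))
    target = z_m + noise * rng.standard_normal(z_m.size) * z_m.std()
    order_m = np.argsort(np.argsort(target))
    order_f = np.argsort(z_f)
    father = father[order_f][order_m]
    return mother, father


def mendelian_consistent(geno: TrioGenotypes) -> np.ndarray:
    """Boolean n x M mask: offspring dosage reachable from parental pair.

    A child allele count is reachable iff it equals t_m + t_f for some
    transmissible t_r (t=0 for dosage 0, t=1 for dosage 2, either for 1).
    """
    lo = (geno.mother_dosages == 2).astype(np.int8) + (geno.father_dosages == 2).astype(np.int8)
    hi = 2 - (geno.mother_dosages == 0).astype(np.int8) - (geno.father_dosages == 0).astype(np.int8)
    off = geno.offspring_dosages
    return (off >= lo) & (off <= hi)


def standardize_by_freqs(dosages: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """(x - 2p) / sqrt(2p(1-p)) per SNP, using generating frequencies."""
    p = np.asarray(freqs, dtype=float)
    return (dosages - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


# ---------------------------------------------------------------------------
# effects & phenotypes


def draw_effect_vectors(config: SimConfig) -> EffectVectors:
    """M independent effect triplets from N(0, Sigma_g / M).

    The genetic block may be singular (components fixed at zero), so the
    factor is built from a clipped eigendecomposition rather than Cholesky.
    """
    sigma = config.truth.genetic_block()
    w, q = np.linalg.eigh(sigma)
    if w.min() < -1e-8 * max(1.0, abs(w).max()):
        raise ConfigError(
            f"genetic covariance block not positive semidefinite: eigenvalue {w.min():.3e}"
        )
    root = q @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    rng = config.rng(2)
    beta = rng.standard_normal((config.n_snps, 3)) @ root.T / np.sqrt(config.n_snps)
    return EffectVectors(beta=beta)


def _simulate_covariates(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Stand-in confounders: child sex, focal age, batch, 10 PC dummies."""
    n = config.n_families
    age_mu, age_sd = DEFAULT_AGES[config.focal_role]
    cov = {
        "sex": rng.integers(0, 2, size=n).astype(float),  # child sex, 1 = female
        "age": rng.normal(age_mu, age_sd, size=n),
        "batch": rng.integers(0, 2, size=n).astype(float),
    }
    for k in range(1, 11):
        cov[f"pc{k}"] = rng.standard_normal(n)
    cov["same_household"] = (rng.uniform(size=n) < config.household_rate).astype(int)
    return pd.DataFrame(cov)


def simulate_latent_phenotypes(
    geno: TrioGenotypes, effects: EffectVectors, config: SimConfig
) -> pd.DataFrame:
    """Latent continuous distress for the focal person at each wave.

    latent_it = Z_focal b_direct + Z_ind1 b_1 + Z_ind2 b_2
                + sum_c coef_c x_c + eta_it

    with genotypes standardized by generating allele frequencies and eta an
    AR(1) residual with marginal variance sigma2_e and lag-1 correlation
    ``wave_autocorrelation``.  One row per focal person per wave.
    """
    if effects.beta.shape[0] != geno.n_snps:
        raise ValueError(
            f"effects have {effects.beta.shape[0]} SNPs but genotypes have {geno.n_snps}"
        )
    roles = focal_slot_roles(config.focal_role)
    g = np.zeros(geno.n_families)
    for slot, role in enumerate(roles):
        z = standardize_by_freqs(geno.dosages(role), geno.allele_freqs)
        g = g + z @ effects.beta[:, slot]

    rng = config.rng(3)
    cov = _simulate_covariates(config, rng)
    fixed = np.zeros(geno.n_families)
    for name, coef in config.fixed_effects.items():
        if name not in cov.columns:
            raise ConfigError(f"fixed effect on unknown covariate {name!r}")
        fixed = fixed + coef * cov[name].to_numpy()

    n, t = geno.n_families, config.n_timepoints
    sde = np.sqrt(config.truth.sigma2_e)
    rho = config.wave_autocorrelation
    eta = np.empty((n, t))
    eta[:, 0] = sde * rng.standard_normal(n)
    for k in range(1, t):
        eta[:, k] = rho * eta[:, k - 1] + np.sqrt(1 - rho**2) * sde * rng.standard_normal(n)

    # biweekly questionnaire windows within the first two lockdown months
    days = np.empty((n, t), dtype=int)
    for k in range(t):
        days[:, k] = np.minimum(14 * k + rng.integers(0, 14, size=n), 60)

    pid = geno.person_ids(config.focal_role)
    rows = []
    for k in range(t):
        df = pd.DataFrame(
            {
                "person_id": pid,
                "family_id": geno.family_ids,
                "maternal_cluster_id": geno.maternal_cluster_ids,
                "role": config.focal_role,
                "wave": k + 1,
                "date_offset_days": days[:, k],
                "latent": g + fixed + eta[:, k],
            }
        )
        rows.append(pd.concat([df, cov], axis=1))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["person_id", "wave"], ignore_index=True)


def render_item_responses(pheno: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Threshold latent scores into five ordinal items, then mask.

    Each item adds independent N(0, item_noise_sd^2) noise to the latent
    score and cuts at three fixed cutpoints, giving categories 1-4 with a
    right-skewed marginal for the default cutpoints.  Items are masked
    independently at ``missing_item_rate``; whole waves at
    ``missing_wave_rate``.  Masked entries are NaN.
    """
    latent = pheno["latent"].to_numpy()
    if not np.all(np.isfinite(latent)):
        raise ValueError("latent scores must be finite")
    rng = config.rng(4)
    n = latent.size
    cut = np.asarray(config.item_cutpoints)
    out = pheno.copy()
    for j in range(1, 6):
        noisy = latent + config.item_noise_sd * rng.standard_normal(n)
        item = 1.0 + (noisy[:, None] > cut[None, :]).sum(axis=1)
        item[rng.uniform(size=n) < config.missing_item_rate] = np.nan
        out[f"item{j}"] = item
    wave_mask = rng.uniform(size=n) < config.missing_wave_rate
    for j in range(1, 6):
        out.loc[wave_mask, f"item{j}"] = np.nan
    return out


# ---------------------------------------------------------------------------
# polygenic scores


def simulate_pgs(
    geno: TrioGenotypes, effects: EffectVectors, config: SimConfig
) -> pd.DataFrame:
    """Polygenic scores as noisy proxies of true genetic values.

    For each trait, true weights w (optionally correlated with the direct
    distress effects through ``pgs_loading``) are perturbed per SNP so that
    corr^2(Z w_hat, Z w) -> pgs_r2[trait]; every family member is scored
    with the SAME noisy weights.  Scores are standardized to mean 0 and
    variance 1 across the whole sample per trait.

    Returns a long frame: person_id, family_id, role, trait, score,
    true_score (the unattenuated genetic value, for validation).
    """
    m = geno.n_snps
    rng = config.rng(5)
    z_by_role = {
        role: standardize_by_freqs(geno.dosages(role), geno.allele_freqs) for role in ROLES
    }
    b_o = effects.beta[:, 0]
    sd_bo = b_o.std()
    frames = []
    for trait, r2 in config.pgs_r2.items():
        load = float(config.pgs_loading.get(trait, 0.0))
        w_indep = rng.standard_normal(m) / np.sqrt(m)
        if load != 0.0 and sd_bo > 0:
            w = load * b_o / (sd_bo * np.sqrt(m)) + np.sqrt(1 - load**2) * w_indep
        else:
            w = w_indep
        noise_sd = np.sqrt((1.0 - r2) / r2) * w.std()
        w_hat = w + noise_sd * rng.standard_normal(m)
        scores, true_scores, pids, roles_col, fids = [], [], [], [], []
        for role in ROLES:
            z = z_by_role[role]
            scores.append(z @ w_hat)
            true_scores.append(z @ w)
            pids.append(geno.person_ids(role))
            roles_col.extend([role] * geno.n_families)
            fids.append(geno.family_ids)
        s = np.concatenate(scores)
        s = (s - s.mean()) / s.std()
        frames.append(
            pd.DataFrame(
                {
                    "person_id": np.concatenate(pids),
                    "family_id": np.concatenate(fids),
                    "role": roles_col,
                    "trait": trait,
                    "score": s,
                    "true_score": np.concatenate(true_scores),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_pgs_outcome(
    pgs: pd.DataFrame,
    trait: str,
    focal_role: str,
    betas: dict[str, float],
    *,
    n_timepoints: int = 3,
    time_slope: float = 0.0,
    pgs_time_slope: float = 0.0,
    intercept_sd: float = 0.5,
    resid_sd: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a long outcome table directly from observed trio PGS.

    The generative model matches the trio-PGS regression being tested:

        y_it = sum_r beta_r PGS_r + time_slope * d_it
               + pgs_time_slope * PGS_focal * (d_it - mean d) + u_i + e_it

    so each ``beta_r`` is exactly the true partial coefficient of that
    family member's observed (standardized) score.  Used by validation
    experiments where the trio-PGS stage is the estimator under test.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    wide = (
        pgs[pgs["trait"] == trait]
        .pivot(index="family_id", columns="role", values="score")
        .reset_index()
    )
    n = len(wide)
    u = intercept_sd * rng.standard_normal(n)
    focal_pid = [
        f"{fid}_{ROLE_CODES[focal_role]}" for fid in wide["family_id"]
    ]
    sex = rng.integers(0, 2, size=n).astype(float)
    age_mu, age_sd = DEFAULT_AGES[focal_role]
    age = rng.normal(age_mu, age_sd, size=n)
    rows = []
    days_all = np.empty((n, n_timepoints))
    for k in range(n_timepoints):
        days_all[:, k] = np.minimum(14 * k + rng.integers(0, 14, size=n), 60)
    d_mean = days_all.mean()
    for k in range(n_timepoints):
        d = days_all[:, k]
        y = (
            betas.get("offspring", 0.0) * wide["offspring"].to_numpy()
            + betas.get("mother", 0.0) * wide["mother"].to_numpy()
            + betas.get("father", 0.0) * wide["father"].to_numpy()
            + time_slope * d
            + pgs_time_slope * wide[focal_role].to_numpy() * (d - d_mean)
            + u
            + resid_sd * rng.standard_normal(n)
        )
        rows.append(
            pd.DataFrame(
                {
                    "person_id": focal_pid,
                    "family_id": wide["family_id"],
                    "maternal_cluster_id": wide["family_id"],
                    "role": focal_role,
                    "wave": k + 1,
                    "date_offset_days": d,
                    "transformed_score": y,
                    "sex": sex,
                    "age": age,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# on-disk formats (plain TSV; PLINK .raw dialect optional)


def write_dosage_tsv(geno: TrioGenotypes, path: str | Path) -> None:
    """One row per person: person_id, family_id, role, then M dosage columns."""
    path = Path(path)
    snp_cols = [f"snp{j}" for j in range(geno.n_snps)]
    frames = []
    for role in ROLES:
        df = pd.DataFrame(geno.dosages(role), columns=snp_cols)
        df.insert(0, "role", role)
        df.insert(0, "family_id", geno.family_ids)
        df.insert(0, "person_id", geno.person_ids(role))
        df["maternal_cluster_id"] = geno.maternal_cluster_ids
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    header = "# allele_freqs\t" + "\t".join(f"{p:.8g}" for p in geno.allele_freqs) + "\n"
    with open(path, "w") as fh:
        fh.write(header)
        out.to_csv(fh, sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> TrioGenotypes:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        freqs = None
        if first.startswith("# allele_freqs"):
            freqs = np.array([float(x) for x in first.strip().split("\t")[1:]])
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    snp_cols = [c for c in df.columns if c.startswith("snp")]
    by_role = {role: df[df["role"] == role].sort_values("family_id") for role in ROLES}
    fam = by_role["mother"]["family_id"].to_numpy()
    cluster = (
        by_role["mother"]["maternal_cluster_id"].to_numpy()
        if "maternal_cluster_id" in df.columns
        else fam.copy()
    )
    mats = {role: by_role[role][snp_cols].to_numpy(dtype=np.int8) for role in ROLES}
    if freqs is None:
        parents = np.vstack([mats["mother"], mats["father"]])
        freqs = parents.mean(axis=0) / 2.0
    return TrioGenotypes(
        family_ids=fam,
        mother_dosages=mats["mother"],
        father_dosages=mats["father"],
        offspring_dosages=mats["offspring"],
        allele_freqs=freqs,
        maternal_cluster_ids=cluster,
    )


def write_plink_raw(geno: TrioGenotypes, path: str | Path) -> None:
    """PLINK ``.raw``-dialect export (FID IID PAT MAT SEX PHENOTYPE SNP_A...)."""
    path = Path(path)
    snp_cols = [f"snp{j}_A" for j in range(geno.n_snps)]
    frames = []
    for role in ROLES:
        pid = geno.person_ids(role)
        df = pd.DataFrame(geno.dosages(role), columns=snp_cols)
        df.insert(0, "PHENOTYPE", -9)
        df.insert(0, "SEX", {"mother": 2, "father": 1, "offspring": 0}[role])
        df.insert(0, "MAT", geno.person_ids("mother") if role == "offspring" else "0")
        df.insert(0, "PAT", geno.person_ids("father") if role == "offspring" else "0")
        df.insert(0, "IID", pid)
        df.insert(0, "FID", geno.family_ids)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep=" ", index=False)


def write_phenotype_tsv(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_pgs_tsv(pgs: pd.DataFrame, path: str | Path) -> None:
    pgs.drop(columns=[c for c in ("true_score",) if c in pgs.columns]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_manifest(config: SimConfig, path: str | Path, extra: dict | None = None) -> None:
    """Echo the full configuration and seed so a run can be reproduced."""
    doc = {"config": config.to_jsonable(), "seed": config.seed}
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
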