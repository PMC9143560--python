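"""Paired synthetic cohorts with known ground truth.

Emulates the data structure of two-cohort plasma metabolomics studies of
smokers with or at risk of COPD: a smaller training cohort and a larger
validation cohort, ~760 metabolites with block correlation, a sparse set
of true linear effects on a continuous outcome (FEV1-like, optionally a
lung-density-like second outcome), abundance-dependent (left-censored)
missingness spanning the three handling tiers, multiplicative batch
effects, technical noise, and clinical covariates that shift between
cohorts and contribute to the outcome.

What it does not emulate: mass-spectral peaks, retention times, or any
annotation chemistry — intensities are log-normal summaries.

The generative outcome model, per cohort, is::

    y_i = b0 + sum_c beta_c * z_ic  + sum_j beta_j * a_ij + eps_i

where ``z_ic`` are standardized clinical covariates, ``a_ij`` are latent
standardized log-abundances with equicorrelated blocks, the ``beta_j``
are nonzero for ``n_true_effects`` metabolites (fixed magnitude
``effect_sd``, random sign, at most one per block, forced into the
low-missingness tier), and ``eps`` is Gaussian.  Observed intensity is
``exp(mu_j + a_ij + technical noise + batch shift)``, then left-censored
per metabolite at a tier-specific abundance quantile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .preprocess import AbundanceMatrix

__all__ = ["SynthConfig", "TruthRecord", "CohortData", "generate_cohort_pair",
           "inject_missingness", "make_pathway_gmt", "write_cohort"]


@dataclass
class SynthConfig:
    """Study conditions for the paired-cohort generator.

    Defaults mirror a two-cohort design: train n=650 / validation n=1120,
    762 metabolites in 40 equicorrelated blocks (rho = 0.5), 25 true
    effects of magnitude 0.25 outcome units per SD of log-abundance, and
    a residual noise SD chosen so metabolites explain ~60% of outcome
    variance.  ``censor_quantiles = (share_low, share_mid)`` is the share
    of metabolites whose censoring lands in the <20% and 20-80% missing
    tiers (remainder > 80%).
    """

    n_train: int = 650
    n_valid: int = 1120
    p_metabolites: int = 762
    n_blocks: int = 40
    within_block_corr: float = 0.5
    n_true_effects: int = 25
    effect_sd: float = 0.25
    noise_sd: float = 0.905
    batch_count: int = 4
    batch_effect_sd: float = 0.3
    tech_noise_sd: float = 0.25
    censor_quantiles: tuple = (0.75, 0.20)
    covariate_effect_sizes: dict = field(default_factory=lambda: {
        "height_cm": 0.40, "age": -0.15, "sex": 0.20})
    cohort_shift: bool = True      # validation cohort: age +4y, different sites
    outcomes: tuple = ("fev1",)
    outcome_scale: dict = field(default_factory=lambda: {
        "fev1": 1.0, "lung_density": 10.0})
    outcome_intercept: dict = field(default_factory=lambda: {
        "fev1": 2.3, "lung_density": 84.0})
    seed: int = 0

    def __post_init__(self):
        if self.n_true_effects > self.p_metabolites:
            raise ValueError("n_true_effects must be <= p_metabolites")
        if not (0 <= self.within_block_corr < 1):
            raise ValueError("within_block_corr must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name in ("n_train", "n_valid", "p_metabolites", "n_blocks",
                     "batch_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if self.censor_quantiles is not None:
            q1, q2 = self.censor_quantiles
            if not (0 <= q1 <= 1 and 0 <= q2 <= 1 and q1 + q2 <= 1):
                raise ValueError("censor_quantiles must be tier shares summing <= 1")


@dataclass
class TruthRecord:
    """Ground truth for one outcome: support, coefficients, generative R^2."""

    true_support: list
    true_coefficients: dict
    true_covariate_effects: dict
    generative_r2: float

    def __post_init__(self):
        nz = {m for m, b in self.true_coefficients.items() if b != 0}
        if nz != set(self.true_support):
            raise ValueError("support must match nonzero coefficients exactly")

    def to_json(self, path=None):
        s = json.dumps(asdict(self))
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source):
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(**obj)


@dataclass
class CohortData:
    """One cohort: raw abundances plus the clinical table (outcome included)."""

    abundance: AbundanceMatrix
    clinical: pd.DataFrame


# ---------------------------------------------------------------------------


def _block_latents(rng, n, p, n_blocks, rho):
    """Standardized log-abundance latents with equicorrelated blocks."""
    sizes = np.full(n_blocks, p // n_blocks)
    sizes[: p % n_blocks] += 1
    shared = rng.standard_normal((n, n_blocks))
    own = rng.standard_normal((n, p))
    block_of = np.repeat(np.arange(n_blocks), sizes)
    return np.sqrt(rho) * shared[:, block_of] + np.sqrt(1 - rho) * own, block_of


def _covariates(rng, n, cfg: SynthConfig, cohort: str):
    shift = cfg.cohort_shift and cohort == "valid"
    age = rng.normal(67.3 if shift else 63.2, 8.9, n)
    sex = rng.binomial(1, 0.50 if shift else 0.54, n)  # 1 = male
    height = rng.normal(168.0, 9.0, n)
    bmi = rng.normal(28.8 if shift else 28.4, 5.5, n)
    race_p = [0.915, 0.085, 0.0] if shift else [0.724, 0.188, 0.088]
    race = rng.choice(["nhw", "black", "other"], size=n, p=race_p)
    smoke_p = [0.06, 0.70, 0.24] if shift else [0.09, 0.58, 0.33]
    smoking = rng.choice(["never", "former", "current"], size=n, p=smoke_p)
    pack_years = np.clip(rng.normal(42.4 if shift else 45.1, 27.0, n), 0, None)
    sites = ["C1", "C2"] if shift else ["S1", "S2", "S3", "S4"]
    site = rng.choice(sites, size=n)
    scanner = rng.choice(["scanA", "scanB"], size=n)
    clin = pd.DataFrame({
        "age": age, "sex": np.where(sex == 1, "male", "female"),
        "height_cm": height, "bmi": bmi, "race": race,
        "smoking_status": smoking, "pack_years": pack_years,
        "site": site, "scanner": scanner,
    })
    # standardized versions used for outcome effects (analytic moments)
    z = {
        "age": (age - (67.3 if shift else 63.2)) / 8.9,
        "sex": (sex - (0.50 if shift else 0.54)) / np.sqrt(0.25),
        "height_cm": (height - 168.0) / 9.0,
        "bmi": (bmi - (28.8 if shift else 28.4)) / 5.5,
    }
    return clin, z


def _metabolite_ids(p):
    return [f"met{j:04d}" for j in range(p)]


def _draw_effects(rng, cfg: SynthConfig, block_of):
    """One true effect per block (wrapping if needed), fixed magnitude."""
    p = cfg.p_metabolites
    n_blocks = cfg.n_blocks
    order = rng.permutation(n_blocks)
    chosen = []
    b = 0
    while len(chosen) < cfg.n_true_effects:
        block = order[b % n_blocks]
        members = np.flatnonzero(block_of == block)
        pick = int(rng.choice(np.setdiff1d(members, chosen)))
        chosen.append(pick)
        b += 1
    beta = np.zeros(p)
    beta[chosen] = cfg.effect_sd * rng.choice([-1.0, 1.0], size=len(chosen))
    return beta


def _signal_variance(beta, block_of, rho):
    """Exact Var(beta' a) under the equicorrelated-block covariance."""
    var = 0.0
    for b in np.unique(block_of):
        bb = beta[block_of == b]
        var += (1 - rho) * float(bb @ bb) + rho * float(bb.sum()) ** 2
    return var


def inject_missingness(matrix: AbundanceMatrix, censor_quantiles,
                       seed=0) -> AbundanceMatrix:
    """Left-censor each metabolite below its abundance quantile.

    ``censor_quantiles`` is a scalar or per-metabolite array of fractions in
    [0, 1]: values strictly below that empirical quantile become missing
    (quantile 1.0 censors everything).  Low-abundance censoring is the
    dominant missingness mechanism in untargeted metabolomics, and makes the
    present/absent dichotomization downstream genuinely informative.
    """
    q = np.broadcast_to(np.asarray(censor_quantiles, dtype=float),
                        (matrix.values.shape[1],))
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("censor quantiles must lie in [0, 1]")
    vals = matrix.values.to_numpy(float).copy()
    for j, qj in enumerate(q):
        if qj <= 0:
            continue
        col = vals[:, j]
        if qj >= 1:
            vals[:, j] = np.nan
            continue
        thresh = np.nanquantile(col, qj)
        vals[col < thresh, j] = np.nan
    out = pd.DataFrame(vals, index=matrix.values.index,
                       columns=matrix.values.columns)
    return AbundanceMatrix(out, matrix.batch.copy(), matrix.metabolite_meta)


def _tier_quantiles(rng, cfg: SynthConfig, true_idx):
    """Per-metabolite censoring quantiles drawn from the tier shares.

    True-effect metabolites are forced into the low-missingness tier so the
    signal survives as continuous features.
    """
    p = cfg.p_metabolites
    q1, q2 = cfg.censor_quantiles
    tier = rng.choice([0, 1, 2], size=p, p=[q1, q2, 1 - q1 - q2])
    tier[true_idx] = 0
    q = np.empty(p)
    q[tier == 0] = rng.uniform(0.0, 0.18, (tier == 0).sum())
    q[tier == 1] = rng.uniform(0.22, 0.78, (tier == 1).sum())
    q[tier == 2] = rng.uniform(0.82, 0.99, (tier == 2).sum())
    return q


def generate_cohort_pair(config: SynthConfig):
    """Generate (train, valid, truth): two cohorts plus per-outcome truth.

    Deterministic given ``config.seed``.  ``truth`` maps outcome name to a
    :class:`TruthRecord`.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_shared, rng_train, rng_valid = [np.random.default_rng(s)
                                        for s in ss.spawn(3)]
    p = cfg.p_metabolites
    met_ids = _metabolite_ids(p)
    mu = rng_shared.normal(6.0, 1.0, p)              # baseline log-abundance
    _, block_of = _block_latents(rng_shared, 1, p, cfg.n_blocks,
                                 cfg.within_block_corr)

    betas, truth = {}, {}
    cov_eff = dict(cfg.covariate_effect_sizes)
    var_cov = float(sum(b * b for b in cov_eff.values()))
    all_true = []
    for outcome in cfg.outcomes:
        beta = _draw_effects(rng_shared, cfg, block_of)
        betas[outcome] = beta
        support_idx = np.flatnonzero(beta)
        all_true.extend(support_idx.tolist())
        var_m = _signal_variance(beta, block_of, cfg.within_block_corr)
        scale = cfg.outcome_scale.get(outcome, 1.0)
        truth[outcome] = TruthRecord(
            true_support=[met_ids[j] for j in support_idx],
            true_coefficients={met_ids[j]: float(beta[j] * scale)
                               for j in support_idx},
            true_covariate_effects={c: float(b * scale)
                                    for c, b in cov_eff.items()},
            generative_r2=var_m / (var_m + var_cov + cfg.noise_sd**2),
        )
    censor_q = (None if cfg.censor_quantiles is None
                else _tier_quantiles(rng_shared, cfg, sorted(set(all_true))))

    meta = pd.DataFrame({
        "super_pathway": [f"super{b % 8}" for b in block_of],
        "sub_pathway": [f"block{b}" for b in block_of],
    }, index=met_ids)

    cohorts = {}
    for cohort, n, rng in (("train", cfg.n_train, rng_train),
                           ("valid", cfg.n_valid, rng_valid)):
        latents, _ = _block_latents(rng, n, p, cfg.n_blocks,
                                    cfg.within_block_corr)
        clin, z = _covariates(rng, n, cfg, cohort)
        sample_ids = [f"{cohort[0].upper()}{i:05d}" for i in range(n)]
        clin.index = pd.Index(sample_ids, name="sample_id")

        for outcome in cfg.outcomes:
            scale = cfg.outcome_scale.get(outcome, 1.0)
            eta_cov = sum(cov_eff[c] * z[c] for c in cov_eff)
            y = (cfg.outcome_intercept.get(outcome, 0.0)
                 + scale * (eta_cov + latents @ betas[outcome]
                            + rng.normal(0, cfg.noise_sd, n)))
            clin[outcome] = y

        prefix = "T" if cohort == "train" else "V"
        batch = pd.Series(rng.integers(0, cfg.batch_count, n),
                          index=clin.index).map(lambda b: f"{prefix}B{b}")
        shift = rng.normal(0.0, cfg.batch_effect_sd,
                           (cfg.batch_count, p))
        bidx = batch.str.slice(2).astype(int).to_numpy()
        log_int = (mu + latents + rng.normal(0, cfg.tech_noise_sd, (n, p))
                   + shift[bidx])
        values = pd.DataFrame(np.exp(log_int), index=clin.index,
                              columns=met_ids)
        clin["batch"] = batch
        matrix = AbundanceMatrix(values, batch, meta)
        if censor_q is not None:
            matrix = inject_missingness(matrix, censor_q, seed=cfg.seed)
        cohorts[cohort] = CohortData(abundance=matrix, clinical=clin)

    return cohorts["train"], cohorts["valid"], truth


# ---------------------------------------------------------------------------


def write_cohort(cohort: CohortData, values_path, clinical_path):
    """Write the sample x metabolite TSV ("NA" missing) and clinical CSV."""
    cohort.abundance.to_tsv(values_path)
    cohort.clinical.to_csv(clinical_path, index_label="sample_id")


def make_pathway_gmt(truth: TruthRecord, metabolite_ids, path, n_pathways=20,
                     pathway_size=30, seed=0):
    """Write a GMT where pathway PW01 contains every true-effect metabolite.

    The remaining pathways are random draws from the non-signal metabolites;
    used to check that over-representation analysis ranks the planted
    pathway first.
    """
    rng = np.random.default_rng(seed)
    ids = list(metabolite_ids)
    signal = list(truth.true_support)
    rest = [m for m in ids if m not in set(signal)]
    lines = []
    pad = rng.choice(rest, size=max(pathway_size - len(signal), 0),
                     replace=False).tolist()
    lines.append("PW01\tplanted signal pathway\t" + "\t".join(signal + pad))
    for k in range(2, n_pathways + 1):
        members = rng.choice(rest, size=pathway_size, replace=False).tolist()
        lines.append(f"PW{k:02d}\trandom pathway {k}\t" + "\t".join(members))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
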