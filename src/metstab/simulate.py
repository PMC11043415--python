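"""Balanced multi-environment trial simulator with known ground truth.

The generative model mirrors the bilinear decomposition the analysis
assumes: an RCBD trial replicated in every environment,

    y_ijr = mu + g_i + e_j + sum_k w_k * gamma_ik * delta_jk + b_r(j) + eps_ijr

with Gaussian genotype, environment, replicate-within-environment and
residual effects.  The interaction loading matrices are drawn exactly
centered and orthonormal (QR of Gaussian draws after projecting out the
constant vector), so the low-rank interaction truth is an exact bilinear
model of the configured rank and weights -- the proportion of interaction
variance on axis k converges to w_k^2 / sum(w^2) as the noise vanishes.

Default parameter values emulate a country-wide replicated rice yield
trial on the kg/ha scale: 20 genotypes, 12 environments, 3 replicates,
grand mean 6700, genotype SD 300, environment SD 1800, replicate SD 1300,
residual SD 1150, rank-2 interaction with weights (5800, 4100).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ammi import ammi_fit
from .anova import combined_anova, variance_components
from .exceptions import ValidationError
from .io import TrialData, cell_means
from .stability import joint_regression, wricke_ecovalence


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated balanced trial (trait units: kg/ha)."""

    g: int = 20
    q: int = 12
    r: int = 3
    mu: float = 6700.0
    sigma_g: float = 300.0
    sigma_env: float = 1800.0
    sigma_rep: float = 1300.0
    sigma_noise: float = 1150.0
    interaction_rank: int = 2
    interaction_weights: tuple = (5800.0, 4100.0)
    seed: int = 0
    zero_interaction_first: bool = False
    trait_name: str = "yield"

    def __post_init__(self) -> None:
        if min(self.g, self.q) < 2 or self.r < 1:
            raise ValidationError("need g >= 2, q >= 2, r >= 1")
        for name in ("sigma_g", "sigma_env", "sigma_rep", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        k = self.interaction_rank
        if k < 0 or k > min(self.g - 1, self.q - 1):
            raise ValidationError("interaction_rank must be in [0, min(g-1, q-1)]")
        w = tuple(float(x) for x in self.interaction_weights)[:k]
        if len(w) != k:
            raise ValidationError("need one interaction weight per rank")
        if any(w[i] < w[i + 1] for i in range(len(w) - 1)) or any(x < 0 for x in w):
            raise ValidationError("interaction weights must be non-negative and non-increasing")
        object.__setattr__(self, "interaction_weights", w)


@dataclass(frozen=True)
class TrialTruth:
    """Effects actually drawn for one simulated trial."""

    config: SimulationConfig
    genotype_effects: np.ndarray
    environment_effects: np.ndarray
    replicate_effects: np.ndarray  # q x r block effects
    interaction_weights: np.ndarray
    genotype_loadings: np.ndarray  # g x K, centered orthonormal columns
    environment_loadings: np.ndarray  # q x K

    @property
    def interaction_matrix(self) -> np.ndarray:
        if len(self.interaction_weights) == 0:
            return np.zeros((self.config.g, self.config.q))
        return (self.genotype_loadings * self.interaction_weights) @ self.environment_loadings.T

    @property
    def expected_interaction_percent(self) -> np.ndarray:
        """Noise-free share of interaction SS per true axis."""
        w2 = self.interaction_weights**2
        return 100.0 * w2 / w2.sum() if w2.sum() > 0 else w2

    def to_dict(self) -> dict:
        d = asdict(self.config)
        d["interaction_weights"] = list(self.config.interaction_weights)
        return {
            "config": d,
            "genotype_effects": self.genotype_effects.tolist(),
            "environment_effects": self.environment_effects.tolist(),
            "replicate_effects": self.replicate_effects.tolist(),
            "interaction_matrix": self.interaction_matrix.tolist(),
        }


def _centered_orthonormal(rng: np.random.Generator, n: int, k: int, skip_first: bool) -> np.ndarray:
    """Columns orthonormal and orthogonal to the constant vector.

    With ``skip_first`` the first coordinate of every column is exactly
    zero (a genotype with no interaction) while the columns stay centered
    over all n coordinates and orthonormal.
    """
    if k == 0:
        return np.zeros((n, 0))
    m = n - 1 if skip_first else n
    if k > m - 1:
        raise ValidationError("interaction rank too high for a zero-interaction genotype")
    A = rng.standard_normal((m, k))
    A -= A.mean(axis=0, keepdims=True)
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))  # deterministic orientation
    if skip_first:
        Q = np.vstack([np.zeros(k), Q])
    return Q


def simulate_trial(config: SimulationConfig) -> tuple[TrialData, TrialTruth]:
    """Draw one balanced replicated trial; returns the data and its truth."""
    rng = np.random.default_rng(config.seed)
    g, q, r, k = config.g, config.q, config.r, config.interaction_rank

    gen_eff = rng.standard_normal(g) * config.sigma_g
    env_eff = rng.standard_normal(q) * config.sigma_env
    rep_eff = rng.standard_normal((q, r)) * config.sigma_rep
    gamma = _centered_orthonormal(rng, g, k, config.zero_interaction_first)
    delta = _centered_orthonormal(rng, q, k, skip_first=False)
    weights = np.asarray(config.interaction_weights, dtype=float)

    inter = (gamma * weights) @ delta.T if k else np.zeros((g, q))
    cells = config.mu + gen_eff[:, None] + env_eff[None, :] + inter
    noise = rng.standard_normal((g, q, r)) * config.sigma_noise
    y = cells[:, :, None] + rep_eff[None, :, :] + noise

    gens = [f"G{i + 1}" for i in range(g)]
    envs = [f"E{j + 1}" for j in range(q)]
    reps = [f"R{t + 1}" for t in range(r)]
    idx = pd.MultiIndex.from_product([gens, envs, reps], names=["gen", "env", "rep"])
    records = pd.DataFrame({"value": y.reshape(-1)}, index=idx).reset_index()
    records = records[["env", "gen", "rep", "value"]]
    data = TrialData(records, trait_name=config.trait_name)
    truth = TrialTruth(
        config=config,
        genotype_effects=gen_eff,
        environment_effects=env_eff,
        replicate_effects=rep_eff,
        interaction_weights=weights,
        genotype_loadings=gamma,
        environment_loadings=delta,
    )
    return data, truth


def expected_heritability(config: SimulationConfig) -> float:
    """Heritability (percent) implied by the mean-square estimators.

    Under the generative model E[GMS] = sigma_noise^2 + q*r*sigma_g^2 and
    E[EMS] = sigma_noise^2, so the (GMS-EMS)/r estimator targets
    q*sigma_g^2 and the implied heritability is
    100 * q*sigma_g^2 / (q*sigma_g^2 + sigma_noise^2 / r).
    """
    sg = config.q * config.sigma_g**2
    se = config.sigma_noise**2 / config.r
    return 100.0 * sg / (sg + se) if sg + se > 0 else 0.0


def recovery_suite(config: SimulationConfig, reps: int = 200) -> pd.DataFrame:
    """Repeated simulate-and-analyse summary of estimator behaviour.

    Runs ``reps`` independent trials (seeds ``config.seed + i``) and
    reports the mean and SD of: estimated broad-sense heritability, the
    first-axis interaction share EP1, the joint-regression slope of the
    first genotype, and -- when ``zero_interaction_first`` -- the
    ecovalence of that interaction-free genotype.  The ``expected`` column
    carries the truth-implied value of each quantity.
    """
    if reps < 2:
        raise ValidationError("recovery_suite needs reps >= 2")
    h2s, ep1s, bis, wi2s = [], [], [], []
    for i in range(reps):
        cfg = SimulationConfig(**{**asdict(config), "seed": config.seed + i,
                                  "interaction_weights": config.interaction_weights})
        data, truth = simulate_trial(cfg)
        means = cell_means(data)
        if cfg.r >= 2:
            comp = variance_components(combined_anova(data))
            h2s.append(comp.heritability)
        ep1s.append(ammi_fit(means).explained_interaction_[0])
        bis.append(joint_regression(means).iloc[0])
        if cfg.zero_interaction_first:
            wi2s.append(wricke_ecovalence(means).iloc[0])

    ep_truth = (
        truth.expected_interaction_percent[0]
        if config.interaction_rank > 0
        else np.nan
    )
    rows = {
        "heritability": (h2s, expected_heritability(config)),
        "ep1": (ep1s, ep_truth),
        "b_first": (bis, 1.0),
    }
    if config.zero_interaction_first:
        # double-centered pure noise leaves (g-1)(q-1)/g * sigma^2/r per row
        exp_wi2 = (
            (config.g - 1) * (config.q - 1) / config.g
            * config.sigma_noise**2 / config.r
        )
        rows["wi2_zero_genotype"] = (wi2s, exp_wi2)
    out = pd.DataFrame(
        {
            name: {
                "mean": float(np.mean(vals)) if vals else np.nan,
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                "se": float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
                "expected": exp,
            }
            for name, (vals, exp) in rows.items()
        }
    ).T
    out.index.name = "quantity"
    return out
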