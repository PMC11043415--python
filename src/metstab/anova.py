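"""Combined ANOVA across environments and variance-component estimators.

The linear model for a balanced trial replicated in every environment is

    y_ijr = mu + E_j + R_r(j) + G_i + (GE)_ij + e_ijr

with replicates (blocks) nested within environments.  Degrees of freedom are
(q-1), q(r-1), (g-1), (g-1)(q-1) and q(g-1)(r-1).  Genotype and interaction
mean squares are tested against the pooled error; the environment mean
square is tested against the replicate-within-environment stratum, which is
its error term under the nested blocking.

Variance components use the mean-square estimators

    sigma2_g = (GMS - EMS) / r        sigma2_e = EMS / r
    sigma2_p = sigma2_g + sigma2_e    h2_B = 100 * sigma2_g / sigma2_p

where GMS and EMS are the genotype and error mean squares.  The divisor r
(rather than the textbook r*q for across-environment trials) is the package
default; pass ``divisor="rq"`` for the textbook estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, ValidationError
from .io import TrialData

SOURCES = ["ENV", "REP(ENV)", "GEN", "GEN:ENV", "ERROR", "TOTAL"]


def combined_anova(data: TrialData) -> pd.DataFrame:
    """Combined analysis of variance over environments.

    Returns a DataFrame indexed by source (ENV, REP(ENV), GEN, GEN:ENV,
    ERROR, TOTAL) with columns ``df``, ``SS``, ``MS``, ``F`` and ``p``.

    Raises
    ------
    DegenerateInputError
        If r = 1 (no within-cell error stratum).
    """
    g, q, r = data.g, data.q, data.r
    if r < 2:
        raise DegenerateInputError("combined ANOVA needs r >= 2 replicates")

    rec = data.records
    y = rec["value"].to_numpy(dtype=float)
    grand = y.mean()
    total_ss = float(((y - grand) ** 2).sum())

    env_means = rec.groupby("env", sort=False)["value"].mean()
    gen_means = rec.groupby("gen", sort=False)["value"].mean()
    cellm = rec.groupby(["env", "gen"], sort=False)["value"].mean()
    repm = rec.groupby(["env", "rep"], sort=False)["value"].mean()

    ss_env = g * r * float(((env_means - grand) ** 2).sum())
    ss_rep = g * float(((repm - env_means.reindex(repm.index.get_level_values("env")).to_numpy()) ** 2).sum())
    ss_gen = q * r * float(((gen_means - grand) ** 2).sum())
    inter = (
        cellm
        - env_means.reindex(cellm.index.get_level_values("env")).to_numpy()
        - gen_means.reindex(cellm.index.get_level_values("gen")).to_numpy()
        + grand
    )
    ss_ge = r * float((inter**2).sum())
    ss_err = total_ss - ss_env - ss_rep - ss_gen - ss_ge
    ss_err = max(ss_err, 0.0)

    dfs = {
        "ENV": q - 1,
        "REP(ENV)": q * (r - 1),
        "GEN": g - 1,
        "GEN:ENV": (g - 1) * (q - 1),
        "ERROR": q * (g - 1) * (r - 1),
    }
    ss = {"ENV": ss_env, "REP(ENV)": ss_rep, "GEN": ss_gen, "GEN:ENV": ss_ge, "ERROR": ss_err}
    ms = {k: ss[k] / dfs[k] for k in dfs}

    rows = []
    for src in ["ENV", "REP(ENV)", "GEN", "GEN:ENV", "ERROR"]:
        denom = "REP(ENV)" if src == "ENV" else "ERROR"
        if src == "ERROR":
            F = p = np.nan
        else:
            F = ms[src] / ms[denom] if ms[denom] > 0 else np.inf
            p = float(stats.f.sf(F, dfs[src], dfs[denom])) if np.isfinite(F) else 0.0
        rows.append((src, dfs[src], ss[src], ms[src], F, p))
    rows.append(("TOTAL", g * q * r - 1, total_ss, np.nan, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["source", "df", "SS", "MS", "F", "p"]).set_index("source")
    table.attrs["r"] = r
    table.attrs["g"] = g
    table.attrs["q"] = q
    return table


@dataclass(frozen=True)
class GeneticComponents:
    """Variance components and broad-sense heritability for one trait.

    ``heritability`` is in percent.  A negative genotypic variance estimate
    (GMS < EMS) is reported as-is with ``negative_genotypic=True`` rather
    than clamped.
    """

    sigma2_g: float
    sigma2_e: float
    sigma2_p: float
    heritability: float
    negative_genotypic: bool = False

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "genotypic_variance": self.sigma2_g,
                "environmental_variance": self.sigma2_e,
                "phenotypic_variance": self.sigma2_p,
                "heritability_percent": self.heritability,
            }
        )


def variance_components_from_ms(
    gms: float, ems: float, r: int, q: int | None = None, divisor: str = "r"
) -> GeneticComponents:
    """Variance components from genotype and error mean squares.

    ``divisor="r"`` (default) uses r alone; ``divisor="rq"`` uses the
    textbook r*q denominator and requires ``q``.
    """
    if divisor == "r":
        denom = r
    elif divisor == "rq":
        if q is None:
            raise ValidationError('divisor="rq" requires the environment count q')
        denom = r * q
    else:
        raise ValidationError(f"unknown divisor {divisor!r}")
    s2g = (gms - ems) / denom
    s2e = ems / denom
    s2p = s2g + s2e
    if s2p == 0:
        raise ZeroDivisionError("phenotypic variance is zero; heritability undefined")
    neg = s2g < 0
    if neg:
        warnings.warn(
            "genotypic variance estimate is negative (GMS < EMS); reported as-is",
            RuntimeWarning,
            stacklevel=2,
        )
    return GeneticComponents(s2g, s2e, s2p, 100.0 * s2g / s2p, negative_genotypic=neg)


def variance_components(
    anova: pd.DataFrame, r: int | None = None, divisor: str = "r"
) -> GeneticComponents:
    """Variance components from a combined ANOVA table."""
    for src in ("GEN", "ERROR"):
        if src not in anova.index:
            raise ValidationError(f"ANOVA table lacks a {src} row")
    if r is None:
        r = anova.attrs.get("r")
        if r is None:
            raise ValidationError("replicate count r not supplied and not recorded in table")
    q = anova.attrs.get("q")
    return variance_components_from_ms(
        float(anova.loc["GEN", "MS"]), float(anova.loc["ERROR", "MS"]), int(r), q=q, divisor=divisor
    )
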