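"""Univariate stability statistics and the blended stability/yield ranking.

All statistics are computed per genotype from a fitted :class:`~metstab.ammi.AMMI`
model or directly from the cell-means matrix:

* ``asv``   -- AMMI stability value (Purchase): the first-axis score is
  inflated by the ratio of the first two interaction sums of squares,
  ASV_i = sqrt( ((SS1/SS2) * s_i1)^2 + s_i2^2 ).
* ``asi``   -- AMMI stability index: the first two scores weighted by the
  fraction of interaction variance each axis explains,
  ASI_i = sqrt( (s_i1 * theta1)^2 + (s_i2 * theta2)^2 ), theta_k = EP_k/100.
* ``joint_regression`` -- Eberhart-Russell slope b_i of a genotype's
  environment means on the environmental index I_j = X.j - X.. .
* ``wricke_ecovalence`` -- W2_i, the genotype's share of the interaction
  sum of squares.
* ``shukla_variance`` -- sigma2_i, the unbiased affine rescaling of W2_i.
* ``waas``  -- weighted (by explained interaction variance) average of the
  absolute scores across the chosen axes.
* ``waasy_ranking`` -- min-max rescales yield (higher is better) and WAAS
  (lower is better) to 0-100 and blends them with a user weight.

Both ASV and ASI use sqrt(lambda)-scaled ("symmetric") scores.  Smaller is
more stable for every statistic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.utils.validation import check_is_fitted

from .ammi import AMMI, ammi_fit
from .exceptions import DegenerateInputError, ValidationError
from .io import CellMeans

__all__ = [
    "asv",
    "asi",
    "joint_regression",
    "wricke_ecovalence",
    "shukla_variance",
    "waas",
    "waasy_ranking",
    "stability_table",
]


def _scores(model: AMMI) -> pd.DataFrame:
    check_is_fitted(model, "genotype_scores_")
    if model.scaling != "symmetric":
        # statistics are defined on sqrt(lambda)-scaled scores
        U = model.genotype_vectors_.to_numpy()
        return pd.DataFrame(
            U * np.sqrt(model.singular_values_),
            index=model.genotypes_,
            columns=model.genotype_scores_.columns,
        )
    return model.genotype_scores_


def asv(model: AMMI) -> pd.Series:
    """AMMI stability value per genotype (needs >= 2 interaction axes).

    When the second singular value is zero the SS ratio is undefined; the
    statistic degrades to |s_i1| with a warning.
    """
    s = _scores(model)
    if s.shape[1] < 2:
        raise DegenerateInputError("ASV needs at least two interaction axes")
    lam = model.singular_values_
    if lam[1] <= 1e-12 * max(lam[0], 1.0):
        warnings.warn(
            "second interaction axis is null; ASV falls back to |IPCA1| scores",
            RuntimeWarning,
            stacklevel=2,
        )
        return s["IPCA1"].abs().rename("ASV")
    weight = lam[0] ** 2 / lam[1] ** 2
    out = np.sqrt((weight * s["IPCA1"]) ** 2 + s["IPCA2"] ** 2)
    return out.rename("ASV")


def asi(model: AMMI) -> pd.Series:
    """AMMI stability index per genotype (needs >= 2 interaction axes)."""
    s = _scores(model)
    if s.shape[1] < 2:
        raise DegenerateInputError("ASI needs at least two interaction axes")
    th1, th2 = model.explained_interaction_[:2] / 100.0
    out = np.sqrt((s["IPCA1"] * th1) ** 2 + (s["IPCA2"] * th2) ** 2)
    return out.rename("ASI")


def joint_regression(means: CellMeans) -> pd.Series:
    """Eberhart-Russell regression slope b_i per genotype.

    b_i regresses the genotype's centered row on the environmental index
    I_j = X.j - X.. without intercept; the slopes average to exactly 1.
    """
    if means.q < 3:
        raise DegenerateInputError("joint regression needs q >= 3 environments")
    X = means.values.to_numpy(dtype=float)
    I = X.mean(axis=0) - X.mean()
    denom = float((I**2).sum())
    if denom == 0:
        raise DegenerateInputError("no environmental spread: all indices I_j are zero")
    centered = X - X.mean(axis=1, keepdims=True)
    b = centered @ I / denom
    return pd.Series(b, index=means.genotypes, name="bi")


def wricke_ecovalence(means: CellMeans) -> pd.Series:
    """Wricke's ecovalence W2_i: row sums of squares of the doubly-centered matrix."""
    Z = means.interaction().to_numpy()
    return pd.Series((Z**2).sum(axis=1), index=means.genotypes, name="Wi2")


def shukla_variance(
    wi2: pd.Series, n_genotypes: int | None = None, n_environments: int | None = None
) -> pd.Series:
    """Shukla's stability variance sigma2_i from the ecovalences.

    sigma2_i = [p / ((p-2)(q-1))] * W2_i  -  sum(W2) / ((p-1)(p-2)(q-1))

    with p genotypes and q environments.  ``n_environments`` is required;
    ``n_genotypes`` defaults to ``len(wi2)``.
    """
    wi2 = pd.Series(wi2)
    p = len(wi2) if n_genotypes is None else int(n_genotypes)
    if n_environments is None:
        raise ValidationError("shukla_variance requires the environment count q")
    q = int(n_environments)
    if p < 3:
        raise DegenerateInputError("Shukla's variance needs p >= 3 genotypes")
    if q < 2:
        raise DegenerateInputError("Shukla's variance needs q >= 2 environments")
    total = float(wi2.sum())
    out = p / ((p - 2) * (q - 1)) * wi2 - total / ((p - 1) * (p - 2) * (q - 1))
    return out.rename("shukla")


def waas(model: AMMI, axes: int | str = "all") -> pd.Series:
    """Weighted average of absolute interaction scores per genotype.

    WAAS_i = sum_k |s_ik| * EP_k / sum_k EP_k over the chosen axes, with
    sqrt(lambda)-scaled scores.  ``axes`` is an axis count or ``"all"``.
    """
    s = _scores(model).to_numpy()
    ep = model.explained_interaction_
    if axes == "all":
        k = s.shape[1]
    else:
        k = int(axes)
        if not 1 <= k <= s.shape[1]:
            raise ValidationError(f"axes must be in [1, {s.shape[1]}]")
    w = ep[:k]
    denom = w.sum()
    if denom == 0:
        vals = np.zeros(s.shape[0])
    else:
        vals = (np.abs(s[:, :k]) * w).sum(axis=1) / denom
    return pd.Series(vals, index=model.genotypes_, name="WAAS")


def _minmax_score(x: pd.Series, higher_is_better: bool) -> pd.Series:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise DegenerateInputError(
            f"cannot rescale {x.name or 'values'}: min equals max ({lo})"
        )
    z = (x - lo) / (hi - lo) * 100.0
    return z if higher_is_better else 100.0 - z


def waasy_ranking(
    waas_values: pd.Series, means: CellMeans, weight_yield: float = 50.0
) -> pd.DataFrame:
    """Blend rescaled yield and rescaled stability into a superiority score.

    Yield is min-max rescaled to 0-100 (higher better); WAAS is rescaled so
    the most stable genotype scores 100.  The blended score is
    ``(weight_yield * yscore + (100 - weight_yield) * sscore) / 100``;
    weight 100 ranks purely on yield, weight 0 purely on stability.

    Each genotype is also classified into the quadrant spanned by
    (mean above/below the grand mean) x (WAAS below/above the median WAAS):
    productive-stable, productive-unstable, unproductive-stable,
    unproductive-unstable.
    """
    if not 0 <= weight_yield <= 100:
        raise ValidationError("weight_yield must be in [0, 100]")
    ym = means.genotype_means.reindex(waas_values.index)
    yscore = _minmax_score(ym.rename("yield"), higher_is_better=True)
    sscore = _minmax_score(waas_values.rename("WAAS"), higher_is_better=False)
    score = (weight_yield * yscore + (100.0 - weight_yield) * sscore) / 100.0

    productive = ym > means.grand_mean
    stable = waas_values < waas_values.median()
    quad = np.where(
        productive & stable, "productive-stable",
        np.where(productive, "productive-unstable",
                 np.where(stable, "unproductive-stable", "unproductive-unstable")),
    )
    return pd.DataFrame(
        {
            "mean": ym,
            "WAAS": waas_values,
            "yield_score": yscore,
            "stability_score": sscore,
            "WAASY": score,
            "quadrant": quad,
        }
    )


def stability_table(
    means: CellMeans,
    model: AMMI | None = None,
    weight_yield: float = 50.0,
    axes: int | str = "all",
) -> pd.DataFrame:
    """All univariate stability statistics with ranks, one row per genotype.

    Columns: mean, ASV, ASI, bi, Wi2, shukla, WAAS, WAASY, quadrant and a
    ``*_rank`` column per statistic (rank 1 = most stable; for mean and
    WAASY rank 1 = best).  Ties receive average ranks.
    """
    if model is None:
        model = ammi_fit(means)
    w = wricke_ecovalence(means)
    table = pd.DataFrame(
        {
            "mean": means.genotype_means,
            "ASV": asv(model),
            "ASI": asi(model),
            "bi": joint_regression(means),
            "Wi2": w,
            "shukla": shukla_variance(w, n_environments=means.q),
            "WAAS": waas(model, axes=axes),
        }
    )
    blended = waasy_ranking(table["WAAS"], means, weight_yield=weight_yield)
    table["WAASY"] = blended["WAASY"]
    table["quadrant"] = blended["quadrant"]

    ascending = {"mean": False, "WAASY": False}
    for col in ["mean", "ASV", "ASI", "Wi2", "shukla", "WAAS", "WAASY"]:
        table[f"{col}_rank"] = table[col].rank(ascending=ascending.get(col, True))
    table["bi_rank"] = (table["bi"] - 1.0).abs().rank()
    return table
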