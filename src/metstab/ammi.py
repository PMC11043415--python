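"""Additive Main effects and Multiplicative Interaction (AMMI) model.

The cell-means table decomposes as

    X_ij = mu + a_i + b_j + sum_k lambda_k * gamma_ik * delta_jk + eps_ij

where the main effects come from the row/column margins and the interaction
principal components come from the SVD of the doubly-centered residual
Z_ij = X_ij - Xi. - X.j + X.. .  The k-th axis carries a share
EP_k = 100 * lambda_k^2 / sum(lambda^2) of the interaction sum of squares.

:class:`AMMI` is a scikit-learn style estimator: ``fit`` ingests a g x q
means matrix (array, DataFrame or :class:`~metstab.io.CellMeans`) and
exposes the decomposition through trailing-underscore attributes;
``fit_transform`` returns the genotype scores, so the estimator composes
with sklearn pipelines as a decomposition step.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .exceptions import DegenerateInputError, MissingReplicatesError, ValidationError
from .io import CellMeans

_SCALINGS = ("symmetric", "none", "full")


def _as_matrix(X):
    """Coerce input to (values array, genotype labels, environment labels, r)."""
    if isinstance(X, CellMeans):
        return X.values.to_numpy(dtype=float), X.genotypes, X.environments, X.r
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.index), list(X.columns), 1
    a = np.asarray(X, dtype=float)
    if a.ndim != 2:
        raise ValidationError("expected a 2-D genotype x environment matrix")
    gens = [f"G{i + 1}" for i in range(a.shape[0])]
    envs = [f"E{j + 1}" for j in range(a.shape[1])]
    return a, gens, envs, 1


def _signed_svd(Z: np.ndarray):
    """SVD with a deterministic sign convention.

    Each singular-vector pair is flipped so that the genotype entry with the
    largest magnitude on that axis is positive (ties broken by the first
    such entry); SVD signs are otherwise arbitrary.
    """
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    for k in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, k])))
        if U[i, k] < 0:
            U[:, k] = -U[:, k]
            Vt[k] = -Vt[k]
    return U, s, Vt


def gollob_df(g: int, q: int, k: int) -> int:
    """Gollob degrees of freedom for the k-th interaction axis: g+q-1-2k."""
    return g + q - 1 - 2 * k


class AMMI(BaseEstimator):
    """AMMI decomposition of a genotype x environment means matrix.

    Parameters
    ----------
    n_components : int or None
        Number of interaction axes to retain; ``None`` keeps all
        K = min(g-1, q-1).
    scaling : {"symmetric", "none", "full"}
        How singular values are folded into the scores.  ``symmetric``
        (default) multiplies both sides by sqrt(lambda_k) -- the convention
        the stability statistics use; ``none`` leaves raw eigenvectors;
        ``full`` puts the whole lambda on the genotype side.

    Attributes
    ----------
    grand_mean_ : float
    genotype_main_effects_, environment_main_effects_ : pandas.Series
        Deviations a_i = Xi. - X.. and b_j = X.j - X.. .
    singular_values_ : ndarray of shape (K,)
    genotype_vectors_, environment_vectors_ : DataFrame
        Orthonormal eigenvectors gamma_ik, delta_jk.
    genotype_scores_, environment_scores_ : DataFrame
        Scaled scores (columns ``IPCA1..IPCAK``).
    explained_interaction_ : ndarray
        EP_k, percent of interaction SS per axis (sums to 100).
    interaction_ : DataFrame
        The doubly-centered matrix Z.
    interaction_ss_ : float
        sum(lambda^2) on the cell-means scale.
    """

    def __init__(self, n_components: int | None = None, scaling: str = "symmetric"):
        self.n_components = n_components
        self.scaling = scaling

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        if self.scaling not in _SCALINGS:
            raise ValidationError(f"scaling must be one of {_SCALINGS}")
        M, gens, envs, r = _as_matrix(X)
        g, q = M.shape
        if g < 3 or q < 3:
            raise DegenerateInputError(
                f"AMMI needs at least 3 genotypes and 3 environments, got {g}x{q}"
            )
        K_full = min(g - 1, q - 1)
        k = K_full if self.n_components is None else int(self.n_components)
        if not 1 <= k <= K_full:
            raise ValidationError(f"n_components must be in [1, {K_full}]")

        grand = M.mean()
        row = M.mean(axis=1)
        col = M.mean(axis=0)
        Z = M - row[:, None] - col[None, :] + grand

        U, s, Vt = _signed_svd(Z)
        U, s, V = U[:, :K_full], s[:K_full], Vt[:K_full].T

        ss = float(np.sum(s**2))
        ep = 100.0 * s**2 / ss if ss > 0 else np.zeros_like(s)

        axes = [f"IPCA{i + 1}" for i in range(K_full)]
        self.genotypes_ = gens
        self.environments_ = envs
        self.r_ = r
        self.n_components_ = k
        self.grand_mean_ = float(grand)
        self.genotype_main_effects_ = pd.Series(row - grand, index=gens)
        self.environment_main_effects_ = pd.Series(col - grand, index=envs)
        self.singular_values_ = s
        self.genotype_vectors_ = pd.DataFrame(U, index=gens, columns=axes)
        self.environment_vectors_ = pd.DataFrame(V, index=envs, columns=axes)
        self.explained_interaction_ = ep
        self.interaction_ = pd.DataFrame(Z, index=gens, columns=envs)
        self.interaction_ss_ = ss

        if self.scaling == "symmetric":
            gs, es = U * np.sqrt(s), V * np.sqrt(s)
        elif self.scaling == "full":
            gs, es = U * s, V
        else:
            gs, es = U, V
        self.genotype_scores_ = pd.DataFrame(gs, index=gens, columns=axes)
        self.environment_scores_ = pd.DataFrame(es, index=envs, columns=axes)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).genotype_scores_.to_numpy()

    def transform(self, X=None):
        check_is_fitted(self, "genotype_scores_")
        return self.genotype_scores_.to_numpy()

    # ------------------------------------------------------------------
    def reconstruct(self, n_components: int | None = None) -> pd.DataFrame:
        """Fitted values mu + a_i + b_j + sum over the first n axes."""
        check_is_fitted(self, "singular_values_")
        k = len(self.singular_values_) if n_components is None else n_components
        U = self.genotype_vectors_.to_numpy()[:, :k]
        V = self.environment_vectors_.to_numpy()[:, :k]
        s = self.singular_values_[:k]
        fitted = (
            self.grand_mean_
            + self.genotype_main_effects_.to_numpy()[:, None]
            + self.environment_main_effects_.to_numpy()[None, :]
            + (U * s) @ V.T
        )
        return pd.DataFrame(fitted, index=self.genotypes_, columns=self.environments_)


def ammi_fit(means, n_components: int | None = None, scaling: str = "symmetric") -> AMMI:
    """Fit an :class:`AMMI` model on a cell-means matrix (thin wrapper)."""
    return AMMI(n_components=n_components, scaling=scaling).fit(means)


def ammi_anova(model: AMMI, anova: pd.DataFrame, r: int | None = None) -> pd.DataFrame:
    """Append interaction-axis rows to a combined ANOVA table.

    For axis k the sum of squares on the observation scale is
    ``r * lambda_k^2`` with Gollob degrees of freedom g+q-1-2k; each axis is
    F-tested against the pooled error mean square.  A residual row absorbs
    whatever interaction SS the retained axes leave behind (zero when all
    axes are kept).

    Raises
    ------
    MissingReplicatesError
        If no replicate-level ANOVA (hence no error stratum) is supplied.
    """
    check_is_fitted(model, "singular_values_")
    if anova is None or "ERROR" not in anova.index:
        raise MissingReplicatesError("AMMI ANOVA needs the replicate-level combined ANOVA")
    if r is None:
        r = anova.attrs.get("r", model.r_)
    r = int(r)
    if r < 2:
        raise MissingReplicatesError("AMMI ANOVA needs r >= 2 replicates behind the means")

    g, q = len(model.genotypes_), len(model.environments_)
    err_ms = float(anova.loc["ERROR", "MS"])
    err_df = int(anova.loc["ERROR", "df"])

    rows = [anova.loc[src] for src in anova.index if src != "TOTAL"]
    names = [src for src in anova.index if src != "TOTAL"]

    lam2 = model.singular_values_ ** 2
    kept = model.n_components_
    cum = 0.0
    out_rows, out_names = [], []
    for src, rowdata in zip(names, rows):
        out_rows.append(rowdata.copy())
        out_names.append(src)
        if src == "GEN:ENV":
            for k in range(kept):
                ss_k = r * lam2[k]
                df_k = gollob_df(g, q, k + 1)
                ms_k = ss_k / df_k
                F = ms_k / err_ms if err_ms > 0 else np.inf
                p = float(stats.f.sf(F, df_k, err_df)) if np.isfinite(F) else 0.0
                prop = model.explained_interaction_[k]
                cum += prop
                out_rows.append(
                    pd.Series(
                        {"df": df_k, "SS": ss_k, "MS": ms_k, "F": F, "p": p,
                         "proportion": prop, "accumulated": cum}
                    )
                )
                out_names.append(f"PC{k + 1}")
            resid_ss = r * float(lam2[kept:].sum())
            resid_df = (g - 1) * (q - 1) - sum(gollob_df(g, q, k + 1) for k in range(kept))
            if resid_df > 0:
                out_rows.append(
                    pd.Series({"df": resid_df, "SS": resid_ss, "MS": resid_ss / resid_df,
                               "F": np.nan, "p": np.nan})
                )
                out_names.append("PC_RESIDUAL")
    if "TOTAL" in anova.index:
        out_rows.append(anova.loc["TOTAL"].copy())
        out_names.append("TOTAL")
    table = pd.DataFrame(out_rows, index=out_names)
    table.index.name = "source"
    for key, val in anova.attrs.items():
        table.attrs[key] = val
    return table


def significant_axes(ammi_table: pd.DataFrame, alpha: float = 0.05) -> int:
    """Count of interaction axes with p < alpha in an AMMI ANOVA table."""
    pcs = [s for s in ammi_table.index if s.startswith("PC") and s != "PC_RESIDUAL"]
    n = 0
    for src in pcs:
        if float(ammi_table.loc[src, "p"]) < alpha:
            n += 1
        else:
            break
    return n
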