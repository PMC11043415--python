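"""Independent brute-force oracles used by the tests.

Every function here recomputes a quantity with explicit loops or a
different matrix route than the package uses, so agreement is evidence,
not tautology.
"""

import numpy as np


def naive_anova_ss(y: dict, gens, envs, reps) -> dict:
    """Sums of squares by explicit summation over a balanced table.

    ``y[(e, g, r)]`` holds one observation per key.
    """
    g, q, r = len(gens), len(envs), len(reps)
    all_vals = [y[(e, gn, rp)] for e in envs for gn in gens for rp in reps]
    grand = sum(all_vals) / len(all_vals)

    env_mean = {e: sum(y[(e, gn, rp)] for gn in gens for rp in reps) / (g * r) for e in envs}
    gen_mean = {gn: sum(y[(e, gn, rp)] for e in envs for rp in reps) / (q * r) for gn in gens}
    cell_mean = {(e, gn): sum(y[(e, gn, rp)] for rp in reps) / r for e in envs for gn in gens}
    rep_mean = {(e, rp): sum(y[(e, gn, rp)] for gn in gens) / g for e in envs for rp in reps}

    ss_env = g * r * sum((env_mean[e] - grand) ** 2 for e in envs)
    ss_rep = g * sum((rep_mean[(e, rp)] - env_mean[e]) ** 2 for e in envs for rp in reps)
    ss_gen = q * r * sum((gen_mean[gn] - grand) ** 2 for gn in gens)
    ss_ge = r * sum(
        (cell_mean[(e, gn)] - env_mean[e] - gen_mean[gn] + grand) ** 2
        for e in envs
        for gn in gens
    )
    ss_tot = sum((v - grand) ** 2 for v in all_vals)
    ss_err = sum(
        (y[(e, gn, rp)] - cell_mean[(e, gn)] - rep_mean[(e, rp)] + env_mean[e]) ** 2
        for e in envs
        for gn in gens
        for rp in reps
    )
    return {
        "ENV": ss_env,
        "REP(ENV)": ss_rep,
        "GEN": ss_gen,
        "GEN:ENV": ss_ge,
        "ERROR": ss_err,
        "TOTAL": ss_tot,
    }


def naive_ecovalence(X: np.ndarray) -> np.ndarray:
    g, q = X.shape
    grand = X.mean()
    out = np.zeros(g)
    for i in range(g):
        for j in range(q):
            z = X[i, j] - X[i].mean() - X[:, j].mean() + grand
            out[i] += z * z
    return out


def naive_shukla(wi2, p: int, q: int) -> np.ndarray:
    wi2 = np.asarray(wi2, float)
    out = np.zeros(p)
    for i in range(p):
        out[i] = p / ((p - 2) * (q - 1)) * wi2[i] - wi2.sum() / ((p - 1) * (p - 2) * (q - 1))
    return out


def naive_waas(scores: np.ndarray, ep: np.ndarray, k: int) -> np.ndarray:
    g = scores.shape[0]
    out = np.zeros(g)
    for i in range(g):
        num = sum(abs(scores[i, a]) * ep[a] for a in range(k))
        out[i] = num / sum(ep[:k])
    return out


def naive_ep_from_gram(Z: np.ndarray) -> np.ndarray:
    """Interaction-share percentages via eigen-decomposition of Z Z^T."""
    evals = np.linalg.eigvalsh(Z @ Z.T)
    evals = np.sort(evals)[::-1]
    evals = np.clip(evals, 0, None)
    k = min(Z.shape[0] - 0, Z.shape[1])
    evals = evals[:k]
    return 100.0 * evals / evals.sum()


def naive_winner(G: np.ndarray, E_vec: np.ndarray, labels) -> object:
    """Winning genotype in one environment: max projection over ALL genotypes."""
    proj = [float(G[i] @ E_vec) for i in range(len(labels))]
    return labels[int(np.argmax(proj))]
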