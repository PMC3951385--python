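"""Independent brute-force oracles used across test modules.

Written with plain loops against the defining formulas, deliberately
avoiding the library's own code paths.
"""

import numpy as np
import pandas as pd


def brute_force_pairwise_sd(a, b):
    """Log2-ratio standard deviation (n-1) of two gene vectors."""
    ratios = [np.log2(x / y) for x, y in zip(a, b)]
    mean = sum(ratios) / len(ratios)
    return (sum((x - mean) ** 2 for x in ratios) / (len(ratios) - 1)) ** 0.5


def brute_force_m_values(m: pd.DataFrame) -> dict:
    """Average pairwise log-ratio SD per gene."""
    out = {}
    for g in m.index:
        sds = [
            brute_force_pairwise_sd(m.loc[g], m.loc[h]) for h in m.index if h != g
        ]
        out[g] = sum(sds) / len(sds)
    return out


def brute_force_v_series(m: pd.DataFrame, stable_first: list) -> dict:
    """SD over samples of log2(NF_n / NF_{n+1}) from first principles."""
    out = {}
    for n in range(2, len(stable_first)):
        nf_n, nf_n1 = [], []
        for s in m.columns:
            vals_n = [m.loc[g, s] for g in stable_first[:n]]
            vals_n1 = [m.loc[g, s] for g in stable_first[: n + 1]]
            nf_n.append(np.exp(np.mean(np.log(vals_n))))
            nf_n1.append(np.exp(np.mean(np.log(vals_n1))))
        ratios = [np.log2(a / b) for a, b in zip(nf_n, nf_n1)]
        mean = sum(ratios) / len(ratios)
        out[n] = (sum((x - mean) ** 2 for x in ratios) / (len(ratios) - 1)) ** 0.5
    return out


def literal_stability_oracle(y: pd.DataFrame, design):
    """Step-by-step recomputation of the variance-decomposition stability.

    Returns ``(d, sigma2, gamma2, rho)`` with dict keys ``(gene, group)``.
    """
    genes, samples = list(y.index), list(y.columns)
    L = len(genes)
    z = {}
    for j in samples:
        col_mean = sum(y.loc[i, j] for i in genes) / L
        for i in genes:
            z[(i, j)] = y.loc[i, j] - col_mean
    groups = {}
    for s in samples:
        groups.setdefault(design.groups[s], []).append(s)
    labels = list(groups)
    n = {g: len(m) for g, m in groups.items()}
    d, s2 = {}, {}
    for i in genes:
        means = {g: sum(z[(i, j)] for j in groups[g]) / n[g] for g in labels}
        overall = sum(n[g] * means[g] for g in labels) / sum(n.values())
        for g in labels:
            d[(i, g)] = means[g] - overall
            var = sum((z[(i, j)] - means[g]) ** 2 for j in groups[g]) / (n[g] - 1)
            s2[(i, g)] = max(0.0, var * L / (L - 1))
    d_vals = list(d.values())
    d_mean = sum(d_vals) / len(d_vals)
    var_d = sum((x - d_mean) ** 2 for x in d_vals) / (len(d_vals) - 1)
    noise = [s2[(i, g)] / n[g] for i in genes for g in labels]
    gamma2 = max(0.0, var_d - sum(noise) / len(noise))
    rho = {}
    for i in genes:
        acc = 0.0
        for g in labels:
            shrink = gamma2 / (gamma2 + s2[(i, g)] / n[g]) if gamma2 > 0 else 0.0
            acc += abs(d[(i, g)] * shrink) + (s2[(i, g)] / n[g]) ** 0.5
        rho[i] = acc / len(labels)
    return d, s2, gamma2, rho


def brute_force_best_pair(y: pd.DataFrame, design, group_sizes: dict):
    """Exhaustive pair search from the literal pair formulas."""
    import itertools

    d, s2, gamma2, _ = literal_stability_oracle(y, design)
    labels = list(group_sizes)
    best_score, best = None, None
    for i, k in itertools.combinations(list(y.index), 2):
        acc = 0.0
        for g in labels:
            d_pair = (d[(i, g)] + d[(k, g)]) / 2
            s2_pair = (s2[(i, g)] + s2[(k, g)]) / 4
            noise = s2_pair / group_sizes[g]
            shrink = gamma2 / (gamma2 + noise) if gamma2 > 0 else 0.0
            acc += abs(d_pair * shrink) + noise**0.5
        score = acc / len(labels)
        if best_score is None or score < best_score:
            best_score, best = score, (i, k)
    return best, best_score
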