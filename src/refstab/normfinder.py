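"""Model-based reference-gene stability (NormFinder-style).

Works on log2 expression values and decomposes each candidate gene's
variation into an inter-group component (a systematic shift of the gene
between experimental groups, e.g. tissues vs. abiotic stress) and an
intra-group component (biological + technical scatter within a group).

Procedure, for a genes x samples log2 matrix ``y`` and a sample -> group
design with L genes and G groups of sizes n_g:

1.  Remove the per-sample global effect (amount of template, overall
    expression level): ``z[i, j] = y[i, j] - mean_i y[i, j]``.
2.  Per gene i and group g, the inter-group difference
    ``d[i, g] = mean_{j in g} z[i, j] - (n_g-weighted mean over groups)``
    and the intra-group variance
    ``sigma2[i, g] = var_{j in g}(z[i, j]) * L / (L - 1)``
    (the L/(L-1) factor undoes the variance shrinkage introduced by the
    gene-mean centering in step 1).
3.  A between-gene dispersion of the true group differences,
    ``gamma2 = max(0, Var_{i,g} d[i, g] - mean_{i,g} sigma2[i, g]/n_g)``,
    estimated by the method of moments, calibrates how much of an
    observed d is signal rather than sampling noise; each d is shrunk by
    ``gamma2 / (gamma2 + sigma2[i, g]/n_g)``.
4.  The stability value combines both sources of error:
    ``rho_i = (1/G) * sum_g (|d*[i, g]| + sqrt(sigma2[i, g]/n_g))``.
    Lower rho = more stable.  With a single group (ungrouped mode)
    ``rho_i = sqrt(sigma2_i)``, i.e. ranking by within-set SD.

The best pair of genes is found by exhaustively scoring every pair as a
pseudo-gene with averaged differences ``(d_i + d_k)/2`` and variance
``(sigma2_i + sigma2_k)/4``; opposite-sign group shifts cancel, which is
why a well-chosen pair can beat the best single gene.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroupDesign",
    "NormFinderResult",
    "remove_sample_effect",
    "group_statistics",
    "stability_values",
    "best_pair",
]


@dataclass(frozen=True)
class GroupDesign:
    """Sample -> group assignment for grouped stability analysis."""

    groups: dict[str, str]  # sample -> group label

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("empty design")

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups.values():
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    def members(self, label: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == label]

    def validate_for(self, samples: list[str], grouped: bool = True) -> None:
        missing = [s for s in samples if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")
        if grouped and self.n_groups >= 2:
            for lab in self.labels:
                n = sum(1 for s in samples if self.groups.get(s) == lab)
                if 0 < n < 2:
                    raise ValueError(f"group {lab!r} has fewer than 2 samples")


@dataclass
class NormFinderResult:
    z: pd.DataFrame
    d: pd.DataFrame  # genes x groups inter-group differences (shrunk: d_star)
    d_raw: pd.DataFrame
    sigma2: pd.DataFrame  # genes x groups intra-group variances
    gamma2: float
    rho: pd.Series  # per-gene stability, ascending = most stable first
    ranking: list[str]
    best_gene: str
    best_pair: tuple[str, str]
    best_pair_rho: float
    ungrouped: bool = False
    pair_ties: list[tuple[str, str]] = field(default_factory=list)


def remove_sample_effect(y: pd.DataFrame) -> pd.DataFrame:
    """Center each sample column on its across-gene mean.

    Absorbs per-sample effects (template amount, global expression) so
    that only gene-relative behaviour remains; column sums of the result
    are zero.
    """
    y = y.astype(float)
    if y.isna().any().any():
        raise ValueError("matrix must be complete; impute or drop upstream")
    return y.sub(y.mean(axis=0), axis=1)


def _group_index(design: GroupDesign, samples: list[str]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for lab in design.labels:
        members = [s for s in design.members(lab) if s in samples]
        if members:
            out[lab] = members
    return out


def group_statistics(
    z: pd.DataFrame, design: GroupDesign
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Inter-group differences d, intra-group variances sigma2, and gamma2.

    With a single group the inter-group terms are zero by definition
    (ungrouped mode); callers detect this via ``design.n_groups``.
    """
    samples = list(z.columns)
    design.validate_for(samples)
    groups = _group_index(design, samples)
    genes = list(z.index)
    L = len(genes)
    if L < 2:
        raise ValueError("need at least 2 genes")

    n_g = {lab: len(m) for lab, m in groups.items()}
    group_means = pd.DataFrame(
        {lab: z[m].mean(axis=1) for lab, m in groups.items()}, index=genes
    )
    # sample variance within each group, corrected for gene-mean centering
    sigma2 = pd.DataFrame(
        {
            lab: z[m].var(axis=1, ddof=1) * (L / (L - 1)) if n_g[lab] >= 2 else 0.0
            for lab, m in groups.items()
        },
        index=genes,
    ).clip(lower=0.0)

    if len(groups) < 2:
        d = pd.DataFrame(0.0, index=genes, columns=list(groups))
        return d, sigma2, 0.0

    weights = np.array([n_g[lab] for lab in groups], dtype=float)
    overall = (group_means * weights).sum(axis=1) / weights.sum()
    d = group_means.sub(overall, axis=0)

    noise = sigma2.div(pd.Series(n_g), axis=1)
    gamma2 = max(0.0, float(d.to_numpy().flatten().var(ddof=1)) - float(noise.to_numpy().mean()))
    return d, sigma2, gamma2


def stability_values(y: pd.DataFrame, design: GroupDesign) -> NormFinderResult:
    """Rank candidate genes by the combined inter/intra-group stability rho."""
    z = remove_sample_effect(y)
    d_raw, sigma2, gamma2 = group_statistics(z, design)
    groups = _group_index(design, list(z.columns))
    n_g = pd.Series({lab: len(m) for lab, m in groups.items()}, dtype=float)
    ungrouped = len(groups) < 2

    if ungrouped:
        lab = list(groups)[0] if groups else "all"
        var_all = z.var(axis=1, ddof=1) * (len(z.index) / (len(z.index) - 1))
        rho = np.sqrt(var_all.clip(lower=0.0))
        d_star = d_raw * 0.0
    else:
        noise = sigma2.div(n_g, axis=1)
        if gamma2 > 0:
            shrink = gamma2 / (gamma2 + noise)
        else:
            shrink = noise * 0.0
        d_star = d_raw * shrink
        rho = (d_star.abs() + np.sqrt(noise)).mean(axis=1)

    rho = rho.astype(float).rename("rho")
    ranking = list(rho.sort_values(kind="stable").index)
    best_gene = ranking[0]
    pair, pair_rho, ties = _best_pair_from_stats(d_raw, sigma2, gamma2, n_g, ungrouped, z)
    return NormFinderResult(
        z=z,
        d=d_star,
        d_raw=d_raw,
        sigma2=sigma2,
        gamma2=gamma2,
        rho=rho,
        ranking=ranking,
        best_gene=best_gene,
        best_pair=pair,
        best_pair_rho=pair_rho,
        ungrouped=ungrouped,
        pair_ties=ties,
    )


def _pair_rho(
    d_raw: pd.DataFrame,
    sigma2: pd.DataFrame,
    gamma2: float,
    n_g: pd.Series,
    i: str,
    k: str,
) -> float:
    """Stability of the pseudo-gene averaging genes i and k."""
    d_pair = (d_raw.loc[i] + d_raw.loc[k]) / 2.0
    s2_pair = (sigma2.loc[i] + sigma2.loc[k]) / 4.0
    noise = s2_pair / n_g
    if gamma2 > 0:
        d_star = d_pair * (gamma2 / (gamma2 + noise))
    else:
        d_star = d_pair * 0.0
    return float((d_star.abs() + np.sqrt(noise)).mean())


def _best_pair_from_stats(
    d_raw: pd.DataFrame,
    sigma2: pd.DataFrame,
    gamma2: float,
    n_g: pd.Series,
    ungrouped: bool,
    z: pd.DataFrame,
) -> tuple[tuple[str, str], float, list[tuple[str, str]]]:
    genes = list(d_raw.index)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for a pair")
    scores: dict[tuple[str, str], float] = {}
    for i, k in itertools.combinations(genes, 2):
        if ungrouped:
            # pseudo-gene = average of the two log2 profiles
            pseudo = (z.loc[i] + z.loc[k]) / 2.0
            L = len(genes)
            scores[(i, k)] = float(
                np.sqrt(max(0.0, pseudo.var(ddof=1) * (L / (L - 1))))
            )
        else:
            scores[(i, k)] = _pair_rho(d_raw, sigma2, gamma2, n_g, i, k)
    best_score = min(scores.values())
    tied = sorted([p for p, v in scores.items() if v == best_score])
    best = tied[0]
    ties = tied[1:]
    return best, best_score, ties


def best_pair(y: pd.DataFrame, design: GroupDesign) -> tuple[str, str, float]:
    """Best two-gene combination: ``(gene_i, gene_k, combined stability)``."""
    res = stability_values(y, design)
    return res.best_pair[0], res.best_pair[1], res.best_pair_rho
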