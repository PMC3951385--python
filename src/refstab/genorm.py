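"""geNorm-style reference-gene stability ranking.

The stability measure rests on one idea: the expression ratio of two
ideal reference genes is the same in every sample, so the standard
deviation of their log-transformed ratio across samples measures how far
a pair departs from ideal.  A gene's M value is its average pairwise
log-ratio SD with every other candidate; the least stable gene (highest
M) is eliminated and M recomputed until two genes remain.

The number of genes worth including in a normalization factor (NF, the
geometric mean of the n most stable genes) is decided from the pairwise
variation V(n, n+1) = SD over samples of log2(NF_n / NF_{n+1}); once
adding a gene moves the NF by less than a cutoff (default 0.15), the
smaller set suffices.

All logs are base 2.  Missing values are allowed: pairwise SDs use the
samples shared by both genes, and an NF is undefined for any sample
missing one of its member genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeNormResult",
    "pairwise_sd",
    "pairwise_sd_matrix",
    "m_values",
    "rank_genes",
    "normalization_factor",
    "pairwise_variation_series",
    "recommend_count",
    "genorm",
]

DEFAULT_CUTOFF = 0.15


class UndefinedPairError(ValueError):
    """Fewer than two shared samples between two genes."""


@dataclass
class GeNormResult:
    """Outcome of a full stability analysis.

    ``ranking`` lists genes least stable first; the final two entries are
    jointly most stable (their order is the tie-broken input order, and
    they share a rank).  ``m_trajectory`` maps elimination round (0-based)
    to that round's gene -> M map.  ``v_series[n]`` is V(n, n+1).
    """

    pairwise_sd: pd.DataFrame
    m_trajectory: list[dict[str, float]]
    ranking: list[str]
    v_series: dict[int, float]
    recommended_n: int
    cutoff: float = DEFAULT_CUTOFF
    exceeds_cutoff: bool = False
    ties: list[tuple[str, str]] = field(default_factory=list)

    @property
    def most_stable_first(self) -> list[str]:
        return list(reversed(self.ranking))

    @property
    def stable_pair(self) -> tuple[str, str]:
        return self.ranking[-2], self.ranking[-1]

    def final_m(self) -> dict[str, float]:
        """Each gene's M in its last round (elimination round, or round G-2)."""
        out: dict[str, float] = {}
        for round_m in self.m_trajectory:
            out.update(round_m)
        return out


def _check_matrix(m: pd.DataFrame) -> pd.DataFrame:
    values = m.to_numpy(dtype=float)
    if (np.nan_to_num(values, nan=1.0) <= 0).any():
        raise ValueError("expression matrix must be strictly positive")
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    return m


def pairwise_sd(a: pd.Series, b: pd.Series) -> float:
    """SD (n-1 denominator) of log2(a/b) over samples present in both."""
    a = pd.Series(a, dtype=float)
    b = pd.Series(b, dtype=float)
    shared = a.notna() & b.notna()
    if int(shared.sum()) < 2:
        raise UndefinedPairError("need >= 2 shared samples for a pairwise SD")
    ratios = np.log2(a[shared].to_numpy() / b[shared].to_numpy())
    return float(np.std(ratios, ddof=1))


def pairwise_sd_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Symmetric gene x gene matrix of pairwise log-ratio SDs (0 diagonal)."""
    _check_matrix(m)
    genes = list(m.index)
    out = pd.DataFrame(0.0, index=genes, columns=genes)
    for i, g in enumerate(genes):
        for h in genes[i + 1 :]:
            v = pairwise_sd(m.loc[g], m.loc[h])
            out.loc[g, h] = out.loc[h, g] = v
    return out


def m_values(m: pd.DataFrame) -> dict[str, float]:
    """Stability value M per gene: mean pairwise SD with all other genes.

    With exactly two genes both M values equal the single pairwise SD.
    """
    _check_matrix(m)
    sd = pairwise_sd_matrix(m)
    n = len(sd)
    if n == 2:
        v = float(sd.iloc[0, 1])
        return {g: v for g in sd.index}
    return {g: float(sd.loc[g].drop(g).mean()) for g in sd.index}


def rank_genes(m: pd.DataFrame) -> tuple[list[str], list[dict[str, float]], list[tuple[str, str]]]:
    """Iterative elimination ranking.

    Repeatedly removes the gene with the highest current M until two
    remain, recording each round's M map.  Ties are broken by removing
    the gene appearing later in the matrix's row order; every tie is
    recorded.  Returns ``(ranking least-stable-first, m_trajectory, ties)``.
    """
    _check_matrix(m)
    if m.shape[0] < 3:
        raise ValueError("ranking needs at least 3 genes")
    current = m.copy()
    eliminated: list[str] = []
    trajectory: list[dict[str, float]] = []
    ties: list[tuple[str, str]] = []
    order = {g: i for i, g in enumerate(m.index)}
    while current.shape[0] > 2:
        mm = m_values(current)
        trajectory.append(mm)
        worst_m = max(mm.values())
        worst_genes = [g for g, v in mm.items() if v == worst_m]
        worst = max(worst_genes, key=order.__getitem__)
        if len(worst_genes) > 1:
            for g in worst_genes:
                if g != worst:
                    ties.append((g, worst))
        eliminated.append(worst)
        current = current.drop(index=worst)
    trajectory.append(m_values(current))
    last_two = sorted(current.index, key=order.__getitem__)
    ranking = eliminated + last_two
    return ranking, trajectory, ties


def normalization_factor(m: pd.DataFrame, genes: list[str]) -> pd.Series:
    """Per-sample NF: geometric mean of the listed genes' quantities.

    NF is NaN for any sample missing one of the member genes.
    """
    if not genes:
        raise ValueError("need at least one reference gene")
    missing = [g for g in genes if g not in m.index]
    if missing:
        raise ValueError(f"genes not in matrix: {missing}")
    sub = m.loc[genes].astype(float)
    if (sub.dropna(how="any", axis=1) <= 0).any().any():
        raise ValueError("reference-gene quantities must be positive")
    logs = np.log2(sub)
    nf = np.exp2(logs.mean(axis=0, skipna=False))
    nf.name = "nf"
    return nf


def pairwise_variation_series(
    m: pd.DataFrame, ranking: list[str] | None = None
) -> dict[int, float]:
    """V(n, n+1) for n = 2 .. G-1.

    ``V(n, n+1)`` is the SD over samples of log2(NF_n / NF_{n+1}) where
    NF_n uses the n most stable genes.  ``ranking`` is least stable first
    (as produced by :func:`rank_genes`); if omitted it is computed.
    """
    if ranking is None:
        ranking, _, _ = rank_genes(m)
    if len(ranking) < 3:
        raise ValueError("pairwise variation needs >= 3 ranked genes")
    stable_first = list(reversed(ranking))
    out: dict[int, float] = {}
    for n in range(2, len(stable_first)):
        nf_n = normalization_factor(m, stable_first[:n])
        nf_n1 = normalization_factor(m, stable_first[: n + 1])
        ratios = np.log2(nf_n / nf_n1).dropna()
        out[n] = float(np.std(ratios, ddof=1))
    return out


def recommend_count(
    v_series: dict[int, float] | list[float], cutoff: float = DEFAULT_CUTOFF
) -> tuple[int, bool]:
    """Smallest n with V(n, n+1) <= cutoff.

    A V value above the cutoff means the (n+1)-th gene still changes the
    NF materially, so more genes are needed; a value at or under the
    cutoff means n genes suffice.  If no entry qualifies, returns the
    full gene count with ``exceeds_cutoff=True``.
    """
    if isinstance(v_series, dict):
        items = sorted(v_series.items())
    else:
        items = list(enumerate(v_series, start=2))
    if not items:
        raise ValueError("empty pairwise-variation series")
    for n, v in items:
        if v <= cutoff:
            return n, False
    return items[-1][0] + 1, True


def genorm(m: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> GeNormResult:
    """Full stability analysis: ranking, V series and recommended count."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    ranking, trajectory, ties = rank_genes(m)
    v_series = pairwise_variation_series(m, ranking)
    recommended_n, exceeds = recommend_count(v_series, cutoff)
    return GeNormResult(
        pairwise_sd=pairwise_sd_matrix(m),
        m_trajectory=trajectory,
        ranking=ranking,
        v_series=v_series,
        recommended_n=recommended_n,
        cutoff=cutoff,
        exceeds_cutoff=exceeds,
        ties=ties,
    )
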