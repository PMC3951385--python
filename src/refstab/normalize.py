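"""Target-gene normalization and comparison of reference-gene choices.

A normalization factor (NF) is the per-sample geometric mean of the
chosen reference genes' starting quantities; a target gene's relative
expression is its R0 divided by the NF.  Because different stability
algorithms can pick different reference sets, this module also
quantifies how much the normalized result moves when the NF changes —
the per-sample relative percent difference between two NFs, which equals
the percent difference induced in every normalized value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import normfinder as _normfinder
from .genorm import genorm as _run_genorm
from .genorm import normalization_factor

__all__ = [
    "NormalizationFactor",
    "normalize_targets",
    "compare_normalizations",
    "summarize_bio_reps",
    "run_validation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationFactor:
    """Per-sample NF with provenance (reference genes + selection method)."""

    values: pd.Series
    reference_genes: tuple[str, ...]
    method: str  # genorm | normfinder | manual

    def __post_init__(self) -> None:
        if not self.reference_genes:
            raise ValueError("provenance must list at least one reference gene")
        vals = pd.Series(self.values, dtype=float)
        if (vals.dropna() <= 0).any():
            raise ValueError("NF values must be positive where defined")
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_matrix(
        cls, m: pd.DataFrame, genes: list[str], method: str = "manual"
    ) -> "NormalizationFactor":
        return cls(
            values=normalization_factor(m, genes),
            reference_genes=tuple(genes),
            method=method,
        )


def normalize_targets(
    targets: pd.DataFrame, nf: NormalizationFactor | pd.Series
) -> pd.DataFrame:
    """Divide each target gene's per-sample quantity by the NF.

    ``targets`` is a genes x samples matrix of positive quantities.
    Samples lacking an NF come back as NaN (reported via a log warning).
    An NF of zero or below is a hard error: it violates the NF invariant
    and means the reference set was built from invalid quantities.
    """
    values = nf.values if isinstance(nf, NormalizationFactor) else pd.Series(nf, dtype=float)
    if (values.dropna() <= 0).any():
        raise ValueError("normalization factor must be positive wherever defined")
    missing = [s for s in targets.columns if s not in values.index or pd.isna(values.get(s))]
    if missing:
        logger.warning("NF undefined for samples %s; normalized values set to NaN", missing)
    aligned = values.reindex(targets.columns)
    return targets.div(aligned, axis=1)


def compare_normalizations(
    nf_a: NormalizationFactor | pd.Series, nf_b: NormalizationFactor | pd.Series
) -> pd.Series:
    """Per-sample relative percent difference between two NFs.

    ``100 * (max(a, b) - min(a, b)) / max(a, b)`` — the relative change,
    expressed against the larger NF, that switching normalization factors
    induces in every normalized expression value.  Symmetric in its
    arguments and bounded in [0, 100).
    """
    a = nf_a.values if isinstance(nf_a, NormalizationFactor) else pd.Series(nf_a, dtype=float)
    b = nf_b.values if isinstance(nf_b, NormalizationFactor) else pd.Series(nf_b, dtype=float)
    shared = a.index.intersection(b.index)
    a, b = a[shared].dropna(), b[shared].dropna()
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        logger.warning("no shared samples between normalization factors")
        return pd.Series(dtype=float, name="percent_difference")
    hi = np.maximum(a[shared], b[shared])
    lo = np.minimum(a[shared], b[shared])
    out = 100.0 * (hi - lo) / hi
    out.name = "percent_difference"
    return out


def summarize_bio_reps(profile: pd.DataFrame, condition_of: dict[str, str]) -> pd.DataFrame:
    """Mean +/- SD of normalized values over biological replicates.

    ``condition_of`` maps sample -> condition; replicates of a condition
    are averaged, matching how expression profiles are usually plotted.
    """
    long = profile.stack().rename("value").reset_index()
    long.columns = ["gene", "sample", "value"]
    long["condition"] = long["sample"].map(condition_of)
    return (
        long.groupby(["gene", "condition"])["value"]
        .agg(mean="mean", sd="std")
        .reset_index()
    )


def run_validation(
    reference: pd.DataFrame,
    targets: pd.DataFrame,
    design: _normfinder.GroupDesign,
    subsets: dict[str, list[str]],
    cutoff: float = 0.15,
    min_subset_size: int = 3,
) -> dict:
    """Cross-validate normalization choices over named sample subsets.

    For each subset: rank the candidate reference genes with both
    stability methods, build the best-set NF per method plus a
    worst-gene NF (the least stable gene under each method), normalize
    the target genes with each NF, and compare the resulting NFs
    pairwise.  Subsets smaller than ``min_subset_size`` are skipped.

    Returns a report dict with, per subset: the rankings, the NFs
    (as :class:`NormalizationFactor`), normalized profiles
    (genes x samples DataFrames) and the mean percent difference for
    each NF pair.
    """
    report: dict = {"subsets": {}, "skipped": []}
    for name, samples in subsets.items():
        samples = [s for s in samples if s in reference.columns]
        if len(samples) < min_subset_size:
            logger.warning("subset %r has < %d samples; skipped", name, min_subset_size)
            report["skipped"].append(name)
            continue
        ref_sub = reference[samples]
        tgt_sub = targets[[s for s in samples if s in targets.columns]]

        gn = _run_genorm(ref_sub, cutoff=cutoff)
        best_gn = gn.most_stable_first[: gn.recommended_n]
        worst_gn = gn.ranking[0]

        sub_design = _normfinder.GroupDesign(
            {s: design.groups[s] for s in samples}
        )
        grouped = sub_design.n_groups >= 2
        nf_res = _normfinder.stability_values(np.log2(ref_sub), sub_design)
        best_nf = list(nf_res.best_pair)
        worst_nf = nf_res.ranking[-1]

        factors = {
            "genorm_best": NormalizationFactor.from_matrix(ref_sub, best_gn, "genorm"),
            "normfinder_best": NormalizationFactor.from_matrix(ref_sub, best_nf, "normfinder"),
            "genorm_worst": NormalizationFactor.from_matrix(ref_sub, [worst_gn], "genorm"),
            "normfinder_worst": NormalizationFactor.from_matrix(ref_sub, [worst_nf], "normfinder"),
        }
        profiles = {k: normalize_targets(tgt_sub, nf) for k, nf in factors.items()}
        comparisons = {}
        names = list(factors)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                diff = compare_normalizations(factors[a], factors[b])
                comparisons[f"{a}_vs_{b}"] = float(diff.mean()) if len(diff) else float("nan")

        report["subsets"][name] = {
            "genorm_ranking_most_stable_first": gn.most_stable_first,
            "genorm_recommended_n": gn.recommended_n,
            "normfinder_ranking": nf_res.ranking,
            "normfinder_grouped": grouped,
            "best_sets": {
                "genorm": best_gn,
                "normfinder": best_nf,
            },
            "worst_genes": {"genorm": worst_gn, "normfinder": worst_nf},
            "factors": factors,
            "profiles": profiles,
            "mean_percent_difference": comparisons,
        }
    return report
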