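"""Efficiency-corrected quantification of raw qPCR amplification data.

Converts per-well fluorescence traces (cycle vs. fluorescence) into
threshold cycles (Ct), per-well amplification efficiencies (E) and
back-calculated starting fluorescence values

    R0 = R_Ct * (1 + E) ** (-Ct)

where ``R_Ct`` is the fluorescence at the detection threshold.  R0 is
proportional to the starting template quantity and is the unit in which
all downstream stability analysis operates.

The module also screens technical-replicate groups for efficiency
outliers (studentized-residual test within groups, plus a one-way
ANOVA for between-group amplification equivalence) and converts
aggregated R0 values into relative quantities scaled to the
highest-expressing sample per gene (the calibrator convention used by
spreadsheet stability tools).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FluorescenceTrace",
    "AmplificationFit",
    "ReplicateSet",
    "NoAmplificationError",
    "ThresholdBelowBaselineError",
    "InsufficientExponentialPhaseError",
    "FlatTraceError",
    "determine_ct",
    "fit_efficiency",
    "compute_r0",
    "solve_ct",
    "fit_well",
    "plate_threshold",
    "detect_outliers",
    "efficiency_equivalence",
    "relative_quantities",
    "quantify_traces",
    "quantify_ct_table",
]

logger = logging.getLogger(__name__)

DEFAULT_BASELINE_CYCLES = (3, 8)
DEFAULT_WINDOW_LENGTH = 4
DEFAULT_THRESHOLD_FRACTION = 0.10


class NoAmplificationError(ValueError):
    """The trace never reaches the detection threshold."""


class ThresholdBelowBaselineError(ValueError):
    """The requested threshold lies below the cycle-1 fluorescence."""


class InsufficientExponentialPhaseError(ValueError):
    """Too few positive baseline-subtracted points for a log-linear fit."""


class FlatTraceError(ValueError):
    """The trace has no variance; no exponential phase exists."""


@dataclass(frozen=True)
class FluorescenceTrace:
    """A single well's raw amplification curve.

    Cycles are 1-based integers as instruments report them; fluorescence
    values are finite and non-negative, in arbitrary instrument units.
    """

    well_id: str
    gene: str
    sample: str
    cycles: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        cycles = np.asarray(self.cycles, dtype=float)
        fluo = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "cycles", cycles)
        object.__setattr__(self, "fluorescence", fluo)
        if cycles.ndim != 1 or fluo.ndim != 1 or len(cycles) != len(fluo):
            raise ValueError("cycles and fluorescence must be 1-D and equal length")
        if len(cycles) < 10:
            raise ValueError("trace needs at least 10 cycles")
        if np.any(np.diff(cycles) <= 0):
            raise ValueError("cycles must be strictly increasing")
        if not np.all(np.isfinite(fluo)) or np.any(fluo < 0):
            raise ValueError("fluorescence must be finite and non-negative")

    def baseline_corrected(
        self, baseline_cycles: tuple[int, int] = DEFAULT_BASELINE_CYCLES
    ) -> np.ndarray:
        """Fluorescence minus the mean over an early-cycle baseline window."""
        lo, hi = baseline_cycles
        mask = (self.cycles >= lo) & (self.cycles <= hi)
        if not mask.any():
            raise ValueError(f"no cycles in baseline window {baseline_cycles}")
        return self.fluorescence - float(self.fluorescence[mask].mean())


@dataclass(frozen=True)
class AmplificationFit:
    """Per-well quantification result.

    ``r0 = r_ct * (1 + efficiency) ** (-ct)`` holds by construction.
    ``fit_window`` is the (first, last) cycle of the log-linear window
    used for the efficiency estimate.
    """

    ct: float
    efficiency: float
    r_ct: float
    r0: float
    fit_window: tuple[float, float]
    fit_r2: float

    def __post_init__(self) -> None:
        if not (-1.0 < self.efficiency <= 1.5):
            raise ValueError(f"efficiency {self.efficiency} outside (-1, 1.5]")
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        expected = compute_r0(self.ct, self.efficiency, self.r_ct)
        if not math.isclose(self.r0, expected, rel_tol=1e-9):
            raise ValueError("r0 inconsistent with r_ct * (1+E)^(-ct)")
        if not 0.0 <= self.fit_r2 <= 1.0 + 1e-12:
            raise ValueError("fit_r2 must lie in [0, 1]")


@dataclass
class ReplicateSet:
    """Technical replicates of one gene in one sample, with outlier flags."""

    gene: str
    sample: str
    fits: list[AmplificationFit]
    outlier_flags: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.fits:
            raise ValueError("a replicate set needs at least one member")
        if not self.outlier_flags:
            self.outlier_flags = [False] * len(self.fits)
        if len(self.outlier_flags) != len(self.fits):
            raise ValueError("outlier_flags must match fits in length")

    @property
    def kept_fits(self) -> list[AmplificationFit]:
        return [f for f, bad in zip(self.fits, self.outlier_flags) if not bad]


def determine_ct(trace_or_fluo, threshold: float, cycles=None) -> float:
    """Fractional cycle at which fluorescence first reaches ``threshold``.

    Linear interpolation between the bracketing cycles.  Accepts either a
    :class:`FluorescenceTrace` or a bare fluorescence array plus cycles.

    Raises
    ------
    NoAmplificationError
        If the trace never reaches the threshold.
    ThresholdBelowBaselineError
        If the threshold lies at or below the cycle-1 fluorescence
        (the crossing would be extrapolated, not observed).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(trace_or_fluo, FluorescenceTrace):
        fluo = trace_or_fluo.fluorescence
        cyc = trace_or_fluo.cycles
    else:
        fluo = np.asarray(trace_or_fluo, dtype=float)
        cyc = np.asarray(cycles, dtype=float)
    if fluo[0] > threshold:
        raise ThresholdBelowBaselineError(
            f"threshold {threshold} below cycle-{cyc[0]:g} fluorescence {fluo[0]:g}"
        )
    above = np.nonzero(fluo >= threshold)[0]
    if len(above) == 0:
        raise NoAmplificationError(f"trace never reaches threshold {threshold}")
    i = int(above[0])
    if fluo[i] == threshold or i == 0:
        return float(cyc[i])
    # interpolate between the last sub-threshold point and the crossing
    f0, f1 = fluo[i - 1], fluo[i]
    c0, c1 = cyc[i - 1], cyc[i]
    return float(c0 + (threshold - f0) / (f1 - f0) * (c1 - c0))


def fit_efficiency(
    trace: FluorescenceTrace,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    baseline_cycles: tuple[int, int] | None = DEFAULT_BASELINE_CYCLES,
) -> tuple[float, tuple[float, float], float]:
    """Estimate per-cycle amplification efficiency from the exponential phase.

    Fits log(fluorescence) on cycle over every contiguous window of
    ``window_length`` cycles whose baseline-subtracted fluorescence is
    strictly positive, keeps the window with the highest R², and returns
    ``(efficiency, (first_cycle, last_cycle), r2)`` where
    ``efficiency = exp(slope) - 1``.

    Set ``baseline_cycles=None`` to skip baseline subtraction.
    """
    if window_length < 3:
        raise ValueError("window_length must be >= 3")
    fluo = (
        trace.baseline_corrected(baseline_cycles)
        if baseline_cycles is not None
        else trace.fluorescence.astype(float)
    )
    if float(np.ptp(trace.fluorescence)) == 0.0:
        raise FlatTraceError("trace has zero variance")
    cyc = trace.cycles
    positive = fluo > 0
    best = None  # (r2, slope, window)
    n = len(cyc)
    for start in range(0, n - window_length + 1):
        stop = start + window_length
        if not positive[start:stop].all():
            continue
        x = cyc[start:stop]
        y = np.log(fluo[start:stop])
        if np.ptp(y) == 0.0:
            continue  # flat in the window: no exponential signal
        res = stats.linregress(x, y)
        r2 = float(res.rvalue**2)
        if res.slope <= 0:
            continue  # amplification must grow
        if best is None or r2 > best[0]:
            best = (r2, float(res.slope), (float(x[0]), float(x[-1])))
    if best is None:
        raise InsufficientExponentialPhaseError(
            f"no window of {window_length} positive, growing cycles"
        )
    r2, slope, window = best
    efficiency = math.exp(slope) - 1.0
    return efficiency, window, r2


def compute_r0(ct: float, efficiency: float, r_ct: float) -> float:
    """Starting fluorescence ``R0 = r_ct * (1 + efficiency) ** (-ct)``."""
    if r_ct <= 0:
        raise ValueError("r_ct must be positive")
    if efficiency <= -1:
        raise ValueError("efficiency must exceed -1")
    if ct < 0:
        raise ValueError("ct must be non-negative")
    return float(r_ct * (1.0 + efficiency) ** (-ct))


def solve_ct(r0: float, efficiency: float, r_ct: float) -> float:
    """Invert :func:`compute_r0`: cycle at which R0 grows to ``r_ct``."""
    if r0 <= 0 or r_ct <= 0:
        raise ValueError("r0 and r_ct must be positive")
    return float(math.log(r_ct / r0) / math.log1p(efficiency))


def plate_threshold(
    traces: list[FluorescenceTrace],
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
    baseline_cycles: tuple[int, int] = DEFAULT_BASELINE_CYCLES,
) -> float:
    """Plate-wide detection threshold.

    Default: ``fraction`` (10%) of the median plateau fluorescence, where
    a well's plateau is the maximum of its baseline-subtracted trace.
    """
    plateaus = [float(t.baseline_corrected(baseline_cycles).max()) for t in traces]
    thr = fraction * float(np.median(plateaus))
    if thr <= 0:
        raise ValueError("non-positive plate threshold; traces may lack signal")
    return thr


def fit_well(
    trace: FluorescenceTrace,
    threshold: float,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    baseline_cycles: tuple[int, int] = DEFAULT_BASELINE_CYCLES,
) -> AmplificationFit:
    """Full per-well quantification: Ct, efficiency and R0.

    Both the threshold crossing and the efficiency fit operate on the
    baseline-subtracted trace, so ``threshold`` is expressed in
    baseline-subtracted units (as returned by :func:`plate_threshold`).
    """
    fluo = trace.baseline_corrected(baseline_cycles)
    ct = determine_ct(fluo, threshold, cycles=trace.cycles)
    efficiency, window, r2 = fit_efficiency(trace, window_length, baseline_cycles)
    r0 = compute_r0(ct, efficiency, threshold)
    return AmplificationFit(
        ct=ct, efficiency=efficiency, r_ct=threshold, r0=r0, fit_window=window, fit_r2=r2
    )


def efficiency_equivalence(sets: list[ReplicateSet], alpha: float = 0.05) -> tuple[float, float, bool]:
    """Between-group amplification equivalence via one-way ANOVA.

    Tests whether mean amplification efficiency is comparable across the
    replicate groups (outlier-flagged members excluded).  Returns
    ``(F, p, equivalent)`` where ``equivalent`` is ``p >= alpha``.
    """
    arrays = [
        np.array([f.efficiency for f in s.kept_fits])
        for s in sets
        if len(s.kept_fits) >= 2
    ]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    if all(np.ptp(a) == 0 for a in arrays) and np.ptp([a[0] for a in arrays]) == 0:
        return 0.0, 1.0, True  # identical everywhere: trivially equivalent
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = stats.f_oneway(*arrays)
    return float(f), float(p), bool(p >= alpha)


def detect_outliers(
    sets: list[ReplicateSet], alpha: float = 0.05, min_effect: float = 0.02
) -> tuple[list[ReplicateSet], list[str]]:
    """Flag wells whose efficiency is inconsistent with their replicates.

    Within-group comparability screen on the replicate groups of one
    primer: iteratively, each member's externally studentized residual
    is computed (its efficiency minus the mean of its group's *other*
    members, over the pooled within-group SD with the member excluded),
    and the largest residual is flagged as an outlier if it exceeds the
    two-sided t critical value Bonferroni-adjusted over all members —
    so under the null the probability of flagging anything is ~ alpha.
    Flagged members are excluded downstream; between-group equivalence
    is the separate :func:`efficiency_equivalence` ANOVA.

    ``min_effect`` guards against statistically-significant-but-
    negligible deviations: a member is only flagged if its efficiency
    deviates from its group's remaining members by more than this
    amount (per-cycle gain units; default 0.02, the typical uncertainty
    of a log-linear efficiency fit).  Near-noiseless data would
    otherwise produce huge test statistics from meaningless scatter.

    Returns the replicate sets (flags filled in place) and a list of
    warning strings for groups too small to test.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if min_effect < 0:
        raise ValueError("min_effect must be >= 0")
    warnings: list[str] = []
    testable = [s for s in sets if len(s.fits) >= 2]
    for s in sets:
        if len(s.fits) < 2:
            warnings.append(
                f"replicate set {s.gene}/{s.sample} has a single member; not tested"
            )
    if not testable:
        return sets, warnings

    # active[(set index, member index)] marks members still in the test
    active = {
        (i, j): float(f.efficiency)
        for i, s in enumerate(testable)
        for j, f in enumerate(s.fits)
    }
    while True:
        groups: dict[int, list[tuple[int, float]]] = {}
        for (i, j), e in active.items():
            groups.setdefault(i, []).append((j, e))
        usable = {i: g for i, g in groups.items() if len(g) >= 2}
        n_total = sum(len(g) for g in usable.values())
        df = n_total - len(usable) - 1  # within-group df, candidate left out
        if not usable or df < 1:
            break
        worst = None  # (|t|, deviation, key)
        for i, g in usable.items():
            values = {j: e for j, e in g}
            for j, e in g:
                others = [v for jj, v in values.items() if jj != j]
                mean_out = float(np.mean(others))
                # pooled within-group SS with the candidate removed
                ss = 0.0
                for ii, gg in usable.items():
                    vals = [v for jj, v in gg if not (ii == i and jj == j)]
                    if len(vals) >= 2:
                        ss += float(((np.asarray(vals) - np.mean(vals)) ** 2).sum())
                s_out = math.sqrt(ss / df) if ss > 0 else 0.0
                dev = abs(e - mean_out)
                if s_out == 0.0:
                    t_val = math.inf if dev > 0 else 0.0
                else:
                    t_val = dev / (s_out * math.sqrt(1.0 + 1.0 / len(others)))
                if worst is None or t_val > worst[0]:
                    worst = (t_val, dev, (i, j))
        t_val, dev, key = worst
        critical = float(stats.t.ppf(1.0 - alpha / (2.0 * n_total), df))
        if t_val <= critical or dev <= min_effect:
            break
        i, j = key
        testable[i].outlier_flags[j] = True
        del active[key]
        logger.info(
            "flagged efficiency outlier %s/%s member %d (|t|=%.2f > %.2f)",
            testable[i].gene, testable[i].sample, j, t_val, critical,
        )
    return sets, warnings


def relative_quantities(r0: pd.DataFrame) -> pd.DataFrame:
    """Scale aggregated R0 values to the highest-expressing sample per gene.

    ``r0`` is a genes x samples DataFrame of positive aggregated R0
    values (NaN allowed for missing cells).  Each gene's row is divided
    by its maximum, so values lie in (0, 1] with at least one exact 1.
    Genes with no surviving values are dropped with a logged warning.
    """
    if (r0 <= 0).any().any():
        raise ValueError("all R0 values must be positive")
    dead = r0.index[r0.isna().all(axis=1)]
    if len(dead):
        logger.warning("dropping genes with no surviving wells: %s", list(dead))
        r0 = r0.drop(index=dead)
    return r0.div(r0.max(axis=1), axis=0)


def _geometric_mean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def quantify_traces(
    traces: list[FluorescenceTrace],
    threshold: float | None = None,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    baseline_cycles: tuple[int, int] = DEFAULT_BASELINE_CYCLES,
    alpha: float = 0.05,
    min_effect: float = 0.02,
) -> pd.DataFrame:
    """Quantify a plate of traces into a per-(gene, sample) summary table.

    Pipeline: plate threshold -> per-well (Ct, E, R0) -> ANOVA outlier
    screen on efficiencies across technical-replicate groups -> geometric
    mean of surviving R0 per gene x sample -> relative quantity scaled to
    each gene's calibrator (highest-expressing) sample.

    Returns a DataFrame with columns ``gene, sample, ct_mean, efficiency,
    r0, relative_quantity, outlier_excluded``.
    """
    if threshold is None:
        threshold = plate_threshold(traces, baseline_cycles=baseline_cycles)
    wells: dict[tuple[str, str], list[AmplificationFit]] = {}
    for t in traces:
        fit = fit_well(t, threshold, window_length, baseline_cycles)
        wells.setdefault((t.gene, t.sample), []).append(fit)
    sets = [
        ReplicateSet(gene=g, sample=s, fits=fits) for (g, s), fits in wells.items()
    ]
    # efficiency is a primer property: screen replicate groups per gene
    by_gene: dict[str, list[ReplicateSet]] = {}
    for s in sets:
        by_gene.setdefault(s.gene, []).append(s)
    for gene_sets in by_gene.values():
        _, warnings = detect_outliers(gene_sets, alpha=alpha, min_effect=min_effect)
        for w in warnings:
            logger.warning(w)

    rows = []
    for s in sets:
        kept = s.kept_fits
        n_excluded = len(s.fits) - len(kept)
        if not kept:  # keep the least-deviant member rather than lose the cell
            kept = s.fits
            n_excluded = 0
        rows.append(
            {
                "gene": s.gene,
                "sample": s.sample,
                "ct_mean": float(np.mean([f.ct for f in kept])),
                "efficiency": float(np.mean([f.efficiency for f in kept])),
                "r0": _geometric_mean(np.array([f.r0 for f in kept])),
                "outlier_excluded": n_excluded,
            }
        )
    summary = pd.DataFrame(rows)
    r0_matrix = summary.pivot(index="gene", columns="sample", values="r0")
    rel = relative_quantities(r0_matrix)
    rel_long = rel.stack().rename("relative_quantity").reset_index()
    summary = summary.merge(rel_long, on=["gene", "sample"], how="left")
    return summary.sort_values(["gene", "sample"]).reset_index(drop=True)


def quantify_ct_table(
    ct_table: pd.DataFrame,
    efficiencies: pd.Series | dict,
    r_ct: float = 1.0,
) -> pd.DataFrame:
    """Quantify from a pre-computed Ct table plus per-primer efficiencies.

    ``ct_table`` has columns ``gene, sample, ct`` (one row per well;
    technical replicates share gene and sample).  With no trace there is
    no threshold fluorescence, so R0 is computed with a unit ``r_ct``;
    the constant cancels in every within-gene ratio downstream.
    """
    eff = pd.Series(efficiencies, dtype=float)
    missing = set(ct_table["gene"]) - set(eff.index)
    if missing:
        raise ValueError(f"no efficiency for genes: {sorted(missing)}")
    rows = []
    for (gene, sample), grp in ct_table.groupby(["gene", "sample"], sort=False):
        e = float(eff[gene])
        r0s = np.array([compute_r0(ct, e, r_ct) for ct in grp["ct"]])
        rows.append(
            {
                "gene": gene,
                "sample": sample,
                "ct_mean": float(grp["ct"].mean()),
                "efficiency": e,
                "r0": _geometric_mean(r0s),
                "outlier_excluded": 0,
            }
        )
    summary = pd.DataFrame(rows)
    rel = relative_quantities(summary.pivot(index="gene", columns="sample", values="r0"))
    rel_long = rel.stack().rename("relative_quantity").reset_index()
    summary = summary.merge(rel_long, on=["gene", "sample"], how="left")
    return summary.sort_values(["gene", "sample"]).reset_index(drop=True)
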