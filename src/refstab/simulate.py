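"""Synthetic qPCR experiments with known ground truth.

Emulates a 96-well SYBR-green RT-qPCR study of candidate reference
genes and target genes across conditions, at the scale of a typical
plant reference-gene validation: 10 conditions (4 tissues + 6 abiotic
stress treatments) x 3 biological replicates = 30 samples, 3 technical
replicates per well group, 11 candidate reference genes and 7 targets.

Generative model
----------------
Per gene: a baseline Ct (transcript abundance), a primer efficiency E,
a biological log2-expression SD, and optional additive per-condition
log2 shifts (what makes a gene "unstable" in a condition-dependent way).

* biological variation: one N(0, bio_sd) log2 deviation per
  (gene, sample), i.e. per biological replicate;
* technical variation: N(0, tech_sd) Ct noise per well;
* trace shape: exponential growth ``G(c) = R0 * (1+E)**c`` saturating
  smoothly at the plateau, ``F(c) = baseline + plateau * (1 - exp(-G/plateau))``,
  over cycles 1..40.

True starting quantities obey ``R0 = r_ct * (1+E)**(-Ct)`` exactly, so
the quantification pipeline's output can be compared to truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .quantify import FluorescenceTrace

__all__ = [
    "GeneSim",
    "SimConfig",
    "SimTruth",
    "SimResult",
    "default_config_paper",
    "simulate_experiment",
    "simulate_relative_quantities",
    "paper_subsets",
    "default_design",
]

EFFICIENCY_RANGE = (0.96, 1.10)

TISSUE_CONDITIONS = ("leaf", "stem", "rachis", "root")
STRESS_CONDITIONS = ("drought", "salt", "cold", "heat", "wounding", "flooding")


@dataclass(frozen=True)
class GeneSim:
    """Generative parameters for one gene.

    ``bio_sd`` is the biological log2-expression SD; ``condition_shifts``
    maps condition name -> additive log2 effect (unlisted conditions
    shift by 0).
    """

    name: str
    baseline_ct: float
    bio_sd: float
    efficiency: float
    condition_shifts: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.bio_sd < 0:
            raise ValueError(f"{self.name}: bio_sd must be >= 0")
        if not 0 < self.efficiency <= 1.5:
            raise ValueError(f"{self.name}: efficiency outside (0, 1.5]")
        if self.baseline_ct <= 0:
            raise ValueError(f"{self.name}: baseline_ct must be positive")

    def shift(self, condition: str) -> float:
        return dict(self.condition_shifts).get(condition, 0.0)


@dataclass(frozen=True)
class SimConfig:
    """Full description of a simulated experiment."""

    ref_genes: tuple[GeneSim, ...]
    target_genes: tuple[GeneSim, ...] = ()
    conditions: tuple[str, ...] = TISSUE_CONDITIONS + STRESS_CONDITIONS
    bio_reps: int = 3
    tech_reps: int = 3
    tech_sd: float = 0.15
    plateau: float = 3.0
    baseline_fluor: float = 0.05
    threshold_fraction: float = 0.10
    n_cycles: int = 40
    seed: int = 0
    efficiency_range: tuple[float, float] = EFFICIENCY_RANGE

    def __post_init__(self) -> None:
        if self.bio_reps < 1 or self.tech_reps < 1:
            raise ValueError("bio_reps and tech_reps must be >= 1")
        if self.tech_sd < 0:
            raise ValueError("tech_sd must be >= 0")
        if self.plateau <= 0:
            raise ValueError("plateau must be positive")
        lo, hi = self.efficiency_range
        for g in self.ref_genes + self.target_genes:
            if not lo <= g.efficiency <= hi:
                raise ValueError(
                    f"{g.name}: efficiency {g.efficiency} outside declared "
                    f"range [{lo}, {hi}]"
                )
        names = [g.name for g in self.ref_genes + self.target_genes]
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")

    @property
    def r_ct(self) -> float:
        """Threshold fluorescence implied by the plateau and fraction."""
        return self.threshold_fraction * self.plateau

    @property
    def samples(self) -> list[str]:
        return [
            f"{cond}_r{b}"
            for cond in self.conditions
            for b in range(1, self.bio_reps + 1)
        ]

    @property
    def all_genes(self) -> tuple[GeneSim, ...]:
        return self.ref_genes + self.target_genes

    def condition_of(self, sample: str) -> str:
        return sample.rsplit("_r", 1)[0]

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)

    def to_dict(self) -> dict:
        def gene_dict(g: GeneSim) -> dict:
            return {
                "name": g.name,
                "baseline_ct": g.baseline_ct,
                "bio_sd": g.bio_sd,
                "efficiency": g.efficiency,
                "condition_shifts": dict(g.condition_shifts),
            }

        return {
            "conditions": list(self.conditions),
            "bio_reps": self.bio_reps,
            "tech_reps": self.tech_reps,
            "tech_sd": self.tech_sd,
            "plateau": self.plateau,
            "baseline_fluor": self.baseline_fluor,
            "threshold_fraction": self.threshold_fraction,
            "n_cycles": self.n_cycles,
            "seed": self.seed,
            "efficiency_range": list(self.efficiency_range),
            "ref_genes": [gene_dict(g) for g in self.ref_genes],
            "target_genes": [gene_dict(g) for g in self.target_genes],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        def gene(d: dict) -> GeneSim:
            return GeneSim(
                name=d["name"],
                baseline_ct=d["baseline_ct"],
                bio_sd=d["bio_sd"],
                efficiency=d["efficiency"],
                condition_shifts=tuple(d.get("condition_shifts", {}).items()),
            )

        return cls(
            ref_genes=tuple(gene(g) for g in data["ref_genes"]),
            target_genes=tuple(gene(g) for g in data.get("target_genes", [])),
            conditions=tuple(data["conditions"]),
            bio_reps=data["bio_reps"],
            tech_reps=data["tech_reps"],
            tech_sd=data["tech_sd"],
            plateau=data["plateau"],
            baseline_fluor=data["baseline_fluor"],
            threshold_fraction=data["threshold_fraction"],
            n_cycles=data["n_cycles"],
            seed=data["seed"],
            efficiency_range=tuple(data["efficiency_range"]),
        )

    def save(self, path) -> None:
        """Write the config (seed included) as structured JSON."""
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "SimConfig":
        import json

        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SimTruth:
    """Ground truth matched to a simulated experiment.

    ``r0`` holds the per-(gene, sample) true starting fluorescence
    before technical noise; ``log2_expression`` the underlying log2
    quantities; ``stability_order`` lists the reference genes most
    stable first by total configured dispersion (biological SD plus
    across-design spread of the condition shifts).
    """

    r0: pd.DataFrame
    log2_expression: pd.DataFrame
    efficiencies: pd.Series
    stability_order: list[str]


@dataclass
class SimResult:
    config: SimConfig
    truth: SimTruth
    well_table: pd.DataFrame  # well_id, gene, sample, ct, r0_well
    traces: list[FluorescenceTrace] = field(default_factory=list)

    @property
    def ct_table(self) -> pd.DataFrame:
        return self.well_table[["gene", "sample", "ct"]].copy()


# per-gene biological log2 SDs mirroring the printed per-gene Ct ranges
# (0.88 .. 5.10 cycles across 30 samples; range of 30 normal draws is
# about 4.1 sigma, giving SDs of roughly 0.25 .. 1.2 log2 units)
_PAPER_REFERENCE_PANEL: tuple[tuple[str, float, float, float], ...] = (
    # name, baseline Ct, bio SD (log2), primer efficiency
    ("U2AF", 24.2, 0.25, 0.968),
    ("CYP5", 23.9, 0.30, 1.039),
    ("UBQ6", 21.0, 0.35, 1.020),
    ("FTSH4", 22.8, 0.40, 1.046),
    ("GAPDH", 22.5, 0.45, 0.993),
    ("eEF-1a", 22.0, 0.50, 1.028),
    ("ACT12", 23.2, 0.55, 0.990),
    ("eIF-4a", 27.0, 0.60, 0.967),
    ("TUA6", 24.6, 0.70, 1.047),
    ("SAMDC", 21.3, 0.90, 1.079),
    ("TUB6", 23.5, 1.20, 1.017),
)

# seven cellulose-synthase-like targets with condition-biased expression
_PAPER_TARGET_PANEL: tuple[tuple[str, float, float, float, tuple[tuple[str, float], ...]], ...] = (
    ("CesA1", 28.5, 0.30, 1.00, (("stem", 2.5), ("root", 1.0), ("leaf", -0.5))),
    ("CesA2", 29.0, 0.30, 1.02, (("root", 2.0), ("stem", 0.8))),
    ("CesA3", 28.8, 0.30, 0.99, (("stem", 1.2), ("rachis", -0.8))),
    ("CesA4", 29.2, 0.30, 1.01, (("root", 1.0), ("cold", 0.8))),
    ("CesA5", 28.6, 0.30, 1.03, (("flooding", 2.5), ("wounding", 2.0), ("rachis", -1.0))),
    ("CesA6", 29.4, 0.30, 0.98, (("flooding", 1.5), ("wounding", 1.2))),
    ("CesA7", 28.2, 0.30, 1.04, (("stem", 2.8), ("root", 2.2), ("flooding", 2.0), ("wounding", 1.8))),
)


def default_config_paper() -> SimConfig:
    """Default experiment: the switchgrass validation design.

    Eleven candidate reference genes with baseline Cts spanning 21-27
    (UBQ6 and SAMDC near 21, eIF-4a at 27), biological SDs spanning
    0.25-1.2 log2 units, primer efficiencies from the published primer
    table (0.967-1.079), and seven CesA-family target genes with
    tissue- and stress-biased expression.  30 samples = 10 conditions x
    3 biological replicates; 3 technical replicates per well group.
    """
    refs = tuple(
        GeneSim(name=n, baseline_ct=ct, bio_sd=sd, efficiency=e)
        for n, ct, sd, e in _PAPER_REFERENCE_PANEL
    )
    targets = tuple(
        GeneSim(name=n, baseline_ct=ct, bio_sd=sd, efficiency=e, condition_shifts=shifts)
        for n, ct, sd, e, shifts in _PAPER_TARGET_PANEL
    )
    return SimConfig(ref_genes=refs, target_genes=targets)


def _total_dispersion(gene: GeneSim, config: SimConfig) -> float:
    """SD of a gene's log2 expression across the whole design."""
    shifts = np.array([gene.shift(c) for c in config.conditions], dtype=float)
    shifts = np.repeat(shifts, config.bio_reps)
    return math.sqrt(gene.bio_sd**2 + float(shifts.var()))


def _draw_log2_expression(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """True log2 quantities per (gene, sample): shift + biological noise.

    Expressed relative to each gene's baseline (0 = baseline abundance).
    """
    samples = config.samples
    rows = {}
    for gene in config.all_genes:
        dev = rng.normal(0.0, gene.bio_sd, size=len(samples))
        shifts = np.array([gene.shift(config.condition_of(s)) for s in samples])
        rows[gene.name] = shifts + dev
    return pd.DataFrame(rows, index=samples).T


def _build_trace(
    well_id: str,
    gene: str,
    sample: str,
    r0: float,
    efficiency: float,
    config: SimConfig,
) -> FluorescenceTrace:
    cycles = np.arange(1, config.n_cycles + 1, dtype=float)
    growth = r0 * (1.0 + efficiency) ** cycles
    fluo = config.baseline_fluor + config.plateau * (1.0 - np.exp(-growth / config.plateau))
    return FluorescenceTrace(
        well_id=well_id, gene=gene, sample=sample, cycles=cycles, fluorescence=fluo
    )


def simulate_experiment(
    config: SimConfig | None = None,
    seed: int | None = None,
    traces: bool = True,
) -> SimResult:
    """Simulate a full experiment; returns wells, traces and truth.

    ``seed`` overrides ``config.seed``.  With ``traces=False`` only the
    Ct/well table is produced (the pre-computed-Ct input path).
    """
    config = config or default_config_paper()
    if seed is not None:
        config = config.with_seed(seed)
    rng = np.random.default_rng(config.seed)

    log2_expr = _draw_log2_expression(config, rng)
    samples = config.samples
    eff = pd.Series({g.name: g.efficiency for g in config.all_genes}, name="efficiency")

    # true per-sample Ct and R0: a log2 deviation x moves Ct by
    # -x / log2(1+E) cycles, so that R0 = r_ct * (1+E)^(-Ct) carries 2^x
    true_ct = pd.DataFrame(index=log2_expr.index, columns=samples, dtype=float)
    for gene in config.all_genes:
        per_cycle = math.log2(1.0 + gene.efficiency)
        true_ct.loc[gene.name] = gene.baseline_ct - log2_expr.loc[gene.name] / per_cycle
    true_r0 = pd.DataFrame(
        {
            s: config.r_ct
            * (1.0 + eff) ** (-true_ct[s])
            for s in samples
        }
    )

    ref_order = sorted(
        config.ref_genes, key=lambda g: (_total_dispersion(g, config), g.name)
    )
    truth = SimTruth(
        r0=true_r0,
        log2_expression=log2_expr,
        efficiencies=eff,
        stability_order=[g.name for g in ref_order],
    )

    rows = []
    trace_list: list[FluorescenceTrace] = []
    for gene in config.all_genes:
        for s in samples:
            base_ct = float(true_ct.loc[gene.name, s])
            for t in range(1, config.tech_reps + 1):
                ct_well = base_ct + rng.normal(0.0, config.tech_sd)
                r0_well = config.r_ct * (1.0 + gene.efficiency) ** (-ct_well)
                well_id = f"{gene.name}|{s}|t{t}"
                rows.append(
                    {
                        "well_id": well_id,
                        "gene": gene.name,
                        "sample": s,
                        "ct": ct_well,
                        "r0_well": r0_well,
                    }
                )
                if traces:
                    trace_list.append(
                        _build_trace(well_id, gene.name, s, r0_well, gene.efficiency, config)
                    )
    well_table = pd.DataFrame(rows)
    return SimResult(config=config, truth=truth, well_table=well_table, traces=trace_list)


def simulate_relative_quantities(
    config: SimConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, SimTruth]:
    """Reference-gene relative quantities straight from the noise model.

    Skips the trace/Ct machinery: draws the log2 expression matrix
    (condition shifts + biological deviations, no technical noise) and
    scales each gene to its highest-expressing sample.  This is the
    statistical envelope the stability methods see.
    """
    config = config or default_config_paper()
    if seed is not None:
        config = config.with_seed(seed)
    rng = np.random.default_rng(config.seed)
    log2_expr = _draw_log2_expression(config, rng)
    ref_names = [g.name for g in config.ref_genes]
    rel = np.exp2(log2_expr.loc[ref_names])
    rel = rel.div(rel.max(axis=1), axis=0)
    eff = pd.Series({g.name: g.efficiency for g in config.ref_genes}, name="efficiency")
    ref_order = sorted(
        config.ref_genes, key=lambda g: (_total_dispersion(g, config), g.name)
    )
    truth = SimTruth(
        r0=np.exp2(log2_expr.loc[ref_names]) * config.r_ct,
        log2_expression=log2_expr.loc[ref_names],
        efficiencies=eff,
        stability_order=[g.name for g in ref_order],
    )
    return rel, truth


def paper_subsets(config: SimConfig | None = None) -> dict[str, list[str]]:
    """The four analysis subsets: all, abiotic, tissue, leaf_stem."""
    config = config or default_config_paper()
    samples = config.samples
    by_cond = lambda conds: [s for s in samples if config.condition_of(s) in conds]
    return {
        "all": list(samples),
        "abiotic": by_cond(STRESS_CONDITIONS),
        "tissue": by_cond(TISSUE_CONDITIONS),
        "leaf_stem": by_cond(("leaf", "stem")),
    }


def default_design(config: SimConfig | None = None) -> "GroupDesign":
    """Two-group design: tissue samples vs abiotic-stress samples."""
    from .normfinder import GroupDesign

    config = config or default_config_paper()
    return GroupDesign(
        {
            s: ("tissue" if config.condition_of(s) in TISSUE_CONDITIONS else "abiotic")
            for s in config.samples
        }
    )
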