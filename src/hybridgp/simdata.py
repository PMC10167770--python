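"""Synthetic parental panels, mating designs, QTL effects and phenotypes.

The generator emulates a testcross hybrid-breeding study: a structured
panel of fully homozygous inbred parents (a few cytoplasmic-male-sterile
female testers plus a larger set of restorer pollinators), three
overlapping tester groups of crosses sharing a common pollinator core, and
multi-environment replicated phenotypes following

    y_ijk = mu + g_i + e_j + (ge)_ij + r_k(j) + eps_ijk

with hybrid genetic values g_i built from additive and dominance effects at
a random subset of QTL markers.  Effect vectors are rescaled so the
realized additive and dominance variances among the simulated hybrids hit
their targets exactly in-sample, which makes heritability targets testable
at small panel sizes.

All randomness flows from ``SimConfig.seed`` through named per-stage
streams, so a configuration reproduces bit-identical data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .hybrids import MatingDesign, make_hybrid_design
from .markers import GenotypeMatrix

TRAIT_NAME = "simtrait"


@dataclass
class SimConfig:
    """Study-design and genetic-architecture parameters for the generator.

    Desk-scale defaults keep every downstream stage fast while preserving
    the structural features the analysis relies on: multiple testers with
    overlapping pollinator groups, chromosome-blocked markers, and a
    multi-environment replicated trial.
    """

    n_pollinators: int = 60
    n_testers: int = 3
    group_sizes: tuple[int, ...] = (25, 20, 22)
    n_shared_pollinators: int = 10
    n_markers: int = 2000
    n_chromosomes: int = 10
    n_qtl: int = 200
    var_additive: float = 1.0
    var_dominance: float = 0.3
    var_gxe: float = 0.5
    var_residual: float = 1.0
    n_environments: int = 4
    n_replicates: int = 3
    n_subpopulations: int = 3
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    env_effect_sd: float = 1.0
    rep_effect_sd: float = 0.5
    mu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_pollinators": self.n_pollinators,
            "n_testers": self.n_testers,
            "n_markers": self.n_markers,
            "n_chromosomes": self.n_chromosomes,
            "n_environments": self.n_environments,
            "n_replicates": self.n_replicates,
            "n_subpopulations": self.n_subpopulations,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be positive, got {v}")
        self.group_sizes = tuple(int(g) for g in self.group_sizes)
        if len(self.group_sizes) != self.n_testers:
            raise ValueError("need one group size per tester")
        if any(g < 1 for g in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if any(g > self.n_pollinators for g in self.group_sizes):
            raise ValueError("group size exceeds the pollinator count")
        if not 0 <= self.n_shared_pollinators <= min(self.group_sizes):
            raise ValueError(
                "shared pollinator count must be <= every group size"
            )
        if not 0 <= self.n_qtl <= self.n_markers:
            raise ValueError("n_qtl must be in [0, n_markers]")
        for name in ("var_additive", "var_dominance", "var_gxe", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.allele_freq_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("allele_freq_range must satisfy 0 < lo <= hi <= 1")

    @classmethod
    def reference_design(cls, **overrides) -> "SimConfig":
        """The study-shaped configuration: 3 female testers crossed to 99
        pollinators in overlapping groups of 77/59/68 hybrids (204 total)
        with a 44-pollinator core common to all groups, four environments
        and three replicates."""
        params = dict(
            n_pollinators=99,
            n_testers=3,
            group_sizes=(77, 59, 68),
            n_shared_pollinators=44,
        )
        params.update(overrides)
        return cls(**params)

    @property
    def n_lines(self) -> int:
        return self.n_testers + self.n_pollinators

    @property
    def n_hybrids(self) -> int:
        return sum(self.group_sizes)

    def rng(self, stage: str) -> np.random.Generator:
        """Named per-stage random stream derived from the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STAGES[stage],))
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_sizes"] = list(self.group_sizes)
        d["allele_freq_range"] = list(self.allele_freq_range)
        return d


_STAGES = {"parents": 0, "design": 1, "effects": 2, "phenotypes": 3}


@dataclass
class TrueGeneticValues:
    """Ground-truth genetic values and marker effects behind a simulation."""

    hybrids: list[str]
    additive_value: np.ndarray
    dominance_value: np.ndarray
    marker_effects: pd.DataFrame  # indexed by marker: columns a, d
    qtl: list[str]

    @property
    def total(self) -> np.ndarray:
        return self.additive_value + self.dominance_value

    def value_series(self) -> pd.Series:
        return pd.Series(self.total, index=self.hybrids, name="genetic_value")


def tester_ids(config: SimConfig) -> list[str]:
    return [f"T{i + 1}" for i in range(config.n_testers)]


def pollinator_ids(config: SimConfig) -> list[str]:
    width = len(str(config.n_pollinators))
    return [f"P{i + 1:0{width}d}" for i in range(config.n_pollinators)]


def subpopulation_labels(config: SimConfig) -> np.ndarray:
    """Subpopulation index per line (testers first, round-robin order)."""
    return np.arange(config.n_lines) % config.n_subpopulations


def simulate_parents(config: SimConfig) -> GenotypeMatrix:
    """Draw fully homozygous parental lines with subpopulation structure.

    Lines (testers first, then pollinators) are assigned to subpopulations
    in round-robin order; each subpopulation draws its own allele frequency
    per marker uniformly from ``allele_freq_range``, and each line is +1 at
    a marker with that frequency, else -1.  Markers are split contiguously
    and as evenly as possible across chromosomes.
    """
    if config.n_subpopulations > config.n_lines:
        raise ValueError("more subpopulations than parental lines")
    rng = config.rng("parents")
    lines = tester_ids(config) + pollinator_ids(config)
    n, m = config.n_lines, config.n_markers
    lo, hi = config.allele_freq_range
    freqs = rng.uniform(lo, hi, size=(config.n_subpopulations, m))
    subpop = subpopulation_labels(config)
    draws = rng.random((n, m))
    codes = np.where(draws < freqs[subpop], 1.0, -1.0)

    counts = np.full(config.n_chromosomes, m // config.n_chromosomes)
    counts[: m % config.n_chromosomes] += 1
    chrom = np.repeat([str(c + 1) for c in range(config.n_chromosomes)], counts)
    pos = np.concatenate([np.arange(c) * 1000 + 1000 for c in counts])
    markers = [f"S{c}_{p}" for c, p in zip(chrom, pos)]
    marker_map = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": "A", "alt": "T"},
        index=pd.Index(markers, name="marker"),
    )
    return GenotypeMatrix(lines=lines, markers=markers, codes=codes,
                          marker_map=marker_map)


def make_mating_design(config: SimConfig) -> MatingDesign:
    """Assign pollinators to tester groups.

    A seeded shuffle picks the shared pollinator core present in every
    group; the remaining group slots are filled round-robin from the other
    pollinators, giving each of them one cross before any receives a
    second (in a different group), so the whole panel is used whenever the
    slot count allows.
    """
    rng = config.rng("design")
    testers = tester_ids(config)
    pollinators = pollinator_ids(config)
    order = [pollinators[i] for i in rng.permutation(config.n_pollinators)]
    shared = order[: config.n_shared_pollinators]
    others = order[config.n_shared_pollinators:]

    members: list[list[str]] = [list(shared) for _ in testers]
    open_slots = [g - config.n_shared_pollinators for g in config.group_sizes]
    if sum(open_slots) > 0 and not others:
        raise ValueError("not enough non-shared pollinators to fill the groups")
    gi = 0
    while sum(open_slots) > 0:
        progressed = False
        for male in others:
            if sum(open_slots) == 0:
                break
            for _ in range(len(testers)):
                g = gi % len(testers)
                gi += 1
                if open_slots[g] > 0 and male not in members[g]:
                    members[g].append(male)
                    open_slots[g] -= 1
                    progressed = True
                    break
        if not progressed:
            raise ValueError(
                "cannot fill tester groups: every remaining pollinator is "
                "already in every group with open slots"
            )
    records = []
    for tester, group in zip(testers, members):
        for male in group:
            records.append(
                {
                    "hybrid": f"{tester}x{male}",
                    "female": tester,
                    "male": male,
                    "group": tester,
                }
            )
    return MatingDesign(pd.DataFrame.from_records(records))


def simulate_effects(
    config: SimConfig,
    genotypes: GenotypeMatrix,
    design: MatingDesign,
) -> TrueGeneticValues:
    """Sample QTL positions and additive/dominance effects.

    ``n_qtl`` markers are chosen without replacement; raw effects are
    mean-zero Gaussian and then rescaled so the variance of K_A a (and of
    K_D d) across the designed hybrids equals ``var_additive``
    (``var_dominance``) exactly in-sample.
    """
    rng = config.rng("effects")
    m = genotypes.n_markers
    if config.n_qtl > m:
        raise ValueError("n_qtl exceeds the marker count")
    qtl_idx = np.sort(rng.choice(m, size=config.n_qtl, replace=False))
    hd = make_hybrid_design(genotypes, design)
    ka = hd.k_a[:, qtl_idx]
    kd = hd.k_d[:, qtl_idx]

    a = np.zeros(m)
    d = np.zeros(m)
    a_raw = rng.standard_normal(config.n_qtl)
    d_raw = rng.standard_normal(config.n_qtl)
    if config.var_additive > 0:
        realized = float(np.var(ka @ a_raw, ddof=1))
        if realized == 0:
            raise ValueError(
                "additive genotypes have zero variance at every QTL; cannot "
                "scale effects to the target variance"
            )
        a[qtl_idx] = a_raw * np.sqrt(config.var_additive / realized)
    if config.var_dominance > 0:
        realized = float(np.var(kd @ d_raw, ddof=1))
        if realized == 0:
            raise ValueError(
                "dominance states have zero variance at every QTL; cannot "
                "scale effects to the target variance"
            )
        d[qtl_idx] = d_raw * np.sqrt(config.var_dominance / realized)

    add_val = hd.k_a @ a
    dom_val = hd.k_d @ d
    effects = pd.DataFrame(
        {"a": a, "d": d}, index=pd.Index(genotypes.markers, name="marker")
    )
    return TrueGeneticValues(
        hybrids=hd.hybrids,
        additive_value=add_val,
        dominance_value=dom_val,
        marker_effects=effects,
        qtl=[genotypes.markers[i] for i in qtl_idx],
    )


def simulate_phenotypes(
    design: MatingDesign,
    values: TrueGeneticValues,
    config: SimConfig,
) -> pd.DataFrame:
    """Long-format phenotypes for every hybrid x environment x replicate.

    Environment and replicate-within-environment effects are fixed shifts
    drawn once per simulation (scales ``env_effect_sd`` / ``rep_effect_sd``);
    genotype-by-environment deviations are independent mean-zero draws with
    variance ``var_gxe`` and residuals with variance ``var_residual``.
    """
    rng = config.rng("phenotypes")
    hybrids = design.hybrids
    missing = set(hybrids) - set(values.hybrids)
    if missing:
        raise ValueError(f"no genetic value for hybrid(s): {sorted(missing)[:5]}")
    g = values.value_series().reindex(hybrids).to_numpy()
    n_h, n_e, n_r = len(hybrids), config.n_environments, config.n_replicates

    env_shift = rng.normal(0.0, config.env_effect_sd, size=n_e) \
        if config.env_effect_sd > 0 else np.zeros(n_e)
    rep_shift = rng.normal(0.0, config.rep_effect_sd, size=(n_e, n_r)) \
        if config.rep_effect_sd > 0 else np.zeros((n_e, n_r))
    gxe = rng.normal(0.0, np.sqrt(config.var_gxe), size=(n_h, n_e)) \
        if config.var_gxe > 0 else np.zeros((n_h, n_e))
    resid = rng.normal(0.0, np.sqrt(config.var_residual), size=(n_h, n_e, n_r)) \
        if config.var_residual > 0 else np.zeros((n_h, n_e, n_r))

    y = (
        config.mu
        + g[:, None, None]
        + env_shift[None, :, None]
        + rep_shift[None, :, :]
        + gxe[:, :, None]
        + resid
    )
    idx = pd.MultiIndex.from_product(
        [hybrids, [f"E{j + 1}" for j in range(n_e)],
         [f"R{k + 1}" for k in range(n_r)]],
        names=["hybrid", "environment", "replicate"],
    )
    table = idx.to_frame(index=False)
    table["trait"] = TRAIT_NAME
    table["value"] = y.ravel()
    return table


@dataclass
class SimulatedStudy:
    """Bundle of everything one simulated study produces."""

    config: SimConfig
    genotypes: GenotypeMatrix
    design: MatingDesign
    values: TrueGeneticValues
    phenotypes: pd.DataFrame


def simulate_study(config: SimConfig | None = None) -> SimulatedStudy:
    """Run the full generator: parents, design, effects, phenotypes."""
    config = config or SimConfig()
    genotypes = simulate_parents(config)
    design = make_mating_design(config)
    values = simulate_effects(config, genotypes, design)
    phenotypes = simulate_phenotypes(design, values, config)
    return SimulatedStudy(config, genotypes, design, values, phenotypes)
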