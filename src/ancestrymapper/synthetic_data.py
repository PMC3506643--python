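"""Synthetic genotype data with two-level population structure.

The generator follows a hierarchical Balding–Nichols model: each SNP's
ancestral allele frequency p is drawn uniformly on (0.05, 0.95); each
continent drifts from the ancestral pool by drawing its frequency from
Beta(p(1-Fc)/Fc, (1-p)(1-Fc)/Fc), whose mean is p and variance
Fc·p·(1-p); each population drifts from its continent the same way with
Fp.  The F parameters are Wright's fixation index for each level of the
hierarchy — the expected pairwise FST between two sibling populations
equals their shared drift parameter.  Genotypes are Binomial(2, freq)
allele counts, additive-coded into {2, 3, 4} (count of allele "2" plus
2), with optional uniform missingness.

Admixed individuals draw each SNP's source population according to their
mixing proportions, emulating cohorts of recent two-way admixture; a
gradient group varies the proportions linearly across its individuals.
A serial-founder variant chains populations along a line, each drifting
from its predecessor, to emulate decay of similarity with distance.

The model produces independent SNPs — no linkage disequilibrium,
recombination or array ascertainment — so it emulates continental-level
allele-frequency structure, not fine-scale haplotype structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SimulationConfigError
from .genotype_io import GenotypeMatrix

_FREQ_CLAMP = (0.01, 0.99)  # avoid fixed SNPs with zero distance variance


@dataclass
class AdmixedGroup:
    """A cohort of admixed individuals drawing from several source
    populations.

    ``gradient=True`` interpolates the first source's proportion linearly
    from 1 to 0 across the group's individuals (two sources only),
    producing an admixture gradient rather than a fixed mixture.
    """

    name: str
    sources: list[str]
    proportions: list[float]
    n: int
    gradient: bool = False


@dataclass
class SimulationConfig:
    """Parameters of the two-level population-structure simulator."""

    n_continents: int = 3
    pops_per_continent: int = 2
    inds_per_pop: int = 30
    n_snps: int = 20_000
    F_continent: float = 0.10
    F_population: float = 0.05
    F_overrides: dict[str, float] = field(default_factory=dict)
    F_continent_overrides: dict[str, float] = field(default_factory=dict)
    admixed_groups: list[AdmixedGroup] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, F in (("F_continent", self.F_continent),
                        ("F_population", self.F_population),
                        *self.F_overrides.items(),
                        *self.F_continent_overrides.items()):
            if not 0.0 <= F < 1.0:
                raise SimulationConfigError(f"{name}={F} outside [0, 1)")
        if self.n_snps < 1:
            raise SimulationConfigError("n_snps must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimulationConfigError("missing_rate must be in [0, 1)")
        for grp in self.admixed_groups:
            if len(grp.sources) != len(grp.proportions):
                raise SimulationConfigError(
                    f"group {grp.name!r}: sources and proportions differ in length"
                )
            if abs(sum(grp.proportions) - 1.0) > 1e-9:
                raise SimulationConfigError(
                    f"group {grp.name!r}: proportions sum to {sum(grp.proportions)}"
                )
            if grp.gradient and len(grp.sources) != 2:
                raise SimulationConfigError(
                    f"group {grp.name!r}: gradient groups need exactly two sources"
                )

    def population_names(self) -> list[str]:
        return [f"C{c + 1}P{p + 1}"
                for c in range(self.n_continents)
                for p in range(self.pops_per_continent)]


@dataclass
class SimulatedDataset:
    """A simulated genotype matrix with full ground truth attached."""

    genotypes: GenotypeMatrix
    metadata: pd.DataFrame
    pop_freqs: dict[str, np.ndarray]
    admixture: dict[str, dict[str, float]]  # sample -> source -> proportion


def _bn_draw(rng: np.random.Generator, parent: np.ndarray, F: float) -> np.ndarray:
    """Balding–Nichols frequency draw around a parent frequency vector."""
    if F <= 0.0:
        return parent.copy()
    ratio = (1.0 - F) / F
    freq = rng.beta(parent * ratio, (1.0 - parent) * ratio)
    return np.clip(freq, *_FREQ_CLAMP)


def _genotypes_from_freqs(rng: np.random.Generator, freqs: np.ndarray) -> np.ndarray:
    """Additive codes in {2,3,4}: allele-2 count plus 2."""
    return rng.binomial(2, freqs).astype(float) + 2.0


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate a dataset under the two-level Balding–Nichols model."""
    rng = np.random.default_rng(config.seed)
    ancestral = rng.uniform(0.05, 0.95, size=config.n_snps)

    pop_freqs: dict[str, np.ndarray] = {}
    pop_continent: dict[str, str] = {}
    for c in range(config.n_continents):
        cont = f"C{c + 1}"
        Fc = config.F_continent_overrides.get(cont, config.F_continent)
        cont_freq = _bn_draw(rng, ancestral, Fc)
        for p in range(config.pops_per_continent):
            pop = f"{cont}P{p + 1}"
            Fp = config.F_overrides.get(pop, config.F_population)
            pop_freqs[pop] = _bn_draw(rng, cont_freq, Fp)
            pop_continent[pop] = cont

    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    admixture: dict[str, dict[str, float]] = {}
    for pop in config.population_names():
        geno = _genotypes_from_freqs(
            rng, np.broadcast_to(pop_freqs[pop], (config.inds_per_pop, config.n_snps))
        )
        for i in range(config.inds_per_pop):
            sid = f"{pop}_{i + 1:03d}"
            sample_ids.append(sid)
            rows.append(geno[i])
            meta_rows.append({"sample_id": sid, "population": pop,
                              "region": pop_continent[pop], "dataset": "sim"})
            admixture[sid] = {pop: 1.0}

    for grp in config.admixed_groups:
        missing_src = [s for s in grp.sources if s not in pop_freqs]
        if missing_src:
            raise SimulationConfigError(
                f"group {grp.name!r}: unknown source populations {missing_src}"
            )
        src_freqs = np.vstack([pop_freqs[s] for s in grp.sources])
        for i in range(grp.n):
            if grp.gradient:
                alpha = 1.0 - i / max(grp.n - 1, 1)
                props = np.array([alpha, 1.0 - alpha])
            else:
                props = np.asarray(grp.proportions, dtype=float)
            source_idx = rng.choice(len(grp.sources), size=config.n_snps, p=props)
            freqs = src_freqs[source_idx, np.arange(config.n_snps)]
            sid = f"{grp.name}_{i + 1:03d}"
            sample_ids.append(sid)
            rows.append(_genotypes_from_freqs(rng, freqs))
            meta_rows.append({"sample_id": sid, "population": grp.name,
                              "region": "ADMIXED", "dataset": "sim"})
            admixture[sid] = dict(zip(grp.sources, props.tolist()))

    values = np.vstack(rows)
    if config.missing_rate > 0.0:
        values[rng.random(values.shape) < config.missing_rate] = np.nan

    snp_ids = [f"snp{j + 1}" for j in range(config.n_snps)]
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    gm = GenotypeMatrix(sample_ids, snp_ids, values, metadata)
    return SimulatedDataset(gm, metadata, pop_freqs, admixture)


def simulate_serial_founder(
    n_pops: int = 6,
    inds_per_pop: int = 20,
    n_snps: int = 10_000,
    F_step: float = 0.02,
    spacing_km: float = 1000.0,
    seed: int = 0,
) -> SimulatedDataset:
    """Stepping-stone chain of populations with stepwise founder drift.

    Population i+1 drifts from population i by ``F_step``; populations
    sit on the equator at ``spacing_km`` intervals, so genetic and
    geographic distance to the chain's origin both grow along the chain.
    """
    rng = np.random.default_rng(seed)
    ancestral = rng.uniform(0.05, 0.95, size=n_snps)
    pop_freqs: dict[str, np.ndarray] = {}
    freq = np.clip(ancestral, *_FREQ_CLAMP)
    for i in range(n_pops):
        pop = f"P{i + 1}"
        freq = _bn_draw(rng, freq, F_step) if i > 0 else freq.copy()
        pop_freqs[pop] = freq

    deg_per_km = 180.0 / (np.pi * 6371.0)
    sample_ids, rows, meta_rows = [], [], []
    admixture: dict[str, dict[str, float]] = {}
    for i, (pop, f) in enumerate(pop_freqs.items()):
        geno = _genotypes_from_freqs(rng, np.broadcast_to(f, (inds_per_pop, n_snps)))
        for j in range(inds_per_pop):
            sid = f"{pop}_{j + 1:03d}"
            sample_ids.append(sid)
            rows.append(geno[j])
            meta_rows.append({
                "sample_id": sid, "population": pop, "region": "CHAIN",
                "dataset": "sim", "latitude": 0.0,
                "longitude": i * spacing_km * deg_per_km,
            })
            admixture[sid] = {pop: 1.0}
    snp_ids = [f"snp{j + 1}" for j in range(n_snps)]
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    gm = GenotypeMatrix(sample_ids, snp_ids, np.vstack(rows), metadata)
    return SimulatedDataset(gm, metadata, pop_freqs, admixture)


def make_standard_fixtures(seed: int = 20_260) -> dict[str, SimulatedDataset]:
    """Named fixed-seed datasets used throughout the test battery.

    * ``continental`` — 3 continents x 2 populations x 30 individuals,
      20,000 SNPs, clean two-level separation (Fc=0.10, Fp=0.05) with
      0.2% missingness, emulating worldwide-panel structure.
    * ``isolate`` — same layout, but one population (C3P2) with doubled
      within-continent drift, emulating a genetic isolate.
    * ``admixed`` — 2 continents x 2 populations plus a 50/50 two-source
      group and a gradient group (sources on different continents),
      emulating recently admixed cohorts.
    * ``tiny`` — 2 populations x 3 individuals x 50 SNPs for exhaustive
      small-instance oracles.
    """
    continental = SimulationConfig(
        n_continents=3, pops_per_continent=2, inds_per_pop=30, n_snps=20_000,
        F_continent=0.10, F_population=0.05, missing_rate=0.002, seed=seed,
    )
    isolate = SimulationConfig(
        n_continents=3, pops_per_continent=2, inds_per_pop=30, n_snps=20_000,
        F_continent=0.10, F_population=0.05, F_overrides={"C3P2": 0.10},
        missing_rate=0.002, seed=seed + 1,
    )
    admixed = SimulationConfig(
        n_continents=2, pops_per_continent=2, inds_per_pop=25, n_snps=15_000,
        F_continent=0.10, F_population=0.05,
        admixed_groups=[
            AdmixedGroup("ADM5050", ["C1P1", "C2P1"], [0.5, 0.5], n=20),
            AdmixedGroup("GRAD", ["C1P1", "C2P1"], [0.5, 0.5], n=20, gradient=True),
        ],
        seed=seed + 2,
    )
    tiny = SimulationConfig(
        n_continents=1, pops_per_continent=2, inds_per_pop=3, n_snps=50,
        F_continent=0.0, F_population=0.20, seed=seed + 3,
    )
    return {
        "continental": simulate(continental),
        "isolate": simulate(isolate),
        "admixed": simulate(admixed),
        "tiny": simulate(tiny),
    }
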