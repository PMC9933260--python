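"""Forward simulator of methylation drift driven by stem-cell replication.

Generative model
----------------
Each CpG on each allele is a two-state Markov chain over divisions: an
unmethylated CpG becomes methylated with per-division probability
``epsilon_gain`` (a de novo maintenance error) and a methylated CpG loses its
mark with probability ``epsilon_loss``, independently per allele, per CpG and
per division.  A tissue's stem cells at age ``a`` months have undergone
``t = round(divisions_per_month[tissue] * a)`` divisions; differentiated
(nonstem) cells are stem cells plus a fixed number of extra differentiation
divisions.  The per-CpG mean methylation after t steps has the closed form

    m_t = m_inf + (m_0 - m_inf) * (1 - eg - el)^t,    m_inf = eg / (eg + el),

which the empirical populations must track (and tests verify).

The simulated genome carries 4-CpG epiallele loci (4 CpGs inside a 60 bp
window, loci 2 kb apart so tiling recovers them exactly) plus isolated
singleton CpGs spaced >= 1 kb apart for per-CpG drift statistics.  Baseline
methylation m_0 is a fixed per-CpG property of the genome, drawn once per
simulation from compartment-dependent ranges, so every sample of a study
shares it.  Read sampling emulates RRBS: per-locus read counts are Poisson,
alleles are drawn with replacement, and per-CpG counts equal the column sums
of the emitted reads.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, UsageError, ValidationError
from .io import (
    CpGCountMatrix,
    EpireadRecord,
    SampleSheet,
    write_bismark_cov,
    write_epireads,
    write_sample_sheet,
)

logger = logging.getLogger(__name__)

__all__ = [
    "COMPARTMENTS",
    "SimulationConfig",
    "GenomeLayout",
    "CellPopulation",
    "build_layout",
    "expected_methylation",
    "simulate_stem_population",
    "differentiate",
    "sample_reads",
    "simulate_study",
    "rng_for",
]

COMPARTMENTS = (
    "Promoter-CpGi",
    "nonPromoter-CpGi",
    "Promoter-nonCpGi",
    "nonPromoter-nonCpGi",
)

# Per-tissue stem-cell divisions per month.  Synthetic values: no quantitative
# division rates are available here, only the qualitative ordering (intestinal
# epithelium fastest; liver/lung/spleen/blood intermediate; heart, kidney and
# skeletal muscle nearly quiescent).
DEFAULT_DIVISIONS_PER_MONTH: dict[str, float] = {
    "colon": 10.0,
    "small_intestine": 8.0,
    "blood": 3.0,
    "spleen": 2.0,
    "lung": 1.0,
    "liver": 1.0,
    "kidney": 0.3,
    "muscle": 0.2,
    "heart": 0.1,
}

# Baseline methylation ranges per compartment: CpG islands start low
# (unmethylated promoters), non-island DNA high, with spread so sites differ.
DEFAULT_INITIAL_METHYLATION: dict[str, tuple[float, float]] = {
    "Promoter-CpGi": (0.0, 0.15),
    "nonPromoter-CpGi": (0.0, 0.30),
    "Promoter-nonCpGi": (0.20, 0.80),
    "nonPromoter-nonCpGi": (0.60, 1.00),
}


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-label random stream derived from one root seed.

    Streams are independent across labels, so adding samples to a study never
    perturbs existing ones.
    """
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode()) & 0x7FFFFFFF]
    )


@dataclass
class SimulationConfig:
    """All knobs of the replication-drift simulator.

    ``initial_methylation``, ``epsilon_gain`` and ``epsilon_loss`` accept a
    scalar (uniform across the genome) or a mapping compartment -> value;
    initial methylation values may also be ``(low, high)`` ranges drawn
    uniformly per CpG.
    """

    n_loci: int = 60
    n_singleton_cpgs: int = 0
    compartment_labels: dict[str, list[str]] | None = None  # keys: loci, singletons
    initial_methylation: float | Mapping[str, object] = field(
        default_factory=lambda: dict(DEFAULT_INITIAL_METHYLATION)
    )
    epsilon_gain: float | Mapping[str, float] = 0.001
    epsilon_loss: float | Mapping[str, float] = 0.001
    divisions_per_month: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIVISIONS_PER_MONTH)
    )
    differentiation_divisions: int = 4
    n_cells: int = 300
    coverage_mean: float = 60.0
    seed: int = 0
    chromosome: str = "chr1"

    def __post_init__(self) -> None:
        if self.n_loci < 0 or self.n_singleton_cpgs < 0:
            raise ConfigurationError("n_loci and n_singleton_cpgs must be non-negative")
        if self.n_loci + self.n_singleton_cpgs == 0:
            raise ConfigurationError("simulation needs at least one CpG")
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if self.coverage_mean < 1:
            raise ConfigurationError("coverage_mean must be >= 1")
        if self.differentiation_divisions < 0:
            raise ConfigurationError("differentiation_divisions must be >= 0")
        for v in self.divisions_per_month.values():
            if v < 0:
                raise ConfigurationError("divisions_per_month values must be >= 0")
        for name, val in (("epsilon_gain", self.epsilon_gain), ("epsilon_loss", self.epsilon_loss)):
            for x in (val.values() if isinstance(val, Mapping) else [val]):
                if not 0.0 <= float(x) <= 1.0:
                    raise ConfigurationError(f"{name} must lie in [0, 1]")
        # gain + loss <= 1 so the per-division flip probabilities are coherent
        def _max(v):
            return max(float(x) for x in (v.values() if isinstance(v, Mapping) else [v]))
        if _max(self.epsilon_gain) + _max(self.epsilon_loss) > 1.0:
            raise ConfigurationError("epsilon_gain + epsilon_loss must be <= 1")

    # -- YAML round trip -----------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        if isinstance(data["initial_methylation"], dict):
            data["initial_methylation"] = {
                k: (list(v) if isinstance(v, (tuple, list)) else v)
                for k, v in data["initial_methylation"].items()
            }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class GenomeLayout:
    """Fixed per-simulation genome: CpG coordinates, compartments, baselines."""

    chromosome: str
    locus_positions: np.ndarray  # (n_loci, 4) int
    singleton_positions: np.ndarray  # (n_singletons,) int
    compartments: np.ndarray  # (n_cpgs,) str; locus CpGs flattened, then singletons
    m0: np.ndarray  # (n_cpgs,) baseline methylation probability
    eps_gain: np.ndarray  # (n_cpgs,)
    eps_loss: np.ndarray  # (n_cpgs,)

    @property
    def n_cpgs(self) -> int:
        return self.locus_positions.size + self.singleton_positions.size

    @property
    def positions(self) -> np.ndarray:
        return np.concatenate([self.locus_positions.ravel(), self.singleton_positions])

    def locus_slice(self, i: int) -> slice:
        return slice(4 * i, 4 * i + 4)

    def singleton_index(self, j: int) -> int:
        return self.locus_positions.size + j


def _per_cpg(value, compartments: np.ndarray, name: str) -> np.ndarray:
    if isinstance(value, Mapping):
        missing = set(compartments) - set(value)
        if missing:
            raise ConfigurationError(f"{name} missing compartments {sorted(missing)}")
        return np.array([float(value[c]) for c in compartments])
    return np.full(len(compartments), float(value))


def build_layout(config: SimulationConfig) -> GenomeLayout:
    """Deterministic genome layout drawn from the config's root seed.

    Loci sit 2 kb apart, each with 4 CpGs inside a 60 bp window (so the
    non-overlapping tiling rule recovers them exactly); singleton CpGs start
    5 kb past the last locus and are 1.2 kb apart, too sparse to form loci.
    """
    rng = rng_for(config.seed, "layout")
    locus_positions = np.zeros((config.n_loci, 4), dtype=np.int64)
    for i in range(config.n_loci):
        start = 10_000 + 2_000 * i
        offsets = np.sort(rng.choice(np.arange(1, 61), size=3, replace=False))
        locus_positions[i] = [start, *(start + offsets)]
    base = 10_000 + 2_000 * config.n_loci + 5_000
    singleton_positions = base + 1_200 * np.arange(config.n_singleton_cpgs, dtype=np.int64)

    if config.compartment_labels is not None:
        locus_comp = list(config.compartment_labels.get("loci", []))
        single_comp = list(config.compartment_labels.get("singletons", []))
        if len(locus_comp) != config.n_loci or len(single_comp) != config.n_singleton_cpgs:
            raise ConfigurationError("compartment_labels lengths must match n_loci / n_singleton_cpgs")
        bad = (set(locus_comp) | set(single_comp)) - set(COMPARTMENTS)
        if bad:
            raise ConfigurationError(f"unknown compartments {sorted(bad)}")
    else:
        locus_comp = [COMPARTMENTS[i % 4] for i in range(config.n_loci)]
        single_comp = [COMPARTMENTS[j % 4] for j in range(config.n_singleton_cpgs)]
    compartments = np.array(
        [c for c in locus_comp for _ in range(4)] + single_comp, dtype=object
    )

    # baseline methylation per CpG: scalar, per-compartment value, or range
    if isinstance(config.initial_methylation, Mapping):
        m0 = np.empty(len(compartments))
        for k, comp in enumerate(compartments):
            spec = config.initial_methylation.get(comp)
            if spec is None:
                raise ConfigurationError(f"initial_methylation missing compartment {comp!r}")
            if isinstance(spec, (tuple, list)):
                lo, hi = float(spec[0]), float(spec[1])
                m0[k] = rng.uniform(lo, hi)
            else:
                m0[k] = float(spec)
    else:
        m0 = np.full(len(compartments), float(config.initial_methylation))
    if (m0 < 0).any() or (m0 > 1).any():
        raise ConfigurationError("initial methylation must lie in [0, 1]")

    return GenomeLayout(
        chromosome=config.chromosome,
        locus_positions=locus_positions,
        singleton_positions=singleton_positions,
        compartments=compartments,
        m0=m0,
        eps_gain=_per_cpg(config.epsilon_gain, compartments, "epsilon_gain"),
        eps_loss=_per_cpg(config.epsilon_loss, compartments, "epsilon_loss"),
    )


def expected_methylation(m0, eps_gain, eps_loss, t: int):
    """Closed-form mean methylation after t divisions of the two-state chain."""
    m0 = np.asarray(m0, dtype=float)
    eg = np.asarray(eps_gain, dtype=float)
    el = np.asarray(eps_loss, dtype=float)
    total = eg + el
    m_inf = np.where(total > 0, np.divide(eg, np.where(total > 0, total, 1.0)), m0)
    return m_inf + (m0 - m_inf) * (1.0 - total) ** t


@dataclass
class CellPopulation:
    """Binary methylation states of tracked alleles (allele x CpG)."""

    tissue: str
    age_months: float
    cell_type: str
    alleles: np.ndarray  # bool, shape (n_cells, n_cpgs)
    layout: GenomeLayout
    divisions: int

    def __post_init__(self) -> None:
        if self.alleles.dtype != bool:
            raise ValidationError("allele states must be boolean")
        if self.alleles.shape[1] != self.layout.n_cpgs:
            raise ValidationError("allele matrix does not match layout")

    def mean_methylation(self) -> np.ndarray:
        return self.alleles.mean(axis=0)


def _markov_steps(
    alleles: np.ndarray, layout: GenomeLayout, t: int, rng: np.random.Generator
) -> np.ndarray:
    """Apply t per-division gain/loss steps in place; returns the array."""
    if t == 0:
        return alleles
    flip_if_meth = layout.eps_loss[None, :]
    flip_if_unmeth = layout.eps_gain[None, :]
    for _ in range(t):
        p_flip = np.where(alleles, flip_if_meth, flip_if_unmeth)
        alleles ^= rng.random(alleles.shape) < p_flip
    return alleles


def simulate_stem_population(
    config: SimulationConfig,
    tissue: str,
    age_months: float,
    layout: GenomeLayout | None = None,
    rng: np.random.Generator | None = None,
) -> CellPopulation:
    """Simulate a stem-cell pool of one mouse at a given age.

    The allele matrix starts from Bernoulli(m_0) draws and undergoes
    ``round(divisions_per_month[tissue] * age_months)`` Markov divisions.
    """
    if tissue not in config.divisions_per_month:
        raise ConfigurationError(
            f"tissue {tissue!r} has no divisions_per_month entry"
        )
    if age_months <= 0:
        raise ValidationError("age_months must be positive")
    layout = layout if layout is not None else build_layout(config)
    if rng is None:
        rng = rng_for(config.seed, f"stem|{tissue}|{age_months}")
    t = int(round(config.divisions_per_month[tissue] * age_months))
    alleles = rng.random((config.n_cells, layout.n_cpgs)) < layout.m0[None, :]
    _markov_steps(alleles, layout, t, rng)
    return CellPopulation(tissue, float(age_months), "stem", alleles, layout, t)


def differentiate(
    population: CellPopulation,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> CellPopulation:
    """Differentiated progeny: extra divisions applied to a copy of the pool.

    The stem input is left untouched.  Only stem populations differentiate.
    """
    if population.cell_type != "stem":
        raise UsageError("differentiate() requires a stem population")
    if rng is None:
        rng = rng_for(config.seed, f"diff|{population.tissue}|{population.age_months}")
    alleles = population.alleles.copy()
    _markov_steps(alleles, population.layout, config.differentiation_divisions, rng)
    return CellPopulation(
        population.tissue,
        population.age_months,
        "nonstem",
        alleles,
        population.layout,
        population.divisions + config.differentiation_divisions,
    )


def sample_reads(
    population: CellPopulation,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    sample_id: str = "sample",
) -> tuple[list[EpireadRecord], CpGCountMatrix]:
    """Emulate RRBS read sampling from a cell population.

    Per locus, a Poisson(coverage_mean) number of alleles is drawn with
    replacement and emitted as complete 4-CpG epireads; per-CpG counts equal
    the column sums of those reads.  Singleton CpGs get Poisson-deep counts
    sampled the same way (no multi-CpG read to emit).
    """
    if rng is None:
        rng = rng_for(config.seed, f"reads|{sample_id}")
    layout = population.layout
    n_cells = population.alleles.shape[0]
    reads: list[EpireadRecord] = []
    rows: list[tuple[str, str, int, int, int]] = []

    for i in range(layout.locus_positions.shape[0]):
        positions = tuple(int(p) for p in layout.locus_positions[i])
        n_reads = int(rng.poisson(config.coverage_mean))
        if n_reads == 0:
            continue
        picked = rng.integers(0, n_cells, size=n_reads)
        states = population.alleles[picked][:, layout.locus_slice(i)]
        for k in range(n_reads):
            pattern = "".join("M" if s else "U" for s in states[k])
            reads.append(
                EpireadRecord(layout.chromosome, f"{sample_id}:L{i}:{k}", positions, pattern)
            )
        col_meth = states.sum(axis=0)
        for j, pos in enumerate(positions):
            rows.append((sample_id, layout.chromosome, pos, int(col_meth[j]), n_reads))

    for j in range(layout.singleton_positions.size):
        n_reads = int(rng.poisson(config.coverage_mean))
        if n_reads == 0:
            continue
        picked = rng.integers(0, n_cells, size=n_reads)
        meth = int(population.alleles[picked, layout.singleton_index(j)].sum())
        rows.append(
            (sample_id, layout.chromosome, int(layout.singleton_positions[j]), meth, n_reads)
        )

    long = pd.DataFrame(rows, columns=["sample_id", "chromosome", "position", "meth", "total"])
    return reads, CpGCountMatrix.from_long(long)


def simulate_study(
    config: SimulationConfig,
    design: SampleSheet,
    outdir: str | Path,
) -> dict[str, object]:
    """Write a full multi-sample study dataset to disk.

    For each (tissue, age) the same simulated mice provide both the stem and
    the nonstem ("whole" counts as nonstem bulk) samples — nonstem pools are
    differentiated copies of the stem pools, mirroring marker-sorted stem and
    progeny fractions of the same animals.  ``pool_size`` mice per sample are
    simulated independently and their read sets concatenated.

    Outputs per sample: ``<id>.epireads.tsv`` and ``<id>.cov``; plus the
    sample sheet, the ground-truth site table (position, compartment,
    baseline methylation, error rates) and per-sample division counts.
    Identical config + design + seed reproduce the files byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = build_layout(config)
    for tissue in design.df["tissue"].unique():
        if tissue not in config.divisions_per_month:
            raise ConfigurationError(f"design tissue {tissue!r} missing from divisions_per_month")

    # mice per (tissue, age): enough for the largest pool requested
    mice_needed: dict[tuple[str, float], int] = {}
    for _, row in design.df.iterrows():
        key = (row["tissue"], float(row["age_months"]))
        mice_needed[key] = max(mice_needed.get(key, 0), int(row["pool_size"]))

    stem_pools: dict[tuple[str, float], list[CellPopulation]] = {}
    nonstem_pools: dict[tuple[str, float], list[CellPopulation]] = {}
    for (tissue, age), n_mice in sorted(mice_needed.items()):
        stem_pools[(tissue, age)] = []
        nonstem_pools[(tissue, age)] = []
        for m in range(n_mice):
            rng = rng_for(config.seed, f"mouse|{tissue}|{age}|{m}")
            stem = simulate_stem_population(config, tissue, age, layout=layout, rng=rng)
            stem_pools[(tissue, age)].append(stem)
            rng_d = rng_for(config.seed, f"diff|{tissue}|{age}|{m}")
            nonstem_pools[(tissue, age)].append(differentiate(stem, config, rng=rng_d))

    manifest: dict[str, object] = {"samples": {}, "outdir": str(outdir)}
    truth_rows = []
    for _, row in design.df.iterrows():
        sample_id = str(row["sample_id"])
        key = (row["tissue"], float(row["age_months"]))
        pools = stem_pools[key] if row["cell_type"] == "stem" else nonstem_pools[key]
        pools = pools[: int(row["pool_size"])]
        all_reads: list[EpireadRecord] = []
        matrix: CpGCountMatrix | None = None
        for m, pop in enumerate(pools):
            rng = rng_for(config.seed, f"reads|{sample_id}|{m}")
            reads, counts = sample_reads(pop, config, rng=rng, sample_id=f"{sample_id}.m{m}")
            all_reads.extend(reads)
            matrix = counts if matrix is None else _sum_counts(matrix, counts, sample_id)
        assert matrix is not None
        if matrix.samples != [sample_id]:
            matrix = CpGCountMatrix(
                matrix.meth.set_axis([sample_id], axis=1),
                matrix.total.set_axis([sample_id], axis=1),
            )
        epireads_path = outdir / f"{sample_id}.epireads.tsv"
        cov_path = outdir / f"{sample_id}.cov"
        write_epireads(all_reads, epireads_path)
        write_bismark_cov(matrix, sample_id, cov_path)
        manifest["samples"][sample_id] = {
            "epireads": str(epireads_path),
            "cov": str(cov_path),
        }
        truth_rows.append(
            {
                "sample_id": sample_id,
                "tissue": row["tissue"],
                "age_months": float(row["age_months"]),
                "cell_type": row["cell_type"],
                "pool_size": int(row["pool_size"]),
                "divisions": pools[0].divisions,
            }
        )

    write_sample_sheet(design, outdir / "sample_sheet.csv")
    sites = pd.DataFrame(
        {
            "chromosome": layout.chromosome,
            "position": layout.positions,
            "compartment": layout.compartments,
            "m0": layout.m0,
            "epsilon_gain": layout.eps_gain,
            "epsilon_loss": layout.eps_loss,
        }
    )
    sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(truth_rows).to_csv(outdir / "truth_samples.tsv", sep="\t", index=False)
    manifest["sample_sheet"] = str(outdir / "sample_sheet.csv")
    manifest["truth_sites"] = str(outdir / "truth_sites.tsv")
    manifest["truth_samples"] = str(outdir / "truth_samples.tsv")
    logger.info("simulate_study: wrote %d samples to %s", len(design.df), outdir)
    return manifest


def _sum_counts(a: CpGCountMatrix, b: CpGCountMatrix, name: str) -> CpGCountMatrix:
    """Element-wise sum of two single-sample matrices (pooled mice)."""
    am, at = a.meth.iloc[:, 0], a.total.iloc[:, 0]
    bm, bt = b.meth.iloc[:, 0], b.total.iloc[:, 0]
    meth = am.add(bm, fill_value=0.0).to_frame(name)
    total = at.add(bt, fill_value=0.0).to_frame(name)
    return CpGCountMatrix(meth, total)
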