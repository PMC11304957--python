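"""Synthetic selection-screen generator.

Emulates the statistical structure of a saturation CXXX reporter screen:

1. a complete 8,000-member C-fixed plasmid library with uneven naive
   abundances (symmetric Dirichlet over variants);
2. per-replicate colony sampling (multinomial draws of ~150,000 CFUs,
   10 replicates per condition);
3. fitness-driven exponential growth over >= 8 population doublings under
   permissive (25C) and restrictive (37C, 42C) conditions, with per-variant
   relative growth rates derived from motif classification;
4. amplicon sequencing: multinomial read sampling at a configured depth
   with a uniform per-base substitution error.

Reads can be materialised as FASTQ (anchor + 9-nt variable region +
anchor), or the same sampling can be kept at the count level for fast
desk-scale runs; the two routes share the ground-truth draws and the error
channel is applied consistently (count-level errors treat the rare
multi-error read, < 0.01% of reads at the default error rate, as a
single-base error).

A companion mode emulates the orthogonal Rho1-style colony viability
screen: colony picks contaminated by gene conversion to the parent plasmid
and by double-picked colonies, with synonymous codon usage so distinct DNA
can encode identical proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .library_space import (
    AMINO_ACIDS,
    SequenceRejected,
    codons_for,
    enumerate_cxxx,
    fitness_category,
    preferred_coding_dna,
    translate_variable_region,
    variant_index,
    DEFAULT_RULESET,
    MotifRuleset,
)
from .reads import CountTable

CONDITIONS = ("naive", "25C", "37C", "42C")

#: Ground-truth relative growth rates per motif category. The ordering is a
#: calibration of the generator, not a measured quantity: shunted motifs
#: grow fastest at restrictive temperature, non-consensus ("unmodified")
#: motifs outgrow canonically-modified ones, and restrictive motifs grow
#: slowest. 37C uses a smaller spread, with canonical motifs most impaired,
#: mirroring the milder selection profile at that temperature; 25C is
#: neutral.
DEFAULT_RULE_TABLES: Mapping[tuple[str, str], Mapping[str, float]] = {
    ("Ydj1", "25C"): {"shunted": 1.0, "canonical": 1.0, "restrictive": 1.0, "other": 1.0},
    ("Ydj1", "37C"): {"shunted": 1.0, "canonical": 0.10, "restrictive": 0.70, "other": 0.75},
    ("Ydj1", "42C"): {"shunted": 1.0, "canonical": 0.15, "restrictive": 0.05, "other": 0.25},
    # Rho1 viability mode: both shunted and canonical motifs keep the
    # reporter functional; everything else is inviable.
    ("Rho1", "viability"): {"shunted": 1.0, "canonical": 1.0, "restrictive": 0.0, "other": 0.0},
}

#: Synthetic wild-type coding DNA for the parent CVLL plasmid (the real
#: plasmid's codon usage is not published).
PARENT_CVLL_DNA = "GTTTTGTTG"


@dataclass(frozen=True)
class SimulationConfig:
    """All simulator knobs plus the seed.

    Defaults are the study conditions of the thermotolerance screen:
    8,000-variant library, ~150,000 CFUs per replicate, 10 replicates per
    condition, at least 8 population doublings. Read depth and the error
    rate are desk-scale sequencing defaults; the naive abundance dispersion
    is the symmetric-Dirichlet concentration emulating uneven naive
    frequencies.
    """

    library_size: int = 8000
    cfu_count: int = 150_000
    replicates: int = 10
    doublings: float = 8.0
    read_depth_per_replicate: int = 100_000
    base_error_rate: float = 0.001
    naive_abundance_dispersion: float = 5.0
    anchor_left: str = "ACGGTTCAGAGCTCGATACC"
    anchor_right: str = "GGATCCTAGCTTGACGTCAA"
    seed: int = 0

    def __post_init__(self):
        if min(self.library_size, self.cfu_count, self.replicates,
               self.read_depth_per_replicate) <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.base_error_rate <= 1.0:
            raise ValueError("base_error_rate must be a probability")
        if self.doublings < 0:
            raise ValueError("doublings must be >= 0")
        if self.naive_abundance_dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FitnessModel:
    """Per-variant relative growth rates for one reporter/condition."""

    reporter: str
    condition: str
    fitness: np.ndarray  # aligned with enumerate_cxxx()[:library_size]

    @property
    def viable_mask(self) -> np.ndarray:
        return self.fitness > 0


@dataclass
class RhoColonySet:
    """Colony DNA sequences picked from a simulated viability screen."""

    sequences: list[str]
    parent_dna: str
    gene_conversion_fraction: float
    duplicate_pick_fraction: float


def assign_fitness(
    rule_table: Mapping[str, float],
    reporter: str = "Ydj1",
    condition: str = "42C",
    library_size: int = 8000,
    ruleset: MotifRuleset = DEFAULT_RULESET,
) -> FitnessModel:
    """Derive a FitnessModel from a motif-category -> growth-rate table."""
    variants = enumerate_cxxx()[:library_size]
    fitness = np.empty(len(variants))
    for i, v in enumerate(variants):
        cat = fitness_category(v, ruleset)
        if cat not in rule_table:
            raise KeyError(f"rule table has no growth rate for category {cat!r}")
        f = float(rule_table[cat])
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"growth rate for {cat!r} outside [0, 1]: {f}")
        fitness[i] = f
    return FitnessModel(reporter=reporter, condition=condition, fitness=fitness)


def default_fitness_model(
    reporter: str = "Ydj1",
    condition: str = "42C",
    library_size: int = 8000,
    ruleset: MotifRuleset = DEFAULT_RULESET,
) -> FitnessModel:
    key = (reporter, "viability" if reporter == "Rho1" else condition)
    return assign_fitness(DEFAULT_RULE_TABLES[key], reporter, key[1],
                          library_size, ruleset)


def build_naive_library(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Library abundance vector and per-replicate colony counts.

    Returns ``(p, colonies)`` where ``p`` is the Dirichlet-distributed
    library-wide abundance (length library_size, all entries nonzero) and
    ``colonies`` is an integer (replicates x library_size) matrix of
    multinomial CFU draws, each row summing to ``cfu_count``.
    """
    if config.library_size > len(enumerate_cxxx()):
        raise ValueError("library_size exceeds the CXXX space")
    alpha = np.full(config.library_size, config.naive_abundance_dispersion)
    p = rng.dirichlet(alpha)
    colonies = rng.multinomial(config.cfu_count, p, size=config.replicates)
    return p, colonies


def grow_population(
    abundances: np.ndarray, fitness: np.ndarray, doublings: float
) -> np.ndarray:
    """Exponential growth N_i' = N_i * 2**(f_i * D); no renormalisation."""
    abundances = np.asarray(abundances, dtype=float)
    if np.any(abundances < 0):
        raise ValueError("abundances must be nonnegative")
    fitness = np.asarray(fitness, dtype=float)
    if np.any((fitness < 0) | (fitness > 1)):
        raise ValueError("fitness values must lie in [0, 1]")
    return abundances * np.exp2(fitness * doublings)


@lru_cache(maxsize=4)
def _mutation_map(library_size: int) -> np.ndarray:
    """(library_size x 27) map: single-base mutants of each variant's fixed
    coding 9-mer -> destination variant index, or -1 when the mutant
    translates through a stop codon (a rejected read)."""
    variants = enumerate_cxxx()[:library_size]
    index = variant_index()
    out = np.empty((library_size, 27), dtype=np.int64)
    bases = "ACGT"
    for vi, protein in enumerate(variants):
        dna = preferred_coding_dna(protein)
        k = 0
        for pos in range(9):
            for b in bases:
                if b == dna[pos]:
                    continue
                mutant = dna[:pos] + b + dna[pos + 1 :]
                try:
                    target = index["C" + translate_variable_region(mutant)]
                except SequenceRejected:
                    target = -1
                if target >= library_size:
                    target = -1
                out[vi, k] = target
                k += 1
    return out


def apply_sequencing_errors(
    counts: np.ndarray,
    error_rate: float,
    rng: np.random.Generator,
    library_size: int | None = None,
) -> tuple[np.ndarray, int]:
    """Count-level substitution-error channel for one replicate.

    Each read independently acquires an error with probability
    1 - (1 - e)**9 over its 9 variable bases; erroneous reads are moved to
    the variant (or stop-codon rejection) reached by a uniformly chosen
    single-base substitution. Returns ``(new_counts, n_rejected)``.
    """
    counts = np.asarray(counts)
    if library_size is None:
        library_size = counts.shape[-1]
    if error_rate == 0:
        return counts.copy(), 0
    mutmap = _mutation_map(library_size)
    p_err = 1.0 - (1.0 - error_rate) ** 9
    k = rng.binomial(counts, p_err)
    moved = rng.multinomial(k, np.full(27, 1 / 27))  # (library_size, 27)
    new = counts - k
    flat_targets = mutmap.ravel()
    flat_moved = moved.ravel()
    valid = flat_targets >= 0
    np.add.at(new, flat_targets[valid], flat_moved[valid])
    n_rejected = int(flat_moved[~valid].sum())
    return new, n_rejected


def sample_replicate_reads(
    grown_abundances: np.ndarray,
    depth: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial read counts proportional to grown abundances."""
    grown_abundances = np.asarray(grown_abundances, dtype=float)
    total = grown_abundances.sum()
    if total <= 0:
        raise ValueError("empty abundance vector")
    return rng.multinomial(depth, grown_abundances / total)


@dataclass
class ScreenResult:
    """Everything the simulator knows about one synthetic screen."""

    config: SimulationConfig
    library_abundance: np.ndarray
    fitness_models: dict[str, FitnessModel]
    tables: dict[str, CountTable]
    #: per condition: (replicates x library_size) true (pre-error) read counts
    true_counts: dict[str, np.ndarray]


def simulate_screen(
    config: SimulationConfig,
    conditions: Sequence[str] = CONDITIONS,
    reporter: str = "Ydj1",
    rule_tables: Mapping[tuple[str, str], Mapping[str, float]] = DEFAULT_RULE_TABLES,
    ruleset: MotifRuleset = DEFAULT_RULESET,
) -> ScreenResult:
    """Run the full counts-level screen simulation.

    For every condition, each replicate draws its own CFU sample from the
    common library abundance, grows it under that condition's fitness model
    and is sequenced to ``read_depth_per_replicate`` with the substitution
    error channel. The naive condition sequences the ungrown colony sample.
    """
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("library", *conditions), root.spawn(1 + len(conditions))
        )
    }
    variants = list(enumerate_cxxx()[: config.library_size])
    p, _ = build_naive_library(config, streams["library"])

    fitness_models: dict[str, FitnessModel] = {}
    tables: dict[str, CountTable] = {}
    true_counts: dict[str, np.ndarray] = {}
    for cond in conditions:
        rng = streams[cond]
        colonies = rng.multinomial(config.cfu_count, p, size=config.replicates)
        if cond == "naive":
            grown = colonies.astype(float)
        else:
            model = assign_fitness(
                rule_tables[(reporter, cond)], reporter, cond,
                config.library_size, ruleset,
            )
            fitness_models[cond] = model
            grown = grow_population(colonies, model.fitness, config.doublings)
        reads = np.stack(
            [
                sample_replicate_reads(row, config.read_depth_per_replicate, rng)
                for row in grown
            ]
        )
        true_counts[cond] = reads
        observed = np.empty_like(reads)
        rejections = []
        for r in range(config.replicates):
            observed[r], n_rej = apply_sequencing_errors(
                reads[r], config.base_error_rate, rng, config.library_size
            )
            rejections.append({"stop_codon": n_rej} if n_rej else {})
        tables[cond] = CountTable.from_matrix(cond, variants, observed, rejections)
    return ScreenResult(
        config=config,
        library_abundance=p,
        fitness_models=fitness_models,
        tables=tables,
        true_counts=true_counts,
    )


# ---------------------------------------------------------------------------
# FASTQ materialisation

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_IDX[_b] = _i


def sequence_reads(
    read_counts: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Materialise one replicate's reads as ``(sequence, quality)`` pairs.

    Each read is anchor_left + coding 9-mer + anchor_right with independent
    per-base substitution errors over the whole read (anchors included) and
    a constant quality string.
    """
    read_counts = np.asarray(read_counts)
    depth = int(read_counts.sum())
    if read_counts.size == 0 or depth == 0:
        raise ValueError("empty abundance vector")
    library_size = read_counts.shape[0]
    variants = enumerate_cxxx()[:library_size]
    template = np.array(
        [
            np.frombuffer(
                (config.anchor_left + preferred_coding_dna(v) + config.anchor_right)
                .encode(),
                dtype=np.uint8,
            )
            for v in variants
        ]
    )
    order = np.repeat(np.arange(library_size), read_counts)
    rng.shuffle(order)
    reads = template[order]  # (depth, read_len) uint8
    if config.base_error_rate > 0:
        flip = rng.random(reads.shape) < config.base_error_rate
        offsets = rng.integers(1, 4, size=reads.shape, dtype=np.uint8)
        idx = _BASE_TO_IDX[reads]
        mutated = _BASE_ARR[(idx + offsets) % 4]
        reads = np.where(flip, mutated, reads)
    qual = "I" * reads.shape[1]
    return [(row.tobytes().decode(), qual) for row in reads]


def write_fastq(
    path: str | Path,
    read_counts: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    read_prefix: str = "sim",
) -> int:
    """Write one replicate's reads to a 4-line FASTQ file; returns the depth."""
    records = sequence_reads(read_counts, config, rng)
    with open(path, "w") as fh:
        for i, (seq, qual) in enumerate(records):
            fh.write(f"@{read_prefix}:{i}\n{seq}\n+\n{qual}\n")
    return len(records)


def write_fitness_tsv(path: str | Path, model: FitnessModel) -> None:
    variants = enumerate_cxxx()[: len(model.fitness)]
    with open(path, "w") as fh:
        fh.write(f"# reporter={model.reporter} condition={model.condition}\n")
        fh.write("variant\tfitness\n")
        for v, f in zip(variants, model.fitness):
            fh.write(f"{v}\t{f:.6g}\n")


# ---------------------------------------------------------------------------
# Rho1-style colony screen

def simulate_rho1_screen(
    n_colonies: int = 200,
    gene_conversion_fraction: float = 83 / 200,
    duplicate_pick_fraction: float = 5 / 117,
    parent_dna: str = PARENT_CVLL_DNA,
    fitness_model: FitnessModel | None = None,
    rng: np.random.Generator | None = None,
    synonymous_codons: bool = True,
) -> RhoColonySet:
    """Simulate colony picking from the viability screen.

    Each pick is the exact parent DNA with probability
    ``gene_conversion_fraction``; otherwise, with probability
    ``duplicate_pick_fraction`` it repeats an earlier non-parent pick
    (a double-picked colony), and otherwise it is a fresh random codon
    encoding of a uniformly chosen viable variant. Defaults are calibrated
    so the expected deduplication ladder is 200 -> 117 -> 112.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 0 <= gene_conversion_fraction <= 1 or not 0 <= duplicate_pick_fraction <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if fitness_model is None:
        fitness_model = default_fitness_model("Rho1")
    viable = np.nonzero(fitness_model.viable_mask)[0]
    if viable.size == 0:
        raise ValueError("no viable variants under the fitness model")
    variants = enumerate_cxxx()[: len(fitness_model.fitness)]
    codon_table = codons_for()

    def random_encoding(protein: str) -> str:
        if not synonymous_codons:
            return preferred_coding_dna(protein)
        return "".join(
            codon_table[aa][rng.integers(len(codon_table[aa]))] for aa in protein[1:]
        )

    picks: list[str] = []
    non_parent: list[str] = []
    for _ in range(n_colonies):
        if rng.random() < gene_conversion_fraction:
            picks.append(parent_dna)
            continue
        if non_parent and rng.random() < duplicate_pick_fraction:
            dna = non_parent[rng.integers(len(non_parent))]
        else:
            dna = random_encoding(variants[viable[rng.integers(viable.size)]])
            if dna == parent_dna:
                # a genuine CVLL pick indistinguishable from gene conversion
                picks.append(dna)
                continue
        picks.append(dna)
        non_parent.append(dna)
    return RhoColonySet(
        sequences=picks,
        parent_dna=parent_dna,
        gene_conversion_fraction=gene_conversion_fraction,
        duplicate_pick_fraction=duplicate_pick_fraction,
    )
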