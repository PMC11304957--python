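"""End-to-end screen replay on synthetic data, with file-based stage boundaries.

``run_full_pipeline`` simulates the screen, materialises FASTQ reads,
counts variants back out of the FASTQ files, computes frequencies and
E-Scores (37C and 42C against naive; the 25C library is computed and
exported but never used as a denominator), exports scatter tables, selects
enriched/de-enriched subsets and their position frequency matrices,
computes composition statistics, the coverage report, and the colony-screen
comparison, then writes a machine-readable run manifest (config, seed,
version, artifact checksums — no timestamps, so reruns with the same seed
are byte-identical).

Every stage writes TSV with a header comment carrying the tool version and
seed; stages communicate through files so real data can enter at any
stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    compute_escores,
    compute_frequencies,
    escore_summary,
    export_scatter,
    select_by_threshold,
    select_top_n,
)
from .library_space import DEFAULT_RULESET, MotifRuleset, enumerate_cxxx
from .motifs import build_pfm, composition_stats, consensus_string, plot_logo
from .reads import CountTable, count_variants, merge_replicates
from .rho1 import crossref_escores, dedup_hits, split_by_consensus
from .coverage import expected_coverage, prob_complete_coverage
from .simulate import (
    CONDITIONS,
    SimulationConfig,
    default_fitness_model,
    simulate_rho1_screen,
    simulate_screen,
    write_fastq,
    write_fitness_tsv,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Replay configuration: simulator knobs plus analysis parameters."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    ruleset: MotifRuleset = field(default_factory=lambda: DEFAULT_RULESET)
    top_n_42c: int = 500
    low_escore_cutoff_37c: float = 0.2
    crossref_bin_edges: tuple[float, float] = (2.0, 0.5)
    rho1_n_colonies: int = 200
    rho1_gene_conversion_fraction: float = 83 / 200
    rho1_duplicate_pick_fraction: float = 5 / 117
    render_logos: bool = False
    seed: int = 0

    def __post_init__(self):
        # the single pipeline seed governs the simulator too
        if self.simulation.seed != self.seed:
            self.simulation = self.simulation.with_(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        ruleset = MotifRuleset.from_dict(raw.pop("ruleset", None))
        if "crossref_bin_edges" in raw:
            raw["crossref_bin_edges"] = tuple(raw["crossref_bin_edges"])
        return cls(simulation=sim, ruleset=ruleset, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ruleset"] = self.ruleset.to_dict()
        d["crossref_bin_edges"] = list(self.crossref_bin_edges)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    """Context manager logging stage timing; failures abort with the stage name."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.monotonic()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.monotonic() - self.t0
        if exc_type is not None:
            logger.error("stage %s: FAILED after %.1fs: %s", self.name, dt, exc)
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        logger.info("stage %s: done in %.1fs", self.name, dt)
        return False


def _write_tsv(df: pd.DataFrame, path: Path, seed: int, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cxxxscreen v{__version__} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def _write_list(items, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cxxxscreen v{__version__} seed={seed}\n")
        for item in items:
            fh.write(f"{item}\n")


def run_full_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run the full synthetic replay; returns the artifact directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    sim = config.simulation
    universe = list(enumerate_cxxx()[: sim.library_size])

    with _Stage("simulate"):
        result = simulate_screen(sim, ruleset=config.ruleset)
        fastq_dir = out / "fastq"
        fastq_dir.mkdir(exist_ok=True)
        fastq_rng = np.random.default_rng(
            np.random.SeedSequence(seed).spawn(100)[99]
        )
        fastq_paths: dict[str, list[Path]] = {}
        for cond in CONDITIONS:
            fastq_paths[cond] = []
            for r in range(sim.replicates):
                path = fastq_dir / f"{cond}_replicate_{r + 1}.fastq"
                write_fastq(path, result.true_counts[cond][r], sim, fastq_rng,
                            read_prefix=f"sim:{cond}:rep{r + 1}")
                fastq_paths[cond].append(path)
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        for cond, model in result.fitness_models.items():
            write_fitness_tsv(truth_dir / f"fitness_{cond}.tsv", model)

    with _Stage("count"):
        counts_dir = out / "counts"
        counts_dir.mkdir(exist_ok=True)
        universe_set = frozenset(universe)
        tables: dict[str, CountTable] = {}
        for cond in CONDITIONS:
            per_rep = []
            for r, path in enumerate(fastq_paths[cond]):
                variants, rejections = count_variants(
                    path, sim.anchor_left, sim.anchor_right,
                    universe=universe_set,
                )
                t = CountTable(cond)
                t.add_replicate(f"replicate_{r + 1}", variants, rejections)
                per_rep.append(t)
            table = merge_replicates(per_rep)
            tables[cond] = table
            table.to_tsv(counts_dir / f"{cond}.counts.tsv", universe=universe,
                         header_comment=f"cxxxscreen v{__version__} seed={seed}")
            _write_tsv(table.rejection_summary(),
                       counts_dir / f"{cond}.rejections.tsv", seed, index=False)

    with _Stage("frequencies"):
        freq_dir = out / "freq"
        freq_dir.mkdir(exist_ok=True)
        freqs = {
            cond: compute_frequencies(tables[cond], universe=universe)
            for cond in CONDITIONS
        }
        for cond, f in freqs.items():
            _write_tsv(f.rename("frequency").to_frame(),
                       freq_dir / f"{cond}.freq.tsv", seed)

    with _Stage("escores"):
        escore_dir = out / "escore"
        escore_dir.mkdir(exist_ok=True)
        escores = {}
        for cond in ("37C", "42C"):
            df = compute_escores(freqs[cond], freqs["naive"])
            escores[cond] = df
            _write_tsv(df, escore_dir / f"{cond}_vs_naive.escore.tsv", seed)
        scatter_dir = out / "scatter"
        scatter_dir.mkdir(exist_ok=True)
        for cond in ("25C", "37C", "42C"):
            _write_tsv(export_scatter(freqs["naive"], freqs[cond]),
                       scatter_dir / f"{cond}_vs_naive.scatter.tsv", seed)

    with _Stage("subsets"):
        subset_dir = out / "subsets"
        subset_dir.mkdir(exist_ok=True)
        n42 = config.top_n_42c
        subsets = {
            "top_42C": select_top_n(escores["42C"], n42, "top"),
            "bottom_42C": select_top_n(escores["42C"], n42, "bottom"),
            "low_37C": select_by_threshold(
                escores["37C"], "<", config.low_escore_cutoff_37c
            ),
        }
        # matched-size top subset at 37C ("equivalent number of top scores")
        n37 = max(len(subsets["low_37C"]), 1)
        subsets["top_37C"] = select_top_n(escores["37C"], n37, "top")
        for name, variants in subsets.items():
            _write_list(variants, subset_dir / f"{name}.variants.txt", seed)

    with _Stage("motifs"):
        motif_dir = out / "motifs"
        motif_dir.mkdir(exist_ok=True)
        comp_rows = []
        for name, variants in subsets.items():
            if not variants:
                continue
            pfm = build_pfm(variants)
            pfm.to_tsv(motif_dir / f"{name}.pfm.tsv",
                       header_comment=f"cxxxscreen v{__version__} seed={seed}")
            comp_rows.append(
                {"subset": name,
                 "consensus": consensus_string(pfm, 0.9),
                 **composition_stats(variants, config.ruleset)}
            )
            if config.render_logos:
                plot_logo(pfm, motif_dir / f"{name}.logo.png", title=name)
        _write_tsv(pd.DataFrame(comp_rows), motif_dir / "composition.tsv",
                   seed, index=False)

    with _Stage("coverage"):
        cov = pd.DataFrame(
            [
                {"library_size": sim.library_size, "sample_size": sim.cfu_count,
                 "mode": "expected",
                 "value": expected_coverage(sim.library_size, sim.cfu_count)},
                {"library_size": sim.library_size, "sample_size": sim.cfu_count,
                 "mode": "complete",
                 "value": prob_complete_coverage(sim.library_size, sim.cfu_count)},
            ]
        )
        _write_tsv(cov, out / "coverage.tsv", seed, index=False)

    with _Stage("rho1"):
        rho_dir = out / "rho1"
        rho_dir.mkdir(exist_ok=True)
        rho_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(101)[100])
        colonies = simulate_rho1_screen(
            n_colonies=config.rho1_n_colonies,
            gene_conversion_fraction=config.rho1_gene_conversion_fraction,
            duplicate_pick_fraction=config.rho1_duplicate_pick_fraction,
            fitness_model=default_fitness_model(
                "Rho1", library_size=sim.library_size, ruleset=config.ruleset
            ),
            rng=rho_rng,
        )
        _write_list(colonies.sequences, rho_dir / "colonies.txt", seed)
        report, unique_dna, proteins = dedup_hits(
            colonies.sequences, colonies.parent_dna
        )
        _write_tsv(report.to_frame(), rho_dir / "dedup_report.tsv", seed,
                   index=False)
        _write_list(unique_dna, rho_dir / "unique_dna.txt", seed)
        _write_list(proteins, rho_dir / "unique_variants.txt", seed)
        _write_tsv(
            crossref_escores(proteins, escores["42C"], config.crossref_bin_edges),
            rho_dir / "crossref_42C.tsv", seed, index=False,
        )
        conforming, nonconforming = split_by_consensus(proteins, config.ruleset)
        for name, sub in (("conforming", conforming),
                          ("nonconforming", nonconforming)):
            _write_list(sub, rho_dir / f"{name}.variants.txt", seed)
            if sub:
                build_pfm(sub).to_tsv(
                    rho_dir / f"{name}.pfm.tsv",
                    header_comment=f"cxxxscreen v{__version__} seed={seed}",
                )

    with _Stage("manifest"):
        artifacts = sorted(
            p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "tool": "cxxxscreen",
            "version": __version__,
            "seed": seed,
            "config": config.to_dict(),
            "escore_summaries": {
                cond: escore_summary(escores[cond],
                                     config.low_escore_cutoff_37c)
                for cond in ("37C", "42C")
            },
            "artifacts": {
                str(p.relative_to(out)): _sha256(p) for p in artifacts
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return out
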