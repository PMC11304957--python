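"""Colony-screen hit processing: deduplication ladder and E-Score cross-reference.

Colony-derived DNA sequences from a viability screen are contaminated by
two artefacts: gene conversion (picks whose insert is the exact parent
plasmid sequence) and double-picked colonies (exact DNA duplicates).
Deduplication removes parent matches, collapses DNA duplicates, translates
the survivors and collapses synonymous encodings to distinct proteins.
"Duplicate" means exact DNA identity; protein-level collapse is a
separate, subsequent step.

The surviving protein set is then cross-referenced against the enrichment
scores of the sequencing screen by binning (defaults: > 2 enriched,
0.5-2 intermediate, < 0.5 de-enriched).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .library_space import (
    DEFAULT_RULESET,
    MotifRuleset,
    SequenceRejected,
    classify_motif,
    translate_variable_region,
)


@dataclass
class DedupReport:
    """Arithmetic ladder of the colony-hit deduplication.

    Invariants: n_remaining = n_input - n_parent_identical;
    n_unique_dna = n_remaining - n_duplicate_dna;
    n_distinct_protein <= n_unique_dna.
    Untranslatable sequences are excluded from all counts and listed under
    ``rejects``.
    """

    n_input: int
    n_parent_identical: int
    n_remaining: int
    n_duplicate_dna: int
    n_unique_dna: int
    n_distinct_protein: int
    codon_multiplicity: dict[str, int] = field(default_factory=dict)
    rejects: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input", self.n_input),
            ("parent_identical", self.n_parent_identical),
            ("remaining", self.n_remaining),
            ("duplicate_dna", self.n_duplicate_dna),
            ("unique_dna", self.n_unique_dna),
            ("distinct_protein", self.n_distinct_protein),
            ("rejected", len(self.rejects)),
        ]
        return pd.DataFrame(rows, columns=["step", "count"])


def dedup_hits(
    dna_list: Sequence[str], parent_dna: str
) -> tuple[DedupReport, list[str], list[str]]:
    """Deduplicate colony DNA sequences against the parent plasmid.

    Returns ``(report, unique_dna, distinct_proteins)``; the protein list
    is in order of first appearance. Sequences that fail translation (stop
    codons, bad bases, wrong length) are excluded from the ladder and
    listed in ``report.rejects``.
    """
    parent_dna = parent_dna.upper()
    valid: list[tuple[str, str]] = []  # (dna, protein)
    rejects: list[str] = []
    for raw in dna_list:
        dna = raw.strip().upper()
        if not dna:
            continue
        try:
            protein = "C" + translate_variable_region(dna)
        except SequenceRejected:
            rejects.append(dna)
            continue
        valid.append((dna, protein))

    n_input = len(valid)
    non_parent = [(d, p) for d, p in valid if d != parent_dna]
    n_parent = n_input - len(non_parent)

    seen_dna: dict[str, str] = {}
    n_duplicates = 0
    for dna, protein in non_parent:
        if dna in seen_dna:
            n_duplicates += 1
        else:
            seen_dna[dna] = protein

    protein_multiplicity = Counter(seen_dna.values())
    distinct_proteins = list(dict.fromkeys(seen_dna.values()))

    report = DedupReport(
        n_input=n_input,
        n_parent_identical=n_parent,
        n_remaining=len(non_parent),
        n_duplicate_dna=n_duplicates,
        n_unique_dna=len(seen_dna),
        n_distinct_protein=len(distinct_proteins),
        codon_multiplicity=dict(protein_multiplicity),
        rejects=rejects,
    )
    return report, list(seen_dna), distinct_proteins


DEFAULT_BIN_EDGES = (2.0, 0.5)  # (upper, lower)


def crossref_escores(
    variant_list: Sequence[str],
    escores: pd.DataFrame,
    bin_edges: tuple[float, float] = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Bin colony-screen hits by their sequencing-screen E-Scores.

    Default bins: score > upper (enriched), lower <= score <= upper,
    score < lower (de-enriched), plus ``undefined`` (no naive frequency)
    and ``not_in_universe`` (variant absent from the score table). Counts
    always sum to the list length.
    """
    upper, lower = bin_edges
    if lower > upper:
        raise ValueError("bin_edges must be (upper, lower) with upper >= lower")
    labels = [f">{upper:g}", f"{lower:g}-{upper:g}", f"<{lower:g}",
              "undefined", "not_in_universe"]
    counts = dict.fromkeys(labels, 0)
    for v in variant_list:
        if v not in escores.index:
            counts["not_in_universe"] += 1
            continue
        row = escores.loc[v]
        if row["status"] != "ok":
            counts["undefined"] += 1
            continue
        s = float(row["escore"])
        if s > upper:
            counts[labels[0]] += 1
        elif s < lower:
            counts[labels[2]] += 1
        else:
            counts[labels[1]] += 1
    n = len(variant_list)
    out = pd.DataFrame(
        {
            "bin": labels,
            "count": [counts[l] for l in labels],
            "fraction": [counts[l] / n if n else 0.0 for l in labels],
        }
    )
    return out


def split_by_consensus(
    variant_list: Sequence[str], ruleset: MotifRuleset = DEFAULT_RULESET
) -> tuple[list[str], list[str]]:
    """Partition variants on the terminal-residue consensus flag.

    Returns ``(conforming, nonconforming)`` — X in the consensus set
    {L, F, I, M, V} versus not — ready for PFM analysis of each side.
    """
    conforming, nonconforming = [], []
    for v in variant_list:
        if classify_motif(v, ruleset).x_consensus:
            conforming.append(v)
        else:
            nonconforming.append(v)
    return conforming, nonconforming
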