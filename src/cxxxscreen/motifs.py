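"""Position frequency matrices, consensus strings and motif composition.

Frequency-scaled (not information-content) matrices, matching the
frequency-based logo analysis convention for this motif family. Matrices
are exported as TSV (rows = residues, columns = positions) so any renderer
can draw them; a matplotlib letter-stack renderer is provided as a
convenience.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .library_space import (
    AMINO_ACIDS,
    CLASS_COLORS,
    DEFAULT_RULESET,
    MotifRuleset,
    classify_motif,
    residue_class,
)


@dataclass
class PositionFrequencyMatrix:
    """Per-position amino-acid frequencies for a variant subset.

    ``matrix`` is a DataFrame with the 20 residues as rows and 1-based
    positions as columns; every column sums to 1. ``n`` is the subset size.
    """

    matrix: pd.DataFrame
    n: int

    @property
    def positions(self) -> list[int]:
        return list(self.matrix.columns)

    def column(self, position: int) -> pd.Series:
        return self.matrix[position]

    def mass(self, position: int, residues: Iterable[str]) -> float:
        """Total frequency mass of ``residues`` at ``position``."""
        return float(self.matrix.loc[list(residues), position].sum())

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(f"# n={self.n}\n")
            self.matrix.to_csv(fh, sep="\t")


def build_pfm(
    subset: Sequence[str], drop_invariant_cysteine: bool = False
) -> PositionFrequencyMatrix:
    """Amino-acid frequency matrix of an equal-length variant subset.

    With ``drop_invariant_cysteine`` the fixed position 1 is omitted and
    columns run 2-4.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("empty subset")
    length = len(subset[0])
    if any(len(s) != length for s in subset):
        raise ValueError("sequences of unequal length")
    start = 1 if drop_invariant_cysteine else 0
    positions = list(range(start + 1, length + 1))
    counts = np.zeros((len(AMINO_ACIDS), len(positions)))
    aa_idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for seq in subset:
        for j, pos in enumerate(positions):
            counts[aa_idx[seq[pos - 1]], j] += 1
    matrix = pd.DataFrame(
        counts / len(subset), index=pd.Index(list(AMINO_ACIDS), name="residue"),
        columns=positions,
    )
    return PositionFrequencyMatrix(matrix=matrix, n=len(subset))


def annotate_classes(pfm: PositionFrequencyMatrix) -> pd.DataFrame:
    """PFM matrix with the five-way residue class and display colour attached."""
    out = pfm.matrix.copy()
    out["class"] = [residue_class(aa) for aa in out.index]
    out["color"] = [CLASS_COLORS[c] for c in out["class"]]
    return out


def composition_stats(
    subset: Sequence[str], ruleset: MotifRuleset = DEFAULT_RULESET
) -> dict:
    """Counts and fractions of motif-classification flags over a subset."""
    subset = list(subset)
    if not subset:
        raise ValueError("empty subset")
    n = len(subset)
    flags = {"restrictive": 0, "canonical_cleavable": 0, "x_consensus": 0,
             "a2_bca": 0, "neither": 0}
    for v in subset:
        c = classify_motif(v, ruleset)
        flags["restrictive"] += c.restrictive
        flags["canonical_cleavable"] += c.canonical_cleavable
        flags["x_consensus"] += c.x_consensus
        flags["a2_bca"] += c.a2_bca
        flags["neither"] += not (c.restrictive or c.x_consensus)
    report = {"n": n}
    for k, count in flags.items():
        report[f"{k}_count"] = int(count)
        report[f"{k}_fraction"] = count / n
    return report


def consensus_string(
    pfm: PositionFrequencyMatrix,
    majority_threshold: float = 0.9,
    max_set_size: int = 5,
) -> str:
    """Degenerate consensus of a PFM.

    Per position, the minimal residue set (by descending frequency) whose
    cumulative frequency reaches ``majority_threshold``; singleton sets
    print as the residue, small sets as ``[A/B]``, and positions needing
    more than ``max_set_size`` residues print as ``x``.
    """
    if not 0 < majority_threshold <= 1:
        raise ValueError("majority_threshold must be in (0, 1]")
    tokens = []
    for pos in pfm.positions:
        col = pfm.column(pos)
        ordered = col.sort_values(ascending=False, kind="mergesort")
        cum = 0.0
        chosen: list[str] = []
        for aa, f in ordered.items():
            if f == 0.0:
                break
            chosen.append(aa)
            cum += f
            if cum >= majority_threshold - 1e-12:
                break
        if len(chosen) == 1:
            tokens.append(chosen[0])
        elif len(chosen) <= max_set_size and cum >= majority_threshold - 1e-12:
            tokens.append("[" + "/".join(chosen) + "]")
        else:
            tokens.append("x")
    return "".join(tokens)


def plot_logo(pfm: PositionFrequencyMatrix, path: str | Path,
              title: str | None = None) -> None:
    """Render a frequency logo as PNG (convenience; the TSV is the contract).

    Letters are stacked per position with height proportional to frequency
    and coloured by residue class (cysteine blue, branched-chain aliphatics
    red, charged green, polar uncharged black, other hydrophobics purple).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(pfm.positions) + 1, 3))
    for j, pos in enumerate(pfm.positions):
        col = pfm.column(pos).sort_values(kind="mergesort")
        bottom = 0.0
        for aa, f in col.items():
            if f <= 0:
                continue
            ax.text(
                j + 0.5, bottom + f / 2, aa,
                ha="center", va="center",
                fontsize=max(6.0, 38 * f), fontweight="bold", family="monospace",
                color=CLASS_COLORS[residue_class(aa)],
            )
            bottom += f
    ax.set_xlim(0, len(pfm.positions))
    ax.set_ylim(0, 1)
    ax.set_xticks([j + 0.5 for j in range(len(pfm.positions))])
    ax.set_xticklabels([str(p) for p in pfm.positions])
    ax.set_ylabel("frequency")
    ax.set_xlabel("position")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
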