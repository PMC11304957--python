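"""FASTQ read processing: anchor extraction and variant counting.

Each amplicon read carries the 9-nt variable region (encoding CXXX
positions 2-4) between two fixed anchor sequences. Reads are processed by
locating both anchors (allowing a limited number of substitutions, no
indels), extracting the enclosed 9-mer, translating it and prepending the
invariant cysteine. Every read ends up either in the variant tally or in a
per-reason rejection tally, so accepted + rejected always equals the number
of records processed.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library_space import SequenceRejected, translate_variable_region

REJECTION_REASONS = (
    "anchor_not_found",
    "bad_length",
    "bad_base",
    "stop_codon",
    "low_quality",
    "not_in_library",
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _hamming_at(seq: str, pattern: str, start: int) -> int:
    return sum(a != b for a, b in zip(seq[start : start + len(pattern)], pattern))


def _find_approx(seq: str, pattern: str, max_mismatch: int, start: int = 0) -> int:
    """Leftmost start of ``pattern`` in ``seq`` with <= max_mismatch substitutions."""
    exact = seq.find(pattern, start)
    if exact != -1 or max_mismatch == 0:
        return exact
    last = len(seq) - len(pattern)
    for i in range(start, last + 1):
        if _hamming_at(seq, pattern, i) <= max_mismatch:
            return i
    return -1


def extract_variable_region(
    read_sequence: str,
    anchor_left: str,
    anchor_right: str,
    max_anchor_mismatch: int = 1,
) -> str:
    """Return the 9-mer between the two anchors of a read.

    Raises :class:`SequenceRejected` with reason ``anchor_not_found`` when
    either anchor is missing, or ``bad_length`` when the enclosed region is
    not exactly 9 nt.
    """
    if not anchor_left or not anchor_right:
        raise ValueError("anchors must be nonempty")
    seq = read_sequence.upper()
    li = _find_approx(seq, anchor_left, max_anchor_mismatch)
    if li == -1:
        raise SequenceRejected("anchor_not_found", "left")
    inner_start = li + len(anchor_left)
    ri = _find_approx(seq, anchor_right, max_anchor_mismatch, start=inner_start)
    if ri == -1:
        raise SequenceRejected("anchor_not_found", "right")
    region = seq[inner_start:ri]
    if len(region) != 9:
        raise SequenceRejected("bad_length", f"{len(region)} nt between anchors")
    return region


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def count_variants(
    fastq_path: str | Path,
    anchor_left: str,
    anchor_right: str,
    max_anchor_mismatch: int = 1,
    min_mean_quality: float | None = None,
    search_reverse_complement: bool = False,
    universe: "set[str] | frozenset[str] | None" = None,
) -> tuple[Counter, Counter]:
    """Tally CXXX variants in one replicate's FASTQ file.

    Returns ``(variant_counts, rejection_counts)``. No quality filter is
    applied by default; ``min_mean_quality`` enables a mean-Phred threshold.
    ``search_reverse_complement`` retries anchor location on the reverse
    complement of each read (off by default; the simulator emits forward
    reads). With ``universe`` supplied (the library's design space),
    translatable reads outside it are tallied under ``not_in_library``.
    """
    variants: Counter = Counter()
    rejections: Counter = Counter()
    record_no = 0
    with _open_text(fastq_path) as handle:
        try:
            for _title, seq, qual in FastqGeneralIterator(handle):
                record_no += 1
                if min_mean_quality is not None:
                    mean_q = np.mean([ord(c) - 33 for c in qual]) if qual else 0.0
                    if mean_q < min_mean_quality:
                        rejections["low_quality"] += 1
                        continue
                try:
                    try:
                        region = extract_variable_region(
                            seq, anchor_left, anchor_right, max_anchor_mismatch
                        )
                    except SequenceRejected:
                        if not search_reverse_complement:
                            raise
                        rc = seq.upper().translate(_COMPLEMENT)[::-1]
                        region = extract_variable_region(
                            rc, anchor_left, anchor_right, max_anchor_mismatch
                        )
                    variant = "C" + translate_variable_region(region)
                    if universe is not None and variant not in universe:
                        rejections["not_in_library"] += 1
                    else:
                        variants[variant] += 1
                except SequenceRejected as rej:
                    rejections[rej.reason] += 1
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ {fastq_path} near record {record_no + 1}: {exc}"
            ) from exc
    return variants, rejections


@dataclass
class CountTable:
    """Per-replicate variant counts for one library (condition).

    ``counts`` maps replicate id -> Counter(variant -> reads); ``rejections``
    holds the per-replicate rejection tallies so that accepted + rejected
    equals reads processed.
    """

    library_id: str
    counts: dict[str, Counter] = field(default_factory=dict)
    rejections: dict[str, Counter] = field(default_factory=dict)

    @property
    def replicate_ids(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def add_replicate(
        self,
        replicate_id: str,
        counts: Mapping[str, int],
        rejections: Mapping[str, int] | None = None,
    ) -> None:
        if replicate_id in self.counts:
            raise ValueError(f"duplicate replicate id: {replicate_id}")
        self.counts[replicate_id] = Counter(counts)
        self.rejections[replicate_id] = Counter(rejections or {})

    def totals(self) -> Counter:
        """Per-variant counts summed over every replicate."""
        total: Counter = Counter()
        for c in self.counts.values():
            total.update(c)
        return total

    @classmethod
    def from_matrix(
        cls,
        library_id: str,
        variants: Iterable[str],
        matrix: np.ndarray,
        rejections: Iterable[Mapping[str, int]] | None = None,
    ) -> "CountTable":
        """Build from a dense (replicates x variants) integer matrix."""
        variants = list(variants)
        matrix = np.asarray(matrix)
        if matrix.ndim != 2 or matrix.shape[1] != len(variants):
            raise ValueError("matrix shape does not match variant list")
        rej_list = list(rejections) if rejections is not None else [{}] * len(matrix)
        table = cls(library_id)
        for r, row in enumerate(matrix):
            nz = np.nonzero(row)[0]
            table.add_replicate(
                f"replicate_{r + 1}",
                {variants[i]: int(row[i]) for i in nz},
                rej_list[r],
            )
        return table

    def to_frame(self, universe: Iterable[str] | None = None) -> pd.DataFrame:
        """Wide DataFrame: one row per variant, one column per replicate, plus total."""
        reps = list(self.counts)
        if universe is None:
            index = sorted(set().union(*self.counts.values())) if reps else []
        else:
            index = list(universe)
        df = pd.DataFrame(0, index=pd.Index(index, name="variant"), columns=reps)
        for rep, counter in self.counts.items():
            ser = pd.Series(counter, dtype="int64")
            ser = ser.reindex(df.index, fill_value=0)
            df[rep] = ser
        df["total"] = df.sum(axis=1)
        return df

    def to_tsv(self, path: str | Path, universe: Iterable[str] | None = None,
               header_comment: str | None = None) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(f"# library_id={self.library_id}\n")
            self.to_frame(universe).to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        path = Path(path)
        library_id = path.stem
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                if line.startswith("# library_id="):
                    library_id = line.strip().split("=", 1)[1]
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t", index_col="variant")
        reps = [c for c in df.columns if c != "total"]
        table = cls(library_id)
        for rep in reps:
            col = df[rep]
            table.add_replicate(rep, {v: int(c) for v, c in col.items() if c > 0})
        return table

    def rejection_summary(self) -> pd.DataFrame:
        rows = []
        for rep in self.counts:
            rej = self.rejections.get(rep, Counter())
            rows.append(
                {
                    "replicate": rep,
                    "accepted": sum(self.counts[rep].values()),
                    **{r: rej.get(r, 0) for r in REJECTION_REASONS},
                }
            )
        return pd.DataFrame(rows)


def merge_replicates(tables: Iterable[CountTable]) -> CountTable:
    """Merge single-replicate tables of the same library into one CountTable."""
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to merge")
    ids = {t.library_id for t in tables}
    if len(ids) != 1:
        raise ValueError(f"library_id mismatch: {sorted(ids)}")
    merged = CountTable(tables[0].library_id)
    for t in tables:
        for rep in t.counts:
            merged.add_replicate(rep, t.counts[rep], t.rejections.get(rep))
    return merged
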