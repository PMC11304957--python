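"""Per-library frequencies, enrichment scores (E-Scores) and subset selection.

The frequency of a variant in a library is its summed count over all
replicates divided by the sum of all accepted variant counts in that
library. The E-Score of a variant is its frequency in a selected
(restrictive-temperature) library divided by its frequency in the naive
library: > 1 means enriched, < 1 de-enriched, 0 means absent after
selection. No pseudocounts are applied — the observed minimum score of 0
implies raw ratios — and a zero naive frequency yields an "undefined"
score that is flagged and excluded from rankings rather than smoothed.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .reads import CountTable

logger = logging.getLogger(__name__)

_COMPARATORS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
}


def compute_frequencies(
    counts: "CountTable | Mapping[str, int]",
    universe: Iterable[str] | None = None,
) -> pd.Series:
    """Per-variant frequencies for one library.

    ``counts`` is a CountTable (replicates are summed) or a plain
    variant -> count mapping. With ``universe`` supplied, variants never
    observed are reported with frequency 0. Frequencies sum to 1 over
    observed variants.
    """
    if isinstance(counts, CountTable):
        name = counts.library_id
        totals = counts.totals()
    else:
        name = "frequency"
        totals = dict(counts)
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("all-zero count table")
    if universe is None:
        index = pd.Index(sorted(totals), name="variant")
    else:
        index = pd.Index(list(universe), name="variant")
        known = set(index)
        missing = [v for v in totals if v not in known]
        if missing:
            raise ValueError(f"counts contain variants outside the universe: {missing[:5]}")
    freq = pd.Series(
        [totals.get(v, 0) / grand for v in index], index=index, name=name, dtype=float
    )
    return freq


def compute_escores(selected: pd.Series, naive: pd.Series) -> pd.DataFrame:
    """E-Score table: selected frequency / naive frequency per variant.

    Both inputs must share the same variant universe. Returns a DataFrame
    indexed by variant with columns ``freq_naive``, ``freq_selected``,
    ``escore`` and ``status`` ("ok", or "undefined" when the naive
    frequency is zero; undefined scores are NaN and excluded from
    rankings).
    """
    if len(selected.index) != len(naive.index) or not selected.index.equals(
        naive.index
    ):
        if set(selected.index) != set(naive.index):
            raise ValueError("variant universes of the two libraries differ")
        naive = naive.reindex(selected.index)
    undefined = naive == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = selected.to_numpy(dtype=float) / naive.to_numpy(dtype=float)
    scores[undefined.to_numpy()] = np.nan
    n_undef = int(undefined.sum())
    if n_undef:
        logger.warning(
            "%d variants have zero naive frequency; their E-Scores are "
            "undefined and excluded from rankings", n_undef,
        )
    df = pd.DataFrame(
        {
            "freq_naive": naive.astype(float),
            "freq_selected": selected.astype(float),
            "escore": scores,
            "status": np.where(undefined, "undefined", "ok"),
        },
        index=selected.index,
    )
    df.index.name = "variant"
    return df


def _defined(escores: pd.DataFrame) -> pd.DataFrame:
    return escores[escores["status"] == "ok"]


def select_by_threshold(
    escores: pd.DataFrame, comparator: str, cutoff: float
) -> list[str]:
    """Variants whose (defined) E-Score satisfies ``comparator cutoff``.

    Deterministic order: ascending score, ties broken lexicographically.
    """
    if comparator not in _COMPARATORS:
        raise ValueError(f"comparator must be one of {sorted(_COMPARATORS)}")
    ok = _defined(escores)
    mask = _COMPARATORS[comparator](ok["escore"].to_numpy(), cutoff)
    hit = ok[mask].reset_index()
    ordered = hit.sort_values(["escore", "variant"], kind="mergesort")
    return list(ordered["variant"])


def select_top_n(
    escores: pd.DataFrame, n: int, direction: str = "top"
) -> list[str]:
    """Top (or bottom) ``n`` variants by defined E-Score.

    Ties at the boundary are broken lexicographically by variant (the
    lexicographically smaller variant wins a slot), so selections are
    stable across runs.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if direction not in ("top", "bottom"):
        raise ValueError("direction must be 'top' or 'bottom'")
    ok = _defined(escores)
    if n > len(ok):
        raise ValueError(f"n={n} exceeds the {len(ok)} defined-score variants")
    ascending = direction == "bottom"
    ordered = ok.reset_index().sort_values(
        ["escore", "variant"], ascending=[ascending, True], kind="mergesort"
    )
    return list(ordered["variant"][:n])


def export_scatter(
    freq_naive: pd.Series, freq_other: pd.Series
) -> pd.DataFrame:
    """Paired per-variant frequency table for 2D frequency plots.

    One row per variant of the shared universe with the naive frequency
    (x), the condition frequency (y) and the E-Score column.
    """
    df = compute_escores(freq_other, freq_naive)
    out = df.rename(columns={"freq_selected": "freq_condition"})
    return out[["freq_naive", "freq_condition", "escore", "status"]]


def escore_summary(escores: pd.DataFrame, low_cutoff: float = 0.2) -> dict:
    """Headline numbers of an E-Score table: max, min, and the size of the
    de-enriched subset below ``low_cutoff``."""
    ok = _defined(escores)["escore"]
    return {
        "n_defined": int(len(ok)),
        "max": float(ok.max()),
        "min": float(ok.min()),
        "n_below_cutoff": int((ok < low_cutoff).sum()),
        "cutoff": low_cutoff,
    }
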