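"""CXXX sequence space, codon translation and motif classification.

The library studied here is the full set of C-terminal four-residue motifs
CXXX — an invariant cysteine followed by any three of the twenty standard
amino acids, giving 20**3 = 8,000 variants. Only the three X positions are
encoded by the 9-nt variable region of the amplicon; the cysteine codon is
fixed in the construct.

Motif vocabulary used throughout the package:

* ``x_consensus`` — the terminal residue X is one of {L, F, I, M, V}, the
  set compatible with geranylgeranylation of the reporter.
* ``a2_bca`` — the a2 position (third residue) is a branched-chain
  aliphatic amino acid {V, I, L}, the preference of the Rce1 CaaX protease.
* ``canonical_cleavable`` — both of the above: the Cx[V/I/L][L/F/I/M/V]
  profile of prenylated-and-cleaved ("canonically modified") sequences.
  The a1 position is deliberately unconstrained (CAIL-like sequences count
  as canonical).
* ``restrictive`` — a2 in {D, E, K, R} or X in {K, R, P}; residues reported
  to interfere with prenylation of the reporter altogether.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

from Bio.Data import CodonTable

#: The twenty standard amino acids in lexicographic one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_standard = CodonTable.unambiguous_dna_by_id[1]
CODON_TABLE: Mapping[str, str] = dict(_standard.forward_table)
STOP_CODONS = frozenset(_standard.stop_codons)

#: Five-way residue classification used for logo colouring. The classes
#: partition the twenty amino acids exactly once each.
RESIDUE_CLASSES: Mapping[str, frozenset] = {
    "cysteine": frozenset("C"),
    "branched_aliphatic": frozenset("VIL"),
    "charged": frozenset("KRHDE"),
    "polar_uncharged": frozenset("SQTN"),
    "other_hydrophobic": frozenset("AGPFWYM"),
}

_CLASS_OF = {aa: name for name, members in RESIDUE_CLASSES.items() for aa in members}

#: Display colours matching the customary logo scheme for this motif family.
CLASS_COLORS = {
    "cysteine": "blue",
    "branched_aliphatic": "red",
    "charged": "green",
    "polar_uncharged": "black",
    "other_hydrophobic": "purple",
}


class SequenceRejected(ValueError):
    """A read or sequence that cannot be turned into a CXXX variant.

    ``reason`` is a short machine-readable tag: ``bad_length``, ``bad_base``,
    ``stop_codon``, ``anchor_not_found`` (the last raised by read
    processing, not translation).
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}{': ' + detail if detail else ''}")


def residue_class(aa: str) -> str:
    """Return the five-way class label for a single amino-acid letter."""
    try:
        return _CLASS_OF[aa]
    except KeyError:
        raise ValueError(f"not a standard amino acid: {aa!r}") from None


@lru_cache(maxsize=1)
def enumerate_cxxx() -> tuple[str, ...]:
    """All 8,000 CXXX variants in deterministic lexicographic order."""
    return tuple(
        "C" + a + b + c
        for a in AMINO_ACIDS
        for b in AMINO_ACIDS
        for c in AMINO_ACIDS
    )


@lru_cache(maxsize=1)
def variant_index() -> Mapping[str, int]:
    """Map variant protein string -> its position in :func:`enumerate_cxxx`."""
    return {v: i for i, v in enumerate(enumerate_cxxx())}


def is_cxxx(protein: str) -> bool:
    return (
        len(protein) == 4
        and protein[0] == "C"
        and all(aa in _CLASS_OF for aa in protein)
    )


def translate_variable_region(dna: str) -> str:
    """Translate the 9-nt variable region into the three X residues.

    Uses the standard nuclear genetic code. Raises :class:`SequenceRejected`
    with reason ``bad_length`` (not 9 nt), ``bad_base`` (non-ACGT) or
    ``stop_codon``.
    """
    dna = dna.upper()
    if len(dna) != 9:
        raise SequenceRejected("bad_length", f"{len(dna)} nt")
    if any(b not in "ACGT" for b in dna):
        raise SequenceRejected("bad_base", dna)
    residues = []
    for i in range(0, 9, 3):
        codon = dna[i : i + 3]
        if codon in STOP_CODONS:
            raise SequenceRejected("stop_codon", codon)
        residues.append(CODON_TABLE[codon])
    return "".join(residues)


@lru_cache(maxsize=1)
def codons_for() -> Mapping[str, tuple[str, ...]]:
    """Synonymous codons per amino acid, lexicographically sorted."""
    table: dict[str, list[str]] = {aa: [] for aa in AMINO_ACIDS}
    for codon, aa in CODON_TABLE.items():
        table[aa].append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in table.items()}


def preferred_coding_dna(protein: str) -> str:
    """A fixed 9-nt encoding of positions 2-4 (lexicographically first codons)."""
    if not is_cxxx(protein):
        raise ValueError(f"not a CXXX variant: {protein!r}")
    table = codons_for()
    return "".join(table[aa][0] for aa in protein[1:])


@dataclass(frozen=True)
class CxxxVariant:
    """A four-residue CXXX motif with an optional 9-nt coding region."""

    protein: str
    coding_dna: str | None = None

    def __post_init__(self):
        if not is_cxxx(self.protein):
            raise ValueError(f"not a CXXX variant: {self.protein!r}")
        if self.coding_dna is not None:
            translated = translate_variable_region(self.coding_dna)
            if translated != self.protein[1:]:
                raise ValueError(
                    f"coding_dna translates to {translated}, "
                    f"expected {self.protein[1:]}"
                )


@dataclass(frozen=True)
class MotifRuleset:
    """Configurable residue sets behind motif classification.

    Defaults reproduce the consensus derived from the thermotolerance
    screen; alternative definitions (e.g. an a1-restricted consensus) can be
    supplied through the pipeline configuration.
    """

    x_consensus: frozenset = frozenset("LFIMV")
    a2_bca: frozenset = frozenset("VIL")
    restrictive_a2: frozenset = frozenset("DEKR")
    restrictive_x: frozenset = frozenset("KRP")

    @classmethod
    def from_dict(cls, d: Mapping[str, str] | None) -> "MotifRuleset":
        if not d:
            return cls()
        kwargs = {k: frozenset(v) for k, v in d.items()}
        return cls(**kwargs)

    def to_dict(self) -> dict[str, str]:
        return {
            "x_consensus": "".join(sorted(self.x_consensus)),
            "a2_bca": "".join(sorted(self.a2_bca)),
            "restrictive_a2": "".join(sorted(self.restrictive_a2)),
            "restrictive_x": "".join(sorted(self.restrictive_x)),
        }


DEFAULT_RULESET = MotifRuleset()


@dataclass(frozen=True)
class MotifClassification:
    protein: str
    x_consensus: bool
    a2_bca: bool
    canonical_cleavable: bool
    restrictive: bool
    residue_classes: tuple[str, str, str, str] = field(repr=False)


def classify_motif(
    variant: "CxxxVariant | str", ruleset: MotifRuleset = DEFAULT_RULESET
) -> MotifClassification:
    """Classify a CXXX variant under the (configurable) consensus rules."""
    protein = variant.protein if isinstance(variant, CxxxVariant) else variant
    if not is_cxxx(protein):
        raise ValueError(f"not a CXXX variant: {protein!r}")
    a2, x = protein[2], protein[3]
    x_cons = x in ruleset.x_consensus
    a2_bca = a2 in ruleset.a2_bca
    return MotifClassification(
        protein=protein,
        x_consensus=x_cons,
        a2_bca=a2_bca,
        canonical_cleavable=a2_bca and x_cons,
        restrictive=(a2 in ruleset.restrictive_a2) or (x in ruleset.restrictive_x),
        residue_classes=tuple(residue_class(aa) for aa in protein),
    )


def fitness_category(
    protein: str, ruleset: MotifRuleset = DEFAULT_RULESET
) -> str:
    """Coarse category used by the screen simulator's ground-truth rules.

    ``canonical`` (prenylated and cleaved), ``restrictive`` (prenylation
    blocked), ``shunted`` (prenylated but not cleaved: consensus X, non-BCA
    a2, no restrictive residues) or ``other`` (everything else, behaving
    like the unmodified reporter).
    """
    c = classify_motif(protein, ruleset)
    if c.canonical_cleavable:
        return "canonical"
    if c.restrictive:
        return "restrictive"
    if c.x_consensus:
        return "shunted"
    return "other"
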