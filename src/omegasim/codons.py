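"""Codon-level classification and fractional site counting.

Single-base changes of a sense codon are classified as synonymous (amino
acid unchanged), missense (amino acid changed) or nonsense (a stop codon is
created).  Site counts follow the Nei-Gojobori convention: each of the nine
possible single-base changes contributes uniform weight 1/3 at its position
to the nonsynonymous (N) or synonymous (S) site total, and stop-producing
changes are excluded from both totals.  Model-weighted mutation tallies use
the same enumeration but weight each change by the substitution model's
normalized per-base probability instead of 1/3; nonsense weights are
likewise discarded.

All counting is done in exact rational arithmetic (``fractions.Fraction``;
Fraction-from-float is exact), so the identity "uniform model weights equal
uniform site weights" holds to machine identity, not merely to tolerance.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from numbers import Real

from Bio.Data import CodonTable as _CodonTable

from .errors import InvalidBaseError, ParameterError, StopCodonError
from .models import BASES, SubstitutionModel

STOP = "*"

_standard = _CodonTable.unambiguous_dna_by_id[1]
#: Standard genetic code (translation table 1): codon -> one-letter amino
#: acid, with stop codons mapped to "*".
GENETIC_CODE: dict[str, str] = dict(_standard.forward_table)
for _c in _standard.stop_codons:
    GENETIC_CODE[_c] = STOP

STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa != STOP))


class ChangeClass(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"


@dataclass(frozen=True)
class SiteCounts:
    """Fractional nonsynonymous (N) and synonymous (S) site counts."""

    n_sites: Real = Fraction(0)
    s_sites: Real = Fraction(0)

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(self.n_sites + other.n_sites, self.s_sites + other.s_sites)

    def as_floats(self) -> tuple[float, float]:
        return float(self.n_sites), float(self.s_sites)


@dataclass(frozen=True)
class MutationCounts:
    """Model-weighted nonsynonymous (n_N) and synonymous (n_S) tallies."""

    n_nonsyn: Real = Fraction(0)
    n_syn: Real = Fraction(0)

    def __add__(self, other: "MutationCounts") -> "MutationCounts":
        return MutationCounts(self.n_nonsyn + other.n_nonsyn, self.n_syn + other.n_syn)

    def as_floats(self) -> tuple[float, float]:
        return float(self.n_nonsyn), float(self.n_syn)


def _check_codon(codon: str) -> str:
    if len(codon) != 3 or any(b not in "TCAG" for b in codon):
        raise InvalidBaseError(f"invalid codon {codon!r}: expected 3 bases from T, C, A, G")
    return codon


def translate(codon: str) -> str:
    """Standard-code amino acid of a codon; stop codons return '*'."""
    return GENETIC_CODE[_check_codon(codon)]


def is_stop(codon: str) -> bool:
    return _check_codon(codon) in STOP_CODONS


def classify_change(codon: str, position: int, alt: str) -> ChangeClass:
    """Classify the single-base change codon[position] -> alt.

    The input codon must be a sense codon and ``alt`` must differ from the
    reference base at ``position``.
    """
    _check_codon(codon)
    if alt not in "TCAG":
        raise InvalidBaseError(f"invalid alternative base {alt!r}")
    if position not in (0, 1, 2):
        raise ParameterError(f"codon position must be 0, 1 or 2, got {position!r}")
    if codon in STOP_CODONS:
        raise StopCodonError(f"stop codon {codon} has no defined change classification")
    if alt == codon[position]:
        raise ParameterError(f"alternative base equals the reference base {alt!r}: not a change")
    mutated = codon[:position] + alt + codon[position + 1 :]
    if mutated in STOP_CODONS:
        return ChangeClass.NONSENSE
    if GENETIC_CODE[mutated] == GENETIC_CODE[codon]:
        return ChangeClass.SYNONYMOUS
    return ChangeClass.MISSENSE


def enumerate_changes(codon: str):
    """Yield (position, alt, ChangeClass) over all nine single-base changes."""
    if is_stop(codon):
        raise StopCodonError(f"stop codon {codon} has no site counts")
    for position in range(3):
        ref = codon[position]
        for alt in BASES:
            if alt != ref:
                yield position, alt, classify_change(codon, position, alt)


def count_sites(codon: str) -> SiteCounts:
    """Fractional N/S site counts of a sense codon (uniform 1/3 weights).

    Stop-producing changes contribute to neither total, so N + S = 3 exactly
    when no single-base change of the codon creates a stop.
    """
    n = Fraction(0)
    s = Fraction(0)
    third = Fraction(1, 3)
    for _pos, _alt, cls in enumerate_changes(codon):
        if cls is ChangeClass.MISSENSE:
            n += third
        elif cls is ChangeClass.SYNONYMOUS:
            s += third
    return SiteCounts(n, s)


def weighted_mutation_counts(codon: str, model: SubstitutionModel) -> MutationCounts:
    """Model-weighted mutation tallies of a sense codon.

    Each alternative at each position carries the model's normalized
    substitution probability for that position's base; missense weights sum
    into n_N, synonymous into n_S, nonsense weights are dropped.
    """
    if is_stop(codon):
        raise StopCodonError(f"stop codon {codon} has no mutation tallies")
    n = Fraction(0)
    s = Fraction(0)
    # normalize in exact rationals from the raw rates (Fraction-from-float is
    # exact), so uniform-rate models weight each change by exactly 1/3
    probs: dict[str, dict[str, Fraction]] = {}
    for b in set(codon):
        raw = {a: Fraction(model.rate(b, a)) for a in model.alternatives(b)}
        total = sum(raw.values())
        probs[b] = {a: r / total for a, r in raw.items()}
    for pos, alt, cls in enumerate_changes(codon):
        w = probs[codon[pos]][alt]
        if cls is ChangeClass.MISSENSE:
            n += w
        elif cls is ChangeClass.SYNONYMOUS:
            s += w
    return MutationCounts(n, s)
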