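"""Exhaustive single-base mutagenesis scan of a coding sequence.

The scan locates the reading frame at the first ATG (or trusts the caller
with ``assume_in_frame``), walks the sequence codon by codon until the
first in-frame stop, and for every sense codon enumerates all nine
single-base changes: uniform 1/3 weights accumulate into site counts
(N, S) and model-normalized probabilities into mutation tallies
(n_N, n_S).  dN/dS is then n_N/N over n_S/S.

Under JC69 the model weights are exactly 1/3, so omega is identically 1
for any coding sequence — the analytic anchor used throughout the tests.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Real

import pandas as pd

from .codons import MutationCounts, SiteCounts, STOP_CODONS, count_sites, weighted_mutation_counts
from .errors import EmptyScanError, InvalidBaseError, NoStartCodonError
from .models import SubstitutionModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CodingSequence:
    """A protein-coding DNA sequence with its scan frame offset."""

    identifier: str
    bases: str
    frame_start: int = 0


@dataclass(frozen=True)
class Region:
    """0-based half-open interval on a named contig (BED convention)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            from .errors import InvalidRegionError

            raise InvalidRegionError(f"region {self.chrom}:{self.start}-{self.end}: start must be < end")


@dataclass(frozen=True)
class DnDsResult:
    """dN, dS and omega = dN/dS, with degenerate-denominator flagging.

    ``omega`` (and ``d_n``/``d_s``) are NaN when their denominators vanish;
    ``degenerate`` is set whenever S = 0, N = 0 or n_S = 0.
    """

    d_n: float
    d_s: float
    omega: float
    degenerate: bool


def locate_reading_frame(bases: str, assume_in_frame: bool = False) -> tuple[int, list[str]]:
    """Find the scan frame and return (frame_start, sense codon list).

    The frame starts at the first ATG anywhere in the sequence (or at base 0
    with ``assume_in_frame``).  Reading stops at — and excludes — the first
    in-frame stop codon; a trailing partial codon is dropped.  Internal
    stops therefore truncate the scan, with a logged warning.
    """
    bases = bases.upper().replace("U", "T")
    if any(b not in "TCAG" for b in bases):
        bad = next(b for b in bases if b not in "TCAG")
        raise InvalidBaseError(f"sequence contains non-ACGT base {bad!r}; cannot scan")
    if assume_in_frame:
        frame_start = 0
    else:
        frame_start = bases.find("ATG")
        if frame_start < 0:
            raise NoStartCodonError("no ATG start codon found in sequence")
    codons: list[str] = []
    stop_at: int | None = None
    for i in range(frame_start, len(bases) - 2, 3):
        codon = bases[i : i + 3]
        if codon in STOP_CODONS:
            stop_at = i
            break
        codons.append(codon)
    if not codons:
        raise EmptyScanError("no sense codons to scan after frame location and trimming")
    if stop_at is not None and stop_at + 3 < len(bases) - 2:
        logger.warning("scan truncated at in-frame stop codon at offset %d; %d bases ignored", stop_at, len(bases) - stop_at - 3)
    return frame_start, codons


@dataclass
class ScanResult:
    """Per-codon ledger plus aggregate counts and the dN/dS of a scan."""

    sequence: CodingSequence
    records: list[dict] = field(repr=False)
    sites: SiteCounts
    mutations: MutationCounts
    dnds: DnDsResult

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records, columns=["codon_index", "codon", "N", "S", "n_N", "n_S"])
        for col in ("N", "S", "n_N", "n_S"):
            df[col] = df[col].astype(float)
        return df


def _merge_intervals(regions: list[Region]) -> dict[str, list[tuple[int, int]]]:
    """Sort and merge per contig; overlapping or touching intervals coalesce."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        merged = by_chrom.setdefault(r.chrom, [])
        if merged and r.start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], r.end))
        else:
            merged.append((r.start, r.end))
    return by_chrom


def _codon_in_regions(start: int, merged: list[tuple[int, int]]) -> bool:
    # merged intervals never touch, so a 3-base codon fits at most one
    return any(s <= start and start + 3 <= e for s, e in merged)


def exhaustive_scan(
    sequence: CodingSequence | str,
    model: SubstitutionModel,
    regions: list[Region] | None = None,
    assume_in_frame: bool = False,
    identifier: str = "seq",
) -> ScanResult:
    """Scan every in-frame sense codon and aggregate site/mutation counts.

    With ``regions``, only codons whose three bases all fall inside a single
    merged region on the sequence's contig are counted; straddling codons
    are skipped (logged).  Returns the per-codon ledger plus aggregates and
    the resulting :class:`DnDsResult`.
    """
    if isinstance(sequence, CodingSequence):
        ident, bases = sequence.identifier, sequence.bases
    else:
        ident, bases = identifier, str(sequence)
    frame_start, codons = locate_reading_frame(bases, assume_in_frame=assume_in_frame)

    merged: list[tuple[int, int]] | None = None
    if regions is not None:
        merged = _merge_intervals(regions).get(ident, [])

    records: list[dict] = []
    sites = SiteCounts()
    muts = MutationCounts()
    skipped = 0
    for i, codon in enumerate(codons):
        start = frame_start + 3 * i
        if merged is not None and not _codon_in_regions(start, merged):
            skipped += 1
            continue
        cs = count_sites(codon)
        cm = weighted_mutation_counts(codon, model)
        sites += cs
        muts += cm
        records.append(
            {"codon_index": i, "codon": codon, "N": cs.n_sites, "S": cs.s_sites, "n_N": cm.n_nonsyn, "n_S": cm.n_syn}
        )
    if skipped:
        logger.info("region restriction skipped %d of %d codons", skipped, len(codons))
    if not records:
        raise EmptyScanError("region restriction excluded every codon")
    return ScanResult(
        sequence=CodingSequence(ident, bases, frame_start),
        records=records,
        sites=sites,
        mutations=muts,
        dnds=compute_dnds(sites, muts),
    )


def compute_dnds(sites: SiteCounts, mutations: MutationCounts) -> DnDsResult:
    """dN = n_N/N, dS = n_S/S, omega = dN/dS, with NaN on zero denominators.

    Exact rational inputs stay exact until the final float conversion, so
    analytically exact ratios (e.g. 1 under JC69) survive unchanged.
    """
    N, S = sites.n_sites, sites.s_sites
    nN, nS = mutations.n_nonsyn, mutations.n_syn
    degenerate = N == 0 or S == 0 or nS == 0
    d_n = float(Fraction(nN) / Fraction(N)) if _exact(nN, N) and N != 0 else (float(nN) / float(N) if N != 0 else math.nan)
    d_s = float(Fraction(nS) / Fraction(S)) if _exact(nS, S) and S != 0 else (float(nS) / float(S) if S != 0 else math.nan)
    if S != 0 and N != 0 and nS != 0:
        if _exact(nN, N, nS, S):
            omega = float((Fraction(nN) * Fraction(S)) / (Fraction(N) * Fraction(nS)))
        else:
            omega = (float(nN) / float(N)) / (float(nS) / float(S))
    else:
        omega = math.nan
    return DnDsResult(d_n=d_n, d_s=d_s, omega=omega, degenerate=bool(degenerate))


def _exact(*values: Real) -> bool:
    return all(isinstance(v, (int, Fraction)) for v in values)


def scan_records(
    records: list[tuple[str, str]],
    model: SubstitutionModel,
    regions: list[Region] | None = None,
    assume_in_frame: bool = False,
) -> tuple[dict[str, ScanResult], SiteCounts, MutationCounts, DnDsResult]:
    """Scan several FASTA records independently and pooled.

    Returns ``(per_record, pooled_sites, pooled_mutations, pooled_dnds)``.
    """
    per_record: dict[str, ScanResult] = {}
    sites = SiteCounts()
    muts = MutationCounts()
    for ident, bases in records:
        res = exhaustive_scan(bases, model, regions=regions, assume_in_frame=assume_in_frame, identifier=ident)
        per_record[ident] = res
        sites += res.sites
        muts += res.mutations
    if not per_record:
        raise EmptyScanError("no sequences to scan")
    return per_record, sites, muts, compute_dnds(sites, muts)
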