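"""FASTA/BED reading and writing plus synthetic-data generators.

The generators make every other module testable without downloads: a
coding-sequence generator (ATG + sense codons + stop, base composition
configurable) and a reference-contig + matching-VCF generator for context
mode.  Both are deterministic given their seed (NumPy PCG64 streams), so
fixtures are byte-identical across platforms and runs.
"""
from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .codons import STOP_CODONS
from .errors import EmptyInputError, InputFormatError, InvalidRegionError, ParameterError
from .exhaustive import CodingSequence, Region
from .models import BASES

# IUPAC nucleotide codes accepted on read (after U -> T normalization)
_IUPAC = set("ACGTRYSWKMBDHVN")

_STOPS = tuple(sorted(STOP_CODONS))


def _as_handle(source):
    if hasattr(source, "read"):
        return source, False
    return open(source), True


def read_fasta(source) -> list[tuple[str, str]]:
    """Read FASTA records as (identifier, sequence) in file order.

    Sequences are uppercased and U is mapped to T.  Characters outside the
    IUPAC nucleotide alphabet raise, naming the record and offset.
    """
    handle, close = _as_handle(source)
    try:
        records = []
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper().replace("U", "T")
            for off, ch in enumerate(seq):
                if ch not in _IUPAC:
                    raise InputFormatError(
                        f"record {rec.id!r}: invalid character {ch!r} at sequence offset {off}"
                    )
            records.append((rec.id, seq))
    finally:
        if close:
            handle.close()
    if not records:
        raise EmptyInputError("FASTA source contains no records")
    return records


def read_reference(source) -> dict[str, str]:
    """Reference FASTA as a contig-name -> sequence mapping (in memory)."""
    return dict(read_fasta(source))


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Write records wrapped at 60 columns."""
    with open(path, "w") as fh:
        fh.write(format_fasta(records))


def format_fasta(records: list[tuple[str, str]]) -> str:
    out = _stdio.StringIO()
    for ident, seq in records:
        out.write(f">{ident}\n")
        for i in range(0, len(seq), 60):
            out.write(seq[i : i + 60] + "\n")
    return out.getvalue()


def read_bed(source) -> list[Region]:
    """Read BED3+ intervals, 0-based half-open, sorted and merged per contig."""
    handle, close = _as_handle(source)
    try:
        regions: list[Region] = []
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise InputFormatError(f"BED line {lineno}: expected >= 3 tab-separated columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise InputFormatError(f"BED line {lineno}: non-integer coordinates") from None
            if start >= end:
                raise InvalidRegionError(f"BED line {lineno}: start {start} must be < end {end}")
            regions.append(Region(cols[0], start, end))
    finally:
        if close:
            handle.close()
    # sort and merge overlapping/touching intervals per contig
    merged: list[Region] = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
            merged[-1] = Region(r.chrom, merged[-1].start, max(merged[-1].end, r.end))
        else:
            merged.append(r)
    return merged


@dataclass(frozen=True)
class SyntheticCdsSpec:
    """Recipe for a synthetic coding sequence: ATG + n_codons sense codons + stop."""

    n_codons: int
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ParameterError("n_codons must be >= 1")
        f = tuple(float(x) for x in self.base_freqs)
        if len(f) != 4 or any(x < 0 for x in f) or abs(sum(f) - 1) > 1e-9:
            raise ParameterError("base_freqs must be 4 non-negative values over (T, C, A, G) summing to 1")
        object.__setattr__(self, "base_freqs", f)


@dataclass(frozen=True)
class SyntheticVcfSpec:
    """Recipe for one uniform-base contig plus a matching SNV-only VCF."""

    n_variants: int
    contig_length: int
    seed: int = 0
    contig_name: str = "syn1"

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ParameterError("n_variants must be >= 1")
        # variant positions keep >= 3 bases of flank on each side
        if self.n_variants > self.contig_length - 6:
            raise ParameterError(
                f"n_variants ({self.n_variants}) exceeds eligible interior positions "
                f"({self.contig_length - 6}) of a {self.contig_length} bp contig"
            )


def generate_cds(spec: SyntheticCdsSpec) -> CodingSequence:
    """Generate ATG + n_codons sense codons + one stop codon.

    Codons are drawn base-wise from ``base_freqs`` with stop codons rejected
    and resampled, so the scan frame runs the full length; the terminal stop
    is chosen uniformly.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    codons = ["ATG"]
    while len(codons) < spec.n_codons + 1:
        codon = "".join(rng.choice(BASES, size=3, p=spec.base_freqs))
        if codon not in STOP_CODONS:
            codons.append(codon)
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return CodingSequence(identifier=f"synthetic_cds_{spec.seed}", bases="".join(codons), frame_start=0)


def generate_reference_and_vcf(spec: SyntheticVcfSpec) -> tuple[str, str]:
    """Generate (FASTA text, VCF text) for context-mode runs.

    One contig of i.i.d. uniform bases; ``n_variants`` distinct 1-based
    positions with at least 3 bases of flank on both sides; every VCF REF
    matches the contig base and ALT is uniform over the other three bases.
    Byte-identical for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    contig = "".join(rng.choice(BASES, size=spec.contig_length))
    eligible = np.arange(3, spec.contig_length - 3)  # 0-based interior
    positions = np.sort(rng.choice(eligible, size=spec.n_variants, replace=False))
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={spec.contig_name},length={spec.contig_length}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for p0 in positions:
        ref = contig[p0]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        lines.append(f"{spec.contig_name}\t{p0 + 1}\t.\t{ref}\t{alt}\t.\t.\t.")
    fasta_text = format_fasta([(spec.contig_name, contig)])
    vcf_text = "\n".join(lines) + "\n"
    return fasta_text, vcf_text


def write_reference_and_vcf(spec: SyntheticVcfSpec, directory) -> tuple[Path, Path]:
    """Materialize the synthetic reference and VCF under ``directory``."""
    fasta_text, vcf_text = generate_reference_and_vcf(spec)
    d = Path(directory)
    fasta_path = d / f"{spec.contig_name}.fa"
    vcf_path = d / f"{spec.contig_name}.vcf"
    fasta_path.write_text(fasta_text)
    vcf_path.write_text(vcf_text)
    return fasta_path, vcf_path
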