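"""Context-aware Monte-Carlo mutagenesis anchored on VCF variant positions.

For each biallelic SNV in a VCF, a codon is constructed from the reference
bases flanking the variant, with the variant base placed at a codon
position drawn uniformly from {0, 1, 2} — fresh for every variant in every
replicate.  The variant base is then mutated once according to the
substitution model and the change classified against the standard genetic
code.  Aggregating over variants gives one simulated dN/dS per replicate;
repeating builds a null distribution of omega values reflecting the local
sequence context of the input variants.

Site normalization covers the variant position only (each of the three
alternatives at uniform weight 1/3, stop-producing changes excluded),
mirroring the fact that exactly one mutation is simulated per variant.
The recorded ALT allele is never used to drive the simulation; it is
retained for audit only.

Replicates are internally vectorized over variants via a precompiled
per-(variant, frame) table; the scalar :func:`simulate_variant` path
exposes the same draw for a single variant.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .codons import ChangeClass, MutationCounts, SiteCounts, classify_change, is_stop
from .errors import (
    AmbiguousFlank,
    EmptyInputError,
    FlankOutOfBounds,
    MissingContigError,
    ParameterError,
    StopContext,
)
from .exhaustive import DnDsResult, compute_dnds
from .models import SubstitutionModel, sample_substitution

SKIP_CATEGORIES = ("indel", "multiallelic", "symbolic", "ref_mismatch", "other")
CONTEXT_SKIP_CATEGORIES = ("out_of_bounds", "ambiguous_flank", "stop_codon_context")

# class codes used in the compiled tables
_SYN, _MIS, _NON = 0, 1, 2
_CLS_CODE = {ChangeClass.SYNONYMOUS: _SYN, ChangeClass.MISSENSE: _MIS, ChangeClass.NONSENSE: _NON}
_REASON_CODE = {"ok": 0, "out_of_bounds": 1, "ambiguous_flank": 2, "stop_codon_context": 3}
_REASON_NAME = {v: k for k, v in _REASON_CODE.items() if v}


@dataclass(frozen=True)
class Variant:
    """A biallelic SNV; ``alt_base`` is audit-only and never simulated."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref_base: str
    alt_base: str


@dataclass(frozen=True)
class ContextCodon:
    """A codon built from reference flanks around a variant position."""

    codon: str
    frame_index: int  # position of the variant base within the codon
    source: tuple[str, int]


@dataclass
class NullDistribution:
    """Replicate-indexed simulated omega values (NaN marks degenerate)."""

    values: np.ndarray
    reps: int
    seed: int
    model_name: str


@dataclass
class ReplicateResult:
    sites: SiteCounts
    mutations: MutationCounts
    dnds: DnDsResult
    skips: dict[str, int]


@dataclass
class ContextResult:
    """A full context-mode run: null distribution, per-replicate table, skips."""

    distribution: NullDistribution
    table: pd.DataFrame = field(repr=False)
    skip_report: dict
    n_variants: int


def load_variants(vcf_source: str, reference: dict[str, str]) -> tuple[list[Variant], dict[str, int]]:
    """Read usable biallelic SNVs from a VCF, checking REF against the FASTA.

    Indels, multiallelic records, symbolic alleles and REF/FASTA mismatches
    are skipped and tallied by category.  Raises if a VCF contig is missing
    from the reference or no usable variant remains.
    """
    skips = {c: 0 for c in SKIP_CATEGORIES}
    variants: list[Variant] = []
    total = 0
    for rec in VCF(str(vcf_source)):
        total += 1
        chrom = rec.CHROM
        if chrom not in reference:
            raise MissingContigError(f"VCF contig {chrom!r} absent from reference FASTA")
        alts = rec.ALT
        if not alts:
            skips["other"] += 1
            continue
        if len(alts) > 1:
            skips["multiallelic"] += 1
            continue
        ref, alt = rec.REF, alts[0]
        if alt.startswith("<") or any(c not in "ACGTacgt" for c in alt) or any(c not in "ACGTacgt" for c in ref):
            skips["symbolic"] += 1
            continue
        if len(ref) != 1 or len(alt) != 1:
            skips["indel"] += 1
            continue
        if reference[chrom][rec.POS - 1].upper() != ref.upper():
            skips["ref_mismatch"] += 1
            continue
        variants.append(Variant(chrom, rec.POS, ref.upper(), alt.upper()))
    if not variants:
        raise EmptyInputError(f"no usable biallelic SNVs in VCF ({total} records, skips: {skips})")
    assert len(variants) + sum(skips.values()) == total
    return variants, skips


def build_context_codon(reference: dict[str, str], variant: Variant, frame_index: int) -> ContextCodon:
    """Construct the codon around ``variant`` with its base at ``frame_index``.

    frame_index 0 places the variant first (codon = ref, +1, +2); 1 centers
    it; 2 places it last.  Raises a skip signal when a flank runs off the
    contig or contains an ambiguous base.
    """
    if frame_index not in (0, 1, 2):
        raise ParameterError(f"frame_index must be 0, 1 or 2, got {frame_index!r}")
    contig = reference[variant.chrom]
    p = variant.pos - 1  # to 0-based
    start = p - frame_index
    if start < 0 or start + 3 > len(contig):
        raise FlankOutOfBounds(f"{variant.chrom}:{variant.pos} frame {frame_index}: flank outside contig")
    codon = contig[start : start + 3].upper()
    if any(b not in "TCAG" for b in codon):
        raise AmbiguousFlank(f"{variant.chrom}:{variant.pos} frame {frame_index}: ambiguous base in codon {codon}")
    return ContextCodon(codon=codon, frame_index=frame_index, source=(variant.chrom, variant.pos))


def simulate_variant(
    context: ContextCodon, model: SubstitutionModel, rng: np.random.Generator
) -> tuple[ChangeClass, str]:
    """Draw one model substitution of the variant base and classify it."""
    if is_stop(context.codon):
        raise StopContext(f"context codon {context.codon} at {context.source} is a stop codon")
    ref = context.codon[context.frame_index]
    alt = sample_substitution(model, ref, rng)
    return classify_change(context.codon, context.frame_index, alt), alt


@dataclass
class _Compiled:
    """Per-(variant, frame) lookup tables for vectorized replicates."""

    n: int
    valid: np.ndarray  # (n, 3) bool
    reason: np.ndarray  # (n, 3) int8; 0 = ok
    site_n: np.ndarray  # (n, 3) float, variant-position N contribution
    site_s: np.ndarray  # (n, 3) float
    cls: np.ndarray  # (n, 3, 3) int8 class code per alternative
    cumv: np.ndarray  # (n, 3) cumulative alt probabilities (frame-independent)


def _compile(variants: list[Variant], reference: dict[str, str], model: SubstitutionModel) -> _Compiled:
    n = len(variants)
    valid = np.zeros((n, 3), dtype=bool)
    reason = np.zeros((n, 3), dtype=np.int8)
    site_n = np.zeros((n, 3))
    site_s = np.zeros((n, 3))
    cls = np.zeros((n, 3, 3), dtype=np.int8)
    cumv = np.zeros((n, 3))
    for vi, v in enumerate(variants):
        cumv[vi] = model._cum[v.ref_base]
        alts = model.alternatives(v.ref_base)
        for f in range(3):
            try:
                ctx = build_context_codon(reference, v, f)
                if is_stop(ctx.codon):
                    raise StopContext(ctx.codon)
            except (FlankOutOfBounds, AmbiguousFlank, StopContext) as skip:
                reason[vi, f] = _REASON_CODE[skip.category]
                continue
            valid[vi, f] = True
            for ai, alt in enumerate(alts):
                c = _CLS_CODE[classify_change(ctx.codon, f, alt)]
                cls[vi, f, ai] = c
                if c == _MIS:
                    site_n[vi, f] += 1.0 / 3.0
                elif c == _SYN:
                    site_s[vi, f] += 1.0 / 3.0
    return _Compiled(n, valid, reason, site_n, site_s, cls, cumv)


def _replicate(comp: _Compiled, rng: np.random.Generator) -> tuple[float, float, int, int, dict[str, int]]:
    """One vectorized replicate: (N, S, n_N, n_S, skip counts)."""
    idx = np.arange(comp.n)
    frames = rng.integers(0, 3, size=comp.n)
    u = rng.random(comp.n)
    valid = comp.valid[idx, frames]
    alt_idx = np.minimum((u[:, None] >= comp.cumv).sum(axis=1), 2)
    cls = comp.cls[idx, frames, alt_idx]
    n_N = int(((cls == _MIS) & valid).sum())
    n_S = int(((cls == _SYN) & valid).sum())
    N = float(comp.site_n[idx, frames][valid].sum())
    S = float(comp.site_s[idx, frames][valid].sum())
    reasons = comp.reason[idx, frames]
    skips = {name: int((reasons == code).sum()) for code, name in _REASON_NAME.items()}
    return N, S, n_N, n_S, skips


def run_replicate(
    variants: list[Variant],
    reference: dict[str, str],
    model: SubstitutionModel,
    rng: np.random.Generator,
) -> ReplicateResult:
    """One simulation replicate over all variants.

    Per variant: draw a uniform frame index, build the context codon (skip
    on bounds/ambiguity/stop), add the variant-position site fractions to
    (N, S), draw one model mutation and add weight 1 to n_N or n_S by its
    class (nonsense draws add nothing).
    """
    if not variants:
        raise EmptyInputError("run_replicate requires at least one variant")
    comp = _compile(variants, reference, model)
    N, S, n_N, n_S, skips = _replicate(comp, rng)
    sites = SiteCounts(N, S)
    muts = MutationCounts(n_N, n_S)
    if N == 0 and S == 0:
        dnds = DnDsResult(math.nan, math.nan, math.nan, True)
    else:
        dnds = compute_dnds(sites, muts)
    return ReplicateResult(sites=sites, mutations=muts, dnds=dnds, skips=skips)


def exact_expected_counts(
    variants: list[Variant], reference: dict[str, str], model: SubstitutionModel
) -> tuple[SiteCounts, MutationCounts]:
    """Analytic expectation of one replicate's aggregate counts.

    Marginalizes over the uniform frame index and the model's alternative
    distribution: invalid (skipped) frames contribute nothing, exactly as
    in :func:`run_replicate`.
    """
    if not variants:
        raise EmptyInputError("exact_expected_counts requires at least one variant")
    comp = _compile(variants, reference, model)
    probs = np.diff(comp.cumv, axis=1, prepend=0.0)  # (n, 3) alt probabilities
    w = comp.valid / 3.0  # frame weight, zero where skipped
    EN = float((comp.site_n * w).sum())
    ES = float((comp.site_s * w).sum())
    EnN = float((w[:, :, None] * probs[:, None, :] * (comp.cls == _MIS)).sum())
    EnS = float((w[:, :, None] * probs[:, None, :] * (comp.cls == _SYN)).sum())
    return SiteCounts(EN, ES), MutationCounts(EnN, EnS)


def simulate_null(
    variants: list[Variant],
    reference: dict[str, str],
    model: SubstitutionModel,
    reps: int,
    master_seed: int,
) -> ContextResult:
    """Run ``reps`` independent replicates with per-replicate derived seeds.

    Replicate i uses ``SeedSequence([master_seed, i])`` so each replicate is
    reproducible independently of run order.
    """
    if reps < 1:
        raise ParameterError(f"reps must be >= 1, got {reps}")
    if not variants:
        raise EmptyInputError("simulate_null requires at least one variant")
    comp = _compile(variants, reference, model)
    rows = []
    omegas = np.empty(reps)
    skip_totals = {c: 0 for c in CONTEXT_SKIP_CATEGORIES}
    for i in range(reps):
        rng = np.random.default_rng(np.random.SeedSequence([master_seed, i]))
        N, S, n_N, n_S, skips = _replicate(comp, rng)
        for c, k in skips.items():
            skip_totals[c] += k
        res = compute_dnds(SiteCounts(N, S), MutationCounts(n_N, n_S)) if (N or S) else DnDsResult(
            math.nan, math.nan, math.nan, True
        )
        omegas[i] = res.omega
        rows.append(
            {
                "replicate": i,
                "n_N": n_N,
                "n_S": n_S,
                "N": N,
                "S": S,
                "dN": res.d_n,
                "dS": res.d_s,
                "omega": res.omega,
            }
        )
    table = pd.DataFrame(rows)
    dist = NullDistribution(values=omegas, reps=reps, seed=master_seed, model_name=model.name)
    return ContextResult(
        distribution=dist,
        table=table,
        skip_report={"context": skip_totals},
        n_variants=len(variants),
    )


def run_context(
    vcf_source: str,
    reference: dict[str, str],
    model: SubstitutionModel,
    reps: int,
    master_seed: int,
) -> ContextResult:
    """Load variants from a VCF and build the null omega distribution."""
    variants, vcf_skips = load_variants(vcf_source, reference)
    result = simulate_null(variants, reference, model, reps, master_seed)
    result.skip_report = {"vcf": vcf_skips, **result.skip_report}
    return result
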