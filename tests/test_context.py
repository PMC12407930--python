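"""Context-mode variant loading, codon construction and null simulation."""
import math

import numpy as np
import pytest

from omegasim import (
    ChangeClass,
    Variant,
    build_context_codon,
    build_model,
    exact_expected_counts,
    load_variants,
    run_context,
    run_replicate,
    simulate_null,
    simulate_variant,
)
from omegasim.context import ContextCodon
from omegasim.errors import (
    AmbiguousFlank,
    EmptyInputError,
    FlankOutOfBounds,
    MissingContigError,
    ParameterError,
)

VCF_HEADER = "##fileformat=VCFv4.2\n##contig=<ID=c1,length=10>\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
CONTIG = "TACGATTGCA"


def _write_vcf(tmp_path, rows, header=VCF_HEADER):
    path = tmp_path / "test.vcf"
    path.write_text(header + "".join(r + "\n" for r in rows))
    return str(path)


class TestLoadVariants:
    def test_filters_and_skip_categories(self, tmp_path):
        rows = [
            "c1\t5\t.\tA\tG\t.\t.\t.",  # kept: FASTA base at pos 5 is A
            "c1\t2\t.\tAC\tA\t.\t.\t.",  # indel
            "c1\t3\t.\tC\tG,T\t.\t.\t.",  # multiallelic
            "c1\t4\t.\tG\t<DEL>\t.\t.\t.",  # symbolic
            "c1\t6\t.\tC\tG\t.\t.\t.",  # ref mismatch (FASTA has T)
        ]
        variants, skips = load_variants(_write_vcf(tmp_path, rows), {"c1": CONTIG})
        assert [(v.chrom, v.pos, v.ref_base, v.alt_base) for v in variants] == [("c1", 5, "A", "G")]
        assert skips == {"indel": 1, "multiallelic": 1, "symbolic": 1, "ref_mismatch": 1, "other": 0}
        assert len(variants) + sum(skips.values()) == len(rows)

    def test_empty_vcf_body_raises(self, tmp_path):
        with pytest.raises(EmptyInputError):
            load_variants(_write_vcf(tmp_path, []), {"c1": CONTIG})

    def test_missing_contig_raises(self, tmp_path):
        rows = ["c1\t5\t.\tA\tG\t.\t.\t."]
        with pytest.raises(MissingContigError):
            load_variants(_write_vcf(tmp_path, rows), {"other": CONTIG})


class TestBuildContextCodon:
    @pytest.mark.parametrize("frame, codon", [(0, "ATT"), (1, "GAT"), (2, "CGA")])
    def test_index_arithmetic_on_worked_contig(self, frame, codon):
        v = Variant("c1", 5, "A", "G")
        ctx = build_context_codon({"c1": CONTIG}, v, frame)
        assert ctx.codon == codon
        assert ctx.codon[ctx.frame_index] == "A"

    def test_out_of_bounds_flank(self):
        with pytest.raises(FlankOutOfBounds):
            build_context_codon({"c1": CONTIG}, Variant("c1", 1, "T", "A"), 2)
        with pytest.raises(FlankOutOfBounds):
            build_context_codon({"c1": CONTIG}, Variant("c1", 10, "A", "G"), 0)

    def test_ambiguous_flank(self):
        with pytest.raises(AmbiguousFlank):
            build_context_codon({"c1": "TANGA"}, Variant("c1", 2, "A", "G"), 0)

    def test_invalid_frame_index(self):
        with pytest.raises(ParameterError):
            build_context_codon({"c1": CONTIG}, Variant("c1", 5, "A", "G"), 3)


class TestSimulateVariant:
    def test_all_missense_context(self, jc69):
        ctx = ContextCodon("GAT", 1, ("c1", 5))
        rng = np.random.default_rng(1)
        for _ in range(60):
            cls, alt = simulate_variant(ctx, jc69, rng)
            assert cls is ChangeClass.MISSENSE
            assert alt != "A"

    def test_synonymous_fraction_matches_enumeration(self, jc69):
        # AAA at frame 2: AAG synonymous (1/3 under JC69), AAT/AAC missense
        ctx = ContextCodon("AAA", 2, ("c1", 1))
        rng = np.random.default_rng(8)
        n = 3000
        syn = sum(simulate_variant(ctx, jc69, rng)[0] is ChangeClass.SYNONYMOUS for _ in range(n))
        p = 1 / 3
        assert abs(syn / n - p) < 4 * math.sqrt(p * (1 - p) / n)

    def test_fixed_seed_identical_draws(self, k2p_ts_biased):
        ctx = ContextCodon("AAA", 2, ("c1", 1))
        draws1 = [simulate_variant(ctx, k2p_ts_biased, np.random.default_rng(5))[1] for _ in range(3)]
        draws2 = [simulate_variant(ctx, k2p_ts_biased, np.random.default_rng(5))[1] for _ in range(3)]
        assert draws1 == draws2


class TestExactExpectedCounts:
    def test_hand_enumerated_single_variant(self, jc69):
        """Variant at pos 5 of TACGATTGCA: frames give ATT/GAT/CGA.

        Under JC69 only the CGA frame (all three changes Arg->Arg) is
        synonymous, so E[n_S] = 1/3, E[S] = 1/3, E[n_N] = E[N] = 2/3.
        """
        ref = {"c1": CONTIG}
        variants = [Variant("c1", 5, "A", "G")]
        sites, muts = exact_expected_counts(variants, ref, jc69)
        assert sites.s_sites == pytest.approx(1 / 3)
        assert sites.n_sites == pytest.approx(2 / 3)
        assert muts.n_syn == pytest.approx(1 / 3)
        assert muts.n_nonsyn == pytest.approx(2 / 3)

    def test_jc69_expected_mutations_equal_expected_sites(self, context_inputs, jc69):
        sites, muts = exact_expected_counts(context_inputs["variants"], context_inputs["reference"], jc69)
        assert muts.n_nonsyn == pytest.approx(sites.n_sites, abs=1e-9)
        assert muts.n_syn == pytest.approx(sites.s_sites, abs=1e-9)

    def test_replicate_means_converge_to_expectation(self, context_inputs):
        """Monte-Carlo means over 2000 replicates within 4 SE of the oracle."""
        model = build_model("K2P", alpha=4.0, beta=1.0)
        variants, reference = context_inputs["variants"], context_inputs["reference"]
        exp_sites, exp_muts = exact_expected_counts(variants, reference, model)
        result = simulate_null(variants, reference, model, reps=2000, master_seed=77)
        for col, expected in (
            ("N", exp_sites.n_sites),
            ("S", exp_sites.s_sites),
            ("n_N", exp_muts.n_nonsyn),
            ("n_S", exp_muts.n_syn),
        ):
            observed = result.table[col].to_numpy(dtype=float)
            se = observed.std(ddof=1) / math.sqrt(len(observed))
            assert abs(observed.mean() - expected) < 4 * se, col


class TestReplicatesAndNull:
    def test_run_replicate_aggregates_and_skips(self, context_inputs, jc69):
        rng = np.random.default_rng(0)
        res = run_replicate(context_inputs["variants"], context_inputs["reference"], jc69, rng)
        used = len(context_inputs["variants"]) - sum(res.skips.values())
        assert used > 0
        assert res.mutations.n_nonsyn + res.mutations.n_syn <= used
        assert res.sites.n_sites + res.sites.s_sites <= used

    def test_all_contexts_invalid_gives_degenerate_empty_result(self, jc69):
        ref = {"c1": "NNNANNN"}
        res = run_replicate([Variant("c1", 4, "A", "G")], ref, jc69, np.random.default_rng(0))
        assert res.dnds.degenerate and math.isnan(res.dnds.omega)
        assert sum(res.skips.values()) == 1

    def test_no_variants_raises(self, jc69):
        with pytest.raises(EmptyInputError):
            run_replicate([], {"c1": CONTIG}, jc69, np.random.default_rng(0))

    def test_simulate_null_is_deterministic(self, context_inputs, jc69):
        args = (context_inputs["variants"], context_inputs["reference"], jc69)
        a = simulate_null(*args, reps=25, master_seed=123)
        b = simulate_null(*args, reps=25, master_seed=123)
        assert np.array_equal(a.distribution.values, b.distribution.values, equal_nan=True)
        assert a.table.equals(b.table)

    def test_different_master_seeds_differ(self, context_inputs, jc69):
        args = (context_inputs["variants"], context_inputs["reference"], jc69)
        a = simulate_null(*args, reps=25, master_seed=1)
        b = simulate_null(*args, reps=25, master_seed=2)
        assert not np.array_equal(a.distribution.values, b.distribution.values, equal_nan=True)

    def test_reps_validation(self, context_inputs, jc69):
        with pytest.raises(ParameterError):
            simulate_null(context_inputs["variants"], context_inputs["reference"], jc69, reps=0, master_seed=1)

    def test_single_replicate_distribution(self, context_inputs, jc69):
        res = simulate_null(context_inputs["variants"], context_inputs["reference"], jc69, reps=1, master_seed=4)
        assert res.distribution.values.shape == (1,)

    def test_run_context_reports_vcf_and_context_skips(self, context_inputs, jc69):
        res = run_context(str(context_inputs["vcf_path"]), context_inputs["reference"], jc69, reps=10, master_seed=9)
        assert res.skip_report["vcf"] == context_inputs["skips"]
        assert set(res.skip_report["context"]) == {"out_of_bounds", "ambiguous_flank", "stop_codon_context"}
        assert res.n_variants == len(context_inputs["variants"])

    def test_jc69_null_median_near_one(self, context_inputs, jc69):
        res = simulate_null(context_inputs["variants"], context_inputs["reference"], jc69, reps=200, master_seed=6)
        defined = res.distribution.values[~np.isnan(res.distribution.values)]
        assert 0.8 < np.median(defined) < 1.25  # tighter band checked at larger n in the acceptance suite
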