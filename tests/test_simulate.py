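"""Synthetic-data generator: determinism, gating, sampling distributions."""

import numpy as np
import pytest

from tph2_isoedit import (
    GenerationParams,
    generate_clone_library,
    generate_genotype_cohort,
    generate_individual,
    generate_kinetic_dataset,
    generate_table1_libraries,
    si_velocity_peak,
)
from tph2_isoedit.reference import ParameterError

RS_FREQS = {"rs4290270": {"AA": 0.25, "AT": 0.5, "TT": 0.25}, "rs7305115": {"AA": 1.0}}


class TestGenerateIndividual:
    def test_homozygous_freqs_fix_both_haplotypes(self, model):
        prof = generate_individual(
            "i1", "control", {"rs4290270": {"TT": 1.0}}, model, seed=1
        )
        idx = model.c_to_index(1125, "a")
        assert prof.haplotypes[0][idx] == prof.haplotypes[1][idx] == "T"

    def test_deterministic_under_seed(self, model):
        a = generate_individual("i1", "suicide", RS_FREQS, model, seed=11)
        b = generate_individual("i1", "suicide", RS_FREQS, model, seed=11)
        assert a == b

    def test_editing_sites_are_reference_in_genome(self, model):
        prof = generate_individual("i1", "control", RS_FREQS, model, seed=2)
        for v in model.variant_catalogue:
            if v.site_class != "editing_candidate":
                continue
            pos = v.c_pos if v.isoform_scope != "b-only" else model.b_to_a_pos(v.c_pos)
            idx = model.c_to_index(pos, "a")
            assert prof.haplotypes[0][idx] == prof.haplotypes[1][idx] == v.ref_base

    def test_genotype_frequencies_respected(self, model):
        n = 3000
        draws = [
            generate_individual(f"i{k}", "control", RS_FREQS, model, seed=k)
            .genotype("rs4290270")
            for k in range(n)
        ]
        frac_aa = sum(1 for g in draws if g == ("A", "A")) / n
        # 3 sigma binomial envelope around 0.25
        assert abs(frac_aa - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n)

    def test_invalid_frequencies_raise(self, model):
        with pytest.raises(ParameterError):
            generate_individual("i", "control", {"rs4290270": {"AA": 0.4}}, model, seed=0)
        with pytest.raises(ParameterError):
            generate_individual("i", "not_a_group", RS_FREQS, model, seed=0)


class TestCloneLibrary:
    def test_gating_homozygous_blocked_allele(self, model):
        prof = generate_individual("i", "control", {"rs4290270": {"AA": 1.0}}, model, seed=3)
        params = GenerationParams(
            n_clones=300, splice_fraction_b=0.9,
            editing_probs={"a": (1.0,) * 4, "b": (1.0,) * 4},
            gating=True, permissive_allele="T", error_rate=0.0, seed=4,
        )
        _, _, truth = generate_clone_library(model, prof, "amygdala", params)
        assert (truth["isoform"] == "a").all()
        assert (truth["edited_indices"] == "").all()

    def test_probability_one_fully_edits_every_clone(self, model):
        prof = generate_individual("i", "control", {"rs4290270": {"TT": 1.0}}, model, seed=3)
        params = GenerationParams(
            n_clones=50, splice_fraction_b=1.0,
            editing_probs={"b": (1.0,) * 4, "a": (0.0,) * 4},
            error_rate=0.0, seed=5,
        )
        _, _, truth = generate_clone_library(model, prof, "pons", params)
        assert (truth["isoform"] == "b").all()
        assert (truth["edited_indices"] == "1234").all()

    def test_edited_fractions_match_probabilities_binomially(self, model):
        probs = (0.78, 0.96, 0.96, 0.96)
        prof = generate_individual("i", "control", {"rs4290270": {"TT": 1.0}}, model, seed=6)
        params = GenerationParams(
            n_clones=1000, splice_fraction_b=1.0,
            editing_probs={"b": probs, "a": (0.0,) * 4},
            error_rate=0.0, seed=7,
        )
        _, _, truth = generate_clone_library(model, prof, "amygdala", params)
        for i, p in enumerate(probs, start=1):
            frac = truth["edited_indices"].str.contains(str(i)).mean()
            assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / 1000)

    def test_byte_reproducible(self, model):
        prof = generate_individual("i", "drug_abuse", RS_FREQS, model, seed=8)
        params = GenerationParams(n_clones=20, seed=9)
        r1, m1, t1 = generate_clone_library(model, prof, "amygdala", params)
        r2, m2, t2 = generate_clone_library(model, prof, "amygdala", params)
        assert r1 == r2 and m1.equals(m2) and t1.equals(t2)

    def test_error_rate_produces_substitutions(self, model):
        prof = generate_individual("i", "control", {"rs4290270": {"TT": 1.0}}, model, seed=3)
        params = GenerationParams(
            n_clones=200, splice_fraction_b=0.0, editing_probs={"a": (0.0,) * 4},
            error_rate=1e-3, seed=10,
        )
        recs, _, truth = generate_clone_library(model, prof, "amygdala", params)
        total = truth["n_seq_errors"].sum()
        L = len(recs[0][1])
        expected = 200 * L * 1e-3
        assert 0 < total < 3 * expected
        # errors really are in the sequences
        rid, seq = recs[truth["n_seq_errors"].idxmax()]
        assert seq != model.transcript_a

    def test_table1_scenario_counts(self, model):
        recs, manifest, truth, profiles = generate_table1_libraries(model, seed=1)
        assert len(recs) == 48 + 17 + 27 + 8 + 19 + 11
        amy_b = truth[(truth["region"] == "amygdala") & (truth["isoform"] == "b")]
        assert len(amy_b) == 27 and (amy_b["allele_origin"] == "A").all()


class TestKineticGenerator:
    def test_half_saturation_at_km(self):
        ds = generate_kinetic_dataset("MM", 100, 1.0, [100.0], 0.0, 1, seed=0)
        assert ds.v[0] == pytest.approx(0.5)

    def test_si_with_huge_ki_matches_mm(self):
        grid = np.geomspace(10, 600, 8)
        mm = generate_kinetic_dataset("MM", 50, 1.0, grid, 0.05, 2, seed=42)
        si = generate_kinetic_dataset("SI", 50, 1.0, grid, 0.05, 2, seed=42, ki=1e12)
        np.testing.assert_allclose(mm.v, si.v, rtol=1e-8)

    def test_si_velocity_peaks_at_sqrt_km_ki(self):
        km, ki = 50.0, 200.0
        peak = si_velocity_peak(km, ki)
        assert peak == pytest.approx(100.0)
        grid = np.linspace(10, 600, 400)
        ds = generate_kinetic_dataset("SI", km, 1.0, grid, 0.0, 1, seed=0, ki=ki)
        assert abs(grid[np.argmax(ds.v)] - peak) < 5.0

    def test_missing_ki_raises(self):
        with pytest.raises(ParameterError):
            generate_kinetic_dataset("SI", 50, 1.0, [10, 100], 0.0, 1, seed=0)

    def test_noise_cv_scale(self):
        ds = generate_kinetic_dataset("MM", 100, 1.0, [100.0], 0.05, 4000, seed=1)
        cv = ds.v.std() / ds.v.mean()
        assert abs(cv - 0.05) < 0.01


class TestGenotypeCohort:
    def test_fixed_allele(self):
        c = generate_genotype_cohort(0.0, 100, seed=0)
        assert (c.n_AA, c.n_AT, c.n_TT) == (0, 0, 100)

    def test_het_fraction_under_hwe(self):
        c = generate_genotype_cohort(0.5, 100_000, seed=1)
        assert abs(c.n_AT / c.n - 0.5) < 3 * np.sqrt(0.25 / 100_000)

    def test_seed_determinism_and_bad_p(self):
        assert generate_genotype_cohort(0.3, 500, seed=7) == generate_genotype_cohort(
            0.3, 500, seed=7
        )
        with pytest.raises(ParameterError):
            generate_genotype_cohort(1.5, 10, seed=0)
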