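"""The generators must reproduce their configured ground truth."""

import io as _io

import numpy as np
import pytest

from relicdx import io
from relicdx.authentication import compute_misincorporation_profile
from relicdx.synthetic_data import (
    DamageModelConfig,
    PanelConfig,
    PlantedPair,
    PlantedVariant,
    VariantTableConfig,
    random_reference,
    simulate_adna_fragments,
    simulate_haplotype_panel,
    simulate_mt_pileup,
    simulate_sexed_alignment_counts,
    simulate_variant_table,
)
from tests.conftest import binomial_se


class TestDamagedFragments:
    def test_damage_disabled_means_no_mismatches(self, reference_50k):
        cfg = DamageModelConfig(terminal_ct_rate=0.0, seed=7)
        reads, _, truth = simulate_adna_fragments(cfg, reference_50k, 1000)
        assert all(not r["damage_positions_5p"] and not r["damage_positions_3p"]
                   for r in truth["reads"])
        prof = compute_misincorporation_profile(reads, {"chr1": reference_50k}, window=10)
        assert np.nansum(prof.five_prime_ct) == 0.0
        assert np.nansum(prof.three_prime_ga) == 0.0

    def test_empirical_frequencies_follow_decay_law(self, reference_50k):
        # position i carries damage probability rate * decay**(i-1)
        cfg = DamageModelConfig(terminal_ct_rate=0.3, decay=0.5, seed=11)
        reads, _, _ = simulate_adna_fragments(cfg, reference_50k, 100_000)
        prof = compute_misincorporation_profile(reads, {"chr1": reference_50k}, window=4)
        for i, expected in enumerate([0.3, 0.15, 0.075, 0.0375]):
            se = binomial_se(expected, prof.five_prime_opportunities[i])
            assert abs(prof.five_prime_ct[i] - expected) < 3 * se
            se3 = binomial_se(expected, prof.three_prime_opportunities[i])
            assert abs(prof.three_prime_ga[i] - expected) < 3 * se3

    def test_partial_udg_confines_damage_to_terminal_base(self, reference_50k):
        cfg = DamageModelConfig(terminal_ct_rate=0.1, udg_mode="partial", seed=13)
        reads, _, truth = simulate_adna_fragments(cfg, reference_50k, 50_000)
        assert all(set(r["damage_positions_5p"]) <= {1} and
                   set(r["damage_positions_3p"]) <= {1} for r in truth["reads"])
        prof = compute_misincorporation_profile(reads, {"chr1": reference_50k}, window=6)
        assert prof.five_prime_ct[0] > 0.05
        assert np.nansum(prof.five_prime_ct[1:]) == 0.0

    def test_contaminant_fragments_carry_no_damage(self, reference_50k):
        cfg = DamageModelConfig(terminal_ct_rate=0.5, contamination_fraction=0.3, seed=3)
        _, _, truth = simulate_adna_fragments(cfg, reference_50k, 5000)
        frac = truth["n_contaminant"] / 5000
        assert abs(frac - 0.3) < 3 * binomial_se(0.3, 5000)
        for r in truth["reads"]:
            if r["contaminant"]:
                assert not r["damage_positions_5p"] and not r["damage_positions_3p"]

    def test_mean_fragment_length_is_recovered(self, reference_50k):
        cfg = DamageModelConfig(mean_fragment_length=90, length_dispersion=0.25, seed=5)
        _, _, truth = simulate_adna_fragments(cfg, reference_50k, 20_000)
        lengths = np.array([r["length"] for r in truth["reads"]])
        se = lengths.std() / np.sqrt(lengths.size)
        assert abs(lengths.mean() - 90) < 3 * se

    def test_invalid_inputs_raise(self, reference_50k):
        with pytest.raises(ValueError):
            simulate_adna_fragments(DamageModelConfig(), reference_50k, 0)
        with pytest.raises(ValueError):
            simulate_adna_fragments(DamageModelConfig(), "", 10)
        with pytest.raises(ValueError):
            DamageModelConfig(contamination_fraction=1.5)
        with pytest.raises(ValueError):
            DamageModelConfig(decay=0.0)

    def test_fixed_seed_gives_byte_identical_sam(self, reference_50k, tmp_path):
        out = []
        for name in ("a.sam", "b.sam"):
            cfg = DamageModelConfig(terminal_ct_rate=0.1, seed=42)
            reads, header, _ = simulate_adna_fragments(cfg, reference_50k, 500)
            io.write_sam(reads, header, tmp_path / name)
            out.append((tmp_path / name).read_bytes())
        assert out[0] == out[1]


class TestSexedCounts:
    def test_female_without_mismapping_has_no_y_reads(self):
        c = simulate_sexed_alignment_counts("XX", 1000, seed=1, female_mismap_rate=0.0)
        assert c["nY"] == 0

    def test_male_ry_lands_in_xy_band(self):
        c = simulate_sexed_alignment_counts("XY", 100_000, seed=2)
        ry = c["nY"] / (c["nX"] + c["nY"])
        assert 0.075 < ry < 0.12

    def test_female_ry_stays_below_xx_cutoff(self):
        c = simulate_sexed_alignment_counts("XX", 100_000, seed=3)
        assert c["nY"] / (c["nX"] + c["nY"]) < 0.016

    def test_unknown_sex_label_rejected(self):
        with pytest.raises(ValueError):
            simulate_sexed_alignment_counts("XYY", 100)


class TestMtPileup:
    def test_pure_endogenous_and_pure_contaminant_extremes(self):
        pile, _ = simulate_mt_pileup(0.0, depth=50, n_diagnostic_sites=10,
                                     error_rate=0.0, seed=1)
        assert all(row.bases == row.endo * 50 for row in pile.itertuples())
        pile, _ = simulate_mt_pileup(1.0, depth=50, n_diagnostic_sites=10,
                                     error_rate=0.0, seed=1)
        assert all(row.bases == row.cont * 50 for row in pile.itertuples())

    def test_contaminant_base_fraction_matches_mixture(self):
        pile, truth = simulate_mt_pileup(0.02, depth=500, n_diagnostic_sites=50, seed=9)
        frac = truth["n_contaminant_bases"] / truth["n_bases"]
        assert abs(frac - 0.02) < 3 * binomial_se(0.02, truth["n_bases"])


class TestVariantTable:
    def test_truth_and_planted_pair_bookkeeping(self):
        variants, truth = simulate_variant_table(VariantTableConfig(seed=21))
        keys = {v.key for v in variants}
        assert set(truth["annotated_retained"]) <= keys
        assert set(truth["predicted_retained"]) <= keys
        # the two pipelines target disjoint annotation states
        assert not set(truth["annotated_retained"]) & set(truth["predicted_retained"])
        assert set(truth["planted_pair_keys"]) <= set(truth["annotated_retained"])

    def test_without_background_classes_only_planted_pair_is_annotated(self):
        cfg = VariantTableConfig(fraction_clinical=0.0, seed=22)
        _, truth = simulate_variant_table(cfg)
        assert sorted(truth["planted_pair_keys"]) == truth["annotated_retained"]

    def test_modifier_planting_counts(self):
        _, truth = simulate_variant_table(VariantTableConfig(seed=23))
        assert truth["modifier"]["ATP6"]["rare"] == 6
        assert truth["modifier"]["RUNX1"]["rare"] == 1
        assert truth["modifier_common_total"] == 28

    def test_planted_pair_incompatible_with_tiny_table(self):
        with pytest.raises(ValueError):
            VariantTableConfig(n_variants=5)

    def test_vcf_roundtrip_preserves_annotations(self, tmp_path):
        variants, _ = simulate_variant_table(VariantTableConfig(n_variants=60, seed=24))
        io.write_variant_vcf(variants, tmp_path / "v.vcf")
        back = io.read_variant_vcf(tmp_path / "v.vcf")
        orig = {v.key: v for v in variants}
        assert set(orig) == {v.key for v in back}
        for v in back:
            o = orig[v.key]
            assert v.genotype == o.genotype and v.gene == o.gene
            assert v.hgmd == o.hgmd and v.effect == o.effect
            for db, f in o.pop_freqs.items():
                if f is None:
                    assert v.pop_freqs[db] is None
                else:
                    assert v.pop_freqs[db] == pytest.approx(f, rel=1e-5)

    def test_tsv_roundtrip(self, tmp_path):
        variants, _ = simulate_variant_table(VariantTableConfig(n_variants=60, seed=25))
        io.write_variant_tsv(variants, tmp_path / "v.tsv")
        back = io.read_variant_tsv(tmp_path / "v.tsv")
        assert {v.key for v in back} == {v.key for v in variants}
        assert {v.key: v.clinvar for v in back} == {v.key: v.clinvar for v in variants}


class TestHaplotypePanel:
    def test_no_recombination_makes_carriers_identical(self):
        cfg = PanelConfig(n_haplotypes=100, recomb_rate=0.0, seed=31)
        panel, truth = simulate_haplotype_panel(cfg)
        carriers = panel.alleles[truth["carrier_indices"]]
        assert (carriers == carriers[0]).all()

    def test_query_allele_absent_in_trans_present_on_carriers_in_cis(self):
        cfg = PanelConfig(n_haplotypes=100, planted_configuration="trans", seed=32)
        panel, truth = simulate_haplotype_panel(cfg)
        assert panel.site_index(truth["query"]["pos"]) is None
        cfg = PanelConfig(n_haplotypes=100, planted_configuration="cis", seed=32)
        panel, truth = simulate_haplotype_panel(cfg)
        q = panel.site_index(truth["query"]["pos"])
        assert q is not None
        assert (panel.alleles[truth["carrier_indices"], q] == 1).all()
        non_carriers = np.setdiff1d(np.arange(cfg.n_haplotypes), truth["carrier_indices"])
        assert (panel.alleles[non_carriers, q] == 0).all()

    def test_anchor_frequency_is_respected(self):
        cfg = PanelConfig(n_haplotypes=500, anchor_frequency=0.03, seed=33)
        panel, truth = simulate_haplotype_panel(cfg)
        a = panel.site_index(truth["anchor"]["pos"])
        assert int((panel.alleles[:, a] == 1).sum()) == 15

    def test_no_carriers_rejected(self):
        with pytest.raises(ValueError):
            PanelConfig(n_haplotypes=10, anchor_frequency=0.01)

    def test_fixed_seed_gives_byte_identical_panel_vcf(self, tmp_path):
        out = []
        for name in ("a.vcf", "b.vcf"):
            panel, _ = simulate_haplotype_panel(PanelConfig(n_haplotypes=50, seed=44))
            io.write_panel_vcf(panel, tmp_path / name)
            out.append((tmp_path / name).read_bytes())
        assert out[0] == out[1]

    def test_panel_vcf_roundtrip(self, tmp_path):
        panel, _ = simulate_haplotype_panel(PanelConfig(n_haplotypes=50, seed=45))
        io.write_panel_vcf(panel, tmp_path / "p.vcf")
        back = io.read_panel_vcf(tmp_path / "p.vcf")
        assert np.array_equal(back.positions, panel.positions)
        assert np.array_equal(back.alleles, panel.alleles)
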