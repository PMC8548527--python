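"""Prioritization pipelines: rule examples, truth recovery, invariants."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from relicdx.prioritization import (
    AnnotatedVariant,
    PrioritizationConfig,
    annotated_pipeline,
    clinical_intersection,
    clinvar_category,
    modifier_scan,
    predicted_pipeline,
    recessive_candidates,
)
from relicdx.synthetic_data import (
    PlantedPair,
    PlantedVariant,
    VariantTableConfig,
    simulate_variant_table,
)


def _var(pos=1, **kw):
    base = dict(
        chrom="chr1", pos=pos, ref="A", alt="G", genotype="het", gene="G1",
        effect="Missense", region="exonic", clinvar=None, hgmd=None,
        pop_freqs={"1000G": None, "gnomAD": None, "ESP": None},
        internal_freq=None, fg_freq=None,
        predictor_calls={t: "tolerated" for t in
                         ("SIFT", "Polyphen2", "MutationTaster",
                          "MutationAssessor", "FATHMM")},
    )
    base.update(kw)
    return AnnotatedVariant(**base)


def _damaging(n):
    tools = ("SIFT", "Polyphen2", "MutationTaster", "MutationAssessor", "FATHMM")
    return {t: ("damaging" if i < n else "tolerated") for i, t in enumerate(tools)}


class TestClinVarMapping:
    @pytest.mark.parametrize(
        "label,cat",
        [
            ("Pathogenic", "retained"),
            ("Pathogenic/Likely pathogenic", "retained"),
            ("Uncertain significance", "retained"),
            ("Conflicting interpretations of pathogenicity", "retained"),
            ("Benign/Likely benign", "benign"),
            ("Likely benign", "benign"),
            (None, "none"),
        ],
    )
    def test_label_categories(self, label, cat):
        assert clinvar_category(label) == cat


class TestAnnotatedPipeline:
    def test_pathogenic_dm_ultra_rare_retained_and_flagged(self):
        v = _var(clinvar="Pathogenic/Likely pathogenic", hgmd="DM",
                 pop_freqs={"1000G": 1.5e-5, "gnomAD": 9e-6, "ESP": None})
        out = annotated_pipeline([v])
        assert out.keys == {v.key}
        assert out.rare_flags[v.key]
        assert set(out.provenance[v.key]) == {"clinvar-retained-class", "hgmd-dm"}

    def test_benign_dmq_retained_via_hgmd_arm_with_rare_flag(self):
        # benign in ClinVar but DM? in HGMD at 3% (< 5%) stays in play
        v = _var(clinvar="Benign/Likely benign", hgmd="DM?",
                 pop_freqs={"1000G": 0.03, "gnomAD": 0.03, "ESP": 0.03})
        out = annotated_pipeline([v])
        assert out.keys == {v.key}
        assert out.provenance[v.key] == ["hgmd-dm"]
        assert out.rare_flags[v.key]

    def test_benign_without_hgmd_excluded(self):
        assert annotated_pipeline([_var(clinvar="Benign")]).keys == set()

    def test_missing_frequency_is_not_evidence_of_commonness(self):
        v = _var(clinvar="Pathogenic")  # absent from every database
        out = annotated_pipeline([v])
        assert out.rare_flags[v.key]

    @given(st.floats(0.05, 0.95), st.floats(0.001, 0.049))
    def test_raising_flag_threshold_never_unflags(self, higher, freq):
        v = _var(clinvar="Pathogenic", pop_freqs={"1000G": freq, "gnomAD": None,
                                                  "ESP": None})
        lo = annotated_pipeline([v], PrioritizationConfig())
        hi = annotated_pipeline(
            [v], PrioritizationConfig(annotated_maf_flag_threshold=max(higher, 0.051))
        )
        if lo.rare_flags[v.key]:
            assert hi.rare_flags[v.key]


class TestPredictedPipeline:
    def test_qualifying_variant_retained_and_flagged(self):
        v = _var(predictor_calls=_damaging(3), fg_freq=0.01,
                 pop_freqs={"1000G": 0.005, "gnomAD": 0.005, "ESP": None})
        out = predicted_pipeline([v])
        assert out.keys == {v.key} and out.rare_flags[v.key]

    def test_two_damaging_calls_insufficient(self):
        assert predicted_pipeline([_var(predictor_calls=_damaging(2))]).keys == set()

    def test_intronic_and_clinically_classified_excluded(self):
        assert predicted_pipeline(
            [_var(region="other", predictor_calls=_damaging(5))]
        ).keys == set()
        assert predicted_pipeline(
            [_var(clinvar="Benign", predictor_calls=_damaging(5))]
        ).keys == set()
        assert predicted_pipeline(
            [_var(hgmd="DM", predictor_calls=_damaging(5))]
        ).keys == set()

    def test_fg_frequency_gate(self):
        assert predicted_pipeline([_var(predictor_calls=_damaging(4),
                                        fg_freq=0.02)]).keys == set()
        assert predicted_pipeline([_var(predictor_calls=_damaging(4),
                                        fg_freq=0.019)]).keys != set()

    def test_disjoint_from_annotated_pipeline(self):
        variants, _ = simulate_variant_table(VariantTableConfig(seed=91))
        ann = annotated_pipeline(variants)
        pred = predicted_pipeline(variants)
        assert not ann.keys & pred.keys


class TestTruthRecovery:
    @pytest.mark.parametrize("seed", range(10))
    def test_retained_sets_equal_generator_truth(self, seed):
        variants, truth = simulate_variant_table(VariantTableConfig(seed=seed))
        ann = annotated_pipeline(variants)
        pred = predicted_pipeline(variants)
        assert sorted(ann.keys) == truth["annotated_retained"]
        assert sorted(pred.keys) == truth["predicted_retained"]
        assert sorted(k for k, f in ann.rare_flags.items() if f) == truth["annotated_rare"]
        assert sorted(k for k, f in pred.rare_flags.items() if f) == truth["predicted_rare"]


class TestClinicalIntersection:
    def test_set_arithmetic(self):
        v1 = _var(pos=1, clinvar="Pathogenic")
        v2 = _var(pos=2, clinvar="Pathogenic", hgmd="DM")
        v3 = _var(pos=3, hgmd="DM?")
        inter = clinical_intersection(annotated_pipeline([v1, v2, v3]))
        assert inter.counts["clinvar"] == 2
        assert inter.counts["hgmd"] == 2
        assert inter.counts["both"] == 1
        assert not inter.severity_filtered

    def test_counts_match_generator_truth(self):
        variants, truth = simulate_variant_table(VariantTableConfig(seed=92))
        inter = clinical_intersection(annotated_pipeline(variants))
        assert sorted(v.key for v in inter.both) == truth["both_members"]
        assert inter.counts["clinvar"] == len(truth["clinvar_members"])
        assert inter.counts["hgmd"] == len(truth["hgmd_members"])

    def test_empty_set(self):
        inter = clinical_intersection(annotated_pipeline([]))
        assert inter.counts == {"clinvar": 0, "hgmd": 0, "both": 0, "rare_clinical": 0}

    def test_severity_lookup_restricts_rare_clinical(self):
        v = _var(clinvar="Pathogenic", gene="GAA")
        w = _var(pos=2, clinvar="Pathogenic", gene="OTHER")
        ann = annotated_pipeline([v, w])
        inter = clinical_intersection(ann, severity_lookup={"GAA": True})
        assert [x.key for x in inter.rare_clinical] == [v.key]
        assert inter.severity_filtered


class TestRecessiveCandidates:
    def test_planted_het_pair_yields_compound_het_candidate(self):
        variants, truth = simulate_variant_table(VariantTableConfig(seed=93))
        inter = clinical_intersection(annotated_pipeline(variants))
        cands = recessive_candidates(inter.rare_clinical)
        gaa = [c for c in cands if c.gene == "GAA"]
        assert len(gaa) == 1 and gaa[0].mechanism == "possible-compound-het"
        assert sorted(v.key for v in gaa[0].variants) == sorted(truth["planted_pair_keys"])

    def test_single_het_is_no_candidate_and_hom_is(self):
        assert recessive_candidates([_var(clinvar="Pathogenic")]) == []
        cands = recessive_candidates([_var(clinvar="Pathogenic", genotype="hom")])
        assert len(cands) == 1 and cands[0].mechanism == "homozygous"

    def test_homozygous_planted_pair_reports_homozygous_mechanism(self):
        pair = PlantedPair(
            first=PlantedVariant(clinvar="Pathogenic/Likely pathogenic",
                                 hgmd="DM", freq=1.5e-5, genotype="hom"),
            second=PlantedVariant(clinvar="Benign/Likely benign",
                                  hgmd="DM?", freq=0.03, genotype="hom"),
        )
        variants, _ = simulate_variant_table(
            VariantTableConfig(planted_pair=pair, fraction_clinical=0.0, seed=94)
        )
        inter = clinical_intersection(annotated_pipeline(variants))
        mechanisms = {c.mechanism for c in recessive_candidates(inter.rare_clinical)
                      if c.gene == "GAA"}
        assert mechanisms == {"homozygous"}


class TestModifierScan:
    def test_planted_counts_reproduced(self):
        variants, _ = simulate_variant_table(VariantTableConfig(seed=95))
        report = modifier_scan(variants)
        assert report["per_gene"]["ATP6"]["rare"] == 6
        assert report["per_gene"]["RUNX1"]["rare"] == 1
        assert report["common_total"] == 28

    def test_empty_gene_list_gives_empty_report(self):
        variants, _ = simulate_variant_table(VariantTableConfig(seed=96))
        report = modifier_scan(variants, modifier_genes=())
        assert report["per_gene"] == {} and report["rare_total"] == 0

    def test_frequency_exactly_at_threshold_is_rare(self):
        v = _var(gene="ATP6", pop_freqs={"1000G": 0.05, "gnomAD": None, "ESP": None})
        report = modifier_scan([v], modifier_genes=("ATP6",))
        assert report["per_gene"]["ATP6"] == {"rare": 1, "common": 0}
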