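"""Medal rules: archetypes, the frequency gate, aggregation, monotonicity."""

from __future__ import annotations

import itertools

from medaltriage.config import Config
from medaltriage.knowledgebase import (
    CuratedVariantRecord,
    HotspotRecord,
    Knowledgebase,
    PopulationFrequencies,
    PredictionProfile,
)
from medaltriage.medal_engine import (
    GateStatus,
    Medal,
    aggregate_prediction,
    assign_germline_medal,
    assign_medals,
    assign_somatic_medal,
)
from medaltriage.nomenclature import ProteinChange
from medaltriage.oracles import aggregate_prediction_oracle, medal_oracle, somatic_medal_oracle
from medaltriage.variants import Consequence, GeneMeta, GenomicVariant, TranscriptAnnotation

from tests.battery import build_battery


def _variant(pos=1000):
    return GenomicVariant("1", pos, "A", "G")


def _ann(consequence=Consequence.MISSENSE, gene="G1", protein=None, codon=None):
    return TranscriptAnnotation(
        gene=gene, transcript="NM_1", consequence=consequence,
        protein_change=protein, codon=codon or (protein.codon if protein else None),
    )


_EMPTY = Knowledgebase()
_NO_FREQ = PopulationFrequencies()
_NO_PRED = PredictionProfile()


def test_truncating_in_lof_gene_is_gold(default_cfg):
    """A novel nonsense variant in a loss-of-function gene medals gold."""
    result = assign_germline_medal(
        _variant(), _ann(Consequence.NONSENSE, protein=ProteinChange("R", 359, "*")),
        _NO_FREQ, _NO_PRED, _EMPTY, GeneMeta("G1", is_lof_gene=True), default_cfg,
    )
    assert result.germline_medal is Medal.GOLD
    assert result.gate_status is GateStatus.PASSED
    assert any(r.rule_id == "truncating_in_lof_gene" for r in result.reasons)


def test_dual_medal_clinvar_silver_somatic_bronze(default_cfg):
    """A curated germline match medals silver while the somatic call is bronze."""
    v = _variant()
    record = CuratedVariantRecord(
        "CLINVAR", genomic_key=v.key, gene="G1", call="P",
        raw_call="Pathogenic", stars=1,
    )
    kb = Knowledgebase(curated=[record])
    ann = _ann(protein=ProteinChange("R", 1350, "L"))
    pred = PredictionProfile(calls=(("Polyphen2", "tolerated"), ("SIFT", "tolerated")))
    result = assign_medals(
        v, ann, _NO_FREQ, pred, kb, GeneMeta("G1"), default_cfg
    )
    assert result.germline_medal is Medal.SILVER
    assert result.somatic_medal is Medal.BRONZE


def test_gate_arithmetic_and_rescue(default_cfg):
    v = _variant()
    ann = _ann()
    pf = PopulationFrequencies(exac_nontcga=0.002)
    pred = PredictionProfile(revel=0.9)

    failed = assign_germline_medal(v, ann, pf, pred, _EMPTY, None, default_cfg)
    assert failed.germline_medal is Medal.UNKNOWN
    assert failed.gate_status is GateStatus.FAILED_FREQUENCY

    kb = Knowledgebase(
        curated=[CuratedVariantRecord("IARC_TP53", genomic_key=v.key, gene="G1")]
    )
    rescued = assign_germline_medal(v, ann, pf, pred, kb, None, default_cfg)
    assert rescued.gate_status is GateStatus.RESCUED_BY_EXCEPTION
    # Once rescued, every rule applies: IARC exact match medals gold.
    assert rescued.germline_medal is Medal.GOLD


def test_gate_boundary_inclusive(default_cfg):
    """Frequency equal to the cutoff passes; any greater value fails."""
    v, ann = _variant(), _ann()
    pred = PredictionProfile(revel=0.9)
    at = assign_germline_medal(
        v, ann, PopulationFrequencies(exac_nontcga=default_cfg.max_af),
        pred, _EMPTY, None, default_cfg,
    )
    assert at.gate_status is GateStatus.PASSED
    assert at.germline_medal is Medal.SILVER
    above = assign_germline_medal(
        v, ann, PopulationFrequencies(exac_nontcga=default_cfg.max_af + 1e-9),
        pred, _EMPTY, None, default_cfg,
    )
    assert above.gate_status is GateStatus.FAILED_FREQUENCY


def test_gate_disabled_makes_frequencies_irrelevant():
    cfg = Config(max_af=None)
    v, ann = _variant(), _ann()
    pred = PredictionProfile(revel=0.9)
    medals = {
        assign_germline_medal(
            v, ann, PopulationFrequencies(exac_nontcga=f), pred, _EMPTY, None, cfg
        ).germline_medal
        for f in [None, 0.0, 0.0005, 0.001, 0.01, 0.2, 0.9]
    }
    assert medals == {Medal.SILVER}


def test_blacklist_forces_unknown_despite_evidence(default_cfg):
    v = _variant()
    result = assign_germline_medal(
        v, _ann(Consequence.NONSENSE, protein=ProteinChange("R", 10, "*")),
        _NO_FREQ, _NO_PRED, _EMPTY, GeneMeta("G1", is_lof_gene=True), default_cfg,
        blacklist={v.key},
    )
    assert result.germline_medal is Medal.UNKNOWN
    assert result.gate_status is GateStatus.BLACKLISTED


def test_whitelist_grants_gold_and_skips_gate(default_cfg):
    v = _variant()
    result = assign_germline_medal(
        v, _ann(), PopulationFrequencies(exac_nontcga=0.01), _NO_PRED,
        _EMPTY, None, default_cfg, whitelist={v.key},
    )
    assert result.germline_medal is Medal.GOLD
    assert result.gate_status is GateStatus.WHITELISTED


def test_imperfect_match_downgraded_one_tier(default_cfg):
    v = _variant()
    ann = _ann(protein=ProteinChange("G", 12, "S"))
    gold_tier_imperfect = Knowledgebase(
        curated=[CuratedVariantRecord(
            "CLINVAR", gene="G1", protein_change=ProteinChange("G", 12, "D"),
            call="P", raw_call="Pathogenic", stars=3,
        )]
    )
    result = assign_germline_medal(
        v, ann, _NO_FREQ, _NO_PRED, gold_tier_imperfect, None, default_cfg
    )
    assert result.germline_medal is Medal.SILVER

    silver_tier_imperfect = Knowledgebase(
        curated=[CuratedVariantRecord(
            "ALSOD", gene="G1", protein_change=ProteinChange("G", 12, "D"),
        )]
    )
    result = assign_germline_medal(
        v, ann, _NO_FREQ, _NO_PRED, silver_tier_imperfect, None, default_cfg
    )
    assert result.germline_medal is Medal.BRONZE


def test_missing_gene_meta_never_silently_gold(default_cfg):
    result = assign_germline_medal(
        _variant(), _ann(Consequence.NONSENSE, protein=ProteinChange("R", 10, "*")),
        _NO_FREQ, _NO_PRED, _EMPTY, None, default_cfg,
    )
    assert result.germline_medal is Medal.SILVER  # truncating in (assumed) non-LoF


def test_somatic_hotspot_direct_vs_imperfect(default_cfg):
    v = _variant()
    kb = Knowledgebase(
        hotspots=[HotspotRecord("COSMIC", "G1", 12, 4000, frozenset({"D", "S", "V"}))]
    )
    direct, _ = assign_somatic_medal(
        v, _ann(protein=ProteinChange("G", 12, "S")), _NO_PRED, kb, None, default_cfg
    )
    assert direct is Medal.GOLD
    imperfect, _ = assign_somatic_medal(
        v, _ann(protein=ProteinChange("G", 12, "W")), _NO_PRED, kb, None, default_cfg
    )
    assert imperfect is Medal.SILVER


def test_somatic_no_evidence_is_unknown(default_cfg):
    medal, reasons = assign_somatic_medal(
        _variant(), _ann(), _NO_PRED, _EMPTY, None, default_cfg
    )
    assert medal is Medal.UNKNOWN and reasons == []


def test_aggregate_prediction_examples(default_cfg):
    assert aggregate_prediction(PredictionProfile(revel=0.9), default_cfg) == "damaging"
    assert (
        aggregate_prediction(
            PredictionProfile(calls=(("a", "tolerated"), ("b", "tolerated"))), default_cfg
        )
        == "tolerated"
    )
    assert aggregate_prediction(PredictionProfile(), default_cfg) == "unknown"


def test_aggregate_prediction_exhaustive_enumeration(default_cfg):
    """All call vectors of length <= 4 x REVEL grid equal the transcription."""
    options = ["damaging", "tolerated", "unknown"]
    for n in range(0, 5):
        for combo in itertools.product(options, repeat=n):
            for revel in (None, 0.2, 0.8):
                profile = PredictionProfile(
                    calls=tuple((f"alg{i}", c) for i, c in enumerate(combo)),
                    revel=revel,
                )
                assert aggregate_prediction(profile, default_cfg) == (
                    aggregate_prediction_oracle(combo, revel, default_cfg)
                ), (combo, revel)


def test_decision_table_battery_agreement(default_cfg):
    """Engine vs independent decision-table oracle on the randomized battery."""
    for case in build_battery(seed=101, n=200):
        result = assign_medals(
            case.variant, case.ann, case.pf, case.pred, case.kb, case.gene_meta,
            default_cfg, whitelist=case.whitelist, blacklist=case.blacklist,
        )
        exp_medal, exp_gate = medal_oracle(case.features, default_cfg)
        assert result.germline_medal.name == exp_medal, case.features
        assert result.gate_status.value == exp_gate, case.features
        assert result.somatic_medal.name == somatic_medal_oracle(
            case.features, default_cfg
        ), case.features


def test_monotonicity_under_added_evidence(default_cfg):
    """Adding a database match, hotspot, whitelist entry, or a high REVEL
    score never lowers the germline medal."""
    base_cases = build_battery(seed=55, n=60)
    for case in base_cases:
        if case.features.blacklisted:
            continue
        base = assign_germline_medal(
            case.variant, case.ann, case.pf, case.pred, case.kb, case.gene_meta,
            default_cfg, whitelist=case.whitelist,
        ).germline_medal

        # + gold-tier exact database match
        extra = CuratedVariantRecord(
            "IARC_TP53", genomic_key=case.variant.key, gene=case.ann.gene
        )
        kb_plus = Knowledgebase(
            curated=list(case.kb.curated) + [extra],
            hotspots=[h for recs in case.kb._hotspots.values() for h in recs],
        )
        with_match = assign_germline_medal(
            case.variant, case.ann, case.pf, case.pred, kb_plus, case.gene_meta,
            default_cfg, whitelist=case.whitelist,
        ).germline_medal
        assert with_match >= base

        # + qualifying hotspot at the variant's codon
        if case.ann.codon is not None:
            kb_hot = Knowledgebase(
                curated=list(case.kb.curated),
                hotspots=[h for recs in case.kb._hotspots.values() for h in recs]
                + [HotspotRecord("COSMIC", case.ann.gene, case.ann.codon, 500)],
            )
            with_hot = assign_germline_medal(
                case.variant, case.ann, case.pf, case.pred, kb_hot, case.gene_meta,
                default_cfg, whitelist=case.whitelist,
            ).germline_medal
            assert with_hot >= base

        # + whitelist entry
        with_wl = assign_germline_medal(
            case.variant, case.ann, case.pf, case.pred, case.kb, case.gene_meta,
            default_cfg, whitelist=case.whitelist | {case.variant.key},
        ).germline_medal
        assert with_wl >= base

        # + REVEL at or above the damaging threshold
        pred_up = PredictionProfile(calls=case.pred.calls, revel=0.95)
        with_revel = assign_germline_medal(
            case.variant, case.ann, case.pf, pred_up, case.kb, case.gene_meta,
            default_cfg, whitelist=case.whitelist,
        ).germline_medal
        assert with_revel >= base, case.features


def test_adding_blacklist_forces_unknown(default_cfg):
    for case in build_battery(seed=56, n=30):
        result = assign_germline_medal(
            case.variant, case.ann, case.pf, case.pred, case.kb, case.gene_meta,
            default_cfg, blacklist={case.variant.key},
        )
        assert result.germline_medal is Medal.UNKNOWN


def test_unknown_iff_no_granting_rule(default_cfg):
    """Audit-trail invariant: UNKNOWN exactly when no rule granted a medal."""
    for case in build_battery(seed=57, n=120):
        result = assign_medals(
            case.variant, case.ann, case.pf, case.pred, case.kb, case.gene_meta,
            default_cfg, whitelist=case.whitelist, blacklist=case.blacklist,
        )
        granting = [r for r in result.reasons if r.medal is not Medal.UNKNOWN]
        if result.germline_medal is Medal.UNKNOWN:
            assert not granting
        else:
            assert granting
            assert result.germline_medal == max(r.medal for r in granting)
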