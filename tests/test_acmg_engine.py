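"""Evidence tags, combining rules, and analyst edits."""

from __future__ import annotations

import itertools

import pytest

from medaltriage.acmg_engine import (
    ALL_CODES,
    AcmgAssessment,
    AcmgTag,
    auto_tags,
    classify,
    edit_tags,
    tag_strength,
)
from medaltriage.knowledgebase import (
    CuratedVariantRecord,
    HotspotRecord,
    Knowledgebase,
    PopulationFrequencies,
)
from medaltriage.nomenclature import ProteinChange
from medaltriage.oracles import classify_oracle
from medaltriage.variants import Consequence, GeneMeta, GenomicVariant, TranscriptAnnotation

from tests.battery import build_battery
from medaltriage.oracles import auto_tags_oracle


def _variant(pos=1000):
    return GenomicVariant("1", pos, "A", "G")


def _ann(consequence=Consequence.MISSENSE, protein=None, gene="G1"):
    return TranscriptAnnotation(
        gene=gene, transcript="NM_1", consequence=consequence,
        protein_change=protein,
        codon=protein.codon if protein else None,
    )


_EMPTY = Knowledgebase()


@pytest.mark.parametrize(
    "codes,expected",
    [
        ({"PVS1", "PM2"}, "LP"),
        (set(), "VUS"),
        ({"BA1"}, "B"),
        ({"PS1", "PS3", "PM1", "PM2"}, "P"),
        ({"PVS1", "PS1"}, "P"),
        ({"PM2"}, "VUS"),
        ({"BS1", "BP4"}, "LB"),
        ({"BP4", "BP7"}, "LB"),
        ({"PVS1", "PM2", "BA1"}, "VUS"),  # conflicting sides
    ],
)
def test_classify_examples(codes, expected):
    assert classify(codes) == expected


def test_classify_rejects_unknown_code():
    with pytest.raises(ValueError, match="PX9"):
        classify({"PX9"})


def test_classify_agrees_with_enumeration_oracle():
    """Exact agreement over all <=6-tag subsets of the 11-code alphabet."""
    alphabet = ["PVS1", "PS1", "PS3", "PM1", "PM2", "PM4", "PM5", "PP3", "BA1", "BS1", "BP4"]
    checked = 0
    for size in range(0, 7):
        for subset in itertools.combinations(alphabet, size):
            codes = set(subset)
            assert classify(codes) == classify_oracle(codes), codes
            checked += 1
    assert checked == 1486  # sum of C(11, k) for k = 0..6


def test_classify_monotone_on_pathogenic_side():
    """Adding a pathogenic-side tag never moves toward benign, except via the
    explicit conflict rule; both halves asserted."""
    order = {"B": 0, "LB": 1, "VUS": 2, "LP": 3, "P": 4}
    alphabet = ["PVS1", "PS1", "PM1", "PM2", "PP3", "BA1", "BS1", "BP4"]
    additions = ["PVS1", "PS3", "PM4", "PP1"]
    for size in range(0, 4):
        for subset in itertools.combinations(alphabet, size):
            base_codes = set(subset)
            base = classify(base_codes)
            for extra in additions:
                if extra in base_codes:
                    continue
                new = classify(base_codes | {extra})
                if new == "VUS" and base in {"B", "LB"}:
                    # conflict rule: benign-side evidence now contradicted
                    continue
                assert order[new] >= order[base], (base_codes, extra)


def test_tag_strengths_from_prefix():
    assert tag_strength("PVS1") == "very_strong"
    assert tag_strength("PS4") == "strong"
    assert tag_strength("PM6") == "moderate"
    assert tag_strength("PP5") == "supporting"
    assert tag_strength("BA1") == "stand_alone_benign"
    assert tag_strength("BS2") == "strong_benign"
    assert tag_strength("BP7") == "supporting_benign"
    assert len(ALL_CODES) == 28


def test_auto_tags_truncating_lof_absent_from_population(default_cfg):
    """A nonsense variant in a loss-of-function gene, unseen in the reference
    population, earns exactly {PVS1, PM2} and classifies likely pathogenic."""
    assessment = auto_tags(
        _variant(), _ann(Consequence.NONSENSE, ProteinChange("R", 359, "*")),
        PopulationFrequencies(), _EMPTY, GeneMeta("G1", is_lof_gene=True), default_cfg,
    )
    assert assessment.codes() == {"PVS1", "PM2"}
    assert assessment.classification == "LP"


def test_auto_tags_hotspot_and_same_codon_match(default_cfg):
    v = _variant()
    kb = Knowledgebase(
        curated=[CuratedVariantRecord(
            "CLINVAR", gene="G1", protein_change=ProteinChange("G", 12, "D"),
            call="P", raw_call="Pathogenic", stars=3,
        )],
        hotspots=[HotspotRecord("COSMIC", "G1", 12, 4000, frozenset({"D", "S"}))],
    )
    assessment = auto_tags(
        v, _ann(protein=ProteinChange("G", 12, "S")), PopulationFrequencies(),
        kb, GeneMeta("G1"), default_cfg,
    )
    assert {"PM1", "PM2", "PM5"} <= assessment.codes()
    assert "PS1" not in assessment.codes()


def test_ps1_requires_same_change(default_cfg):
    v = _variant()
    kb = Knowledgebase(
        curated=[CuratedVariantRecord(
            "COMMITTEE", gene="G1", protein_change=ProteinChange("G", 12, "S"),
            call="LP", raw_call="Likely pathogenic",
        )]
    )
    assessment = auto_tags(
        v, _ann(protein=ProteinChange("G", 12, "S")), PopulationFrequencies(),
        kb, None, default_cfg,
    )
    assert "PS1" in assessment.codes()
    assert "PM5" not in assessment.codes()


def test_pm1_is_cosmic_only(default_cfg):
    kb = Knowledgebase(
        hotspots=[HotspotRecord("PCGP", "G1", 12, 3, frozenset({"S"}), curated_flag=True)]
    )
    assessment = auto_tags(
        _variant(), _ann(protein=ProteinChange("G", 12, "S")),
        PopulationFrequencies(), kb, None, default_cfg,
    )
    assert "PM1" not in assessment.codes()


def test_ba1_fires_above_floor(default_cfg):
    assessment = auto_tags(
        _variant(), _ann(), PopulationFrequencies(exac_nontcga=0.20),
        _EMPTY, None, default_cfg,
    )
    assert "BA1" in assessment.codes()
    assert "PM2" not in assessment.codes()
    assert assessment.classification == "B"


def test_pm2_ba1_thresholds_recovered_by_sweep(default_cfg):
    """Grid sweep recovers the PM2 ceiling and BA1 floor at the configured values."""
    pm2_largest = ba1_absent_largest = None
    for i in range(0, 1001):  # 0 .. 0.1 in steps of 1e-4
        freq = round(i * 1e-4, 8)
        codes = auto_tags(
            _variant(), _ann(), PopulationFrequencies(exac_nontcga=freq),
            _EMPTY, None, default_cfg,
        ).codes()
        if "PM2" in codes:
            pm2_largest = freq
        if "BA1" not in codes:
            ba1_absent_largest = freq
        assert not {"PM2", "BA1"} <= codes  # mutual exclusivity
    assert pm2_largest == default_cfg.pm2_max_af
    assert ba1_absent_largest == default_cfg.ba1_min_af


def test_pm2_fires_when_frequency_absent(default_cfg):
    codes = auto_tags(
        _variant(), _ann(), PopulationFrequencies(), _EMPTY, None, default_cfg
    ).codes()
    assert "PM2" in codes


def test_auto_tags_battery_agreement(default_cfg):
    """Tag engine vs independent tag oracle on the randomized battery."""
    for case in build_battery(seed=202, n=150):
        assessment = auto_tags(
            case.variant, case.ann, case.pf, case.kb, case.gene_meta, default_cfg
        )
        assert assessment.codes() == auto_tags_oracle(case.features, default_cfg), (
            case.features
        )


def test_edit_tags_remove_and_add(default_cfg):
    base = AcmgAssessment(
        variant_key="1:1000:A>G",
        tags={
            "PVS1": AcmgTag("PVS1"),
            "PM2": AcmgTag("PM2"),
        },
    )
    assert base.classification == "LP"

    removed = edit_tags(base, remove=["PVS1"])
    assert removed.codes() == {"PM2"}
    assert removed.classification == "VUS"

    added = edit_tags(base, add=[AcmgTag("PS3", origin="manual", pubmed_ids=("8351519",))])
    assert added.classification == "P"
    assert added.tags["PS3"].origin == "manual"
    assert added.tags["PS3"].pubmed_ids == ("8351519",)

    # Involution: add then remove restores the original classification.
    round_trip = edit_tags(added, remove=["PS3"])
    assert round_trip.classification == base.classification

    # Removing an absent code is a warning-level no-op.
    noop = edit_tags(base, remove=["BS1"])
    assert noop.codes() == base.codes()


def test_assessment_json_round_trip():
    assessment = AcmgAssessment(
        variant_key="12:41250:C>T",
        tags={
            "PVS1": AcmgTag("PVS1", note="nonsense in loss-of-function gene"),
            "PM2": AcmgTag("PM2"),
            "PS3": AcmgTag("PS3", origin="manual", pubmed_ids=("123", "456")),
        },
    )
    loaded = AcmgAssessment.from_json(assessment.to_json())
    assert loaded.variant_key == assessment.variant_key
    assert loaded.codes() == assessment.codes()
    assert loaded.tags["PS3"].pubmed_ids == ("123", "456")
    assert loaded.classification == assessment.classification
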