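"""Snapshot loading, graded matching, hotspots, and the gate exception."""

from __future__ import annotations

import random

import pytest

from medaltriage.config import Config
from medaltriage.knowledgebase import (
    CuratedVariantRecord,
    HotspotRecord,
    Knowledgebase,
    MatchGrade,
    PopulationFrequencies,
    load_snapshot,
    save_snapshot,
)
from medaltriage.nomenclature import ProteinChange
from medaltriage.variants import Consequence, GenomicVariant, TranscriptAnnotation


def _ann(gene="G1", codon=None, protein=None):
    return TranscriptAnnotation(
        gene=gene,
        transcript="NM_1",
        consequence=Consequence.MISSENSE,
        protein_change=protein,
        codon=codon if codon is not None else (protein.codon if protein else None),
    )


def test_load_suite_snapshot_counts_match_manifest(suite_dir, suite_manifest):
    kb = load_snapshot(suite_dir / "kb")
    assert kb.manifest["counts"] == suite_manifest["kb_counts"]
    assert kb.label == suite_manifest["snapshot_label"]


def test_empty_directory_is_valid_empty_knowledgebase(tmp_path):
    kb = load_snapshot(tmp_path)
    v = GenomicVariant("1", 100, "A", "G")
    assert kb.match(v, _ann(codon=10)) == []
    assert kb.frequencies(v) == PopulationFrequencies()
    assert kb.is_hotspot("G1", 10, Config()) == (False, None)


def test_stars_out_of_range_is_load_error(tmp_path):
    (tmp_path / "curated.tsv").write_text(
        "source\tchrom\tpos\tref\talt\tgene\tprotein_change\tcall\tstars\tpubmed_ids\n"
        "CLINVAR\t1\t100\tA\tG\tG1\t\tPathogenic\t5\t\n"
    )
    with pytest.raises(ValueError, match="stars"):
        load_snapshot(tmp_path)


def test_unknown_column_names_file_and_column(tmp_path):
    (tmp_path / "hotspots.tsv").write_text(
        "source\tgene\tcodon\ttumor_count\taa_changes\tcurated_flag\tbogus\n"
        "COSMIC\tG1\t10\t50\tD\t0\tx\n"
    )
    with pytest.raises(ValueError, match=r"hotspots\.tsv.*bogus"):
        load_snapshot(tmp_path)


def test_duplicate_curated_key_last_wins_with_warning(tmp_path):
    (tmp_path / "curated.tsv").write_text(
        "source\tchrom\tpos\tref\talt\tgene\tprotein_change\tcall\tstars\tpubmed_ids\n"
        "CLINVAR\t1\t100\tA\tG\tG1\t\tBenign\t1\t\n"
        "CLINVAR\t1\t100\tA\tG\tG1\t\tPathogenic\t3\t\n"
    )
    kb = load_snapshot(tmp_path)
    assert kb.manifest["warnings"]["duplicate_curated_key"] == 1
    (match,) = kb.match(GenomicVariant("1", 100, "A", "G"))
    assert match.record.call == "P" and match.record.stars == 3


def test_match_grades_examples():
    records = [
        CuratedVariantRecord("CLINVAR", genomic_key="1:100:A>G", gene="G1",
                             protein_change=ProteinChange("R", 10, "G"),
                             call="P", raw_call="Pathogenic", stars=3),
        CuratedVariantRecord("CLINVAR", genomic_key="1:100:A>T", gene="G1",
                             call="P", raw_call="Pathogenic", stars=2),
        CuratedVariantRecord("IARC_TP53", gene="G1",
                             protein_change=ProteinChange("R", 10, "W")),
        CuratedVariantRecord("ALSOD", gene="G1",
                             protein_change=ProteinChange("R", 10, "G")),
    ]
    kb = Knowledgebase(curated=records)
    v = GenomicVariant("1", 100, "A", "G")
    ann = _ann(protein=ProteinChange("R", 10, "G"))
    grades = {(m.record.source, m.grade) for m in kb.match(v, ann)}
    assert ("CLINVAR", MatchGrade.EXACT_GENOMIC) in grades
    assert ("CLINVAR", MatchGrade.SAME_POSITION_DIFF_ALLELE) in grades
    assert ("IARC_TP53", MatchGrade.SAME_CODON_DIFF_AA) in grades
    assert ("ALSOD", MatchGrade.EXACT_PROTEIN) in grades


def test_match_agrees_with_quadratic_oracle():
    """Indexed matching equals a brute-force all-pairs comparison, 200x200."""
    rng = random.Random(5)
    genes = [f"G{i}" for i in range(8)]
    aa = ["R", "G", "W", "L", "*"]

    records = []
    for i in range(200):
        gene = rng.choice(genes)
        codon = rng.randint(1, 30)
        has_key = rng.random() < 0.7
        protein = (
            ProteinChange(rng.choice(aa[:4]), codon, rng.choice(aa))
            if (rng.random() < 0.7 or not has_key)
            else None
        )
        key = (
            f"{rng.randint(1, 3)}:{rng.randint(1, 60)}:A>{rng.choice('CGT')}"
            if has_key
            else None
        )
        records.append(
            CuratedVariantRecord("CLINVAR", genomic_key=key, gene=gene,
                                 protein_change=protein, call="P",
                                 raw_call="Pathogenic", stars=rng.randint(0, 4))
        )
    kb = Knowledgebase(curated=records)

    queries = []
    for _ in range(200):
        v = GenomicVariant(str(rng.randint(1, 3)), rng.randint(1, 60), "A", rng.choice("CGT"))
        protein = ProteinChange(rng.choice(aa[:4]), rng.randint(1, 30), rng.choice(aa))
        queries.append((v, _ann(gene=rng.choice(genes), protein=protein)))

    index_by_id = {id(rec): idx for idx, rec in enumerate(records)}
    for v, ann in queries:
        expected = {}
        for idx, rec in enumerate(records):
            best = MatchGrade.NONE
            if rec.genomic_key:
                chrom, pos, alleles = rec.genomic_key.split(":")
                if chrom == v.chrom and int(pos) == v.pos:
                    if rec.genomic_key == v.key:
                        best = MatchGrade.EXACT_GENOMIC
                    else:
                        best = MatchGrade.SAME_POSITION_DIFF_ALLELE
            if rec.protein_change is not None and rec.gene == ann.gene:
                if rec.protein_change.codon == ann.codon:
                    if rec.protein_change.same_change(ann.protein_change):
                        best = max(best, MatchGrade.EXACT_PROTEIN)
                    else:
                        best = max(best, MatchGrade.SAME_CODON_DIFF_AA)
            if best is not MatchGrade.NONE:
                expected[idx] = best
        got = {index_by_id[id(m.record)]: m.grade for m in kb.match(v, ann)}
        assert got == expected


def test_hotspot_threshold_sweep(default_cfg):
    """Smallest qualifying COSMIC tumor count equals the configured minimum."""
    qualifying = []
    for count in range(1, 26):
        kb = Knowledgebase(hotspots=[HotspotRecord("COSMIC", "G1", 12, count)])
        hot, _ = kb.is_hotspot("G1", 12, default_cfg)
        if hot:
            qualifying.append(count)
    assert qualifying[0] == default_cfg.hotspot_min_tumors
    assert qualifying == list(range(default_cfg.hotspot_min_tumors, 26))


def test_pcgp_hotspot_requires_curated_flag(default_cfg):
    flagged = Knowledgebase(
        hotspots=[HotspotRecord("PCGP", "G1", 12, 2, curated_flag=True)]
    )
    unflagged = Knowledgebase(
        hotspots=[HotspotRecord("PCGP", "G1", 12, 500, curated_flag=False)]
    )
    assert flagged.is_hotspot("G1", 12, default_cfg)[0]
    assert not unflagged.is_hotspot("G1", 12, default_cfg)[0]


def test_hotspot_source_restriction(default_cfg):
    kb = Knowledgebase(
        hotspots=[HotspotRecord("PCGP", "G1", 12, 2, curated_flag=True)]
    )
    assert kb.is_hotspot("G1", 12, default_cfg)[0]
    assert not kb.is_hotspot("G1", 12, default_cfg, sources=frozenset({"COSMIC"}))[0]


@pytest.mark.parametrize(
    "source,call,stars,expected",
    [
        ("CLINVAR", "Pathogenic", 3, True),
        ("CLINVAR", "Pathogenic", 2, True),
        ("CLINVAR", "Pathogenic", 1, False),
        ("CLINVAR", "Benign", 3, False),
        ("IARC_TP53", "", None, True),
        ("ALSOD", "Pathogenic", None, False),
    ],
)
def test_frequency_gate_exception(source, call, stars, expected, default_cfg):
    from medaltriage.nomenclature import standardize_pathogenicity

    record = CuratedVariantRecord(
        source=source,
        genomic_key="1:100:A>G",
        gene="G1",
        call=standardize_pathogenicity(call) if call else None,
        raw_call=call,
        stars=stars,
    )
    kb = Knowledgebase(curated=[record])
    v = GenomicVariant("1", 100, "A", "G")
    rescued, _ = kb.frequency_gate_exception(v, _ann(), default_cfg)
    assert rescued is expected


def test_imperfect_match_never_rescues(default_cfg):
    record = CuratedVariantRecord(
        source="IARC_TP53", genomic_key="1:100:A>T", gene="G1"
    )
    kb = Knowledgebase(curated=[record])
    v = GenomicVariant("1", 100, "A", "G")  # same position, different allele
    assert kb.frequency_gate_exception(v, _ann(), default_cfg) == (False, None)


def test_snapshot_round_trip_stability(suite_dir, tmp_path, default_cfg):
    """Save + reload yields identical query answers on every suite variant."""
    kb1 = load_snapshot(suite_dir / "kb")
    save_snapshot(kb1, tmp_path / "kb2")
    kb2 = load_snapshot(tmp_path / "kb2")

    probes = sorted(kb1.frequencies_by_key) + sorted(kb1.predictions_by_key)
    for key in probes:
        chrom, pos, alleles = key.split(":")
        ref, alt = alleles.split(">")
        v = GenomicVariant(chrom, int(pos), ref, alt)
        assert kb1.frequencies(v) == kb2.frequencies(v)
        assert kb1.predictions(v) == kb2.predictions(v)
    for rec in kb1.curated:
        if rec.genomic_key is None:
            continue
        chrom, pos, alleles = rec.genomic_key.split(":")
        ref, alt = alleles.split(">")
        v = GenomicVariant(chrom, int(pos), ref, alt)
        ann = _ann(gene=rec.gene, protein=rec.protein_change)
        m1 = [(m.record.source, m.grade) for m in kb1.match(v, ann)]
        m2 = [(m.record.source, m.grade) for m in kb2.match(v, ann)]
        assert m1 == m2
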