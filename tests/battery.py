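"""Randomized rule-coverage battery: realize abstract evidence profiles.

Each battery case starts from a :class:`~medaltriage.oracles.RuleFeatures`
profile sampled over every rule dimension (consequence, gene mechanism,
frequency, match grades and sources, hotspot counts, predictions,
white/blacklisting) and is *realized* into concrete engine inputs — a
variant, an annotation, a per-case knowledgebase — whose evidence content
matches the profile exactly. The engine's answers on the realized inputs
are then comparable with the oracle's answers on the abstract profile.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from medaltriage.config import Config
from medaltriage.knowledgebase import (
    CuratedVariantRecord,
    HotspotRecord,
    Knowledgebase,
    PopulationFrequencies,
    PredictionProfile,
)
from medaltriage.nomenclature import ProteinChange
from medaltriage.oracles import MatchFeature, RuleFeatures
from medaltriage.variants import Consequence, GeneMeta, GenomicVariant, TranscriptAnnotation

_CONSEQUENCES = [
    "nonsense", "frameshift", "splice", "splice_region",
    "inframe_indel", "missense", "silent", "stoploss",
]
# Consequences realized without a parseable protein substitution.
_NO_PROTEIN = {"frameshift", "splice", "splice_region", "inframe_indel", "stoploss"}
_SOURCES = [
    "CLINVAR", "IARC_TP53", "ASU_TERT", "ARUP_MEN2", "NHGRI_BIC",
    "BRCA_SHARE", "ALSOD", "LOVD_APC", "LOVD_MSH2", "RB1", "COMMITTEE",
]
_GRADES = ["EXACT_GENOMIC", "EXACT_PROTEIN", "SAME_POSITION_DIFF_ALLELE", "SAME_CODON_DIFF_AA"]
_FREQS = [None, 0.00005, 0.0005, 0.001, 0.002, 0.01, 0.2]
_CALLS = [None, "Pathogenic", "Likely pathogenic", "Uncertain significance", "Benign"]


@dataclass
class RealizedCase:
    features: RuleFeatures
    variant: GenomicVariant
    ann: TranscriptAnnotation
    pf: PopulationFrequencies
    pred: PredictionProfile
    kb: Knowledgebase
    gene_meta: GeneMeta
    whitelist: frozenset[str]
    blacklist: frozenset[str]


def sample_features(rng: random.Random) -> RuleFeatures:
    consequence = rng.choice(_CONSEQUENCES)
    has_protein = consequence not in _NO_PROTEIN
    matches = []
    for _ in range(rng.randint(0, 2)):
        source = rng.choice(_SOURCES)
        grade = rng.choice(_GRADES)
        if not has_protein and grade == "EXACT_PROTEIN":
            grade = "EXACT_GENOMIC"
        call_raw = rng.choice(_CALLS)
        call = {
            "Pathogenic": "P",
            "Likely pathogenic": "LP",
            "Uncertain significance": "VUS",
            "Benign": "B",
            None: None,
        }[call_raw]
        stars = rng.randint(0, 4) if source == "CLINVAR" else None
        matches.append(MatchFeature(source=source, grade=grade, call=call, stars=stars))
    cosmic = rng.choice([None, None, 4, 9, 10, 4000])
    pcgp = rng.random() < 0.15
    direct = has_protein and (cosmic is not None or pcgp) and rng.random() < 0.5
    return RuleFeatures(
        consequence=consequence,
        is_lof_gene=rng.random() < 0.5,
        exac_af=rng.choice(_FREQS),
        matches=tuple(matches),
        cosmic_hotspot_count=cosmic,
        pcgp_hotspot_curated=pcgp,
        hotspot_aa_direct=direct,
        prediction=rng.choice(["damaging", "tolerated", "unknown", "unknown"]),
        whitelisted=rng.random() < 0.08,
        blacklisted=rng.random() < 0.08,
    )


def realize(features: RuleFeatures, index: int, cfg: Config) -> RealizedCase:
    """Build concrete engine inputs embodying one abstract evidence profile."""
    gene_symbol = "GENE_BATTERY"
    chrom = "2"
    pos = 1_000_000 + index * 10
    v = GenomicVariant(chrom, pos, "A", "G")
    codon = 100 + index

    consequence = Consequence(features.consequence)
    has_protein = features.consequence not in _NO_PROTEIN
    if features.consequence == "nonsense":
        protein = ProteinChange("R", codon, "*")
    elif features.consequence == "silent":
        protein = ProteinChange("L", codon, "=")
    elif has_protein:
        protein = ProteinChange("R", codon, "G")
    else:
        protein = None
    ann = TranscriptAnnotation(
        gene=gene_symbol,
        transcript="NM_BATTERY1",
        consequence=consequence,
        protein_change=protein,
        codon=codon,
    )

    curated: list[CuratedVariantRecord] = []
    other_alt = "T"
    for m in features.matches:
        stars = m.stars if m.source == "CLINVAR" else None
        raw_call = m.call or ""
        if m.grade == "EXACT_GENOMIC":
            curated.append(
                CuratedVariantRecord(
                    source=m.source, genomic_key=v.key, gene=gene_symbol,
                    protein_change=protein, call=m.call, raw_call=raw_call, stars=stars,
                )
            )
        elif m.grade == "EXACT_PROTEIN":
            curated.append(
                CuratedVariantRecord(
                    source=m.source, gene=gene_symbol, protein_change=protein,
                    call=m.call, raw_call=raw_call, stars=stars,
                )
            )
        elif m.grade == "SAME_POSITION_DIFF_ALLELE":
            curated.append(
                CuratedVariantRecord(
                    source=m.source,
                    genomic_key=f"{chrom}:{pos}:A>{other_alt}",
                    gene=gene_symbol, call=m.call, raw_call=raw_call, stars=stars,
                )
            )
        else:  # SAME_CODON_DIFF_AA
            curated.append(
                CuratedVariantRecord(
                    source=m.source, gene=gene_symbol,
                    protein_change=ProteinChange("R", codon, "W"),
                    call=m.call, raw_call=raw_call, stars=stars,
                )
            )

    variant_aa = protein.aa_alt if protein else None
    observed = frozenset({variant_aa}) if (features.hotspot_aa_direct and variant_aa) else frozenset({"Q"})
    hotspots: list[HotspotRecord] = []
    if features.cosmic_hotspot_count is not None:
        hotspots.append(
            HotspotRecord("COSMIC", gene_symbol, codon, features.cosmic_hotspot_count, observed)
        )
    if features.pcgp_hotspot_curated:
        hotspots.append(
            HotspotRecord("PCGP", gene_symbol, codon, 3, observed, curated_flag=True)
        )

    pf = PopulationFrequencies(exac_nontcga=features.exac_af)
    if features.prediction == "damaging":
        pred = PredictionProfile(revel=0.9)
    elif features.prediction == "tolerated":
        pred = PredictionProfile(calls=(("Polyphen2", "tolerated"), ("SIFT", "tolerated")))
    else:
        pred = PredictionProfile()

    return RealizedCase(
        features=features,
        variant=v,
        ann=ann,
        pf=pf,
        pred=pred,
        kb=Knowledgebase(curated=curated, hotspots=hotspots),
        gene_meta=GeneMeta(symbol=gene_symbol, is_lof_gene=features.is_lof_gene),
        whitelist=frozenset({v.key}) if features.whitelisted else frozenset(),
        blacklist=frozenset({v.key}) if features.blacklisted else frozenset(),
    )


def build_battery(seed: int, n: int, cfg: Config | None = None) -> list[RealizedCase]:
    cfg = cfg or Config()
    rng = random.Random(seed)
    return [realize(sample_features(rng), i, cfg) for i in range(n)]
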