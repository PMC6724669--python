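"""Independent reference implementations of the classification rules.

These oracles are deliberately written as direct, flat transcriptions of the
rule definitions — the medal tier diagram, the evidence-tag definitions, and
the ACMG evidence-combining table — over an abstract per-variant feature
vector. They share no code with the engines they ground-truth: the medal
engine works on variants, annotations and knowledgebase indexes, while the
oracles work on declared features. The synthetic-suite manifest is produced
exclusively by these oracles, so the master regression test (pipeline vs
manifest) compares two independent routes to the same answers.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import Config

__all__ = [
    "MatchFeature",
    "RuleFeatures",
    "medal_oracle",
    "somatic_medal_oracle",
    "auto_tags_oracle",
    "classify_oracle",
    "aggregate_prediction_oracle",
]

_TRUNCATING = {"nonsense", "frameshift", "splice"}
_GOLD_PRESENCE = {"IARC_TP53", "ASU_TERT", "ARUP_MEN2", "NHGRI_BIC"}
_SILVER_PRESENCE = {"BRCA_SHARE", "ALSOD", "LOVD_APC", "LOVD_MSH2", "RB1"}
_EXACT = {"EXACT_GENOMIC", "EXACT_PROTEIN"}
_IMPERFECT = {"SAME_POSITION_DIFF_ALLELE", "SAME_CODON_DIFF_AA"}


@dataclass(frozen=True)
class MatchFeature:
    """One curated-database match as the oracle sees it."""

    source: str
    grade: str  # EXACT_GENOMIC / EXACT_PROTEIN / SAME_POSITION_DIFF_ALLELE / SAME_CODON_DIFF_AA
    call: str | None = None  # standardized B/LB/VUS/LP/P
    stars: int | None = None


@dataclass(frozen=True)
class RuleFeatures:
    """Abstract evidence profile of one variant, declared (not derived)."""

    consequence: str = "missense"
    is_lof_gene: bool = False
    exac_af: float | None = None
    matches: tuple[MatchFeature, ...] = ()
    cosmic_hotspot_count: int | None = None
    pcgp_hotspot_curated: bool = False
    hotspot_aa_direct: bool = False  # variant's amino-acid change observed at the hotspot
    prediction: str = "unknown"  # aggregated in-silico verdict
    whitelisted: bool = False
    blacklisted: bool = False


def aggregate_prediction_oracle(
    calls: tuple[str, ...], revel: float | None, cfg: Config
) -> str:
    """Brute-force transcription of the prediction-aggregation definition."""
    if revel is not None and revel >= cfg.revel_damaging:
        return "damaging"
    informative = [c for c in calls if c != "unknown"]
    if informative:
        needed = (
            cfg.min_damaging_calls
            if cfg.min_damaging_calls is not None
            else len(informative) // 2 + 1
        )
        if sum(1 for c in informative if c == "damaging") >= needed:
            return "damaging"
        if all(c == "tolerated" for c in informative) and (
            revel is None or revel < cfg.revel_damaging
        ):
            return "tolerated"
    return "unknown"


def _match_tier(m: MatchFeature, cfg: Config) -> str | None:
    if m.source in _GOLD_PRESENCE:
        return "gold"
    if m.source in _SILVER_PRESENCE:
        return "silver"
    if m.source == "COMMITTEE":
        return "gold" if m.call in {"P", "LP"} else None
    if m.source == "CLINVAR" and m.call in {"P", "LP"}:
        if m.stars is not None and m.stars >= cfg.clinvar_min_stars:
            return "gold"
        return "silver"
    return None


def _gate_exception(f: RuleFeatures, cfg: Config) -> bool:
    for m in f.matches:
        if m.grade not in _EXACT:
            continue
        if m.source == "IARC_TP53":
            return True
        if (
            m.source == "CLINVAR"
            and m.call in {"P", "LP"}
            and m.stars is not None
            and m.stars >= cfg.clinvar_min_stars
        ):
            return True
    return False


def _is_hotspot(f: RuleFeatures, cfg: Config) -> bool:
    if f.cosmic_hotspot_count is not None and f.cosmic_hotspot_count >= cfg.hotspot_min_tumors:
        return True
    return f.pcgp_hotspot_curated


def medal_oracle(f: RuleFeatures, cfg: Config) -> tuple[str, str]:
    """Germline (medal, gate_status) straight from the tier diagram."""
    if f.blacklisted:
        return "UNKNOWN", "blacklisted"

    gate_status = "passed"
    if f.whitelisted:
        gate_status = "whitelisted"
    elif cfg.max_af is not None and f.exac_af is not None and f.exac_af > cfg.max_af:
        if _gate_exception(f, cfg):
            gate_status = "rescued_by_exception"
        else:
            return "UNKNOWN", "failed_frequency"

    medals: list[str] = []
    if f.whitelisted:
        medals.append("GOLD")
    truncating = f.consequence in _TRUNCATING
    if truncating and f.is_lof_gene:
        medals.append("GOLD")
    if truncating and not f.is_lof_gene:
        medals.append("SILVER")
    if f.consequence == "inframe_indel":
        medals.append("SILVER")
    for m in f.matches:
        tier = _match_tier(m, cfg)
        if tier is None:
            continue
        if m.grade in _EXACT:
            medals.append("GOLD" if tier == "gold" else "SILVER")
        elif m.grade in _IMPERFECT:
            medals.append("SILVER" if tier == "gold" else "BRONZE")
    if _is_hotspot(f, cfg):
        medals.append("GOLD")
    if f.prediction == "damaging":
        medals.append("SILVER")

    rank = {"GOLD": 3, "SILVER": 2, "BRONZE": 1}
    best = max(medals, key=lambda m: rank[m], default=None)
    if f.prediction == "tolerated" and (best is None or rank[best] < 2):
        best = best if best is not None and rank[best] >= 1 else "BRONZE"
    return (best or "UNKNOWN"), gate_status


def somatic_medal_oracle(f: RuleFeatures, cfg: Config) -> str:
    """Somatic medal: hotspot and loss-of-function reasoning only."""
    medals: list[str] = []
    if _is_hotspot(f, cfg):
        medals.append("GOLD" if f.hotspot_aa_direct else "SILVER")
    if f.consequence in _TRUNCATING and f.is_lof_gene:
        medals.append("GOLD")
    if f.prediction == "damaging":
        medals.append("SILVER")
    rank = {"GOLD": 3, "SILVER": 2, "BRONZE": 1}
    best = max(medals, key=lambda m: rank[m], default=None)
    if f.prediction == "tolerated" and best is None:
        best = "BRONZE"
    return best or "UNKNOWN"


def auto_tags_oracle(f: RuleFeatures, cfg: Config) -> set[str]:
    """Expected automated evidence tags from the declared features."""
    tags: set[str] = set()
    if f.consequence in _TRUNCATING and f.is_lof_gene:
        tags.add("PVS1")
    if f.cosmic_hotspot_count is not None and f.cosmic_hotspot_count >= cfg.hotspot_min_tumors:
        tags.add("PM1")
    if f.exac_af is None or f.exac_af <= cfg.pm2_max_af:
        tags.add("PM2")
    elif f.exac_af > cfg.ba1_min_af:
        tags.add("BA1")
    if f.consequence == "inframe_indel":
        tags.add("PM4")
    for m in f.matches:
        if m.source in {"CLINVAR", "COMMITTEE"} and m.call in {"P", "LP"}:
            if m.grade in _EXACT:
                tags.add("PS1")
            elif m.grade == "SAME_CODON_DIFF_AA":
                tags.add("PM5")
    return tags


def classify_oracle(codes: set[str]) -> str:
    """Brute-force evaluator of the ACMG evidence-combining rules."""
    pvs = sum(1 for c in codes if c.startswith("PVS"))
    ps = sum(1 for c in codes if c.startswith("PS"))
    pm = sum(1 for c in codes if c.startswith("PM"))
    pp = sum(1 for c in codes if c.startswith("PP"))
    ba = sum(1 for c in codes if c.startswith("BA"))
    bs = sum(1 for c in codes if c.startswith("BS"))
    bp = sum(1 for c in codes if c.startswith("BP"))

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm >= 1)
        or (ps >= 1 and pm >= 1)
        or (ps >= 1 and pp >= 2)
        or pm >= 3
        or (pm >= 2 and pp >= 2)
        or (pm >= 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    pathogenic_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if pathogenic_side and benign_side:
        return "VUS"
    if pathogenic:
        return "P"
    if likely_pathogenic:
        return "LP"
    if benign:
        return "B"
    if likely_benign:
        return "LB"
    return "VUS"
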