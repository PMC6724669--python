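"""Medal assignment: three-tier triage of germline variants, plus a somatic call.

Variants are triaged into gold, silver, or bronze medals as decreasing
strength of pathogenicity evidence; variants meeting no rule stay
``unknown``. The germline classifier first applies hard gates (a blacklist
that always suppresses medals, a whitelist that always grants one, and a
population-frequency gate with curated-database rescue exceptions), then
evaluates the rule tiers:

* **Gold** — truncating consequence in a loss-of-function disease gene;
  exact match to a highly curated database (IARC TP53, ClinVar P/LP with
  two or more review stars, the TERT and MEN2 locus databases, the breast
  cancer information core, committee-reviewed P/LP); somatic hotspot at the
  variant's codon.
* **Silver** — in-frame indels; truncations in non-loss-of-function genes;
  predicted damaging in silico; exact matches to lower-confidence databases
  (ClinVar P/LP below the star minimum, the BRCA, ALS, APC/MSH2 and RB1
  locus databases); imperfect matches to gold-tier databases.
* **Bronze** — predicted tolerated (unless otherwise medaled); imperfect
  matches to silver-tier databases.

All fired rules are recorded as an ordered audit trail; the final medal is
the highest granted. Imperfect matches (different allele at the same
position, or different amino-acid change at the same codon) are always
downgraded exactly one tier.

The somatic medal is computed by separate logic that consults only somatic
resources (hotspot tables and loss-of-function reasoning) — never the
germline curated databases — so the two medals can legitimately differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum, IntEnum

from .config import Config
from .knowledgebase import (
    EXACT_GRADES,
    IMPERFECT_GRADES,
    Knowledgebase,
    Match,
    PopulationFrequencies,
    PredictionProfile,
)
from .variants import Consequence, GeneMeta, GenomicVariant, TranscriptAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "Medal",
    "GateStatus",
    "MedalReason",
    "MedalResult",
    "aggregate_prediction",
    "assign_germline_medal",
    "assign_somatic_medal",
    "assign_medals",
]


# Genes already warned about for missing metadata (warn once per gene).
_warned_missing_gene: set[str] = set()


class Medal(IntEnum):
    """Triage medal, ordered so that ``max`` picks the strongest."""

    UNKNOWN = 0
    BRONZE = 1
    SILVER = 2
    GOLD = 3


class GateStatus(str, Enum):
    PASSED = "passed"
    FAILED_FREQUENCY = "failed_frequency"
    RESCUED_BY_EXCEPTION = "rescued_by_exception"
    WHITELISTED = "whitelisted"
    BLACKLISTED = "blacklisted"


@dataclass(frozen=True)
class MedalReason:
    """One fired rule: its identifier, the medal it grants, and evidence."""

    rule_id: str
    medal: Medal
    evidence: str = ""


@dataclass
class MedalResult:
    """Germline and somatic medals with the full audit trail."""

    germline_medal: Medal = Medal.UNKNOWN
    somatic_medal: Medal = Medal.UNKNOWN
    reasons: list[MedalReason] = field(default_factory=list)
    somatic_reasons: list[MedalReason] = field(default_factory=list)
    gate_status: GateStatus = GateStatus.PASSED


def aggregate_prediction(pred: PredictionProfile, cfg: Config) -> str:
    """Collapse per-algorithm calls and the REVEL score into one verdict.

    ``damaging`` when REVEL is at or above ``cfg.revel_damaging``, or when
    enough categorical algorithms call damaging (``cfg.min_damaging_calls``,
    defaulting to a strict majority of the non-unknown calls). ``tolerated``
    when at least one categorical call is present, every non-unknown call
    says tolerated, and REVEL (if present) is below the damaging threshold.
    ``unknown`` otherwise.
    """
    informative = [call for _, call in pred.calls if call != "unknown"]
    damaging_n = sum(1 for c in informative if c == "damaging")

    if pred.revel is not None and pred.revel >= cfg.revel_damaging:
        return "damaging"
    if informative:
        needed = (
            cfg.min_damaging_calls
            if cfg.min_damaging_calls is not None
            else len(informative) // 2 + 1
        )
        if damaging_n >= needed:
            return "damaging"
        if damaging_n == 0 and (
            pred.revel is None or pred.revel < cfg.revel_damaging
        ):
            return "tolerated"
    return "unknown"


# Curated sources whose exact matches are gold-tier evidence regardless of a
# pathogenicity call (highly curated locus databases).
_GOLD_PRESENCE_SOURCES = frozenset({"IARC_TP53", "ASU_TERT", "ARUP_MEN2", "NHGRI_BIC"})
# Sources whose exact matches are silver-tier evidence by presence.
_SILVER_PRESENCE_SOURCES = frozenset({"BRCA_SHARE", "ALSOD", "LOVD_APC", "LOVD_MSH2", "RB1"})


def _record_tier(match: Match, cfg: Config) -> str | None:
    """Evidence tier ('gold'/'silver') a curated record would grant, or None."""
    rec = match.record
    if rec.source in _GOLD_PRESENCE_SOURCES:
        return "gold"
    if rec.source in _SILVER_PRESENCE_SOURCES:
        return "silver"
    if rec.source == "COMMITTEE":
        return "gold" if rec.is_pathogenic_call else None
    if rec.source == "CLINVAR" and rec.is_pathogenic_call:
        if rec.stars is not None and rec.stars >= cfg.clinvar_min_stars:
            return "gold"
        return "silver"
    return None


def _is_truncating(ann: TranscriptAnnotation, cfg: Config) -> bool:
    if ann.is_truncating:
        return True
    return (
        cfg.splice_region_is_truncating
        and ann.consequence is Consequence.SPLICE_REGION
    )


def assign_germline_medal(
    v: GenomicVariant,
    ann: TranscriptAnnotation,
    pf: PopulationFrequencies,
    pred: PredictionProfile,
    kb: Knowledgebase,
    gene: GeneMeta | None,
    cfg: Config,
    whitelist: frozenset[str] | set[str] = frozenset(),
    blacklist: frozenset[str] | set[str] = frozenset(),
) -> MedalResult:
    """Assign the germline medal for one variant (most-severe annotation).

    Evaluation order: blacklist, whitelist, frequency gate (with rescue
    exceptions), then the gold/silver/bronze rule tiers. All fired rules are
    accumulated; the final medal is the highest granted. A missing gene
    record is treated as non-loss-of-function with a logged warning, never
    silently gold.
    """
    result = MedalResult()
    reasons = result.reasons

    if v.key in blacklist:
        result.gate_status = GateStatus.BLACKLISTED
        reasons.append(
            MedalReason("blacklist", Medal.UNKNOWN, f"blacklisted key {v.key}")
        )
        result.germline_medal = Medal.UNKNOWN
        return result

    whitelisted = v.key in whitelist
    if whitelisted:
        result.gate_status = GateStatus.WHITELISTED
        reasons.append(
            MedalReason("whitelist", Medal.GOLD, f"whitelisted key {v.key}")
        )
    elif cfg.max_af is not None:
        freq = pf.exac_nontcga
        if freq is not None and freq > cfg.max_af:
            rescued, why = kb.frequency_gate_exception(v, ann, cfg)
            if rescued:
                result.gate_status = GateStatus.RESCUED_BY_EXCEPTION
                reasons.append(
                    MedalReason(
                        "frequency_gate_rescued",
                        Medal.UNKNOWN,
                        f"frequency {freq} > {cfg.max_af} but {why}",
                    )
                )
            else:
                result.gate_status = GateStatus.FAILED_FREQUENCY
                reasons.append(
                    MedalReason(
                        "frequency_gate_failed",
                        Medal.UNKNOWN,
                        f"ExAC non-TCGA frequency {freq} > {cfg.max_af}",
                    )
                )
                result.germline_medal = Medal.UNKNOWN
                return result

    if gene is None and ann.gene not in _warned_missing_gene:
        _warned_missing_gene.add(ann.gene)
        logger.warning(
            "no gene metadata for %s: treating its variants as non-loss-of-function",
            ann.gene,
        )
    is_lof_gene = bool(gene and gene.is_lof_gene)
    truncating = _is_truncating(ann, cfg)

    # Gold: truncating consequence in a loss-of-function disease gene.
    if truncating and is_lof_gene:
        reasons.append(
            MedalReason(
                "truncating_in_lof_gene",
                Medal.GOLD,
                f"{ann.consequence.value} in loss-of-function gene {ann.gene}",
            )
        )
    elif truncating:
        reasons.append(
            MedalReason(
                "truncating_in_non_lof_gene",
                Medal.SILVER,
                f"{ann.consequence.value} in non-loss-of-function gene {ann.gene}",
            )
        )

    # Silver: in-frame indels.
    if ann.consequence is Consequence.INFRAME_INDEL:
        reasons.append(
            MedalReason("inframe_indel", Medal.SILVER, "in-frame indel")
        )

    # Curated-database matches, downgraded one tier when imperfect.
    for m in kb.match(v, ann):
        tier = _record_tier(m, cfg)
        if tier is None:
            continue
        evidence = (
            f"{m.record.source} {m.grade.name}"
            + (f" call={m.record.call}" if m.record.call else "")
            + (f" stars={m.record.stars}" if m.record.stars is not None else "")
        )
        if m.grade in EXACT_GRADES:
            medal = Medal.GOLD if tier == "gold" else Medal.SILVER
            reasons.append(MedalReason(f"exact_{tier}_db_match", medal, evidence))
        elif m.grade in IMPERFECT_GRADES:
            medal = Medal.SILVER if tier == "gold" else Medal.BRONZE
            reasons.append(MedalReason(f"imperfect_{tier}_db_match", medal, evidence))

    # Gold: somatic hotspot at the variant's codon (COSMIC count threshold,
    # or explicitly curated pediatric-cohort hotspots).
    if ann.codon is not None and ann.gene:
        hot, best = kb.is_hotspot(ann.gene, ann.codon, cfg)
        if hot and best is not None:
            reasons.append(
                MedalReason(
                    "hotspot",
                    Medal.GOLD,
                    f"{best.source} hotspot {ann.gene} codon {best.codon} "
                    f"({best.tumor_count} tumors)",
                )
            )

    # In-silico prediction aggregate.
    verdict = aggregate_prediction(pred, cfg)
    if verdict == "damaging":
        reasons.append(
            MedalReason("predicted_damaging", Medal.SILVER, "in-silico damaging")
        )

    best_medal = max(
        (r.medal for r in reasons), default=Medal.UNKNOWN
    )
    # Bronze applies only when nothing stronger fired.
    if verdict == "tolerated" and best_medal < Medal.SILVER:
        reasons.append(
            MedalReason("predicted_tolerated", Medal.BRONZE, "in-silico tolerated")
        )
        best_medal = max(best_medal, Medal.BRONZE)

    result.germline_medal = best_medal
    return result


def assign_somatic_medal(
    v: GenomicVariant,
    ann: TranscriptAnnotation,
    pred: PredictionProfile,
    kb: Knowledgebase,
    gene: GeneMeta | None,
    cfg: Config,
) -> tuple[Medal, list[MedalReason]]:
    """Assign the somatic-context medal from somatic resources only.

    Gold for a direct hotspot match (the variant's amino-acid change is
    among those observed at a qualifying hotspot codon) or a truncating
    variant in a loss-of-function gene; silver for an imperfect hotspot
    match (qualifying codon, different amino-acid change) or an in-silico
    damaging prediction; bronze for predicted tolerated; unknown otherwise.
    Germline-only resources are never consulted.
    """
    reasons: list[MedalReason] = []

    if ann.codon is not None and ann.gene:
        for hs in kb.hotspot_records(ann.gene, ann.codon):
            qualifies = (
                hs.tumor_count >= cfg.hotspot_min_tumors
                if hs.source == "COSMIC"
                else hs.curated_flag
            )
            if not qualifies:
                continue
            direct = (
                ann.protein_change is not None
                and ann.protein_change.aa_alt in hs.aa_changes
            )
            if direct:
                reasons.append(
                    MedalReason(
                        "somatic_hotspot_direct",
                        Medal.GOLD,
                        f"{hs.source} hotspot {ann.gene} codon {hs.codon}, "
                        f"observed change {ann.protein_change.one_letter()}",
                    )
                )
            else:
                reasons.append(
                    MedalReason(
                        "somatic_hotspot_imperfect",
                        Medal.SILVER,
                        f"{hs.source} hotspot {ann.gene} codon {hs.codon}, "
                        "different amino-acid change",
                    )
                )

    if _is_truncating(ann, cfg) and gene is not None and gene.is_lof_gene:
        reasons.append(
            MedalReason(
                "somatic_truncating_in_lof_gene",
                Medal.GOLD,
                f"{ann.consequence.value} in loss-of-function gene {ann.gene}",
            )
        )

    verdict = aggregate_prediction(pred, cfg)
    if verdict == "damaging":
        reasons.append(
            MedalReason("somatic_predicted_damaging", Medal.SILVER, "in-silico damaging")
        )

    best = max((r.medal for r in reasons), default=Medal.UNKNOWN)
    if verdict == "tolerated" and best < Medal.SILVER:
        reasons.append(
            MedalReason("somatic_predicted_tolerated", Medal.BRONZE, "in-silico tolerated")
        )
        best = max(best, Medal.BRONZE)
    return best, reasons


def assign_medals(
    v: GenomicVariant,
    ann: TranscriptAnnotation,
    pf: PopulationFrequencies,
    pred: PredictionProfile,
    kb: Knowledgebase,
    gene: GeneMeta | None,
    cfg: Config,
    whitelist: frozenset[str] | set[str] = frozenset(),
    blacklist: frozenset[str] | set[str] = frozenset(),
) -> MedalResult:
    """Run germline and somatic medal assignment and merge the results."""
    result = assign_germline_medal(
        v, ann, pf, pred, kb, gene, cfg, whitelist=whitelist, blacklist=blacklist
    )
    somatic, somatic_reasons = assign_somatic_medal(v, ann, pred, kb, gene, cfg)
    result.somatic_medal = somatic
    result.somatic_reasons = somatic_reasons
    return result
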