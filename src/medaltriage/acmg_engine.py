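"""ACMG/AMP evidence tags and the five-tier classification.

Seven criteria are automated from the triage evidence (PVS1, PM1, PM2, BA1,
PM4, PS1, PM5); the remaining criteria — segregation, de novo status,
functional assays and so on — require analyst judgement and are entered
manually. Every tag carries its provenance (auto vs manual), optional PubMed
identifiers and a free-text note; auto tags may be removed by the analyst.

The five-tier classification (P/LP/VUS/LB/B) is a pure function of the tag
codes, recomputed on every edit. The evidence-combining disjuncts ship as a
reviewable data table (``data/acmg_combining_rules.tsv``) rather than code;
pathogenic-side and benign-side rules are evaluated independently, and any
conflict between the two sides — or no fired rule at all — yields VUS.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .config import Config
from .knowledgebase import (
    EXACT_GRADES,
    Knowledgebase,
    MatchGrade,
    PopulationFrequencies,
)
from .medal_engine import _is_truncating
from .variants import Consequence, GeneMeta, GenomicVariant, TranscriptAnnotation

__all__ = [
    "ALL_CODES",
    "AcmgTag",
    "AcmgAssessment",
    "tag_strength",
    "auto_tags",
    "classify",
    "edit_tags",
]

ALL_CODES: tuple[str, ...] = (
    "PVS1",
    "PS1", "PS2", "PS3", "PS4",
    "PM1", "PM2", "PM3", "PM4", "PM5", "PM6",
    "PP1", "PP2", "PP3", "PP4", "PP5",
    "BA1",
    "BS1", "BS2", "BS3", "BS4",
    "BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7",
)

_PREFIX_STRENGTH = (
    ("PVS", "very_strong"),
    ("PS", "strong"),
    ("PM", "moderate"),
    ("PP", "supporting"),
    ("BA", "stand_alone_benign"),
    ("BS", "strong_benign"),
    ("BP", "supporting_benign"),
)


def tag_strength(code: str) -> str:
    """Evidence strength implied by the code prefix."""
    if code not in ALL_CODES:
        raise ValueError(f"unknown ACMG code {code!r}")
    for prefix, strength in _PREFIX_STRENGTH:
        if code.startswith(prefix):
            return strength
    raise AssertionError(code)


@dataclass(frozen=True)
class AcmgTag:
    """One evidence tag with provenance and supporting references."""

    code: str
    origin: str = "auto"
    pubmed_ids: tuple[str, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if self.code not in ALL_CODES:
            raise ValueError(f"unknown ACMG code {self.code!r}")
        if self.origin not in {"auto", "manual"}:
            raise ValueError(f"origin must be auto or manual, got {self.origin!r}")

    @property
    def strength(self) -> str:
        return tag_strength(self.code)


@lru_cache(maxsize=1)
def _combining_rules() -> tuple[tuple[str, dict[str, int]], ...]:
    ref = resources.files("medaltriage.data").joinpath("acmg_combining_rules.tsv")
    rules: list[tuple[str, dict[str, int]]] = []
    with ref.open("r", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    header = rows[0]
    for row in rows[1:]:
        record = dict(zip(header, row))
        outcome = record.pop("outcome")
        rules.append((outcome, {k: int(v) for k, v in record.items()}))
    return tuple(rules)


def _strength_counts(codes: set[str]) -> dict[str, int]:
    counts = {"min_pvs": 0, "min_ps": 0, "min_pm": 0, "min_pp": 0,
              "min_ba": 0, "min_bs": 0, "min_bp": 0}
    key_by_strength = {
        "very_strong": "min_pvs",
        "strong": "min_ps",
        "moderate": "min_pm",
        "supporting": "min_pp",
        "stand_alone_benign": "min_ba",
        "strong_benign": "min_bs",
        "supporting_benign": "min_bp",
    }
    for code in codes:
        counts[key_by_strength[tag_strength(code)]] += 1
    return counts


def classify(codes: set[str] | frozenset[str] | list[str]) -> str:
    """Five-tier classification from a set of tag codes.

    Pathogenic-side disjuncts (P, then LP) and benign-side disjuncts (B,
    then LB) are evaluated independently from the shipped combining-rule
    table; if rules fire on both sides, or on neither, the result is VUS.
    """
    code_set = set(codes)
    for code in code_set:
        if code not in ALL_CODES:
            raise ValueError(f"unknown ACMG code {code!r}")
    counts = _strength_counts(code_set)
    fired = {"P": False, "LP": False, "B": False, "LB": False}
    for outcome, mins in _combining_rules():
        if all(counts[k] >= v for k, v in mins.items()):
            fired[outcome] = True
    pathogenic_side = fired["P"] or fired["LP"]
    benign_side = fired["B"] or fired["LB"]
    if pathogenic_side and benign_side:
        return "VUS"
    if fired["P"]:
        return "P"
    if fired["LP"]:
        return "LP"
    if fired["B"]:
        return "B"
    if fired["LB"]:
        return "LB"
    return "VUS"


@dataclass
class AcmgAssessment:
    """A tag set plus its derived classification (recomputed on every edit)."""

    variant_key: str = ""
    tags: dict[str, AcmgTag] = field(default_factory=dict)

    @property
    def classification(self) -> str:
        return classify(set(self.tags))

    def codes(self) -> set[str]:
        return set(self.tags)

    def to_json(self) -> str:
        payload = {
            "variant_key": self.variant_key,
            "tags": [
                {
                    "code": t.code,
                    "origin": t.origin,
                    "pubmed_ids": list(t.pubmed_ids),
                    "note": t.note,
                }
                for t in sorted(self.tags.values(), key=lambda t: ALL_CODES.index(t.code))
            ],
            "classification": self.classification,
        }
        return json.dumps(payload, indent=None, sort_keys=False)

    @classmethod
    def from_json(cls, text: str) -> "AcmgAssessment":
        payload = json.loads(text)
        tags = {
            t["code"]: AcmgTag(
                code=t["code"],
                origin=t.get("origin", "manual"),
                pubmed_ids=tuple(t.get("pubmed_ids", [])),
                note=t.get("note", ""),
            )
            for t in payload.get("tags", [])
        }
        return cls(variant_key=payload.get("variant_key", ""), tags=tags)


def auto_tags(
    v: GenomicVariant,
    ann: TranscriptAnnotation,
    pf: PopulationFrequencies,
    kb: Knowledgebase,
    gene: GeneMeta | None,
    cfg: Config,
) -> AcmgAssessment:
    """Generate the automated evidence tags for one variant.

    PVS1 — truncating consequence in a loss-of-function gene; PM1 — COSMIC
    somatic hotspot at the variant's codon; PM2 — absent from the reference
    population or at frequency ≤ ``cfg.pm2_max_af``; BA1 — population
    frequency > ``cfg.ba1_min_af`` (mutually exclusive with PM2 by
    construction); PM4 — in-frame indel; PS1 — exact match (genomic or
    identical amino-acid change) to a P/LP record in ClinVar or committee
    review; PM5 — different amino-acid change at the same codon as such a
    record.
    """
    assessment = AcmgAssessment(variant_key=v.key)

    def _add(code: str, note: str, pubmed_ids: tuple[str, ...] = ()) -> None:
        assessment.tags[code] = AcmgTag(
            code=code, origin="auto", note=note, pubmed_ids=pubmed_ids
        )

    if _is_truncating(ann, cfg) and gene is not None and gene.is_lof_gene:
        _add("PVS1", f"{ann.consequence.value} in loss-of-function gene {ann.gene}")

    if ann.codon is not None and ann.gene:
        hot, best = kb.is_hotspot(ann.gene, ann.codon, cfg, sources=frozenset({"COSMIC"}))
        if hot and best is not None:
            _add(
                "PM1",
                f"COSMIC hotspot {ann.gene} codon {best.codon} "
                f"({best.tumor_count} tumors)",
            )

    freq = pf.exac_nontcga
    if freq is None or freq <= cfg.pm2_max_af:
        _add(
            "PM2",
            "absent from ExAC non-TCGA"
            if freq is None
            else f"ExAC non-TCGA frequency {freq} <= {cfg.pm2_max_af}",
        )
    elif freq > cfg.ba1_min_af:
        _add("BA1", f"ExAC non-TCGA frequency {freq} > {cfg.ba1_min_af}")

    if ann.consequence is Consequence.INFRAME_INDEL:
        _add("PM4", "in-frame protein insertion/deletion")

    ps1_note, pm5_note = None, None
    ps1_pm: tuple[str, ...] = ()
    pm5_pm: tuple[str, ...] = ()
    for m in kb.match(v, ann):
        rec = m.record
        if rec.source not in {"CLINVAR", "COMMITTEE"} or not rec.is_pathogenic_call:
            continue
        if m.grade in EXACT_GRADES and ps1_note is None:
            ps1_note = f"{rec.source} {rec.call} match, same amino-acid change ({m.grade.name})"
            ps1_pm = rec.pubmed_ids
        elif m.grade is MatchGrade.SAME_CODON_DIFF_AA and pm5_note is None:
            pm5_note = f"{rec.source} {rec.call} at same codon, different amino-acid change"
            pm5_pm = rec.pubmed_ids
    if ps1_note:
        _add("PS1", ps1_note, ps1_pm)
    if pm5_note:
        _add("PM5", pm5_note, pm5_pm)

    return assessment


def edit_tags(
    assessment: AcmgAssessment,
    add: list[AcmgTag] | tuple[AcmgTag, ...] = (),
    remove: list[str] | tuple[str, ...] = (),
) -> AcmgAssessment:
    """Apply analyst edits, returning a new assessment.

    Added tags keep their provenance and PubMed identifiers; removing a code
    that is not present is a warning-level no-op. The classification of the
    returned assessment reflects the edited tag set.
    """
    import logging

    tags = dict(assessment.tags)
    for code in remove:
        if code not in tags:
            logging.getLogger(__name__).warning(
                "remove of absent ACMG code %s: no-op", code
            )
            continue
        del tags[code]
    for tag in add:
        tags[tag.code] = tag
    return AcmgAssessment(variant_key=assessment.variant_key, tags=tags)
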