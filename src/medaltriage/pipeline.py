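"""End-to-end pipeline: VCF through medals and evidence tags to a result table.

The funnel mirrors the triage workflow: decompose the VCF, keep variants in
the disease-gene panel, enhance and filter annotations to coding and
splice-related classes, apply the frequency gate and medal rules, then
auto-generate evidence tags and the five-tier classification. Each retained
variant yields one row keyed by ``chrom:pos:ref>alt``, carrying the selected
(most severe) annotation, per-source frequencies, the medal audit trail, the
tag set and the knowledgebase snapshot label; a funnel summary reports the
count surviving each step.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .acmg_engine import AcmgAssessment, auto_tags
from .annotation_enhance import (
    filter_functional,
    load_annotations,
    load_exon_models,
    reclassify_splice,
    select_most_severe,
)
from .config import Config
from .knowledgebase import load_snapshot
from .medal_engine import Medal, MedalResult, aggregate_prediction, assign_medals
from .variants import GeneMeta, GenomicVariant
from .vcf_ingest import IngestStats, filter_to_panel, load_panel, read_vcf

__all__ = [
    "PipelineResult",
    "run_pipeline",
    "write_reports",
    "load_gene_meta",
    "load_key_list",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = [
    "variant_key", "chrom", "pos", "ref", "alt", "vtype",
    "gene", "transcript", "consequence", "promoted_from",
    "protein_change", "exac_nontcga", "esp", "kg1000", "pcgp",
    "prediction", "germline_medal", "gate_status", "germline_reasons",
    "somatic_medal", "somatic_reasons", "acmg_tags", "classification",
    "genotypes", "snapshot_label",
]

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}


def _chrom_key(chrom: str) -> tuple[int, str]:
    return _CHROM_ORDER.get(chrom, 99), chrom


def load_gene_meta(path: str | os.PathLike) -> dict[str, GeneMeta]:
    """Load gene metadata: symbol, panels, is_lof_gene, inheritance (TSV)."""
    out: dict[str, GeneMeta] = {}
    with open(path, encoding="utf-8") as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            row = dict(zip(header, fields))
            out[row["symbol"]] = GeneMeta(
                symbol=row["symbol"],
                panels=frozenset(p for p in row.get("panels", "").split(",") if p),
                is_lof_gene=row.get("is_lof_gene", "0").strip() in {"1", "true", "yes"},
                inheritance=row.get("inheritance", "unknown") or "unknown",
            )
    return out


def load_key_list(path: str | os.PathLike) -> frozenset[str]:
    """Load a whitelist/blacklist file: one ``chrom:pos:ref>alt`` key per line."""
    keys = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                keys.add(line)
    return frozenset(keys)


@dataclass
class PipelineResult:
    """Per-variant result rows plus the processing funnel."""

    rows: list[dict] = field(default_factory=list)
    assessments: dict[str, AcmgAssessment] = field(default_factory=dict)
    medal_results: dict[str, MedalResult] = field(default_factory=dict)
    funnel: dict = field(default_factory=dict)
    snapshot_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=REPORT_COLUMNS)


def _fmt_reasons(reasons) -> str:
    return ";".join(f"{r.rule_id}[{r.evidence}]" for r in reasons)


def run_pipeline(
    vcf: str | os.PathLike,
    panel: str | os.PathLike,
    annotations: str | os.PathLike,
    exons: str | os.PathLike | None,
    kb_dir: str | os.PathLike,
    cfg: Config | None = None,
    whitelist: str | os.PathLike | None = None,
    blacklist: str | os.PathLike | None = None,
    genes: str | os.PathLike | None = None,
) -> PipelineResult:
    """Run the full triage pipeline and return the result table + funnel."""
    cfg = cfg or Config()
    kb = load_snapshot(kb_dir)
    panel_obj = load_panel(panel)
    exon_models = load_exon_models(exons) if exons else {}
    gene_meta = load_gene_meta(genes) if genes else {}
    wl = load_key_list(whitelist) if whitelist else frozenset()
    bl = load_key_list(blacklist) if blacklist else frozenset()

    stats = IngestStats()
    vcf_variants = list(read_vcf(vcf, stats=stats))
    ann_table = load_annotations(
        annotations, known_keys={vv.variant.key for vv in vcf_variants}
    )

    # Panel filter: unique variants with at least one overlapping panel gene.
    seen: set[str] = set()
    panel_variants = []
    for vv, _gene in filter_to_panel(vcf_variants, panel_obj):
        if vv.variant.key not in seen:
            seen.add(vv.variant.key)
            panel_variants.append(vv)
    panel_variants.sort(
        key=lambda vv: (_chrom_key(vv.variant.chrom), vv.variant.pos,
                        vv.variant.ref, vv.variant.alt)
    )

    result = PipelineResult(snapshot_label=kb.label)
    n_functional = n_gate_passed = n_medaled = 0
    for vv in panel_variants:
        v: GenomicVariant = vv.variant
        anns = ann_table.get(v.key, [])
        anns = [
            reclassify_splice(a, exon_models.get(a.transcript), cfg, v.pos)
            for a in anns
        ]
        functional = filter_functional(anns)
        if not functional:
            continue
        n_functional += 1
        ann = select_most_severe(functional)
        pf = kb.frequencies(v)
        pred = kb.predictions(v)
        gm = gene_meta.get(ann.gene)
        medal = assign_medals(
            v, ann, pf, pred, kb, gm, cfg, whitelist=wl, blacklist=bl
        )
        assessment = auto_tags(v, ann, pf, kb, gm, cfg)
        if medal.gate_status.value not in {"failed_frequency", "blacklisted"}:
            n_gate_passed += 1
        if medal.germline_medal is not Medal.UNKNOWN:
            n_medaled += 1
        result.medal_results[v.key] = medal
        result.assessments[v.key] = assessment
        result.rows.append(
            {
                "variant_key": v.key,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "vtype": v.vtype.value,
                "gene": ann.gene,
                "transcript": ann.transcript,
                "consequence": ann.consequence.value,
                "promoted_from": ann.promoted_from.value if ann.promoted_from else "",
                "protein_change": (
                    ann.protein_change.one_letter() if ann.protein_change else ""
                ),
                "exac_nontcga": pf.exac_nontcga,
                "esp": pf.esp,
                "kg1000": pf.kg1000,
                "pcgp": pf.pcgp,
                "prediction": aggregate_prediction(pred, cfg),
                "germline_medal": medal.germline_medal.name,
                "gate_status": medal.gate_status.value,
                "germline_reasons": _fmt_reasons(medal.reasons),
                "somatic_medal": medal.somatic_medal.name,
                "somatic_reasons": _fmt_reasons(medal.somatic_reasons),
                "acmg_tags": ",".join(sorted(assessment.codes())),
                "classification": assessment.classification,
                "genotypes": "|".join(vv.genotypes),
                "snapshot_label": kb.label,
            }
        )

    result.funnel = {
        "vcf_records": stats.records,
        "decomposed_variants": stats.emitted,
        "skipped_symbolic": stats.skipped_symbolic,
        "panel_filtered": len(panel_variants),
        "functional_retained": n_functional,
        "gate_passed": n_gate_passed,
        "medaled": n_medaled,
    }
    return result


def write_reports(
    result: PipelineResult,
    out_dir: str | os.PathLike,
    formats: tuple[str, ...] = ("tsv", "json"),
    basename: str = "results",
) -> list[Path]:
    """Write the result table as TSV and/or JSON; both round-trip loadable."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "tsv" in formats:
        path = out / f"{basename}.tsv"
        result.to_frame().to_csv(path, sep="\t", index=False)
        written.append(path)
    if "json" in formats:
        path = out / f"{basename}.json"
        payload = []
        for row in result.rows:
            assessment = result.assessments[row["variant_key"]]
            payload.append(
                {**row, "assessment": json.loads(assessment.to_json())}
            )
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
        written.append(path)
    funnel_path = out / f"{basename}_funnel.json"
    funnel_path.write_text(json.dumps(result.funnel, indent=2) + "\n", encoding="utf-8")
    written.append(funnel_path)
    return written
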