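"""Deterministic synthetic test-data generator.

Emits a complete, self-consistent input set for the triage pipeline — VCF,
gene panels, gene metadata, exon models, annotation table, knowledgebase
snapshot, whitelist/blacklist — together with a machine-readable manifest of
ground-truth expectations (medal, gate status, automated tags, five-tier
classification) for every variant. The manifest is computed exclusively by
the independent rule oracles in :mod:`medaltriage.oracles`, never by the
engines under test, so a full pipeline run versus the manifest compares two
independently written routes to the same answers.

The suite covers every medal rule and every automated evidence tag at least
once, including five fixed archetype variants modeled on well-known
clinical cases: a nonsense truncation in a leukemia tumor-suppressor gene
(ETV6-like), a hotspot missense in an oncogene (NRAS G12S-like), a
dual-medal missense (NOTCH1-like: germline silver from a curated match,
somatic bronze), a retained silent variant (MLH1-like), and an ALS
founder missense (SOD1 Ala5Val-like). Gene symbols are real for
readability but all coordinates, exon structures and database contents are
synthetic.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path

from .config import Config
from .nomenclature import AA_1TO3, standardize_pathogenicity
from .oracles import (
    MatchFeature,
    RuleFeatures,
    aggregate_prediction_oracle,
    auto_tags_oracle,
    classify_oracle,
    medal_oracle,
    somatic_medal_oracle,
)

__all__ = ["generate_suite", "generate_frequency_sweep", "predefined_panel_genes", "GENES"]

SNAPSHOT_LABEL = "synthetic-suite-v1"


@dataclass(frozen=True)
class _Gene:
    symbol: str
    chrom: str
    panel_start: int  # 0-based half-open panel interval
    panel_end: int
    strand: str
    lof: bool
    panels: tuple[str, ...]
    transcript: str
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive
    inheritance: str = "AD"


GENES: dict[str, _Gene] = {
    g.symbol: g
    for g in [
        _Gene("NRAS", "1", 11000, 12000, "-", False, ("cancer",), "NM_NRAS01", ((11100, 11400),)),
        _Gene("MLH1", "3", 21000, 22000, "+", True, ("cancer",), "NM_MLH101", ((21100, 21400),), "AD_AR"),
        _Gene("NOTCH1", "9", 31000, 32000, "-", False, ("cancer",), "NM_NOTCH101", ((31100, 31400),)),
        _Gene("ETV6", "12", 41000, 42000, "+", True, ("cancer", "hematological"), "NM_ETV601", ((41100, 41400),)),
        _Gene("BRCA2", "13", 71000, 72000, "+", True, ("cancer",), "NM_BRCA201", ((71100, 71600),)),
        _Gene("MYH7", "14", 81000, 82000, "+", False, ("cardiovascular",), "NM_MYH701", ((81100, 81600),)),
        _Gene("TP53", "17", 51000, 52000, "+", True, ("cancer",), "NM_TP5301", ((51100, 51200), (51300, 51400))),
        _Gene("SOD1", "21", 61000, 62000, "+", False, ("als",), "NM_SOD101", ((61100, 61400),)),
        _Gene("BTK", "X", 91000, 92000, "+", True, ("immunodeficiency",), "NM_BTK01", ((91100, 91600),), "unknown"),
    ]
}

PANEL_CATEGORIES = ("cancer", "cardiovascular", "hematological", "immunodeficiency", "als")


def predefined_panel_genes() -> dict[str, list[str]]:
    """Gene membership of the predefined fixture panels."""
    out: dict[str, list[str]] = {cat: [] for cat in PANEL_CATEGORIES}
    for gene in GENES.values():
        for cat in gene.panels:
            out[cat].append(gene.symbol)
    return {cat: sorted(genes) for cat, genes in out.items()}


@dataclass
class _Case:
    """One planned variant with the evidence the generator attaches to it."""

    name: str
    gene: str | None
    chrom: str
    pos: int
    ref: str
    alt: str
    # (transcript, consequence_term, protein_text); first entry belongs to the
    # gene's canonical transcript
    anns: tuple[tuple[str, str, str], ...] = ()
    final_consequence: str = "missense"  # expected post-enhancement class
    codon: int | None = None
    aa_alt: str | None = None
    exac: float | None = None
    esp: float | None = None
    pred_calls: tuple[tuple[str, str], ...] = ()
    revel: float | None = None
    matches: tuple[dict, ...] = ()
    whitelist: bool = False
    blacklist: bool = False
    gt: str = "0/1"
    in_panel: bool = True
    retained: bool = True

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def _aa3(one: str) -> str:
    return AA_1TO3[one]


def _protein(aa_ref: str, codon: int, aa_alt: str) -> str:
    alt = "=" if aa_alt == "=" else _aa3(aa_alt)
    return f"p.{_aa3(aa_ref)}{codon}{alt}"


def _m(source: str, mode: str, call: str | None = None, stars: int | None = None,
       record_protein: str | None = None, pubmed: str = "") -> dict:
    return {
        "source": source,
        "mode": mode,
        "call": call,
        "stars": stars,
        "record_protein": record_protein,
        "pubmed": pubmed,
    }


def _build_cases(rng: random.Random) -> list[_Case]:
    cases: list[_Case] = [
        # --- archetypes -------------------------------------------------- #
        _Case(
            "etv6_nonsense", "ETV6", "12", 41250, "C", "T",
            anns=(("NM_ETV601", "stop_gained", _protein("R", 359, "*")),),
            final_consequence="nonsense", codon=359, aa_alt="*",
        ),
        _Case(
            "nras_hotspot", "NRAS", "1", 11385, "C", "T",
            anns=(("NM_NRAS01", "missense_variant", _protein("G", 12, "S")),),
            final_consequence="missense", codon=12, aa_alt="S",
            matches=(_m("CLINVAR", "same_codon", "Pathogenic", 3, _protein("G", 12, "D"), "25157968"),),
        ),
        _Case(
            "notch1_dual", "NOTCH1", "9", 31250, "G", "T",
            anns=(("NM_NOTCH101", "missense_variant", _protein("R", 1350, "L")),),
            final_consequence="missense", codon=1350, aa_alt="L",
            pred_calls=(("SIFT", "tolerated"), ("Polyphen2", "tolerated")),
            matches=(_m("CLINVAR", "exact_genomic", "Pathogenic", 1, pubmed="20301595"),),
        ),
        _Case(
            "mlh1_silent", "MLH1", "3", 21250, "C", "T",
            anns=(("NM_MLH101", "synonymous_variant", _protein("L", 294, "=")),),
            final_consequence="silent", codon=294, aa_alt="=",
            esp=0.0005,
        ),
        _Case(
            "sod1_missense", "SOD1", "21", 61150, "C", "T",
            anns=(("NM_SOD101", "missense_variant", _protein("A", 5, "V")),),
            final_consequence="missense", codon=5, aa_alt="V",
            revel=0.85,
            pred_calls=(("SIFT", "damaging"), ("Polyphen2", "damaging")),
            matches=(_m("ALSOD", "exact_protein", pubmed="8351519"),),
        ),
        # --- splice promotion at exon edges ------------------------------ #
        _Case(
            "tp53_splice_promoted_donor", "TP53", "17", 51200, "G", "A",
            anns=(("NM_TP5301", "synonymous_variant", _protein("T", 125, "=")),),
            final_consequence="splice_region", codon=125, aa_alt="=",
        ),
        _Case(
            "tp53_splice_promoted_window", "TP53", "17", 51398, "G", "A",
            anns=(("NM_TP5301", "synonymous_variant", _protein("E", 224, "=")),),
            final_consequence="splice_region", codon=224, aa_alt="=",
        ),
        # --- frequency-gate rescues (3x) --------------------------------- #
        _Case(
            "tp53_iarc_rescue", "TP53", "17", 51350, "G", "C",
            anns=(("NM_TP5301", "missense_variant", _protein("R", 273, "P")),),
            final_consequence="missense", codon=273, aa_alt="P",
            exac=0.002,
            matches=(_m("IARC_TP53", "exact_genomic"),),
        ),
        _Case(
            "brca2_clinvar_rescue", "BRCA2", "13", 71150, "A", "G",
            anns=(("NM_BRCA201", "missense_variant", _protein("N", 372, "H")),),
            final_consequence="missense", codon=372, aa_alt="H",
            exac=0.005,
            matches=(_m("CLINVAR", "exact_genomic", "Pathogenic", 3, pubmed="9497265"),),
        ),
        _Case(
            "mlh1_clinvar_rescue", "MLH1", "3", 21300, "T", "C",
            anns=(("NM_MLH101", "missense_variant", _protein("I", 310, "T")),),
            final_consequence="missense", codon=310, aa_alt="T",
            exac=0.002,
            matches=(_m("CLINVAR", "exact_protein", "Likely pathogenic", 2),),
        ),
        # --- frequency-gate failures (3x) -------------------------------- #
        _Case(
            "nras_common", "NRAS", "1", 11200, "A", "G",
            anns=(("NM_NRAS01", "missense_variant", _protein("T", 50, "A")),),
            final_consequence="missense", codon=50, aa_alt="A",
            exac=0.002, revel=0.9,
        ),
        _Case(
            "myh7_common", "MYH7", "14", 81200, "C", "T",
            anns=(("NM_MYH701", "missense_variant", _protein("R", 100, "C")),),
            final_consequence="missense", codon=100, aa_alt="C",
            exac=0.01,
        ),
        _Case(
            "brca2_common_ba1", "BRCA2", "13", 71180, "G", "A",
            anns=(("NM_BRCA201", "missense_variant", _protein("V", 382, "I")),),
            final_consequence="missense", codon=382, aa_alt="I",
            exac=0.20, gt="1/1",
        ),
        # --- whitelist (3x) ----------------------------------------------- #
        _Case(
            "wl_brca2", "BRCA2", "13", 71300, "T", "G",
            anns=(("NM_BRCA201", "missense_variant", _protein("S", 439, "A")),),
            final_consequence="missense", codon=439, aa_alt="A",
            whitelist=True,
        ),
        _Case(
            "wl_myh7", "MYH7", "14", 81300, "A", "C",
            anns=(("NM_MYH701", "missense_variant", _protein("K", 133, "Q")),),
            final_consequence="missense", codon=133, aa_alt="Q",
            exac=0.002, whitelist=True,
        ),
        _Case(
            "wl_btk", "BTK", "X", 91200, "C", "G",
            anns=(("NM_BTK01", "synonymous_variant", _protein("P", 34, "=")),),
            final_consequence="silent", codon=34, aa_alt="=",
            whitelist=True,
        ),
        # --- blacklist (3x) ------------------------------------------------ #
        _Case(
            "bl_etv6", "ETV6", "12", 41300, "G", "T",
            anns=(("NM_ETV601", "stop_gained", _protein("E", 376, "*")),),
            final_consequence="nonsense", codon=376, aa_alt="*",
            blacklist=True,
        ),
        _Case(
            "bl_nras", "NRAS", "1", 11300, "G", "A",
            anns=(("NM_NRAS01", "missense_variant", _protein("A", 30, "T")),),
            final_consequence="missense", codon=30, aa_alt="T",
            pred_calls=(("SIFT", "damaging"), ("Polyphen2", "damaging"), ("MutationTaster", "damaging")),
            blacklist=True,
        ),
        _Case(
            "bl_mlh1", "MLH1", "3", 21350, "G", "C",
            anns=(("NM_MLH101", "missense_variant", _protein("E", 327, "Q")),),
            final_consequence="missense", codon=327, aa_alt="Q",
            blacklist=True,
        ),
        # --- remaining rule coverage --------------------------------------- #
        _Case(
            "brca2_trunc_clinvar2star", "BRCA2", "13", 71400, "C", "T",
            anns=(("NM_BRCA201", "stop_gained", _protein("R", 472, "*")),),
            final_consequence="nonsense", codon=472, aa_alt="*",
            matches=(_m("CLINVAR", "exact_genomic", "Pathogenic", 2, pubmed="12228710"),),
        ),
        _Case(
            "myh7_inframe", "MYH7", "14", 81350, "AGCT", "A",
            anns=(("NM_MYH701", "inframe_deletion", "p.Lys150del"),),
            final_consequence="inframe_indel", codon=150, aa_alt=None,
        ),
        _Case(
            "myh7_trunc_nonlof", "MYH7", "14", 81400, "C", "T",
            anns=(("NM_MYH701", "stop_gained", _protein("Q", 167, "*")),),
            final_consequence="nonsense", codon=167, aa_alt="*",
        ),
        _Case(
            "brca2_imperfect_gold", "BRCA2", "13", 71450, "G", "A",
            anns=(("NM_BRCA201", "missense_variant", _protein("G", 489, "D")),),
            final_consequence="missense", codon=489, aa_alt="D",
            matches=(_m("CLINVAR", "same_codon", "Pathogenic", 3, _protein("G", 489, "C")),),
        ),
        _Case(
            "sod1_imperfect_silver", "SOD1", "21", 61200, "C", "A",
            anns=(("NM_SOD101", "missense_variant", _protein("L", 22, "M")),),
            final_consequence="missense", codon=22, aa_alt="M",
            matches=(_m("ALSOD", "same_codon", record_protein=_protein("L", 22, "V")),),
        ),
        _Case(
            "myh7_tolerated", "MYH7", "14", 81450, "T", "C",
            anns=(("NM_MYH701", "missense_variant", _protein("F", 184, "L")),),
            final_consequence="missense", codon=184, aa_alt="L",
            pred_calls=(("SIFT", "tolerated"), ("Polyphen2", "tolerated"), ("LRT", "tolerated")),
        ),
        _Case(
            "btk_tolerated", "BTK", "X", 91300, "A", "G",
            anns=(("NM_BTK01", "missense_variant", _protein("I", 67, "V")),),
            final_consequence="missense", codon=67, aa_alt="V",
            pred_calls=(("SIFT", "tolerated"), ("Polyphen2", "tolerated")),
            revel=0.1,
        ),
        _Case(
            "nras_damaging_only", "NRAS", "1", 11350, "T", "A",
            anns=(("NM_NRAS01", "missense_variant", _protein("Y", 80, "N")),),
            final_consequence="missense", codon=80, aa_alt="N",
            revel=0.9,
        ),
        _Case(
            "brca2_noevidence_a", "BRCA2", "13", 71500, "A", "G",
            anns=(("NM_BRCA201", "missense_variant", _protein("T", 505, "A")),),
            final_consequence="missense", codon=505, aa_alt="A",
            pred_calls=(("SIFT", "unknown"),),
        ),
        _Case(
            "brca2_noevidence_b", "BRCA2", "13", 71500, "A", "T",
            anns=(("NM_BRCA201", "missense_variant", _protein("T", 505, "S")),),
            final_consequence="missense", codon=505, aa_alt="S",
        ),
        _Case(
            "myh7_somatic_imperfect", "MYH7", "14", 81500, "G", "T",
            anns=(("NM_MYH701", "missense_variant", _protein("G", 200, "V")),),
            final_consequence="missense", codon=200, aa_alt="V",
        ),
        _Case(
            "btk_frameshift", "BTK", "X", 91400, "C", "CA",
            anns=(("NM_BTK01", "frameshift_variant", "p.Thr100fs"),),
            final_consequence="frameshift", codon=100, aa_alt=None,
        ),
        _Case(
            "brca2_severity_select", "BRCA2", "13", 71550, "C", "G",
            anns=(
                ("NM_BRCA201", "missense_variant", _protein("S", 522, "C")),
                ("NM_BRCA202", "stop_gained", _protein("S", 522, "*")),
            ),
            final_consequence="nonsense", codon=522, aa_alt="*",
        ),
        _Case(
            "notch1_pcgp_hotspot", "NOTCH1", "9", 31350, "A", "T",
            anns=(("NM_NOTCH101", "missense_variant", _protein("S", 1383, "C")),),
            final_consequence="missense", codon=1383, aa_alt="C",
        ),
        _Case(
            "mlh1_committee", "MLH1", "3", 21380, "C", "G",
            anns=(("NM_MLH101", "missense_variant", _protein("P", 337, "A")),),
            final_consequence="missense", codon=337, aa_alt="A",
            matches=(_m("COMMITTEE", "exact_genomic", "Likely pathogenic", pubmed="30322717"),),
        ),
        # --- dropped at functional / panel stages -------------------------- #
        _Case(
            "mlh1_intronic", "MLH1", "3", 21500, "A", "G",
            anns=(("NM_MLH101", "intron_variant", ""),),
            final_consequence="intron", retained=False,
        ),
        _Case(
            "nras_utr", "NRAS", "1", 11450, "C", "T",
            anns=(("NM_NRAS01", "3_prime_utr_variant", ""),),
            final_consequence="utr", retained=False,
        ),
        _Case(
            "nonpanel", None, "7", 5000, "A", "C",
            anns=(("NM_OFFPANEL1", "intergenic_variant", ""),),
            final_consequence="intergenic", in_panel=False, retained=False,
        ),
    ]

    # Seeded filler: evidence-free missense variants in the BRCA2 exon
    # interior, adding unknown-medal bulk.
    candidates = [71120, 71230, 71260, 71530, 71560, 71570]
    positions = sorted(rng.sample(candidates, 4))
    bases = "ACGT"
    aa_letters = [a for a in AA_1TO3 if a != "*"]
    used_codons: set[int] = set()
    for i, pos in enumerate(positions):
        ref = rng.choice(bases)
        alt = rng.choice([b for b in bases if b != ref])
        codon = rng.randint(600, 700)
        while codon in used_codons:
            codon = rng.randint(600, 700)
        used_codons.add(codon)
        aa_ref = rng.choice(aa_letters)
        aa_alt = rng.choice([a for a in aa_letters if a != aa_ref])
        cases.append(
            _Case(
                f"filler_{i}", "BRCA2", "13", pos, ref, alt,
                anns=(("NM_BRCA201", "missense_variant", _protein(aa_ref, codon, aa_alt)),),
                final_consequence="missense", codon=codon, aa_alt=aa_alt,
            )
        )
    return cases


# Hotspot table: (source, gene, codon, tumor_count, aa_changes, curated_flag)
_HOTSPOTS = [
    ("COSMIC", "NRAS", 12, 4000, ("D", "S", "V"), False),
    ("COSMIC", "MYH7", 200, 15, ("D",), False),
    ("COSMIC", "SOD1", 22, 4, ("M",), False),
    ("PCGP", "NOTCH1", 1383, 3, ("C",), True),
]

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}


def _chrom_key(chrom: str) -> int:
    return _CHROM_ORDER.get(chrom, 99)


def _case_features(case: _Case, cfg: Config) -> RuleFeatures:
    matches = []
    grade_by_mode = {
        "exact_genomic": "EXACT_GENOMIC",
        "exact_protein": "EXACT_PROTEIN",
        "same_pos": "SAME_POSITION_DIFF_ALLELE",
        "same_codon": "SAME_CODON_DIFF_AA",
    }
    for m in case.matches:
        call = standardize_pathogenicity(m["call"]) if m["call"] else None
        matches.append(
            MatchFeature(source=m["source"], grade=grade_by_mode[m["mode"]],
                         call=call, stars=m["stars"])
        )
    cosmic_count = None
    pcgp_curated = False
    direct = False
    for source, gene, codon, count, aa_changes, flag in _HOTSPOTS:
        if gene != case.gene or codon != case.codon:
            continue
        if source == "COSMIC":
            cosmic_count = count
            if count >= cfg.hotspot_min_tumors and case.aa_alt in aa_changes:
                direct = True
        else:
            pcgp_curated = pcgp_curated or flag
            if flag and case.aa_alt in aa_changes:
                direct = True
    prediction = aggregate_prediction_oracle(
        tuple(call for _, call in case.pred_calls), case.revel, cfg
    )
    return RuleFeatures(
        consequence=case.final_consequence,
        is_lof_gene=bool(case.gene and GENES[case.gene].lof),
        exac_af=case.exac,
        matches=tuple(matches),
        cosmic_hotspot_count=cosmic_count,
        pcgp_hotspot_curated=pcgp_curated,
        hotspot_aa_direct=direct,
        prediction=prediction,
        whitelisted=case.whitelist,
        blacklisted=case.blacklist,
    )


def _write_vcf(cases: list[_Case], path: Path) -> dict[str, int]:
    groups: dict[tuple[str, int, str], list[str]] = {}
    gts: dict[tuple[str, int, str], str] = {}
    for case in cases:
        key = (case.chrom, case.pos, case.ref)
        groups.setdefault(key, []).append(case.alt)
        gts[key] = case.gt
    # One symbolic-ALT record, skipped (and counted) by the reader.
    symbolic_key = ("13", 71600, "T")
    groups[symbolic_key] = ["<DEL>"]
    gts[symbolic_key] = "0/1"

    ordered = sorted(groups, key=lambda k: (_chrom_key(k[0]), k[1], k[2]))
    chroms = sorted({k[0] for k in ordered}, key=_chrom_key)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE01")
    for key in ordered:
        chrom, pos, ref = key
        alts = ",".join(groups[key])
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alts}\t50\tPASS\t.\tGT\t{gts[key]}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    n_alts = sum(len(a) for a in groups.values())
    return {
        "vcf_records": len(ordered),
        "decomposed_variants": n_alts - 1,
        "skipped_symbolic": 1,
    }


def _write_panels(out_dir: Path) -> None:
    rows = []
    for gene in GENES.values():
        rows.append((gene.chrom, gene.panel_start, gene.panel_end, gene.symbol, gene.panels))
    rows.sort(key=lambda r: (_chrom_key(r[0]), r[1]))
    header = "# chrom\tstart\tend\tgene_symbol\n"
    with open(out_dir / "panel.tsv", "w", encoding="utf-8") as fh:
        fh.write(header)
        for chrom, start, end, gene, _ in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{gene}\n")
    for category in PANEL_CATEGORIES:
        with open(out_dir / f"panel_{category}.tsv", "w", encoding="utf-8") as fh:
            fh.write(header)
            for chrom, start, end, gene, panels in rows:
                if category in panels:
                    fh.write(f"{chrom}\t{start}\t{end}\t{gene}\n")


def _write_genes(out_dir: Path) -> None:
    with open(out_dir / "genes.tsv", "w", encoding="utf-8") as fh:
        fh.write("symbol\tpanels\tis_lof_gene\tinheritance\n")
        for symbol in sorted(GENES):
            g = GENES[symbol]
            fh.write(
                f"{symbol}\t{','.join(g.panels)}\t{int(g.lof)}\t{g.inheritance}\n"
            )


def _write_exons(out_dir: Path) -> None:
    with open(out_dir / "exons.tsv", "w", encoding="utf-8") as fh:
        fh.write("transcript\tstrand\texon_start\texon_end\n")
        for symbol in sorted(GENES):
            g = GENES[symbol]
            for start, end in g.exons:
                fh.write(f"{g.transcript}\t{g.strand}\t{start}\t{end}\n")
        # Alternate transcript used by the severity-selection case.
        fh.write("NM_BRCA202\t+\t71100\t71600\n")


def _write_annotations(cases: list[_Case], out_dir: Path) -> int:
    rows = []
    for case in cases:
        for transcript, term, protein in case.anns:
            rows.append(
                (case.chrom, case.pos, case.ref, case.alt,
                 case.gene or "OFFPANEL", transcript, term, "", protein)
            )
    rows.sort(key=lambda r: (_chrom_key(r[0]), r[1], r[3], r[5]))
    with open(out_dir / "annotations.tsv", "w", encoding="utf-8") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\ttranscript\tconsequence\tcdna_hgvs\tprotein_hgvs\n")
        for row in rows:
            fh.write("\t".join(str(f) for f in row) + "\n")
    return len(rows)


def _write_knowledgebase(cases: list[_Case], kb_dir: Path) -> dict[str, int]:
    kb_dir.mkdir(parents=True, exist_ok=True)
    (kb_dir / "snapshot_label.txt").write_text(SNAPSHOT_LABEL + "\n", encoding="utf-8")
    _OTHER_BASE = {"A": "C", "C": "G", "G": "T", "T": "A"}

    curated_rows = []
    for case in cases:
        primary_protein = case.anns[0][2] if case.anns else ""
        for m in case.matches:
            mode = m["mode"]
            if mode == "exact_genomic":
                coords = (case.chrom, case.pos, case.ref, case.alt)
                protein = primary_protein
            elif mode == "exact_protein":
                coords = ("", "", "", "")
                protein = primary_protein
            elif mode == "same_pos":
                other = _OTHER_BASE[case.alt[0]]
                if other == case.ref:
                    other = _OTHER_BASE[other]
                coords = (case.chrom, case.pos, case.ref, other)
                protein = ""
            else:  # same_codon
                coords = ("", "", "", "")
                protein = m["record_protein"] or ""
            curated_rows.append(
                (m["source"], *coords, case.gene or "", protein,
                 m["call"] or "", "" if m["stars"] is None else m["stars"], m["pubmed"])
            )
    curated_rows.sort(key=lambda r: (r[0], str(r[1]), str(r[2]), r[5], r[6]))
    with open(kb_dir / "curated.tsv", "w", encoding="utf-8") as fh:
        fh.write("source\tchrom\tpos\tref\talt\tgene\tprotein_change\tcall\tstars\tpubmed_ids\n")
        for row in curated_rows:
            fh.write("\t".join(str(f) for f in row) + "\n")

    with open(kb_dir / "hotspots.tsv", "w", encoding="utf-8") as fh:
        fh.write("source\tgene\tcodon\ttumor_count\taa_changes\tcurated_flag\n")
        for source, gene, codon, count, aa_changes, flag in sorted(_HOTSPOTS):
            fh.write(
                f"{source}\t{gene}\t{codon}\t{count}\t{','.join(sorted(aa_changes))}\t{int(flag)}\n"
            )

    freq_rows = [
        (case.chrom, case.pos, case.ref, case.alt, case.exac, case.esp)
        for case in cases
        if case.exac is not None or case.esp is not None
    ]
    freq_rows.sort(key=lambda r: (_chrom_key(r[0]), r[1], r[3]))
    with open(kb_dir / "frequencies.tsv", "w", encoding="utf-8") as fh:
        fh.write("chrom\tpos\tref\talt\texac_nontcga\tesp\tkg1000\tpcgp\n")
        for chrom, pos, ref, alt, exac, esp in freq_rows:
            exac_s = "" if exac is None else repr(exac)
            esp_s = "" if esp is None else repr(esp)
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{exac_s}\t{esp_s}\t\t\n")

    pred_rows = []
    for case in cases:
        revel_s = "" if case.revel is None else repr(case.revel)
        if case.pred_calls:
            for j, (algo, call) in enumerate(case.pred_calls):
                pred_rows.append(
                    (case.chrom, case.pos, case.ref, case.alt, algo, call,
                     revel_s if j == 0 else "")
                )
        elif case.revel is not None:
            pred_rows.append((case.chrom, case.pos, case.ref, case.alt, "", "", revel_s))
    pred_rows.sort(key=lambda r: (_chrom_key(r[0]), r[1], r[3], r[4]))
    with open(kb_dir / "predictions.tsv", "w", encoding="utf-8") as fh:
        fh.write("chrom\tpos\tref\talt\talgorithm\tcall\trevel\n")
        for row in pred_rows:
            fh.write("\t".join(str(f) for f in row) + "\n")

    return {
        "curated": len(curated_rows),
        "hotspots": len(_HOTSPOTS),
        "frequencies": len(freq_rows),
        "predictions": len(pred_rows),
    }


def generate_suite(seed: int, out_dir: str | Path, cfg: Config | None = None) -> dict:
    """Generate the full synthetic suite; returns (and writes) the manifest.

    Identical seeds produce byte-identical outputs. The manifest's expected
    medals, gate statuses, tags and classifications come from the
    independent oracles, and the generator self-checks that every germline
    medal tier and every gate status is represented at least three times.
    """
    cfg = cfg or Config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    cases = _build_cases(rng)

    vcf_stats = _write_vcf(cases, out / "suite.vcf")
    _write_panels(out)
    _write_genes(out)
    _write_exons(out)
    annotation_rows = _write_annotations(cases, out)
    kb_counts = _write_knowledgebase(cases, out / "kb")

    wl = sorted(c.key for c in cases if c.whitelist)
    bl = sorted(c.key for c in cases if c.blacklist)
    (out / "whitelist.txt").write_text(
        "# whitelisted variant keys\n" + "".join(k + "\n" for k in wl), encoding="utf-8"
    )
    (out / "blacklist.txt").write_text(
        "# blacklisted variant keys\n" + "".join(k + "\n" for k in bl), encoding="utf-8"
    )

    variants: dict[str, dict] = {}
    tier_counts: dict[str, int] = {}
    gate_counts: dict[str, int] = {}
    funnel_panel = funnel_functional = funnel_gate = funnel_medaled = 0
    for case in cases:
        entry: dict = {
            "name": case.name,
            "gene": case.gene,
            "in_panel": case.in_panel,
            "retained": case.retained,
        }
        if case.in_panel:
            funnel_panel += 1
        if case.in_panel and case.retained:
            funnel_functional += 1
            features = _case_features(case, cfg)
            germline, gate_status = medal_oracle(features, cfg)
            somatic = somatic_medal_oracle(features, cfg)
            tags = auto_tags_oracle(features, cfg)
            entry.update(
                {
                    "consequence": case.final_consequence,
                    "germline_medal": germline,
                    "gate_status": gate_status,
                    "somatic_medal": somatic,
                    "auto_tags": sorted(tags),
                    "classification": classify_oracle(tags),
                }
            )
            tier_counts[germline] = tier_counts.get(germline, 0) + 1
            gate_counts[gate_status] = gate_counts.get(gate_status, 0) + 1
            if gate_status not in {"failed_frequency", "blacklisted"}:
                funnel_gate += 1
            if germline != "UNKNOWN":
                funnel_medaled += 1
        variants[case.key] = entry

    for tier in ("GOLD", "SILVER", "BRONZE", "UNKNOWN"):
        assert tier_counts.get(tier, 0) >= 3, f"medal tier {tier} underrepresented"
    for status in ("passed", "failed_frequency", "rescued_by_exception", "whitelisted", "blacklisted"):
        assert gate_counts.get(status, 0) >= 3, f"gate status {status} underrepresented"

    manifest = {
        "seed": seed,
        "snapshot_label": SNAPSHOT_LABEL,
        "funnel": {
            **vcf_stats,
            "panel_filtered": funnel_panel,
            "functional_retained": funnel_functional,
            "gate_passed": funnel_gate,
            "medaled": funnel_medaled,
        },
        "kb_counts": kb_counts,
        "annotation_rows": annotation_rows,
        "medal_counts": dict(sorted(tier_counts.items())),
        "gate_counts": dict(sorted(gate_counts.items())),
        "archetypes": {
            c.name: c.key
            for c in cases
            if c.name in {
                "etv6_nonsense", "nras_hotspot", "notch1_dual",
                "mlh1_silent", "sod1_missense",
            }
        },
        "variants": variants,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


def generate_frequency_sweep(
    variant_key: str, grid: list[float], out_dir: str | Path
) -> Path:
    """Write a frequency sweep: one row per grid point for one variant key.

    The driver table lists the sweep index and the ExAC non-TCGA frequency
    to apply at that point; consumers construct per-point frequency profiles
    from it.
    """
    for f in grid:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"grid frequency {f} outside [0,1]")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "frequency_sweep.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("index\tvariant_key\texac_nontcga\n")
        for i, f in enumerate(grid):
            fh.write(f"{i}\t{variant_key}\t{f!r}\n")
    return path
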