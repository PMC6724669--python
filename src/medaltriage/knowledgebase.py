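"""Curated-database snapshots and graded variant matching.

The resources behind variant triage — curated pathogenicity calls (ClinVar,
IARC TP53, locus-specific databases, committee review), somatic hotspot
counts (COSMIC, pediatric cancer cohorts), population allele frequencies and
in-silico damage predictions — are consumed as versioned tab-delimited
snapshot files. Queries return *graded* matches: an exact genomic match is
stronger evidence than an identical protein change on another transcript,
which in turn is stronger than a different allele at the same position or a
different amino-acid change at the same codon. Downstream rules downgrade
medals for the imperfect grades.

Protein-level matching requires the same gene and codon number; transcript
identity is deliberately not required, because locus databases rarely state
transcripts. The grade system communicates the residual uncertainty.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import pandas as pd

from .config import Config
from .nomenclature import ProteinChange, parse_protein_change, standardize_pathogenicity
from .variants import GenomicVariant, TranscriptAnnotation, canonical_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "CURATED_SOURCES",
    "HOTSPOT_SOURCES",
    "MatchGrade",
    "CuratedVariantRecord",
    "HotspotRecord",
    "PopulationFrequencies",
    "PredictionProfile",
    "Match",
    "Knowledgebase",
    "load_snapshot",
    "save_snapshot",
]

CURATED_SOURCES = frozenset(
    {
        "CLINVAR",
        "IARC_TP53",
        "ASU_TERT",
        "ARUP_MEN2",
        "NHGRI_BIC",
        "BRCA_SHARE",
        "ALSOD",
        "LOVD_APC",
        "LOVD_MSH2",
        "RB1",
        "COMMITTEE",
    }
)
HOTSPOT_SOURCES = frozenset({"COSMIC", "PCGP"})

_CURATED_COLUMNS = [
    "source", "chrom", "pos", "ref", "alt", "gene",
    "protein_change", "call", "stars", "pubmed_ids",
]
_HOTSPOT_COLUMNS = ["source", "gene", "codon", "tumor_count", "aa_changes", "curated_flag"]
_FREQUENCY_COLUMNS = ["chrom", "pos", "ref", "alt", "exac_nontcga", "esp", "kg1000", "pcgp"]
_PREDICTION_COLUMNS = ["chrom", "pos", "ref", "alt", "algorithm", "call", "revel"]


class MatchGrade(IntEnum):
    """Match specificity, ordered from weakest to strongest."""

    NONE = 0
    SAME_CODON_DIFF_AA = 1
    SAME_POSITION_DIFF_ALLELE = 2
    EXACT_PROTEIN = 3
    EXACT_GENOMIC = 4


#: Grades that count as a direct (non-imperfect) database hit.
EXACT_GRADES = frozenset({MatchGrade.EXACT_GENOMIC, MatchGrade.EXACT_PROTEIN})
#: Grades that count as imperfect hits, medaled one tier lower.
IMPERFECT_GRADES = frozenset(
    {MatchGrade.SAME_POSITION_DIFF_ALLELE, MatchGrade.SAME_CODON_DIFF_AA}
)


@dataclass(frozen=True)
class CuratedVariantRecord:
    """One curated-variant assertion from a pathogenicity database."""

    source: str
    genomic_key: str | None = None
    gene: str = ""
    protein_change: ProteinChange | None = None
    call: str | None = None  # standardized B/LB/VUS/LP/P, or None
    raw_call: str = ""
    stars: int | None = None  # ClinVar review stars, 0-4
    pubmed_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.source not in CURATED_SOURCES:
            raise ValueError(f"unknown curated source {self.source!r}")
        if self.genomic_key is None and not (self.gene and self.protein_change):
            raise ValueError(
                "curated record needs a genomic key or (gene + protein change)"
            )
        if self.stars is not None:
            if self.source != "CLINVAR":
                raise ValueError("stars are only valid for CLINVAR records")
            if not 0 <= self.stars <= 4:
                raise ValueError(f"stars must be 0-4, got {self.stars}")

    @property
    def is_pathogenic_call(self) -> bool:
        return self.call in {"P", "LP"}


@dataclass(frozen=True)
class HotspotRecord:
    """Recurrently mutated codon in a somatic database (pre-aggregated)."""

    source: str
    gene: str
    codon: int
    tumor_count: int
    aa_changes: frozenset[str] = frozenset()
    curated_flag: bool = False

    def __post_init__(self) -> None:
        if self.source not in HOTSPOT_SOURCES:
            raise ValueError(f"unknown hotspot source {self.source!r}")
        if self.tumor_count < 1:
            raise ValueError(f"tumor_count must be >= 1, got {self.tumor_count}")


@dataclass(frozen=True)
class PopulationFrequencies:
    """Per-source allele frequencies; ``None`` means not observed.

    Absent and 0.0 differ only in provenance — both satisfy every
    absent-or-rare predicate; only a present value above a threshold fails.
    """

    exac_nontcga: float | None = None
    esp: float | None = None
    kg1000: float | None = None
    pcgp: float | None = None

    def __post_init__(self) -> None:
        for name in ("exac_nontcga", "esp", "kg1000", "pcgp"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {value}")

    def as_dict(self) -> dict[str, float | None]:
        return {
            "exac_nontcga": self.exac_nontcga,
            "esp": self.esp,
            "kg1000": self.kg1000,
            "pcgp": self.pcgp,
        }


@dataclass(frozen=True)
class PredictionProfile:
    """In-silico damage predictions: categorical calls plus a REVEL score."""

    calls: tuple[tuple[str, str], ...] = ()  # (algorithm, damaging/tolerated/unknown)
    revel: float | None = None

    def __post_init__(self) -> None:
        if self.revel is not None and not 0.0 <= self.revel <= 1.0:
            raise ValueError(f"revel must be in [0,1], got {self.revel}")
        for algo, call in self.calls:
            if call not in {"damaging", "tolerated", "unknown"}:
                raise ValueError(f"bad prediction call {call!r} for {algo}")

    @property
    def is_empty(self) -> bool:
        return self.revel is None and not self.calls


@dataclass(frozen=True)
class Match:
    """A curated record together with its best applicable match grade."""

    record: CuratedVariantRecord
    grade: MatchGrade


class Knowledgebase:
    """Indexed snapshots with graded match queries.

    Built by :func:`load_snapshot` (or directly from record lists in tests
    and fixtures). Indexes: genomic key, (chrom, pos), (gene, codon) for
    curated records; (gene, codon) for hotspots; genomic key for frequencies
    and predictions.
    """

    def __init__(
        self,
        curated: list[CuratedVariantRecord] | None = None,
        hotspots: list[HotspotRecord] | None = None,
        frequencies: dict[str, PopulationFrequencies] | None = None,
        predictions: dict[str, PredictionProfile] | None = None,
        label: str = "unversioned",
        manifest: dict | None = None,
    ) -> None:
        self.curated = list(curated or [])
        self.frequencies_by_key = dict(frequencies or {})
        self.predictions_by_key = dict(predictions or {})
        self.label = label
        self.manifest = manifest or {
            "label": label,
            "counts": {
                "curated": len(self.curated),
                "hotspots": len(hotspots or []),
                "frequencies": len(self.frequencies_by_key),
                "predictions": len(self.predictions_by_key),
            },
            "warnings": {},
        }

        self._by_key: dict[str, list[CuratedVariantRecord]] = {}
        self._by_pos: dict[tuple[str, int], list[CuratedVariantRecord]] = {}
        self._by_gene_codon: dict[tuple[str, int], list[CuratedVariantRecord]] = {}
        for rec in self.curated:
            if rec.genomic_key:
                self._by_key.setdefault(rec.genomic_key, []).append(rec)
                chrom, pos, _ = rec.genomic_key.split(":", 2)
                self._by_pos.setdefault((chrom, int(pos)), []).append(rec)
            if rec.gene and rec.protein_change is not None:
                key = (rec.gene, rec.protein_change.codon)
                self._by_gene_codon.setdefault(key, []).append(rec)

        self._hotspots: dict[tuple[str, int], list[HotspotRecord]] = {}
        for hs in hotspots or []:
            self._hotspots.setdefault((hs.gene, hs.codon), []).append(hs)

    # ------------------------------------------------------------------ #
    # lookups

    def frequencies(self, v: GenomicVariant) -> PopulationFrequencies:
        return self.frequencies_by_key.get(v.key, PopulationFrequencies())

    def predictions(self, v: GenomicVariant) -> PredictionProfile:
        return self.predictions_by_key.get(v.key, PredictionProfile())

    def hotspot_records(self, gene: str, codon: int) -> list[HotspotRecord]:
        return sorted(
            self._hotspots.get((gene, codon), []),
            key=lambda h: (h.source, -h.tumor_count),
        )

    # ------------------------------------------------------------------ #
    # graded matching

    def match(
        self, v: GenomicVariant, ann: TranscriptAnnotation | None = None
    ) -> list[Match]:
        """All curated records sharing the variant's position or codon.

        Each record appears once with its best applicable grade; ordering is
        deterministic (source, then grade strongest-first, then key).
        """
        grades: dict[int, tuple[CuratedVariantRecord, MatchGrade]] = {}

        def _offer(rec: CuratedVariantRecord, grade: MatchGrade) -> None:
            prev = grades.get(id(rec))
            if prev is None or grade > prev[1]:
                grades[id(rec)] = (rec, grade)

        for rec in self._by_pos.get((v.chrom, v.pos), []):
            if rec.genomic_key == v.key:
                _offer(rec, MatchGrade.EXACT_GENOMIC)
            else:
                _offer(rec, MatchGrade.SAME_POSITION_DIFF_ALLELE)

        if ann is not None and ann.gene and ann.codon is not None:
            for rec in self._by_gene_codon.get((ann.gene, ann.codon), []):
                assert rec.protein_change is not None
                if ann.protein_change is not None and rec.protein_change.same_change(
                    ann.protein_change
                ):
                    _offer(rec, MatchGrade.EXACT_PROTEIN)
                else:
                    _offer(rec, MatchGrade.SAME_CODON_DIFF_AA)

        matches = [Match(rec, grade) for rec, grade in grades.values()]
        matches.sort(key=lambda m: (m.record.source, -m.grade, m.record.genomic_key or ""))
        return matches

    def is_hotspot(
        self,
        gene: str,
        codon: int,
        cfg: Config,
        sources: frozenset[str] | None = None,
    ) -> tuple[bool, HotspotRecord | None]:
        """Whether (gene, codon) is a qualifying somatic hotspot.

        COSMIC records qualify at ``tumor_count >= cfg.hotspot_min_tumors``;
        pediatric-cohort (PCGP) records qualify only via their explicit
        curated-hotspot flag, independent of count.
        """
        best: HotspotRecord | None = None
        for hs in self.hotspot_records(gene, codon):
            if sources is not None and hs.source not in sources:
                continue
            qualifies = (
                hs.tumor_count >= cfg.hotspot_min_tumors
                if hs.source == "COSMIC"
                else hs.curated_flag
            )
            if qualifies and (best is None or hs.tumor_count > best.tumor_count):
                best = hs
        return best is not None, best

    def frequency_gate_exception(
        self, v: GenomicVariant, ann: TranscriptAnnotation | None, cfg: Config
    ) -> tuple[bool, str | None]:
        """Rescue from the frequency gate via high-confidence curated matches.

        True for an exact (genomic or protein) match to the IARC TP53
        database, or to a ClinVar P/LP record with at least
        ``cfg.clinvar_min_stars`` review stars.
        """
        for m in self.match(v, ann):
            if m.grade not in EXACT_GRADES:
                continue
            rec = m.record
            if rec.source == "IARC_TP53":
                return True, f"exact match to IARC_TP53 ({m.grade.name})"
            if (
                rec.source == "CLINVAR"
                and rec.is_pathogenic_call
                and rec.stars is not None
                and rec.stars >= cfg.clinvar_min_stars
            ):
                return True, (
                    f"exact ClinVar {rec.call} match with {rec.stars} stars "
                    f"({m.grade.name})"
                )
        return False, None


# ---------------------------------------------------------------------- #
# snapshot I/O


def _read_table(path: Path, expected_columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    unknown = [c for c in df.columns if c not in expected_columns]
    if unknown:
        raise ValueError(f"{path.name}: unknown column {unknown[0]!r}")
    missing = [c for c in expected_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column {missing[0]!r}")
    return df


def _genomic_key(chrom: str, pos: str, ref: str, alt: str) -> str | None:
    if chrom and pos and ref and alt:
        return f"{canonical_chrom(chrom)}:{int(pos)}:{ref}>{alt}"
    return None


def _opt_float(value: str, where: str) -> float | None:
    if value == "":
        return None
    try:
        return float(value)
    except ValueError as exc:
        raise ValueError(f"{where}: bad numeric value {value!r}") from exc


def load_snapshot(snapshot_dir: str | os.PathLike) -> Knowledgebase:
    """Load a snapshot directory into an indexed :class:`Knowledgebase`.

    Any subset of ``curated.tsv``, ``hotspots.tsv``, ``frequencies.tsv``,
    ``predictions.tsv`` may be present; an empty directory yields an empty
    (but valid) knowledgebase. Duplicate curated ``(source, genomic_key)``
    pairs resolve last-wins with a counted warning. An optional
    ``snapshot_label.txt`` names the snapshot version; otherwise the
    directory name is used.
    """
    root = Path(snapshot_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"snapshot directory not found: {root}")

    label_file = root / "snapshot_label.txt"
    label = label_file.read_text(encoding="utf-8").strip() if label_file.exists() else root.name
    warnings: dict[str, int] = {}
    counts: dict[str, int] = {}

    curated: list[CuratedVariantRecord] = []
    path = root / "curated.tsv"
    if path.exists():
        df = _read_table(path, _CURATED_COLUMNS)
        counts["curated"] = len(df)
        seen: dict[tuple[str, str], int] = {}
        rows: list[CuratedVariantRecord] = []
        for i, row in enumerate(df.itertuples(index=False)):
            stars = None
            if row.stars != "":
                stars = int(row.stars)
                if not 0 <= stars <= 4:
                    raise ValueError(f"{path.name} row {i + 2}: stars must be 0-4, got {stars}")
            parse = parse_protein_change(row.protein_change) if row.protein_change else None
            call = standardize_pathogenicity(row.call) if row.call else None
            if call == "unmapped":
                warnings["unmapped_pathogenicity_label"] = (
                    warnings.get("unmapped_pathogenicity_label", 0) + 1
                )
                logger.warning(
                    "%s row %d: unmapped pathogenicity label %r", path.name, i + 2, row.call
                )
            rec = CuratedVariantRecord(
                source=row.source,
                genomic_key=_genomic_key(row.chrom, row.pos, row.ref, row.alt),
                gene=row.gene,
                protein_change=parse.change if parse and parse.ok else None,
                call=call,
                raw_call=row.call,
                stars=stars,
                pubmed_ids=tuple(p for p in row.pubmed_ids.split(",") if p),
            )
            if rec.genomic_key is not None:
                dup_key = (rec.source, rec.genomic_key)
                if dup_key in seen:
                    warnings["duplicate_curated_key"] = (
                        warnings.get("duplicate_curated_key", 0) + 1
                    )
                    rows[seen[dup_key]] = None  # type: ignore[call-overload]
                seen[dup_key] = len(rows)
            rows.append(rec)
        curated = [r for r in rows if r is not None]

    hotspots: list[HotspotRecord] = []
    path = root / "hotspots.tsv"
    if path.exists():
        df = _read_table(path, _HOTSPOT_COLUMNS)
        counts["hotspots"] = len(df)
        by_key: dict[tuple[str, str, int], HotspotRecord] = {}
        for row in df.itertuples(index=False):
            rec = HotspotRecord(
                source=row.source,
                gene=row.gene,
                codon=int(row.codon),
                tumor_count=int(row.tumor_count),
                aa_changes=frozenset(a for a in row.aa_changes.split(",") if a),
                curated_flag=row.curated_flag.strip().lower() in {"1", "true", "yes"},
            )
            key = (rec.source, rec.gene, rec.codon)
            if key in by_key:
                warnings["duplicate_hotspot_key"] = warnings.get("duplicate_hotspot_key", 0) + 1
            by_key[key] = rec
        hotspots = list(by_key.values())

    frequencies: dict[str, PopulationFrequencies] = {}
    path = root / "frequencies.tsv"
    if path.exists():
        df = _read_table(path, _FREQUENCY_COLUMNS)
        counts["frequencies"] = len(df)
        for i, row in enumerate(df.itertuples(index=False)):
            key = _genomic_key(row.chrom, row.pos, row.ref, row.alt)
            if key is None:
                raise ValueError(f"{path.name} row {i + 2}: incomplete variant key")
            frequencies[key] = PopulationFrequencies(
                exac_nontcga=_opt_float(row.exac_nontcga, f"{path.name} row {i + 2}"),
                esp=_opt_float(row.esp, f"{path.name} row {i + 2}"),
                kg1000=_opt_float(row.kg1000, f"{path.name} row {i + 2}"),
                pcgp=_opt_float(row.pcgp, f"{path.name} row {i + 2}"),
            )

    predictions: dict[str, PredictionProfile] = {}
    path = root / "predictions.tsv"
    if path.exists():
        df = _read_table(path, _PREDICTION_COLUMNS)
        counts["predictions"] = len(df)
        calls_by_key: dict[str, list[tuple[str, str]]] = {}
        revel_by_key: dict[str, float] = {}
        for i, row in enumerate(df.itertuples(index=False)):
            key = _genomic_key(row.chrom, row.pos, row.ref, row.alt)
            if key is None:
                raise ValueError(f"{path.name} row {i + 2}: incomplete variant key")
            if row.algorithm:
                call = row.call if row.call else "unknown"
                calls_by_key.setdefault(key, []).append((row.algorithm, call))
            revel = _opt_float(row.revel, f"{path.name} row {i + 2}")
            if revel is not None:
                revel_by_key[key] = revel
        for key in set(calls_by_key) | set(revel_by_key):
            predictions[key] = PredictionProfile(
                calls=tuple(sorted(calls_by_key.get(key, []))),
                revel=revel_by_key.get(key),
            )

    manifest = {"label": label, "counts": counts, "warnings": warnings}
    return Knowledgebase(
        curated=curated,
        hotspots=hotspots,
        frequencies=frequencies,
        predictions=predictions,
        label=label,
        manifest=manifest,
    )


def save_snapshot(kb: Knowledgebase, out_dir: str | os.PathLike) -> None:
    """Serialize a knowledgebase back to the snapshot TSV dialect."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    (root / "snapshot_label.txt").write_text(kb.label + "\n", encoding="utf-8")

    def _split_key(key: str | None) -> tuple[str, str, str, str]:
        if not key:
            return "", "", "", ""
        chrom, pos, rest = key.split(":", 2)
        ref, alt = rest.split(">", 1)
        return chrom, pos, ref, alt

    curated_rows = []
    for rec in kb.curated:
        chrom, pos, ref, alt = _split_key(rec.genomic_key)
        curated_rows.append(
            {
                "source": rec.source,
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene": rec.gene,
                "protein_change": rec.protein_change.one_letter() if rec.protein_change else "",
                "call": rec.raw_call,
                "stars": "" if rec.stars is None else str(rec.stars),
                "pubmed_ids": ",".join(rec.pubmed_ids),
            }
        )
    pd.DataFrame(curated_rows, columns=_CURATED_COLUMNS).to_csv(
        root / "curated.tsv", sep="\t", index=False
    )

    hotspot_rows = []
    for (gene, codon), recs in sorted(kb._hotspots.items()):
        for hs in recs:
            hotspot_rows.append(
                {
                    "source": hs.source,
                    "gene": hs.gene,
                    "codon": str(hs.codon),
                    "tumor_count": str(hs.tumor_count),
                    "aa_changes": ",".join(sorted(hs.aa_changes)),
                    "curated_flag": "1" if hs.curated_flag else "0",
                }
            )
    pd.DataFrame(hotspot_rows, columns=_HOTSPOT_COLUMNS).to_csv(
        root / "hotspots.tsv", sep="\t", index=False
    )

    freq_rows = []
    for key in sorted(kb.frequencies_by_key):
        chrom, pos, ref, alt = _split_key(key)
        pf = kb.frequencies_by_key[key]
        freq_rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                **{
                    k: ("" if v is None else repr(v))
                    for k, v in pf.as_dict().items()
                },
            }
        )
    pd.DataFrame(freq_rows, columns=_FREQUENCY_COLUMNS).to_csv(
        root / "frequencies.tsv", sep="\t", index=False
    )

    pred_rows = []
    for key in sorted(kb.predictions_by_key):
        chrom, pos, ref, alt = _split_key(key)
        profile = kb.predictions_by_key[key]
        revel_str = "" if profile.revel is None else repr(profile.revel)
        if profile.calls:
            for j, (algo, call) in enumerate(profile.calls):
                pred_rows.append(
                    {
                        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                        "algorithm": algo, "call": call,
                        "revel": revel_str if j == 0 else "",
                    }
                )
        else:
            pred_rows.append(
                {
                    "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                    "algorithm": "", "call": "", "revel": revel_str,
                }
            )
    pd.DataFrame(pred_rows, columns=_PREDICTION_COLUMNS).to_csv(
        root / "predictions.tsv", sep="\t", index=False
    )
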