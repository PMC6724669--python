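"""Consequence-table ingestion and splice-aware enhancement.

Transcript consequences are consumed from an annotation table (the dialect
emulates standard effect-predictor output) rather than computed from a
genome. Two enhancements are applied on top of the raw consequences:

* **Splice promotion** — silent or missense calls whose position sits within
  a small exonic window of an exon edge are promoted to ``splice_region``,
  because such substitutions can disrupt splicing despite their benign
  protein-level annotation. The original class is preserved for audit, and
  promotion never demotes or touches other classes.
* **Functional retention** — only coding and splice-related classes proceed
  to medal assignment. Silent variants are deliberately retained: in rare
  cases they act as pathogenic splice variants.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable

from .config import Config
from .nomenclature import parse_protein_change
from .variants import Consequence, TranscriptAnnotation, canonical_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "ExonModel",
    "load_exon_models",
    "load_annotations",
    "reclassify_splice",
    "filter_functional",
    "is_retained",
    "select_most_severe",
    "CONSEQUENCE_SEVERITY",
]

#: Consequence classes retained for medal assignment.
RETAINED_CONSEQUENCES = frozenset(
    {
        Consequence.SILENT,
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.SPLICE,
        Consequence.SPLICE_REGION,
        Consequence.INFRAME_INDEL,
        Consequence.STOPLOSS,
    }
)

#: Severity ranking used to select the annotation the medal engine sees
#: (higher = more severe). Ties break by lexicographic transcript accession.
CONSEQUENCE_SEVERITY = {
    Consequence.FRAMESHIFT: 11,
    Consequence.NONSENSE: 10,
    Consequence.SPLICE: 9,
    Consequence.SPLICE_REGION: 8,
    Consequence.INFRAME_INDEL: 7,
    Consequence.STOPLOSS: 6,
    Consequence.MISSENSE: 5,
    Consequence.SILENT: 4,
    Consequence.UTR: 3,
    Consequence.INTRON: 2,
    Consequence.INTERGENIC: 1,
    Consequence.OTHER: 0,
}

# Effect-predictor vocabulary -> internal consequence classes. Internal names
# are accepted verbatim as well.
_CONSEQUENCE_ALIASES = {
    "synonymous_variant": Consequence.SILENT,
    "silent": Consequence.SILENT,
    "missense_variant": Consequence.MISSENSE,
    "missense": Consequence.MISSENSE,
    "stop_gained": Consequence.NONSENSE,
    "nonsense": Consequence.NONSENSE,
    "frameshift_variant": Consequence.FRAMESHIFT,
    "frameshift": Consequence.FRAMESHIFT,
    "splice_donor_variant": Consequence.SPLICE,
    "splice_acceptor_variant": Consequence.SPLICE,
    "splice": Consequence.SPLICE,
    "splice_region_variant": Consequence.SPLICE_REGION,
    "splice_region": Consequence.SPLICE_REGION,
    "inframe_insertion": Consequence.INFRAME_INDEL,
    "inframe_deletion": Consequence.INFRAME_INDEL,
    "inframe_indel": Consequence.INFRAME_INDEL,
    "stop_lost": Consequence.STOPLOSS,
    "stoploss": Consequence.STOPLOSS,
    "5_prime_utr_variant": Consequence.UTR,
    "3_prime_utr_variant": Consequence.UTR,
    "utr": Consequence.UTR,
    "intron_variant": Consequence.INTRON,
    "intron": Consequence.INTRON,
    "intergenic_variant": Consequence.INTERGENIC,
    "intergenic": Consequence.INTERGENIC,
}


def parse_consequence(term: str) -> Consequence:
    return _CONSEQUENCE_ALIASES.get(term.strip().lower(), Consequence.OTHER)


@dataclass(frozen=True)
class ExonModel:
    """Genomic exon structure of one transcript.

    Exons are 1-based inclusive genomic intervals, stored in genomic order;
    they must not overlap. ``strand`` orients donor (3') vs acceptor (5')
    edges.
    """

    transcript: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        ordered = tuple(sorted(self.exons))
        object.__setattr__(self, "exons", ordered)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.transcript}: exons overlap at {e1}/{s2}")
        for s, e in ordered:
            if e < s or s < 1:
                raise ValueError(f"{self.transcript}: bad exon [{s},{e}]")

    def containing_exon(self, pos: int) -> tuple[int, int] | None:
        for s, e in self.exons:
            if s <= pos <= e:
                return s, e
        return None

    def boundary_distance(self, pos: int) -> int | None:
        """Signed distance (in bases) from the nearest exon edge.

        Exonic positions give positive distances (1 at an edge base);
        intronic/flanking positions give negative distances (-1 adjacent to
        an exon). ``None`` when there are no exons.
        """
        if not self.exons:
            return None
        exon = self.containing_exon(pos)
        if exon is not None:
            s, e = exon
            return min(pos - s, e - pos) + 1
        nearest = min(
            min(abs(pos - s), abs(pos - e)) for s, e in self.exons
        )
        return -nearest


def load_exon_models(path: str | os.PathLike) -> dict[str, ExonModel]:
    """Load exon models: tab-delimited transcript, strand, exon_start, exon_end."""
    raw: dict[str, dict] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "transcript":  # header
                continue
            if len(fields) < 4:
                raise ValueError(f"exon model line {lineno}: expected 4 columns")
            tx, strand, start, end = fields[0], fields[1], int(fields[2]), int(fields[3])
            entry = raw.setdefault(tx, {"strand": strand, "exons": []})
            if entry["strand"] != strand:
                raise ValueError(f"exon model line {lineno}: strand mismatch for {tx}")
            entry["exons"].append((start, end))
    return {
        tx: ExonModel(transcript=tx, strand=entry["strand"], exons=tuple(entry["exons"]))
        for tx, entry in raw.items()
    }


def load_annotations(
    path: str | os.PathLike,
    known_keys: set[str] | None = None,
) -> dict[str, list[TranscriptAnnotation]]:
    """Load the annotation table into per-variant-key annotation lists.

    Columns: chrom, pos, ref, alt, gene, transcript, consequence, cdna_hgvs,
    protein_hgvs (tab-delimited, ``#`` comments allowed). Protein fields run
    through the protein-change parser; unparseable fields keep the
    annotation with a ``failed`` parse status — annotation tables are dirty
    by design. Rows for variants outside ``known_keys`` (when given) warn
    but are retained, since annotation tables may be supersets of the VCF.
    """
    out: dict[str, list[TranscriptAnnotation]] = {}
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                expected = [
                    "chrom", "pos", "ref", "alt", "gene",
                    "transcript", "consequence", "cdna_hgvs", "protein_hgvs",
                ]
                if header != expected:
                    raise ValueError(
                        f"annotation table {path}: bad header {header!r}"
                    )
                continue
            row = dict(zip(header, fields))
            key = (
                f"{canonical_chrom(row['chrom'])}:{int(row['pos'])}:"
                f"{row['ref']}>{row['alt']}"
            )
            if known_keys is not None and key not in known_keys:
                logger.warning(
                    "annotation line %d: variant %s absent from VCF set (retained)",
                    lineno,
                    key,
                )
            parse = parse_protein_change(row["protein_hgvs"]) if row["protein_hgvs"] else None
            ann = TranscriptAnnotation(
                gene=row["gene"],
                transcript=row["transcript"],
                consequence=parse_consequence(row["consequence"]),
                cdna_hgvs=row["cdna_hgvs"],
                protein_change=parse.change if parse and parse.ok else None,
                codon=parse.codon if parse else None,
                parse_status=parse.status.value if parse else "failed",
            )
            out.setdefault(key, []).append(ann)
    for anns in out.values():
        anns.sort(key=lambda a: a.transcript)
    return out


def reclassify_splice(
    ann: TranscriptAnnotation,
    exons: ExonModel | None,
    cfg: Config,
    pos: int,
) -> TranscriptAnnotation:
    """Promote exon-edge silent/missense calls to ``splice_region``.

    Promotion applies when the variant position lies within
    ``cfg.splice_donor_exonic_window`` exonic bases of the exon's donor (3')
    edge or ``cfg.splice_acceptor_exonic_window`` bases of its acceptor (5')
    edge, orientation taken from the transcript strand. Other consequence
    classes pass through untouched; promotion never demotes. The original
    class is preserved in ``promoted_from`` and the signed exon-boundary
    distance is recorded either way.
    """
    if ann.consequence not in {Consequence.SILENT, Consequence.MISSENSE}:
        return ann
    if exons is None:
        logger.info(
            "no exon model for transcript %s: splice reclassification skipped",
            ann.transcript,
        )
        return ann
    dist = exons.boundary_distance(pos)
    ann.exon_boundary_dist = dist
    exon = exons.containing_exon(pos)
    if exon is None:
        return ann
    start, end = exon
    if exons.strand == "+":
        donor_dist, acceptor_dist = end - pos + 1, pos - start + 1
    else:
        donor_dist, acceptor_dist = pos - start + 1, end - pos + 1
    if (
        donor_dist <= cfg.splice_donor_exonic_window
        or acceptor_dist <= cfg.splice_acceptor_exonic_window
    ):
        ann.promoted_from = ann.consequence
        ann.consequence = Consequence.SPLICE_REGION
    return ann


def filter_functional(anns: list[TranscriptAnnotation]) -> list[TranscriptAnnotation]:
    """Keep coding and splice-related annotations (silent included)."""
    return [a for a in anns if a.consequence in RETAINED_CONSEQUENCES]


def is_retained(anns: Iterable[TranscriptAnnotation]) -> bool:
    """A variant survives functional filtering if ANY annotation is retained."""
    return any(a.consequence in RETAINED_CONSEQUENCES for a in anns)


def select_most_severe(anns: list[TranscriptAnnotation]) -> TranscriptAnnotation:
    """The annotation the medal engine sees: most severe, ties by transcript."""
    if not anns:
        raise ValueError("cannot select from an empty annotation list")
    return min(
        anns, key=lambda a: (-CONSEQUENCE_SEVERITY[a.consequence], a.transcript)
    )
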