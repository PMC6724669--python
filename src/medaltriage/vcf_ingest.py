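"""VCF ingestion: decompose records into normalized variants, filter to a panel.

Reading goes through cyvcf2 (plain or bgzip VCF v4.x). Every multi-allelic
record is decomposed into one :class:`~medaltriage.variants.GenomicVariant`
per ALT allele before any downstream step; symbolic and star alleles are
skipped and counted. Panel intervals follow the BED convention (0-based,
half-open) while variant positions are 1-based (VCF convention); the
intersection converts explicitly, and indels are intersected by their full
REF span so deletions crossing a panel boundary are retained.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from cyvcf2 import VCF
from intervaltree import IntervalTree

from .variants import GenomicVariant, canonical_chrom, normalize

logger = logging.getLogger(__name__)

__all__ = [
    "VcfParseError",
    "VcfVariant",
    "IngestStats",
    "GenePanel",
    "load_panel",
    "read_vcf",
    "filter_to_panel",
]


class VcfParseError(ValueError):
    """Malformed VCF header or record, with the offending record number."""


@dataclass(frozen=True)
class VcfVariant:
    """A decomposed variant plus opaque per-sample genotype columns.

    Genotype columns are carried through verbatim for reporting (e.g. the
    recessive sign-out note) and are never interpreted by the medal engine.
    """

    variant: GenomicVariant
    genotypes: tuple[str, ...] = ()
    record_index: int = 0


@dataclass
class IngestStats:
    """Counters accumulated while streaming a VCF."""

    records: int = 0
    emitted: int = 0
    skipped_symbolic: int = 0

    @property
    def total_alts(self) -> int:
        return self.emitted + self.skipped_symbolic


def _is_symbolic(alt: str) -> bool:
    return (
        not alt
        or alt == "*"
        or alt.startswith("<")
        or "[" in alt
        or "]" in alt
        or alt == "."
    )


def read_vcf(
    path: str | os.PathLike,
    stats: IngestStats | None = None,
    build: str = "GRCh37",
) -> Iterator[VcfVariant]:
    """Stream normalized variants out of a VCF file, one per ALT allele.

    Symbolic ALTs (``<DEL>``, breakends, ``*``) are skipped and counted in
    ``stats``. Record order is preserved. A zero-byte file yields an empty
    stream; malformed input raises :class:`VcfParseError` naming the record.
    """
    if stats is None:
        stats = IngestStats()
    path = os.fspath(path)
    if os.path.getsize(path) == 0:
        logger.info("empty VCF file %s: emitting no variants", path)
        return
    if build == "GRCh38":
        logger.warning(
            "GRCh38 input is accepted as a labeled pass-through only; "
            "coordinates must already be GRCh37-equivalent (no liftover is performed)"
        )
    try:
        reader = VCF(path)
    except Exception as exc:  # cyvcf2 raises on malformed headers
        raise VcfParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    try:
        record_index = 0
        for record in reader:
            record_index += 1
            stats.records += 1
            try:
                raw_fields = str(record).rstrip("\n").split("\t")
                genotypes = tuple(raw_fields[9:]) if len(raw_fields) > 9 else ()
                for alt in record.ALT:
                    if _is_symbolic(alt):
                        stats.skipped_symbolic += 1
                        logger.info(
                            "skipping symbolic ALT %r at record %d", alt, record_index
                        )
                        continue
                    variant = normalize(
                        GenomicVariant(
                            chrom=canonical_chrom(record.CHROM),
                            pos=record.POS,
                            ref=record.REF,
                            alt=alt,
                            build=build,
                        )
                    )
                    stats.emitted += 1
                    yield VcfVariant(variant, genotypes, record_index)
            except ValueError as exc:
                raise VcfParseError(
                    f"malformed VCF record {record_index} in {path}: {exc}"
                ) from exc
    finally:
        reader.close()


@dataclass
class GenePanel:
    """A named disease-gene panel: genomic intervals tagged with gene symbols.

    Intervals are 0-based half-open. Intervals within a gene may overlap;
    intervals of different genes may overlap too, in which case a variant
    inside both is emitted once per gene.
    """

    name: str
    intervals: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for gene, spans in self.intervals.items():
            for chrom, start, end in spans:
                if end <= start:
                    raise ValueError(
                        f"bad interval for {gene}: [{start},{end}) on {chrom}"
                    )
                tree = self._trees.setdefault(canonical_chrom(chrom), IntervalTree())
                tree.addi(start, end, gene)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.intervals)

    def genes_overlapping(self, chrom: str, start0: int, end0: int) -> list[str]:
        """Genes whose intervals overlap the 0-based half-open span."""
        tree = self._trees.get(canonical_chrom(chrom))
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start0, end0)})


def load_panel(path: str | os.PathLike, name: str | None = None) -> GenePanel:
    """Load a BED-like panel file: chrom, start, end, gene_symbol (tab-delimited)."""
    intervals: dict[str, list[tuple[str, int, int]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"panel line {lineno}: expected 4 columns, got {len(fields)}")
            chrom, start, end, gene = fields[0], int(fields[1]), int(fields[2]), fields[3]
            intervals.setdefault(gene, []).append((chrom, start, end))
    return GenePanel(name=name or os.path.basename(os.fspath(path)), intervals=intervals)


def filter_to_panel(
    variants: Iterable[VcfVariant], panel: GenePanel
) -> Iterator[tuple[VcfVariant, str]]:
    """Retain variants whose REF span intersects a panel interval.

    Yields one ``(variant, gene)`` pair per overlapping gene. Panel
    intervals are half-open: a variant is retained iff some position ``p``
    of its REF span ``[pos, pos+len(ref))`` satisfies ``start <= p < end``
    — so a variant exactly at ``end`` falls outside.
    """
    for vv in variants:
        v = vv.variant
        for gene in panel.genes_overlapping(v.chrom, v.pos, v.pos + len(v.ref)):
            yield vv, gene
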