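"""Core domain types: genomic variants, transcript annotations, gene metadata.

Variants are represented as normalized allele substitutions on a reference
build. Chromosome names are canonicalized (no ``chr`` prefix; ``X``, ``Y``,
``MT`` uppercased) so that keys derived from VCF records and from
knowledgebase snapshots compare equal. The serialized key used throughout
reports is ``chrom:pos:ref>alt``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum

from .nomenclature import ProteinChange

__all__ = [
    "VariantType",
    "Consequence",
    "TRUNCATING_CONSEQUENCES",
    "GenomicVariant",
    "TranscriptAnnotation",
    "GeneMeta",
    "classify_variant_type",
    "normalize",
    "canonical_chrom",
    "parse_variant_key",
]

_ALLELE_RE = re.compile(r"^[ACGT]+$")


class VariantType(str, Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"
    MNV = "MNV"
    COMPLEX = "COMPLEX"


class Consequence(str, Enum):
    SILENT = "silent"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    SPLICE_REGION = "splice_region"
    INFRAME_INDEL = "inframe_indel"
    STOPLOSS = "stoploss"
    UTR = "utr"
    INTRON = "intron"
    INTERGENIC = "intergenic"
    OTHER = "other"


#: Consequences expected to abolish the protein product.
TRUNCATING_CONSEQUENCES = frozenset(
    {Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.SPLICE}
)


def canonical_chrom(name: str) -> str:
    """Canonicalize a chromosome name: strip ``chr``, uppercase X/Y/MT."""
    s = name.strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in {"X", "Y", "MT"}:
        return s.upper()
    if s.upper() == "M":
        return "MT"
    return s


def _validate_allele(value: str, name: str) -> None:
    if not value:
        raise ValueError(f"{name} allele must be non-empty")
    if not _ALLELE_RE.match(value):
        raise ValueError(f"{name} allele must be over {{A,C,G,T}}, got {value!r}")


def classify_variant_type(ref: str, alt: str) -> VariantType:
    """Classify an allele substitution by (len(ref), len(alt), anchor).

    SNV for 1/1; INS for 1/k sharing the leading anchor base; DEL for k/1
    sharing the anchor; MNV for equal lengths > 1; COMPLEX otherwise
    (including unanchored length changes).
    """
    _validate_allele(ref, "ref")
    _validate_allele(alt, "alt")
    if ref == alt:
        raise ValueError("ref and alt alleles must differ")
    if len(ref) == 1 and len(alt) == 1:
        return VariantType.SNV
    if len(ref) == 1 and len(alt) > 1:
        return VariantType.INS if alt[0] == ref else VariantType.COMPLEX
    if len(ref) > 1 and len(alt) == 1:
        return VariantType.DEL if ref[0] == alt else VariantType.COMPLEX
    if len(ref) == len(alt):
        return VariantType.MNV
    return VariantType.COMPLEX


@dataclass(frozen=True)
class GenomicVariant:
    """One normalized allele substitution on a reference build.

    ``pos`` is the 1-based position of the first reference base. Construction
    canonicalizes the chromosome name and validates alleles.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    build: str = "GRCh37"

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", canonical_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        _validate_allele(self.ref, "ref")
        _validate_allele(self.alt, "alt")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.build not in {"GRCh37", "GRCh38"}:
            raise ValueError(f"build must be GRCh37 or GRCh38, got {self.build!r}")

    @property
    def vtype(self) -> VariantType:
        return classify_variant_type(self.ref, self.alt)

    @property
    def key(self) -> str:
        """Serialized ``chrom:pos:ref>alt`` key used in all reports."""
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def end(self) -> int:
        """1-based inclusive last reference base (REF span end)."""
        return self.pos + len(self.ref) - 1


_KEY_RE = re.compile(r"^([^:]+):(\d+):([ACGT]+)>([ACGT]+)$")


def parse_variant_key(key: str, build: str = "GRCh37") -> GenomicVariant:
    """Parse a ``chrom:pos:ref>alt`` key back into a :class:`GenomicVariant`."""
    m = _KEY_RE.match(key.strip())
    if not m:
        raise ValueError(f"malformed variant key {key!r}")
    return GenomicVariant(m.group(1), int(m.group(2)), m.group(3), m.group(4), build=build)


def normalize(variant: GenomicVariant) -> GenomicVariant:
    """Trim shared leading/trailing bases, keeping one anchor base.

    Anchor-trim only: no reference-genome-aware left-alignment is performed.
    Idempotent, and never changes the genomic edit implied by
    ``(pos, ref, alt)`` when re-expanded against a reference sequence.
    """
    ref, alt, pos = variant.ref, variant.alt, variant.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (ref, alt, pos) == (variant.ref, variant.alt, variant.pos):
        return variant
    return replace(variant, pos=pos, ref=ref, alt=alt)


@dataclass
class TranscriptAnnotation:
    """Gene/transcript consequence and protein change for one variant.

    ``parse_status`` records how the protein field parsed (annotation tables
    are dirty by design). ``promoted_from`` holds the original consequence
    when a silent/missense call was promoted to ``splice_region`` at an exon
    boundary. ``exon_boundary_dist`` is signed bases from the nearest exon
    edge (negative = intronic), when an exon model was available.
    """

    gene: str
    transcript: str
    consequence: Consequence
    cdna_hgvs: str = ""
    protein_change: ProteinChange | None = None
    codon: int | None = None
    parse_status: str = "full"
    exon_boundary_dist: int | None = None
    promoted_from: Consequence | None = None

    def __post_init__(self) -> None:
        if self.codon is None and self.protein_change is not None:
            self.codon = self.protein_change.codon

    @property
    def is_truncating(self) -> bool:
        return self.consequence in TRUNCATING_CONSEQUENCES

    def is_complete(self) -> bool:
        """Whether protein-level fields required by the consequence are present."""
        needs_protein = self.consequence in {
            Consequence.SILENT,
            Consequence.MISSENSE,
            Consequence.NONSENSE,
            Consequence.INFRAME_INDEL,
        }
        if needs_protein:
            return self.protein_change is not None and self.codon is not None
        return True


@dataclass(frozen=True)
class GeneMeta:
    """Per-gene disease metadata used by the medal and tag engines.

    ``is_lof_gene`` marks genes whose disease mechanism is loss of function
    (e.g. tumor suppressors), where truncating variants are presumptively
    damaging. ``inheritance`` is reported for sign-out context only and never
    consulted by per-variant rules.
    """

    symbol: str
    panels: frozenset[str] = frozenset()
    is_lof_gene: bool = False
    inheritance: str = "unknown"

    def __post_init__(self) -> None:
        if self.inheritance not in {"AD", "AR", "AD_AR", "unknown"}:
            raise ValueError(f"bad inheritance {self.inheritance!r}")
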