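"""Protein-change and pathogenicity-label standardization.

Locus-specific and aggregate variant databases describe the same protein
change in many dialects: one- or three-letter amino-acid codes, five
different spellings of the stop codon ("Ter", "Term", "*", "X", "Stop"),
optional ``p.`` prefixes and parentheses, and "=" for synonymous changes.
Pathogenicity labels are equally heterogeneous. This module normalizes both
into small canonical forms so that records from different sources can be
compared: a :class:`ProteinChange` with one-letter codes ("*" for stop,
"=" for synonymous) and a five-tier pathogenicity code (B/LB/VUS/LP/P).

Parsing never raises on dirty input: a string that is not a recognizable
protein change yields a ``codon_only`` result when a codon number can be
salvaged, or ``failed`` otherwise.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from functools import lru_cache

__all__ = [
    "ProteinChange",
    "ParseStatus",
    "ProteinParse",
    "parse_protein_change",
    "standardize_pathogenicity",
    "PATHOGENICITY_CODES",
]

# One-letter <-> three-letter amino acid codes (20 standard + stop).
AA_3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}
AA_1TO3 = {one: three for three, one in AA_3TO1.items()}

# Accepted stop-codon spellings (case-insensitive where worded).
_STOP_SPELLINGS = {"ter", "term", "stop", "*", "x"}

PATHOGENICITY_CODES = ("B", "LB", "VUS", "LP", "P")


class ParseStatus(str, Enum):
    FULL = "full"
    CODON_ONLY = "codon_only"
    FAILED = "failed"


@dataclass(frozen=True)
class ProteinChange:
    """A protein-level substitution in minimal one-letter form.

    ``aa_alt`` is "*" for stop gains and "=" for synonymous changes;
    ``aa_ref`` may be "*" for stop-loss events. ``raw`` preserves the
    original text for audit.
    """

    aa_ref: str
    codon: int
    aa_alt: str
    raw: str = ""

    def __post_init__(self) -> None:
        if self.codon < 1:
            raise ValueError(f"codon must be >= 1, got {self.codon}")
        if self.aa_ref not in AA_1TO3:
            raise ValueError(f"aa_ref must be a one-letter code or '*', got {self.aa_ref!r}")
        if self.aa_alt != "=" and self.aa_alt not in AA_1TO3:
            raise ValueError(f"aa_alt must be a one-letter code, '*' or '=', got {self.aa_alt!r}")

    def one_letter(self) -> str:
        """Canonical one-letter rendering, e.g. ``R359*`` or ``L294=``."""
        return f"{self.aa_ref}{self.codon}{self.aa_alt}"

    def three_letter(self) -> str:
        """Canonical three-letter rendering, e.g. ``Arg359Ter`` or ``Leu294=``."""
        alt = "=" if self.aa_alt == "=" else AA_1TO3[self.aa_alt]
        return f"{AA_1TO3[self.aa_ref]}{self.codon}{alt}"

    def same_change(self, other: "ProteinChange") -> bool:
        """True when both describe the identical amino-acid change."""
        return (
            self.codon == other.codon
            and self.aa_ref == other.aa_ref
            and self.aa_alt == other.aa_alt
        )


@dataclass(frozen=True)
class ProteinParse:
    """Outcome of parsing a free-form protein notation string."""

    status: ParseStatus
    change: ProteinChange | None = None
    codon: int | None = None
    raw: str = ""

    @property
    def ok(self) -> bool:
        return self.status is ParseStatus.FULL


# Reference amino acid: three-letter code, one-letter code, or a stop spelling
# (for stop-loss). Alternate: additionally "=" for synonymous.
_AA3_PAT = "|".join(AA_3TO1)
_REF_PAT = rf"(?P<ref>{_AA3_PAT}|Term|Stop|[A-Z]|\*)"
_ALT_PAT = rf"(?P<alt>{_AA3_PAT}|Term|Stop|[A-Za-z]|\*|=)"
_CHANGE_RE = re.compile(rf"^{_REF_PAT}(?P<codon>\d+)(?:{_ALT_PAT})$")

# Nucleotide-level HGVS prefixes: these are a different grammar entirely, and
# their positions are not codon numbers, so they fail outright.
_NUCLEOTIDE_RE = re.compile(r"^[cgmnor]\.", re.IGNORECASE)

_CODON_RE = re.compile(r"(\d+)")


def _decode_ref(token: str) -> str | None:
    if token in AA_3TO1:
        return AA_3TO1[token]
    if token.lower() in {"term", "stop"} or token == "*":
        return "*"
    if len(token) == 1 and token in AA_1TO3 and token != "X":
        # "X" denotes a stop only in the alternate position; an unknown
        # reference amino acid is not salvageable.
        return token
    return None


def _decode_alt(token: str) -> str | None:
    if token == "=":
        return "="
    if token in AA_3TO1:
        return AA_3TO1[token]
    if token.lower() in _STOP_SPELLINGS:
        return "*"
    if len(token) == 1 and token in AA_1TO3:
        return token
    return None


def parse_protein_change(text: str) -> ProteinParse:
    """Parse a free-form protein-change notation.

    Accepts an optional ``p.`` prefix, surrounding parentheses, one- or
    three-letter amino-acid codes, all common stop spellings ("Ter", "Term",
    "Stop", "X", "*"), and "=" for synonymous. Never raises: unparseable
    input yields ``codon_only`` when a codon number can be extracted from an
    otherwise incomplete annotation, else ``failed``.
    """
    raw = text
    s = text.strip()
    if not s:
        return ProteinParse(ParseStatus.FAILED, raw=raw)
    if _NUCLEOTIDE_RE.match(s) or ">" in s:
        return ProteinParse(ParseStatus.FAILED, raw=raw)
    s = s.strip("()")
    if s.lower().startswith("p."):
        s = s[2:]
    s = s.strip("()")

    m = _CHANGE_RE.match(s)
    if m:
        ref = _decode_ref(m.group("ref"))
        alt = _decode_alt(m.group("alt"))
        codon = int(m.group("codon"))
        if ref is not None and alt is not None and codon >= 1:
            change = ProteinChange(ref, codon, alt, raw=raw)
            return ProteinParse(ParseStatus.FULL, change=change, codon=codon, raw=raw)

    cm = _CODON_RE.search(s)
    if cm:
        codon = int(cm.group(1))
        if codon >= 1:
            return ProteinParse(ParseStatus.CODON_ONLY, codon=codon, raw=raw)
    return ProteinParse(ParseStatus.FAILED, raw=raw)


@lru_cache(maxsize=1)
def _pathogenicity_table() -> dict[str, str]:
    """Load the editable raw-label -> five-tier mapping table."""
    table: dict[str, str] = {}
    ref = resources.files("medaltriage.data").joinpath("pathogenicity_map.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            raw_label, code = row[0], row[1]
            if code not in PATHOGENICITY_CODES:
                raise ValueError(f"bad standardized code {code!r} for label {raw_label!r}")
            table[raw_label.strip().lower()] = code
    return table


def standardize_pathogenicity(text: str) -> str:
    """Map a free-form pathogenicity label onto B/LB/VUS/LP/P.

    Unrecognized labels return ``"unmapped"`` — never a pathogenic tier by
    default, so dirty labels cannot inflate classifications.
    """
    key = " ".join(text.strip().lower().split())
    return _pathogenicity_table().get(key, "unmapped")
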