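"""Tunable parameters for triage, with validated defaults.

Frequencies are allele fractions in [0, 1]. ``max_af`` may be set to ``None``
to disable the population-frequency gate entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class Config:
    """Pipeline configuration.

    Parameters
    ----------
    max_af
        Germline medal frequency gate on the ExAC non-TCGA allele frequency;
        variants with a frequency strictly above this are not medaled unless
        rescued by a curated-database exception. ``None`` disables the gate.
    pm2_max_af
        Ceiling for the PM2 (absent-or-very-rare) evidence tag.
    ba1_min_af
        Floor above which the stand-alone benign BA1 tag fires.
    hotspot_min_tumors
        Minimum per-codon tumor count for COSMIC somatic-hotspot status.
    clinvar_min_stars
        Minimum ClinVar review stars for gold-tier pathogenic matches and
        for the frequency-gate rescue exception.
    splice_donor_exonic_window, splice_acceptor_exonic_window
        Exonic bases at the donor (3') and acceptor (5') exon edges within
        which silent/missense calls are promoted to ``splice_region``.
    splice_region_is_truncating
        Whether promoted splice-region calls count as truncating for medal
        rules (off by default; canonical splice-site calls always count).
    revel_damaging
        REVEL score at or above which a variant is predicted damaging.
    min_damaging_calls
        Number of categorical damaging calls required for a damaging
        aggregate; ``None`` means a strict majority of non-unknown calls.
    """

    max_af: float | None = 0.001
    pm2_max_af: float = 0.0001
    ba1_min_af: float = 0.05
    hotspot_min_tumors: int = 10
    clinvar_min_stars: int = 2
    splice_donor_exonic_window: int = 3
    splice_acceptor_exonic_window: int = 1
    splice_region_is_truncating: bool = False
    revel_damaging: float = 0.5
    min_damaging_calls: int | None = None

    def __post_init__(self) -> None:
        for name in ("pm2_max_af", "ba1_min_af", "revel_damaging"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {value}")
        if self.max_af is not None:
            if not 0.0 <= self.max_af <= 1.0:
                raise ValueError(f"max_af must be in [0,1] or None, got {self.max_af}")
            if not self.pm2_max_af <= self.max_af <= self.ba1_min_af:
                raise ValueError(
                    "require pm2_max_af <= max_af <= ba1_min_af, got "
                    f"{self.pm2_max_af} / {self.max_af} / {self.ba1_min_af}"
                )
        elif self.pm2_max_af > self.ba1_min_af:
            raise ValueError("require pm2_max_af <= ba1_min_af")
        for name in (
            "hotspot_min_tumors",
            "clinvar_min_stars",
            "splice_donor_exonic_window",
            "splice_acceptor_exonic_window",
        ):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
        if self.min_damaging_calls is not None and self.min_damaging_calls < 1:
            raise ValueError("min_damaging_calls must be >= 1 or None")

    def with_updates(self, **kwargs) -> "Config":
        return replace(self, **kwargs)
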