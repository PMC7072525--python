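"""Core record types shared by every pipeline stage.

All coordinates are 1-based (MAF/VCF convention) and are stored exactly as
given. Optional numeric fields use ``None`` as the explicit missing marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CONSEQUENCES",
    "TRUNCATING_CONSEQUENCES",
    "VariantRecord",
    "PanelDefinition",
    "ClinicalRecord",
    "RecordError",
]

#: Controlled vocabulary for the functional consequence of a variant.
CONSEQUENCES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "splice_site",
        "inframe_indel",
        "synonymous",
        "other",
    }
)

#: Consequences that truncate the protein (the APC criterion of the
#: Schell scheme): nonsense, frameshift and splice-site changes.
TRUNCATING_CONSEQUENCES = frozenset({"nonsense", "frameshift", "splice_site"})

COUNTRIES = frozenset({"USA", "Germany"})
TREATMENTS = frozenset({"SOC", "SOC_plus_IND"})
TUMOR_SIDES = frozenset({"right", "left", "rectum"})
GENDERS = frozenset({"male", "female"})


class RecordError(ValueError):
    """A record violates one of its declared invariants."""


@dataclass
class VariantRecord:
    """One somatic variant call with the QC fields the technical filters use.

    Parameters
    ----------
    sample_id : str
        Tumor sample identifier.
    gene : str
        HGNC-style gene symbol.
    chrom, pos, ref, alt
        1-based genomic coordinate and alleles.
    consequence : str
        One of :data:`CONSEQUENCES`.
    tumor_vaf : float
        Variant allele frequency in the tumor, a fraction in [0, 1].
    variant_depth, tumor_depth, normal_depth : int or None
        Reads supporting the alternate allele, and total depths.
    base_quality : float or None
        Phred-scaled mean base quality of supporting reads.
    population_af : float or None
        Population allele frequency (ExAC/1000G style), fraction in [0, 1].
    strand_bias_fail, damage_artifact : bool
        Upstream caller flags: failed strand-bias test / oxidative-damage
        artifact. These are consumed, never recomputed, by the filters.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    tumor_vaf: float
    variant_depth: int | None = None
    tumor_depth: int | None = None
    normal_depth: int | None = None
    base_quality: float | None = None
    population_af: float | None = None
    strand_bias_fail: bool = False
    damage_artifact: bool = False

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise RecordError(
                f"unknown consequence {self.consequence!r} "
                f"(expected one of {sorted(CONSEQUENCES)})"
            )
        if self.pos < 1:
            raise RecordError(f"pos must be >= 1, got {self.pos}")
        if not 0.0 <= self.tumor_vaf <= 1.0:
            raise RecordError(f"tumor_vaf must be in [0, 1], got {self.tumor_vaf}")
        if self.population_af is not None and not 0.0 <= self.population_af <= 1.0:
            raise RecordError(
                f"population_af must be in [0, 1], got {self.population_af}"
            )
        if (
            self.variant_depth is not None
            and self.tumor_depth is not None
            and self.variant_depth > self.tumor_depth
        ):
            raise RecordError(
                f"variant_depth ({self.variant_depth}) exceeds tumor_depth "
                f"({self.tumor_depth})"
            )

    @property
    def is_truncating(self) -> bool:
        return self.consequence in TRUNCATING_CONSEQUENCES

    @property
    def is_synonymous(self) -> bool:
        return self.consequence == "synonymous"


@dataclass(frozen=True)
class PanelDefinition:
    """A targeted sequencing panel: its gene content and covered territory."""

    name: str
    genes: frozenset[str]
    size_mb: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if self.size_mb <= 0:
            raise RecordError(f"panel size_mb must be > 0, got {self.size_mb}")
        if not self.genes:
            raise RecordError("panel gene set must be non-empty")

    @staticmethod
    def shared_genes(a: "PanelDefinition", b: "PanelDefinition") -> frozenset[str]:
        """Genes covered by both panels (the feature space for the
        landscape analyses)."""
        return a.genes & b.genes


@dataclass
class ClinicalRecord:
    """Per-patient clinical metadata and time-to-event outcome.

    ``os_months`` is overall survival from diagnosis in months; ``event``
    is True when death was observed (False = right-censored).
    ``msi_matched`` records whether a matched normal was available, which
    selects the matched (MSS/MSI-L/MSI-H) versus tumor-only (MSS/MSI)
    microsatellite calling mode downstream.
    """

    sample_id: str
    country: str
    treatment: str
    os_months: float
    event: bool
    tumor_side: str | None = None
    age_years: float | None = None
    gender: str | None = None
    msi_score: float | None = None
    msi_matched: bool = True

    def __post_init__(self) -> None:
        if self.country not in COUNTRIES:
            raise RecordError(f"unknown country {self.country!r}")
        if self.treatment not in TREATMENTS:
            raise RecordError(f"unknown treatment {self.treatment!r}")
        if self.os_months < 0:
            raise RecordError(f"os_months must be >= 0, got {self.os_months}")
        if self.tumor_side is not None and self.tumor_side not in TUMOR_SIDES:
            raise RecordError(f"unknown tumor_side {self.tumor_side!r}")
        if self.gender is not None and self.gender not in GENDERS:
            raise RecordError(f"unknown gender {self.gender!r}")
        if self.msi_score is not None and self.msi_score < 0:
            raise RecordError(f"msi_score must be >= 0, got {self.msi_score}")
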