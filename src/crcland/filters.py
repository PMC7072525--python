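"""Technical filtering of somatic calls and clonal/subclonal classification.

The technical filters mirror a conservative tumor/normal panel pipeline:
minimum alt-supporting depth, minimum base quality, minimum VAF, a minimum
total depth in either the tumor or the matched normal, a population
allele-frequency cap (germline leak removal), and caller-provided
strand-bias and DNA-damage flags. "Minimal X" rules use >= (a value exactly
at the threshold passes); "less than" exclusions use strict <.

Clonality is proxied by VAF relative to the sample's maximum VAF: a variant
is clonal when its VAF reaches 25% of the maximum. Non-clonal variants are
excluded (not counted at all downstream) when below 1/10 of the maximum or
below 3% absolute VAF; otherwise they are subclonal. The exclusion rules
apply only to non-clonal variants, so the maximum-VAF variant is always
clonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .records import VariantRecord

__all__ = [
    "FilterThresholds",
    "ClonalityThresholds",
    "ClonalityCall",
    "FilterError",
    "apply_technical_filters",
    "classify_clonality",
]


class FilterError(ValueError):
    """Invalid thresholds or a record missing a field an enabled rule needs."""


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds of the technical filter battery.

    ``low_freq_low_depth_rule`` is an optional joint rule removing variants
    with VAF below the first element AND tumor depth below the second
    (a bcbio-style guard against low-frequency noise); it is disabled by
    default.
    """

    min_variant_depth: int = 7
    min_base_quality: float = 30.0
    min_vaf: float = 0.003
    min_either_depth: int = 10
    max_population_af: float = 0.0001  # "0.01%" read literally as a fraction
    drop_strand_bias: bool = True
    drop_damage: bool = True
    low_freq_low_depth_rule: tuple[float, int] | None = None

    def __post_init__(self) -> None:
        for name in ("min_variant_depth", "min_base_quality", "min_vaf",
                     "min_either_depth", "max_population_af"):
            if getattr(self, name) < 0:
                raise FilterError(f"{name} must be >= 0")
        if self.low_freq_low_depth_rule is not None:
            a, b = self.low_freq_low_depth_rule
            if a < 0 or b < 0:
                raise FilterError("low_freq_low_depth_rule thresholds must be >= 0")


#: Suggested parameters for the joint low-frequency/low-depth rule.
SUGGESTED_LOW_FREQ_LOW_DEPTH = (0.05, 30)


def _require(value, rule: str, record: VariantRecord):
    if value is None:
        raise FilterError(
            f"rule {rule!r} is enabled but {record.sample_id} "
            f"{record.gene} {record.chrom}:{record.pos} lacks the field it needs"
        )
    return value


def apply_technical_filters(
    variants: Iterable[VariantRecord],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, list[str]]]]:
    """Partition variants into kept and removed.

    Returns ``(kept, removed)`` where each removed entry is
    ``(record, reason_codes)`` with at least one reason code. A record is
    kept iff it passes every enabled rule; reason codes name the rule(s)
    that failed.
    """
    thresholds = thresholds or FilterThresholds()
    kept: list[VariantRecord] = []
    removed: list[tuple[VariantRecord, list[str]]] = []
    for rec in variants:
        reasons: list[str] = []
        # a threshold of 0 (or an AF cap of 1) disables the rule, so a
        # missing field is only an error when the rule can actually bite
        if thresholds.min_variant_depth > 0:
            if _require(rec.variant_depth, "min_variant_depth", rec) < thresholds.min_variant_depth:
                reasons.append("min_variant_depth")
        if thresholds.min_base_quality > 0:
            if _require(rec.base_quality, "min_base_quality", rec) < thresholds.min_base_quality:
                reasons.append("min_base_quality")
        if rec.tumor_vaf < thresholds.min_vaf:
            reasons.append("min_vaf")
        if thresholds.min_either_depth > 0:
            depths = [d for d in (rec.tumor_depth, rec.normal_depth) if d is not None]
            if not depths:
                raise FilterError(
                    f"rule 'min_either_depth' is enabled but {rec.sample_id} "
                    f"{rec.chrom}:{rec.pos} has neither tumor nor normal depth"
                )
            if max(depths) < thresholds.min_either_depth:
                reasons.append("min_either_depth")
        if thresholds.max_population_af < 1.0:
            if _require(rec.population_af, "max_population_af", rec) > thresholds.max_population_af:
                reasons.append("max_population_af")
        if thresholds.drop_strand_bias and rec.strand_bias_fail:
            reasons.append("strand_bias")
        if thresholds.drop_damage and rec.damage_artifact:
            reasons.append("damage_artifact")
        if thresholds.low_freq_low_depth_rule is not None:
            vaf_below, depth_below = thresholds.low_freq_low_depth_rule
            tdp = _require(rec.tumor_depth, "low_freq_low_depth", rec)
            if rec.tumor_vaf < vaf_below and tdp < depth_below:
                reasons.append("low_freq_low_depth")
        if reasons:
            removed.append((rec, reasons))
        else:
            kept.append(rec)
    return kept, removed


@dataclass(frozen=True)
class ClonalityThresholds:
    clonal_fraction_of_max: float = 0.25
    exclusion_fraction_of_max: float = 0.10
    exclusion_absolute_vaf: float = 0.03

    def __post_init__(self) -> None:
        for name in ("clonal_fraction_of_max", "exclusion_fraction_of_max",
                     "exclusion_absolute_vaf"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise FilterError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class ClonalityCall:
    label: str  # {"clonal", "subclonal", "excluded"}
    max_vaf_used: float


def classify_clonality(
    sample_variants: Sequence[VariantRecord],
    thresholds: ClonalityThresholds | None = None,
) -> list[ClonalityCall]:
    """Classify each variant of ONE sample as clonal, subclonal or excluded.

    With ``vmax`` the sample's maximum tumor VAF:

    * clonal iff ``vaf >= clonal_fraction_of_max * vmax``;
    * otherwise excluded iff ``vaf < exclusion_fraction_of_max * vmax``
      or ``vaf < exclusion_absolute_vaf`` (strict);
    * otherwise subclonal.

    The exclusion rules act only on non-clonal variants, so the variant
    carrying ``vmax`` is always clonal.
    """
    thresholds = thresholds or ClonalityThresholds()
    if not sample_variants:
        raise FilterError("clonality classification needs at least one variant")
    vafs = [v.tumor_vaf for v in sample_variants if v.tumor_vaf is not None]
    if not vafs:
        raise FilterError("all VAFs missing in sample")
    vmax = max(vafs)
    calls: list[ClonalityCall] = []
    for rec in sample_variants:
        vaf = rec.tumor_vaf
        if vaf >= thresholds.clonal_fraction_of_max * vmax:
            label = "clonal"
        elif (vaf < thresholds.exclusion_fraction_of_max * vmax
              or vaf < thresholds.exclusion_absolute_vaf):
            label = "excluded"
        else:
            label = "subclonal"
        calls.append(ClonalityCall(label=label, max_vaf_used=vmax))
    return calls
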