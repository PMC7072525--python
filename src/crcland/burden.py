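"""Tumor mutational burden and microsatellite-instability calling.

TMB is the number of (post-filter, by default non-synonymous) somatic
mutations per megabase of panel territory, rounded half-away-from-zero to
one decimal place (clinical-report convention).

MSI status comes from an MSIsensor-style score. With a matched normal the
score maps to MSS (< 10), MSI-L (10-30 inclusive) or MSI-H (> 30); in
tumor-only mode a single cutoff of 25 separates MSS from MSI (strictly
greater). When a score falls close to a cutoff (within ``adjudication_delta``)
the sample's TMB adjudicates: a hypermutated sample (TMB >= ``tmb_high``)
is pushed to the MSI side of that cutoff, otherwise to the MSS side. With
``adjudication_delta=0`` the adjudication layer is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

__all__ = [
    "TmbResult",
    "MsiCutoffs",
    "MsiCall",
    "compute_tmb",
    "call_msi_matched",
    "call_msi_tumor_only",
]


@dataclass(frozen=True)
class TmbResult:
    mutation_count: int
    panel_size_mb: float
    tmb: float  # mutations per Mb, rounded to 1 decimal


@dataclass(frozen=True)
class MsiCutoffs:
    """Score cutoffs and the TMB-based adjudication window.

    ``adjudication_delta`` quantifies "close to a cutoff" as
    ``|score - cutoff| < delta`` (strict, so delta=0 disables adjudication); ``tmb_high`` (mutations/Mb) is the
    hypermutation threshold that decides the adjudication direction.
    """

    mss_below: float = 10.0
    msih_above: float = 30.0
    tumor_only_cutoff: float = 25.0
    adjudication_delta: float = 5.0
    tmb_high: float = 20.0

    def __post_init__(self) -> None:
        if self.mss_below > self.msih_above:
            raise ValueError("mss_below must not exceed msih_above")
        if self.adjudication_delta < 0:
            raise ValueError("adjudication_delta must be >= 0")


@dataclass(frozen=True)
class MsiCall:
    status: str  # matched: {MSS, MSI-L, MSI-H}; tumor-only: {MSS, MSI}
    adjudicated: bool
    score: float


def compute_tmb(mutation_count: int, panel_size_mb: float) -> TmbResult:
    """Mutations per megabase, rounded half-away-from-zero to 1 decimal.

    Rounding uses exact decimal arithmetic so that e.g. 7 mutations over
    0.8 Mb (= 8.75/Mb) report as 8.8, not 8.7.
    """
    if panel_size_mb <= 0:
        raise ValueError(f"panel_size_mb must be > 0, got {panel_size_mb}")
    if mutation_count < 0:
        raise ValueError(f"mutation_count must be >= 0, got {mutation_count}")
    exact = Decimal(mutation_count) / Decimal(str(panel_size_mb))
    tmb = float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return TmbResult(mutation_count=mutation_count, panel_size_mb=panel_size_mb, tmb=tmb)


def _near_cutoff(score: float, cutoffs: list[float], delta: float) -> float | None:
    """The nearest cutoff strictly within delta, or None (so delta=0 never
    triggers adjudication). Ties go to the lower cutoff."""
    near = [c for c in cutoffs if abs(score - c) < delta]
    if not near:
        return None
    return min(near, key=lambda c: (abs(score - c), c))


def call_msi_matched(score: float, tmb: float, cutoffs: MsiCutoffs | None = None) -> MsiCall:
    """Three-level MSI call for a tumor with a matched normal.

    Base call: MSS below ``mss_below``; MSI-L between the cutoffs
    (inclusive); MSI-H above ``msih_above``. Near either cutoff the TMB
    adjudicates: hypermutated samples take the higher-instability side of
    that cutoff, others the lower side.
    """
    cutoffs = cutoffs or MsiCutoffs()
    if score < 0:
        raise ValueError(f"score must be >= 0, got {score}")
    if score < cutoffs.mss_below:
        status = "MSS"
    elif score <= cutoffs.msih_above:
        status = "MSI-L"
    else:
        status = "MSI-H"
    cut = _near_cutoff(score, [cutoffs.mss_below, cutoffs.msih_above],
                       cutoffs.adjudication_delta)
    adjudicated = cut is not None
    if adjudicated:
        high_side = tmb >= cutoffs.tmb_high
        if cut == cutoffs.mss_below:
            status = "MSI-L" if high_side else "MSS"
        else:
            status = "MSI-H" if high_side else "MSI-L"
    return MsiCall(status=status, adjudicated=adjudicated, score=score)


def call_msi_tumor_only(
    score: float,
    cutoffs: MsiCutoffs | None = None,
    tmb: float | None = None,
) -> MsiCall:
    """Two-level MSI call without a matched normal: MSI iff score strictly
    exceeds ``tumor_only_cutoff`` (a score exactly at the cutoff is MSS).
    Near the cutoff, the TMB adjudicates when provided."""
    cutoffs = cutoffs or MsiCutoffs()
    if score < 0:
        raise ValueError(f"score must be >= 0, got {score}")
    status = "MSI" if score > cutoffs.tumor_only_cutoff else "MSS"
    adjudicated = False
    if tmb is not None and abs(score - cutoffs.tumor_only_cutoff) < cutoffs.adjudication_delta:
        status = "MSI" if tmb >= cutoffs.tmb_high else "MSS"
        adjudicated = True
    return MsiCall(status=status, adjudicated=adjudicated, score=score)
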