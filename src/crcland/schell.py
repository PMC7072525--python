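"""Schell mutational classification of colorectal cancers and risk strata.

The scheme combines the number of clonal truncating APC mutations
(nonsense, frameshift, splice site) with the mutation status of TP53 and
KRAS:

========  ==============================  =====================
class     truncating APC                  TP53 / KRAS
========  ==============================  =====================
0         none                            any
1         one                             one of the two mutated
2         two or more                     one of the two mutated
3         one                             both mutated
4         two or more                     both mutated
========  ==============================  =====================

Classes 0 and 4 carry the worst prognosis and form the "high-risk"
stratum; classes 1-3 are "low-risk".

The published enumeration has a gap: a tumor with truncating APC but with
NEITHER TP53 nor KRAS mutated fits no listed class. Such tumors are
assigned the corresponding single/double-APC class (1 or 2) — the
conservative low-risk branch — with ``fallback_applied=True`` surfaced in
the result. NRAS does not substitute for KRAS here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .records import TRUNCATING_CONSEQUENCES, VariantRecord

__all__ = [
    "SchellInput",
    "SchellResult",
    "classify_schell",
    "stratify_risk",
    "derive_schell_input",
]

HIGH_RISK_CLASSES = frozenset({0, 4})


@dataclass(frozen=True)
class SchellInput:
    truncating_apc_count: int
    tp53_mutated: bool
    kras_mutated: bool

    def __post_init__(self) -> None:
        if self.truncating_apc_count < 0:
            raise ValueError("truncating_apc_count must be >= 0")


@dataclass(frozen=True)
class SchellResult:
    schell_class: int
    risk: str  # {"high", "low"}
    fallback_applied: bool


def classify_schell(inp: SchellInput) -> SchellResult:
    """Assign the Schell class (0-4) and risk stratum. Total on all inputs."""
    n = inp.truncating_apc_count
    both = inp.tp53_mutated and inp.kras_mutated
    neither = not (inp.tp53_mutated or inp.kras_mutated)
    if n == 0:
        cls, fallback = 0, False
    elif n == 1:
        cls, fallback = (3, False) if both else (1, neither)
    else:
        cls, fallback = (4, False) if both else (2, neither)
    return SchellResult(schell_class=cls, risk=stratify_risk(cls), fallback_applied=fallback)


def stratify_risk(schell_class: int) -> str:
    """Risk stratum of a Schell class: 0 and 4 are high risk, 1-3 low."""
    if schell_class not in {0, 1, 2, 3, 4}:
        raise ValueError(f"schell_class must be in 0..4, got {schell_class}")
    return "high" if schell_class in HIGH_RISK_CLASSES else "low"


def derive_schell_input(sample_clonal_variants: Iterable[VariantRecord]) -> SchellInput:
    """Summarise a sample's CLONAL variants into the classifier's input.

    Truncating APC mutations are clonal APC variants with a nonsense,
    frameshift or splice-site consequence; TP53/KRAS count as mutated when
    they carry at least one clonal non-synonymous variant.
    """
    apc = 0
    tp53 = False
    kras = False
    for rec in sample_clonal_variants:
        if rec.is_synonymous:
            continue
        if rec.gene == "APC" and rec.consequence in TRUNCATING_CONSEQUENCES:
            apc += 1
        elif rec.gene == "TP53":
            tp53 = True
        elif rec.gene == "KRAS":
            kras = True
    return SchellInput(truncating_apc_count=apc, tp53_mutated=tp53, kras_mutated=kras)
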