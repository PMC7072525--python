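"""Synthetic two-country metastatic colorectal cancer cohorts.

The generator emulates the statistical structure the downstream analysis
assumes: two cohorts (USA and Germany, 54 patients each by default),
roughly 10% MSI-high hypermutated samples, Schell class frequencies
matching the stage-IV margins of the study population (23:24:16:11:14 over
classes 0-4), and stratum-specific exponential overall survival with
configurable medians. Every sample's driver content (truncating APC, TP53,
KRAS) is drawn to be consistent with its Schell class, MSI samples carry
no truncating APC (class 0) plus elevated mutation counts and a BRAF
mutation with probability 0.73, and VAFs are laid out so that driver
mutations re-classify as clonal downstream.

All randomness flows from one ``numpy`` Generator seeded from the config;
draws happen in a fixed documented order (country by country, patient by
patient: MSI -> class -> treatment -> survival -> demographics -> MSI
score -> mutations), so identical configs give identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .records import ClinicalRecord, VariantRecord
from .schell import stratify_risk

__all__ = ["CohortConfig", "ConfigError", "generate_cohort", "survival_sampler"]


class ConfigError(ValueError):
    """Internally inconsistent cohort configuration."""


#: Background (non-driver) gene weights: the relative chance that a
#: passenger mutation hits each gene. These are plausible colorectal
#: cancer frequencies chosen for the simulator — the real per-gene
#: probabilities of the study cohorts are not published.
DEFAULT_GENE_WEIGHTS: dict[str, float] = {
    "PIK3CA": 0.18,
    "FBXW7": 0.11,
    "SMAD4": 0.10,
    "ARID1A": 0.08,
    "BRAF": 0.08,
    "SOX9": 0.06,
    "TCF7L2": 0.06,
    "ATM": 0.06,
    "PTEN": 0.05,
    "NRAS": 0.04,
    "CTNNB1": 0.04,
    "RNF43": 0.04,
    "BRCA2": 0.03,
    "ERBB2": 0.03,
    "GNAS": 0.02,
    "POLE": 0.02,
}

#: Stage-IV Schell class margins of the combined study population.
DEFAULT_SCHELL_PROBS = (23 / 88, 24 / 88, 16 / 88, 11 / 88, 14 / 88)

#: Stratum medians (months) keyed by (risk, country, treatment): high-risk
#: Americans 29 under SOC+IND vs 13 under SOC alone; Germany 19.5 overall;
#: low-risk Americans near the cohort medians (34 SOC, 33 SOC+IND).
DEFAULT_SURVIVAL_MEDIANS: dict[tuple[str, str, str], float] = {
    ("high", "USA", "SOC_plus_IND"): 29.0,
    ("high", "USA", "SOC"): 13.0,
    ("low", "USA", "SOC_plus_IND"): 33.0,
    ("low", "USA", "SOC"): 34.0,
    ("high", "Germany", "SOC"): 19.5,
    ("low", "Germany", "SOC"): 19.5,
}


@dataclass
class CohortConfig:
    n_per_country: int = 54
    msi_fraction: float = 0.10
    schell_class_probs: tuple[float, ...] = DEFAULT_SCHELL_PROBS
    gene_mutation_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_WEIGHTS)
    )
    tp53_prob: float = 0.60
    kras_prob: float = 0.45
    mss_mutation_count_mean: float = 8.0
    msi_mutation_count_mean: float = 40.0
    #: Beta(a, b) for the clonal VAF peak (the sample's maximum VAF).
    vaf_clonal_beta: tuple[float, float] = (8.0, 12.0)
    #: Beta(a, b) positioning subclonal VAFs inside the subclonal band.
    vaf_subclonal_beta: tuple[float, float] = (2.0, 2.0)
    subclonal_fraction: float = 0.30
    braf_given_msi: float = 0.73
    ind_fraction_usa: float = 35 / 54
    survival_median_months: Mapping[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_SURVIVAL_MEDIANS)
    )
    censor_fraction: float = 0.20
    seed: int = 0

    def validate(self) -> None:
        probs = list(self.schell_class_probs)
        if len(probs) != 5 or any(p < 0 or p > 1 for p in probs):
            raise ConfigError("schell_class_probs must be 5 probabilities")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError("schell_class_probs must sum to 1")
        for name in ("msi_fraction", "tp53_prob", "kras_prob",
                     "subclonal_fraction", "braf_given_msi", "censor_fraction",
                     "ind_fraction_usa"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if any(m <= 0 for m in self.survival_median_months.values()):
            raise ConfigError("survival medians must be > 0")
        if (probs[3] > 0 or probs[4] > 0) and (self.tp53_prob == 0 or self.kras_prob == 0):
            raise ConfigError(
                "classes 3/4 need both TP53 and KRAS mutable "
                "(tp53_prob and kras_prob must be > 0)"
            )
        if (probs[1] > 0 or probs[2] > 0) and (self.tp53_prob + self.kras_prob == 0):
            raise ConfigError("classes 1/2 need TP53 or KRAS mutable")


def survival_sampler(median_months: float, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Exponential survival times with the requested median:
    T ~ Exp(rate = ln 2 / median)."""
    if median_months <= 0:
        raise ConfigError("median_months must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return np.array([], dtype=float)
    return rng.exponential(scale=median_months / math.log(2), size=n)


def _censor_upper(median: float, frac: float) -> float:
    """Upper limit c of an independent Uniform(0, c) censoring time such
    that P(censored) = frac for Exp(ln2/median) survival."""
    lam = math.log(2) / median
    # P(C < T) = (1 - exp(-lam*c)) / (lam*c), decreasing from 1 to 0 in c
    f = lambda c: (1 - math.exp(-lam * c)) / (lam * c) - frac
    return brentq(f, 1e-9, 1e6)


_APC_TRUNC = (("nonsense", 0.45), ("frameshift", 0.45), ("splice_site", 0.10))
_BACKGROUND_CSQ = (("missense", 0.60), ("synonymous", 0.10), ("nonsense", 0.10),
                   ("frameshift", 0.10), ("splice_site", 0.05), ("inframe_indel", 0.05))
_ALLELES = {
    "missense": ("C", "T"),
    "nonsense": ("C", "A"),
    "synonymous": ("G", "A"),
    "frameshift": ("CT", "C"),
    "splice_site": ("G", "T"),
    "inframe_indel": ("CTT", "C"),
    "other": ("A", "G"),
}


def _choice(rng: np.random.Generator, pairs) -> str:
    labels = [l for l, _ in pairs]
    w = np.array([p for _, p in pairs], dtype=float)
    return labels[rng.choice(len(labels), p=w / w.sum())]


def generate_cohort(config: CohortConfig | None = None, return_truth: bool = False):
    """Draw a full synthetic cohort.

    Returns
    -------
    (variants, clinical) : (list[VariantRecord], list[ClinicalRecord])
        Deterministic given ``config.seed``. With ``return_truth=True`` a
        third element records each sample's generating ground truth
        (Schell class, MSI flag, risk, stratum median) for validation.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth: list[dict] = []

    gene_pool = sorted(config.gene_mutation_probs)
    gene_locus = {g: i + 1 for i, g in enumerate(sorted(
        set(gene_pool) | {"APC", "TP53", "KRAS", "BRAF"}))}
    censor_cache: dict[float, float] = {}

    variants: list[VariantRecord] = []
    clinical: list[ClinicalRecord] = []

    for country, prefix in (("USA", "US"), ("Germany", "DE")):
        for k in range(config.n_per_country):
            sample_id = f"{prefix}{k + 1:03d}"
            is_msi = rng.random() < config.msi_fraction
            schell_class = int(rng.choice(5, p=np.asarray(config.schell_class_probs)))
            if is_msi:
                schell_class = 0  # MSI tumors lack truncating APC
            if country == "USA":
                treatment = ("SOC_plus_IND" if rng.random() < config.ind_fraction_usa
                             else "SOC")
            else:
                treatment = "SOC"
            risk = stratify_risk(schell_class)
            median = config.survival_median_months[(risk, country, treatment)]
            t_death = float(survival_sampler(median, 1, rng)[0])
            if config.censor_fraction > 0:
                if median not in censor_cache:
                    censor_cache[median] = _censor_upper(median, config.censor_fraction)
                t_censor = float(rng.uniform(0, censor_cache[median]))
                event = t_death <= t_censor
                os_months = t_death if event else t_censor
            else:
                event, os_months = True, t_death
            gender = "male" if rng.random() < 0.565 else "female"
            age = float(np.clip(rng.normal(64, 11), 25, 95))
            if is_msi:
                side = "right" if rng.random() < 0.91 else "left"
            elif country == "Germany":
                side = _choice(rng, (("right", 0.33), ("left", 0.39), ("rectum", 0.28)))
            else:
                side = _choice(rng, (("right", 0.52), ("left", 0.39), ("NA", 0.09)))
            msi_score = float(rng.uniform(32, 80) if is_msi else rng.uniform(0, 8))
            clinical.append(
                ClinicalRecord(
                    sample_id=sample_id,
                    country=country,
                    treatment=treatment,
                    os_months=round(os_months, 2),
                    event=bool(event),
                    tumor_side=None if side == "NA" else side,
                    age_years=round(age, 1),
                    gender=gender,
                    msi_score=round(msi_score, 2),
                    msi_matched=(country == "Germany"),
                )
            )
            variants.extend(
                _sample_variants(rng, config, sample_id, schell_class, is_msi,
                                 gene_pool, gene_locus)
            )
            truth.append(
                {"sample_id": sample_id, "schell_class": schell_class,
                 "is_msi": is_msi, "risk": risk, "median_months": median}
            )
    if return_truth:
        return variants, clinical, truth
    return variants, clinical


def _sample_variants(rng, config: CohortConfig, sample_id: str, schell_class: int,
                     is_msi: bool, gene_pool: list[str], gene_locus: dict[str, int]
                     ) -> list[VariantRecord]:
    # driver content implied by the Schell class
    drivers: list[tuple[str, str]] = []  # (gene, consequence)
    n_apc = {0: 0, 1: 1, 2: 2, 3: 1, 4: 2}[schell_class]
    for _ in range(n_apc):
        drivers.append(("APC", _choice(rng, _APC_TRUNC)))
    if schell_class in (3, 4):
        tp53, kras = True, True
    elif schell_class in (1, 2):
        p = config.tp53_prob / (config.tp53_prob + config.kras_prob)
        tp53 = rng.random() < p
        kras = not tp53
    else:
        tp53 = rng.random() < config.tp53_prob
        kras = rng.random() < config.kras_prob
    if tp53:
        drivers.append(("TP53", _choice(rng, (("missense", 0.7), ("nonsense", 0.15),
                                              ("frameshift", 0.15)))))
    if kras:
        drivers.append(("KRAS", "missense"))
    if is_msi and rng.random() < config.braf_given_msi:
        drivers.append(("BRAF", "missense"))

    mean = config.msi_mutation_count_mean if is_msi else config.mss_mutation_count_mean
    total = int(rng.poisson(mean))
    n_background = max(0, total - len(drivers))
    pool = [g for g in gene_pool if g not in {"APC", "TP53", "KRAS"}]
    if is_msi:
        pool = [g for g in pool if g != "BRAF"]
    w = np.array([config.gene_mutation_probs[g] for g in pool], dtype=float)
    w = w / w.sum()

    # VAF layout: the clonal peak vmax sets the sample's maximum VAF;
    # clonal variants sit in [0.3, 1.0] x vmax (safely above the 25% rule),
    # subclonal ones in [0.105, 0.245] x vmax (below it, above the 1/10
    # exclusion). Drivers are always clonal.
    vmax = float(rng.beta(*config.vaf_clonal_beta))
    while vmax < 0.10:
        vmax = float(rng.beta(*config.vaf_clonal_beta))

    records: list[VariantRecord] = []

    def add(gene: str, csq: str, vaf: float) -> None:
        tumor_depth = 100 + int(rng.poisson(450))
        variant_depth = max(1, int(round(vaf * tumor_depth)))
        ref, alt = _ALLELES[csq]
        locus = gene_locus[gene]
        records.append(
            VariantRecord(
                sample_id=sample_id,
                gene=gene,
                chrom=f"chr{1 + (locus - 1) % 22}",
                pos=1_000_000 * locus + int(rng.integers(0, 10_000)),
                ref=ref,
                alt=alt,
                consequence=csq,
                tumor_vaf=round(vaf, 4),
                variant_depth=variant_depth,
                tumor_depth=tumor_depth,
                normal_depth=100 + int(rng.poisson(450)),
                base_quality=float(np.round(rng.uniform(30, 40), 1)),
                population_af=0.0,
                strand_bias_fail=False,
                damage_artifact=False,
            )
        )

    first = True
    for gene, csq in drivers:
        vaf = vmax if first else vmax * float(rng.uniform(0.3, 1.0))
        first = False
        add(gene, csq, vaf)
    for _ in range(n_background):
        gene = pool[int(rng.choice(len(pool), p=w))]
        if rng.random() < config.subclonal_fraction:
            frac = 0.105 + 0.14 * float(rng.beta(*config.vaf_subclonal_beta))
            vaf = vmax * frac
        else:
            vaf = vmax if first else vmax * float(rng.uniform(0.3, 1.0))
            first = False
        add(gene, csq=_choice(rng, _BACKGROUND_CSQ), vaf=vaf)
    if first:
        # a tumor sample with zero mutations still needs none recorded;
        # nothing to do — downstream drops it from the matrix
        pass
    return records
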