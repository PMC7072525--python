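"""End-to-end orchestration: filter -> clonality -> TMB/MSI -> Schell ->
binary matrix -> PCA/network -> survival -> contingency.

:func:`analyze_cohort` is the in-memory pipeline; :func:`run_pipeline`
wraps it with file I/O, writing every artifact plus a manifest of
content hashes so that identical inputs and config provably reproduce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .burden import MsiCutoffs, call_msi_matched, call_msi_tumor_only, compute_tmb
from .contingency import compare_cohort_composition
from .filters import (ClonalityThresholds, FilterThresholds,
                      apply_technical_filters, classify_clonality)
from .landscape import annotate_network, build_mj_network, run_pca
from .matrix import encode_binary_matrix, gene_counts_by_sample
from .records import ClinicalRecord, VariantRecord
from .schell import classify_schell, derive_schell_input
from .survival import compare_strata

__all__ = ["PipelineConfig", "CohortResults", "analyze_cohort", "run_pipeline"]


@dataclass
class PipelineConfig:
    variant_path: str
    clinical_path: str
    out_dir: str
    variant_dialect: str = "maf_tsv"
    shared_genes_path: str | None = None       # plain-text gene list; None = all observed
    panel_size_mb: float = 1.1
    filter_thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    clonality_thresholds: ClonalityThresholds = field(default_factory=ClonalityThresholds)
    msi_cutoffs: MsiCutoffs = field(default_factory=MsiCutoffs)
    tmb_include_synonymous: bool = False
    epsilon: int = 0
    n_components: int = 2
    seed: int = 0


@dataclass
class CohortResults:
    """Everything the pipeline computes, stage by stage."""

    kept_variants: list[VariantRecord]
    removed_variants: list            # (record, reason codes)
    clonality: pd.DataFrame           # per-variant sample/gene/vaf/label
    sample_summary: pd.DataFrame      # tmb, msi, schell class, risk per sample
    binary_matrix: object             # BinaryMatrix
    pca: object | None                # PcaResult
    network: object | None            # networkx.Graph
    km_curves: dict
    logrank_tests: list
    contingency: dict                 # variable -> (table, p)


def _msi_group(status: str | None) -> str | None:
    if status is None or status == "NA":
        return None
    return "MSI" if status in {"MSI", "MSI-H"} else "MSS"


def analyze_cohort(
    variants: Sequence[VariantRecord],
    clinical: Sequence[ClinicalRecord],
    shared_genes: Sequence[str] | None = None,
    panel_size_mb: float = 1.1,
    filter_thresholds: FilterThresholds | None = None,
    clonality_thresholds: ClonalityThresholds | None = None,
    msi_cutoffs: MsiCutoffs | None = None,
    tmb_include_synonymous: bool = False,
    epsilon: int = 0,
    n_components: int = 2,
    build_network: bool = True,
) -> CohortResults:
    """Run the full analysis in memory and return every stage's result."""
    filter_thresholds = filter_thresholds or FilterThresholds()
    clonality_thresholds = clonality_thresholds or ClonalityThresholds()
    msi_cutoffs = msi_cutoffs or MsiCutoffs()

    kept, removed = apply_technical_filters(variants, filter_thresholds)

    by_sample: dict[str, list[VariantRecord]] = {}
    for rec in kept:
        by_sample.setdefault(rec.sample_id, []).append(rec)

    clonality_rows = []
    clonal_by_sample: dict[str, list[VariantRecord]] = {}
    for sample, recs in by_sample.items():
        calls = classify_clonality(recs, clonality_thresholds)
        for rec, call in zip(recs, calls):
            clonality_rows.append(
                {"sample_id": sample, "gene": rec.gene, "chrom": rec.chrom,
                 "pos": rec.pos, "tumor_vaf": rec.tumor_vaf,
                 "label": call.label, "max_vaf_used": call.max_vaf_used}
            )
            if call.label == "clonal":
                clonal_by_sample.setdefault(sample, []).append(rec)
    clonality_df = pd.DataFrame(
        clonality_rows,
        columns=["sample_id", "gene", "chrom", "pos", "tumor_vaf", "label",
                 "max_vaf_used"],
    )

    clin_by_sample = {c.sample_id: c for c in clinical}
    summary_rows = []
    risk_by_sample: dict[str, str] = {}
    msi_status: dict[str, str] = {}
    for clin in clinical:
        sample = clin.sample_id
        recs = by_sample.get(sample, [])
        n_mut = sum(
            1 for r in recs if tmb_include_synonymous or not r.is_synonymous
        )
        tmb = compute_tmb(n_mut, panel_size_mb)
        if clin.msi_score is None:
            status, adjudicated = "NA", False
        elif clin.msi_matched:
            call = call_msi_matched(clin.msi_score, tmb.tmb, msi_cutoffs)
            status, adjudicated = call.status, call.adjudicated
        else:
            call = call_msi_tumor_only(clin.msi_score, msi_cutoffs, tmb=tmb.tmb)
            status, adjudicated = call.status, call.adjudicated
        schell = classify_schell(derive_schell_input(clonal_by_sample.get(sample, [])))
        risk_by_sample[sample] = schell.risk
        msi_status[sample] = status
        summary_rows.append(
            {"sample_id": sample, "country": clin.country,
             "treatment": clin.treatment, "n_kept": len(recs),
             "n_clonal": len(clonal_by_sample.get(sample, [])),
             "mutation_count": n_mut, "tmb": tmb.tmb, "msi_score": clin.msi_score,
             "msi_status": status, "msi_adjudicated": adjudicated,
             "schell_class": schell.schell_class, "risk": schell.risk,
             "fallback_applied": schell.fallback_applied}
        )
    sample_summary = pd.DataFrame(summary_rows)

    all_clonal = [r for recs in clonal_by_sample.values() for r in recs]
    if shared_genes is None:
        shared_genes = sorted({r.gene for r in all_clonal}) or ["NONE"]
    bm = encode_binary_matrix(gene_counts_by_sample(all_clonal), shared_genes)

    pca = run_pca(bm, n_components) if bm.data.shape[0] >= 2 else None
    network = None
    if build_network and bm.data.shape[0] >= 1:
        network = build_mj_network(bm, epsilon=epsilon)
        ras = {
            s: ("yes" if any(r.gene in {"KRAS", "NRAS"} for r in recs) else "no")
            for s, recs in clonal_by_sample.items()
        }
        braf = {
            s: ("yes" if any(r.gene == "BRAF" for r in recs) else "no")
            for s, recs in clonal_by_sample.items()
        }
        annotate_network(network, msi_status=msi_status,
                         gene_status={"ras_mutated": ras, "braf_mutated": braf})

    km_curves, logrank_tests = compare_strata(
        clinical, risk_by_sample=risk_by_sample,
        by=("country", "treatment", "risk"),
    )

    contingency: dict[str, tuple] = {}
    msi_groups = {s: _msi_group(v) for s, v in msi_status.items()}
    schell_vals = {row["sample_id"]: str(row["schell_class"]) for row in summary_rows}
    for name, kwargs in (
        ("gender", {"variable": "gender"}),
        ("tumor_side", {"variable": "tumor_side"}),
        ("msi", {"variable": "msi", "values": msi_groups}),
        ("schell", {"variable": "schell", "values": schell_vals}),
    ):
        try:
            contingency[name] = compare_cohort_composition(clinical, **kwargs)
        except ValueError:
            continue  # degenerate (single-country or single-category) input

    return CohortResults(
        kept_variants=kept,
        removed_variants=removed,
        clonality=clonality_df,
        sample_summary=sample_summary,
        binary_matrix=bm,
        pca=pca,
        network=network,
        km_curves=km_curves,
        logrank_tests=logrank_tests,
        contingency=contingency,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_dict(config: PipelineConfig) -> dict:
    def conv(v):
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            return {k: conv(x) for k, x in dataclasses.asdict(v).items()}
        if isinstance(v, tuple):
            return list(v)
        return v
    return {f.name: conv(getattr(config, f.name))
            for f in dataclasses.fields(config)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, write all artifacts under ``config.out_dir``
    and return the manifest (artifact name -> sha256). Any stage failure
    aborts with the stage name attached to the error."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "read_inputs"
    try:
        variants = cio.read_variant_table(config.variant_path, config.variant_dialect)
        clinical = cio.read_clinical_table(config.clinical_path)
        shared = None
        if config.shared_genes_path:
            shared = [
                line.strip()
                for line in Path(config.shared_genes_path).read_text().splitlines()
                if line.strip()
            ]
        stage = "analysis"
        res = analyze_cohort(
            variants, clinical,
            shared_genes=shared,
            panel_size_mb=config.panel_size_mb,
            filter_thresholds=config.filter_thresholds,
            clonality_thresholds=config.clonality_thresholds,
            msi_cutoffs=config.msi_cutoffs,
            tmb_include_synonymous=config.tmb_include_synonymous,
            epsilon=config.epsilon,
            n_components=config.n_components,
        )
        stage = "write_outputs"
        cio.write_variant_table(res.kept_variants, out / "filtered_variants.tsv")
        with open(out / "removed_variants.tsv", "w") as fh:
            fh.write("sample_id\tgene\tchrom\tpos\treasons\n")
            for rec, reasons in res.removed_variants:
                fh.write(f"{rec.sample_id}\t{rec.gene}\t{rec.chrom}\t{rec.pos}\t"
                         f"{','.join(reasons)}\n")
        res.clonality.to_csv(out / "clonality.tsv", sep="\t", index=False)
        res.sample_summary.to_csv(out / "sample_summary.tsv", sep="\t", index=False)
        res.binary_matrix.to_tsv(out / "binary_matrix.tsv")
        (out / "dropped_samples.txt").write_text(
            "\n".join(res.binary_matrix.dropped_samples) + "\n"
            if res.binary_matrix.dropped_samples else ""
        )
        if res.pca is not None:
            res.pca.scores.to_csv(out / "pca_scores.tsv", sep="\t",
                                  index_label="sample_id")
        if res.network is not None:
            cio.write_network(res.network, out / "network.gml", format="gml")
        with open(out / "km_curves.tsv", "w") as fh:
            fh.write("stratum\ttime\tat_risk\tevents\tsurvival\tci_lower\tci_upper\n")
            for key, curve in res.km_curves.items():
                name = "/".join(map(str, key))
                for t, n, d, s, lo, hi in zip(curve.event_times, curve.at_risk,
                                              curve.events, curve.survival,
                                              curve.ci_lower, curve.ci_upper):
                    fh.write(f"{name}\t{t}\t{int(n)}\t{int(d)}\t{s:.6f}\t"
                             f"{lo:.6f}\t{hi:.6f}\n")
        comparisons = {
            "medians": {"/".join(map(str, k)): c.median_os
                        for k, c in res.km_curves.items()},
            "logrank": [
                {"a": t.label_a, "b": t.label_b, "chi_square": t.chi_square,
                 "p_value": t.p_value, "hazard_ratio": t.hazard_ratio,
                 "hr_ci": list(t.hr_ci)}
                for t in res.logrank_tests
            ],
        }
        (out / "survival_comparisons.json").write_text(
            json.dumps(comparisons, indent=1, sort_keys=True, allow_nan=True))
        cont = {
            name: {"rows": tab.row_labels, "cols": tab.col_labels,
                   "counts": tab.counts.tolist(), "p_value": p}
            for name, (tab, p) in res.contingency.items()
        }
        (out / "contingency.json").write_text(
            json.dumps(cont, indent=1, sort_keys=True))
        (out / "resolved_config.json").write_text(
            json.dumps(_config_dict(config), indent=1, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
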