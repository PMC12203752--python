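"""The metastasis-associated gene discovery cascade.

Order of operations on a cohort of primaries, metastases, non-prostate
normal tissues and BPH prostate controls:

1. permissive DE call, metastases over primaries (adj-p <= 0.1);
2. per-tissue control filter: primaries vs each non-prostate normal
   tissue;
3. pooled control filter: primaries vs all non-prostate normals combined;
4. BPH filter: BPH vs pooled non-prostate normals;
5. pairwise concordance filter across matched patients.

Filters 2–4 remove a DEG when the control contrast is significant
(adj-p < 0.01) *and* oriented so that baseline tissue expression — not
metastasis — explains the observed change.  Every control contrast is
oriented prostate-side over control-side; a DEG with metastasis direction
``d`` is tissue-driven exactly when the significant control fold change
has sign ``-d`` (high in the control tissue explains high in metastases
located in that tissue, and symmetrically for down-regulated genes).

Every gene entering the cascade leaves an audit trail of one decision per
stage it reached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .diffexp import Contrast, DEGCall, call_degs, nb_wald_test, size_factors
from .types import ConfigurationError, CountMatrix, SampleRecord

log = logging.getLogger("metscreen")

STAGES = ("de", "tissue_per", "tissue_pooled", "bph", "pairwise")


@dataclass
class FilterDecision:
    gene_id: str
    stage: str
    kept: bool
    reason: str
    stats: dict[str, Any] = field(default_factory=dict)


@dataclass
class DiscoveryReport:
    """Full audit of the cascade: stage counts, decisions, final calls."""

    stage_counts: list[dict[str, int]]
    decisions: list[FilterDecision]
    final: pd.DataFrame  # gene_id index; direction, log2fc, adj_p
    de_results: pd.DataFrame

    def decisions_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": d.gene_id,
                "stage": d.stage,
                "kept": d.kept,
                "reason": d.reason,
                **{k: v for k, v in d.stats.items() if np.isscalar(v)},
            }
            for d in self.decisions
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "stages": self.stage_counts,
            "n_final": int(len(self.final)),
            "n_final_up": int((self.final["direction"] > 0).sum()),
            "n_final_down": int((self.final["direction"] < 0).sum()),
        }


def _split_design(samples: list[SampleRecord]) -> dict[str, list[SampleRecord]]:
    by_cat: dict[str, list[SampleRecord]] = {c: [] for c in ("primary", "metastasis", "normal", "bph")}
    for s in samples:
        by_cat[s.category].append(s)
    return by_cat


def tissue_baseline_filter(
    degs: DEGCall,
    counts: CountMatrix,
    samples: list[SampleRecord],
    alpha: float = 0.01,
) -> list[FilterDecision]:
    """Remove DEGs explained by baseline expression in any single control tissue.

    For each non-prostate normal tissue with >= 2 samples, runs the
    genome-wide contrast primary-over-normal_t; a DEG with metastasis
    direction d is removed if any tissue shows adj-p < alpha with fold
    change of sign -d.  Tissues with fewer than 2 normals are skipped
    with a warning (they still join the pooled filter).
    """
    by_cat = _split_design(samples)
    primaries = [s.sample_id for s in by_cat["primary"]]
    tissues: dict[str, list[str]] = {}
    for s in by_cat["normal"]:
        tissues.setdefault(s.tissue, []).append(s.sample_id)
    usable = {t: ids for t, ids in tissues.items() if len(ids) >= 2}
    for t, ids in tissues.items():
        if len(ids) < 2:
            log.warning("tissue %s has %d normal sample(s); skipped by the per-tissue filter", t, len(ids))
    if not usable:
        raise ConfigurationError("per-tissue filter needs >= 1 non-prostate normal tissue with >= 2 samples")

    contrasts = {
        t: nb_wald_test(counts, Contrast(numerator=primaries, denominator=ids))
        for t, ids in usable.items()
    }
    decisions = []
    for gene in degs.genes:
        d = degs.direction(gene)
        removed_by = None
        stats: dict[str, Any] = {}
        for t, res in contrasts.items():
            row = res.loc[gene]
            if row["status"] != "tested" or not np.isfinite(row["adj_p"]):
                continue
            if row["adj_p"] < alpha and np.sign(row["log2fc"]) == -d:
                removed_by = t
                stats = {"tissue": t, "log2fc": float(row["log2fc"]), "adj_p": float(row["adj_p"])}
                break
        if removed_by is None:
            decisions.append(FilterDecision(gene, "tissue_per", True, "no opposing control change"))
        else:
            decisions.append(
                FilterDecision(
                    gene, "tissue_per", False,
                    f"baseline expression in {removed_by}", stats,
                )
            )
    return decisions


def _pooled_style_filter(
    stage: str,
    reason_removed: str,
    degs: DEGCall,
    results: pd.DataFrame,
    alpha: float,
) -> list[FilterDecision]:
    decisions = []
    for gene in degs.genes:
        d = degs.direction(gene)
        row = results.loc[gene]
        significant = (
            row["status"] == "tested"
            and np.isfinite(row["adj_p"])
            and row["adj_p"] < alpha
            and np.sign(row["log2fc"]) == -d
        )
        if significant:
            decisions.append(
                FilterDecision(
                    gene, stage, False, reason_removed,
                    {"log2fc": float(row["log2fc"]), "adj_p": float(row["adj_p"])},
                )
            )
        else:
            decisions.append(FilterDecision(gene, stage, True, "no opposing control change"))
    return decisions


def pooled_tissue_filter(
    degs: DEGCall,
    counts: CountMatrix,
    samples: list[SampleRecord],
    alpha: float = 0.01,
) -> list[FilterDecision]:
    """Remove DEGs with generally higher (or lower) expression outside the prostate.

    One pooled contrast: all primaries over all non-prostate normals
    combined; removal rule as in :func:`tissue_baseline_filter`.
    """
    by_cat = _split_design(samples)
    primaries = [s.sample_id for s in by_cat["primary"]]
    normals = [s.sample_id for s in by_cat["normal"]]
    if len(normals) < 2:
        raise ConfigurationError("pooled filter needs >= 2 non-prostate normal samples")
    res = nb_wald_test(counts, Contrast(numerator=primaries, denominator=normals))
    return _pooled_style_filter(
        "tissue_pooled", "higher baseline expression outside the prostate", degs, res, alpha
    )


def bph_filter(
    degs: DEGCall,
    counts: CountMatrix,
    samples: list[SampleRecord],
    alpha: float = 0.01,
) -> list[FilterDecision]:
    """Remove DEGs explained by prostate-vs-other-tissue differences.

    Contrast: BPH (benign prostate) over pooled non-prostate normals.
    """
    by_cat = _split_design(samples)
    bph = [s.sample_id for s in by_cat["bph"]]
    normals = [s.sample_id for s in by_cat["normal"]]
    if len(bph) < 2:
        raise ConfigurationError("BPH filter needs >= 2 BPH samples")
    if len(normals) < 2:
        raise ConfigurationError("BPH filter needs >= 2 pooled non-prostate normals")
    res = nb_wald_test(counts, Contrast(numerator=bph, denominator=normals))
    return _pooled_style_filter(
        "bph", "differential expression between BPH and normal tissues", degs, res, alpha
    )


def pairwise_concordance_filter(
    degs: DEGCall,
    norm_counts: pd.DataFrame,
    samples: list[SampleRecord],
    max_divergent: int = 2,
    two_primary_rule: str = "any",
) -> list[FilterDecision]:
    """Remove DEGs whose per-patient direction contradicts the global call.

    For each matched patient (one with both a primary and >= 1
    metastasis) the per-patient direction is the sign of
    mean(normalized counts over that patient's metastases) minus the
    normalized count of the patient's primary.  A patient is *divergent*
    when that sign is the negative of the gene's global metastasis
    direction; an exact tie (difference 0) counts as concordant.  A gene
    is removed when more than ``max_divergent`` patients are divergent.

    A patient with two primaries contributes one comparison per primary
    and is divergent if any comparison is (``two_primary_rule='any'``),
    or is judged on the mean of their primaries (``'mean'``).
    """
    by_patient_primary: dict[str, list[str]] = {}
    by_patient_mets: dict[str, list[str]] = {}
    for s in samples:
        if s.category == "primary":
            by_patient_primary.setdefault(s.patient_id, []).append(s.sample_id)
        elif s.category == "metastasis":
            by_patient_mets.setdefault(s.patient_id, []).append(s.sample_id)
    matched = sorted(p for p in by_patient_primary if p in by_patient_mets)
    if not matched:
        raise ConfigurationError("pairwise filter needs >= 1 patient with both a primary and a metastasis")

    decisions = []
    for gene in degs.genes:
        d = degs.direction(gene)
        directions: dict[str, int] = {}
        for patient in matched:
            met_mean = float(norm_counts.loc[gene, by_patient_mets[patient]].mean())
            prim_vals = [float(norm_counts.loc[gene, p]) for p in by_patient_primary[patient]]
            if len(prim_vals) > 1 and two_primary_rule == "mean":
                prim_vals = [float(np.mean(prim_vals))]
            signs = [int(np.sign(met_mean - pv)) for pv in prim_vals]
            divergent = any(s == -d for s in signs)
            directions[patient] = -d if divergent else (d if d in signs else 0)
        n_divergent = sum(1 for v in directions.values() if v == -d)
        stats = {"n_divergent": n_divergent, "directions": directions}
        if n_divergent > max_divergent:
            decisions.append(
                FilterDecision(
                    gene, "pairwise", False,
                    f"divergent direction in {n_divergent} patients (> {max_divergent})",
                    stats,
                )
            )
        else:
            decisions.append(FilterDecision(gene, "pairwise", True, "concordant across patients", stats))
    return decisions


def run_discovery(
    counts: CountMatrix,
    samples: list[SampleRecord],
    cfg: PipelineConfig | None = None,
) -> DiscoveryReport:
    """Run the full cascade and return the audited report."""
    cfg = cfg or PipelineConfig()
    by_cat = _split_design(samples)
    primaries = [s.sample_id for s in by_cat["primary"]]
    mets = [s.sample_id for s in by_cat["metastasis"]]
    normals = [s.sample_id for s in by_cat["normal"]]
    bph = [s.sample_id for s in by_cat["bph"]]
    if len(primaries) < 2 or len(mets) < 2:
        raise ConfigurationError("discovery needs >= 2 primary and >= 2 metastasis samples")
    if len(normals) < 2:
        raise ConfigurationError("discovery needs >= 2 non-prostate normal samples")
    if len(bph) < 2:
        raise ConfigurationError("discovery needs >= 2 BPH samples")
    known = {s.sample_id for s in samples}
    extra = [s for s in counts.sample_ids if s not in known]
    if extra:
        raise ConfigurationError(f"count matrix samples missing from the design: {extra[:5]}")

    log.info("stage de: %d metastases vs %d primaries", len(mets), len(primaries))
    de_res = nb_wald_test(counts, Contrast(numerator=mets, denominator=primaries))
    degs = call_degs(de_res, cfg.alpha_de, strict=False)
    decisions: list[FilterDecision] = [
        FilterDecision(
            g, "de", True, "differentially expressed",
            {"log2fc": float(de_res.loc[g, "log2fc"]), "adj_p": float(de_res.loc[g, "adj_p"])},
        )
        for g in degs.genes
    ]
    stage_counts = [
        {
            "stage": "de",
            "n_in": counts.shape[0],
            "n_kept": len(degs.genes),
            "n_up": len(degs.up),
            "n_down": len(degs.down),
        }
    ]

    current = degs
    norm = pd.DataFrame(
        counts.counts / size_factors(counts),
        index=pd.Index(counts.gene_ids, name="gene_id"),
        columns=counts.sample_ids,
    )
    stage_runners = [
        ("tissue_per", lambda d: tissue_baseline_filter(d, counts, samples, cfg.alpha_filter)),
        ("tissue_pooled", lambda d: pooled_tissue_filter(d, counts, samples, cfg.alpha_filter)),
        ("bph", lambda d: bph_filter(d, counts, samples, cfg.alpha_filter)),
        (
            "pairwise",
            lambda d: pairwise_concordance_filter(
                d, norm, samples, cfg.max_divergent_patients, cfg.two_primary_rule
            ),
        ),
    ]
    for stage, runner in stage_runners:
        log.info("stage %s: %d genes in", stage, len(current.genes))
        try:
            stage_decisions = runner(current)
        except ConfigurationError as exc:
            raise ConfigurationError(f"stage {stage}: {exc}") from exc
        decisions.extend(stage_decisions)
        kept = {dcs.gene_id for dcs in stage_decisions if dcs.kept}
        current = DEGCall(
            up=[g for g in current.up if g in kept],
            down=[g for g in current.down if g in kept],
        )
        stage_counts.append(
            {
                "stage": stage,
                "n_in": len(stage_decisions),
                "n_kept": len(current.genes),
                "n_up": len(current.up),
                "n_down": len(current.down),
            }
        )

    final = pd.DataFrame(
        {
            "direction": [1] * len(current.up) + [-1] * len(current.down),
            "log2fc": [float(de_res.loc[g, "log2fc"]) for g in current.genes],
            "adj_p": [float(de_res.loc[g, "adj_p"]) for g in current.genes],
        },
        index=pd.Index(current.genes, name="gene_id"),
    )
    return DiscoveryReport(stage_counts, decisions, final, de_res)
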