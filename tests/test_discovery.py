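"""Tissue-control filters, pairwise concordance, and the full cascade."""

import numpy as np
import pandas as pd
import pytest

from metscreen.diffexp import DEGCall
from metscreen.discovery import (
    _pooled_style_filter,
    bph_filter,
    pairwise_concordance_filter,
    pooled_tissue_filter,
    run_discovery,
    tissue_baseline_filter,
)
from metscreen.simulate import simulate_cohort
from metscreen.types import ConfigurationError, CountMatrix, SampleRecord

from conftest import small_sim_config


def _constant_cohort(gene_means: dict[str, dict[str, int]]):
    """Deterministic cohort: per-gene constant counts within each group.

    Groups: 4 primaries, 6 liver metastases, 4 liver normals, 4 bone
    normals, 4 BPH.  Twenty filler genes at a constant 100 anchor the
    size factors at 1.
    """
    design = (
        [("primary", "prostate", "P", 4)]
        + [("metastasis", "liver", "M", 6)]
        + [("normal", "liver", "NL", 4)]
        + [("normal", "bone", "NB", 4)]
        + [("bph", "prostate", "B", 4)]
    )
    samples, group_of = [], {}
    for category, tissue, prefix, n in design:
        for k in range(n):
            sid = f"{prefix}{k}"
            samples.append(SampleRecord(sid, f"{prefix}pat{k}", category, tissue))
            group_of[sid] = prefix
    gene_ids = list(gene_means) + [f"filler{i}" for i in range(20)]
    counts = np.empty((len(gene_ids), len(samples)), dtype=int)
    for i, g in enumerate(gene_ids):
        means = gene_means.get(g, {})
        for j, s in enumerate(samples):
            counts[i, j] = means.get(group_of[s.sample_id], 100)
    return CountMatrix(gene_ids, [s.sample_id for s in samples], counts), samples


class TestTissueBaselineFilter:
    def test_sign_and_significance_rules(self):
        # all three genes are up in mets (d = +1)
        counts, samples = _constant_cohort(
            {
                "removed": {"P": 100, "M": 400, "NL": 400},  # primary-over-liver = -2, sig
                "kept_ns": {"P": 100, "M": 400, "NL": 100},  # liver same as primary
                "kept_sign": {"P": 100, "M": 400, "NL": 25},  # primary-over-liver = +2
            }
        )
        degs = DEGCall(up=["removed", "kept_ns", "kept_sign"])
        decisions = {d.gene_id: d for d in tissue_baseline_filter(degs, counts, samples)}
        assert not decisions["removed"].kept
        assert "liver" in decisions["removed"].reason
        assert decisions["kept_ns"].kept
        assert decisions["kept_sign"].kept

    def test_requires_usable_normal_tissue(self):
        counts, samples = _constant_cohort({})
        stripped = [s for s in samples if s.category != "normal"]
        sub = CountMatrix(
            counts.gene_ids,
            [s.sample_id for s in stripped],
            counts.counts[:, counts.sample_columns([s.sample_id for s in stripped])],
        )
        with pytest.raises(ConfigurationError):
            tissue_baseline_filter(DEGCall(up=["filler0"]), sub, stripped)


class TestPooledAndBphFilters:
    def test_pooled_removal_both_directions(self):
        counts, samples = _constant_cohort(
            {
                "up_removed": {"P": 100, "M": 400, "NL": 400, "NB": 400},
                "down_removed": {"P": 400, "M": 100, "NL": 100, "NB": 100},
            }
        )
        degs = DEGCall(up=["up_removed"], down=["down_removed"])
        decisions = {d.gene_id: d for d in pooled_tissue_filter(degs, counts, samples)}
        assert not decisions["up_removed"].kept
        assert not decisions["down_removed"].kept

    def test_bph_sign_rule(self):
        counts, samples = _constant_cohort(
            {
                "removed": {"P": 100, "M": 400, "B": 100, "NL": 400, "NB": 400},
                "kept": {"P": 100, "M": 400, "B": 400, "NL": 100, "NB": 100},
            }
        )
        degs = DEGCall(up=["removed", "kept"])
        decisions = {d.gene_id: d for d in bph_filter(degs, counts, samples)}
        assert not decisions["removed"].kept  # BPH-over-normals = -2, sign -d
        assert decisions["kept"].kept  # BPH-over-normals = +2, same sign as d

    def test_threshold_is_strictly_below_alpha(self):
        # exercise the removal rule on exact adj-p values
        degs = DEGCall(up=["g1", "g2"])
        res = pd.DataFrame(
            {
                "log2fc": [-2.0, -2.0],
                "adj_p": [0.005, 0.02],
                "status": ["tested", "tested"],
            },
            index=pd.Index(["g1", "g2"], name="gene_id"),
        )
        decisions = {d.gene_id: d for d in _pooled_style_filter("bph", "r", degs, res, alpha=0.01)}
        assert not decisions["g1"].kept  # 0.005 < 0.01
        assert decisions["g2"].kept  # 0.02 >= 0.01


def _pairwise_inputs(per_patient_diffs, d=1, n_patients=6, two_primary_first=False):
    """norm-count frame realizing the requested met-minus-primary signs."""
    samples, data = [], {}
    for i in range(n_patients):
        pid = f"P{i}"
        n_prim = 2 if (two_primary_first and i == 0) else 1
        diffs = per_patient_diffs[i]
        diffs = diffs if isinstance(diffs, (list, tuple)) else [diffs] * n_prim
        met_val = 100.0
        for k in range(n_prim):
            sid = f"{pid}_pri{k}"
            samples.append(SampleRecord(sid, pid, "primary", "prostate"))
            data[sid] = met_val - diffs[k]
        sid = f"{pid}_met"
        samples.append(SampleRecord(sid, pid, "metastasis", "liver"))
        data[sid] = met_val
    norm = pd.DataFrame([data], index=pd.Index(["gene"], name="gene_id"))
    return DEGCall(up=["gene"]) if d > 0 else DEGCall(down=["gene"]), norm, samples


class TestPairwiseConcordance:
    def test_three_of_six_divergent_removed(self):
        degs, norm, samples = _pairwise_inputs([+5, +5, +5, -5, -5, -5])
        (decision,) = pairwise_concordance_filter(degs, norm, samples, max_divergent=2)
        assert not decision.kept
        assert decision.stats["n_divergent"] == 3

    def test_two_of_six_divergent_kept(self):
        degs, norm, samples = _pairwise_inputs([+5, +5, +5, +5, -5, -5])
        (decision,) = pairwise_concordance_filter(degs, norm, samples, max_divergent=2)
        assert decision.kept
        assert decision.stats["n_divergent"] == 2

    def test_tie_counts_as_concordant(self):
        degs, norm, samples = _pairwise_inputs([+5, +5, +5, +5, 0, +5])
        (decision,) = pairwise_concordance_filter(degs, norm, samples, max_divergent=2)
        assert decision.kept
        assert decision.stats["n_divergent"] == 0

    def test_two_primary_patient_divergent_if_any(self):
        # patient 0 has primaries on both sides of the metastasis mean
        degs, norm, samples = _pairwise_inputs(
            [[+5, -5], +5, +5, +5, -5, -5], two_primary_first=True
        )
        (decision,) = pairwise_concordance_filter(degs, norm, samples, max_divergent=2)
        assert not decision.kept  # patients 0, 4, 5 divergent
        (decision,) = pairwise_concordance_filter(
            degs, norm, samples, max_divergent=2, two_primary_rule="mean"
        )
        assert decision.kept  # mean of the two primaries equals the met value: tie

    def test_requires_matched_patients(self):
        degs, norm, samples = _pairwise_inputs([+5] * 6)
        unmatched = [s for s in samples if s.category == "metastasis"]
        with pytest.raises(ConfigurationError):
            pairwise_concordance_filter(degs, norm, unmatched)


class TestRunDiscovery:
    def test_stage_monotonicity_and_audit_completeness(self, small_cohort):
        counts, samples, _, _ = small_cohort
        report = run_discovery(counts, samples)
        kept = [sc["n_kept"] for sc in report.stage_counts]
        assert all(a >= b for a, b in zip(kept, kept[1:]))
        for prev, nxt in zip(report.stage_counts, report.stage_counts[1:]):
            assert prev["n_kept"] == nxt["n_in"]
        initial = {d.gene_id for d in report.decisions if d.stage == "de"}
        removed = {d.gene_id for d in report.decisions if not d.kept}
        assert removed | set(report.final.index) == initial
        assert not (removed & set(report.final.index))
        # a removed gene has no decisions at later stages
        stage_order = {s: i for i, s in enumerate(["de", "tissue_per", "tissue_pooled", "bph", "pairwise"])}
        first_removal = {}
        for d in report.decisions:
            if not d.kept:
                first_removal.setdefault(d.gene_id, stage_order[d.stage])
        for d in report.decisions:
            if d.gene_id in first_removal:
                assert stage_order[d.stage] <= first_removal[d.gene_id]

    def test_gene_order_independence(self, small_cohort):
        counts, samples, _, _ = small_cohort
        ref = run_discovery(counts, samples)
        rng = np.random.default_rng(0)
        perm = rng.permutation(counts.shape[0])
        shuffled = CountMatrix(
            [counts.gene_ids[i] for i in perm],
            counts.sample_ids,
            counts.counts[perm],
        )
        alt = run_discovery(shuffled, samples)
        assert set(ref.final.index) == set(alt.final.index)

    def test_missing_controls_raise_before_computation(self):
        cfg = small_sim_config(seed=3)
        counts, samples, _, _ = simulate_cohort(cfg)
        tumor_only = [s for s in samples if s.category in ("primary", "metastasis")]
        sub = CountMatrix(
            counts.gene_ids,
            [s.sample_id for s in tumor_only],
            counts.counts[:, counts.sample_columns([s.sample_id for s in tumor_only])],
        )
        with pytest.raises(ConfigurationError):
            run_discovery(sub, tumor_only)
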