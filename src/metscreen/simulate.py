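"""Synthetic cohort generator emulating the autopsy-study design.

The generator reproduces the statistical structure the discovery cascade
is built for, without any controlled-access data:

* 25 patients with 82 metastases across five sites (liver 12, adrenal 7,
  bone 18, subdural 6, lymph node 39); six patients with matched
  primaries, one of whom has two primary tumors; in-cohort normal tissue
  from liver (14) and adrenal (2); external normal bone (14) and adrenal
  (3) controls; seven BPH prostate controls.
* counts ~ NB with mean L_s * 2^(b_g + u_patient + t_{g,tissue} +
  d_g * I[metastasis]) and per-gene dispersion alpha_g
  (var = mu + alpha * mu^2).  Patient effects u are shared between a
  patient's primary and metastases — the dominance of patient identity
  over sample origin that makes the pairwise filter informative.
* tissue effects t are nonzero only for planted tissue-specific genes in
  samples (normal or metastatic) from their tissue; planted
  metastasis effects d apply to every metastasis.
* TF peak sets with configurable per-gene hit probabilities inside
  regulatory windows, including AR tumor/normal and FOXA1/HOXB13 sets
  wired for co-occupancy.
* an independent prostatectomy-style survival cohort with exponential
  event times driven by planted prognostic genes and Cox covariates,
  under uniform independent censoring calibrated to a target fraction.

Same config and seed => byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .regulome import build_windows, regulatory_window
from .types import (
    CountMatrix,
    GeneAnnotation,
    GenomicInterval,
    PeakSet,
    SampleRecord,
    SurvivalRecord,
    ValidationError,
)

MET_SITE_DEFAULT = {"liver": 12, "adrenal": 7, "bone": 18, "subdural": 6, "lymph_node": 39}
NORMALS_DEFAULT = {"liver": 14, "adrenal": 5, "bone": 14}

ENRICHED_TFS = ("EZH2", "SUZ12", "TLE3", "TP63", "CBX7", "RNF2", "SP140", "JARID2", "CBX8")
NULL_TFS = ("CTCF", "MYC", "GATA2", "ETS1", "NKX3-1", "FOXO1")


@dataclass
class TFSimSpec:
    """Peak-placement rule for one simulated TF."""

    name: str
    p_target: float  # P(>= 1 peak in window) for genes of the target set
    p_background: float  # same for all other genes
    condition: str = "metacluster"

    def __post_init__(self) -> None:
        for p in (self.p_target, self.p_background):
            if not 0 <= p <= 1:
                raise ValidationError(f"TF {self.name}: probabilities must lie in [0, 1]")


@dataclass
class SimConfig:
    """Everything the generator needs; defaults emulate the study design."""

    n_genes: int = 10000
    n_patients: int = 25
    met_sites: dict[str, int] = field(default_factory=lambda: dict(MET_SITE_DEFAULT))
    n_matched_patients: int = 6          # patients with a primary; first has two
    n_normals: dict[str, int] = field(default_factory=lambda: dict(NORMALS_DEFAULT))
    n_bph: int = 7

    baseline_log2_mean: float = 4.0      # log2 mean expression across genes
    baseline_log2_sd: float = 2.0
    sigma_patient: float = 0.5           # patient random effect, log2 scale
    dispersion_log_mean: float = float(np.log(0.08))
    dispersion_log_sd: float = 0.4
    library_size_range: tuple[float, float] = (0.7, 1.4)

    n_met_up: int = 150
    n_met_down: int = 150
    met_log2fc: float = 1.5
    n_tissue_specific: dict[str, int] = field(
        default_factory=lambda: {"liver": 67, "adrenal": 66, "bone": 67}
    )
    tissue_log2fc: float = 5.0

    n_prognostic: int = 5
    prognostic_log_hr: float = float(np.log(2.0))
    n_survival_patients: int = 300
    censoring_fraction: float = 0.3
    baseline_hazard: float = float(np.log(2.0) / 40.0)  # median PFS ~40 months
    covariate_log_hr: dict[str, float] = field(
        default_factory=lambda: {
            "age_high": 0.4,
            "psa_intermediate": 0.2,
            "psa_high": 1.3,
            "gs_intermediate": 0.4,
            "gs_high": 0.8,
            "pt_high": 0.55,
        }
    )
    gleason_missing_rate: float = 0.05

    tf_specs: list[TFSimSpec] = field(default_factory=list)
    arbs_p_target: float = 0.55          # AR tumor peak rate on DEG windows
    arbs_p_background: float = 0.10
    ar_normal_p_target: float = 0.27
    co_occupancy_fraction: float = 0.30  # of AR-tumor-hit targets, FOXA1+HOXB13 co-bound
    peak_width: tuple[int, int] = (200, 400)

    allow_overlapping_planted_sets: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.censoring_fraction < 1:
            raise ValidationError("censoring_fraction must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be > 0")
        n_planted = self.n_met_up + self.n_met_down + sum(self.n_tissue_specific.values())
        if not self.allow_overlapping_planted_sets and n_planted + self.n_prognostic > self.n_genes:
            raise ValidationError(
                f"planted sets ({n_planted + self.n_prognostic}) exceed n_genes ({self.n_genes})"
            )
        if self.n_patients < 1 or (self.n_patients == 0 and not self.met_sites):
            raise ValidationError("empty sample design")
        if not self.tf_specs:
            self.tf_specs = [TFSimSpec(tf, 0.6, 0.05) for tf in ENRICHED_TFS] + [
                TFSimSpec(tf, 0.05, 0.05) for tf in NULL_TFS
            ]


@dataclass
class SimTruth:
    """Ground truth of every planted effect, for recovery testing."""

    met_up: list[str]
    met_down: list[str]
    tissue_specific: dict[str, tuple[str, int]]  # gene -> (tissue, direction)
    prognostic: dict[str, float]  # gene -> true log hazard ratio

    @property
    def met_degs(self) -> list[str]:
        return self.met_up + self.met_down

    def to_json(self, path: str | Path) -> None:
        data = {
            "met_up": self.met_up,
            "met_down": self.met_down,
            "tissue_specific": {g: list(v) for g, v in self.tissue_specific.items()},
            "prognostic": self.prognostic,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            met_up=d["met_up"],
            met_down=d["met_down"],
            tissue_specific={g: (t, int(s)) for g, (t, s) in d["tissue_specific"].items()},
            prognostic={g: float(v) for g, v in d["prognostic"].items()},
        )


# ------------------------------------------------------------- design

def _build_design(cfg: SimConfig) -> list[SampleRecord]:
    """Deterministic sample sheet mirroring the study layout."""
    records: list[SampleRecord] = []
    patients = [f"P{i + 1:02d}" for i in range(cfg.n_patients)]

    for i in range(cfg.n_matched_patients):
        n_prim = 2 if i == 0 else 1  # first matched patient has two primaries
        for k in range(n_prim):
            records.append(
                SampleRecord(f"{patients[i]}_pri{k + 1}", patients[i], "primary", "prostate")
            )
    site_stream = [site for site in cfg.met_sites for _ in range(cfg.met_sites[site])]
    per_patient_counter: dict[str, int] = {}
    for j, site in enumerate(site_stream):
        patient = patients[j % cfg.n_patients]
        per_patient_counter[patient] = per_patient_counter.get(patient, 0) + 1
        records.append(
            SampleRecord(
                f"{patient}_met{per_patient_counter[patient]}_{site}", patient, "metastasis", site
            )
        )
    # liver (and the first two adrenal) normals come from the autopsy
    # patients themselves; bone and extra adrenal normals stand in for
    # external public controls with their own patient effects
    in_cohort = {"liver": min(14, cfg.n_patients), "adrenal": 2}
    for tissue, n in sorted(cfg.n_normals.items()):
        shared = in_cohort.get(tissue, 0)
        for k in range(n):
            if k < shared and k < cfg.n_patients:
                patient = patients[k] if tissue == "liver" else patients[-(k + 1)]
            else:
                patient = f"N_{tissue}_{k + 1}"
            records.append(SampleRecord(f"norm_{tissue}_{k + 1}", patient, "normal", tissue))
    for k in range(cfg.n_bph):
        records.append(SampleRecord(f"bph_{k + 1}", f"BPH_{k + 1}", "bph", "prostate"))
    if not records:
        raise ValidationError("empty sample design")
    return records


def _build_annotation(cfg: SimConfig, rng: np.random.Generator) -> list[GeneAnnotation]:
    chroms = [f"chr{c}" for c in range(1, 23)]
    per_chrom = int(np.ceil(cfg.n_genes / len(chroms)))
    annotations = []
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    for i in range(cfg.n_genes):
        chrom = chroms[i // per_chrom]
        pos_in_chrom = i % per_chrom
        tss = 100_000 + pos_in_chrom * 50_000  # spacing >> window width: windows never collide
        annotations.append(
            GeneAnnotation(f"G{i + 1:05d}", chrom, str(strands[i]), tss)
        )
    return annotations


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[CountMatrix, list[SampleRecord], list[GeneAnnotation], SimTruth]:
    """Generate counts, sample sheet, annotation and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    samples = _build_design(cfg)
    annotations = _build_annotation(cfg, rng)
    gene_ids = [a.gene_id for a in annotations]
    n_genes, n_samples = cfg.n_genes, len(samples)

    perm = rng.permutation(n_genes)
    cursor = 0

    def take(n: int) -> list[int]:
        nonlocal cursor
        if cfg.allow_overlapping_planted_sets:
            return list(rng.choice(n_genes, size=n, replace=False))
        out = list(perm[cursor:cursor + n])
        cursor += n
        return out

    met_up_idx = take(cfg.n_met_up)
    met_down_idx = take(cfg.n_met_down)
    tissue_idx: dict[str, list[int]] = {t: take(n) for t, n in sorted(cfg.n_tissue_specific.items())}

    # prognostic effects live in the separate prostatectomy-style cohort
    # (simulate_prognostic_cohort); the autopsy cohort truth lists none
    truth = SimTruth(
        met_up=[gene_ids[i] for i in met_up_idx],
        met_down=[gene_ids[i] for i in met_down_idx],
        tissue_specific={
            gene_ids[i]: (t, 1) for t, idxs in tissue_idx.items() for i in idxs
        },
        prognostic={},
    )

    b = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n_genes)
    alpha = np.exp(rng.normal(cfg.dispersion_log_mean, cfg.dispersion_log_sd, size=n_genes))
    patient_ids = sorted({s.patient_id for s in samples})
    u = dict(zip(patient_ids, rng.normal(0.0, cfg.sigma_patient, size=len(patient_ids))))
    lo, hi = cfg.library_size_range
    lib = rng.uniform(lo, hi, size=n_samples)

    log2_mu = np.tile(b[:, None], (1, n_samples))
    for j, s in enumerate(samples):
        log2_mu[:, j] += u[s.patient_id]
        if s.category == "metastasis":
            log2_mu[met_up_idx, j] += cfg.met_log2fc
            log2_mu[met_down_idx, j] -= cfg.met_log2fc
        if s.tissue in tissue_idx:
            log2_mu[tissue_idx[s.tissue], j] += cfg.tissue_log2fc
    mu = lib[None, :] * np.exp2(log2_mu)

    # gamma-poisson mixture: var = mu + alpha mu^2
    lam = rng.gamma(shape=1.0 / alpha[:, None], scale=mu * alpha[:, None])
    counts = rng.poisson(lam)
    matrix = CountMatrix(gene_ids, [s.sample_id for s in samples], counts)
    return matrix, samples, annotations, truth


# ------------------------------------------------------------- peaks

def _place_peak(
    window_start: int, window_end: int, width: int, rng: np.random.Generator
) -> GenomicInterval:
    """One peak inside (or straddling by at most its width) the window."""
    lo = max(1, window_start - width + 1)
    start = int(rng.integers(lo, window_end + 1))
    return GenomicInterval("", start, start + width - 1)  # chrom filled by caller


def simulate_peaks(
    annotations: list[GeneAnnotation],
    truth: SimTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    target_genes: list[str] | None = None,
    upstream: int = 15000,
    downstream: int = 2000,
) -> list[PeakSet]:
    """Peak sets for the configured TFs plus the AR/FOXA1/HOXB13 quartet.

    Each gene's regulatory window receives >= 1 peak with probability
    ``p_target`` if the gene belongs to the TF's target set (default: the
    planted metastasis DEGs) and ``p_background`` otherwise.  The AR
    tumor set additionally drives FOXA1/HOXB13 co-occupancy: a configured
    fraction of AR-hit target genes get FOXA1 and HOXB13 peaks overlapping
    the AR peak itself.
    """
    if not annotations:
        raise ValidationError("simulate_peaks needs a nonempty annotation")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    targets = set(target_genes if target_genes is not None else truth.met_degs)
    windows = {a.gene_id: regulatory_window(a, upstream, downstream) for a in annotations}
    wmin, wmax = cfg.peak_width

    def bernoulli_peaks(p_target: float, p_background: float) -> dict[str, GenomicInterval]:
        out = {}
        for a in annotations:
            p = p_target if a.gene_id in targets else p_background
            if rng.random() < p:
                w = windows[a.gene_id].interval
                width = int(rng.integers(wmin, wmax + 1))
                pk = _place_peak(w.start, w.end, width, rng)
                out[a.gene_id] = GenomicInterval(a.chrom, pk.start, pk.end)
        return out

    peak_sets = []
    for spec in cfg.tf_specs:
        hits = bernoulli_peaks(spec.p_target, spec.p_background)
        peak_sets.append(
            PeakSet(spec.name, spec.condition, [hits[g] for g in sorted(hits)])
        )

    ar_hits = bernoulli_peaks(cfg.arbs_p_target, cfg.arbs_p_background)
    ar_normal_hits = bernoulli_peaks(cfg.ar_normal_p_target, cfg.arbs_p_background)
    foxa1: list[GenomicInterval] = []
    hoxb13: list[GenomicInterval] = []
    for g in sorted(ar_hits):
        pk = ar_hits[g]
        co = g in targets and rng.random() < cfg.co_occupancy_fraction
        if co:
            for out in (foxa1, hoxb13):
                shift = int(rng.integers(-100, 101))
                width = int(rng.integers(wmin, wmax + 1))
                start = max(1, pk.start + shift)
                out.append(GenomicInterval(pk.chrom, start, start + width - 1))
    peak_sets.append(PeakSet("AR", "tumor", [ar_hits[g] for g in sorted(ar_hits)]))
    peak_sets.append(PeakSet("AR", "normal", [ar_normal_hits[g] for g in sorted(ar_normal_hits)]))
    peak_sets.append(PeakSet("FOXA1", "tumor", foxa1))
    peak_sets.append(PeakSet("HOXB13", "tumor", hoxb13))
    return peak_sets


# ------------------------------------------------------------- survival

def _draw_covariates(n: int, cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    age = np.round(rng.normal(62.0, 7.0, size=n), 1)
    psa = np.round(np.exp(rng.normal(np.log(9.0), 0.7, size=n)), 2)
    gleason = rng.choice([6, 7, 8, 9], size=n, p=[0.35, 0.40, 0.15, 0.10])
    pt = rng.choice(["pT2a", "pT2b", "pT3a", "pT3b"], size=n, p=[0.25, 0.30, 0.30, 0.15])
    return pd.DataFrame({"age": age, "psa": psa, "gleason": gleason, "pt_stage": pt})


def _covariate_lp(cov: pd.DataFrame, cfg: SimConfig) -> np.ndarray:
    g = cfg.covariate_log_hr
    return (
        g["age_high"] * (cov["age"] > 62).to_numpy()
        + g["psa_intermediate"] * ((cov["psa"] > 10) & (cov["psa"] < 20)).to_numpy()
        + g["psa_high"] * (cov["psa"] >= 20).to_numpy()
        + g["gs_intermediate"] * (cov["gleason"] == 7).to_numpy()
        + g["gs_high"] * (cov["gleason"] > 7).to_numpy()
        + g["pt_high"] * cov["pt_stage"].isin(["pT3a", "pT3b"]).to_numpy()
    )


def simulate_survival(
    expression_labels: pd.Series | pd.DataFrame,
    log_hr: float | np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    include_covariate_effects: bool = True,
) -> list[SurvivalRecord]:
    """Exponential survival driven by high/low labels and clinical covariates.

    ``expression_labels`` is a Series of {'high','low'} per sample (one
    gene) or a samples x genes DataFrame of such labels, with ``log_hr``
    scalar or per-gene.  Event times are Exponential(h0 * exp(lp));
    censoring times are Uniform(0, tau) with tau calibrated so the
    expected censored fraction matches ``cfg.censoring_fraction``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    if isinstance(expression_labels, pd.Series):
        indicator = (expression_labels == "high").to_numpy(float)[:, None]
        betas = np.array([float(log_hr)])
        index = expression_labels.index
    else:
        indicator = (expression_labels == "high").to_numpy(float)
        betas = np.broadcast_to(np.asarray(log_hr, dtype=float), (indicator.shape[1],))
        index = expression_labels.index
    n = indicator.shape[0]
    cov = _draw_covariates(n, cfg, rng)
    lp = indicator @ betas
    if include_covariate_effects:
        lp = lp + _covariate_lp(cov, cfg)
    rates = cfg.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rates)

    if cfg.censoring_fraction == 0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        def censored_fraction(tau: float) -> float:
            x = rates * tau
            return float(np.mean((1.0 - np.exp(-x)) / x))

        target = cfg.censoring_fraction
        tau = brentq(lambda t: censored_fraction(t) - target, 1e-9, 1e9, xtol=1e-9)
        c = rng.uniform(0.0, tau, size=n)
        event = (t_event <= c).astype(int)
        time = np.minimum(t_event, c)
    time = np.maximum(time, 1e-6)

    gleason_vals: list[int | None] = list(cov["gleason"])
    if cfg.gleason_missing_rate > 0:
        miss = rng.random(n) < cfg.gleason_missing_rate
        gleason_vals = [None if m else int(g) for g, m in zip(gleason_vals, miss)]
    else:
        gleason_vals = [int(g) for g in gleason_vals]

    return [
        SurvivalRecord(
            sample_id=str(index[i]),
            time=float(time[i]),
            event=int(event[i]),
            age=float(cov["age"][i]),
            psa=float(cov["psa"][i]),
            gleason=gleason_vals[i],
            pt_stage=str(cov["pt_stage"][i]),
        )
        for i in range(n)
    ]


def simulate_prognostic_cohort(
    cfg: SimConfig,
    n_genes: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[SurvivalRecord], list[str]]:
    """Expression matrix + survival for a prostatectomy-style cohort.

    Returns (genes x samples log-normal expression, survival records,
    planted prognostic gene ids).  Survival depends on the planted genes
    through their Q3 high/low indicator at the true log hazard ratio.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 3)
    n = cfg.n_survival_patients
    gene_ids = [f"PG{i + 1:04d}" for i in range(n_genes)]
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    base = rng.normal(6.0, 1.5, size=n_genes)
    expr = np.exp2(base[:, None] + rng.normal(0.0, 1.0, size=(n_genes, n)))
    expression = pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)

    planted = list(rng.choice(gene_ids, size=cfg.n_prognostic, replace=False))
    labels = pd.DataFrame(index=pd.Index(sample_ids), columns=planted, dtype=object)
    for g in planted:
        v = expression.loc[g].to_numpy()
        q3 = np.quantile(v, 0.75)
        labels[g] = np.where(v > q3, "high", "low")
    records = simulate_survival(labels, cfg.prognostic_log_hr, cfg, rng=rng)
    return expression, records, planted


def write_cohort(outdir: str | Path, cfg: SimConfig) -> None:
    """Run the full generator and write every artifact into ``outdir``."""
    from . import io as msio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "peaks").mkdir(exist_ok=True)
    matrix, samples, annotations, truth = simulate_cohort(cfg)
    msio.write_counts(matrix, outdir / "counts.tsv")
    msio.write_samples(samples, outdir / "samples.tsv")
    msio.write_annotation(annotations, outdir / "genes.tsv")
    for ps in simulate_peaks(annotations, truth, cfg):
        name = ps.tf_name if ps.condition in ("metacluster", "tumor") else f"{ps.tf_name}_{ps.condition}"
        if ps.tf_name in ("AR",):
            name = f"AR_{ps.condition}"
        msio.write_bed_peaks(ps, outdir / "peaks" / f"{name}.bed")
    expression, records, planted = simulate_prognostic_cohort(cfg)
    expression.round(4).to_csv(outdir / "expression.tsv", sep="\t", lineterminator="\n", float_format="%.10g")
    msio.write_survival(records, outdir / "survival.tsv")
    truth.prognostic = {g: cfg.prognostic_log_hr for g in planted}
    truth.to_json(outdir / "truth.json")
    with open(outdir / "sim_config.json", "w", encoding="utf-8") as fh:
        json.dump(
            {k: v for k, v in dataclasses.asdict(cfg).items() if not isinstance(v, list) or k != "tf_specs"},
            fh, indent=2, sort_keys=True, default=str,
        )
        fh.write("\n")
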