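"""Negative-binomial Wald differential expression for two-group contrasts.

The engine mirrors the classical count-based DE recipe: median-of-ratios
size factors, per-gene NB dispersion by method of moments, a two-group
log-link NB GLM with the size factor as offset, a Wald test on the group
coefficient, and Benjamini–Hochberg adjustment.  Deliberately omitted
relative to heavier DE packages: dispersion shrinkage, independent
filtering and fold-change shrinkage — the pipeline's filtering logic, not
the estimator refinements, is what this package exists for.

All genes are fit simultaneously: the IRLS normal equations for a
two-parameter design collapse to per-gene 2x2 solves, vectorized across
the gene axis, which keeps genome-wide contrasts in the tens of
milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm as _normal

from .types import CountMatrix, NormalizationError, ValidationError

ALPHA_MIN = 1e-8  # dispersion floor: Poisson-like and degenerate genes
_LN2 = np.log(2.0)

STATUS_TESTED = "tested"
STATUS_ALL_ZERO = "all_zero"
STATUS_FAILED = "failed_fit"


@dataclass(frozen=True)
class Contrast:
    """Two disjoint sample groups; fold changes are numerator over denominator."""

    numerator: tuple[str, ...]
    denominator: tuple[str, ...]
    allow_single: bool = False

    def __init__(self, numerator, denominator, allow_single: bool = False) -> None:
        object.__setattr__(self, "numerator", tuple(numerator))
        object.__setattr__(self, "denominator", tuple(denominator))
        object.__setattr__(self, "allow_single", bool(allow_single))
        if not self.numerator or not self.denominator:
            raise ValidationError("contrast groups must be nonempty")
        if set(self.numerator) & set(self.denominator):
            raise ValidationError("contrast groups must be disjoint")
        min_n = 1 if allow_single else 2
        if len(self.numerator) < min_n or len(self.denominator) < min_n:
            raise ValidationError(
                "each contrast side needs >= 2 samples for dispersion "
                "estimation (pass allow_single=True to override)"
            )

    def swapped(self) -> "Contrast":
        return Contrast(self.denominator, self.numerator, self.allow_single)


def size_factors(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (one per sample).

    The reference is the per-gene geometric mean over samples, restricted
    to genes with no zero count; the factor for sample *s* is the median
    over those genes of count/reference.
    """
    arr = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    if arr.ndim != 2 or arr.shape[1] == 0:
        raise ValidationError("size_factors needs a 2-D genes x samples matrix")
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no gene has nonzero counts in every sample; "
            "median-of-ratios normalization is undefined"
        )
    ref = arr[positive].astype(float)
    geomean = np.exp(np.log(ref).mean(axis=1, keepdims=True))
    return np.median(ref / geomean, axis=0)


def estimate_dispersion(
    norm_counts: np.ndarray, groups: list[np.ndarray], alpha_min: float = ALPHA_MIN
) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion from normalized counts.

    Under var = mu + alpha * mu^2, alpha is estimated as
    (pooled within-group variance - mean) / mean^2, floored at
    ``alpha_min``; genes whose counts look Poisson or constant sit on the
    floor.
    """
    norm_counts = np.asarray(norm_counts, dtype=float)
    if norm_counts.ndim == 1:
        norm_counts = norm_counts[None, :]
    cols = np.concatenate(groups)
    n_total = len(cols)
    n_groups = sum(1 for g in groups if len(g) > 0)
    if n_total - n_groups < 1:
        raise ValidationError("dispersion estimation needs >= 2 samples in some group")
    ss = np.zeros(norm_counts.shape[0])
    for g in groups:
        if len(g) == 0:
            continue
        sub = norm_counts[:, g]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    var = ss / (n_total - n_groups)
    mean = norm_counts[:, cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mean) / mean**2
    alpha[~np.isfinite(alpha)] = alpha_min
    return np.maximum(alpha, alpha_min)


def _nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene NB deviance, summed over samples (rows are genes)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
        inv_a = 1.0 / alpha
        term2 = (y + inv_a) * np.log((1.0 + alpha * y) / (1.0 + alpha * mu))
    return 2.0 * (term1 - term2).sum(axis=1)


def _irls_two_group(
    y: np.ndarray,
    x: np.ndarray,
    log_sf: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for mu = sf * exp(b0 + b1 * x) with NB variance.

    ``x`` is the symmetric group coding (+1/2 numerator, -1/2
    denominator), so swapping the groups negates b1 exactly.  Returns
    (b0, b1, se_b1, converged).
    """
    n_genes = y.shape[0]
    alpha = alpha[:, None]
    # moment start: overall normalized mean, zero group effect
    base = np.log(np.maximum((y / np.exp(log_sf)).mean(axis=1), 1e-8))
    b0 = base.copy()
    b1 = np.zeros(n_genes)
    eta_lin = b0[:, None] + b1[:, None] * x
    mu = np.exp(np.clip(eta_lin + log_sf, -50.0, 50.0))
    dev = _nb_deviance(y, mu, alpha)
    converged = np.zeros(n_genes, dtype=bool)
    active = np.ones(n_genes, dtype=bool)
    for _ in range(max_iter):
        w = mu / (1.0 + alpha * mu)
        z = eta_lin + (y - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * x).sum(axis=1)
        swxx = (w * x * x).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * x * z).sum(axis=1)
        det = sw * swxx - swx * swx
        ok = det > 0
        new_b1 = np.where(ok, (sw * swxz - swx * swz) / np.where(det > 0, det, 1.0), b1)
        new_b0 = np.where(ok, (swz - swx * new_b1) / np.where(sw > 0, sw, 1.0), b0)
        upd = active & ok
        step = np.abs(new_b0 - b0) + np.abs(new_b1 - b1)
        b0 = np.where(upd, new_b0, b0)
        b1 = np.where(upd, np.clip(new_b1, -50.0, 50.0), b1)
        eta_lin = b0[:, None] + b1[:, None] * x
        mu = np.exp(np.clip(eta_lin + log_sf, -50.0, 50.0))
        new_dev = _nb_deviance(y, mu, alpha)
        delta = np.abs(new_dev - dev)
        just_conv = active & ((delta < tol) | (step < 1e-13))
        converged |= just_conv
        active &= ~just_conv
        dev = new_dev
        if not active.any():
            break
    # observed-information SE from the final weights
    w = mu / (1.0 + alpha * mu)
    sw = w.sum(axis=1)
    swx = (w * x).sum(axis=1)
    swxx = (w * x * x).sum(axis=1)
    det = sw * swxx - swx * swx
    with np.errstate(divide="ignore", invalid="ignore"):
        se_b1 = np.sqrt(np.where(det > 0, sw / det, np.nan))
    return b0, b1, se_b1, converged


def nb_wald_test(
    counts: CountMatrix,
    contrast: Contrast,
    sf: np.ndarray | None = None,
    dispersions: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Two-group NB Wald test for every gene.

    Returns a DataFrame indexed by gene_id with columns base_mean, log2fc,
    se, p, adj_p, status.  Fold changes are numerator over denominator in
    log2; ``p`` is the two-sided Wald p-value; BH adjustment runs over
    tested genes only.  All-zero genes get status ``all_zero``; fits that
    fail to converge get ``failed_fit`` — neither aborts the run.
    """
    num_idx = counts.sample_columns(contrast.numerator)
    den_idx = counts.sample_columns(contrast.denominator)
    cols = np.concatenate([den_idx, num_idx])
    y = counts.counts[:, cols].astype(float)
    x = np.concatenate([np.full(len(den_idx), -0.5), np.full(len(num_idx), 0.5)])

    if sf is None:
        sf = size_factors(counts.counts[:, cols])
    else:
        sf = np.asarray(sf, dtype=float)[cols] if len(sf) == counts.shape[1] else np.asarray(sf, dtype=float)
    if sf.shape != (len(cols),):
        raise ValidationError("size factor vector does not match contrast samples")
    log_sf = np.log(sf)[None, :]
    norm_y = y / sf

    groups = [np.arange(len(den_idx)), np.arange(len(den_idx), len(cols))]
    if dispersions is None:
        dispersions = estimate_dispersion(norm_y, groups)
    else:
        dispersions = np.asarray(dispersions, dtype=float)

    all_zero = (y == 0).all(axis=1)
    testable = ~all_zero

    b0 = np.full(counts.shape[0], np.nan)
    b1 = np.full(counts.shape[0], np.nan)
    se = np.full(counts.shape[0], np.nan)
    conv = np.zeros(counts.shape[0], dtype=bool)
    if testable.any():
        r_b0, r_b1, r_se, r_conv = _irls_two_group(
            y[testable], x, log_sf, dispersions[testable], max_iter=max_iter, tol=tol
        )
        b0[testable], b1[testable], se[testable], conv[testable] = r_b0, r_b1, r_se, r_conv

    status = np.where(all_zero, STATUS_ALL_ZERO, np.where(conv & np.isfinite(se), STATUS_TESTED, STATUS_FAILED))
    tested = status == STATUS_TESTED

    p = np.full(counts.shape[0], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(b1[tested] / se[tested])
    p[tested] = 2.0 * _normal.sf(z)
    adj_p = np.full(counts.shape[0], np.nan)
    if tested.any():
        adj_p[tested] = bh_adjust(p[tested])

    return pd.DataFrame(
        {
            "base_mean": norm_y.mean(axis=1),
            "log2fc": b1 / _LN2,
            "se": se / _LN2,
            "p": p,
            "adj_p": adj_p,
            "status": status,
        },
        index=pd.Index(counts.gene_ids, name="gene_id"),
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving.

    adj_(i) = min_{j >= i} m * p_(j) / j, capped at 1, mapped back to the
    input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = m * p[order] / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


@dataclass
class DEGCall:
    """Genes passing the DE threshold for one contrast, split by direction."""

    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return self.up + self.down

    def direction(self, gene_id: str) -> int:
        if gene_id in set(self.up):
            return 1
        if gene_id in set(self.down):
            return -1
        raise KeyError(gene_id)


def call_degs(results: pd.DataFrame, alpha: float, strict: bool = False) -> DEGCall:
    """Partition significant genes into up/down by the sign of log2fc.

    ``strict=False`` uses adj_p <= alpha (the permissive discovery call);
    ``strict=True`` uses adj_p < alpha.
    """
    tested = results[results["status"] == STATUS_TESTED]
    sig = tested[tested["adj_p"] < alpha] if strict else tested[tested["adj_p"] <= alpha]
    zero_fc = sig[sig["log2fc"] == 0.0]
    if not zero_fc.empty:
        # Wald p = 1 whenever b1 = 0; a significant zero fold change is impossible
        raise ValidationError(
            f"significant gene(s) with zero fold change: {list(zero_fc.index[:3])}"
        )
    return DEGCall(
        up=list(sig.index[sig["log2fc"] > 0]),
        down=list(sig.index[sig["log2fc"] < 0]),
    )
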