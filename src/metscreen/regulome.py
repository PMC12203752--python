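"""Regulatory windows around the TSS, peak overlap, and TF enrichment.

A gene's regulatory window spans 15 kb upstream to 2 kb downstream of
the TSS by default, strand-aware, clamped at position 1.  A peak hits a
window when they share at least one base pair.  Enrichment of a TF's
binding sites in the windows of a DEG set versus a background gene
universe is tested with a one-tailed (greater) Fisher exact test and BH
adjustment across TFs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .diffexp import bh_adjust
from .types import (
    ConfigurationError,
    GeneAnnotation,
    GenomicInterval,
    PeakSet,
    ValidationError,
)


@dataclass(frozen=True)
class RegulatoryWindow:
    gene_id: str
    interval: GenomicInterval


def regulatory_window(
    gene: GeneAnnotation, upstream: int = 15000, downstream: int = 2000
) -> RegulatoryWindow:
    """Strand-aware TSS window: [tss-upstream, tss+downstream] on '+',
    mirrored on '-', clamped so start >= 1."""
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    return RegulatoryWindow(gene.gene_id, GenomicInterval(gene.chrom, max(start, 1), end))


def build_windows(
    annotations: list[GeneAnnotation], upstream: int = 15000, downstream: int = 2000
) -> list[RegulatoryWindow]:
    return [regulatory_window(a, upstream, downstream) for a in annotations]


def _windows_by_chrom(windows: list[RegulatoryWindow]):
    out: dict[str, list[tuple[int, int, int]]] = {}
    for i, w in enumerate(windows):
        out.setdefault(w.interval.chrom, []).append((w.interval.start, w.interval.end, i))
    return out


def count_overlaps(windows: list[RegulatoryWindow], peaks: PeakSet) -> pd.DataFrame:
    """Number of peaks overlapping each window (>= 1 bp, 1-based inclusive).

    Two inclusive intervals overlap iff max(starts) <= min(ends).  Counts
    use the identity  #overlaps = #(peak_start <= win_end) - #(peak_end <
    win_start)  on per-chromosome sorted coordinate arrays, because every
    peak ending before the window starts also starts before the window
    ends.
    """
    starts_by_chrom: dict[str, np.ndarray] = {}
    ends_by_chrom: dict[str, np.ndarray] = {}
    for chrom in {iv.chrom for iv in peaks.intervals}:
        ivs = [iv for iv in peaks.intervals if iv.chrom == chrom]
        starts_by_chrom[chrom] = np.sort(np.array([iv.start for iv in ivs]))
        ends_by_chrom[chrom] = np.sort(np.array([iv.end for iv in ivs]))
    counts = np.zeros(len(windows), dtype=int)
    for chrom, triples in _windows_by_chrom(windows).items():
        if chrom not in starts_by_chrom:
            continue
        s = starts_by_chrom[chrom]
        e = ends_by_chrom[chrom]
        w_start = np.array([t[0] for t in triples])
        w_end = np.array([t[1] for t in triples])
        idx = np.array([t[2] for t in triples])
        n_start_before = np.searchsorted(s, w_end, side="right")
        n_end_before = np.searchsorted(e, w_start, side="left")
        counts[idx] = n_start_before - n_end_before
    return pd.DataFrame(
        {"count": counts, "present": counts >= 1},
        index=pd.Index([w.gene_id for w in windows], name="gene_id"),
    )


def fisher_one_tailed(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Odds ratio and one-tailed (greater) Fisher exact p for the table
    [[a, b], [c, d]]."""
    odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)


def tf_enrichment(
    deg_ids: list[str],
    windows: list[RegulatoryWindow],
    peaks_by_tf: dict[str, PeakSet] | list[PeakSet],
    alpha: float = 0.15,
    background_includes_degs: bool = False,
) -> pd.DataFrame:
    """Per-TF binding-site enrichment in DEG windows versus the gene universe.

    The 2x2 table per TF is (DEGs with >= 1 site, DEGs without) against
    (background genes with >= 1 site, background without).  By default
    the background excludes the DEGs so the table cells are disjoint; the
    inclusive background (every annotated gene, DEGs double-counted) is
    available for sensitivity analysis via ``background_includes_degs``.
    """
    if isinstance(peaks_by_tf, list):
        peaks_by_tf = {p.tf_name: p for p in peaks_by_tf}
    if not peaks_by_tf:
        raise ValidationError("tf_enrichment needs >= 1 TF peak set")
    deg_set = set(deg_ids)
    if not deg_set:
        raise ValidationError("tf_enrichment needs a nonempty DEG set")
    universe = {w.gene_id for w in windows}
    missing = deg_set - universe
    if missing:
        raise ValidationError(f"DEGs absent from the gene universe: {sorted(missing)[:5]}")

    gene_ids = [w.gene_id for w in windows]
    is_deg = np.array([g in deg_set for g in gene_ids])
    rows = []
    for tf in sorted(peaks_by_tf):
        present = count_overlaps(windows, peaks_by_tf[tf])["present"].to_numpy()
        a = int((present & is_deg).sum())
        b = int((~present & is_deg).sum())
        if background_includes_degs:
            c, d = int(present.sum()), int((~present).sum())
        else:
            c = int((present & ~is_deg).sum())
            d = int((~present & ~is_deg).sum())
        odds, p = fisher_one_tailed(a, b, c, d)
        rows.append({"tf_name": tf, "a": a, "b": b, "c": c, "d": d, "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows).set_index("tf_name")
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["enriched"] = out["adj_p"] < alpha
    return out


def _overlap_flags(queries: list[GenomicInterval], peaks: PeakSet) -> np.ndarray:
    """present flag per query interval, via count_overlaps plumbing."""
    ws = [RegulatoryWindow(str(i), iv) for i, iv in enumerate(queries)]
    return count_overlaps(ws, peaks)["present"].to_numpy()


def annotate_arbs(
    deg_windows: list[RegulatoryWindow],
    ar_tumor: PeakSet,
    ar_normal: PeakSet,
    foxa1: PeakSet,
    hoxb13: PeakSet,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-DEG AR binding-site flags and FOXA1/HOXB13 co-occupancy.

    ``co_occupied`` is peak-level: some tumor AR peak overlapping the
    gene's window itself overlaps (>= 1 bp) both a FOXA1 and a HOXB13
    peak.  A FOXA1 site elsewhere in the window does not count.
    """
    for name, ps in (("ar_tumor", ar_tumor), ("ar_normal", ar_normal), ("foxa1", foxa1), ("hoxb13", hoxb13)):
        if ps is None:
            raise ConfigurationError(f"missing peak set: {name}")

    ar_peaks = ar_tumor.intervals
    ar_hits_foxa1 = _overlap_flags(ar_peaks, foxa1) if ar_peaks else np.zeros(0, dtype=bool)
    ar_hits_hoxb13 = _overlap_flags(ar_peaks, hoxb13) if ar_peaks else np.zeros(0, dtype=bool)
    co_peak = ar_hits_foxa1 & ar_hits_hoxb13

    has_tumor = _overlap_flags([w.interval for w in deg_windows], ar_tumor)
    has_normal = _overlap_flags([w.interval for w in deg_windows], ar_normal)

    co_occupied = np.zeros(len(deg_windows), dtype=bool)
    for i, w in enumerate(deg_windows):
        if not has_tumor[i]:
            continue
        co_occupied[i] = any(
            co_peak[j]
            for j, pk in enumerate(ar_peaks)
            if pk.overlaps(w.interval)
        )

    flags = pd.DataFrame(
        {
            "has_tumor_arbs": has_tumor,
            "has_normal_arbs": has_normal,
            "co_occupied": co_occupied,
        },
        index=pd.Index([w.gene_id for w in deg_windows], name="gene_id"),
    )
    summary = {
        "n_tumor_arbs": int(has_tumor.sum()),
        "n_normal_arbs": int(has_normal.sum()),
        "n_co_occupied": int(co_occupied.sum()),
    }
    return flags, summary
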