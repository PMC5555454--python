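"""Per-SNP differentiation along the genome.

Three per-marker statistics over two or more predefined groups:

* Weir & Cockerham's theta — the variance-components F_ST estimator, from
  the a (between-population), b (between-individual) and c (within-
  individual) components;
* Nei's G_ST = (H_T - H_S) / H_T with unweighted group means;
* Jost's D = [(H_T - H_S) / (1 - H_S)] * k/(k-1), which unlike F_ST is not
  bounded by within-group heterozygosity.

The scan orders markers by consensus-map position (Manhattan coordinate =
cM offset by cumulative linkage-group lengths), the multilocus F_ST is the
ratio-of-sums estimator sum(a) / sum(a+b+c), and outliers are flagged by
empirical quantile — an explicitly model-free stand-in for Bayesian
outlier machinery.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .gio import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "group_counts",
    "wc_fst_components",
    "wc_fst",
    "nei_gst",
    "jost_d",
    "scan",
    "mean_multilocus_fst",
    "anova_fst_by_lg",
    "empirical_outliers",
]


def group_counts(genotypes: GenotypeMatrix, groups: pd.Series, labels=None):
    """Per-marker, per-group sample sizes, ALT frequencies and observed het fractions.

    Returns ``(labels, n, p, h)`` with arrays of shape (n_markers, n_groups);
    ``n`` counts called diploid individuals, and ``p``/``h`` are NaN where a
    group has no calls at the marker.
    """
    labels = list(labels) if labels is not None else sorted(groups.unique())
    m = genotypes.n_markers
    n = np.zeros((m, len(labels)))
    p = np.full((m, len(labels)), np.nan)
    h = np.full((m, len(labels)), np.nan)
    for k, lab in enumerate(labels):
        members = list(groups.index[groups == lab])
        if not members:
            raise ValueError(f"group {lab!r} has no accessions")
        d = genotypes.dosage[genotypes.accession_indices(members)]
        called = ~np.isnan(d)
        nk = called.sum(axis=0)
        n[:, k] = nk
        ok = nk > 0
        with np.errstate(invalid="ignore"):
            p[ok, k] = np.nansum(d, axis=0)[ok] / (2.0 * nk[ok])
            h[ok, k] = (d == 1).sum(axis=0)[ok] / nk[ok]
    return labels, n, p, h


def _as_2d(n, p, h):
    n = np.atleast_2d(np.asarray(n, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    h = np.atleast_2d(np.asarray(h, dtype=float))
    return n, p, h


def wc_fst_components(n, p, h):
    """Weir–Cockerham variance components (a, b, c) per marker.

    ``n, p, h`` have shape (n_markers, n_groups) (or (n_groups,) for one
    marker); groups with no calls at a marker are dropped for that marker.
    Markers with fewer than two usable groups, or mean sample size <= 1,
    return NaN components.
    """
    n, p, h = _as_2d(n, p, h)
    use = (n >= 1) & ~np.isnan(p)
    nu = np.where(use, n, 0.0)
    pu = np.where(use, p, 0.0)
    hu = np.where(use, np.where(np.isnan(h), 0.0, h), 0.0)
    r = use.sum(axis=1).astype(float)
    n_tot = nu.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_tot / r
        nc = (n_tot - (nu**2).sum(axis=1) / n_tot) / (r - 1.0)
        pbar = (nu * pu).sum(axis=1) / n_tot
        s2 = (nu * (pu - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1.0) * nbar)
        hbar = (nu * hu).sum(axis=1) / n_tot
        inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    bad = (r < 2) | (nbar <= 1.0) | ~np.isfinite(nc) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def wc_fst(n, p, h):
    """Per-marker Weir–Cockerham theta = a / (a + b + c); NaN where undefined."""
    a, b, c = wc_fst_components(n, p, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)
    theta = np.asarray(theta)
    return float(theta[0]) if theta.size == 1 else theta


def _hs_ht(p, valid):
    """Unweighted H_S and H_T over usable groups per marker."""
    pu = np.where(valid, p, np.nan)
    with np.errstate(invalid="ignore"):
        hs = np.nanmean(2.0 * pu * (1.0 - pu), axis=1)
        pbar = np.nanmean(pu, axis=1)
    ht = 2.0 * pbar * (1.0 - pbar)
    k = valid.sum(axis=1).astype(float)
    hs[k < 2] = np.nan
    ht[k < 2] = np.nan
    return hs, ht, k


def nei_gst(n, p, h=None):
    """Nei's G_ST = (H_T - H_S)/H_T with unweighted group means; NaN where H_T = 0."""
    n, p, _ = _as_2d(n, p, p if h is None else h)
    valid = (n >= 1) & ~np.isnan(p)
    hs, ht, _ = _hs_ht(p, valid)
    with np.errstate(invalid="ignore", divide="ignore"):
        gst = np.where(ht > 0, (ht - hs) / ht, np.nan)
    gst = np.asarray(gst)
    return float(gst[0]) if gst.size == 1 else gst


def jost_d(n, p, h=None):
    """Jost's D = [(H_T - H_S)/(1 - H_S)] * k/(k-1); NaN where H_S = 1 or H_T = 0."""
    n, p, _ = _as_2d(n, p, p if h is None else h)
    valid = (n >= 1) & ~np.isnan(p)
    hs, ht, k = _hs_ht(p, valid)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where((hs < 1.0) & (ht > 0), (ht - hs) / (1.0 - hs) * k / (k - 1.0), np.nan)
    d = np.asarray(d)
    return float(d[0]) if d.size == 1 else d


def _cumulative_positions(marker_map: pd.DataFrame, gap_cM: float = 5.0) -> pd.DataFrame:
    mm = marker_map.sort_values(["linkage_group", "cM"]).copy()
    offset = 0.0
    offsets = {}
    for lg, sub in mm.groupby("linkage_group", sort=True):
        offsets[lg] = offset
        offset += float(sub["cM"].max()) + gap_cM
    mm["cum_pos"] = mm["cM"] + mm["linkage_group"].map(offsets)
    return mm


def scan(
    genotypes: GenotypeMatrix,
    groups: pd.Series,
    marker_map: pd.DataFrame,
    group_labels=None,
) -> pd.DataFrame:
    """Genome-wide per-SNP differentiation scan, Manhattan-ordered by map position.

    Columns: marker, linkage_group, cM, cum_pos, n_groups_used, fst_wc, gst,
    jost_d and per-group He.  Markers monomorphic across all used groups are
    excluded (count logged); unmapped markers are dropped with a log line.
    """
    labels, n, p, h = group_counts(genotypes, groups, group_labels)
    if len(labels) < 2:
        raise ValueError("need at least two groups for a differentiation scan")
    a, b, c = wc_fst_components(n, p, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)
    gst = nei_gst(n, p, h)
    d = jost_d(n, p, h)
    valid = (n >= 1) & ~np.isnan(p)
    pbar = np.where(valid, p, np.nan)
    df = pd.DataFrame({"marker": genotypes.marker_ids})
    df["n_groups_used"] = valid.sum(axis=1)
    df["fst_wc"] = np.atleast_1d(theta)
    df["gst"] = np.atleast_1d(gst)
    df["jost_d"] = np.atleast_1d(d)
    df["fst_a"], df["fst_b"], df["fst_c"] = a, b, c
    for k, lab in enumerate(labels):
        df[f"he_{lab}"] = 2.0 * pbar[:, k] * (1.0 - pbar[:, k])
    # degenerate = monomorphic in every used group (H_T == 0)
    with np.errstate(invalid="ignore"):
        poly_any = np.nanmax(np.where(valid, p * (1 - p), np.nan), axis=1) > 0
    n_degenerate = int((~poly_any).sum())
    if n_degenerate:
        logger.info("excluding %d markers monomorphic in all used groups", n_degenerate)
    df = df[poly_any]
    mm = _cumulative_positions(marker_map)
    merged = df.merge(mm[["marker", "linkage_group", "cM", "cum_pos"]], on="marker", how="left")
    unmapped = merged["linkage_group"].isna()
    if unmapped.any():
        logger.info("dropping %d markers absent from the map", int(unmapped.sum()))
    merged = merged[~unmapped].sort_values(["linkage_group", "cM"]).reset_index(drop=True)
    cols = ["marker", "linkage_group", "cM", "cum_pos", "n_groups_used",
            "fst_wc", "gst", "jost_d", "fst_a", "fst_b", "fst_c"]
    cols += [c for c in merged.columns if c.startswith("he_")]
    return merged[cols]


def mean_multilocus_fst(
    genotypes: GenotypeMatrix,
    groups: pd.Series,
    exclude_groups=(),
) -> dict:
    """Multi-group multilocus F_ST over all usable markers.

    Returns both the ratio-of-sums Weir–Cockerham estimate
    ``sum(a) / sum(a+b+c)`` (the headline number) and the simple mean of
    per-marker theta, with the marker count used.
    """
    keep = groups[~groups.isin(set(exclude_groups))]
    if keep.nunique() < 2:
        raise ValueError("need at least two groups after exclusion")
    sub = genotypes.subset_accessions([a for a in genotypes.accession_ids if a in set(keep.index)])
    _, n, p, h = group_counts(sub, keep)
    a, b, c = wc_fst_components(n, p, h)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = a + b + c
    per_marker_ok = ok & (denom != 0)
    if not ok.any():
        raise ValueError("no usable markers for the multilocus estimate")
    ratio = float(a[ok].sum() / denom[ok].sum())
    theta = a[per_marker_ok] / denom[per_marker_ok]
    return {
        "fst_ratio_of_sums": ratio,
        "fst_mean_per_marker": float(theta.mean()),
        "n_markers": int(ok.sum()),
        "n_groups": int(keep.nunique()),
    }


def anova_fst_by_lg(scan_df: pd.DataFrame, value_col: str = "fst_wc"):
    """One-way fixed-effects ANOVA of per-marker F_ST across linkage groups.

    Returns (F, (df_between, df_within), p).
    """
    samples = []
    for _, sub in scan_df.groupby("linkage_group"):
        vals = sub[value_col].dropna().to_numpy()
        if len(vals) >= 2:
            samples.append(vals)
    if len(samples) < 2:
        raise ValueError("need at least two linkage groups with >= 2 markers each")
    f, p = stats.f_oneway(*samples)
    df_between = len(samples) - 1
    df_within = sum(len(s) for s in samples) - len(samples)
    return float(f), (df_between, df_within), float(p)


def empirical_outliers(scan_df: pd.DataFrame, top_quantile: float = 0.995) -> pd.DataFrame:
    """Markers at or above the empirical F_ST quantile.

    This is quantile flagging on the observed distribution — empirical, not
    model-based — and carries no significance guarantee; the ``method``
    column says so.
    """
    if scan_df.empty:
        raise ValueError("empty scan")
    vals = scan_df["fst_wc"].dropna()
    cutoff = float(np.quantile(vals.to_numpy(), top_quantile))
    flagged = scan_df[scan_df["fst_wc"] >= cutoff].copy()
    flagged = flagged.sort_values("fst_wc", ascending=False)
    flagged["rank"] = np.arange(1, len(flagged) + 1)
    flagged["fst_cutoff"] = cutoff
    flagged["method"] = "empirical_quantile"
    return flagged.reset_index(drop=True)
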