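"""Intrachromosomal linkage disequilibrium.

LD between two biallelic markers is measured as the squared Pearson
correlation r² of genotype dosages — for near-fully inbred lines this
coincides with the haplotype r², so no phasing is attempted.  Decay
profiles bin marker pairs by genetic (cM) or physical (bp) distance and
summarize each bin by quantiles of r².

Population and kinship structure generate spurious long-range LD.  The
kinship-corrected statistic r²_V removes it by whitening both dosage
vectors with the Cholesky factor of the kinship matrix (a generalized
least squares partial correlation) before correlating.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular

from .gio import GenotypeMatrix
from .relmat import PairwiseMatrix

__all__ = [
    "pairwise_r2",
    "r2v",
    "intra_lg_ld",
    "physical_ld",
    "ld_decay_profile",
    "ld_matrix",
    "DEFAULT_QUANTILES",
]

DEFAULT_QUANTILES = tuple(range(5, 100, 5))  # 5, 10, ..., 95 percent


def pairwise_r2(g_a, g_b) -> float:
    """Squared Pearson correlation of two dosage vectors over pairwise-complete entries.

    Returns NaN when fewer than two complete pairs remain or either marker
    has zero variance on them.
    """
    g_a = np.asarray(g_a, dtype=float)
    g_b = np.asarray(g_b, dtype=float)
    ok = ~np.isnan(g_a) & ~np.isnan(g_b)
    a, b = g_a[ok], g_b[ok]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def r2v(g_a, g_b, kin: PairwiseMatrix | np.ndarray, ridge: float = 1e-6) -> float:
    """Kinship-corrected r²: GLS partial correlation squared.

    Restricted to accessions called at both markers, the kinship submatrix V
    is Cholesky-factored (with ``ridge`` added to the diagonal if V is not
    positive definite); both dosage vectors are whitened by the inverse
    factor, the whitened intercept is projected out, and the squared Pearson
    correlation of the residuals is returned, clipped to [0, 1].

    With K = I this equals :func:`pairwise_r2` exactly.
    """
    g_a = np.asarray(g_a, dtype=float)
    g_b = np.asarray(g_b, dtype=float)
    k = kin.values if isinstance(kin, PairwiseMatrix) else np.asarray(kin, dtype=float)
    ok = ~np.isnan(g_a) & ~np.isnan(g_b)
    a, b = g_a[ok], g_b[ok]
    if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    v = k[np.ix_(ok, ok)]
    try:
        chol = cholesky(v, lower=True)
    except np.linalg.LinAlgError:
        try:
            chol = cholesky(v + ridge * np.eye(v.shape[0]), lower=True)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("kinship submatrix singular even after regularization") from exc
    w = solve_triangular(chol, np.column_stack([a, b, np.ones_like(a)]), lower=True)
    wa, wb, w1 = w[:, 0], w[:, 1], w[:, 2]
    denom = w1 @ w1
    ra = wa - w1 * (w1 @ wa) / denom
    rb = wb - w1 * (w1 @ wb) / denom
    na, nb = np.linalg.norm(ra), np.linalg.norm(rb)
    if na == 0 or nb == 0:
        return float("nan")
    r = (ra @ rb) / (na * nb)
    return float(np.clip(r * r, 0.0, 1.0))


def _pairwise_complete_r2_matrix(d: np.ndarray) -> np.ndarray:
    """All-pairs r² over pairwise-complete accessions, NaN where undefined.

    Uses indicator algebra so every pair's sums run over its own joint-called
    accession set without an explicit pair loop.
    """
    called = ~np.isnan(d)
    m = called.astype(float)
    z = np.where(called, d, 0.0)
    z2 = z * z
    n = m.T @ m
    sx = z.T @ m          # sum of x_j over accessions where both j,k called
    sxx = z2.T @ m
    sxy = z.T @ z
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        var_x = sxx - sx * sx / n
        var_y = var_x.T
        r2 = cov * cov / (var_x * var_y)
    r2[(n < 2) | ~(var_x > 0) | ~(var_y > 0)] = np.nan
    return r2


def _lg_pairs(markers: pd.DataFrame, r2_mat: np.ndarray, max_dist: float | None) -> pd.DataFrame:
    pos = markers["cM"].to_numpy()
    ids = markers["marker"].to_numpy()
    iu, ju = np.triu_indices(len(ids), k=1)
    dist = np.abs(pos[iu] - pos[ju])
    if max_dist is not None:
        keep = dist <= max_dist
        iu, ju, dist = iu[keep], ju[keep], dist[keep]
    return pd.DataFrame(
        {
            "marker_a": ids[iu],
            "marker_b": ids[ju],
            "linkage_group": markers["linkage_group"].iloc[0],
            "dist_cM": dist,
            "r2": r2_mat[iu, ju],
        }
    )


def intra_lg_ld(
    genotypes: GenotypeMatrix,
    marker_map: pd.DataFrame,
    max_dist_cM: float | None = None,
) -> pd.DataFrame:
    """r² for every within-linkage-group marker pair (optionally distance-capped).

    Markers absent from the map are excluded.  Pairs where r² is undefined
    (monomorphic on the joint-called set) carry NaN and are dropped by
    :func:`ld_decay_profile`.
    """
    mm = marker_map[marker_map["marker"].isin(genotypes.marker_ids)]
    frames = []
    for _, markers in mm.groupby("linkage_group", sort=True):
        markers = markers.sort_values("cM").reset_index(drop=True)
        if len(markers) < 2:
            continue
        sub = genotypes.subset_markers(markers["marker"].tolist())
        r2_mat = _pairwise_complete_r2_matrix(sub.dosage)
        frames.append(_lg_pairs(markers, r2_mat, max_dist_cM))
    if not frames:
        return pd.DataFrame(columns=["marker_a", "marker_b", "linkage_group", "dist_cM", "r2"])
    return pd.concat(frames, ignore_index=True)


def physical_ld(genotypes: GenotypeMatrix, marker_map: pd.DataFrame) -> pd.DataFrame:
    """r² against physical distance for marker pairs sharing a scaffold."""
    mm = marker_map[
        marker_map["marker"].isin(genotypes.marker_ids) & marker_map["scaffold"].notna()
    ]
    frames = []
    for scaffold, markers in mm.groupby("scaffold", sort=True):
        if len(markers) < 2:
            continue
        markers = markers.sort_values("bp").reset_index(drop=True)
        sub = genotypes.subset_markers(markers["marker"].tolist())
        r2_mat = _pairwise_complete_r2_matrix(sub.dosage)
        iu, ju = np.triu_indices(len(markers), k=1)
        bp = markers["bp"].to_numpy(dtype=float)
        frames.append(
            pd.DataFrame(
                {
                    "marker_a": markers["marker"].to_numpy()[iu],
                    "marker_b": markers["marker"].to_numpy()[ju],
                    "linkage_group": markers["linkage_group"].iloc[0],
                    "scaffold": scaffold,
                    "dist_bp": np.abs(bp[iu] - bp[ju]).astype(int),
                    "r2": r2_mat[iu, ju],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["marker_a", "marker_b", "linkage_group", "scaffold", "dist_bp", "r2"]
        )
    return pd.concat(frames, ignore_index=True)


def ld_decay_profile(
    pairs: pd.DataFrame,
    bin_width: float = 0.5,
    dist_col: str = "dist_cM",
    quantiles=DEFAULT_QUANTILES,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Quantile decay curve: r² quantiles per fixed-width distance bin.

    Bins with fewer than ``min_pairs`` defined pairs are suppressed.  Output
    is long format: one row per (bin, quantile), plus a ``median`` row (q=50
    is included in the default quantile grid).
    """
    if pairs.empty:
        raise ValueError("no marker pairs to profile")
    ok = pairs.dropna(subset=["r2", dist_col])
    bins = np.floor(ok[dist_col].to_numpy() / bin_width).astype(int)
    rows = []
    qs = np.asarray(sorted(quantiles), dtype=float)
    for b in np.unique(bins):
        vals = ok["r2"].to_numpy()[bins == b]
        if vals.size < min_pairs:
            continue
        qvals = np.percentile(vals, qs)
        for q, v in zip(qs, qvals):
            rows.append(
                {
                    "bin_left": b * bin_width,
                    "bin_right": (b + 1) * bin_width,
                    "n_pairs": vals.size,
                    "quantile": q,
                    "r2": v,
                }
            )
    return pd.DataFrame(rows, columns=["bin_left", "bin_right", "n_pairs", "quantile", "r2"])


def ld_matrix(
    genotypes: GenotypeMatrix,
    marker_map: pd.DataFrame,
    linkage_group: str,
    kin: PairwiseMatrix | None = None,
    max_markers: int | None = None,
) -> tuple[list[str], np.ndarray]:
    """Symmetric unit-diagonal LD matrix for one linkage group, markers ordered by cM.

    With ``kin`` the kinship-corrected r²_V is computed instead of r²; for
    that case missing dosages are mean-imputed so a single whitening of the
    genotype block serves all pairs.
    """
    markers = (
        marker_map[(marker_map["linkage_group"].astype(str) == str(linkage_group))
                   & marker_map["marker"].isin(genotypes.marker_ids)]
        .sort_values("cM")["marker"]
        .tolist()
    )
    if max_markers is not None:
        markers = markers[:max_markers]
    if len(markers) < 2:
        raise ValueError(f"fewer than two mapped markers on linkage group {linkage_group!r}")
    sub = genotypes.subset_markers(markers)
    if kin is None:
        mat = _pairwise_complete_r2_matrix(sub.dosage)
    else:
        d = sub.dosage.copy()
        col_mean = np.nanmean(d, axis=0)
        nan_r, nan_c = np.where(np.isnan(d))
        d[nan_r, nan_c] = col_mean[nan_c]
        k = kin.values
        try:
            chol = cholesky(k, lower=True)
        except np.linalg.LinAlgError:
            chol = cholesky(k + 1e-6 * np.eye(k.shape[0]), lower=True)
        w = solve_triangular(chol, np.column_stack([d, np.ones(d.shape[0])]), lower=True)
        w1 = w[:, -1]
        wd = w[:, :-1]
        wd = wd - np.outer(w1, (w1 @ wd) / (w1 @ w1))
        norms = np.linalg.norm(wd, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (wd.T @ wd) / np.outer(norms, norms)
        mat = np.clip(corr * corr, 0.0, 1.0)
        mat[np.isnan(corr)] = np.nan
    np.fill_diagonal(mat, 1.0)
    return markers, mat
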