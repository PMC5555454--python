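"""Within-group diversity: MAF spectra, Nei's He, joint frequency histograms,
and sample-size-equalizing He resampling.

Nei's expected heterozygosity (gene diversity) of a biallelic marker with
allele frequency p is He = 2p(1-p).  Comparing mean He between groups of
different sizes conflates diversity with sampling depth, so the resampling
routine repeatedly subsamples the larger group down to a reference size and
averages He over replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gio import GenotypeMatrix

__all__ = [
    "nei_he",
    "group_allele_freq",
    "maf_histogram",
    "joint_maf_histogram",
    "group_he_summary",
    "resampled_group_he",
]


def nei_he(p):
    """Nei's gene diversity 2p(1-p) for allele frequency p (scalar or array)."""
    p = np.asarray(p, dtype=float)
    out = 2.0 * p * (1.0 - p)
    return float(out) if out.ndim == 0 else out


def group_allele_freq(genotypes: GenotypeMatrix, subset=None) -> np.ndarray:
    """Per-marker ALT frequency over called genotypes of ``subset`` (NaN if no calls)."""
    d = genotypes.dosage
    if subset is not None:
        d = d[genotypes.accession_indices(list(subset))]
    n_called = (~np.isnan(d)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * n_called)
    p[n_called == 0] = np.nan
    return p


def maf_histogram(
    genotypes: GenotypeMatrix,
    subset=None,
    n_bins: int = 20,
    include_monomorphic: bool = True,
) -> pd.DataFrame:
    """Histogram of within-subset MAF over ``n_bins`` equal bins on [0, 0.5].

    Markers monomorphic in the subset have MAF 0 and land in the first bin
    (set ``include_monomorphic=False`` to drop them).  Markers with no calls
    in the subset are always excluded.
    """
    p = group_allele_freq(genotypes, subset)
    maf = np.minimum(p, 1.0 - p)
    maf = maf[~np.isnan(maf)]
    if not include_monomorphic:
        maf = maf[maf > 0]
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    counts, _ = np.histogram(maf, bins=edges)
    # MAF == 0.5 is a legal value; np.histogram puts it in the last bin already
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})


def joint_maf_histogram(
    genotypes: GenotypeMatrix,
    group_a,
    group_b,
    n_bins: int = 10,
    axis: str = "global_minor",
) -> pd.DataFrame:
    """Joint allele-frequency histogram between two disjoint accession groups.

    For ``axis="global_minor"`` (default) each marker contributes the
    within-group frequency of the allele that is minor in the pooled pair of
    groups — a consistent allele on both axes, which preserves between-group
    frequency correlation.  ``axis="per_group"`` bins each group's own MAF
    instead.  Ten equal bins on [0, 1] per axis ([0, 0.5] for per-group MAF);
    markers without calls in either group are excluded.

    Returns a long DataFrame (bin_a, bin_b, count) whose counts sum to the
    number of markers defined in both groups.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    p_a = group_allele_freq(genotypes, group_a)
    p_b = group_allele_freq(genotypes, group_b)
    ok = ~np.isnan(p_a) & ~np.isnan(p_b)
    if axis == "global_minor":
        p_pool = group_allele_freq(genotypes, group_a + group_b)
        flip = p_pool > 0.5  # express as frequency of the globally-minor allele
        x = np.where(flip, 1.0 - p_a, p_a)[ok]
        y = np.where(flip, 1.0 - p_b, p_b)[ok]
        hi = 1.0
    elif axis == "per_group":
        x = np.minimum(p_a, 1 - p_a)[ok]
        y = np.minimum(p_b, 1 - p_b)[ok]
        hi = 0.5
    else:
        raise ValueError(f"unknown axis {axis!r}")
    edges = np.linspace(0.0, hi, n_bins + 1)
    counts, _, _ = np.histogram2d(x, y, bins=[edges, edges])
    ii, jj = np.meshgrid(np.arange(n_bins), np.arange(n_bins), indexing="ij")
    return pd.DataFrame(
        {
            "bin_a": ii.ravel(),
            "bin_b": jj.ravel(),
            "freq_a_left": edges[ii.ravel()],
            "freq_b_left": edges[jj.ravel()],
            "count": counts.ravel().astype(int),
        }
    )


def _mean_he(genotypes: GenotypeMatrix, accessions) -> float:
    p = group_allele_freq(genotypes, accessions)
    return float(np.nanmean(nei_he(p)))


def group_he_summary(genotypes: GenotypeMatrix, groups: pd.Series) -> pd.DataFrame:
    """Mean He per group (within-group frequencies, markers with calls only)."""
    rows = []
    for label, members in groups.groupby(groups).groups.items():
        accs = list(members)
        rows.append(
            {
                "group": label,
                "n_accessions": len(accs),
                "n_markers": int((~np.isnan(group_allele_freq(genotypes, accs))).sum()),
                "mean_He": _mean_he(genotypes, accs),
            }
        )
    return pd.DataFrame(rows)


def resampled_group_he(
    genotypes: GenotypeMatrix,
    groups: pd.Series,
    target_group: str,
    reference_n: int,
    n_reps: int = 50,
    seed: int | np.random.Generator = 0,
) -> tuple[float, np.ndarray]:
    """Mean He of ``target_group`` equalized to ``reference_n`` accessions.

    Each replicate draws ``reference_n`` accessions without replacement and
    computes the mean He over markers; the first return value is the mean
    over replicates, the second the per-replicate values.
    """
    members = list(groups.index[groups == target_group])
    if not members:
        raise ValueError(f"no accessions in group {target_group!r}")
    if reference_n > len(members):
        raise ValueError(f"reference_n={reference_n} exceeds group size {len(members)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reps = np.empty(n_reps)
    for r in range(n_reps):
        draw = rng.choice(members, size=reference_n, replace=False)
        reps[r] = _mean_he(genotypes, draw)
    return float(reps.mean()), reps
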