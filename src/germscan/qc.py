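"""Per-SNP summaries and marker filters.

Array-genotyped germplasm panels of selfing species are filtered on three
marker-level statistics before any population analysis: call rate,
observed heterozygosity (inbred lines should be near-homozygous, so a
heterozygote excess flags a clustering artifact), and minor allele
frequency.  The defaults — discard at missing rate >= 0.2 or observed
het >= 0.05, keep MAF >= 0.02 (0.05 for LD work) — follow standard
practice for diversity panels on fixed SNP arrays.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .gio import GenotypeMatrix

__all__ = ["snp_summary", "filter_snps", "polymorphic_count"]


def snp_summary(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker call counts, missing rate, het rate, ALT frequency and MAF.

    Frequencies are computed over called genotypes only.  Markers with no
    calls get NaN frequencies and ``defined = False``.
    """
    d = genotypes.dosage
    n_acc = genotypes.n_accessions
    called = ~np.isnan(d)
    n_called = called.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty-slice means on no-call markers
        alt_sum = np.nansum(d, axis=0)
        p_alt = np.where(n_called > 0, alt_sum / (2.0 * np.maximum(n_called, 1)), np.nan)
        het = np.where(n_called > 0, (d == 1).sum(axis=0) / np.maximum(n_called, 1), np.nan)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    return pd.DataFrame(
        {
            "marker": genotypes.marker_ids,
            "n_called": n_called.astype(int),
            "missing_rate": (n_acc - n_called) / n_acc,  # exact ratio: 2/10 must not pass a 0.2 cutoff
            "het_rate": het,
            "p_alt": p_alt,
            "maf": maf,
            "defined": n_called > 0,
        }
    )


def filter_snps(
    genotypes: GenotypeMatrix,
    max_missing: float = 0.2,
    max_het: float = 0.05,
    min_maf: float = 0.02,
) -> GenotypeMatrix:
    """Keep markers with missing_rate < max_missing, het_rate < max_het and maf >= min_maf.

    The missing/het bounds are exclusive (a marker *at* the threshold is
    discarded) while the MAF bound is inclusive.  The accession set is
    unchanged; an empty survivor set raises a warning, not an error.
    """
    for name, t in (("max_missing", max_missing), ("max_het", max_het), ("min_maf", min_maf)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name}={t} outside [0, 1]")
    s = snp_summary(genotypes)
    keep = (
        s["defined"].to_numpy()
        & (s["missing_rate"].to_numpy() < max_missing)
        & (s["het_rate"].to_numpy() < max_het)
        & (s["maf"].to_numpy() >= min_maf)
    )
    if not keep.any():
        warnings.warn("no markers survive the SNP filters", stacklevel=2)
    survivors = [m for m, k in zip(genotypes.marker_ids, keep) if k]
    return genotypes.subset_markers(survivors)


def polymorphic_count(genotypes: GenotypeMatrix, subset) -> int:
    """Number of markers with >= 2 distinct alleles among called genotypes of ``subset``.

    A single heterozygous call already carries both alleles, so it counts.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    idx = genotypes.accession_indices(subset)
    d = genotypes.dosage[idx]
    has_ref = np.nansum((d == 0) | (d == 1), axis=0) > 0
    has_alt = np.nansum((d == 2) | (d == 1), axis=0) > 0
    return int((has_ref & has_alt).sum())
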