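"""Synthetic inbred-line genotype panels with controlled structure.

The generator emulates the statistical anatomy of an array-genotyped
germplasm collection of a selfing crop: a few strongly diverged groups of
near-homozygous lines, allele frequencies drifted from a common ancestral
pool under the Balding–Nichols model, linkage disequilibrium decaying
with genetic map distance, planted high-differentiation outlier loci, an
optional array-ascertainment filter that depletes rare alleles in the
discovery groups, and uniform missingness.

Haplotypes are founder mosaics rather than coalescent output: each group
has a small pool of founder haplotypes drawn site-independently from the
group's allele frequencies, and every sample haplotype copies one founder
at a time, switching founders at Poisson points along the cM axis.  Two
knobs — founder count and switch rate — then set the amount and decay
scale of LD.

``drift_F`` is the *realized* group-level drift: because resampling a
finite founder pool adds drift of its own (~1/n_founders), the
Balding–Nichols stage is deflated so that the total variance of group
frequencies around the ancestral value matches F * p(1-p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gio import GenotypeMatrix

__all__ = ["SimulationConfig", "SimulationTruth", "SimulationResult", "simulate", "ld_expectation_check"]

DEFAULT_GROUP_NAMES = ("wild", "winter", "spring")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic panel; defaults give a desk-scale analogue of a
    three-group diversity panel (~2,000 SNPs on 7 linkage groups, 100 inbred
    lines per group, realized multi-group drift 0.3, steep LD decay)."""

    seed: int = 0
    n_groups: int = 3
    n_per_group: int | tuple = 100
    drift_F: float | tuple = 0.3
    group_names: tuple | None = None
    n_linkage_groups: int = 7
    markers_per_lg: int = 286
    lg_length_cM: float = 100.0
    n_founders: int = 8
    switch_rate_per_cM: float = 0.1
    inbreeding_prob: float = 0.97
    het_residual_rate: float = 0.01
    missing_rate: float = 0.03
    ancestral_freq_range: tuple = (0.05, 0.95)
    # planted outliers: (linkage_group, cM, pair_F) between outlier_pair groups
    outlier_loci: tuple = ()
    outlier_pair: tuple = ("winter", "spring")
    scaffold_span_cM: float = 0.5
    bp_per_cM: float = 5.6e6
    ascertainment_min_maf: float | None = None
    ascertainment_groups: tuple | None = None  # default: all but the first group
    compensate_founder_drift: bool = True

    def resolved_group_names(self) -> list[str]:
        if self.group_names is not None:
            names = list(self.group_names)
        elif self.n_groups == 3:
            names = list(DEFAULT_GROUP_NAMES)
        else:
            names = [f"group{i + 1}" for i in range(self.n_groups)]
        if len(names) != self.n_groups:
            raise ValueError("group_names length must equal n_groups")
        return names

    def per_group(self, value) -> np.ndarray:
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            arr = np.repeat(arr, self.n_groups)
        if arr.shape != (self.n_groups,):
            raise ValueError("per-group parameter has wrong length")
        return arr

    def validate(self) -> None:
        if self.n_groups < 1:
            raise ValueError("need at least one group")
        if np.any(self.per_group(self.n_per_group) < 1):
            raise ValueError("empty group in n_per_group")
        if self.n_founders < 1:
            raise ValueError("need at least one founder haplotype")
        if self.markers_per_lg < 2:
            raise ValueError("markers_per_lg must be >= 2")
        for name in ("inbreeding_prob", "het_residual_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        f = self.per_group(self.drift_F)
        if np.any((f <= 0) | (f >= 1)):
            raise ValueError("drift_F values must lie in (0, 1)")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside the panel for recovery tests."""

    markers: pd.DataFrame      # marker, linkage_group, cM, ancestral_p, p_<group>..., outlier
    accessions: pd.DataFrame   # accession, group
    founder_freq: pd.DataFrame  # realized founder-pool frequency per group


@dataclass
class SimulationResult:
    genotypes: GenotypeMatrix
    marker_map: pd.DataFrame
    groups: pd.Series
    truth: SimulationTruth
    config: SimulationConfig = field(repr=False, default=None)


def _beta_drift(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Balding–Nichols draw: Beta(p(1-F)/F, (1-p)(1-F)/F) around ancestral p."""
    if f < 1e-6:
        return p.copy()
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    return rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))


def _effective_beta_f(f: float, n_founders: int, compensate: bool) -> float:
    """Deflate the Beta-stage F so founder resampling lands total drift at F."""
    if not compensate:
        return f
    return max((f - 1.0 / n_founders) / (1.0 - 1.0 / n_founders), 1e-7)


def _mosaic_haplotype(
    rng: np.random.Generator,
    founders: np.ndarray,
    lg_slices: list[tuple[slice, np.ndarray]],
    switch_rate: float,
    lg_length: float,
) -> np.ndarray:
    """One haplotype: per linkage group, copy founders piecewise along the cM axis."""
    n_f = founders.shape[0]
    hap = np.empty(founders.shape[1], dtype=np.int8)
    for sl, pos in lg_slices:
        n_switch = rng.poisson(switch_rate * lg_length)
        if n_switch == 0:
            hap[sl] = founders[rng.integers(n_f), sl]
            continue
        cuts = np.sort(rng.uniform(0.0, lg_length, size=n_switch))
        founder_ids = rng.integers(n_f, size=n_switch + 1)
        seg = np.searchsorted(cuts, pos, side="right")
        hap[sl] = founders[:, sl][founder_ids[seg], np.arange(pos.size)]
    return hap


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate (genotypes, marker map, group labels, truth) from one seed.

    The master seed is split into named child streams (map, ancestral,
    drift, founders, mosaics, het, missing) so each stage's randomness is
    reproducible independently of the others.
    """
    config.validate()
    names = config.resolved_group_names()
    sizes = config.per_group(config.n_per_group).astype(int)
    drift = config.per_group(config.drift_F)
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_map, rng_anc, rng_drift, rng_found, rng_mosaic, rng_het, rng_miss = (
        np.random.default_rng(s) for s in streams
    )

    # --- map -------------------------------------------------------------
    lgs, positions, marker_ids = [], [], []
    for g in range(config.n_linkage_groups):
        lg = f"LG{g + 1}"
        pos = np.sort(rng_map.uniform(0.0, config.lg_length_cM, size=config.markers_per_lg))
        lgs += [lg] * config.markers_per_lg
        positions.append(pos)
        marker_ids += [f"M_{lg}_{i + 1:04d}" for i in range(config.markers_per_lg)]
    pos_all = np.concatenate(positions)
    m = pos_all.size
    lg_arr = np.asarray(lgs)
    lg_slices = []
    start = 0
    for pos in positions:
        lg_slices.append((slice(start, start + pos.size), pos))
        start += pos.size

    # scaffolds: consecutive markers within scaffold_span_cM of the scaffold start
    scaffold = np.empty(m, dtype=object)
    bp = np.empty(m, dtype=float)
    s_id = 0
    for sl, pos in lg_slices:
        anchor = None
        for j, cm in enumerate(pos):
            if anchor is None or cm - anchor > config.scaffold_span_cM:
                anchor = cm
                s_id += 1
            scaffold[sl.start + j] = f"scf{s_id:05d}"
            bp[sl.start + j] = round((cm - anchor) * config.bp_per_cM) + 1
    marker_map = pd.DataFrame(
        {"marker": marker_ids, "linkage_group": lg_arr, "cM": pos_all, "scaffold": scaffold, "bp": bp}
    )

    # --- allele frequencies ----------------------------------------------
    lo, hi = config.ancestral_freq_range
    p_anc = rng_anc.uniform(lo, hi, size=m)
    p_group = np.empty((config.n_groups, m))
    for k in range(config.n_groups):
        fb = _effective_beta_f(drift[k], config.n_founders, config.compensate_founder_drift)
        p_group[k] = _beta_drift(rng_drift, p_anc, fb)

    outlier_flag = np.zeros(m, dtype=bool)
    pair_idx = None
    if config.outlier_loci:
        pair = config.outlier_pair
        try:
            pair_idx = (names.index(pair[0]), names.index(pair[1]))
        except ValueError as exc:
            raise ValueError(f"outlier_pair group not in panel: {exc}") from None
        for lg, cm, f_pair in config.outlier_loci:
            on_lg = np.where(lg_arr == str(lg))[0]
            if on_lg.size == 0:
                raise ValueError(f"outlier linkage group {lg!r} not simulated")
            j = on_lg[np.argmin(np.abs(pos_all[on_lg] - float(cm)))]
            # plant the pair at parametric divergence F: mu +/- delta with
            # delta^2 = F mu (1 - mu), the two-group Nei F_ST closed form;
            # mu must lie in [F/(1+F), 1/(1+F)] for both frequencies to stay
            # in [0, 1], so the ancestral value is clamped into that band
            f = float(f_pair)
            mu = float(np.clip(p_anc[j], f / (1.0 + f), 1.0 / (1.0 + f)))
            delta = np.sqrt(f * mu * (1.0 - mu))
            hi = min(mu + delta, 1.0)
            lo = max(mu - delta, 0.0)
            if rng_drift.random() < 0.5:
                hi, lo = lo, hi
            p_group[pair_idx[0], j] = hi
            p_group[pair_idx[1], j] = lo
            outlier_flag[j] = True

    # --- founders and sample haplotypes ----------------------------------
    acc_ids: list[str] = []
    group_labels: list[str] = []
    geno = np.empty((int(sizes.sum()), m), dtype=float)
    founder_freq = np.empty((config.n_groups, m))
    row = 0
    for k, (name, n_k) in enumerate(zip(names, sizes)):
        founders = (rng_found.random((config.n_founders, m)) < p_group[k]).astype(np.int8)
        founder_freq[k] = founders.mean(axis=0)
        for i in range(n_k):
            hap1 = _mosaic_haplotype(rng_mosaic, founders, lg_slices,
                                     config.switch_rate_per_cM, config.lg_length_cM)
            if rng_mosaic.random() < config.inbreeding_prob:
                hap2 = hap1
            else:
                hap2 = _mosaic_haplotype(rng_mosaic, founders, lg_slices,
                                         config.switch_rate_per_cM, config.lg_length_cM)
            geno[row] = hap1 + hap2
            acc_ids.append(f"{name}_{i + 1:03d}")
            group_labels.append(name)
            row += 1

    # residual heterozygous calls (clustering noise on a selfing panel)
    if config.het_residual_rate > 0:
        mask = rng_het.random(geno.shape) < config.het_residual_rate
        geno[mask] = 1.0
    if config.missing_rate > 0:
        geno[rng_miss.random(geno.shape) < config.missing_rate] = np.nan

    groups = pd.Series(group_labels, index=acc_ids, name="group")
    truth_markers = pd.DataFrame(
        {"marker": marker_ids, "linkage_group": lg_arr, "cM": pos_all, "ancestral_p": p_anc}
    )
    for k, name in enumerate(names):
        truth_markers[f"p_{name}"] = p_group[k]
    truth_markers["outlier"] = outlier_flag
    ff = pd.DataFrame({f"founder_p_{name}": founder_freq[k] for k, name in enumerate(names)})
    ff.insert(0, "marker", marker_ids)

    # --- ascertainment ----------------------------------------------------
    keep = np.ones(m, dtype=bool)
    if config.ascertainment_min_maf is not None:
        asc_groups = (
            list(config.ascertainment_groups) if config.ascertainment_groups is not None else names[1:]
        )
        sel = np.asarray([g in asc_groups for g in group_labels])
        d = geno[sel]
        n_called = (~np.isnan(d)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_pool = np.nansum(d, axis=0) / (2.0 * np.maximum(n_called, 1))
        maf = np.minimum(p_pool, 1.0 - p_pool)
        keep = (n_called > 0) & (maf >= config.ascertainment_min_maf)

    kept_ids = [mid for mid, k_ in zip(marker_ids, keep) if k_]
    genotypes = GenotypeMatrix(acc_ids, kept_ids, geno[:, keep])
    marker_map = marker_map[keep].reset_index(drop=True)
    truth = SimulationTruth(
        markers=truth_markers[keep].reset_index(drop=True),
        accessions=pd.DataFrame({"accession": acc_ids, "group": group_labels}),
        founder_freq=ff[keep].reset_index(drop=True),
    )
    return SimulationResult(genotypes, marker_map, groups, truth, config)


def ld_expectation_check(
    config: SimulationConfig | None = None,
    result: SimulationResult | None = None,
    bin_width_cM: float = 1.0,
    max_dist_cM: float = 25.0,
    min_pairs: int = 20,
) -> dict:
    """Mean r² per distance bin on a simulated panel, with a decay summary.

    Returns the binned profile plus the fraction of adjacent bin transitions
    that are non-increasing (1.0 = perfectly monotone decay) and the
    short-range (first bin) vs long-range (last bin) means.
    """
    from .ldcalc import intra_lg_ld
    from .qc import filter_snps

    if result is None:
        if config is None:
            raise ValueError("give a config or a simulation result")
        result = simulate(config)
    filtered = filter_snps(result.genotypes, max_missing=1.0, max_het=1.0, min_maf=0.05)
    pairs = intra_lg_ld(filtered, result.marker_map, max_dist_cM=max_dist_cM)
    ok = pairs.dropna(subset=["r2"])
    bins = np.floor(ok["dist_cM"].to_numpy() / bin_width_cM).astype(int)
    rows = []
    for b in np.unique(bins):
        vals = ok["r2"].to_numpy()[bins == b]
        if vals.size >= min_pairs:
            rows.append({"bin_left": b * bin_width_cM, "bin_right": (b + 1) * bin_width_cM,
                         "n_pairs": vals.size, "mean_r2": float(vals.mean()),
                         "median_r2": float(np.median(vals))})
    profile = pd.DataFrame(rows)
    means = profile["mean_r2"].to_numpy()
    steps = np.diff(means)
    return {
        "profile": profile,
        "monotone_fraction": float((steps <= 0).mean()) if steps.size else 1.0,
        "short_range_mean_r2": float(means[0]) if means.size else float("nan"),
        "long_range_mean_r2": float(means[-1]) if means.size else float("nan"),
    }


def default_outlier_loci(pair_f: float = 0.8) -> tuple:
    """Ten planted outliers: a broad cluster on LG5 (37-87 cM) and a tight one
    on LG6 (46-50 cM), the classic geography of a spring/winter sowing-type
    differentiation scan."""
    lg5 = [37.8, 45.0, 53.6, 60.2, 67.3, 71.7, 86.2]
    lg6 = [46.9, 47.4, 49.1]
    return tuple(("LG5", cm, pair_f) for cm in lg5) + tuple(("LG6", cm, pair_f) for cm in lg6)
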