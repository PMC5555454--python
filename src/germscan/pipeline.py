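"""End-to-end orchestration of the panel analysis.

One :class:`RunConfig` — real input files or a simulation — drives the
stages in dependency order:

1. QC filters (two filtered views of the same input: MAF >= 0.02 for
   structure/diversity work, MAF >= 0.05 for LD);
2. relatedness matrices (allele-sharing distance, IBS, kinship), Ward
   dendrogram, thresholded IBS network;
3. diversity (MAF spectra per group, joint frequency histograms, group He
   with size-equalizing resampling);
4. LD (within-LG pair table, quantile decay profile, physical-distance
   pairs, per-LG heatmap matrices raw and kinship-corrected);
5. differentiation scan (per-SNP F_ST / G_ST / Jost's D Manhattan table,
   multilocus mean F_ST, ANOVA across linkage groups, empirical outliers).

Every run writes a JSON manifest listing the artifacts with SHA-256
checksums, marker/accession counts after each filter, thresholds, seed and
package versions, so any number in the outputs can be audited.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import divstats, diffscan, gio, ldcalc, qc, relmat, syndata

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """Inputs, thresholds and toggles for a full run.

    Exactly one of (``genotypes_path``) or (``simulation``) must be set.
    """

    out_dir: str = "germscan_out"
    seed: int = 0
    # real-data inputs
    genotypes_path: str | None = None
    genotypes_format: str = "table"
    map_path: str | None = None
    groups_path: str | None = None
    # or a simulation
    simulation: syndata.SimulationConfig | None = None
    # marker filters
    max_missing: float = 0.2
    max_het: float = 0.05
    min_maf_structure: float = 0.02
    min_maf_ld: float = 0.05
    # stage toggles
    do_diversity: bool = True
    do_relatedness: bool = True
    do_ld: bool = True
    do_ld_kinship_corrected: bool = True
    do_fstscan: bool = True
    # stage parameters
    resample_to: str | None = None     # group whose size equalizes He resampling
    resample_reps: int = 50
    ibs_threshold: float = 0.8
    ld_bin_width_cM: float = 0.5
    ld_max_dist_cM: float | None = None
    heatmap_lg: str | None = None
    heatmap_max_markers: int = 60
    contrast: tuple | None = None      # group labels for the scan (default: all)
    exclude_groups: tuple = ()
    outlier_quantile: float = 0.995
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_files = self.genotypes_path is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ValueError("exactly one of genotypes_path or simulation must be given")
        if has_files and (self.map_path is None or self.groups_path is None):
            raise ValueError("file-backed runs need map_path and groups_path")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "outlier_loci" in sim:
                sim["outlier_loci"] = tuple(tuple(x) for x in sim["outlier_loci"])
            sim = syndata.SimulationConfig(**sim)
        for key in ("contrast", "exclude_groups"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, config: RunConfig):
        self.out_dir = out_dir
        self.data: dict = {
            "package": "germscan",
            "version": __version__,
            "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "seed": config.seed,
            "thresholds": {
                "max_missing": config.max_missing,
                "max_het": config.max_het,
                "min_maf_structure": config.min_maf_structure,
                "min_maf_ld": config.min_maf_ld,
                "ibs_threshold": config.ibs_threshold,
                "outlier_quantile": config.outlier_quantile,
            },
            "counts": {},
            "inputs": {},
            "artifacts": {},
        }

    def add(self, name: str, path: Path) -> None:
        self.data["artifacts"][name] = {
            "path": str(path.relative_to(self.out_dir)),
            "sha256": _sha256(path),
        }

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
        return path


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config)

    # --- inputs ----------------------------------------------------------
    if config.simulation is not None:
        sim = syndata.simulate(config.simulation)
        genotypes, marker_map, groups = sim.genotypes, sim.marker_map, sim.groups
        gio.write_genotypes(genotypes, str(out / "genotypes.tsv"))
        gio.write_map(marker_map, str(out / "map.tsv"))
        gio.write_groups(groups, str(out / "groups.tsv"))
        gio.write_vcf(genotypes, marker_map, str(out / "genotypes.vcf"))
        gio.write_table(sim.truth.markers, str(out / "truth_markers.tsv"))
        for name in ("genotypes.tsv", "map.tsv", "groups.tsv", "genotypes.vcf", "truth_markers.tsv"):
            manifest.add(name.split(".")[0] if name != "truth_markers.tsv" else "truth", out / name)
        manifest.data["inputs"]["simulation"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config.simulation).items()
        }
    else:
        genotypes = gio.read_genotypes(config.genotypes_path, format=config.genotypes_format)
        marker_map = gio.read_map(config.map_path)
        groups = gio.read_groups(config.groups_path)
        gio.validate_groups(groups, genotypes)
        for key, p in (("genotypes", config.genotypes_path), ("map", config.map_path),
                       ("groups", config.groups_path)):
            manifest.data["inputs"][key] = {"path": p, "sha256": _sha256(Path(p))}

    manifest.data["counts"]["input"] = {
        "accessions": genotypes.n_accessions,
        "markers": genotypes.n_markers,
    }

    # --- QC: two filtered views of the same input ------------------------
    g_struct = qc.filter_snps(genotypes, config.max_missing, config.max_het, config.min_maf_structure)
    g_ld = qc.filter_snps(genotypes, config.max_missing, config.max_het, config.min_maf_ld)
    gio.write_table(qc.snp_summary(genotypes), str(out / "snp_summary.tsv"))
    manifest.add("snp_summary", out / "snp_summary.tsv")
    manifest.data["counts"]["after_structure_filter"] = {"markers": g_struct.n_markers}
    manifest.data["counts"]["after_ld_filter"] = {"markers": g_ld.n_markers}
    logger.info("filters: %d markers in, %d for structure (MAF>=%.3g), %d for LD (MAF>=%.3g)",
                genotypes.n_markers, g_struct.n_markers, config.min_maf_structure,
                g_ld.n_markers, config.min_maf_ld)

    labels = sorted(groups.unique())
    kin = None

    # --- relatedness ------------------------------------------------------
    if config.do_relatedness:
        dist = relmat.allele_sharing_distance(g_struct)
        ibs = relmat.ibs_matrix(g_struct)
        kin = relmat.kinship(g_struct)
        dist.write(str(out / "distance.tsv"))
        ibs.write(str(out / "ibs.tsv"))
        kin.write(str(out / "kinship.tsv"))
        link = relmat.ward_tree(dist)
        (out / "tree.nwk").write_text(relmat.tree_to_newick(link, dist.accession_ids) + "\n")
        net = relmat.ibs_network(ibs, threshold=config.ibs_threshold, node_attrs=groups)
        edges = relmat.network_edge_list(net)
        if not edges.empty:
            gio.write_table(edges, str(out / "ibs_network_edges.tsv"))
            manifest.add("ibs_network_edges", out / "ibs_network_edges.tsv")
        import networkx as nx

        nx.write_graphml(net, out / "ibs_network.graphml")
        for name in ("distance.tsv", "ibs.tsv", "kinship.tsv", "tree.nwk", "ibs_network.graphml"):
            manifest.add(name.split(".")[0], out / name)
        manifest.data["counts"]["ibs_network"] = {
            "nodes": net.number_of_nodes(), "edges": net.number_of_edges(),
        }

    # --- diversity --------------------------------------------------------
    if config.do_diversity:
        hist_total = divstats.maf_histogram(g_struct)
        hist_total["group"] = "total"
        hists = [hist_total]
        for lab in labels:
            h = divstats.maf_histogram(g_struct, list(groups.index[groups == lab]))
            h["group"] = lab
            hists.append(h)
        gio.write_table(pd.concat(hists, ignore_index=True), str(out / "maf_histograms.tsv"))
        joints = []
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                j = divstats.joint_maf_histogram(
                    g_struct, list(groups.index[groups == la]), list(groups.index[groups == lb])
                )
                j["pair"] = f"{la}-{lb}"
                joints.append(j)
        if joints:
            gio.write_table(pd.concat(joints, ignore_index=True), str(out / "joint_maf_histograms.tsv"))
            manifest.add("joint_maf_histograms", out / "joint_maf_histograms.tsv")
        he = divstats.group_he_summary(g_struct, groups)
        ref_group = config.resample_to or (labels[0] if labels else None)
        if ref_group is not None:
            ref_n = int((groups == ref_group).sum())
            resampled = []
            for lab in labels:
                size = int((groups == lab).sum())
                if size >= ref_n:
                    mean_he, _ = divstats.resampled_group_he(
                        g_struct, groups, lab, ref_n, config.resample_reps, config.seed
                    )
                    resampled.append(mean_he)
                else:
                    resampled.append(np.nan)
            he["resampled_mean_He"] = resampled
            he["resampled_to_n"] = ref_n
            he["n_reps"] = config.resample_reps
        gio.write_table(he, str(out / "group_he.tsv"))
        manifest.add("maf_histograms", out / "maf_histograms.tsv")
        manifest.add("group_he", out / "group_he.tsv")

    # --- LD ---------------------------------------------------------------
    if config.do_ld:
        pairs = ldcalc.intra_lg_ld(g_ld, marker_map, max_dist_cM=config.ld_max_dist_cM)
        gio.write_table(pairs, str(out / "ld_pairs.tsv"))
        profile = ldcalc.ld_decay_profile(pairs, bin_width=config.ld_bin_width_cM)
        gio.write_table(profile, str(out / "ld_decay_profile.tsv"))
        manifest.add("ld_pairs", out / "ld_pairs.tsv")
        manifest.add("ld_decay_profile", out / "ld_decay_profile.tsv")
        phys = ldcalc.physical_ld(g_ld, marker_map)
        if not phys.empty:
            gio.write_table(phys, str(out / "ld_physical_pairs.tsv"))
            manifest.add("ld_physical_pairs", out / "ld_physical_pairs.tsv")
        lg = config.heatmap_lg or str(marker_map["linkage_group"].iloc[0])
        ids, raw = ldcalc.ld_matrix(g_ld, marker_map, lg, max_markers=config.heatmap_max_markers)
        pd.DataFrame(raw, index=ids, columns=ids).to_csv(
            out / f"ld_heatmap_{lg}.tsv", sep="\t", float_format="%.6f", index_label="marker")
        manifest.add(f"ld_heatmap_{lg}", out / f"ld_heatmap_{lg}.tsv")
        if config.do_ld_kinship_corrected:
            if kin is None:
                kin = relmat.kinship(g_struct)
            ids, corrected = ldcalc.ld_matrix(
                g_ld, marker_map, lg, kin=kin, max_markers=config.heatmap_max_markers)
            pd.DataFrame(corrected, index=ids, columns=ids).to_csv(
                out / f"ld_heatmap_{lg}_kinship_corrected.tsv", sep="\t",
                float_format="%.6f", index_label="marker")
            manifest.add(f"ld_heatmap_{lg}_kinship_corrected",
                         out / f"ld_heatmap_{lg}_kinship_corrected.tsv")
        manifest.data["counts"]["ld"] = {"pairs": len(pairs)}

    # --- differentiation scan --------------------------------------------
    if config.do_fstscan:
        scan_groups = groups[~groups.isin(set(config.exclude_groups))]
        contrast = list(config.contrast) if config.contrast else sorted(scan_groups.unique())
        scan_groups = scan_groups[scan_groups.isin(contrast)]
        scan_df = diffscan.scan(g_struct, scan_groups, marker_map, contrast)
        outliers = diffscan.empirical_outliers(scan_df, config.outlier_quantile)
        scan_df["outlier_flag"] = scan_df["marker"].isin(outliers["marker"]).astype(int)
        gio.write_table(scan_df, str(out / "fst_scan.tsv"))
        gio.write_table(outliers, str(out / "fst_outliers.tsv"))
        summary = diffscan.mean_multilocus_fst(g_struct, scan_groups)
        try:
            f_stat, dfree, p_val = diffscan.anova_fst_by_lg(scan_df)
            summary.update({"anova_F": f_stat, "anova_df_between": dfree[0],
                            "anova_df_within": dfree[1], "anova_p": p_val})
        except ValueError:
            pass
        gio.write_table(pd.DataFrame([summary]), str(out / "fst_summary.tsv"))
        for name in ("fst_scan", "fst_outliers", "fst_summary"):
            manifest.add(name, out / f"{name}.tsv")
        manifest.data["counts"]["fst_scan"] = {
            "markers": len(scan_df), "outliers": len(outliers), "groups": contrast,
        }

    path = manifest.write()
    logger.info("run complete: %d artifacts, manifest at %s",
                len(manifest.data["artifacts"]), path)
    return manifest.data
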