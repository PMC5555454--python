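"""Genotype, map and group-label I/O.

The central container is :class:`GenotypeMatrix`: an accessions × markers
dosage matrix coding each biallelic genotype as the count of the
(arbitrarily designated) ALT allele — 0, 1 or 2 — with ``numpy.nan`` for
missing calls.  All downstream statistics are invariant under the
orientation flip ``g -> 2 - g``, so which allele carries the label "ALT"
never matters.

Tables are tab/comma separated text; VCF input is handled through cyvcf2
and restricted to biallelic SNPs.  ``read(write(x))`` round-trips every
container exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_TOKENS = {"NA", "-9", "", "NaN", "nan"}

__all__ = [
    "GenotypeMatrix",
    "GenotypeParseError",
    "ValidationError",
    "read_genotypes",
    "write_genotypes",
    "write_vcf",
    "read_map",
    "write_map",
    "read_groups",
    "write_groups",
    "write_table",
]


class ValidationError(ValueError):
    """An input violates a container invariant (duplicate ids, bad range...)."""


class GenotypeParseError(ValueError):
    """A cell could not be interpreted; the message names row and column."""


@dataclass
class GenotypeMatrix:
    """Accessions × markers ALT-dosage matrix.

    Parameters
    ----------
    accession_ids : list of str
        Row labels, unique, in matrix order.
    marker_ids : list of str
        Column labels, unique, in matrix order.
    dosage : ndarray of float, shape (n_accessions, n_markers)
        Entries in {0, 1, 2} or ``nan`` for missing.
    """

    accession_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray
    _acc_index: dict[str, int] = field(init=False, repr=False)
    _mark_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.accession_ids), len(self.marker_ids)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"({len(self.accession_ids)}, {len(self.marker_ids)}) ids"
            )
        for kind, ids in (("accession", self.accession_ids), ("marker", self.marker_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({x for x in ids if ids.count(x) > 1})
                raise ValidationError(f"duplicate {kind} ids: {dup[:5]}")
        called = self.dosage[~np.isnan(self.dosage)]
        if called.size and not np.isin(called, (0.0, 1.0, 2.0)).all():
            bad = called[~np.isin(called, (0.0, 1.0, 2.0))]
            raise ValidationError(f"non-{{0,1,2}} dosage values present, e.g. {bad[:3]}")
        self._acc_index = {a: i for i, a in enumerate(self.accession_ids)}
        self._mark_index = {m: j for j, m in enumerate(self.marker_ids)}

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def accession_indices(self, accessions) -> np.ndarray:
        try:
            return np.array([self._acc_index[a] for a in accessions], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown accession {exc.args[0]!r}") from None

    def marker_indices(self, markers) -> np.ndarray:
        try:
            return np.array([self._mark_index[m] for m in markers], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown marker {exc.args[0]!r}") from None

    def subset_accessions(self, accessions) -> "GenotypeMatrix":
        idx = self.accession_indices(accessions)
        return GenotypeMatrix([self.accession_ids[i] for i in idx], list(self.marker_ids), self.dosage[idx])

    def subset_markers(self, markers) -> "GenotypeMatrix":
        idx = self.marker_indices(markers)
        return GenotypeMatrix(list(self.accession_ids), [self.marker_ids[j] for j in idx], self.dosage[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.accession_ids, columns=self.marker_ids)


def _parse_cell(token: str, row_label: str, col_label: str) -> float:
    token = token.strip()
    if token in MISSING_TOKENS:
        return np.nan
    try:
        value = float(token)
    except ValueError:
        raise GenotypeParseError(
            f"cannot parse genotype {token!r} at accession {row_label!r}, marker {col_label!r}"
        ) from None
    if value not in (0.0, 1.0, 2.0):
        raise GenotypeParseError(
            f"genotype {token!r} at accession {row_label!r}, marker {col_label!r} not in {{0,1,2,NA}}"
        )
    return value


def _sniff_delimiter(path: str) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_genotypes(
    path: str,
    format: str = "table",
    delimiter: str | None = None,
    skip_multiallelic: bool = True,
) -> GenotypeMatrix:
    """Read a genotype matrix from a delimited table or a VCF.

    Table layout: first column accession id, header row of marker ids,
    cells in ``{0,1,2,NA}``.  VCF: biallelic SNP records; the GT field is
    converted to ALT dosage; multi-allelic records are skipped if
    ``skip_multiallelic`` else rejected.
    """
    if format == "table":
        return _read_genotype_table(path, delimiter)
    if format == "vcf":
        return _read_genotype_vcf(path, skip_multiallelic)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotype_table(path: str, delimiter: str | None) -> GenotypeMatrix:
    sep = delimiter or _sniff_delimiter(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows:
        raise GenotypeParseError(f"{path}: empty genotype table")
    header = [c.strip() for c in rows[0]]
    marker_ids = header[1:]
    accession_ids: list[str] = []
    data = np.empty((len(rows) - 1, len(marker_ids)))
    for i, row in enumerate(rows[1:]):
        if len(row) != len(header):
            raise GenotypeParseError(f"{path}: row {i + 2} has {len(row)} fields, expected {len(header)}")
        accession_ids.append(row[0].strip())
        for j, token in enumerate(row[1:]):
            data[i, j] = _parse_cell(token, row[0], marker_ids[j])
    return GenotypeMatrix(accession_ids, marker_ids, data)


def _read_genotype_vcf(path: str, skip_multiallelic: bool) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    accession_ids = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            if skip_multiallelic:
                continue
            raise ValidationError(f"multi-allelic record at {variant.CHROM}:{variant.POS}")
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(variant.gt_types, dtype=float)
        dose = np.where(gt == 3, 2.0, gt)
        dose[gt == 2] = np.nan
        marker_ids.append(variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}")
        columns.append(dose)
    vcf.close()
    data = np.column_stack(columns) if columns else np.empty((len(accession_ids), 0))
    return GenotypeMatrix(accession_ids, marker_ids, data)


def write_genotypes(genotypes: GenotypeMatrix, path: str, delimiter: str = "\t") -> None:
    """Write a genotype table (accessions in rows, integer dosages, NA missing)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["accession", *genotypes.marker_ids])
        for i, acc in enumerate(genotypes.accession_ids):
            row = genotypes.dosage[i]
            writer.writerow([acc] + ["NA" if np.isnan(v) else str(int(v)) for v in row])


def write_vcf(genotypes: GenotypeMatrix, marker_map: pd.DataFrame, path: str) -> None:
    """Write genotypes as a minimal biallelic VCF (contig = linkage group).

    Positions come from the map's cM column scaled to an integer ordinate so
    that records remain sorted; alleles are placeholders (A ref / T alt) since
    the dosage coding carries no nucleotide information.
    """
    mm = marker_map.set_index("marker")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for lg in pd.unique(mm["linkage_group"]):
            fh.write(f"##contig=<ID={lg}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genotypes.accession_ids) + "\n")
        gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        records = []
        for j, m in enumerate(genotypes.marker_ids):
            if m not in mm.index:
                continue
            lg = mm.loc[m, "linkage_group"]
            pos = int(round(float(mm.loc[m, "cM"]) * 1e4)) + 1
            records.append((str(lg), pos, j, m))
        records.sort(key=lambda r: (r[0], r[1]))
        for lg, pos, j, m in records:
            calls = "\t".join(
                "./." if np.isnan(v) else gt_code[v] for v in genotypes.dosage[:, j]
            )
            fh.write(f"{lg}\t{pos}\t{m}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def read_map(
    path: str,
    column_map: dict[str, str] | None = None,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a marker map table.

    Expected columns ``marker, linkage_group, cM`` and optionally
    ``scaffold, bp``; ``column_map`` renames nonstandard headers
    (e.g. ``{"LG": "linkage_group"}``).  Returns a DataFrame with one row
    per marker; ``scaffold``/``bp`` are NaN where absent.
    """
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    required = {"marker", "linkage_group", "cM"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"map file missing columns: {sorted(missing)}")
    df["marker"] = df["marker"].astype(str)
    df["linkage_group"] = df["linkage_group"].astype(str)
    df["cM"] = df["cM"].astype(float)
    if df["marker"].duplicated().any():
        dup = df["marker"][df["marker"].duplicated()].tolist()
        raise ValidationError(f"duplicate markers in map: {dup[:5]}")
    if (df["cM"] < 0).any():
        bad = df.loc[df["cM"] < 0, "marker"].tolist()
        raise ValidationError(f"negative cM positions for markers: {bad[:5]}")
    if "scaffold" not in df.columns:
        df["scaffold"] = pd.NA
    if "bp" not in df.columns:
        df["bp"] = np.nan
    has_scaffold = df["scaffold"].notna()
    has_bp = df["bp"].notna()
    if (has_scaffold != has_bp).any():
        bad = df.loc[has_scaffold != has_bp, "marker"].tolist()
        raise ValidationError(f"scaffold and bp must be given together; offending markers: {bad[:5]}")
    if (df.loc[has_bp, "bp"] < 0).any():
        raise ValidationError("negative bp positions in map")
    return df[["marker", "linkage_group", "cM", "scaffold", "bp"]]


def write_map(marker_map: pd.DataFrame, path: str) -> None:
    out = marker_map.copy()
    out["bp"] = out["bp"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out["scaffold"] = out["scaffold"].map(lambda v: "" if pd.isna(v) else str(v))
    out.to_csv(path, sep="\t", index=False)


def read_groups(path: str, delimiter: str | None = None) -> pd.Series:
    """Read a two-column ``accession<TAB>group`` table as a Series."""
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValidationError("group file needs two columns: accession, group")
    acc_col, grp_col = df.columns[:2]
    ser = pd.Series(df[grp_col].astype(str).values, index=df[acc_col].astype(str).values, name="group")
    if ser.index.duplicated().any():
        dup = ser.index[ser.index.duplicated()].tolist()
        raise ValidationError(f"accessions assigned twice: {dup[:5]}")
    return ser


def write_groups(groups: pd.Series, path: str) -> None:
    pd.DataFrame({"accession": groups.index, "group": groups.values}).to_csv(path, sep="\t", index=False)


def validate_groups(groups: pd.Series, genotypes: GenotypeMatrix) -> None:
    """Every assigned accession must exist in the paired genotype matrix."""
    unknown = [a for a in groups.index if a not in genotypes._acc_index]
    if unknown:
        raise ValidationError(f"group assignment references unknown accessions: {unknown[:5]}")


def write_table(records, path: str, float_format: str = "%.6f") -> None:
    """Write a result table as TSV with a header and fixed float precision.

    ``records`` is a DataFrame or a non-empty list of dicts.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records))
    if records.empty:
        raise ValueError("refusing to write an empty result table")
    records.to_csv(path, sep="\t", index=False, float_format=float_format)
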