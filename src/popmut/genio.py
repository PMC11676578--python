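"""Input/output for the formats the pipeline touches.

SNP genotypes travel as VCF 4.2 (read through cyvcf2, written by a small
GT-only emitter); population maps, STR panels and STR genotype tables are
tab-separated text. All coordinates are 1-based inclusive, VCF-style,
including the STR panel's start/end columns. Reading is gzip-transparent
(cyvcf2 natively; TSVs via pandas' compression inference).

Parse failures raise :class:`~popmut.errors.FormatError` with as much
location detail as the underlying parser exposes (cyvcf2 does not report
line numbers for malformed records, so VCF errors carry its message only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import FormatError, ParameterError

log = logging.getLogger(__name__)

#: Sentinel for a missing diploid genotype call in dosage matrices.
MISSING: int = -1


class Locus(NamedTuple):
    """A biallelic SNP site keyed by position with its two alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class SnpGenotypeMatrix:
    """Samples x biallelic-SNP loci, stored as alternate-allele dosage.

    ``genotypes[i, j]`` is the number of alternate alleles (0, 1, 2) that
    sample ``sample_ids[i]`` carries at ``loci[j]``, or :data:`MISSING`.
    Phase is never used by any downstream analysis, so it is not retained.
    """

    sample_ids: list[str]
    loci: list[Locus]
    genotypes: np.ndarray  # (n_samples, n_loci) int8

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.loci)):
            raise ParameterError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ParameterError("duplicate sample ids")
        positions = {(l.chrom, l.pos) for l in self.loci}
        if len(positions) != len(self.loci):
            raise ParameterError("duplicate (chromosome, position) among loci")
        valid = np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.genotypes[~valid])
            raise ParameterError(f"dosages outside {{0,1,2,missing}}: {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def subset_samples(self, ids: Sequence[str]) -> "SnpGenotypeMatrix":
        idx = [self.sample_index(s) for s in ids]
        return SnpGenotypeMatrix(list(ids), list(self.loci), self.genotypes[idx])

    def subset_loci(self, mask: np.ndarray) -> "SnpGenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        loci = [l for l, keep in zip(self.loci, mask) if keep]
        return SnpGenotypeMatrix(list(self.sample_ids), loci, self.genotypes[:, mask])


@dataclass
class PopulationMap:
    """Assignment of each sample to exactly one population label."""

    assignments: dict[str, str]

    def population_of(self, sample_id: str) -> str:
        try:
            return self.assignments[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in population map") from None

    def samples(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p)
        return list(seen)


@dataclass
class StrPanel:
    """Definition of the STR loci to genotype: where they are and what repeats.

    One row per locus: locus_id, chrom, start, end (1-based inclusive),
    motif_length, motif, source_panel.
    """

    df: pd.DataFrame

    REQUIRED = ("locus_id", "chrom", "start", "end", "motif_length", "motif")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise FormatError(f"STR panel missing columns: {missing}")
        if "source_panel" not in self.df.columns:
            self.df = self.df.assign(source_panel="unspecified")
        if self.df["locus_id"].duplicated().any():
            dup = self.df.loc[self.df["locus_id"].duplicated(), "locus_id"].tolist()
            raise FormatError(f"duplicate STR locus ids: {dup}")
        bad = self.df[self.df["start"] >= self.df["end"]]
        if len(bad):
            raise FormatError(
                f"start >= end for loci: {bad['locus_id'].tolist()}"
            )
        if (self.df["motif_length"] < 1).any():
            raise FormatError("motif_length must be >= 1")

    @property
    def locus_ids(self) -> list[str]:
        return self.df["locus_id"].tolist()

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class StrGenotypeTable:
    """Long-format STR calls: one row per (sample, locus).

    Columns: sample, locus_id, allele1_repeats, allele2_repeats (nullable
    integer repeat counts), likelihood (log-likelihood of the call, as
    GangSTR-style callers report it).
    """

    df: pd.DataFrame

    COLUMNS = ("sample", "locus_id", "allele1_repeats", "allele2_repeats", "likelihood")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"STR genotype table missing columns: {missing}")
        if self.df.duplicated(subset=["sample", "locus_id"]).any():
            raise FormatError("duplicate (sample, locus_id) rows in STR table")
        for col in ("allele1_repeats", "allele2_repeats"):
            vals = self.df[col]
            if ((vals.dropna() < 1)).any():
                raise FormatError(f"{col}: repeat counts must be >= 1 when present")

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique().tolist())

    @property
    def locus_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for l in self.df["locus_id"]:
            seen.setdefault(l)
        return list(seen)


# ---------------------------------------------------------------------------
# VCF


def _is_snp(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref != "*" and alt != "*"


def read_vcf(path: str | Path) -> SnpGenotypeMatrix:
    """Read a VCF into a dosage matrix, keeping only biallelic SNPs.

    Multiallelic and non-SNP records are skipped (count logged); a
    half-missing diploid call is treated as fully missing, since the
    analyses here all need both alleles.
    """
    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    loci: list[Locus] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    try:
        for var in vcf:
            if len(var.ALT) != 1 or not _is_snp(var.REF, var.ALT[0]):
                n_skipped += 1
                continue
            dos = np.empty(len(samples), dtype=np.int8)
            for k, call in enumerate(var.genotypes):
                alleles = call[:-1]  # last element is the phase flag
                if len(alleles) < 2 or min(alleles) < 0:
                    dos[k] = MISSING
                else:
                    dos[k] = int(alleles[0] > 0) + int(alleles[1] > 0)
            loci.append(Locus(var.CHROM, var.POS, var.REF, var.ALT[0]))
            rows.append(dos)
    except Exception as exc:
        raise FormatError(f"malformed record in {path}: {exc}") from exc
    if n_skipped:
        log.info("read_vcf(%s): skipped %d multiallelic/non-SNP records", path, n_skipped)
    genotypes = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return SnpGenotypeMatrix(samples, loci, genotypes)


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: SnpGenotypeMatrix, path: str | Path) -> None:
    """Write a dosage matrix as minimal VCF 4.2 with a GT-only FORMAT."""
    path = Path(path)
    chroms: dict[str, None] = {}
    for l in matrix.loci:
        chroms.setdefault(l.chrom)
    lines = ["##fileformat=VCFv4.2", "##source=popmut"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.sample_ids)
    )
    for j, locus in enumerate(matrix.loci):
        gts = "\t".join(_GT_STRING[int(d)] for d in matrix.genotypes[:, j])
        lines.append(
            f"{locus.chrom}\t{locus.pos}\t.\t{locus.ref}\t{locus.alt}\t.\t.\t.\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")


def merge_on_shared_loci(
    a: SnpGenotypeMatrix, b: SnpGenotypeMatrix
) -> SnpGenotypeMatrix:
    """Merge two sample sets on their shared loci, dropping incomplete loci.

    Loci are matched on (chromosome, position). When the two files disagree
    on allele order (a's ref is b's alt and vice versa) b's dosages are
    recoded to a's orientation; any other allele disagreement drops the
    locus (strand flips are never attempted — A/T and C/G sites would be
    ambiguous). Loci carrying any missing genotype in the merged matrix are
    removed, mirroring the complete-cases requirement of the downstream
    polarization step.
    """
    overlap = set(a.sample_ids) & set(b.sample_ids)
    if overlap:
        raise ParameterError(f"sample sets must be disjoint; shared: {sorted(overlap)}")
    b_index = {(l.chrom, l.pos): j for j, l in enumerate(b.loci)}
    loci: list[Locus] = []
    cols_a: list[int] = []
    cols_b: list[int] = []
    flip_b: list[bool] = []
    n_irreconcilable = 0
    for i, la in enumerate(a.loci):
        j = b_index.get((la.chrom, la.pos))
        if j is None:
            continue
        lb = b.loci[j]
        if (la.ref, la.alt) == (lb.ref, lb.alt):
            flip = False
        elif (la.ref, la.alt) == (lb.alt, lb.ref):
            flip = True
        else:
            n_irreconcilable += 1
            continue
        loci.append(la)
        cols_a.append(i)
        cols_b.append(j)
        flip_b.append(flip)
    if n_irreconcilable:
        log.info(
            "merge_on_shared_loci: dropped %d loci with irreconcilable alleles",
            n_irreconcilable,
        )
    ga = a.genotypes[:, cols_a]
    gb = b.genotypes[:, cols_b].copy()
    if flip_b:
        flip_arr = np.array(flip_b)
        missing = gb[:, flip_arr] == MISSING
        gb[:, flip_arr] = 2 - gb[:, flip_arr]
        gb[:, flip_arr][missing] = MISSING
    merged = np.vstack([ga, gb])
    complete = (merged != MISSING).all(axis=0)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("merge_on_shared_loci: dropped %d loci with missing genotypes", n_dropped)
    loci = [l for l, keep in zip(loci, complete) if keep]
    return SnpGenotypeMatrix(
        a.sample_ids + b.sample_ids, loci, merged[:, complete]
    )


# ---------------------------------------------------------------------------
# TSVs


def read_popmap(path: str | Path) -> PopulationMap:
    """Read a two-column sample<TAB>population map (no header)."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["sample", "population"],
            dtype=str, comment="#",
        )
    except Exception as exc:
        raise FormatError(f"cannot parse population map {path}: {exc}") from exc
    if df.isna().any().any():
        raise FormatError(f"population map {path}: incomplete rows")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise FormatError(f"population map {path}: duplicate samples {dup}")
    return PopulationMap(dict(zip(df["sample"], df["population"])))


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    pd.DataFrame(popmap.assignments.items()).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_str_panel(path: str | Path) -> StrPanel:
    """Read an STR panel TSV (header row; 1-based inclusive start/end)."""
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#",
            dtype={"locus_id": str, "chrom": str, "motif": str},
        )
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        df["motif_length"] = df["motif_length"].astype(int)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse STR panel {path}: {exc}") from exc
    return StrPanel(df)


def write_str_panel(panel: StrPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# STR panel; start/end are 1-based inclusive\n")
        panel.df.to_csv(fh, sep="\t", index=False)


def read_str_table(path: str | Path) -> StrGenotypeTable:
    """Read a long-format STR genotype TSV (header row, NA for no-calls)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample": str, "locus_id": str})
        for col in ("allele1_repeats", "allele2_repeats"):
            df[col] = df[col].astype("Int64")  # rejects non-integer values
        df["likelihood"] = df["likelihood"].astype(float)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse STR genotype table {path}: {exc}") from exc
    return StrGenotypeTable(df)


def write_str_table(table: StrGenotypeTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)
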