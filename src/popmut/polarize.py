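"""Outgroup polarization: designate ancestral alleles and recode to derived dosage.

An outgroup lineage (for canids, e.g. basenji or gray wolf) external to the
study populations defines the ancestral state at each site. Only loci where
*every* outgroup individual is homozygous for the *same* allele are kept —
a single outgroup heterozygote is enough to exclude a locus, the strictest
reading that minimizes pre-split variation persisting into the comparison.
The shared outgroup allele becomes the ancestral allele; study genotypes
are recoded as derived-allele dosage, flipping loci where the outgroup
carried the file's alternate allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .errors import MissingDataError, ParameterError
from .genio import MISSING, SnpGenotypeMatrix

__all__ = ["PolarizedLocus", "PolarizedDataset", "polarize", "pair_informative"]


class PolarizedLocus(NamedTuple):
    chrom: str
    pos: int
    ancestral: str
    derived: str


@dataclass
class PolarizedDataset:
    """Study samples x polarized loci, genotypes as derived-allele dosage.

    Invariant by construction: at every retained locus every outgroup
    individual has derived dosage 0, and no genotype is missing.
    """

    sample_ids: list[str]
    loci: list[PolarizedLocus]
    genotypes: np.ndarray  # (n_study_samples, n_loci) int8, values {0,1,2}
    outgroup_ids: list[str]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def to_vcf(self, path: str | Path) -> None:
        """Write with the ancestral allele as REF and an AA INFO tag."""
        path = Path(path)
        chroms: dict[str, None] = {}
        for l in self.loci:
            chroms.setdefault(l.chrom)
        lines = ["##fileformat=VCFv4.2", "##source=popmut-polarize"]
        lines += [f"##contig=<ID={c}>" for c in chroms]
        lines.append(
            '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">'
        )
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(self.sample_ids)
        )
        gt_string = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, locus in enumerate(self.loci):
            gts = "\t".join(gt_string[int(d)] for d in self.genotypes[:, j])
            lines.append(
                f"{locus.chrom}\t{locus.pos}\t.\t{locus.ancestral}\t{locus.derived}"
                f"\t.\t.\tAA={locus.ancestral}\tGT\t{gts}"
            )
        path.write_text("\n".join(lines) + "\n")


def polarize(
    matrix: SnpGenotypeMatrix,
    outgroup_ids: Sequence[str],
    study_ids: Sequence[str],
) -> PolarizedDataset:
    """Retain outgroup-homozygous loci and recode study genotypes as derived dosage.

    A locus is retained iff all outgroup individuals are homozygous for the
    same allele (all dosage 0 or all dosage 2). Where the shared outgroup
    allele is the file's alternate, the ancestral/derived roles are swapped
    and each study dosage d becomes 2 - d (ancestral-as-reference recode).

    Genotypes must be complete over the outgroup and study samples — run
    the merge/missingness filter first; missing calls raise
    :class:`MissingDataError`.
    """
    if not outgroup_ids:
        raise ParameterError("outgroup_ids is empty")
    if not study_ids:
        raise ParameterError("study_ids is empty")
    overlap = set(outgroup_ids) & set(study_ids)
    if overlap:
        raise ParameterError(f"outgroup and study ids overlap: {sorted(overlap)}")

    out_idx = [matrix.sample_index(s) for s in outgroup_ids]
    study_idx = [matrix.sample_index(s) for s in study_ids]
    g_out = matrix.genotypes[out_idx]
    g_study = matrix.genotypes[study_idx]
    if (g_out == MISSING).any() or (g_study == MISSING).any():
        raise MissingDataError(
            "missing genotypes present; apply the missingness filter before polarizing"
        )

    anc_is_ref = (g_out == 0).all(axis=0)
    anc_is_alt = (g_out == 2).all(axis=0)
    keep = anc_is_ref | anc_is_alt

    genotypes = g_study[:, keep].copy()
    swap = anc_is_alt[keep]
    genotypes[:, swap] = 2 - genotypes[:, swap]

    loci = []
    for j in np.flatnonzero(keep):
        l = matrix.loci[j]
        if anc_is_ref[j]:
            loci.append(PolarizedLocus(l.chrom, l.pos, l.ref, l.alt))
        else:
            loci.append(PolarizedLocus(l.chrom, l.pos, l.alt, l.ref))
    return PolarizedDataset(list(study_ids), loci, genotypes, list(outgroup_ids))


def pair_informative(g_a: int, g_b: int) -> bool:
    """True iff the four alleles of a pair include both states.

    Among the two diploid genotypes (derived dosages ``g_a``, ``g_b``) at
    least one ancestral and at least one derived allele must be present,
    i.e. 0 < g_a + g_b < 4. Pairs failing this carry no information about
    which individual accumulated more derived alleles.
    """
    for name, g in (("g_a", g_a), ("g_b", g_b)):
        if g not in (0, 1, 2):
            raise ParameterError(f"{name} must be a dosage in {{0,1,2}}, got {g}")
    return 0 < g_a + g_b < 4
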