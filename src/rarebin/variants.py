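"""Genotype and phenotype input, and per-group allele frequencies.

Genotypes are held as a dense matrix of allele indices: ``calls`` has
shape ``(n_samples, n_loci, 2)`` with ``-1`` marking a missing allele.
Multiallelic VCF records are kept as a single polyallelic locus (never
split into biallelic records), because the rarity rule operates on the
full allele set of one locus.  Phasing is ignored: ``|`` and ``/``
separators are treated identically, as burden counting is phase-free.

Allele frequencies are computed separately for the case and the control
group, with observed-allele denominators (missing alleles are excluded).
Every allele of the locus appears in each group's frequency record, with
frequency 0.0 when the group carries no copy — a locus fixed in one
group but polymorphic in the other is therefore still visible to the
rarity rules, which is what drives pairwise population comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("case", "control")

_CASE_WORDS = {"1", "case", "cases", "affected"}
_CONTROL_WORDS = {"0", "control", "controls", "unaffected"}

MISSING = -1


class VariantInputError(Exception):
    """Raised for malformed genotype or phenotype input."""


@dataclass(frozen=True)
class Locus:
    """One genomic position with its ordered allele list (reference first)."""

    chromosome: str
    position: int
    alleles: tuple

    @property
    def key(self) -> tuple:
        return (self.chromosome, self.position)


@dataclass
class GenotypeMatrix:
    sample_ids: list
    loci: list
    calls: np.ndarray  # (n_samples, n_loci, 2) int16 allele indices, -1 missing

    def __post_init__(self):
        n_s, n_l = len(self.sample_ids), len(self.loci)
        if self.calls.shape != (n_s, n_l, 2):
            raise VariantInputError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{n_s} samples x {n_l} loci")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)


@dataclass
class PhenotypeAssignment:
    """Mapping sample_id -> 'case' | 'control'."""

    assignment: dict

    @property
    def cases(self) -> list:
        return [s for s, g in self.assignment.items() if g == "case"]

    @property
    def controls(self) -> list:
        return [s for s, g in self.assignment.items() if g == "control"]

    def group_of(self, sample_id: str):
        return self.assignment.get(sample_id)

    def validate_two_group(self) -> None:
        if not self.cases or not self.controls:
            raise VariantInputError(
                "two-group analysis needs both cases and controls "
                f"(got {len(self.cases)} cases, {len(self.controls)} controls)")


@dataclass
class GroupFrequencyTable:
    """Per locus, per group: allele -> relative frequency among observed alleles.

    ``freqs[i][group]`` is a dict over the full allele list of locus *i*
    (zeros included); it is empty when the group has no observed allele
    at that locus.
    """

    loci: list
    freqs: list = field(default_factory=list)  # list of {group: {allele: f}}

    def case(self, i: int) -> dict:
        return self.freqs[i]["case"]

    def control(self, i: int) -> dict:
        return self.freqs[i]["control"]


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF (v4.x, optionally bgzipped) into a :class:`GenotypeMatrix`.

    One locus per record; multiallelic records stay polyallelic.  Missing
    genotypes (``./.``) are preserved; half-calls keep the one observed
    allele with the other slot missing.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise VariantInputError(f"{path}: VCF has no sample columns")
    loci: list[Locus] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        where = f"{path}:{var.CHROM}:{var.POS}"
        if "GT" not in (var.FORMAT or ()):
            raise VariantInputError(f"{where}: record has no GT field")
        alleles = (var.REF, *var.ALT)
        col = np.full((len(samples), 2), MISSING, dtype=np.int16)
        try:
            gts = var.genotypes
        except Exception as exc:  # pragma: no cover - cyvcf2 internal
            raise VariantInputError(f"{where}: malformed genotypes ({exc})")
        for s, row in enumerate(gts):
            allele_part = row[:-1]  # last entry is the phased flag
            for slot, a in enumerate(allele_part[:2]):
                if a is None or a < 0:
                    continue
                if a >= len(alleles):
                    raise VariantInputError(
                        f"{where}: sample {samples[s]} calls allele index {a} "
                        f"but record has {len(alleles)} alleles")
                col[s, slot] = a
        loci.append(Locus(str(var.CHROM), int(var.POS), alleles))
        columns.append(col)
    calls = (np.stack(columns, axis=1) if columns
             else np.empty((len(samples), 0, 2), dtype=np.int16))
    return GenotypeMatrix(samples, loci, calls)


def read_phenotypes(path, sep: str | None = None) -> PhenotypeAssignment:
    """Read a two-column sample/status table (TSV by default, CSV for .csv).

    Status vocabulary: ``0``/``control`` vs ``1``/``case`` (case-insensitive).
    Any other status is an error naming the offending row.  Both groups
    must be non-empty for a two-group analysis.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    if table.shape[1] < 2:
        raise VariantInputError(
            f"{path}: expected two columns (sample_id, status)")
    assignment: dict[str, str] = {}
    for idx, row in table.iterrows():
        sample, status = str(row.iloc[0]).strip(), str(row.iloc[1]).strip().lower()
        if status in _CASE_WORDS:
            assignment[sample] = "case"
        elif status in _CONTROL_WORDS:
            assignment[sample] = "control"
        else:
            raise VariantInputError(
                f"{path} row {idx + 2}: unrecognized status {row.iloc[1]!r} "
                f"for sample {sample!r}")
    phen = PhenotypeAssignment(assignment)
    phen.validate_two_group()
    return phen


def sample_groups(matrix: GenotypeMatrix,
                  phen: PhenotypeAssignment) -> np.ndarray:
    """Per-sample group codes: 1 = case, 0 = control, -1 = dropped.

    Samples genotyped but unphenotyped are dropped with a warning;
    phenotyped samples absent from the genotypes are reported and ignored.
    """
    codes = np.full(matrix.n_samples, -1, dtype=np.int8)
    for i, sid in enumerate(matrix.sample_ids):
        grp = phen.group_of(sid)
        if grp == "case":
            codes[i] = 1
        elif grp == "control":
            codes[i] = 0
    dropped = [s for s, c in zip(matrix.sample_ids, codes) if c < 0]
    if dropped:
        logger.warning("dropping %d unphenotyped sample(s): %s",
                       len(dropped), ", ".join(dropped[:10]))
    extra = set(phen.assignment) - set(matrix.sample_ids)
    if extra:
        logger.warning("%d phenotyped sample(s) absent from genotypes: %s",
                       len(extra), ", ".join(sorted(extra)[:10]))
    if not (codes == 1).any() or not (codes == 0).any():
        raise VariantInputError(
            "after matching genotypes to phenotypes, one group is empty")
    return codes


def group_allele_frequencies(matrix: GenotypeMatrix,
                             phen: PhenotypeAssignment) -> GroupFrequencyTable:
    """Observed-allele frequencies per locus, separately per phenotype group."""
    codes = sample_groups(matrix, phen)
    table = GroupFrequencyTable(loci=list(matrix.loci))
    masks = {"case": codes == 1, "control": codes == 0}
    for i, locus in enumerate(matrix.loci):
        per_group: dict[str, dict[str, float]] = {}
        for grp, mask in masks.items():
            flat = matrix.calls[mask, i, :].ravel()
            observed = flat[flat >= 0]
            if observed.size == 0:
                per_group[grp] = {}
                continue
            counts = np.bincount(observed, minlength=len(locus.alleles))
            total = counts.sum()
            per_group[grp] = {a: counts[k] / total
                              for k, a in enumerate(locus.alleles)}
        table.freqs.append(per_group)
    return table


def allele_counts(matrix: GenotypeMatrix, codes: np.ndarray,
                  locus_index: int) -> dict:
    """Raw observed allele counts per group for one locus (testing aid)."""
    locus = matrix.loci[locus_index]
    out = {}
    for grp, code in (("case", 1), ("control", 0)):
        flat = matrix.calls[codes == code, locus_index, :].ravel()
        observed = flat[flat >= 0]
        counts = np.bincount(observed, minlength=len(locus.alleles))
        out[grp] = {a: int(counts[k]) for k, a in enumerate(locus.alleles)}
    return out


def write_vcf(matrix: GenotypeMatrix, path,
              source_tag: str = "rarebin") -> None:
    """Write a minimal GT-only VCF v4.2 (plain text, deterministic)."""
    loci_order = sorted(range(matrix.n_loci),
                        key=lambda i: (matrix.loci[i].chromosome,
                                       matrix.loci[i].position))
    chroms = []
    for i in loci_order:
        c = matrix.loci[i].chromosome
        if c not in chroms:
            chroms.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source_tag}\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        for i in loci_order:
            locus = matrix.loci[i]
            alt = ",".join(locus.alleles[1:]) if len(locus.alleles) > 1 else "."
            gts = []
            for s in range(matrix.n_samples):
                a, b = matrix.calls[s, i, :]
                gts.append("{}/{}".format("." if a < 0 else int(a),
                                          "." if b < 0 else int(b)))
            fh.write(f"{locus.chromosome}\t{locus.position}\t.\t"
                     f"{locus.alleles[0]}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def write_phenotypes(phen: PhenotypeAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tstatus\n")
        for sid, grp in phen.assignment.items():
            fh.write(f"{sid}\t{1 if grp == 'case' else 0}\n")
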