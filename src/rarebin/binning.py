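"""Rarity calls, feature-bin construction and per-individual burden matrices.

The collapsing model
--------------------

At each locus the minor allele frequency (MAF) is the frequency of the
*second most frequent* allele, computed separately in the case and the
control group.  A locus is *rare* — and its non-major alleles are binned
— when its MAF is strictly below the configured threshold in at least
one group ("rare in either group").  All non-major alleles of a rare
locus are binned identically; when both groups trigger, each group
contributes its own non-major alleles and the union is binned.  Loci
that are common in both groups are not binned and play no further part.

Bins are genomic features drawn from a knowledge store: gene bins
(region boundaries), pathway bins (the deduplicated union of the member
genes' rare loci), and intergenic catch-all windows — fixed
non-overlapping tiles of ``intergenic_window`` bp, counted from position
1 of each chromosome, that collect rare loci not assigned to any
requested gene/pathway bin.  Bins may share loci; non-independence
between bins is accepted by design.

A sample's *burden* in a bin is the additive count of binned alleles it
carries over the bin's loci (0, 1 or 2 per locus for diploids; a missing
call contributes 0).

Boundary behaviour that changes results, stated prominently:

* the rarity inequality is **strict** — MAF equal to the threshold is
  *not* binned;
* ties for the second most frequent allele: the tied frequency is the
  MAF regardless of which allele ranks second; a 50/50 tie for the major
  allele is broken lexicographically (and logged);
* alleles observed in neither group are never binned, so loci
  monomorphic in both groups are excluded before binning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .knowledge import KnowledgeBase, KnowledgeError
from .variants import GenotypeMatrix, GroupFrequencyTable, GROUPS

logger = logging.getLogger(__name__)

FEATURE_TYPES = ("gene", "pathway", "intergenic")
_FEATURE_ORDER = {ft: i for i, ft in enumerate(FEATURE_TYPES)}


class BinningError(Exception):
    """Raised for unsatisfiable binning requests."""


@dataclass
class BinningConfig:
    """Knobs of a binning run.

    maf_threshold
        Rarity threshold on the per-group MAF (strict ``<``); typical
        values 0.02–0.10.
    feature_types
        Subset of ``{"gene", "pathway", "intergenic"}`` requested.
    intergenic_window
        Width in bp of the catch-all windows (default 50 kb).
    subfeature_filter
        ``"exon"``/``"intron"``-style splitting of bins (``None`` off).
    prediction_split
        Split bins by functional-prediction category.
    """

    maf_threshold: float = 0.05
    feature_types: tuple = ("gene", "pathway", "intergenic")
    intergenic_window: int = 50_000
    subfeature_filter: str | None = None
    prediction_split: bool = False

    def __post_init__(self):
        if not 0.0 <= self.maf_threshold <= 1.0:
            raise BinningError("maf_threshold must lie in [0, 1]")
        if self.intergenic_window < 1:
            raise BinningError("intergenic_window must be >= 1")
        bad = set(self.feature_types) - set(FEATURE_TYPES)
        if bad:
            raise BinningError(f"unknown feature types {sorted(bad)}")
        if self.subfeature_filter not in (None, "none", "exon", "intron"):
            raise BinningError(
                f"unknown subfeature filter {self.subfeature_filter!r}")
        if self.subfeature_filter == "none":
            self.subfeature_filter = None


@dataclass(frozen=True)
class LocusRarity:
    """Rarity decision for one locus."""

    maf: dict  # group -> MAF (None when group unobserved)
    rare: bool
    binned_alleles: frozenset  # allele symbols contributing to bins


@dataclass(frozen=True)
class BinDefinition:
    bin_id: str
    feature_type: str
    locus_indices: tuple  # indices into the genotype matrix loci
    loci: tuple           # matching (chromosome, position) pairs
    provenance: tuple     # region/group ids backing this bin

    @property
    def n_loci(self) -> int:
        return len(self.locus_indices)

    def span(self) -> tuple:
        chrom = self.loci[0][0]
        positions = [p for _, p in self.loci]
        return (chrom, min(positions), max(positions))


@dataclass
class BinMatrix:
    """bins x samples table of summed minor-allele counts."""

    bins: list
    sample_ids: list
    values: np.ndarray  # (n_bins, n_samples) int32

    @property
    def locus_counts(self) -> np.ndarray:
        return np.array([b.n_loci for b in self.bins], dtype=np.int64)

    @property
    def totals(self) -> np.ndarray:
        """Total variant count per bin (sum of entries across samples)."""
        return self.values.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.T, index=pd.Index(self.sample_ids,
                                                          name="sample_id"),
                            columns=[b.bin_id for b in self.bins])

    def summary_frame(self, codes: np.ndarray | None = None) -> pd.DataFrame:
        rows = []
        for b, row in zip(self.bins, self.values):
            chrom, lo, hi = b.span()
            rec = {"bin_id": b.bin_id, "feature_type": b.feature_type,
                   "chromosome": chrom, "span_start": lo, "span_stop": hi,
                   "n_loci": b.n_loci, "total_variants": int(row.sum())}
            if codes is not None:
                rec["case_variants"] = int(row[codes == 1].sum())
                rec["control_variants"] = int(row[codes == 0].sum())
            rows.append(rec)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rarity
# ---------------------------------------------------------------------------

def minor_allele_frequency(freqs: dict) -> float:
    """Frequency of the second most frequent allele in one group.

    0.0 when only one allele is present.  Ties: the second-ranked
    frequency is returned whichever allele carries it.
    """
    if not freqs:
        raise BinningError("locus unobserved in this group: no MAF")
    if len(freqs) == 1:
        return 0.0
    ranked = sorted(freqs.values(), reverse=True)
    return float(ranked[1])


def major_allele(freqs: dict) -> str:
    """Most frequent allele; 50/50 ties break lexicographically (logged)."""
    if not freqs:
        raise BinningError("locus unobserved in this group: no major allele")
    top = max(freqs.values())
    tied = sorted(a for a, f in freqs.items() if f == top)
    if len(tied) > 1:
        logger.debug("major-allele tie among %s; choosing %r", tied, tied[0])
    return tied[0]


def classify_rarity(case_freqs: dict, control_freqs: dict,
                    threshold: float) -> LocusRarity:
    """Apply the either-group rarity rule to one locus.

    Rare iff MAF < threshold (strict) in the case group OR the control
    group.  The binned-allele set is the union, over triggering groups,
    of that group's non-major alleles — minus alleles with zero observed
    frequency in *both* groups (nothing to count).  A locus whose binned
    set comes out empty is reported as not rare.
    """
    if not case_freqs and not control_freqs:
        raise BinningError("locus unobserved in both groups")
    maf = {"case": minor_allele_frequency(case_freqs) if case_freqs else None,
           "control": (minor_allele_frequency(control_freqs)
                       if control_freqs else None)}
    binned: set = set()
    for grp, freqs in (("case", case_freqs), ("control", control_freqs)):
        if not freqs or maf[grp] is None:
            continue
        if maf[grp] < threshold:
            maj = major_allele(freqs)
            binned.update(a for a in freqs if a != maj)
    # an allele absent from both groups is not a variant here
    observed = {a for freqs in (case_freqs, control_freqs)
                for a, f in freqs.items() if f > 0.0}
    binned &= observed
    return LocusRarity(maf=maf, rare=bool(binned),
                       binned_alleles=frozenset(binned))


def classify_all(freq_table: GroupFrequencyTable,
                 threshold: float) -> list:
    return [classify_rarity(freq_table.case(i), freq_table.control(i),
                            threshold)
            for i in range(len(freq_table.loci))]


# ---------------------------------------------------------------------------
# bin construction
# ---------------------------------------------------------------------------

def intergenic_window_index(position: int, window: int) -> int:
    """0-based index of the fixed tile [k*W+1, (k+1)*W] holding *position*."""
    return (position - 1) // window


def _sort_bins(bins: list) -> list:
    return sorted(bins, key=lambda b: (_FEATURE_ORDER.get(b.feature_type, 99),
                                       b.span()[0], b.span()[1], b.bin_id))


def build_feature_bins(loci: list, rarity: list, kb: KnowledgeBase | None,
                       config: BinningConfig) -> list:
    """Assemble gene / pathway / intergenic bins over the rare loci.

    ``loci`` and ``rarity`` are parallel lists (one entry per genotype
    matrix locus).  Feature selection fully drives assignment: a rare
    locus inside a gene still falls to an intergenic window when the
    gene feature is not requested; empty bins are never emitted.
    """
    features = set(config.feature_types)
    if features & {"gene", "pathway"} and kb is None:
        raise BinningError("gene/pathway features need a knowledge base")
    rare_idx = [i for i, r in enumerate(rarity) if r.rare]

    bins: list[BinDefinition] = []
    gene_loci: dict[int, list] = {}  # region_id -> locus indices
    if features & {"gene", "pathway"}:
        for i in rare_idx:
            for region in kb.regions_containing(loci[i].chromosome,
                                                loci[i].position, "gene"):
                gene_loci.setdefault(region.region_id, []).append(i)

    if "gene" in features:
        for rid, idxs in gene_loci.items():
            region = kb.region(rid)
            bins.append(BinDefinition(
                bin_id=region.label, feature_type="gene",
                locus_indices=tuple(sorted(set(idxs))),
                loci=tuple(loci[i].key for i in sorted(set(idxs))),
                provenance=(rid,)))

    if "pathway" in features:
        if kb.n_groups() == 0:
            raise BinningError(
                "pathway feature requested but no groups are loaded")
        pathway_loci: dict[int, set] = {}
        for rid, idxs in gene_loci.items():
            for group in kb.groups_of(rid):
                pathway_loci.setdefault(group.group_id, set()).update(idxs)
        for gid, idxs in pathway_loci.items():
            group = kb._group(gid)
            bins.append(BinDefinition(
                bin_id=group.label, feature_type="pathway",
                locus_indices=tuple(sorted(idxs)),
                loci=tuple(loci[i].key for i in sorted(idxs)),
                provenance=(gid,)))

    if "intergenic" in features:
        assigned = {i for b in bins for i in b.locus_indices}
        windows: dict[tuple, list] = {}
        for i in rare_idx:
            if i in assigned:
                continue
            k = intergenic_window_index(loci[i].position,
                                        config.intergenic_window)
            windows.setdefault((loci[i].chromosome, k), []).append(i)
        for (chrom, k), idxs in windows.items():
            bins.append(BinDefinition(
                bin_id=f"{chrom}:window_{k}", feature_type="intergenic",
                locus_indices=tuple(sorted(idxs)),
                loci=tuple(loci[i].key for i in sorted(idxs)),
                provenance=()))

    return _sort_bins(bins)


def apply_subfeature_filter(bins: list, kb: KnowledgeBase,
                            which: str) -> list:
    """Split gene/pathway bins into exonic and intronic halves.

    A locus is exonic iff it lies inside any exon region of a gene that
    contains it (among the bin's provenance genes for gene bins, or any
    containing gene for pathway bins).  ``which`` keeps ``"exon"``,
    ``"intron"``, or pass each bin through :func:`split_exon_intron` for
    both halves by calling with ``"both"``.  Intergenic bins have no
    parent gene and pass through unchanged.
    """
    if which not in ("exon", "intron", "both"):
        raise BinningError(f"unknown subfeature filter {which!r}")
    if kb.n_regions("exon") == 0:
        raise BinningError(
            "subfeature filter requested but no exon regions are loaded")
    out: list[BinDefinition] = []
    for b in bins:
        if b.feature_type == "intergenic":
            out.append(b)
            continue
        exonic, intronic = [], []
        for i, (chrom, pos) in zip(b.locus_indices, b.loci):
            genes = kb.regions_containing(chrom, pos, "gene")
            is_exonic = False
            for gene in genes:
                for exon in kb.regions_overlapping(chrom, gene.start,
                                                   gene.stop, "exon"):
                    if exon.start <= pos <= exon.stop:
                        is_exonic = True
                        break
                if is_exonic:
                    break
            (exonic if is_exonic else intronic).append((i, (chrom, pos)))
        halves = []
        if which in ("exon", "both") and exonic:
            halves.append(("_exon", exonic))
        if which in ("intron", "both") and intronic:
            halves.append(("_intron", intronic))
        for suffix, pairs in halves:
            out.append(BinDefinition(
                bin_id=b.bin_id + suffix, feature_type=b.feature_type,
                locus_indices=tuple(i for i, _ in pairs),
                loci=tuple(key for _, key in pairs),
                provenance=b.provenance))
    return _sort_bins(out)


def read_predictions(path) -> dict:
    """TSV of chromosome, position, category (extra columns ignored)."""
    out: dict[tuple, str] = {}
    for lineno, line in enumerate(Path(path).open(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise BinningError(
                f"{path} line {lineno}: expected chromosome, position, "
                "category")
        try:
            pos = int(fields[1])
        except ValueError:
            raise BinningError(
                f"{path} line {lineno}: unparseable position {fields[1]!r}")
        if len(fields) > 3:
            logger.debug("prediction line %d: ignoring score column %r",
                         lineno, fields[3])
        out[(fields[0].strip(), pos)] = fields[2].strip()
    return out


def apply_prediction_split(bins: list, predictions: dict) -> list:
    """Split each bin into one bin per functional-prediction category.

    Loci without a prediction record are excluded from the split bins
    entirely — only predicted variants remain in the analysis.
    """
    out: list[BinDefinition] = []
    for b in bins:
        by_cat: dict[str, list] = {}
        for i, key in zip(b.locus_indices, b.loci):
            cat = predictions.get(key)
            if cat is None:
                continue
            by_cat.setdefault(cat, []).append((i, key))
        for cat in sorted(by_cat):
            pairs = by_cat[cat]
            out.append(BinDefinition(
                bin_id=f"{b.bin_id}_{cat}", feature_type=b.feature_type,
                locus_indices=tuple(i for i, _ in pairs),
                loci=tuple(key for _, key in pairs),
                provenance=b.provenance))
    if bins and not out:
        raise BinningError(
            "prediction split removed every locus from every bin; disable "
            "the split or supply a prediction table covering the loci")
    return _sort_bins(out)


# ---------------------------------------------------------------------------
# burden matrix
# ---------------------------------------------------------------------------

def build_bin_matrix(bins: list, matrix: GenotypeMatrix,
                     rarity: list) -> BinMatrix:
    """Sum binned-allele counts per (bin, sample).

    Each genotype call contributes the number of its alleles that are in
    the locus's binned-allele set (0–2); missing alleles contribute 0.
    """
    if not bins:
        raise BinningError("no bins to build a matrix for")
    if len(rarity) != matrix.n_loci:
        raise BinningError("rarity calls do not match the genotype loci")
    # per-locus per-sample count of binned alleles
    per_locus = np.zeros((matrix.n_samples, matrix.n_loci), dtype=np.int32)
    for i, (locus, r) in enumerate(zip(matrix.loci, rarity)):
        if not r.binned_alleles:
            continue
        binned_idx = np.array(
            [k for k, a in enumerate(locus.alleles) if a in r.binned_alleles],
            dtype=np.int16)
        col = matrix.calls[:, i, :]
        per_locus[:, i] = np.isin(col, binned_idx).sum(axis=1)
    values = np.zeros((len(bins), matrix.n_samples), dtype=np.int32)
    for j, b in enumerate(bins):
        idxs = np.array(b.locus_indices, dtype=np.int64)
        values[j] = per_locus[:, idxs].sum(axis=1)
    bm = BinMatrix(bins=list(bins), sample_ids=list(matrix.sample_ids),
                   values=values)
    if (bm.values.max(initial=0) > 2 * bm.locus_counts.max(initial=0)):
        raise BinningError("burden exceeds 2 x locus count; inconsistent input")
    return bm


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_bin_summary(bm: BinMatrix, path, codes=None,
                      metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        bm.summary_frame(codes).to_csv(fh, sep="\t", index=False)


def write_bin_matrix(bm: BinMatrix, path,
                     metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        bm.to_dataframe().to_csv(fh)


def read_bin_matrix_csv(path) -> pd.DataFrame:
    """Read back a bin-matrix CSV written by :func:`write_bin_matrix`."""
    return pd.read_csv(path, comment="#", index_col="sample_id")
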