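import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the reference module

from rarebin import GenotypeMatrix, KnowledgeBase, Locus, PhenotypeAssignment
from rarebin.simulate import DemographyConfig, simulate_region

BASES = ("A", "C", "G", "T")


def make_matrix(sample_ids, loci, calls):
    return GenotypeMatrix(list(sample_ids), list(loci),
                          np.asarray(calls, dtype=np.int16))


def phen_from_codes(sample_ids, codes):
    return PhenotypeAssignment({s: ("case" if c == 1 else "control")
                                for s, c in zip(sample_ids, codes)})


def random_dataset(rng, n_samples=None, n_loci=None, n_genes=None,
                   n_pathways=None):
    """A random in-memory cohort + knowledge for equivalence testing.

    Includes overlapping genes, multiallelic loci and missing calls.
    Returns (matrix, codes, phen, kb, genes, pathways).
    """
    n_samples = n_samples or int(rng.integers(6, 31))
    n_loci = n_loci or int(rng.integers(10, 101))
    n_genes = n_genes or int(rng.integers(1, 11))
    n_pathways = n_pathways if n_pathways is not None else int(rng.integers(0, 4))
    chroms = ["1", "2"]

    genes = []
    for g in range(n_genes):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(1, 200_001))
        length = int(rng.integers(500, 30_001))
        genes.append((f"G{g}", chrom, start, start + length - 1))
    pathways = {}
    for p in range(n_pathways):
        size = int(rng.integers(1, n_genes + 1))
        members = rng.choice(n_genes, size=size, replace=False)
        pathways[f"P{p}"] = [genes[m][0] for m in sorted(members)]

    loci = []
    used = set()
    for _ in range(n_loci):
        while True:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(1, 260_001))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                break
        n_alleles = int(rng.choice([2, 2, 2, 3]))
        symbols = tuple(np.array(BASES)[
            rng.choice(4, size=n_alleles, replace=False)])
        loci.append(Locus(chrom, pos, symbols))

    calls = np.full((n_samples, n_loci, 2), -1, dtype=np.int16)
    for i, locus in enumerate(loci):
        n_all = len(locus.alleles)
        # skewed allele draw so rare alleles actually occur
        probs = np.array([0.85] + [0.15 / (n_all - 1)] * (n_all - 1))
        for s in range(n_samples):
            if rng.random() < 0.05:
                continue  # missing genotype
            pair = rng.choice(n_all, size=2, p=probs)
            calls[s, i, :] = pair
            if rng.random() < 0.02:
                calls[s, i, 1] = -1  # half-call
    codes = np.zeros(n_samples, dtype=np.int8)
    codes[rng.permutation(n_samples)[:n_samples // 2]] = 1
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    matrix = make_matrix(sample_ids, loci, calls)
    phen = phen_from_codes(sample_ids, codes)

    kb = KnowledgeBase.in_memory()
    label_to_id = {}
    for label, chrom, start, stop in genes:
        label_to_id[label] = kb.add_region(label, chrom, start, stop, "gene").region_id
    for plabel, members in pathways.items():
        kb.add_group(plabel, [label_to_id[m] for m in members])
    return matrix, codes, phen, kb, genes, pathways


@pytest.fixture(scope="session")
def study_pools():
    """Shared rescaled haplotype pools for the Monte-Carlo studies."""
    config = DemographyConfig(scaling=100.0)
    return [simulate_region(config, 1000 + i) for i in range(100)]


@pytest.fixture()
def small_kb():
    """The worked three-gene store used across knowledge-query tests."""
    kb = KnowledgeBase.in_memory()
    kb.add_region("GENE_A", "1", 1000, 2000, "gene")
    kb.add_region("GENE_B", "1", 5000, 9000, "gene")
    kb.add_region("GENE_C", "2", 100, 400, "gene")
    return kb
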