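"""Synthetic data: rare-variant region simulator and evaluation harnesses.

Region simulator
----------------

A forward-time Wright–Fisher model of a single short region (default
5 kb, no recombination).  The population is a pool of haplotypes; each
generation, parents are drawn multinomially (weighted by fitness when
purifying selection is on) and new mutations arrive at a fixed
per-nucleotide rate (default 1.8e-8 per generation) on an
infinite-sites approximation of the region.  The demographic history is
an epoch schedule — by default a long constant phase (Ne 8100), a brief
bottleneck shift to 7900, and a recent explosive expansion to 900 000,
which piles up an excess of very rare variants the way human
resequencing data does.  Selection coefficients for new mutations follow
a Kryukov-style gamma distribution of deleterious effects.

Running the full-size history is not a desk job, so the standard
population-genetics rescaling is built in: sizes and durations divide by
a scaling factor λ while the mutation rate and selection coefficients
multiply by λ, preserving θ = 4Nμ and Ns while shrinking run time.  The
unscaled path (λ = 1) remains available.

Phenotype model
---------------

Case/control status follows a logistic model whose log-odds are additive
in per-site derived-allele counts: detrimental sites contribute
log(2.5), protective sites log(0.9) by default.  Which sites are causal
is not observable in real data and is configurable here; the default
(causal_fraction and the detrimental share) is calibrated so that the
burden signal per causal allele matches the published operating regime
of the evaluation design — see docs/methods.md.  Under the null (both
odds ratios 1.0) status is assigned by balanced random labelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.special import expit, logit

from .knowledge import KnowledgeBase
from .variants import (GenotypeMatrix, Locus, PhenotypeAssignment,
                       write_phenotypes, write_vcf)
from .stats import wilcoxon_rank_sum

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


class SimulationError(Exception):
    pass


@dataclass(frozen=True)
class Epoch:
    """One demographic phase; size interpolates exponentially start->end."""

    start_size: int
    end_size: int
    generations: int

    def __post_init__(self):
        if self.start_size < 1 or self.end_size < 1 or self.generations < 1:
            raise SimulationError("epoch sizes and durations must be positive")


DEFAULT_EPOCHS = (
    Epoch(8100, 8100, 5000),
    Epoch(8100, 7900, 10),
    Epoch(7900, 900_000, 370),
)


@dataclass(frozen=True)
class DemographyConfig:
    region_length: int = 5000
    mutation_rate: float = 1.8e-8      # per nucleotide per generation
    epochs: tuple = DEFAULT_EPOCHS
    selection: str = "kryukov"         # or "neutral"
    sel_shape: float = 0.206           # gamma shape of selection coefficients
    sel_mean: float = 0.043            # gamma mean of selection coefficients
    scaling: float = 1.0               # rescaling factor lambda (>= 1)

    def __post_init__(self):
        if self.scaling < 1:
            raise SimulationError("scaling factor must be >= 1")
        if self.selection not in ("kryukov", "neutral"):
            raise SimulationError(f"unknown selection model {self.selection!r}")
        if self.mutation_rate < 0:
            raise SimulationError("mutation rate must be >= 0")

    def scaled_schedule(self) -> list:
        """Haploid pool size for every simulated generation, plus gen 0."""
        sizes = [max(1, round(self.epochs[0].start_size / self.scaling))]
        for ep in self.epochs:
            n0 = ep.start_size / self.scaling
            n1 = ep.end_size / self.scaling
            gens = max(1, round(ep.generations / self.scaling))
            ratio = n1 / n0
            for t in range(1, gens + 1):
                sizes.append(max(1, round(n0 * ratio ** (t / gens))))
        if min(sizes) < 50:
            raise SimulationError(
                f"scaling {self.scaling} shrinks the population to "
                f"{min(sizes)} diploids (< 50): drift would be degenerate")
        return [2 * s for s in sizes]  # haplotypes


@dataclass
class HaplotypePool:
    """Final-generation haplotypes over the segregating sites of one run."""

    chromosome: str
    positions: np.ndarray    # 1-based, sorted
    ref: np.ndarray          # ancestral allele symbols
    alt: np.ndarray          # derived allele symbols
    sel: np.ndarray          # unscaled selection coefficients per site
    haplotypes: np.ndarray   # (n_haplotypes, n_sites) uint8 derived counts
    config: DemographyConfig
    seed: int
    schedule: tuple = ()     # haploid sizes actually simulated

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def derived_frequencies(self) -> np.ndarray:
        if self.n_sites == 0:
            return np.zeros(0)
        return self.haplotypes.mean(axis=0)


@dataclass(frozen=True)
class EffectModel:
    """Odds-ratio model mapping genotypes to case probability.

    or_detrimental / or_protective are per-allele odds ratios under an
    additive mode of inheritance.  causal_fraction of segregating sites
    carry an effect; of those, p_detrimental are detrimental and the
    rest protective.  prevalence sets the baseline case probability at
    the mean genetic score (0.5 = balanced ascertainment).
    """

    or_detrimental: float = 2.5
    or_protective: float = 0.9
    mode: str = "additive"
    causal_fraction: float = 1.0
    p_detrimental: float = 0.9
    prevalence: float = 0.5

    def __post_init__(self):
        if self.or_detrimental <= 0 or self.or_protective <= 0:
            raise SimulationError("odds ratios must be positive")
        if self.mode != "additive":
            raise SimulationError("only the additive mode is supported")
        if not 0.0 <= self.causal_fraction <= 1.0:
            raise SimulationError("causal_fraction must lie in [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise SimulationError("prevalence must lie in (0, 1)")

    @property
    def is_null(self) -> bool:
        return self.or_detrimental == 1.0 and self.or_protective == 1.0

    @classmethod
    def null(cls) -> "EffectModel":
        return cls(or_detrimental=1.0, or_protective=1.0)


@dataclass(frozen=True)
class ReplicateResult:
    index: int
    pvalue: float
    n_rare_loci: int
    pool_index: int


@dataclass
class StudyResult:
    rejection_fraction: float
    replicates: list
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def simulate_region(config: DemographyConfig, seed: int) -> HaplotypePool:
    """Run one forward-time realization and return the final haplotype pool.

    Deterministic in (config, seed).  With mutation_rate 0 the pool has
    zero variant sites.
    """
    schedule = config.scaled_schedule()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    lam = config.scaling
    mu_hap = config.mutation_rate * config.region_length * lam

    n0 = schedule[0]
    H = np.zeros((n0, 0), dtype=np.uint8)
    positions = np.zeros(0, dtype=np.int64)
    sel = np.zeros(0, dtype=float)
    used_positions: set = set()

    for n_next in schedule[1:]:
        n_cur = H.shape[0]
        # fitness-weighted parent draw (genic selection, multiplicative)
        if sel.size and config.selection == "kryukov":
            s_eff = np.minimum(sel * lam, 0.95)
            logw = H.astype(np.float64) @ np.log1p(-s_eff)
            w = np.exp(logw - logw.max())
            prob = w / w.sum()
            parents = rng.choice(n_cur, size=n_next, p=prob)
        else:
            parents = rng.integers(0, n_cur, size=n_next)
        H = H[parents]
        # new mutations, infinite-sites on the region
        n_new = rng.poisson(mu_hap * n_next)
        if n_new:
            free = config.region_length - len(used_positions)
            if n_new > free:
                raise SimulationError(
                    "mutation supply exhausted the region: increase "
                    "region_length or reduce scaling")
            new_pos = []
            while len(new_pos) < n_new:
                cand = int(rng.integers(1, config.region_length + 1))
                if cand not in used_positions:
                    used_positions.add(cand)
                    new_pos.append(cand)
            carriers = rng.integers(0, n_next, size=n_new)
            cols = np.zeros((n_next, n_new), dtype=np.uint8)
            cols[carriers, np.arange(n_new)] = 1
            H = np.concatenate([H, cols], axis=1)
            positions = np.concatenate([positions, np.array(new_pos)])
            if config.selection == "kryukov":
                new_sel = rng.gamma(config.sel_shape,
                                    config.sel_mean / config.sel_shape,
                                    size=n_new)
            else:
                new_sel = np.zeros(n_new)
            sel = np.concatenate([sel, new_sel])
        # prune lost and fixed sites
        counts = H.sum(axis=0)
        keep = (counts > 0) & (counts < H.shape[0])
        if not keep.all():
            lost = positions[~keep]
            for p in lost[counts[~keep] == 0]:
                used_positions.discard(int(p))  # lost sites can re-mutate
            H = H[:, keep]
            positions = positions[keep]
            sel = sel[keep]

    order = np.argsort(positions, kind="stable")
    positions, sel = positions[order], sel[order]
    H = np.ascontiguousarray(H[:, order])
    allele_rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    ref_idx = allele_rng.integers(0, 4, size=len(positions))
    alt_idx = (ref_idx + allele_rng.integers(1, 4, size=len(positions))) % 4
    return HaplotypePool(
        chromosome="1", positions=positions,
        ref=_BASES[ref_idx], alt=_BASES[alt_idx], sel=sel, haplotypes=H,
        config=config, seed=seed, schedule=tuple(schedule))


# ---------------------------------------------------------------------------
# effect assignment and case/control sampling
# ---------------------------------------------------------------------------

def assign_effects(pool: HaplotypePool, model: EffectModel,
                   seed: int) -> np.ndarray:
    """Per-site log odds ratios (0 for non-causal sites)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    beta = np.zeros(pool.n_sites)
    if model.is_null:
        return beta
    causal = rng.random(pool.n_sites) < model.causal_fraction
    detrimental = rng.random(pool.n_sites) < model.p_detrimental
    beta[causal & detrimental] = np.log(model.or_detrimental)
    beta[causal & ~detrimental] = np.log(model.or_protective)
    return beta


def _draw_case_control_indices(pool: HaplotypePool, beta: np.ndarray,
                               n_cases: int, n_controls: int,
                               prevalence: float, rng,
                               max_batches: int = 500):
    """Rejection-sample haplotype pairs until both group quotas are met."""
    hs = pool.haplotypes.astype(np.float64) @ beta
    b0 = logit(prevalence) - 2.0 * hs.mean()
    case_pairs: list = []
    ctrl_pairs: list = []
    batch = max(256, 2 * (n_cases + n_controls))
    for _ in range(max_batches):
        i1 = rng.integers(0, pool.n_haplotypes, size=batch)
        i2 = rng.integers(0, pool.n_haplotypes, size=batch)
        p_case = expit(b0 + hs[i1] + hs[i2])
        is_case = rng.random(batch) < p_case
        for a, b, c in zip(i1, i2, is_case):
            if c and len(case_pairs) < n_cases:
                case_pairs.append((a, b))
            elif not c and len(ctrl_pairs) < n_controls:
                ctrl_pairs.append((a, b))
        if len(case_pairs) >= n_cases and len(ctrl_pairs) >= n_controls:
            return np.array(case_pairs), np.array(ctrl_pairs)
    raise SimulationError(
        "could not fill the case/control quotas; the prevalence or effect "
        "model is too extreme for this pool")


def _genotypes_from_pairs(pool: HaplotypePool, pairs: np.ndarray) -> np.ndarray:
    return (pool.haplotypes[pairs[:, 0]].astype(np.int16)
            + pool.haplotypes[pairs[:, 1]])


def sample_case_control(pool: HaplotypePool, n_samples: int,
                        model: EffectModel, seed: int,
                        beta: np.ndarray | None = None):
    """Draw a balanced diploid case/control cohort from the pool.

    Returns (GenotypeMatrix, PhenotypeAssignment).  Under the null model
    the labels are a balanced random permutation independent of
    genotype; otherwise the logistic odds-ratio model assigns status and
    sampling continues until the per-group quotas are met.
    """
    if n_samples < 2:
        raise SimulationError("need at least 2 samples")
    if pool.n_sites == 0 and not model.is_null:
        raise SimulationError("effect model on an empty pool is undefined")
    n_cases = n_samples // 2
    n_controls = n_samples - n_cases
    ss = np.random.SeedSequence([seed, 505])
    r_geno, r_phen = [np.random.default_rng(s) for s in ss.spawn(2)]
    if model.is_null:
        pairs = r_geno.integers(0, pool.n_haplotypes, size=(n_samples, 2))
        G = _genotypes_from_pairs(pool, pairs)
        labels = np.zeros(n_samples, dtype=bool)
        labels[r_phen.permutation(n_samples)[:n_cases]] = True
    else:
        if beta is None:
            beta = assign_effects(pool, model, seed)
        case_pairs, ctrl_pairs = _draw_case_control_indices(
            pool, beta, n_cases, n_controls, model.prevalence, r_geno)
        G = np.concatenate([_genotypes_from_pairs(pool, case_pairs),
                            _genotypes_from_pairs(pool, ctrl_pairs)])
        labels = np.zeros(n_samples, dtype=bool)
        labels[:n_cases] = True
    sample_ids = [f"I{i:05d}" for i in range(n_samples)]
    loci = [Locus(pool.chromosome, int(p), (r, a))
            for p, r, a in zip(pool.positions, pool.ref, pool.alt)]
    calls = np.full((n_samples, pool.n_sites, 2), 0, dtype=np.int16)
    calls[:, :, 0] = (G >= 1).astype(np.int16)
    calls[:, :, 1] = (G == 2).astype(np.int16)
    matrix = GenotypeMatrix(sample_ids, loci, calls)
    phen = PhenotypeAssignment({sid: ("case" if c else "control")
                                for sid, c in zip(sample_ids, labels)})
    return matrix, phen


def spike_in_variant(matrix: GenotypeMatrix, phen: PhenotypeAssignment,
                     chromosome: str, position: int,
                     gene_label: str | None = None,
                     kb: KnowledgeBase | None = None,
                     ref: str = "A", alt: str = "T") -> GenotypeMatrix:
    """Append a fully penetrant biallelic locus: every case heterozygous,
    every control homozygous reference.

    The total number of added variants equals the number of cases.  When
    a knowledge base and gene label are given, the position is checked to
    lie inside that gene's region.  A position colliding with an existing
    locus is an error, as is a cohort with zero cases (the spike would be
    monomorphic).
    """
    cases = set(phen.cases)
    if not cases:
        raise SimulationError("spike-in with zero cases would be monomorphic")
    if any(l.chromosome == chromosome and l.position == position
           for l in matrix.loci):
        raise SimulationError(
            f"spike position {chromosome}:{position} collides with an "
            "existing locus")
    if kb is not None and gene_label is not None:
        region = kb.region_by_label(gene_label, "gene")
        if not (region.chromosome == chromosome
                and region.start <= position <= region.stop):
            raise SimulationError(
                f"spike position {chromosome}:{position} lies outside "
                f"{gene_label} [{region.start}, {region.stop}]")
    new_col = np.zeros((matrix.n_samples, 1, 2), dtype=np.int16)
    for i, sid in enumerate(matrix.sample_ids):
        if sid in cases:
            new_col[i, 0, 1] = 1  # heterozygous ref/alt
    loci = list(matrix.loci) + [Locus(chromosome, position, (ref, alt))]
    calls = np.concatenate([matrix.calls, new_col], axis=1)
    return GenotypeMatrix(list(matrix.sample_ids), loci, calls)


# ---------------------------------------------------------------------------
# vectorized single-bin replicate pipeline
# ---------------------------------------------------------------------------

def rare_binned_burden(G: np.ndarray, is_case: np.ndarray, threshold: float,
                       ref: np.ndarray, alt: np.ndarray):
    """Per-sample burden of binned alleles for a biallelic site matrix.

    Mirrors the binning engine's rules exactly (per-group second-most-
    frequent-allele MAF, strict threshold, either-group trigger,
    per-group non-major alleles unioned, alleles unobserved in both
    groups dropped, lexicographic major at a 50/50 tie) but operates on
    a dense derived-allele count matrix.  Returns (burden vector,
    number of binned loci).
    """
    n_ca = int(is_case.sum())
    n_co = int((~is_case).sum())
    if G.shape[1] == 0:
        return np.zeros(G.shape[0], dtype=np.int64), 0
    f_ca = G[is_case].sum(axis=0) / (2.0 * n_ca)
    f_co = G[~is_case].sum(axis=0) / (2.0 * n_co)
    alt_wins_tie = alt < ref  # major allele ties break to the smaller symbol
    minor_der_ca = (f_ca < 0.5) | ((f_ca == 0.5) & ~alt_wins_tie)
    minor_der_co = (f_co < 0.5) | ((f_co == 0.5) & ~alt_wins_tie)
    maf_ca = np.where(minor_der_ca, f_ca, 1.0 - f_ca)
    maf_co = np.where(minor_der_co, f_co, 1.0 - f_co)
    rare_ca = maf_ca < threshold
    rare_co = maf_co < threshold
    total = G.sum(axis=0)
    der_observed = total > 0
    anc_observed = total < 2 * (n_ca + n_co)
    der_binned = (((rare_ca & minor_der_ca) | (rare_co & minor_der_co))
                  & der_observed)
    anc_binned = (((rare_ca & ~minor_der_ca) | (rare_co & ~minor_der_co))
                  & anc_observed)
    burden = G[:, der_binned].sum(axis=1).astype(np.int64)
    if anc_binned.any():
        burden += (2 * int(anc_binned.sum())
                   - G[:, anc_binned].sum(axis=1)).astype(np.int64)
    n_loci = int((der_binned | anc_binned).sum())
    return burden, n_loci


def run_error_power_study(config: DemographyConfig, model: EffectModel,
                          n_samples: int, replicates: int,
                          threshold: float = 0.05, seed: int = 0,
                          pools: list | None = None, n_pools: int = 100,
                          rejection_level: float = 0.05) -> StudyResult:
    """Monte-Carlo type-I-error / power study on single-region bins.

    Per replicate: take one haplotype pool (rotating over the pool set),
    sample a balanced case/control cohort under the effect model, bin
    the whole region as one bin at the MAF threshold, and run the
    Wilcoxon rank-sum test.  The rejection fraction is the share of
    replicates with p <= rejection_level.
    """
    if replicates < 1:
        raise SimulationError("need at least one replicate")
    ss = np.random.SeedSequence([seed, 606])
    pool_ss, eff_ss, rep_ss = ss.spawn(3)
    if pools is None:
        pool_seeds = [int(s.generate_state(1)[0] % (2**31))
                      for s in pool_ss.spawn(n_pools)]
        pools = [simulate_region(config, s) for s in pool_seeds]
    eff_seed = int(eff_ss.generate_state(1)[0] % (2**31))
    betas = [assign_effects(p, model, eff_seed) for p in pools]
    n_cases = n_samples // 2
    n_controls = n_samples - n_cases
    results: list[ReplicateResult] = []
    rep_rngs = rep_ss.spawn(replicates)
    for rep in range(replicates):
        k = rep % len(pools)
        pool, beta = pools[k], betas[k]
        rng = np.random.default_rng(rep_rngs[rep])
        if model.is_null:
            pairs = rng.integers(0, pool.n_haplotypes, size=(n_samples, 2))
            G = _genotypes_from_pairs(pool, pairs)
            is_case = np.zeros(n_samples, dtype=bool)
            is_case[rng.permutation(n_samples)[:n_cases]] = True
        else:
            case_pairs, ctrl_pairs = _draw_case_control_indices(
                pool, beta, n_cases, n_controls, model.prevalence, rng)
            G = np.concatenate([_genotypes_from_pairs(pool, case_pairs),
                                _genotypes_from_pairs(pool, ctrl_pairs)])
            is_case = np.zeros(n_samples, dtype=bool)
            is_case[:n_cases] = True
        burden, n_rare = rare_binned_burden(G, is_case, threshold,
                                            pool.ref, pool.alt)
        res = wilcoxon_rank_sum(burden[is_case], burden[~is_case])
        results.append(ReplicateResult(index=rep, pvalue=res.pvalue,
                                       n_rare_loci=n_rare, pool_index=k))
    rejections = sum(r.pvalue <= rejection_level for r in results)
    meta = {
        "n_samples": n_samples, "replicates": replicates,
        "threshold": threshold, "rejection_level": rejection_level,
        "n_pools": len(pools), "scaling": config.scaling,
        "or_detrimental": model.or_detrimental,
        "or_protective": model.or_protective,
        "causal_fraction": model.causal_fraction,
        "p_detrimental": model.p_detrimental,
        "epochs": [(e.start_size, e.end_size, e.generations)
                   for e in config.epochs],
        "mean_rare_loci": float(np.mean([r.n_rare_loci for r in results])),
        "seed": seed,
    }
    return StudyResult(rejection_fraction=rejections / replicates,
                       replicates=results, metadata=meta)


def write_study_tables(study: StudyResult, out_dir,
                       prefix: str = "study") -> tuple:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rep_path = out_dir / f"{prefix}_replicates.tsv"
    with open(rep_path, "w") as fh:
        fh.write("replicate\tpool\tp_value\tn_rare_loci\n")
        for r in study.replicates:
            fh.write(f"{r.index}\t{r.pool_index}\t{r.pvalue:.6g}\t"
                     f"{r.n_rare_loci}\n")
    sum_path = out_dir / f"{prefix}_summary.tsv"
    with open(sum_path, "w") as fh:
        for k, v in study.metadata.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("rejection_fraction\n")
        fh.write(f"{study.rejection_fraction:.6g}\n")
    return rep_path, sum_path


# ---------------------------------------------------------------------------
# toy dataset generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToySpec:
    """Shape of a self-consistent toy dataset.

    Loci are placed inside genes and in intergenic gaps with exact,
    generator-chosen per-group allele counts, so rarity at
    ``maf_threshold`` is known by construction and the expected bins can
    be derived without running the engine.
    """

    n_genes: int = 3
    n_pathways: int = 1
    n_samples: int = 20
    n_loci: int = 30
    maf_threshold: float = 0.05
    intergenic_fraction: float = 0.3
    common_fraction: float = 0.3
    intergenic_window: int = 50_000
    chromosome: str = "1"
    gene_length: int = 2_000
    gene_spacing: int = 120_000

    def __post_init__(self):
        if min(self.n_genes, self.n_samples, self.n_loci) < 1:
            raise SimulationError("toy spec counts must be positive")
        if self.n_pathways > 0 and self.n_genes < 1:
            raise SimulationError("pathways need genes")


@dataclass
class ToyTruth:
    threshold: float
    rare_loci: set            # (chrom, pos) keys expected to be binned
    gene_bins: dict           # gene label -> set of keys
    pathway_bins: dict        # pathway label -> set of keys
    intergenic_bins: dict     # bin_id -> set of keys


@dataclass
class ToyFixture:
    vcf: Path
    phenotypes: Path
    regions: Path
    groups: Path
    matrix: GenotypeMatrix
    phen: PhenotypeAssignment
    truth: ToyTruth


def _place_alt_alleles(calls: np.ndarray, locus_idx: int,
                       member_rows: np.ndarray, count: int, rng) -> None:
    slots = [(s, k) for s in member_rows for k in (0, 1)]
    chosen = rng.choice(len(slots), size=count, replace=False)
    for c in chosen:
        s, k = slots[int(c)]
        calls[s, locus_idx, k] = 1


def generate_toy_dataset(spec: ToySpec, seed: int, out_dir) -> ToyFixture:
    """Write a VCF + phenotype + region + GMT fixture with known truth.

    Deterministic in (spec, seed): identical files byte for byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 707]))

    # genes and exons
    genes = []
    for g in range(spec.n_genes):
        start = 10_001 + g * spec.gene_spacing
        stop = start + spec.gene_length - 1
        genes.append((f"GENE_{g}", start, stop))
    exons = []
    for label, start, stop in genes:
        length = stop - start + 1
        exons.append((f"{label}_ex1", start, start + max(1, length // 4)))
        e2 = start + (6 * length) // 10
        exons.append((f"{label}_ex2", e2, min(stop, e2 + max(1, length // 5))))

    pathways = []
    for p in range(spec.n_pathways):
        size = min(spec.n_genes, 2 + int(rng.integers(0, max(1, spec.n_genes - 1))))
        members = sorted(rng.choice(spec.n_genes, size=size, replace=False))
        pathways.append((f"PATH_{p}", [genes[m][0] for m in members]))

    # samples and phenotype groups
    n = spec.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    n_cases = n // 2
    case_rows = np.sort(rng.permutation(n)[:n_cases])
    is_case = np.zeros(n, dtype=bool)
    is_case[case_rows] = True
    phen = PhenotypeAssignment({sid: ("case" if c else "control")
                                for sid, c in zip(sample_ids, is_case)})
    group_rows = {"case": np.where(is_case)[0], "control": np.where(~is_case)[0]}

    # locus placement
    n_intergenic = int(round(spec.intergenic_fraction * spec.n_loci))
    n_genic = spec.n_loci - n_intergenic
    per_gene = [n_genic // spec.n_genes] * spec.n_genes
    for g in range(n_genic % spec.n_genes):
        per_gene[g] += 1
    if max(per_gene, default=0) > spec.gene_length // 2:
        raise SimulationError("requested loci denser than the gene length")
    taken: set = set()
    placements = []  # (pos, gene_index or None)
    for g, (label, start, stop) in enumerate(genes):
        for _ in range(per_gene[g]):
            while True:
                pos = int(rng.integers(start, stop + 1))
                if pos not in taken:
                    taken.add(pos)
                    break
            placements.append((pos, g))
    gap_lo = genes[-1][2] + 10_000
    gap_hi = gap_lo + spec.n_genes * spec.gene_spacing
    for _ in range(n_intergenic):
        while True:
            pos = int(rng.integers(gap_lo, gap_hi))
            in_gene = any(s <= pos <= e for _, s, e in genes)
            if pos not in taken and not in_gene:
                taken.add(pos)
                break
        placements.append((pos, None))
    placements.sort()

    # genotypes with exact per-group alt counts
    calls = np.zeros((n, len(placements), 2), dtype=np.int16)
    loci = []
    rare_flags = []
    thr = spec.maf_threshold
    for i, (pos, g) in enumerate(placements):
        ref, alt = rng.choice(4, size=2, replace=False)
        loci.append(Locus(spec.chromosome, pos,
                          (str(_BASES[ref]), str(_BASES[alt]))))
        make_common = rng.random() < spec.common_fraction
        counts = {}
        if make_common:
            ok = True
            for grp, rows in group_rows.items():
                two_n = 2 * len(rows)
                lo = int(np.ceil(thr * two_n))
                hi = two_n // 2
                if lo > hi or lo == 0:
                    ok = False
                    break
                counts[grp] = min(max(int(round(0.3 * two_n)), lo), hi)
            make_common = ok
        if not make_common:
            for grp, rows in group_rows.items():
                two_n = 2 * len(rows)
                c_max = int(np.ceil(thr * two_n)) - 1  # strict threshold
                counts[grp] = int(rng.integers(0, c_max + 1)) if c_max >= 1 else 0
            if sum(counts.values()) == 0:
                counts["control"] = 1  # rare via the zero-count case group
        for grp, rows in group_rows.items():
            if counts[grp]:
                _place_alt_alleles(calls, i, rows, counts[grp], rng)
        rare_flags.append(not make_common)

    matrix = GenotypeMatrix(sample_ids, loci, calls)

    # expected truth
    rare_keys = {loci[i].key for i, r in enumerate(rare_flags) if r}
    gene_bins: dict[str, set] = {}
    for label, start, stop in genes:
        keys = {k for k in rare_keys if start <= k[1] <= stop}
        if keys:
            gene_bins[label] = keys
    pathway_bins: dict[str, set] = {}
    for label, members in pathways:
        keys: set = set()
        for m in members:
            keys |= gene_bins.get(m, set())
        if keys:
            pathway_bins[label] = keys
    assigned = set().union(*gene_bins.values()) if gene_bins else set()
    assigned |= set().union(*pathway_bins.values()) if pathway_bins else set()
    intergenic_bins: dict[str, set] = {}
    for k in rare_keys - assigned:
        widx = (k[1] - 1) // spec.intergenic_window
        intergenic_bins.setdefault(f"{k[0]}:window_{widx}", set()).add(k)
    truth = ToyTruth(threshold=thr, rare_loci=rare_keys, gene_bins=gene_bins,
                     pathway_bins=pathway_bins,
                     intergenic_bins=intergenic_bins)

    # write files
    vcf_path = out_dir / "toy.vcf"
    phen_path = out_dir / "phenotypes.tsv"
    region_path = out_dir / "regions.tsv"
    gmt_path = out_dir / "groups.gmt"
    write_vcf(matrix, vcf_path, source_tag="rarebin-toy")
    write_phenotypes(phen, phen_path)
    with open(region_path, "w") as fh:
        for label, start, stop in genes:
            fh.write(f"{spec.chromosome}\t{start}\t{stop}\t{label}\tgene\n")
        for label, start, stop in exons:
            fh.write(f"{spec.chromosome}\t{start}\t{stop}\t{label}\texon\n")
    with open(gmt_path, "w") as fh:
        for label, members in pathways:
            fh.write(label + "\ttoy pathway\t" + "\t".join(members) + "\n")
    return ToyFixture(vcf=vcf_path, phenotypes=phen_path, regions=region_path,
                      groups=gmt_path, matrix=matrix, phen=phen, truth=truth)
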