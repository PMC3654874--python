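"""Independent brute-force reference implementations used as oracles.

Everything here is deliberately written with plain nested loops and no
shared code with the package: per-allele tallies, linear scans over
regions, direct enumeration of rank-sum permutations.  Slow but obvious.
"""

from itertools import combinations


# ---------------------------------------------------------------------------
# frequencies and rarity
# ---------------------------------------------------------------------------

def ref_group_freqs(matrix, codes):
    """Per locus, per group, allele -> frequency (zeros for unobserved)."""
    out = []
    for i, locus in enumerate(matrix.loci):
        rec = {}
        for grp, code in (("case", 1), ("control", 0)):
            counts = {a: 0 for a in locus.alleles}
            total = 0
            for s in range(matrix.n_samples):
                if codes[s] != code:
                    continue
                for k in (0, 1):
                    a = matrix.calls[s, i, k]
                    if a >= 0:
                        counts[locus.alleles[a]] += 1
                        total += 1
            rec[grp] = ({a: c / total for a, c in counts.items()}
                        if total else {})
        out.append(rec)
    return out


def ref_maf(freqs):
    vals = sorted(freqs.values(), reverse=True)
    return vals[1] if len(vals) > 1 else 0.0


def ref_binned_alleles(case_freqs, ctrl_freqs, threshold):
    """The union-over-triggering-groups binned allele set (may be empty)."""
    binned = set()
    for freqs in (case_freqs, ctrl_freqs):
        if not freqs:
            continue
        if ref_maf(freqs) < threshold:
            top = max(freqs.values())
            major = sorted(a for a, f in freqs.items() if f == top)[0]
            binned |= {a for a in freqs if a != major}
    observed = {a for freqs in (case_freqs, ctrl_freqs)
                for a, f in freqs.items() if f > 0.0}
    return binned & observed


# ---------------------------------------------------------------------------
# binning pipeline
# ---------------------------------------------------------------------------

def ref_pipeline(matrix, codes, genes, pathways, threshold,
                 features=("gene", "pathway", "intergenic"),
                 window=50_000):
    """Full reference pipeline.

    genes: list of (label, chrom, start, stop); pathways: dict
    label -> list of gene labels.  Returns dict
    (feature_type, bin_id) -> (sorted locus keys, burden list per sample).
    """
    freqs = ref_group_freqs(matrix, codes)
    binned_sets = [ref_binned_alleles(f["case"], f["control"], threshold)
                   for f in freqs]
    rare = [bool(b) for b in binned_sets]

    gene_members = {}
    for label, chrom, start, stop in genes:
        idxs = [i for i, locus in enumerate(matrix.loci)
                if rare[i] and locus.chromosome == chrom
                and start <= locus.position <= stop]
        if idxs:
            gene_members[label] = idxs

    bins = {}
    if "gene" in features:
        for label, idxs in gene_members.items():
            bins[("gene", label)] = idxs
    if "pathway" in features:
        for plabel, members in pathways.items():
            idxs = sorted({i for m in members
                           for i in gene_members.get(m, [])})
            if idxs:
                bins[("pathway", plabel)] = idxs
    if "intergenic" in features:
        assigned = {i for idxs in bins.values() for i in idxs}
        for i, locus in enumerate(matrix.loci):
            if rare[i] and i not in assigned:
                k = (locus.position - 1) // window
                bins.setdefault(
                    ("intergenic", f"{locus.chromosome}:window_{k}"),
                    []).append(i)

    out = {}
    for key, idxs in bins.items():
        idxs = sorted(set(idxs))
        burdens = []
        for s in range(matrix.n_samples):
            total = 0
            for i in idxs:
                locus = matrix.loci[i]
                for k in (0, 1):
                    a = matrix.calls[s, i, k]
                    if a >= 0 and locus.alleles[a] in binned_sets[i]:
                        total += 1
            burdens.append(total)
        out[key] = (tuple(matrix.loci[i].key for i in idxs), burdens)
    return out


# ---------------------------------------------------------------------------
# rank-sum enumeration
# ---------------------------------------------------------------------------

def ref_midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def ref_exact_wilcoxon_p(x, y):
    """Two-sided permutation p of the rank sum, by full enumeration."""
    pooled = list(x) + list(y)
    ranks = ref_midranks(pooled)
    n1, n = len(x), len(pooled)
    mu = n1 * (n + 1) / 2
    obs = abs(sum(ranks[:n1]) - mu)
    hits = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(sum(ranks[i] for i in idx) - mu) >= obs - 1e-9:
            hits += 1
    return hits / total
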