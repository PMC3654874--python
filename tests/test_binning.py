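import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rarebin import (BinningConfig, BinningError, KnowledgeBase, Locus,
                     apply_prediction_split, apply_subfeature_filter,
                     build_bin_matrix, build_feature_bins, classify_all,
                     classify_rarity, group_allele_frequencies,
                     minor_allele_frequency)
from rarebin.binning import intergenic_window_index

from conftest import make_matrix, phen_from_codes, random_dataset
from reference import ref_binned_alleles, ref_pipeline


class TestMinorAlleleFrequency:
    @pytest.mark.parametrize("freqs,expected", [
        ({"C": 0.97, "T": 0.03}, 0.03),
        ({"T": 0.80, "A": 0.16, "G": 0.04}, 0.16),
        ({"A": 1.0}, 0.0),
        ({"A": 0.5, "C": 0.25, "G": 0.25}, 0.25),  # tied second rank
        ({"A": 0.5, "T": 0.5}, 0.5),
    ])
    def test_second_most_frequent_rule(self, freqs, expected):
        assert minor_allele_frequency(freqs) == pytest.approx(expected)

    def test_unobserved_group_errors(self):
        with pytest.raises(BinningError):
            minor_allele_frequency({})


class TestClassifyRarity:
    def test_common_in_both_groups_not_binned(self):
        r = classify_rarity({"A": 0.92, "T": 0.08}, {"A": 0.92, "T": 0.08}, 0.05)
        assert not r.rare and r.binned_alleles == frozenset()

    def test_just_under_threshold_binned(self):
        r = classify_rarity({"A": 0.951, "T": 0.049}, {"A": 0.92, "T": 0.08}, 0.05)
        assert r.rare and r.binned_alleles == {"T"}

    def test_threshold_boundary_is_strict(self):
        r = classify_rarity({"A": 0.95, "T": 0.05}, {"A": 0.95, "T": 0.05}, 0.05)
        assert not r.rare

    def test_polyallelic_bins_all_non_major(self):
        freqs = {"G": 0.95, "C": 0.03, "T": 0.02}
        r = classify_rarity(freqs, dict(freqs), 0.05)
        assert r.binned_alleles == {"C", "T"}

    def test_either_group_triggers(self):
        r = classify_rarity({"A": 0.96, "T": 0.04}, {"A": 0.7, "T": 0.3}, 0.05)
        assert r.rare and r.binned_alleles == {"T"}

    def test_group_specific_minor_alleles_unioned(self):
        # minor allele differs per group; both trigger, union binned
        r = classify_rarity({"A": 0.97, "T": 0.03}, {"T": 0.99, "A": 0.01}, 0.05)
        assert r.binned_alleles == {"A", "T"}

    def test_fixed_in_one_group_is_binned(self):
        # zero-frequency allele in cases, common in controls: the case
        # group triggers with MAF 0 and contributes the absent allele
        r = classify_rarity({"A": 1.0, "T": 0.0}, {"A": 0.5, "T": 0.5}, 0.05)
        assert r.rare and r.binned_alleles == {"T"}
        assert r.maf["case"] == 0.0

    def test_monomorphic_everywhere_excluded(self):
        r = classify_rarity({"A": 1.0}, {"A": 1.0}, 0.05)
        assert not r.rare and r.binned_alleles == frozenset()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           threshold=st.sampled_from([0.02, 0.03, 0.05, 0.10]))
    def test_matches_reference_rule(self, seed, threshold):
        rng = np.random.default_rng(seed)
        alleles = ["A", "C", "G"][: int(rng.integers(2, 4))]
        def draw():
            w = rng.dirichlet([0.5] * len(alleles))
            return dict(zip(alleles, w))
        case, ctrl = draw(), draw()
        r = classify_rarity(case, ctrl, threshold)
        assert r.binned_alleles == frozenset(
            ref_binned_alleles(case, ctrl, threshold))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rarity_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.dirichlet([0.5, 0.5, 0.5])
        case = dict(zip("ACG", w))
        ctrl = dict(zip("ACG", rng.dirichlet([0.5, 0.5, 0.5])))
        previous = frozenset()
        for t in (0.01, 0.02, 0.05, 0.1, 0.5, 1.0):
            r = classify_rarity(case, ctrl, t)
            assert previous <= r.binned_alleles
            previous = r.binned_alleles


def _toy_cohort(loci_spec, n_case=5, n_ctrl=5):
    """loci_spec: list of (chrom, pos, alleles, case_alt_counts, ctrl_alt_counts)
    with counts as dict allele_index -> count of alleles to place."""
    n = n_case + n_ctrl
    codes = np.array([1] * n_case + [0] * n_ctrl)
    loci, cols = [], []
    for chrom, pos, alleles, ca, co in loci_spec:
        loci.append(Locus(chrom, pos, alleles))
        col = np.zeros((n, 2), dtype=np.int16)
        slots = {1: [(s, k) for s in range(n_case) for k in (0, 1)],
                 0: [(s + n_case, k) for s in range(n_ctrl) for k in (0, 1)]}
        for grp, counts in ((1, ca), (0, co)):
            free = list(slots[grp])
            for aidx, cnt in counts.items():
                for _ in range(cnt):
                    s, k = free.pop(0)
                    col[s, k] = aidx
        cols.append(col)
    calls = np.stack(cols, axis=1)
    ids = [f"S{i}" for i in range(n)]
    return make_matrix(ids, loci, calls), codes, phen_from_codes(ids, codes)


class TestBuildFeatureBins:
    def _rarity(self, matrix, phen, threshold=0.05):
        return classify_all(group_allele_frequencies(matrix, phen), threshold)

    def test_single_gene_bin(self, small_kb):
        matrix, codes, phen = _toy_cohort(
            [("1", 1500, ("A", "T"), {1: 1}, {})], n_case=20, n_ctrl=20)
        rarity = self._rarity(matrix, phen)
        bins = build_feature_bins(matrix.loci, rarity, small_kb,
                                  BinningConfig(feature_types=("gene",)))
        assert [(b.bin_id, b.n_loci) for b in bins] == [("GENE_A", 1)]

    def test_pathway_union_deduplicates_shared_locus(self):
        kb = KnowledgeBase.in_memory()
        a = kb.add_region("GENE_A", "1", 1000, 3000, "gene")
        b = kb.add_region("GENE_B", "1", 2500, 5000, "gene")  # overlaps A
        kb.add_group("PATH_1", [a.region_id, b.region_id])
        # locus at 2600 sits in both genes; two more private rare loci
        matrix, codes, phen = _toy_cohort(
            [("1", 1200, ("A", "T"), {1: 1}, {}),
             ("1", 2600, ("A", "T"), {1: 1}, {}),
             ("1", 4800, ("A", "T"), {}, {1: 1})], n_case=20, n_ctrl=20)
        rarity = self._rarity(matrix, phen)
        bins = build_feature_bins(
            matrix.loci, rarity, kb,
            BinningConfig(feature_types=("gene", "pathway")))
        path = [x for x in bins if x.feature_type == "pathway"][0]
        assert path.n_loci == 3  # shared locus counted once
        genes = {x.bin_id: x.n_loci for x in bins if x.feature_type == "gene"}
        assert genes == {"GENE_A": 2, "GENE_B": 2}

    def test_intergenic_window_arithmetic(self, small_kb):
        matrix, codes, phen = _toy_cohort(
            [("1", 120_000, ("A", "T"), {1: 1}, {})], n_case=20, n_ctrl=20)
        rarity = self._rarity(matrix, phen)
        bins = build_feature_bins(
            matrix.loci, rarity, small_kb,
            BinningConfig(feature_types=("gene", "intergenic")))
        assert intergenic_window_index(120_000, 50_000) == 2
        assert [b.bin_id for b in bins] == ["1:window_2"]

    def test_gene_locus_falls_to_window_when_gene_not_requested(self, small_kb):
        matrix, codes, phen = _toy_cohort(
            [("1", 1500, ("A", "T"), {1: 1}, {})], n_case=20, n_ctrl=20)
        rarity = self._rarity(matrix, phen)
        bins = build_feature_bins(
            matrix.loci, rarity, small_kb,
            BinningConfig(feature_types=("intergenic",)))
        assert [b.bin_id for b in bins] == ["1:window_0"]

    def test_pathway_without_groups_errors(self, small_kb):
        matrix, codes, phen = _toy_cohort(
            [("1", 1500, ("A", "T"), {1: 1}, {})], n_case=20, n_ctrl=20)
        rarity = self._rarity(matrix, phen)
        with pytest.raises(BinningError):
            build_feature_bins(matrix.loci, rarity, small_kb,
                               BinningConfig(feature_types=("pathway",)))

    def test_zero_threshold_produces_no_bins(self, small_kb):
        matrix, codes, phen = _toy_cohort(
            [("1", 1500, ("A", "T"), {1: 1}, {})], n_case=20, n_ctrl=20)
        rarity = self._rarity(matrix, phen, threshold=0.0)
        config = BinningConfig(maf_threshold=0.0,
                               feature_types=("gene", "intergenic"))
        assert build_feature_bins(matrix.loci, rarity, small_kb, config) == []

    def test_unit_threshold_bins_every_polymorphic_locus(self, small_kb):
        matrix, codes, phen = _toy_cohort(
            [("1", 1500, ("A", "T"), {1: 10}, {1: 10}),   # common
             ("1", 6000, ("A", "T"), {1: 1}, {}),          # rare
             ("1", 7000, ("A",), {}, {})],                 # monomorphic
            n_case=20, n_ctrl=20)
        rarity = self._rarity(matrix, phen, threshold=1.0)
        bins = build_feature_bins(
            matrix.loci, rarity, small_kb,
            BinningConfig(maf_threshold=1.0,
                          feature_types=("gene", "intergenic")))
        binned = {key for b in bins for key in b.loci}
        assert binned == {("1", 1500), ("1", 6000)}  # monomorphic never binned

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_gene_plus_intergenic_cover_every_rare_locus(self, seed):
        rng = np.random.default_rng(seed)
        matrix, codes, phen, kb, genes, pathways = random_dataset(rng)
        rarity = self._rarity(matrix, phen)
        bins = build_feature_bins(
            matrix.loci, rarity, kb,
            BinningConfig(feature_types=("gene", "intergenic")))
        covered = {i for b in bins for i in b.locus_indices}
        rare = {i for i, r in enumerate(rarity) if r.rare}
        assert covered == rare


class TestSubfeatureAndPredictionSplits:
    def _setup(self):
        kb = KnowledgeBase.in_memory()
        kb.add_region("GENE_A", "1", 1000, 5000, "gene")
        kb.add_region("GENE_A_ex1", "1", 1000, 2000, "exon")
        kb.add_region("GENE_A_ex2", "1", 4000, 4500, "exon")
        matrix, codes, phen = _toy_cohort(
            [("1", 1500, ("A", "T"), {1: 1}, {}),
             ("1", 4200, ("A", "T"), {}, {1: 1}),
             ("1", 3000, ("A", "T"), {1: 1}, {})], n_case=20, n_ctrl=20)
        rarity = classify_all(group_allele_frequencies(matrix, phen), 0.05)
        bins = build_feature_bins(matrix.loci, rarity, kb,
                                  BinningConfig(feature_types=("gene",)))
        return kb, matrix, rarity, bins

    def test_exon_intron_partition(self):
        kb, matrix, rarity, bins = self._setup()
        split = apply_subfeature_filter(bins, kb, "both")
        sizes = {b.bin_id: b.n_loci for b in split}
        assert sizes == {"GENE_A_exon": 2, "GENE_A_intron": 1}

    def test_all_exonic_drops_empty_half(self):
        kb, matrix, rarity, bins = self._setup()
        only_exonic = [b for b in bins]
        # restrict to the two exonic loci
        restricted = [type(b)(b.bin_id, b.feature_type,
                              tuple(i for i, key in zip(b.locus_indices, b.loci)
                                    if key[1] != 3000),
                              tuple(key for key in b.loci if key[1] != 3000),
                              b.provenance) for b in only_exonic]
        split = apply_subfeature_filter(restricted, kb, "both")
        assert [b.bin_id for b in split] == ["GENE_A_exon"]

    def test_filter_without_exon_regions_errors(self, small_kb):
        matrix, codes, phen = _toy_cohort(
            [("1", 1500, ("A", "T"), {1: 1}, {})], n_case=20, n_ctrl=20)
        rarity = classify_all(group_allele_frequencies(matrix, phen), 0.05)
        bins = build_feature_bins(matrix.loci, rarity, small_kb,
                                  BinningConfig(feature_types=("gene",)))
        with pytest.raises(BinningError):
            apply_subfeature_filter(bins, small_kb, "both")

    def test_prediction_split_categories(self):
        kb, matrix, rarity, bins = self._setup()
        preds = {("1", 1500): "risk", ("1", 4200): "risk", ("1", 3000): "benign"}
        split = apply_prediction_split(bins, preds)
        assert {(b.bin_id, b.n_loci) for b in split} == {
            ("GENE_A_risk", 2), ("GENE_A_benign", 1)}

    def test_unpredicted_locus_excluded_entirely(self):
        kb, matrix, rarity, bins = self._setup()
        preds = {("1", 1500): "risk", ("1", 4200): "risk"}
        split = apply_prediction_split(bins, preds)
        assert {(b.bin_id, b.n_loci) for b in split} == {("GENE_A_risk", 2)}
        assert all(("1", 3000) not in b.loci for b in split)

    def test_uniform_category_keeps_single_bin(self):
        kb, matrix, rarity, bins = self._setup()
        preds = {key: "risk" for b in bins for key in b.loci}
        split = apply_prediction_split(bins, preds)
        assert [(b.bin_id, b.n_loci) for b in split] == [("GENE_A_risk", 3)]

    def test_empty_prediction_table_errors(self):
        kb, matrix, rarity, bins = self._setup()
        with pytest.raises(BinningError, match="disable"):
            apply_prediction_split(bins, {})


class TestBinMatrix:
    def _run(self, loci_spec, features=("gene",), kb=None, threshold=0.05,
             n_case=20, n_ctrl=20):
        if kb is None:
            kb = KnowledgeBase.in_memory()
            kb.add_region("GENE_A", "1", 1000, 9000, "gene")
        matrix, codes, phen = _toy_cohort(loci_spec, n_case, n_ctrl)
        rarity = classify_all(group_allele_frequencies(matrix, phen), threshold)
        bins = build_feature_bins(matrix.loci, rarity, kb,
                                  BinningConfig(maf_threshold=threshold,
                                                feature_types=features))
        return build_bin_matrix(bins, matrix, rarity), matrix, codes

    def test_heterozygote_contributes_one(self):
        bm, matrix, codes = self._run([("1", 1500, ("A", "T"), {1: 1}, {})])
        assert bm.values[0].sum() == 1
        assert bm.values[0].max() == 1

    def test_homozygote_contributes_two(self):
        # place both alt alleles in the same sample
        matrix, codes, phen = _toy_cohort(
            [("1", 1500, ("A", "T"), {1: 2}, {})], n_case=20, n_ctrl=20)
        matrix.calls[1, 0, :] = 0
        matrix.calls[0, 0, :] = 1  # S0 hom alt
        rarity = classify_all(group_allele_frequencies(matrix, phen), 0.05)
        kb = KnowledgeBase.in_memory()
        kb.add_region("GENE_A", "1", 1000, 9000, "gene")
        bins = build_feature_bins(matrix.loci, rarity, kb,
                                  BinningConfig(feature_types=("gene",)))
        bm = build_bin_matrix(bins, matrix, rarity)
        assert bm.values[0, 0] == 2

    def test_two_binned_alleles_in_one_genotype(self):
        # genotype (C, T) at a locus where both C and T are binned
        matrix, codes, phen = _toy_cohort(
            [("1", 1500, ("G", "C", "T"), {1: 1, 2: 1}, {})],
            n_case=20, n_ctrl=20)
        matrix.calls[0, 0, :] = (1, 2)
        matrix.calls[1, 0, :] = 0
        rarity = classify_all(group_allele_frequencies(matrix, phen), 0.05)
        assert rarity[0].binned_alleles == {"C", "T"}
        kb = KnowledgeBase.in_memory()
        kb.add_region("GENE_A", "1", 1000, 9000, "gene")
        bins = build_feature_bins(matrix.loci, rarity, kb,
                                  BinningConfig(feature_types=("gene",)))
        bm = build_bin_matrix(bins, matrix, rarity)
        assert bm.values[0, 0] == 2

    def test_missing_call_contributes_zero(self):
        matrix, codes, phen = _toy_cohort(
            [("1", 1500, ("A", "T"), {1: 1}, {})], n_case=20, n_ctrl=20)
        matrix.calls[5, 0, :] = -1
        rarity = classify_all(group_allele_frequencies(matrix, phen), 0.05)
        kb = KnowledgeBase.in_memory()
        kb.add_region("GENE_A", "1", 1000, 9000, "gene")
        bins = build_feature_bins(matrix.loci, rarity, kb,
                                  BinningConfig(feature_types=("gene",)))
        bm = build_bin_matrix(bins, matrix, rarity)
        assert bm.values[0, 5] == 0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_totals_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        matrix, codes, phen, kb, genes, pathways = random_dataset(rng)
        rarity = classify_all(group_allele_frequencies(matrix, phen), 0.05)
        features = (("gene", "pathway", "intergenic") if pathways
                    else ("gene", "intergenic"))
        bins = build_feature_bins(matrix.loci, rarity, kb,
                                  BinningConfig(feature_types=features))
        if not bins:
            return
        bm = build_bin_matrix(bins, matrix, rarity)
        assert (bm.totals == bm.values.sum(axis=1)).all()
        assert (bm.values.max(axis=1) <= 2 * bm.locus_counts).all()
        assert (bm.locus_counts > 0).all()


class TestPipelineAgainstBruteForce:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           threshold=st.sampled_from([0.03, 0.05, 0.10]))
    def test_matches_reference_pipeline(self, seed, threshold):
        rng = np.random.default_rng(seed)
        matrix, codes, phen, kb, genes, pathways = random_dataset(rng)
        features = (("gene", "pathway", "intergenic") if pathways
                    else ("gene", "intergenic"))
        rarity = classify_all(group_allele_frequencies(matrix, phen), threshold)
        bins = build_feature_bins(
            matrix.loci, rarity, kb,
            BinningConfig(maf_threshold=threshold, feature_types=features))
        expected = ref_pipeline(matrix, codes,
                                [(l, c, s, e) for l, c, s, e in genes],
                                pathways, threshold, features)
        got = {}
        if bins:
            bm = build_bin_matrix(bins, matrix, rarity)
            for b, row in zip(bm.bins, bm.values):
                got[(b.feature_type, b.bin_id)] = (b.loci, list(row))
        assert got == expected
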