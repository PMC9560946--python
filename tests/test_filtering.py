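import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sporesnp import (
    ALT,
    MISSING,
    REF,
    HardFilterThresholds,
    NucleusMaskRule,
    ObsParams,
    apply_site_hard_filters,
    call_genotypes,
    call_haploid_genotype,
    extract_snp_sites,
    filter_by_missingness,
    mask_unreliable_cells,
    run_filter_chain,
    simulate_nucleus_population,
    simulate_observations,
    simulate_reference,
)
from sporesnp.filtering import DataError
from sporesnp.model import GenotypeMatrix, Site

from conftest import make_annotations, make_obs


class TestHardFilters:
    def test_low_qd_fails(self):
        ann = make_annotations(1, qd=1.9)
        assert not apply_site_hard_filters(ann)[0]

    def test_high_sor_fails(self):
        ann = make_annotations(1, sor=3.1)
        assert not apply_site_hard_filters(ann)[0]

    def test_all_boundary_values_pass(self):
        # strict inequalities: the threshold value itself always passes
        ann = make_annotations(
            1, qd=2.0, fs=60.0, mq=40.0, mqrs=-12.5, rprs=-8.0, qual=30.0,
            sor=3.0,
        )
        assert apply_site_hard_filters(ann)[0]

    @pytest.mark.parametrize(
        "field,value",
        [("qd", 1.999), ("fs", 60.001), ("mq", 39.999), ("mqrs", -12.501),
         ("rprs", -8.001), ("qual", 29.999), ("sor", 3.001)],
    )
    def test_each_threshold_enforced(self, field, value):
        ann = make_annotations(1, **{field: value})
        assert not apply_site_hard_filters(ann)[0]

    def test_missing_rank_sum_never_fails(self):
        ann = make_annotations(
            2, mqrs=np.nan, rprs=np.nan, mqrs_missing=True, rprs_missing=True
        )
        assert apply_site_hard_filters(ann).all()

    def test_missing_mandatory_annotation_is_error(self):
        ann = make_annotations(2)
        ann.qd[1] = np.nan
        with pytest.raises(DataError, match="QD"):
            apply_site_hard_filters(ann)


class TestHaploidCall:
    @pytest.mark.parametrize(
        "depth,ref,alt,expected",
        [
            (0, 0, 0, MISSING),
            (10, 2, 8, ALT),
            (10, 8, 2, REF),
            (6, 3, 3, MISSING),  # tie with coverage
            (5, 0, 0, MISSING),  # covered but no informative reads -> tie at 0
        ],
    )
    def test_examples(self, depth, ref, alt, expected):
        assert call_haploid_genotype(depth, ref, alt) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            call_haploid_genotype(5, -1, 2)

    def test_counts_exceeding_depth_rejected(self):
        with pytest.raises(ValueError):
            call_haploid_genotype(5, 4, 4)

    @given(
        st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_under_ref_alt_swap(self, gap, ref, alt):
        depth = ref + alt + gap
        call = call_haploid_genotype(depth, ref, alt)
        swapped = call_haploid_genotype(depth, alt, ref)
        flip = {REF: ALT, ALT: REF, MISSING: MISSING}
        assert swapped == flip[call]

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        ref = rng.integers(0, 10, (20, 5))
        alt = rng.integers(0, 10, (20, 5))
        depth = ref + alt + rng.integers(0, 3, (20, 5))
        obs = make_obs(depth, ref, alt)
        gt = call_genotypes(obs)
        for i in range(20):
            for j in range(5):
                assert gt.calls[i, j] == call_haploid_genotype(
                    depth[i, j], ref[i, j], alt[i, j]
                )


class TestCellMask:
    def _one_cell(self, depth, ref, alt, combine="AND"):
        obs = make_obs([[depth]], [[ref]], [[alt]])
        gt = call_genotypes(obs)
        masked = mask_unreliable_cells(gt, obs, NucleusMaskRule(combine=combine))
        return gt.calls[0, 0], masked.calls[0, 0]

    def test_low_depth_ambiguous_af_masked(self):
        _, after = self._one_cell(4, 2, 2)
        assert after == MISSING

    def test_deep_ambiguous_unchanged_with_and(self):
        before, after = self._one_cell(30, 15, 15)
        assert after == before

    def test_deep_ambiguous_masked_with_or(self):
        _, after = self._one_cell(30, 15, 15, combine="OR")
        assert after == MISSING

    def test_low_depth_clean_af_unchanged_with_and(self):
        before, after = self._one_cell(4, 0, 4)
        assert before == ALT and after == ALT

    @pytest.mark.parametrize("combine", ["AND", "OR"])
    @pytest.mark.parametrize("ref,alt", [(9, 1), (1, 9)])  # AF exactly 0.1 / 0.9
    def test_af_boundaries_never_mask(self, combine, ref, alt):
        before, after = self._one_cell(10, ref, alt, combine=combine)
        assert after == before != MISSING

    def test_zero_informative_reads_not_ambiguous(self):
        # depth >= min_depth, all reads gated out: AF undefined -> unmasked
        before, after = self._one_cell(8, 0, 0, combine="OR")
        assert after == before == MISSING  # stays MISSING from the tie rule
        obs = make_obs([[8]], [[0]], [[0]])
        gt = GenotypeMatrix(obs.sites, np.array([[REF]], dtype=np.int8))
        masked = mask_unreliable_cells(gt, obs, NucleusMaskRule(combine="OR"))
        assert masked.calls[0, 0] == REF

    def test_invalid_combine_rejected(self):
        with pytest.raises(ValueError, match="combine"):
            NucleusMaskRule(combine="XOR")


class TestMissingness:
    def _matrix(self, missing_per_site, n_nuclei=9, n_sites=None):
        rows = []
        for m in missing_per_site:
            row = [MISSING] * m + [ALT] + [REF] * (n_nuclei - m - 1)
            rows.append(row)
        sites = [Site("c", i + 1, "A", "T") for i in range(len(rows))]
        return GenotypeMatrix(sites, np.array(rows, dtype=np.int8))

    def test_exact_third_retained(self):
        gt = self._matrix([3])  # 3 of 9 = exactly 1/3, not strictly greater
        retained, report = filter_by_missingness(gt)
        assert retained.tolist() == [0]
        assert report.n_sites_removed_missingness == 0

    def test_above_third_removed(self):
        gt = self._matrix([4])  # 4/9 > 1/3
        retained, report = filter_by_missingness(gt)
        assert retained.tolist() == []
        assert report.n_sites_removed_missingness == 1

    def test_no_missing_is_identity(self):
        gt = self._matrix([0, 0, 0])
        retained, _ = filter_by_missingness(gt)
        assert retained.tolist() == [0, 1, 2]

    def test_exact_third_scales_with_nucleus_count(self):
        for k in (1, 2, 5, 11):
            gt = self._matrix([k], n_nuclei=3 * k)
            retained, _ = filter_by_missingness(gt)
            assert retained.tolist() == [0], f"3k={3 * k}"

    def test_mismatched_n_nuclei_rejected(self):
        gt = self._matrix([0])
        with pytest.raises(ValueError, match="n_nuclei"):
            filter_by_missingness(gt, n_nuclei=5)


class TestExtractSnpSites:
    def test_all_ref_gives_empty(self):
        sites = [Site("c", 1, "A", "T")]
        gt = GenotypeMatrix(sites, np.full((1, 5), REF, dtype=np.int8))
        assert extract_snp_sites(gt, np.array([0])) == []

    def test_single_alt_among_nineteen(self):
        sites = [Site("c", 1, "A", "T")]
        calls = np.full((1, 19), REF, dtype=np.int8)
        calls[0, 7] = ALT
        gt = GenotypeMatrix(sites, calls)
        assert extract_snp_sites(gt, np.array([0])) == sites

    def test_matches_naive_scan(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([REF, ALT, MISSING], size=(10, 6)).astype(np.int8)
        sites = [Site("c", i + 1, "A", "T") for i in range(10)]
        gt = GenotypeMatrix(sites, calls)
        retained = np.arange(10)
        expected = [
            sites[i] for i in range(10)
            if any(calls[i, j] == ALT for j in range(6))
        ]
        assert extract_snp_sites(gt, retained) == expected


def _scripted_oracle(obs, ann, thr, rule, max_missing):
    """Independent per-site/per-cell re-implementation with plain loops."""
    snps = []
    for i, site in enumerate(obs.sites):
        if ann.qd[i] < thr.qd_min or ann.fs[i] > thr.fs_max:
            continue
        if ann.mq[i] < thr.mq_min or ann.qual[i] < thr.qual_min:
            continue
        if ann.sor[i] > thr.sor_max:
            continue
        if not ann.mq_rank_sum_missing[i] and ann.mq_rank_sum[i] < thr.mqranksum_min:
            continue
        if (not ann.read_pos_rank_sum_missing[i]
                and ann.read_pos_rank_sum[i] < thr.readposranksum_min):
            continue
        calls = []
        for j in range(obs.n_nuclei):
            d = obs.depth[i, j]
            r, a = obs.ref_count[i, j], obs.alt_count[i, j]
            if d == 0 or r == a:
                call = "MISS"
            elif r > a:
                call = "REF"
            else:
                call = "ALT"
            low = d < rule.min_depth
            amb = (r + a) > 0 and rule.af_low < a / (r + a) < rule.af_high
            hit = (low and amb) if rule.combine == "AND" else (low or amb)
            if hit:
                call = "MISS"
            calls.append(call)
        n_missing = calls.count("MISS")
        if n_missing / obs.n_nuclei > max_missing:
            continue
        if "ALT" in calls:
            snps.append(site)
    return snps


class TestFilterChain:
    def test_empty_input(self):
        obs = make_obs(np.zeros((0, 4)), np.zeros((0, 4)), np.zeros((0, 4)))
        snps, report = run_filter_chain(obs, make_annotations(0))
        assert snps == []
        assert report.n_sites_input == 0
        assert report.n_snp_sites == 0

    def test_single_hard_filter_failure_isolated(self):
        depth = np.full((2, 4), 20)
        alt = np.full((2, 4), 20)
        obs = make_obs(depth, depth - alt, alt)
        ann = make_annotations(2, qd=[25.0, 1.0])
        snps, report = run_filter_chain(obs, ann)
        assert report.n_failed_hard_filters == 1
        assert [s.pos for s in snps] == [1]

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("combine", ["AND", "OR"])
    def test_matches_scripted_oracle_on_random_fixtures(self, seed, combine):
        rng = np.random.default_rng(seed)
        n_sites, n_nuclei = 50, 10
        depth = rng.integers(0, 12, (n_sites, n_nuclei))
        split = rng.random((n_sites, n_nuclei))
        informative = rng.binomial(depth, 0.9)
        alt = np.rint(informative * split).astype(np.int64)
        ref = informative - alt
        obs = make_obs(depth, ref, alt)
        ann = make_annotations(
            n_sites,
            qd=rng.uniform(0, 10, n_sites),
            fs=rng.uniform(0, 100, n_sites),
            sor=rng.uniform(0, 4, n_sites),
            mqrs=rng.uniform(-15, 2, n_sites),
            mqrs_missing=rng.random(n_sites) < 0.2,
        )
        thr, rule = HardFilterThresholds(), NucleusMaskRule(combine=combine)
        snps, report = run_filter_chain(obs, ann, thr, rule, 1 / 3)
        expected = _scripted_oracle(obs, ann, thr, rule, 1 / 3)
        assert snps == expected
        assert report.n_snp_sites == len(expected)

    def test_report_counts_are_consistent(self):
        rng = np.random.default_rng(7)
        depth = rng.integers(0, 30, (40, 8))
        alt = rng.binomial(depth, 0.4)
        obs = make_obs(depth, depth - alt, alt)
        ann = make_annotations(40, qd=rng.uniform(0, 30, 40))
        snps, report = run_filter_chain(obs, ann)
        assert report.n_sites_input == 40
        assert 0 <= report.n_snp_sites <= 40 - report.n_failed_hard_filters
        assert report.n_all_alt_sites <= report.n_snp_sites

    def test_perfect_recovery_on_noiseless_heterokaryon(self):
        # error 0, no dropout: output is exactly the simulated truth set
        ref = simulate_reference(200_000, 2, 0.2, 0.1, 1)
        truth = simulate_nucleus_population(
            ref, 10, "heterokaryon", divergence_per_kb=0.5,
            private_mut_per_kb=0.1, seed=2,
        )
        obs, ann = simulate_observations(
            truth, ref, ObsParams(mean_depth=30), seed=3,
            annotation_violation_rate=0.0,
        )
        snps, _ = run_filter_chain(obs, ann)
        assert [(s.contig, s.pos) for s in snps] == [
            (v.contig, v.pos) for v in truth.variant_sites
        ]


@pytest.fixture(scope="module")
def noisy_fixture():
    ref = simulate_reference(100_000, 2, 0.1, 0.1, 5)
    truth = simulate_nucleus_population(
        ref, 12, "heterokaryon", divergence_per_kb=1.0,
        private_mut_per_kb=0.2, seed=6,
    )
    return simulate_observations(
        truth, ref,
        ObsParams(mean_depth=8, depth_dispersion=0.8, dropout_rate=0.15,
                  error_rate=0.05),
        seed=7,
    )


class TestMonotonicity:
    def _count(self, fixture, rule=None, max_missing=1 / 3):
        obs, ann = fixture
        snps, _ = run_filter_chain(obs, ann, rule=rule,
                                   max_missing_fraction=max_missing)
        return len(snps)

    def test_raising_min_depth_never_increases_snps(self, noisy_fixture):
        counts = [
            self._count(noisy_fixture, NucleusMaskRule(min_depth=d, combine="OR"))
            for d in (0, 3, 5, 8, 12)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_widening_af_band_never_increases_snps(self, noisy_fixture):
        counts = [
            self._count(
                noisy_fixture,
                NucleusMaskRule(af_low=lo, af_high=hi, combine="OR"),
            )
            for lo, hi in ((0.45, 0.55), (0.3, 0.7), (0.1, 0.9), (0.01, 0.99))
        ]
        assert counts == sorted(counts, reverse=True)

    def test_lowering_max_missing_never_increases_snps(self, noisy_fixture):
        counts = [
            self._count(noisy_fixture, max_missing=f)
            for f in (1.0, 0.5, 1 / 3, 0.2, 0.05)
        ]
        assert counts == sorted(counts, reverse=True)


class TestStageOrder:
    def test_hard_filter_position_changes_counts_not_final_set(self):
        # the site-level hard filter commutes with the cell-level stages,
        # so moving it to the end leaves the final SNP set unchanged while
        # the per-stage accounting differs
        ref = simulate_reference(100_000, 1, 0.0, 0.0, 1)
        truth = simulate_nucleus_population(
            ref, 9, "heterokaryon", divergence_per_kb=3.0, seed=1
        )
        obs, ann = simulate_observations(
            truth, ref,
            ObsParams(mean_depth=6, depth_dispersion=0.9, dropout_rate=0.25,
                      error_rate=0.02),
            seed=2, annotation_violation_rate=0.3,
        )
        rule = NucleusMaskRule(combine="AND")
        snps, report = run_filter_chain(obs, ann, rule=rule)

        # alternative order: cell stages first, hard filters last
        gt = call_genotypes(obs)
        masked = mask_unreliable_cells(gt, obs, rule)
        retained, _ = filter_by_missingness(masked)
        passed = apply_site_hard_filters(ann)
        retained_and_passed = np.array(
            [i for i in retained if passed[i]], dtype=np.int64
        )
        alt_snps = extract_snp_sites(masked, retained_and_passed)
        alt_n_failed_hard = int(sum(~passed[retained]))

        assert alt_snps == snps
        assert alt_n_failed_hard != report.n_failed_hard_filters
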