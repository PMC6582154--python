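"""Platform concordance classification and accuracy summaries."""

import numpy as np
import pytest

from skimgt.concordance import (
    classify_matrices,
    classify_pair,
    dh_adjusted_accuracy,
    optimal_supporting_reads,
    per_sample_accuracy,
    per_snp_accuracy,
    zygosity_breakdown,
)
from skimgt.filters import FilterSpec
from skimgt.types import (
    ConcordanceClass,
    Genotype,
    GenotypeCall,
    GenotypeMatrix,
    SnpLocus,
)

HR, HE, HA, MI = Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT, Genotype.MISSING


def call(gt, dp=3):
    if gt is MI:
        return GenotypeCall(gt=gt, dp=0)
    return GenotypeCall(gt=gt, dp=dp, ad=(dp, 0), pl=(0, 10, 20))


def matrix(gts, dps=None):
    n_loci, n_samples = len(gts), len(gts[0])
    loci = [SnpLocus("chr1", i + 1, "A", "C") for i in range(n_loci)]
    samples = [f"s{j}" for j in range(n_samples)]
    calls = [
        [
            call(g, dp=(dps[i][j] if dps else 3))
            for j, g in enumerate(row)
        ]
        for i, row in enumerate(gts)
    ]
    return GenotypeMatrix(loci, samples, calls)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "ref,query,expected",
        [
            (HR, HR, ConcordanceClass.CONCORDANT),
            (HA, HA, ConcordanceClass.CONCORDANT),
            (HE, HE, ConcordanceClass.CONCORDANT),
            (HE, HR, ConcordanceClass.HET_REF_HOM_QUERY),
            (HE, HA, ConcordanceClass.HET_REF_HOM_QUERY),
            (HR, HE, ConcordanceClass.HOM_REF_HET_QUERY),
            (HA, HE, ConcordanceClass.HOM_REF_HET_QUERY),
            (HR, HA, ConcordanceClass.ALT_HOM),
            (HA, HR, ConcordanceClass.ALT_HOM),
            (MI, HR, ConcordanceClass.NOT_COMPARABLE),
            (HE, MI, ConcordanceClass.NOT_COMPARABLE),
            (MI, MI, ConcordanceClass.NOT_COMPARABLE),
        ],
    )
    def test_exhaustive_classification(self, ref, query, expected):
        assert classify_pair(call(ref), call(query)) is expected


class TestPerSampleAccuracy:
    def test_identical_matrices_fully_concordant(self):
        m = matrix([[HR, HA], [HA, HR], [HE, HE]])
        rep = per_sample_accuracy(m, m)
        assert rep.pooled.pct_concordant == 100.0
        assert rep.pooled.pct_discrepant == 0.0

    def test_one_discrepant_in_ten(self):
        ref = matrix([[HR] * 2] * 5)
        gts = [[HR] * 2 for _ in range(5)]
        gts[0][0] = HA
        query = matrix(gts)
        rep = per_sample_accuracy(ref, query)
        assert rep.pooled.n_comparable == 10
        assert rep.pooled.pct_concordant == 90.0
        assert rep.pooled.pct_discrepant == 10.0

    def test_zero_comparable_flagged(self):
        ref = matrix([[MI, MI]])
        query = matrix([[HR, HA]])
        rep = per_sample_accuracy(ref, query)
        assert rep.pooled.n_comparable == 0
        assert np.isnan(rep.pooled.pct_concordant)

    def test_reference_side_min_depth_two(self):
        # reference dp=1 cells are not comparable (dp_min=2 on reference)
        ref = matrix([[HR]], dps=[[1]])
        query = matrix([[HR]])
        rep = per_sample_accuracy(ref, query)
        assert rep.pooled.n_comparable == 0

    def test_fig2_style_ordering_on_simulation(self, small_study):
        st = small_study
        a_none = per_sample_accuracy(
            st.ref_matrix, st.query_matrix, FilterSpec()
        ).pooled.pct_concordant
        a_hom = per_sample_accuracy(
            st.ref_matrix, st.query_matrix, FilterSpec(drop_het=True)
        ).pooled.pct_concordant
        a_hom_dp = per_sample_accuracy(
            st.ref_matrix, st.query_matrix,
            FilterSpec(drop_het=True, dp_min=2, dp_max=5),
        ).pooled.pct_concordant
        assert a_hom_dp >= a_hom >= a_none

    def test_drop_het_never_lowers_concordance(self, small_study):
        st = small_study
        before = per_sample_accuracy(st.ref_matrix, st.query_matrix)
        after = per_sample_accuracy(
            st.ref_matrix, st.query_matrix, FilterSpec(drop_het=True)
        )
        assert after.pooled.pct_concordant >= before.pooled.pct_concordant


class TestDhAdjustedAccuracy:
    def test_paper_style_arithmetic(self):
        assert dh_adjusted_accuracy(94.7, 5.3, 70.3) == 98.4

    def test_no_discrepancy(self):
        assert dh_adjusted_accuracy(100.0, 0.0, 55.0) == 100.0

    def test_zero_het_share(self):
        assert dh_adjusted_accuracy(90.0, 10.0, 0.0) == 90.0

    def test_bounded_between_concordant_and_100(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            conc = rng.uniform(0, 100)
            share = rng.uniform(0, 100)
            adj = dh_adjusted_accuracy(round(conc, 1), round(100 - conc, 1), share)
            assert round(conc, 1) - 0.05 <= adj <= 100.0

    @pytest.mark.parametrize("args", [(-1, 101, 50), (60, 40, 150), (94, 5, 50)])
    def test_domain_errors(self, args):
        with pytest.raises(ValueError):
            dh_adjusted_accuracy(*args)


class TestPerSnpAccuracy:
    def test_all_correct_hits_100_at_top_threshold(self):
        m = matrix([[HR] * 9] * 4)
        res = per_snp_accuracy(m, m, min_samples=7)
        assert res.n_snps == 4
        assert res.cumulative_pct[-1] == 100.0  # t = 1.0

    def test_single_error_caps_snp_below_one(self):
        ref = matrix([[HR] * 9] * 2)
        gts = [[HR] * 9 for _ in range(2)]
        gts[0][3] = HA
        query = matrix(gts)
        res = per_snp_accuracy(ref, query, min_samples=7)
        key = ("chr1", 1)
        assert res.proportions[key] == pytest.approx(8 / 9)
        # the SNP counts at thresholds <= 8/9 but not at 0.9 or 1.0
        t_idx = {t: i for i, t in enumerate(res.thresholds)}
        assert res.cumulative_pct[t_idx[0.8]] == 100.0
        assert res.cumulative_pct[t_idx[0.9]] == 50.0
        assert res.cumulative_pct[t_idx[1.0]] == 50.0

    def test_min_samples_exclusion(self):
        gts = [[HR] * 6 + [MI] * 3]
        res = per_snp_accuracy(matrix(gts), matrix(gts), min_samples=7)
        assert res.n_snps == 0

    def test_curve_matches_brute_force_tabulation(self, small_study):
        """The cumulative curve must equal an independent tabulation of the
        raw per-cell classification table (pandas pivot route)."""
        import pandas as pd

        st = small_study
        sub = {l.key for l in st.truth.loci[:20]}
        ref = st.ref_matrix.subset_loci(sub)
        query = st.query_matrix.subset_loci(sub)
        res = per_snp_accuracy(ref, query, min_samples=7)

        records = classify_matrices(ref, query)
        df = pd.DataFrame(
            [
                {"locus": r.locus_key, "cls": r.cls.value}
                for r in records
                if r.cls is not ConcordanceClass.NOT_COMPARABLE
            ]
        )
        grp = df.groupby("locus")["cls"]
        props = {
            k: (v == "concordant").mean()
            for k, v in grp
            if len(v) >= 7
        }
        assert set(props) == set(res.proportions)
        for k in props:
            assert res.proportions[k] == pytest.approx(props[k])
        for t, pct in zip(res.thresholds, res.cumulative_pct):
            expect = 100.0 * np.mean(
                [p >= t - 1e-12 for p in props.values()]
            )
            assert pct == pytest.approx(expect, abs=0.05)

    def test_curve_monotone_and_complete_at_zero(self, small_study):
        st = small_study
        res = per_snp_accuracy(st.ref_matrix, st.query_matrix, min_samples=7)
        assert res.cumulative_pct[0] == 100.0  # t = 0
        assert all(
            a >= b for a, b in zip(res.cumulative_pct, res.cumulative_pct[1:])
        )

    def test_dh_adjustment_raises_curve(self, small_study):
        st = small_study
        plain = per_snp_accuracy(st.ref_matrix, st.query_matrix, min_samples=7)
        adj = per_snp_accuracy(
            st.ref_matrix, st.query_matrix, min_samples=7,
            count_het_ref_as_correct=True,
        )
        assert all(a >= p for a, p in zip(adj.cumulative_pct, plain.cumulative_pct))


class TestZygosityBreakdown:
    def test_identical_matrices_all_same(self):
        m = matrix([[HR, HE], [HA, HE]])
        z = zygosity_breakdown(m, m)
        assert z.hom_pct_same == 100.0
        assert z.het_pct_same == 100.0

    def test_one_het_flip_among_twenty(self):
        ref = matrix([[HR] * 4] * 5)
        gts = [[HR] * 4 for _ in range(5)]
        gts[2][1] = HE
        query = matrix(gts)
        z = zygosity_breakdown(ref, query)
        assert z.n_ref_hom == 20
        assert z.hom_pct_discrepant == 5.0
        assert z.hom_discrepant_pct_het == 100.0

    def test_hand_tally_on_mixed_fixture(self):
        ref = matrix(
            [
                [HR, HR, HE],
                [HA, HE, HR],
                [HR, HA, HE],
            ]
        )
        query = matrix(
            [
                [HR, HE, HR],
                [HR, HE, HR],
                [HE, HA, HE],
            ]
        )
        z = zygosity_breakdown(ref, query)
        # reference hom cells: (0,0)ok (0,1)het (1,0)althom (1,2)ok
        # (2,0)het (2,1)ok  -> 3/6 same, discrepant 2 het + 1 hom
        assert z.n_ref_hom == 6
        assert z.hom_pct_same == 50.0
        assert z.hom_discrepant_pct_het == pytest.approx(66.7)
        assert z.hom_discrepant_pct_hom == pytest.approx(33.3)
        # reference het cells: (0,2)hom (1,1)het (2,2)het -> 2/3 same
        assert z.n_ref_het == 3
        assert z.het_pct_same == pytest.approx(66.7)
        assert z.het_pct_query_hom == pytest.approx(33.3)


class TestOptimalSupportingReads:
    def _strata_matrices(self, acc_by_dp, n_per_stratum=30):
        """Build matrices where query accuracy per exact-DP stratum is known."""
        gts_ref, gts_query, dps = [], [], []
        for dp, acc in acc_by_dp.items():
            n_bad = round(n_per_stratum * (1 - acc))
            for i in range(n_per_stratum):
                gts_ref.append([HR])
                gts_query.append([HA if i < n_bad else HR])
                dps.append([dp])
        ref = matrix(gts_ref)
        query = matrix(gts_query, dps=dps)
        return ref, query

    def test_single_peak_recovered(self):
        ref, query = self._strata_matrices({2: 0.7, 3: 0.9, 4: 0.8})
        res = optimal_supporting_reads(ref, query, min_cells=10)
        assert res.optimal_dp["s0"] == 3

    def test_tie_resolves_to_smaller_depth(self):
        ref, query = self._strata_matrices({2: 0.8, 3: 0.8, 4: 0.8})
        res = optimal_supporting_reads(ref, query, min_cells=10)
        assert res.optimal_dp["s0"] == 2

    def test_sparse_strata_excluded(self):
        ref, query = self._strata_matrices({2: 0.7, 3: 1.0}, n_per_stratum=30)
        # add a tiny perfect stratum that must not win
        ref2, query2 = self._strata_matrices({9: 1.0}, n_per_stratum=3)
        loci = [SnpLocus("chr1", i + 1, "A", "C") for i in range(63)]
        refm = GenotypeMatrix(
            loci, ["s0"], ref.calls + ref2.calls
        )
        querym = GenotypeMatrix(
            loci, ["s0"], query.calls + query2.calls
        )
        res = optimal_supporting_reads(refm, querym, min_cells=10)
        assert res.optimal_dp["s0"] == 3
        assert 9 not in res.accuracy_by_dp["s0"]

    def test_optimum_tracks_coverage_on_simulation(self):
        from skimgt.pipeline import run_study, study_config

        depths = tuple(np.linspace(0.5, 5.0, 9))
        cfg = study_config(n_loci=3000, seed=7, query_depths=depths)
        st = run_study(cfg)
        res = optimal_supporting_reads(
            st.ref_matrix, st.query_matrix, coverage=depths
        )
        assert res.pearson_r > 0
        assert res.p_value < 0.05
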