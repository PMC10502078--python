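"""Risk-score engine: panel loading, the four schemes, missing-SNP
handling, subset scores and median dichotomization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import foodgrs as fg
from foodgrs.errors import ConfigurationError, DomainError, FormatError

from conftest import make_genotypes, make_panel


class TestLoadPanel:
    def test_default_panel_has_30_entries(self, panel):
        assert len(panel) == 30
        assert panel.rsids[0] == "rs11165643"
        assert panel.rsids[-1] == "rs3810291"
        assert len(set(panel.rsids)) == 30

    def test_duplicate_rsid_rejected(self, tmp_path, panel):
        df = panel.entries.copy()
        df.loc[len(df)] = df.iloc[24]  # duplicate the FTO row
        p = tmp_path / "dup.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(FormatError, match="rs1421085"):
            fg.load_panel(p)

    def test_missing_column_rejected(self, tmp_path, panel):
        df = panel.entries.drop(columns=["risk_allele"])
        p = tmp_path / "bad.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(FormatError, match="risk_allele"):
            fg.load_panel(p)

    def test_subset_file_preserves_order(self, tmp_path, panel):
        sub = panel.entries.iloc[[5, 2, 9, 0, 7, 1, 3, 11, 4, 6, 8]]
        p = tmp_path / "sub.tsv"
        sub.to_csv(p, sep="\t", index=False)
        loaded = fg.load_panel(p)
        assert len(loaded) == 11
        assert loaded.rsids == list(sub["rsid"])


class TestScore:
    def test_hand_arithmetic_weighted(self):
        panel = make_panel(["rs1", "rs2"], betas_s=[0.1, 0.2])
        gm = make_genotypes([[2, 1]])
        sv = fg.score(gm, panel, "speliotes")
        assert sv.values.iloc[0] == pytest.approx((0.2 + 0.2) / 2)

    def test_unit_weights_equal_unweighted_over_panel_size(self, rng):
        rsids = [f"rs{i}" for i in range(8)]
        panel = make_panel(rsids, betas_s=[1.0] * 8)
        gm = make_genotypes(rng.integers(0, 3, size=(25, 8)), rsids=rsids)
        w = fg.score(gm, panel, "speliotes").values
        u = fg.score(gm, panel, "unweighted").values
        assert np.allclose(w, u / 8, atol=1e-14)

    def test_matches_brute_force_oracle_with_missingness(self, rng):
        m = 30
        rsids = [f"rs{i}" for i in range(m)]
        betas = rng.uniform(0.05, 0.4, size=m)
        panel = make_panel(rsids, betas_s=list(betas))
        arr = rng.integers(0, 3, size=(50, m)).astype(float)
        arr[rng.random(arr.shape) < 0.05] = np.nan
        # keep at least one non-missing SNP per row
        arr[:, 0] = rng.integers(0, 3, size=50)
        gm = make_genotypes(arr, rsids=rsids)
        for scheme in ("unweighted", "speliotes", "finhit", "ratio"):
            sv = fg.score(gm, panel, scheme)
            w = panel.weights(scheme).to_numpy()
            for i in range(50):
                tot, nn = 0.0, 0
                for j in range(m):
                    if not np.isnan(arr[i, j]):
                        nn += 1
                        tot += (1.0 if scheme == "unweighted" else w[j]) * arr[i, j]
                expect = tot if scheme == "unweighted" else tot / nn
                assert sv.values.iloc[i] == pytest.approx(expect, abs=1e-12)

    def test_per_allele_flag_halves_weighted_score(self, rng):
        panel = make_panel(["rs1", "rs2", "rs3"], betas_s=[0.1, 0.2, 0.3])
        gm = make_genotypes(rng.integers(0, 3, size=(10, 3)))
        a = fg.score(gm, panel, "speliotes").values
        b = fg.score(gm, panel, "speliotes", per_allele=True).values
        assert np.allclose(a, 2 * b)

    def test_all_missing_individual_excluded_with_warning(self):
        panel = make_panel(["rs1", "rs2"])
        gm = make_genotypes([[1, 2], [np.nan, np.nan]])
        with pytest.warns(UserWarning, match="all panel SNPs missing"):
            sv = fg.score(gm, panel, "unweighted")
        assert sv.individual_ids == ["s1"]

    def test_panel_rsid_absent_from_genotypes_errors(self, panel):
        gm = make_genotypes([[1, 2]], rsids=panel.rsids[:2])
        with pytest.raises(ConfigurationError, match="absent"):
            fg.score(gm, panel)

    def test_permutation_invariance(self, rng, panel, small_study):
        gm = small_study.genotypes
        sv = fg.score(gm, panel, "speliotes")
        perm_cols = rng.permutation(gm.rsids)
        perm_rows = rng.permutation(gm.individual_ids)
        gm2 = fg.GenotypeMatrix(gm.dosage.loc[perm_rows, perm_cols])
        sv2 = fg.score(gm2, panel, "speliotes")
        assert np.allclose(
            sv.values.sort_index(), sv2.values.sort_index(), atol=1e-12
        )

    @given(st.integers(0, 29), st.integers(0, 49))
    def test_adding_risk_allele_never_decreases_any_scheme(self, j, i):
        rng = np.random.default_rng(7)
        m = 30
        rsids = [f"rs{k}" for k in range(m)]
        panel = make_panel(
            rsids,
            betas_s=list(rng.uniform(0.05, 0.4, size=m)),
            betas_f=list(rng.uniform(0.05, 0.4, size=m)),
        )
        arr = rng.integers(0, 3, size=(50, m)).astype(float)
        if arr[i, j] == 2:
            arr[i, j] = 1
        gm = make_genotypes(arr.copy(), rsids=rsids)
        arr2 = arr.copy()
        arr2[i, j] += 1
        gm2 = make_genotypes(arr2, rsids=rsids)
        for scheme in ("unweighted", "speliotes", "finhit", "ratio"):
            a = fg.score(gm, panel, scheme).values.iloc[i]
            b = fg.score(gm2, panel, scheme).values.iloc[i]
            assert b >= a - 1e-12


class TestSubsetScore:
    def test_full_subset_identical_to_whole_score(self, panel, small_study):
        gm = small_study.genotypes
        a = fg.score(gm, panel, "unweighted").values
        b = fg.subset_score(gm, panel, panel.rsids, "unweighted").values
        assert a.equals(b)

    def test_single_snp_subset_equals_dosage(self, panel, small_study):
        gm = small_study.genotypes
        sv = fg.subset_score(gm, panel, ["rs1421085"])
        d = gm.dosage["rs1421085"].fillna(0.0)
        assert np.allclose(sv.values, d)

    def test_pizza_subset_bounded_by_two_alleles_per_snp(
        self, panel, small_study
    ):
        from foodgrs.reference import load_published_food_grs

        rsids = load_published_food_grs()["pizza"]
        assert len(rsids) == 11
        sv = fg.subset_score(small_study.genotypes, panel, rsids)
        assert sv.values.max() <= 22

    def test_unknown_rsid_rejected(self, panel, small_study):
        with pytest.raises(ConfigurationError):
            fg.subset_score(small_study.genotypes, panel, ["rs999"])


class TestDichotomize:
    def test_three_point_case(self):
        sv = fg.ScoreVector(
            values=pd.Series([1.0, 2.0, 3.0], index=list("abc")),
            scheme="unweighted",
            n_nonmissing=pd.Series([2, 2, 2], index=list("abc")),
        )
        labels, cutoff = fg.dichotomize(sv)
        assert cutoff == 2
        assert list(labels) == ["low", "low", "high"]

    def test_median_value_goes_to_low_group(self, rng):
        counts = pd.Series(rng.integers(17, 40, size=501).astype(float))
        labels, cutoff = fg.median_split(counts)
        assert (counts[labels == "low"] <= cutoff).all()
        assert (counts[labels == "high"] > cutoff).all()

    def test_constant_vector_all_low_with_warning(self):
        v = pd.Series([5.0] * 4)
        with pytest.warns(UserWarning, match="constant"):
            labels, _ = fg.median_split(v)
        assert (labels == "low").all()

    def test_single_individual_rejected(self):
        with pytest.raises(DomainError):
            fg.median_split(pd.Series([1.0]))
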