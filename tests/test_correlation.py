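"""Spearman statistics, F/B ratio, and the correlation network."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from synscav.correlation import (
    AbundanceTable,
    BiomarkerTable,
    build_network,
    edges_to_frame,
    fb_ratio,
    read_abundance_tsv,
    read_biomarker_tsv,
    relative_abundance,
    spearman_pvalue,
    spearman_rho,
    spearman_test,
)
from synscav.errors import (
    JoinError,
    MissingPhylumError,
    NormalizationError,
    UndefinedCorrelationError,
    ValidationError,
)
from synscav.simulate import PlantedLink, simulate_association_tables


def _phylum_table(data: dict, samples=("s1", "s2", "s3")) -> AbundanceTable:
    df = pd.DataFrame(data, index=list(samples)).T
    return AbundanceTable(data=df, ranks=pd.Series("phylum", index=df.index))


class TestRelativeAbundance:
    def test_counts_normalize(self):
        t = AbundanceTable.from_frame(pd.DataFrame({"s1": [2.0, 3.0, 5.0]}, index=list("abc")))
        out = relative_abundance(t)
        assert list(out.data["s1"]) == [0.2, 0.3, 0.5]

    def test_idempotent(self):
        t = AbundanceTable.from_frame(pd.DataFrame({"s1": [0.25, 0.75]}, index=list("ab")))
        out = relative_abundance(relative_abundance(t))
        assert np.allclose(out.data["s1"], [0.25, 0.75])

    def test_all_zero_sample_named_in_error(self):
        t = AbundanceTable.from_frame(pd.DataFrame({"good": [1.0], "dead": [0.0]}, index=["a"]))
        with pytest.raises(NormalizationError, match="dead"):
            relative_abundance(t)


class TestFBRatio:
    def test_simple_ratio(self):
        t = _phylum_table({"Firmicutes": [0.2, 0.3, 0.1], "Bacteroidota": [0.1, 0.3, 0.0]})
        r = fb_ratio(t)
        assert r["s1"] == pytest.approx(2.0)
        assert r["s2"] == pytest.approx(1.0)
        assert np.isnan(r["s3"])  # undefined, flagged not fatal

    def test_synonym_and_case_insensitive_match(self):
        t = _phylum_table({"firmicutes": [0.4] * 3, "Bacteroidetes": [0.2] * 3})
        assert np.allclose(fb_ratio(t), 2.0)

    def test_missing_phylum_is_labeled_error(self):
        t = _phylum_table({"Firmicutes": [0.2] * 3})
        with pytest.raises(MissingPhylumError, match="bacteroidota"):
            fb_ratio(t)

    def test_scale_invariance(self):
        t = _phylum_table({"Firmicutes": [0.2, 4.0, 9.0], "Bacteroidota": [0.1, 2.0, 3.0]})
        scaled = AbundanceTable(data=t.data * 7.5, ranks=t.ranks)
        pd.testing.assert_series_equal(fb_ratio(t), fb_ratio(scaled))

    def test_genus_rank_rejected(self):
        df = pd.DataFrame({"s1": [1.0]}, index=["Firmicutes"])
        t = AbundanceTable.from_frame(df, rank="genus")
        with pytest.raises(ValidationError):
            fb_ratio(t)


class TestSpearmanRho:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert spearman_rho(x, x**3) == 1.0
        assert spearman_rho(x, -x) == -1.0

    def test_ties_match_rank_then_correlate_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 4.0])
        y = np.array([10.0, 20.0, 30.0, 40.0])
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert spearman_rho(x, y) == pytest.approx(oracle, rel=1e-12)

    @given(st.integers(0, 2**31 - 1), st.integers(5, 20))
    @settings(max_examples=30, deadline=None)
    def test_matches_scipy_on_random_data(self, seed, n):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=n), rng.normal(size=n)
        assert spearman_rho(x, y) == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=10), rng.normal(size=10)
        rho = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(rho, abs=1e-12)
        assert spearman_rho(x, 3 * y + 7) == pytest.approx(rho, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_rho(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))


class TestSpearmanPValue:
    def test_exact_n3_monotone_enumeration(self):
        # All 6 orderings of 3 ranks: |rho| in {1, 1, .5, .5, .5, .5}; two reach 1.
        assert spearman_pvalue(1.0, 3, "exact_permutation") == pytest.approx(1 / 3)

    def test_zero_rho_has_p_one(self):
        for n in (4, 6, 8):
            assert spearman_pvalue(0.0, n, "exact_permutation") == pytest.approx(1.0)
        assert spearman_pvalue(0.0, 30, "t_approx") == pytest.approx(1.0)

    def test_t_approx_matches_permutation_monte_carlo(self):
        rho_obs, n = 0.5, 30
        p_t = spearman_pvalue(rho_obs, n, "t_approx")
        rng = np.random.default_rng(12345)
        base = np.arange(n, dtype=float)
        draws = 20000
        count = 0
        for _ in range(draws):
            perm = rng.permutation(n).astype(float)
            rho = np.corrcoef(base, perm)[0, 1]
            count += abs(rho) >= rho_obs - 1e-12
        p_mc = count / draws
        se = np.sqrt(p_mc * (1 - p_mc) / draws)
        assert abs(p_t - p_mc) < 3 * se + 1e-4

    def test_perfect_correlation_t_approx_returns_positive_floor(self):
        p = spearman_pvalue(1.0, 10, "t_approx")
        assert 0 < p < 1e-100

    def test_auto_switches_at_small_n(self):
        assert spearman_pvalue(1.0, 3, "auto") == spearman_pvalue(1.0, 3, "exact_permutation")
        assert spearman_pvalue(0.5, 30, "auto") == spearman_pvalue(0.5, 30, "t_approx")

    def test_exact_p_symmetric_in_inputs(self):
        x = np.array([3.0, 1.0, 2.0, 5.0])
        y = np.array([10.0, 30.0, 20.0, 40.0])
        assert spearman_test(x, y, "exact_permutation")[1] == pytest.approx(
            spearman_test(y, x, "exact_permutation")[1]
        )


class TestNetwork:
    def _tables(self, seed=0, links=(), n=12, noise=0.0):
        a, b = simulate_association_tables(
            n, ["Cetobacterium", "Bosea", "Mycobacterium"], ["NRF2", "GPX", "SOD"],
            links=links, noise=noise, seed=seed,
        )
        return AbundanceTable.from_frame(a), BiomarkerTable(b)

    def test_planted_link_is_single_strong_edge(self):
        at, bt = self._tables(links=[PlantedLink("Cetobacterium", "NRF2", "positive")])
        edges = build_network(at, bt, alpha=1e-4)
        assert len(edges) == 1
        e = edges[0]
        assert (e.taxon, e.marker, e.rho, e.sign) == ("Cetobacterium", "NRF2", 1.0, "positive")

    def test_boundary_p_equal_alpha_included(self):
        samples = ["s1", "s2", "s3"]
        at = AbundanceTable.from_frame(
            pd.DataFrame([[1.0, 2.0, 3.0]], index=["T"], columns=samples)
        )
        bt = BiomarkerTable(pd.DataFrame([[1.0, 2.0, 3.0]], index=["M"], columns=samples))
        # n = 3 monotone: exact two-sided p = 1/3; inclusive threshold keeps it.
        edges = build_network(at, bt, alpha=1 / 3, p_method="exact_permutation")
        assert len(edges) == 1

    def test_bh_edges_are_subset_of_unadjusted(self):
        at, bt = self._tables(seed=9, links=[PlantedLink("Bosea", "SOD", "negative")], noise=0.5)
        raw = {(e.taxon, e.marker) for e in build_network(at, bt, adjust="none")}
        bh = {(e.taxon, e.marker) for e in build_network(at, bt, adjust="bh")}
        assert bh <= raw

    def test_deterministic_lexicographic_ordering(self):
        at, bt = self._tables(seed=4)
        edges = build_network(at, bt, alpha=1.0)
        keys = [(e.taxon, e.marker) for e in edges]
        assert keys == sorted(keys)

    def test_no_shared_samples_is_join_error(self):
        at = AbundanceTable.from_frame(
            pd.DataFrame([[1.0, 2.0, 3.0]], index=["T"], columns=["a1", "a2", "a3"])
        )
        bt = BiomarkerTable(pd.DataFrame([[1.0, 2.0, 3.0]], index=["M"], columns=["b1", "b2", "b3"]))
        with pytest.raises(JoinError):
            build_network(at, bt)

    def test_edge_frame_layout(self):
        at, bt = self._tables(links=[PlantedLink("Cetobacterium", "GPX", "positive")])
        df = edges_to_frame(build_network(at, bt, alpha=1e-4))
        assert list(df.columns) == ["taxon", "marker", "rho", "p", "sign"]


class TestTableIO:
    def test_abundance_and_biomarker_round_trip(self, tmp_path):
        ap = tmp_path / "abund.tsv"
        ap.write_text(
            "taxon\trank\ts1\ts2\ts3\ts4\n"
            "Cetobacterium\tgenus\t1\t2\t3\t4\n"
            "Bosea\tgenus\t4\t3\t2\t1\n"
        )
        bp = tmp_path / "markers.tsv"
        bp.write_text("marker\ts1\ts2\ts3\ts4\nNRF2\t1\t2\t3\t4\n")
        at = read_abundance_tsv(ap)
        bt = read_biomarker_tsv(bp)
        # n = 4 monotone: exact two-sided p = 2/24 = 1/12.
        edges = build_network(at, bt, alpha=0.1, p_method="exact_permutation")
        assert {(e.taxon, e.sign) for e in edges} == {
            ("Cetobacterium", "positive"), ("Bosea", "negative"),
        }
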