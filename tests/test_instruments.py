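import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivmr.errors import DomainError
from ivmr.instruments import (LDReference, SelectionConfig,
                              TraitAssociationCatalog, build_instrument_set,
                              f_statistic, ld_clump, screen_confounders,
                              select_significant, variance_explained)
from ivmr.simulate import SimulationConfig, simulate_study
from ivmr.sumstats import SummaryStatsTable

from conftest import snp


class TestSelectSignificant:
    def test_threshold_is_strict(self):
        t = SummaryStatsTable("x", [snp("rs1", pvalue=1e-9),
                                    snp("rs2", pos=2000, pvalue=1e-7)])
        kept = select_significant(t, 5e-8)
        assert kept.rsids == ["rs1"]
        assert kept.provenance[-1].dropped == ["rs2"]

    def test_threshold_one_keeps_all(self, small_table):
        assert len(select_significant(small_table, 1.0)) == 3

    def test_matches_brute_force_on_simulated_nulls(self):
        study = simulate_study(SimulationConfig(k=1, n_null_snps=1000, seed=11))
        t = study.exposure_table
        kept = select_significant(t, 5e-8)
        brute = sum(1 for r in t.records if r.pvalue < 5e-8)
        assert len(kept) == brute
        assert len(kept) + len(kept.provenance[-1].dropped) == len(t)

    def test_output_sorted_by_pvalue(self, small_table):
        kept = select_significant(small_table, 1.0)
        ps = [r.pvalue for r in kept.records]
        assert ps == sorted(ps)


def _ld(pairs, positions):
    ref = LDReference()
    for (a, b), r2 in pairs.items():
        ref.set_r2(a, b, r2)
    ref.positions.update(positions)
    return ref


class TestLDClump:
    def test_pair_outside_window_both_kept(self):
        # 20,001 kb apart with r2 = 0.9: distance exceeds the window
        t = SummaryStatsTable("x", [snp("rs1", pos=1, pvalue=1e-10),
                                    snp("rs2", pos=20_001_001, pvalue=1e-9)])
        ld = _ld({("rs1", "rs2"): 0.9},
                 {"rs1": ("1", 1), "rs2": ("1", 20_001_001)})
        assert len(ld_clump(t, ld)) == 2

    def test_hand_traced_greedy_pass(self):
        # rs1 (best p) removes rs2 (r2 = 0.5) but not rs3 (r2 = 0.0005)
        t = SummaryStatsTable("x", [snp("rs1", pos=1000, pvalue=1e-10),
                                    snp("rs2", pos=2000, pvalue=1e-9),
                                    snp("rs3", pos=3000, pvalue=1e-8)])
        ld = _ld({("rs1", "rs2"): 0.5, ("rs1", "rs3"): 0.0005},
                 {"rs1": ("1", 1000), "rs2": ("1", 2000), "rs3": ("1", 3000)})
        out = ld_clump(t, ld, r2_max=0.001, window_kb=10_000)
        assert out.rsids == ["rs1", "rs3"]
        assert out.provenance[-1].details["removed_by"] == {"rs2": "rs1"}

    def test_no_ld_is_identity(self, small_table):
        ld = _ld({}, {r.rsid: (r.chrom, r.pos) for r in small_table.records})
        assert len(ld_clump(small_table, ld)) == 3

    def test_output_independent_postcheck_and_order_invariance(self):
        rng = np.random.default_rng(3)
        records = [snp(f"rs{i}", chrom=str(1 + i % 3), pos=1000 + (i // 3) * 5000,
                       pvalue=float(rng.uniform(1e-12, 1e-6)))
                   for i in range(20)]
        positions = {r.rsid: (r.chrom, r.pos) for r in records}
        pairs = {}
        for a, b in itertools.combinations(records, 2):
            if a.chrom == b.chrom and rng.random() < 0.5:
                pairs[(a.rsid, b.rsid)] = float(rng.uniform(0, 1))
        ld = _ld(pairs, positions)
        t = SummaryStatsTable("x", records)
        out = ld_clump(t, ld, r2_max=0.1, window_kb=10)
        # exhaustive post-check: no kept pair within window has r2 > r2_max
        for a, b in itertools.combinations(out.records, 2):
            if a.chrom == b.chrom and abs(a.pos - b.pos) <= 10_000:
                assert ld.r2(a.rsid, b.rsid) <= 0.1
        # row-order invariance
        shuffled = SummaryStatsTable("x", [records[i] for i in
                                           rng.permutation(len(records))])
        assert ld_clump(shuffled, ld, r2_max=0.1, window_kb=10).rsids == out.rsids

    def test_snp_without_position_retained_and_logged(self):
        t = SummaryStatsTable("x", [snp("rs1", pvalue=1e-10),
                                    snp("rs2", pos=2000, pvalue=1e-9)])
        ld = _ld({("rs1", "rs2"): 0.99}, {})
        out = ld_clump(t, ld)
        # positions fall back to the record's own coordinates
        assert "rs2" not in out.rsids
        assert set(out.provenance[-1].details["not_in_ld_reference"]) == {"rs1", "rs2"}


class TestScreenConfounders:
    def test_empty_catalog_is_identity(self, small_table):
        out = screen_confounders(small_table, TraitAssociationCatalog(),
                                 {"smoking"})
        assert len(out) == 3

    def test_direct_hit_removed(self, small_table):
        cat = TraitAssociationCatalog([("rs1", "smoking", 1e-9)])
        out = screen_confounders(small_table, cat, {"smoking"})
        assert "rs1" not in out.rsids and len(out) == 2

    @pytest.mark.parametrize("proxy_r2, cat_p, listed, removed", [
        (0.85, 1e-10, True, True),    # strong proxy, significant, listed
        (0.75, 1e-10, True, False),   # proxy below r2 threshold
        (0.85, 1e-4, True, False),    # association not significant
        (0.85, 1e-10, False, False),  # trait not a listed confounder
    ])
    def test_proxy_rule_table(self, small_table, proxy_r2, cat_p, listed, removed):
        cat = TraitAssociationCatalog([("rsP", "smoking", cat_p)],
                                      proxies={"rs1": [("rsP", proxy_r2)]})
        traits = {"smoking"} if listed else {"bmi"}
        out = screen_confounders(small_table, cat, traits,
                                 p_thr=5e-8, proxy_r2=0.80)
        assert ("rs1" not in out.rsids) == removed


class TestStrengthMetrics:
    def test_variance_explained_direct(self):
        assert variance_explained(snp(eaf=0.5, beta=0.1)) == pytest.approx(0.005)

    def test_zero_beta_gives_zero(self):
        assert variance_explained(snp(beta=0.0)) == 0.0

    def test_maf_folding_symmetry(self):
        assert variance_explained(snp(eaf=0.9)) == pytest.approx(
            variance_explained(snp(eaf=0.1)))

    def test_trait_sd_domain(self):
        with pytest.raises(DomainError):
            variance_explained(snp(), trait_sd=0.0)

    def test_f_direct_substitution(self):
        assert f_statistic(0.005, 1001, 1) == pytest.approx(5.0201, abs=1e-4)

    def test_f_zero_r2(self):
        assert f_statistic(0.0, 100, 2) == 0.0

    def test_f_domain_error(self):
        with pytest.raises(DomainError):
            f_statistic(0.01, 3, 2)

    @given(r2=st.floats(0.001, 0.5), n=st.integers(100, 10_000),
           k=st.integers(1, 40))
    @settings(max_examples=50, deadline=None)
    def test_f_monotone_in_r2_and_n(self, r2, n, k):
        f = f_statistic(r2, n, k)
        assert f_statistic(min(r2 * 1.1, 0.999), n, k) >= f
        assert f_statistic(r2, n + 50, k) >= f


class TestBuildInstrumentSet:
    def test_passthrough_without_confounders(self):
        study = simulate_study(SimulationConfig(k=10, n_null_snps=200, seed=21))
        cfg = SelectionConfig(n_exposure=86_640)
        iv = build_instrument_set(study.exposure_table, study.ld, study.catalog, cfg)
        sig = select_significant(study.exposure_table, 5e-8)
        assert iv.rsids == sig.rsids  # no LD, no confounders: same set
        assert iv.total_r2 == pytest.approx(sum(iv.per_snp_r2.values()))
        assert iv.f_statistic > 0 and iv.is_strong is not None

    def test_planted_confounder_appears_in_drop_log(self):
        spec = (("rs1002", "smoking", 1e-10),)
        study = simulate_study(SimulationConfig(k=10, seed=22,
                                                confounder_spec=spec))
        cfg = SelectionConfig(n_exposure=86_640,
                              confounder_traits=("smoking",))
        iv = build_instrument_set(study.exposure_table, study.ld,
                                  study.catalog, cfg)
        screen = [e for e in iv.provenance if e.step == "screen_confounders"][0]
        assert screen.dropped == ["rs1002"]
        assert iv.k == 9

    def test_provenance_conserves_counts(self):
        study = simulate_study(SimulationConfig(k=10, n_null_snps=100, seed=23,
                                                ld_block_spec=((3, 0.9),)))
        cfg = SelectionConfig(n_exposure=86_640)
        iv = build_instrument_set(study.exposure_table, study.ld, study.catalog, cfg)
        for e in iv.provenance:
            if e.step.startswith("warning"):
                continue
            assert e.n_in == e.n_out + len(e.dropped)

    def test_empty_set_is_warning_not_error(self, small_table):
        ld = LDReference()
        iv = build_instrument_set(small_table, ld, None,
                                  SelectionConfig(p_threshold=1e-30))
        assert iv.k == 0
        assert any(e.step == "warning_empty_set" for e in iv.provenance)
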