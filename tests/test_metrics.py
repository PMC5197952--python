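import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rtsig import metrics
from rtsig.metrics import (CsaConfig, arrest_rate, csa, csa_profile,
                           heterogeneous_sites, high_rate_sites,
                           mismatch_rate, reference_summary)

from conftest import random_profile


def literal_csa(arrest, i, r=5, pseudocount=0.0):
    """Direct re-evaluation of the definition: A_i over the median of the
    up-to-r neighbors on each side (i excluded, ends truncated)."""
    a = [0.0 if (x is None or math.isnan(x)) else x for x in arrest]
    idx = i - 1
    window = a[max(0, idx - r):idx] + a[idx + 1:idx + r + 1]
    if not window:
        return float("nan")
    window.sort()
    k = len(window)
    med = window[k // 2] if k % 2 else (window[k // 2 - 1] + window[k // 2]) / 2
    return (a[idx] + pseudocount) / (med + pseudocount)


class TestArrestRate:
    def test_quotient_of_downstream_starts_and_coverage(self):
        assert arrest_rate(5, 50) == pytest.approx(0.1)
        assert arrest_rate(0, 30) == 0.0

    def test_zero_coverage_undefined(self):
        assert math.isnan(arrest_rate(0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            arrest_rate(-1, 10)


class TestMismatchRate:
    def test_non_reference_calls_over_coverage(self):
        assert mismatch_rate(18, 0, 2, 0, "A", 20) == pytest.approx(0.1)
        assert mismatch_rate(20, 0, 0, 0, "A", 20) == 0.0

    def test_undefined_cases(self):
        assert math.isnan(mismatch_rate(0, 0, 0, 0, "A", 0))
        assert math.isnan(mismatch_rate(5, 5, 5, 5, "N", 20))

    def test_complement_identity_oracle(self):
        # M == 1 - F_ref - F_del - F_N, recomputed independently
        rng = np.random.default_rng(0)
        for _ in range(200):
            cov = int(rng.integers(1, 100))
            parts = rng.multinomial(cov, rng.dirichlet(np.ones(6)))
            nA, nC, nG, nT, ndel, nN = (int(x) for x in parts)
            m = mismatch_rate(nA, nC, nG, nT, "G", cov)
            assert m == pytest.approx(1 - nG / cov - ndel / cov - nN / cov)


class TestCsa:
    def test_flat_profile_is_one(self):
        a = np.full(21, 0.1)
        assert csa(a, 11, CsaConfig(pseudocount=0.0)) == pytest.approx(1.0)

    def test_fivefold_spike(self):
        a = np.full(11, 0.1)
        a[5] = 0.5
        assert csa(a, 6, CsaConfig(pseudocount=0.0)) == pytest.approx(5.0)

    def test_interior_window_holds_2r_neighbors(self):
        # only the 10 nearest neighbors matter at r=5: perturbing the 6th
        # neighbor must not change the value, while shifting a value inside
        # the window across the median must
        a = np.arange(30) * 0.01
        base = csa(a, 15)
        out = a.copy()
        out[14 + 6] = 0.9  # distance 6: outside the window
        assert csa(out, 15) == base
        inside = a.copy()
        inside[14 + 1] = 0.0  # distance 1: drops below the window median
        assert csa(inside, 15) != base

    def test_truncated_window_at_sequence_start(self):
        rng = np.random.default_rng(1)
        a = rng.random(40)
        got = csa(a, 1, CsaConfig(pseudocount=0.0))
        assert got == pytest.approx(literal_csa(a, 1, r=5))

    def test_single_position_profile_undefined(self):
        assert math.isnan(csa(np.array([0.3]), 1))

    def test_na_arrest_treated_as_zero(self):
        a = np.array([0.1, np.nan, 0.1, 0.5, 0.1, np.nan, 0.1])
        expect = literal_csa(a.tolist(), 4, pseudocount=0.001)
        assert csa(a, 4) == pytest.approx(expect)

    def test_oracle_equivalence_random_profiles(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0.01, 1.0, size=2000)
        got = csa_profile(a, CsaConfig(pseudocount=0.0))
        for i in rng.choice(2000, 300, replace=False):
            assert got[i] == pytest.approx(literal_csa(a, i + 1))

    @given(st.floats(min_value=0.1, max_value=100.0),
           st.integers(min_value=0, max_value=10 ** 6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance_without_pseudocount(self, scale, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.05, 1.0, size=25)
        cfg = CsaConfig(pseudocount=0.0)
        before = csa(a, 13, cfg)
        after = csa(a * scale, 13, cfg)
        assert after == pytest.approx(before, rel=1e-9)

    def test_equal_to_one_when_site_equals_window_median(self):
        a = np.array([0.0, 0.2, 0.4, 0.2, 0.1, 0.3])
        # median of neighbors of i=3 (0.0,0.2,0.2,0.1,0.3) is 0.2 != A_3=0.4
        med = np.median([0.0, 0.2, 0.2, 0.1, 0.3])
        a[2] = med
        assert csa(a, 3, CsaConfig(pseudocount=0.0)) == pytest.approx(1.0)


class TestHeterogeneousSites:
    def _row(self, ref, cov, nA, nG, nT, nC):
        return pd.DataFrame([{
            "pos": 1, "ref_base": ref, "coverage": cov,
            "mismatch_rate": np.nan, "n_A": nA, "n_G": nG, "n_T": nT,
            "n_C": nC, "arrest_rate": 0.0,
        }])

    def test_hand_evaluated_example(self):
        # ref A, cov 25: mF = {8/25, 5/25, 2/25} = {0.32, 0.20, 0.08},
        # median 0.20 >= 0.1 -> counts
        assert heterogeneous_sites(self._row("A", 25, 10, 8, 5, 2)) == 1

    def test_coverage_gate_at_20(self):
        assert heterogeneous_sites(self._row("A", 19, 8, 6, 4, 1)) == 0
        assert heterogeneous_sites(self._row("A", 20, 8, 6, 4, 2)) == 1

    def test_single_mismatch_type_excluded(self):
        # one dominant mismatch type only: median of {0.3, 0.02, 0.01} < 0.1
        assert heterogeneous_sites(self._row("A", 100, 67, 30, 2, 1)) == 0

    def test_ref_n_never_counts(self):
        assert heterogeneous_sites(self._row("N", 100, 30, 30, 20, 20)) == 0

    def test_monotone_in_mismatch_counts(self):
        low = self._row("A", 40, 32, 4, 3, 1)
        high = self._row("A", 40, 24, 8, 5, 3)
        assert heterogeneous_sites(low) <= heterogeneous_sites(high)

    def test_naive_per_row_oracle(self):
        rng = np.random.default_rng(10)
        rows = random_profile(rng, 1000, max_cov=60)
        expect = 0
        for r in rows.itertuples(index=False):
            if r.coverage < 20 or r.ref_base not in "ACGT":
                continue
            mf = sorted(getattr(r, f"n_{b}") / r.coverage
                        for b in "ACGT" if b != r.ref_base)
            if mf[1] >= 0.1:  # median of three
                expect += 1
        assert heterogeneous_sites(rows) == expect


class TestHighRateSites:
    def test_zero_events_never_count(self):
        rows = random_profile(np.random.default_rng(0), 50)
        rows[["n_A", "n_C", "n_G", "n_T"]] = 0
        rows["arrest_rate"] = 0.0
        assert high_rate_sites(rows, "mismatch") == 0
        assert high_rate_sites(rows, "arrest") == 0

    def test_fixed_rate_captured_only_at_high_coverage(self):
        # 10% events against p0=0.05: insignificant at c=20, significant
        # once coverage is large — the coverage-normalized threshold
        def one(cov, k):
            df = pd.DataFrame([{"pos": 1, "ref_base": "A", "coverage": cov,
                                "mismatch_rate": k / cov, "n_A": cov - k,
                                "n_G": k, "n_T": 0, "n_C": 0,
                                "arrest_rate": 0.0}])
            return high_rate_sites(df, "mismatch", p0=0.05, alpha=0.001)

        assert one(20, 2) == 0
        assert one(2000, 200) == 1
        # membership monotone in coverage at fixed rate
        flags = [one(c, c // 10) for c in (50, 200, 500, 1000, 2000)]
        assert flags == sorted(flags)

    def test_brute_force_binomial_oracle(self):
        rng = np.random.default_rng(12)
        rows = random_profile(rng, 300, max_cov=80)
        for which in ("mismatch", "arrest"):
            got = high_rate_sites(rows, which, p0=0.05, alpha=0.01)
            k, c = metrics._event_counts(rows, which)
            expect = 0
            for ki, ci in zip(k, c):
                if ci > 0 and ki > 0:
                    tail = sum(stats.binom.pmf(j, int(ci), 0.05)
                               for j in range(int(ki), int(ci) + 1))
                    if tail <= 0.01:
                        expect += 1
            assert got == expect

    def test_flat_rate_mode(self):
        rows = random_profile(np.random.default_rng(13), 200)
        got = high_rate_sites(rows, "mismatch", mode="rate", rate_threshold=0.3)
        mm = rows["mismatch_rate"].to_numpy()
        expect = int(np.nansum((mm >= 0.3) & (rows["coverage"] > 0)
                               & (rows["mismatch_rate"].notna())))
        assert got == expect


class TestReferenceSummary:
    def test_empty_coverage(self):
        rows = random_profile(np.random.default_rng(0), 10)
        rows["coverage"] = 0
        rows[["n_A", "n_C", "n_G", "n_T"]] = 0
        rows["arrest_rate"] = np.nan
        st_ = reference_summary(rows, "refX", "ACGT" * 25, mapped_reads=0)
        assert st_.coverage_peak == 0
        assert (st_.S_A, st_.S_M, st_.S_H) == (0, 0, 0)
        assert st_.length == 100 and st_.sequence_head == "ACGT" * 25

    def test_coverage_peak_spike(self):
        rows = random_profile(np.random.default_rng(1), 50, max_cov=10)
        rows.loc[30, "coverage"] = 77
        st_ = reference_summary(rows, "r", "A" * 50, 5)
        assert st_.coverage_peak == 77

    def test_sequence_head_truncated_at_100(self):
        rows = random_profile(np.random.default_rng(2), 300)
        st_ = reference_summary(rows, "r", "G" * 300, 1)
        assert len(st_.sequence_head) == 100

    def test_planted_heterogeneous_sites_counted(self):
        rng = np.random.default_rng(3)
        n = 500
        rows = random_profile(rng, n, max_cov=0)  # all zero coverage
        rows[["n_A", "n_C", "n_G", "n_T"]] = 0
        rows["ref_base"] = "A"
        rows["coverage"] = 50
        rows["n_A"] = 50
        rows["mismatch_rate"] = 0.0
        for pos in (50, 200, 400):  # three planted heterogeneous sites
            rows.loc[pos, ["n_A", "n_G", "n_T", "n_C"]] = [30, 10, 8, 2]
            rows.loc[pos, "mismatch_rate"] = 20 / 50
        st_ = reference_summary(rows, "r", "A" * n, 100)
        assert st_.S_H == 3
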