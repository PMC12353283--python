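"""Cohort generator: sampling correctness, determinism, structural invariants."""

import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lefttrunc as lt
from lefttrunc.scenarios import ParameterError
from lefttrunc.simulate import AbruptionProbs


def _cells():
    return list(itertools.product((0, 1), repeat=4))


@st.composite
def valid_params(draw):
    """Random well-formed, probability-valid scenario."""
    base = lt.build_grid("primary")[0]
    pc = draw(st.floats(0.01, 0.2))
    rr_cz = draw(st.floats(1.0, 6.0))
    rr_cx = draw(st.floats(1.0, 6.0))
    if pc * rr_cz * rr_cx > 1.0:
        rr_cx = 1.0 / (pc * rr_cz)
    po = draw(st.floats(1e-4, 0.02))
    rr_m = draw(st.floats(1.0, 15.0))
    rr_oz = draw(st.floats(1.0, 4.0))
    if po * rr_m * rr_oz > 1.0:
        rr_oz = 1.0 / (po * rr_m)
    pi_z = draw(st.floats(0.0, 0.5))
    return dataclasses.replace(base, pi_Z=pi_z, pC_base=pc, rr_C_Z=rr_cz,
                               rr_C_X=rr_cx, pOut_base=po, rr_Out_M=rr_m,
                               rr_Out_Z=rr_oz)


class TestDrawAbruptionProbs:
    def test_draws_stay_inside_supports(self, primary_grid):
        rng = np.random.default_rng(3)
        for _ in range(500):
            px = lt.draw_abruption_probs(primary_grid[0], rng)
            assert 0.005 <= px.z1 <= 0.050
            assert 0.001 <= px.z0 <= 0.020

    def test_zero_width_support_is_point_mass(self, primary_grid):
        p = dataclasses.replace(primary_grid[0], pX_range_Z1=(0.02, 0.02))
        rng = np.random.default_rng(0)
        assert lt.draw_abruption_probs(p, rng).z1 == 0.02

    def test_means_match_support_midpoints(self, primary_grid):
        rng = np.random.default_rng(11)
        draws = [lt.draw_abruption_probs(primary_grid[0], rng) for _ in range(4000)]
        # SE of a U(a,b) mean is (b-a)/sqrt(12 n)
        se1 = 0.045 / np.sqrt(12 * 4000)
        se0 = 0.019 / np.sqrt(12 * 4000)
        assert np.mean([d.z1 for d in draws]) == pytest.approx(0.0275, abs=3 * se1)
        assert np.mean([d.z0 for d in draws]) == pytest.approx(0.0105, abs=3 * se0)


class TestCellProbability:
    def test_conditional_sab_risk_at_baseline(self, primary_grid):
        p = primary_grid[0]
        px = AbruptionProbs(0.0275, 0.0105)
        joint_c1 = sum(lt.cell_probability(p, px, 0, 0, 1, y) for y in (0, 1))
        joint = sum(lt.cell_probability(p, px, 0, 0, c, y)
                    for c in (0, 1) for y in (0, 1))
        assert joint_c1 / joint == pytest.approx(0.05)

    def test_sab_precludes_outcome(self, primary_grid):
        px = AbruptionProbs(0.0275, 0.0105)
        for p in lt.build_grid("primary"):
            for z in (0, 1):
                for x in (0, 1):
                    assert lt.cell_probability(p, px, z, x, 1, 1) == 0.0

    def test_outcome_risk_in_diagnosed_abnormal_cell(self, primary_grid):
        # Pr(Y=1 | M=1, Z=1, C=0) = 0.0082 * 14.5 * 4 under rr_Out_Z = 4
        p = next(q for q in lt.build_grid("primary")
                 if q.rr_Out_Z == 4.0 and q.rr_C_Z == 2.0 and q.rr_C_X == 2.0)
        px = AbruptionProbs(0.0275, 0.0105)
        y1 = lt.cell_probability(p, px, 1, 1, 0, 1)
        y_any = y1 + lt.cell_probability(p, px, 1, 1, 0, 0)
        assert y1 / y_any == pytest.approx(0.4756)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(valid_params(), st.floats(0.005, 0.05), st.floats(0.001, 0.02))
    def test_cell_probabilities_sum_to_one(self, p, px1, px0):
        px = AbruptionProbs(px1, px0)
        total = sum(lt.cell_probability(p, px, *cell) for cell in _cells())
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_invalid_setup_rejected(self, primary_grid):
        p = dataclasses.replace(primary_grid[0], rr_C_Z=6.0, rr_C_X=4.5)
        with pytest.raises(ParameterError):
            lt.cell_probability(p, AbruptionProbs(0.0275, 0.0105), 0, 0, 0, 0)


class TestSimulateCohort:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(valid_params(), st.integers(0, 2**31 - 1))
    def test_conservation_and_structural_zero(self, p, seed):
        rng = np.random.default_rng(seed)
        co = lt.simulate_cohort(p, 5000, rng)
        assert co.counts.sum() == 5000
        assert (co.counts >= 0).all()
        assert co.counts[:, :, 1, 1].sum() == 0  # SAB precludes the outcome
        lo1, hi1 = p.pX_range_Z1
        lo0, hi0 = p.pX_range_Z0
        assert lo1 <= co.drawn_pX_Z1 <= hi1
        assert lo0 <= co.drawn_pX_Z0 <= hi0

    def test_degenerate_probabilities_concentrate_mass(self, primary_grid):
        p = dataclasses.replace(primary_grid[0], pi_Z=0.0,
                                pX_range_Z1=(0.0, 0.0), pX_range_Z0=(0.0, 0.0))
        co = lt.simulate_cohort(p, 1000, np.random.default_rng(0))
        assert co.counts[0, 0, :, :].sum() == 1000

    def test_empty_cohort_rejected(self, primary_grid):
        with pytest.raises(ValueError, match="empty cohort"):
            lt.simulate_cohort(primary_grid[0], 0, np.random.default_rng(0))

    def test_goodness_of_fit_against_cell_probabilities(self, primary_grid):
        """Empirical cell frequencies at n=10^6 match the generative law."""
        p = primary_grid[0]
        n = 1_000_000
        co = lt.simulate_cohort(p, n, np.random.default_rng(5), px_mode="midpoint")
        px = AbruptionProbs(0.0275, 0.0105)
        for cell in _cells():
            prob = lt.cell_probability(p, px, *cell)
            se = np.sqrt(prob * (1 - prob) / n)
            assert co.counts[cell] / n == pytest.approx(prob, abs=max(3 * se, 1e-9))

    def test_censoring_invariant_to_px_draw_mode(self, primary_grid):
        """E[censoring] is linear in pX, so per-cohort draws and the midpoint agree."""
        p = primary_grid[0]
        sab = {}
        for mode in ("per_cohort", "midpoint"):
            cohorts = [lt.simulate_cohort(p, 50_000, np.random.default_rng(100 + i),
                                          px_mode=mode) for i in range(60)]
            fr = np.array([c.sab_fraction for c in cohorts])
            sab[mode] = (fr.mean(), fr.std(ddof=1) / np.sqrt(len(fr)))
        diff_se = np.hypot(sab["per_cohort"][1], sab["midpoint"][1])
        assert abs(sab["per_cohort"][0] - sab["midpoint"][0]) < 3 * diff_se


class TestSimulateStudy:
    def test_same_master_seed_is_bit_identical(self, primary_grid):
        p = primary_grid[0]
        a = lt.simulate_study(p, n_replicates=5, n_total=10_000, master_seed=42)
        b = lt.simulate_study(p, n_replicates=5, n_total=10_000, master_seed=42)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.counts, cb.counts)
            assert ca.drawn_pX_Z1 == cb.drawn_pX_Z1
        c = lt.simulate_study(p, n_replicates=5, n_total=10_000, master_seed=43)
        assert any(not np.array_equal(ca.counts, cc.counts) for ca, cc in zip(a, c))

    def test_replicate_count_and_size(self, primary_study):
        cohorts = primary_study["cohorts"]
        assert (cohorts.groupby("setup_id").size() == 200).all()
        assert (cohorts["n_total"] == 100_000).all()

    def test_drawn_probabilities_independent_across_replicates(self, primary_grid):
        cohorts = lt.simulate_study(primary_grid[0], n_replicates=400,
                                    n_total=100, master_seed=9)
        z1 = np.array([c.drawn_pX_Z1 for c in cohorts])
        z0 = np.array([c.drawn_pX_Z0 for c in cohorts])
        # lag-1 autocorrelation and cross-correlation ~ 0 (|r| < 3/sqrt(n))
        for r in (np.corrcoef(z1[:-1], z1[1:])[0, 1],
                  np.corrcoef(z0[:-1], z0[1:])[0, 1],
                  np.corrcoef(z1, z0)[0, 1]):
            assert abs(r) < 3 / np.sqrt(len(z1) - 1)

    def test_mean_censoring_matches_oracle_example(self, primary_study, primary_grid):
        # setup (rr_C_Z=2, rr_C_X=2): expected marginal censoring 0.0557
        p = primary_grid[0]
        vals = primary_study["cohorts"].query("setup_id == @p.setup_id")["sab_fraction"]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert vals.mean() == pytest.approx(0.0557475, abs=3 * se)


class TestSerialization:
    def test_counts_frame_has_16_cells_and_provenance(self, cohort):
        frame = lt.counts_to_frame(cohort)
        assert len(frame) == 16
        assert frame["count"].sum() == cohort.n_total
        assert set(frame.columns) >= {"setup_id", "replicate_id", "seed",
                                      "z", "x", "c", "y", "count"}

    def test_individual_records_match_counts(self, primary_grid):
        co = lt.simulate_cohort(primary_grid[0], 2000, np.random.default_rng(2))
        ind = lt.to_individuals(co)
        assert len(ind) == 2000
        # diagnosis is missing exactly on SAB rows, equals x elsewhere
        assert ind.loc[ind.c == 1, "m"].isna().all()
        assert (ind.loc[ind.c == 0, "m"] == ind.loc[ind.c == 0, "x"]).all()
        for (z, x, c, y), grp in ind.groupby(["z", "x", "c", "y"]):
            assert len(grp) == co.counts[z, x, c, y]
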