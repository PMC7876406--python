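"""STEP pipeline: filtering, gridding, extraction, clustering, scoring."""

import numpy as np
import pytest

from stepnet import bna, synth
from stepnet.bna import (
    ATTRIBUTES,
    BandSpec,
    BNAConfig,
    DEFAULT_BANDS,
    ERPGrid,
    MainSTEP,
    STEP,
    bandpass_filter,
    build_reference_group,
    cluster_steps,
    compute_condition_erp,
    extract_steps,
    interpolate_grid,
    match_steps,
    percentile_score,
    score_subject,
    subject_steps,
)
from stepnet.montage import grid_montage
from tests.conftest import make_epochs

DELTA, THETA, ALPHA = DEFAULT_BANDS
FS = 250.0


# ---------------------------------------------------------------------------
# band filtering
# ---------------------------------------------------------------------------

class TestBandpassFilter:
    def test_zero_in_zero_out(self):
        out = bandpass_filter(np.zeros((4, 800)), ALPHA, FS)
        assert out.shape == (4, 800)
        assert np.allclose(out, 0.0)

    def test_alpha_passband_gain_and_phase(self):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass_filter(x, ALPHA, FS)
        mid = slice(500, 1500)
        amp = np.sqrt(2) * y[mid].std()
        assert amp == pytest.approx(1.0, abs=0.05)
        # zero net phase: peaks unshifted
        xp = 500 + np.argmax(x[mid])
        assert abs(int(np.argmax(y[xp - 10 : xp + 10])) - 10) <= 1

    def test_stopband_attenuation(self):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 20.0 * t)
        y = bandpass_filter(x, DELTA, FS)
        rms_ratio = y[500:1500].std() / x[500:1500].std()
        assert rms_ratio < 10 ** (-20 / 20)  # ≥ 20 dB down

    def test_peak_time_preserved_in_own_band(self):
        times = -200 + np.arange(350) * 4.0
        bump = np.exp(-0.5 * ((times - 300.0) / 50.0) ** 2)
        y = bandpass_filter(bump, DELTA, FS)
        assert abs(times[np.argmax(y)] - 300.0) <= 4.0  # ±1 sample

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(100), ALPHA, FS)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(1000), ALPHA, 20.0)


# ---------------------------------------------------------------------------
# condition averaging
# ---------------------------------------------------------------------------

class TestConditionERP:
    def test_identical_epochs_average_to_single_epoch(self, montage16, rng):
        one = rng.normal(size=(1, 16, 100))
        epochs = make_epochs(np.tile(one, (7, 1, 1)), montage16)
        erp = compute_condition_erp(epochs, "A")
        base = one[0, :, :50].mean(axis=1, keepdims=True)
        assert np.allclose(erp, one[0] - base)

    def test_constant_offset_removed_by_baseline(self, montage16, rng):
        data = rng.normal(size=(10, 16, 100)) + 42.0
        erp = compute_condition_erp(make_epochs(data, montage16), "A")
        pre = erp[:, :50]  # 50 samples before stimulus at 250 Hz / −200 ms
        assert np.allclose(pre.mean(axis=1), 0.0, atol=1e-12)

    def test_residual_noise_shrinks_as_sqrt_n(self, montage16, rng):
        signal = np.sin(np.linspace(0, 2 * np.pi, 100))[None, None, :]
        sds = []
        for n in (10, 40, 160):
            data = signal + rng.normal(0, 2.0, (n, 16, 100))
            erp = compute_condition_erp(make_epochs(data, montage16), "A")
            sds.append((erp - (signal[0] - signal[0, :, :50].mean())).std())
        assert sds[0] / sds[1] == pytest.approx(2.0, rel=0.3)
        assert sds[1] / sds[2] == pytest.approx(2.0, rel=0.3)

    def test_missing_condition_raises(self, montage16):
        epochs = make_epochs(np.zeros((3, 16, 50)), montage16)
        with pytest.raises(ValueError):
            compute_condition_erp(epochs, "Nonexistent")


# ---------------------------------------------------------------------------
# grid interpolation
# ---------------------------------------------------------------------------

class TestInterpolateGrid:
    def test_constant_field_reproduced(self, montage64):
        erp = np.full((64, 5), 3.3)
        grid = interpolate_grid(erp, montage64, np.arange(5) * 4.0)
        inside = np.isfinite(grid.values)
        assert inside.any()
        assert np.allclose(grid.values[inside], 3.3, atol=1e-6)

    def test_exact_at_electrode_coinciding_with_node(self, rng):
        # 31-node grid spans −1…1 in steps of 1/15; electrodes at ±0.2/±0.6
        # (multiples of 1/15) coincide with grid nodes exactly
        montage = grid_montage(n_side=4, extent=0.6)
        erp = rng.normal(size=(16, 3))
        grid = interpolate_grid(erp, montage, np.arange(3) * 4.0,
                                resolution=(31, 31))
        xs, ys = grid.xs, grid.ys
        for ch, (px, py) in enumerate(montage.positions):
            ix = int(np.argmin(np.abs(xs - px)))
            iy = int(np.argmin(np.abs(ys - py)))
            assert abs(xs[ix] - px) < 1e-9 and abs(ys[iy] - py) < 1e-9
            assert grid.values[ix, iy, :] == pytest.approx(erp[ch], abs=1e-8)

    def test_hotspot_argmax_near_source_electrode(self, montage64):
        erp = np.zeros((64, 1))
        target = 20
        erp[target, 0] = 10.0
        grid = interpolate_grid(erp, montage64, np.array([0.0]))
        v = np.where(np.isfinite(grid.values[:, :, 0]), grid.values[:, :, 0], -np.inf)
        ix, iy = np.unravel_index(np.argmax(v), v.shape)
        cell = 2.0 / 31
        assert abs(grid.xs[ix] - montage64.positions[target, 0]) <= 1.5 * cell
        assert abs(grid.ys[iy] - montage64.positions[target, 1]) <= 1.5 * cell

    def test_outside_head_masked(self, montage64):
        grid = interpolate_grid(np.ones((64, 2)), montage64, np.arange(2) * 4.0)
        assert np.isnan(grid.values[0, 0, 0])  # corner of the square grid

    def test_degenerate_montage_rejected(self):
        from stepnet.montage import ChannelGeometry

        collinear = ChannelGeometry(
            ch_names=("a", "b", "c", "d"),
            positions=np.c_[np.linspace(-1, 1, 4), np.zeros(4)],
        )
        with pytest.raises(ValueError):
            interpolate_grid(np.ones((4, 2)), collinear, np.arange(2.0))


# ---------------------------------------------------------------------------
# STEP extraction with brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_steps(grid: ERPGrid, min_abs: float):
    """Exhaustive scan: a strict extremum against every in-bounds finite
    neighbor of its 3×3×3 neighborhood, post-stimulus, above threshold."""
    v = grid.values
    W, H, T = v.shape
    found = []
    for ix in range(W):
        for iy in range(H):
            for it in range(T):
                if grid.times_ms[it] < 0 or not np.isfinite(v[ix, iy, it]):
                    continue
                x = v[ix, iy, it]
                if abs(x) < min_abs:
                    continue
                neigh = []
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dt in (-1, 0, 1):
                            if (dx, dy, dt) == (0, 0, 0):
                                continue
                            jx, jy, jt = ix + dx, iy + dy, it + dt
                            if 0 <= jx < W and 0 <= jy < H and 0 <= jt < T:
                                if np.isfinite(v[jx, jy, jt]):
                                    neigh.append(v[jx, jy, jt])
                if not neigh:
                    continue
                if x > 0 and x > max(neigh):
                    found.append(((ix, iy, it), +1))
                elif x < 0 and x < min(neigh):
                    found.append(((ix, iy, it), -1))
    return found


def random_smooth_grid(rng, shape=(16, 16, 50), mask_disc=False):
    from scipy.ndimage import gaussian_filter

    v = gaussian_filter(rng.normal(size=shape), sigma=(2.0, 2.0, 3.0))
    v *= 8.0 / np.abs(v).max()
    times = -40 + np.arange(shape[2]) * 4.0  # a few pre-stimulus slices
    if mask_disc:
        xs = np.linspace(-1, 1, shape[0])
        ys = np.linspace(-1, 1, shape[1])
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        v[np.hypot(gx, gy) > 1.0] = np.nan
    return ERPGrid(
        values=v,
        xs=np.linspace(-1, 1, shape[0]),
        ys=np.linspace(-1, 1, shape[1]),
        times_ms=times,
    )


def gaussian_bump_grid(amp=10.0, center=(8, 8, 25), sign=+1, shape=(16, 16, 50)):
    ix, iy, it = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    v = sign * amp * np.exp(
        -((ix - center[0]) ** 2 + (iy - center[1]) ** 2) / (2 * 3.0**2)
        - (it - center[2]) ** 2 / (2 * 5.0**2)
    )
    return ERPGrid(
        values=v,
        xs=np.linspace(-1, 1, shape[0]),
        ys=np.linspace(-1, 1, shape[1]),
        times_ms=np.arange(shape[2]) * 4.0,
    )


class TestExtractSteps:
    def test_single_bump_yields_single_step(self):
        steps = extract_steps(gaussian_bump_grid(), min_abs_amplitude=1.0)
        assert len(steps) == 1
        assert steps[0].idx == (8, 8, 25)
        assert steps[0].amplitude == pytest.approx(10.0)
        assert steps[0].polarity == 1

    def test_two_opposite_bumps(self):
        g1 = gaussian_bump_grid(center=(4, 4, 12))
        g2 = gaussian_bump_grid(amp=6.0, center=(12, 12, 38), sign=-1)
        grid = ERPGrid(values=g1.values + g2.values, xs=g1.xs, ys=g1.ys,
                       times_ms=g1.times_ms)
        steps = extract_steps(grid, min_abs_amplitude=1.0)
        assert len(steps) == 2
        assert steps[0].polarity == 1 and steps[1].polarity == -1
        assert steps[0].idx[2] == 12 and steps[1].idx[2] == 38

    def test_half_amplitude_surround_property(self):
        grid = gaussian_bump_grid(amp=10.0)
        (step,) = extract_steps(grid, min_abs_amplitude=1.0, with_surround=True)
        vals = grid.values[tuple(step.surround.T)]
        assert np.all(vals >= 5.0 - 1e-12)
        assert any(tuple(p) == step.idx for p in step.surround)

    def test_surround_connected_and_maximal(self):
        grid = gaussian_bump_grid(amp=10.0)
        (step,) = extract_steps(grid, min_abs_amplitude=1.0, with_surround=True)
        # every above-half cell of this unimodal bump belongs to the surround
        assert len(step.surround) == int((grid.values >= 5.0).sum())

    def test_matches_brute_force_on_random_smooth_grids(self, rng):
        for i in range(25):
            grid = random_smooth_grid(rng, mask_disc=(i % 3 == 0))
            fast = extract_steps(grid, min_abs_amplitude=1.0, with_surround=False)
            oracle = brute_force_steps(grid, 1.0)
            assert {(s.idx, s.polarity) for s in fast} == set(oracle)

    def test_sorted_by_absolute_amplitude(self, rng):
        grid = random_smooth_grid(rng)
        steps = extract_steps(grid, min_abs_amplitude=0.5, with_surround=False)
        amps = [abs(s.amplitude) for s in steps]
        assert amps == sorted(amps, reverse=True)

    def test_pre_stimulus_extrema_ignored(self):
        grid = gaussian_bump_grid(center=(8, 8, 5))
        grid.times_ms = -40 + np.arange(50) * 4.0  # bump now at t = −20 ms
        assert extract_steps(grid, min_abs_amplitude=1.0) == []


# ---------------------------------------------------------------------------
# clustering and matching
# ---------------------------------------------------------------------------

def _step(t, x=0.0, y=0.0, amp=5.0, pol=+1, band="delta", cond="Novel"):
    return STEP(amplitude=pol * abs(amp), time_ms=t, location=(x, y),
                polarity=pol, idx=(0, 0, 0), surround=None, band=band,
                condition=cond)


class TestClusterSteps:
    def test_unanimous_identical_steps_single_cluster(self):
        per = {f"s{i}": [_step(300.0, 0.1, 0.2)] for i in range(10)}
        main = cluster_steps(per)
        assert len(main) == 1
        assert main[0].prevalence == 1.0
        assert main[0].centroid_time == pytest.approx(300.0)

    def test_sixty_percent_prevalence_filtered_out(self):
        per = {f"s{i}": [_step(300.0)] if i < 6 else [] for i in range(10)}
        assert cluster_steps(per) == []

    def test_exactly_seventy_percent_retained(self):
        per = {f"s{i}": [_step(300.0)] if i < 7 else [] for i in range(10)}
        assert len(cluster_steps(per)) == 1

    def test_two_populations_recovered_within_10ms(self, rng):
        per = {}
        for i in range(12):
            per[f"s{i}"] = [
                _step(250.0 + rng.uniform(-20, 20), rng.normal(0, 0.05),
                      rng.normal(0, 0.05)),
                _step(450.0 + rng.uniform(-20, 20), rng.normal(0, 0.05),
                      rng.normal(0, 0.05)),
            ]
        main = cluster_steps(per)
        assert len(main) == 2
        times = sorted(m.centroid_time for m in main)
        assert abs(times[0] - 250.0) < 10 and abs(times[1] - 450.0) < 10

    def test_opposite_polarities_never_merge(self):
        per = {f"s{i}": [_step(300.0), _step(305.0, pol=-1)] for i in range(8)}
        main = cluster_steps(per)
        assert len(main) == 2
        assert {m.polarity for m in main} == {-1, 1}

    def test_one_step_per_subject_per_cluster(self):
        per = {f"s{i}": [_step(300.0), _step(310.0)] for i in range(6)}
        main = cluster_steps(per)
        assert len(main) == 1 and main[0].prevalence == 1.0

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValueError):
            cluster_steps({"only": [_step(300.0)]})


class TestMatchSteps:
    def _main(self, t=300.0, loc=(0.0, 0.2), st=20.0, ss=0.08, pol=+1):
        return MainSTEP(label="M", centroid_time=t, centroid_location=loc,
                        time_dispersion=st, spatial_dispersion=ss,
                        prevalence=1.0, polarity=pol, band="delta",
                        condition="Novel")

    def test_exact_centroid_match(self):
        ms = self._main()
        res = match_steps([_step(300.0, 0.0, 0.2)], [ms])
        assert res["M"] is not None and res["M"].time_ms == 300.0

    def test_outside_window_unmatched(self):
        ms = self._main()
        res = match_steps([_step(600.0, 0.0, 0.2)], [ms], windows=(100.0, 0.3))
        assert res["M"] is None

    def test_nearer_candidate_wins(self):
        ms = self._main()
        near, far = _step(320.0, 0.0, 0.2), _step(360.0, 0.0, 0.2)
        res = match_steps([far, near], [ms])
        assert res["M"].time_ms == 320.0

    def test_polarity_must_agree(self):
        ms = self._main(pol=-1)
        assert match_steps([_step(300.0, 0.0, 0.2)], [ms])["M"] is None

    def test_each_step_used_at_most_once(self):
        m1 = self._main(t=300.0)
        m2 = MainSTEP(label="M2", centroid_time=320.0,
                      centroid_location=(0.0, 0.2), time_dispersion=20.0,
                      spatial_dispersion=0.08, prevalence=1.0, polarity=1,
                      band="delta", condition="Novel")
        res = match_steps([_step(310.0, 0.0, 0.2)], [m1, m2])
        matched = [k for k, v in res.items() if v is not None]
        assert len(matched) == 1


class TestPercentileScore:
    def test_extremes(self):
        ref = np.array([1.0, 2, 3, 4])
        assert percentile_score(10.0, ref) == 100.0
        assert percentile_score(-10.0, ref) == 0.0

    def test_midrank_tie_handling(self):
        assert percentile_score(2.0, np.array([1.0, 2, 3, 4])) == pytest.approx(37.5)

    def test_monotone_non_decreasing(self, rng):
        ref = np.sort(rng.normal(size=50))
        xs = np.sort(rng.normal(size=100))
        scores = [percentile_score(x, ref) for x in xs]
        assert all(a <= b for a, b in zip(scores, scores[1:]))

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            percentile_score(1.0, np.array([]))


# ---------------------------------------------------------------------------
# reference group and single-subject scoring
# ---------------------------------------------------------------------------

def _synthetic_cohort_steps(rng, n=120, lat_mu=300.0, lat_sd=15.0,
                            amp_mu=5.0, amp_sd=1.0):
    return {
        f"r{i:03d}": [
            _step(rng.normal(lat_mu, lat_sd), rng.normal(0, 0.06),
                  0.2 + rng.normal(0, 0.06), amp=rng.normal(amp_mu, amp_sd))
        ]
        for i in range(n)
    }


class TestReferenceGroup:
    def test_reference_stores_sorted_values_for_all_members(self, rng):
        cohort = _synthetic_cohort_steps(rng)
        main = cluster_steps(cohort)
        entries = build_reference_group(cohort, main)
        assert len(entries) == 1
        for attr in ATTRIBUTES:
            vals = entries[0].values[attr]
            assert len(vals) <= 120
            assert np.all(np.diff(vals) >= 0)
        assert entries[0].n_matched >= 110

    def test_identical_members_give_constant_lists(self):
        cohort = {f"r{i}": [_step(300.0, 0.0, 0.2, amp=5.0)] for i in range(20)}
        main = cluster_steps(cohort)
        entries = build_reference_group(cohort, main)
        assert np.allclose(entries[0].values["latency"], 300.0)
        assert np.allclose(entries[0].values["amplitude"], 5.0)

    def test_sparse_template_dropped(self, rng):
        cohort = _synthetic_cohort_steps(rng, n=20)
        main = cluster_steps(cohort)
        # add a phantom template nobody matches
        phantom = MainSTEP(label="ghost", centroid_time=900.0,
                           centroid_location=(0.9, 0.0), time_dispersion=5.0,
                           spatial_dispersion=0.02, prevalence=0.9,
                           polarity=-1, band="delta", condition="Novel")
        entries = build_reference_group(cohort, main + [phantom])
        assert all(e.main_step.label != "ghost" for e in entries)

    def test_self_scoring_percentiles_uniform(self, rng):
        from scipy.stats import kstest

        cohort = _synthetic_cohort_steps(rng)
        main = cluster_steps(cohort)
        entries = build_reference_group(cohort, main)
        ref = entries[0]
        pct = []
        for steps in cohort.values():
            matched = match_steps(steps, [ref.main_step])
            st = matched[ref.main_step.label]
            if st is not None:
                pct.append(percentile_score(st.time_ms, ref.values["latency"]))
        assert len(pct) >= 110
        stat = kstest(np.array(pct) / 100.0, "uniform")
        assert stat.pvalue > 0.01
        assert abs(np.median(pct) - 50.0) <= 5.0


class TestScoreSubject:
    def test_empty_registry_empty_scores(self, montage16, rng):
        from stepnet.bna import ReferenceGroup

        epochs = make_epochs(rng.normal(size=(5, 16, 500)), montage16,
                             conditions=["Novel"] * 5)
        scores = score_subject(epochs, ReferenceGroup(n_members=0))
        assert scores == []

    def test_planted_latency_shift_scores_above_90th_percentile(self, montage64):
        """A patient-like subject whose P3a is 60 ms later than the
        reference (no trial jitter, no noise) must land in the top decile
        of the latency distribution."""
        import pandas as pd
        from stepnet.bna import build_reference

        cfg = BNAConfig(bands=(DELTA,))
        seq = pd.DataFrame({"condition": ["Novel"] * 8,
                            "onset_ms": np.arange(8) * 1500.0,
                            "tone_hz": np.full(8, 900.0)})

        def subject(latency, seed):
            comp = synth.ComponentSpec(
                "P3a", +1, (0.0, 0.3), 0.5, latency, 0.0, 5.0, 0.0,
                "delta", frozenset({"Novel"}), temporal_sd_ms=50.0)
            params = synth.SubjectParams(
                group="healthy", components=(comp,),
                trial_latency_jitter_sd=0.0, trial_amplitude_jitter_sd=0.0,
                noise_sd=0.0, blink_rate=0.0)
            return synth.simulate_subject_eeg(seq, params, montage64, seed)

        rng = np.random.default_rng(5)
        per = {
            f"r{i}": subject_steps(subject(300.0 + rng.normal(0, 12.0), i),
                                   cfg, ("Novel",))
            for i in range(25)
        }
        reference = build_reference(per, cfg)
        scores = score_subject(subject(360.0, 99), reference, cfg)
        latency = [s for s in scores if s.attribute == "latency" and s.matched]
        assert latency and all(s.percentile > 90 for s in latency)
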