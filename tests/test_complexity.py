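"""Temporal-complexity features: closed-form checks, brute-force oracle
equivalence, and invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from fmricomplexity import (
    EntropyTrajectory,
    coarse_grain,
    generate_fgn,
    hurst_rs,
    multiscale_entropy_auc,
    multiscale_entropy_trajectory,
    range_entropy_B,
    range_entropy_B_auc,
    range_entropy_B_trajectory,
    sample_entropy,
    weighted_permutation_entropy,
)


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation paths they check)
# ---------------------------------------------------------------------------

def brute_sample_entropy(x, m, r):
    sd = x.std()
    rad = r * sd
    n = len(x)
    nt = n - m
    B = A = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= rad:
                B += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= rad:
                A += 1
    if A == 0 or B == 0:
        return float("nan")
    return -math.log(A / B)


def brute_range_distance(a, b):
    d = [abs(u - v) for u, v in zip(a, b)]
    mx, mn = max(d), min(d)
    return 0.0 if mx + mn == 0 else (mx - mn) / (mx + mn)


def brute_range_entropy(x, m, r):
    n = len(x)
    nt = n - m
    B = A = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if brute_range_distance(x[i:i + m], x[j:j + m]) <= r:
                B += 1
            if brute_range_distance(x[i:i + m + 1], x[j:j + m + 1]) <= r:
                A += 1
    if A == 0 or B == 0:
        return float("nan")
    return -math.log(A / B)


def brute_wpe(x, m):
    from collections import defaultdict

    weights = defaultdict(float)
    for i in range(len(x) - m + 1):
        window = x[i:i + m]
        pattern = tuple(sorted(range(m), key=lambda k: (window[k], k)))
        weights[pattern] += np.var(window)
    total = sum(weights.values())
    p = [w / total for w in weights.values() if w > 0]
    H = -sum(q * math.log2(q) for q in p)
    return H / math.log2(math.factorial(m))


# ---------------------------------------------------------------------------
# Hurst exponent
# ---------------------------------------------------------------------------

class TestHurst:
    def test_white_noise_recovers_half(self):
        est = [
            hurst_rs(np.random.default_rng(s).standard_normal(8192))
            for s in range(50)
        ]
        assert abs(np.mean(est) - 0.5) < 0.05
        assert all(0.40 < e < 0.62 for e in est)

    @pytest.mark.parametrize("H", [0.3, 0.5, 0.7, 0.9])
    def test_fgn_parameter_recovery(self, H):
        est = [hurst_rs(generate_fgn(8192, H, s)) for s in range(20)]
        assert abs(np.mean(est) - H) < 0.1

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant|degenerate"):
            hurst_rs(np.full(512, 3.0))


# ---------------------------------------------------------------------------
# weighted permutation entropy
# ---------------------------------------------------------------------------

class TestWPE:
    def test_monotone_ramp_is_zero(self):
        """A single ordinal pattern carries zero entropy."""
        assert weighted_permutation_entropy(
            np.arange(1.0, 201.0), m=4
        ) == pytest.approx(0.0)

    def test_iid_noise_near_one(self):
        x = np.random.default_rng(0).uniform(size=100_000)
        assert weighted_permutation_entropy(x, m=4) >= 0.97

    def test_matches_brute_force_on_alternating_series(self):
        base = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0])
        x = np.concatenate([base + 8 * k for k in range(8)])  # length 64
        assert weighted_permutation_entropy(x, m=4, tau=1) == pytest.approx(
            brute_wpe(x, 4), abs=1e-12
        )

    def test_matches_brute_force_on_noise(self, rng):
        x = rng.standard_normal(300)
        assert weighted_permutation_entropy(x, m=4) == pytest.approx(
            brute_wpe(x, 4), abs=1e-12
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        x=hnp.arrays(
            float, st.integers(10, 60),
            elements=st.floats(-50, 50, allow_nan=False),
        ),
        a=st.floats(0.1, 10),
        b=st.floats(-5, 5),
    )
    def test_bounds_and_affine_invariance(self, x, a, b):
        """wPE lies in [0, 1] and is exactly invariant to positive affine
        maps (rank invariance; variance weights rescale uniformly)."""
        v = weighted_permutation_entropy(x, m=2)
        assert 0.0 <= v <= 1.0
        if np.var(x) > 1e-6:
            w = weighted_permutation_entropy(a * x + b, m=2)
            assert w == pytest.approx(v, abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            weighted_permutation_entropy(np.arange(4.0), m=4)


# ---------------------------------------------------------------------------
# sample entropy
# ---------------------------------------------------------------------------

class TestSampleEntropy:
    def test_matches_brute_force_on_noise(self, rng):
        x = rng.standard_normal(300)
        for m, r in [(2, 0.5), (2, 0.2), (3, 1.0)]:
            assert sample_entropy(x, m=m, r=r) == pytest.approx(
                brute_sample_entropy(x, m, r), abs=1e-12
            )

    def test_sinusoid_more_regular_than_noise(self, rng):
        t = np.arange(2000)
        sine = np.sin(2 * np.pi * t / 50)
        noise = rng.standard_normal(2000)
        assert sample_entropy(sine, 2, 0.5) < 0.25 * sample_entropy(noise, 2, 0.5)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant|degenerate"):
            sample_entropy(np.full(100, 1.0))

    def test_affine_invariance_with_sd_relative_tolerance(self, rng):
        x = rng.standard_normal(400)
        assert sample_entropy(3.7 * x + 11.0, 2, 0.5) == pytest.approx(
            sample_entropy(x, 2, 0.5), abs=1e-12
        )

    def test_undefined_marker_not_exception(self):
        # widely separated spikes: no template pair within a tiny tolerance
        x = np.array([0.0, 100.0, -100.0, 50.0, -50.0, 25.0, -25.0, 12.0])
        assert math.isnan(sample_entropy(x, m=2, r=1e-6))


# ---------------------------------------------------------------------------
# range entropy (type B)
# ---------------------------------------------------------------------------

class TestRangeEntropy:
    def test_zero_at_unit_tolerance(self, rng):
        """The range distance is bounded by 1, so every template pair matches
        at r = 1 and the entropy is exactly 0."""
        for x in [rng.standard_normal(490), np.sin(np.arange(100) / 3.0)]:
            assert range_entropy_B(x, m=2, r=1.0) == 0.0

    def test_nonincreasing_in_tolerance(self, rng):
        x = rng.standard_normal(2000)
        assert range_entropy_B(x, 2, 0.2) > range_entropy_B(x, 2, 0.8)

    def test_matches_brute_force(self, rng):
        x = rng.standard_normal(200)
        for r in (0.3, 0.6, 1.0):
            assert range_entropy_B(x, m=2, r=r) == pytest.approx(
                brute_range_entropy(x, 2, r), abs=1e-12
            )

    @pytest.mark.parametrize("r", [0.0, -0.5, 1.5])
    def test_tolerance_outside_unit_interval_rejected(self, r, rng):
        with pytest.raises(ValueError):
            range_entropy_B(rng.standard_normal(64), 2, r)

    def test_auc_stable_under_grid_refinement(self, rng):
        x = rng.standard_normal(2000)
        coarse = range_entropy_B_auc(x, 2, np.linspace(0.02, 1.0, 51))
        fine = range_entropy_B_auc(x, 2, np.linspace(0.02, 1.0, 501))
        assert coarse == pytest.approx(fine, rel=0.02)

    def test_trajectory_monotone_nonincreasing_statistically(self):
        grids = []
        for s in range(20):
            x = np.random.default_rng(s).standard_normal(500)
            grids.append(range_entropy_B_trajectory(x, 2).entropy)
        mean_traj = np.nanmean(grids, axis=0)
        diffs = np.diff(mean_traj[np.isfinite(mean_traj)])
        assert np.all(diffs < 1e-6)


# ---------------------------------------------------------------------------
# coarse-graining and multiscale entropy
# ---------------------------------------------------------------------------

class TestMSE:
    def test_coarse_grain_identity_and_means(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        assert np.array_equal(coarse_grain(x, 1), x)
        assert np.array_equal(coarse_grain(x, 2), [1.5, 3.5, 5.5])
        assert np.array_equal(coarse_grain(np.array([1.0, 2, 3, 4, 5]), 2),
                              [1.5, 3.5])

    def test_coarse_grain_scale_too_large(self):
        with pytest.raises(ValueError):
            coarse_grain(np.arange(10.0), 6)

    def test_white_noise_trajectory_nonincreasing(self):
        trajs = [
            multiscale_entropy_trajectory(
                np.random.default_rng(s).standard_normal(4096)
            ).entropy
            for s in range(20)
        ]
        mean_traj = np.mean(trajs, axis=0)
        assert np.all(np.diff(mean_traj) < 0.005)

    def test_persistent_fgn_exceeds_white_noise_at_coarse_scales(self):
        """Long-memory series keep variance (hence entropy) under
        coarse-graining; white noise does not."""
        white, persistent = [], []
        for s in range(10):
            white.append(
                multiscale_entropy_trajectory(
                    np.random.default_rng(s).standard_normal(4096)
                ).entropy
            )
            persistent.append(
                multiscale_entropy_trajectory(generate_fgn(4096, 0.9, s)).entropy
            )
        white = np.mean(white, axis=0)
        persistent = np.mean(persistent, axis=0)
        assert np.all(persistent[4:] > white[4:])

    def test_constant_trajectory_auc(self):
        traj = EntropyTrajectory(
            abscissa=np.arange(1.0, 11.0), entropy=np.full(10, 0.7),
            kind="mse_scale",
        )
        assert traj.auc() / 10 == pytest.approx(0.7 * 9 / 10)

    def test_auc_affine_invariance(self, rng):
        x = rng.standard_normal(1000)
        assert multiscale_entropy_auc(2.0 * x - 3.0) == pytest.approx(
            multiscale_entropy_auc(x), abs=1e-12
        )
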