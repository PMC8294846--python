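"""Synthetic generators: connectomes, cascades, embeddings, branching
process, leadfield surrogate."""

import numpy as np
import pytest
from scipy import stats

from avaconn.detect import bin_raster, binarize, detect_avalanches, zscore_series
from avaconn.errors import (
    DegenerateGeneratorError,
    ParameterError,
    PlacementError,
)
from avaconn.synth import (
    embed_continuous,
    gen_connectome,
    gen_leadfield_surrogate,
    simulate_branching_process,
    simulate_cascades,
)
from avaconn.types import CascadeGroundTruth, SurrogateSpec

from conftest import brute_force_transition_freq


def detect_chain(series, threshold=3.0, bin_size=3, min_duration=1, fs=1024.0):
    z = zscore_series(series, fs)
    raster = bin_raster(binarize(z, threshold), bin_size, fs=fs, threshold=threshold)
    return detect_avalanches(raster, min_duration=min_duration)


class TestGenConnectome:
    def test_smallest_valid_graph(self):
        sc = gen_connectome(2, density=1.0, seed=1)
        assert sc.weights[0, 1] > 0
        assert sc.weights[0, 1] == sc.weights[1, 0]
        assert sc.weights[0, 0] == sc.weights[1, 1] == 0

    def test_seeded_determinism(self):
        a = gen_connectome(66, density=0.3, seed=7)
        b = gen_connectome(66, density=0.3, seed=7)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_density_within_binomial_ci(self):
        sc = gen_connectome(66, density=0.3, seed=7)
        iu = np.triu_indices(66, 1)
        n_pairs = len(iu[0])
        observed = (sc.weights[iu] > 0).sum()
        lo, hi = stats.binom.interval(0.99, n_pairs, 0.3)
        assert lo <= observed <= hi

    def test_invariants(self):
        sc = gen_connectome(20, density=0.1, weight_dispersion=2.0, seed=0)
        np.testing.assert_array_equal(sc.weights, sc.weights.T)
        assert (sc.weights >= 0).all()
        assert (np.diag(sc.weights) == 0).all()
        assert (sc.weights > 0).any()

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_regions=1), dict(n_regions=10, density=0.0),
         dict(n_regions=10, density=1.5), dict(n_regions=10, weight_dispersion=0)],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ParameterError):
            gen_connectome(**{"density": 0.5, **kwargs})


class TestSimulateCascades:
    def test_sigma_target_zero_gives_duration_one(self):
        sc = gen_connectome(10, seed=0)
        gt = simulate_cascades(sc, coupling=0.5, sigma_target=0.0, n_cascades=50, seed=1)
        assert all(r.shape[1] == 1 for r in gt.rasters)

    def test_every_bin_active(self):
        sc = gen_connectome(12, seed=0)
        gt = simulate_cascades(sc, coupling=0.7, sigma_target=1.3, n_cascades=200, seed=2)
        assert all(r.any(axis=0).all() for r in gt.rasters)

    def test_seeded_determinism(self):
        sc = gen_connectome(12, seed=0)
        a = simulate_cascades(sc, 0.5, 1.0, 50, seed=3)
        b = simulate_cascades(sc, 0.5, 1.0, 50, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a.rasters, b.rasters))

    def test_all_zero_connectome_fully_coupled_raises(self):
        from avaconn.types import StructuralConnectome

        sc = StructuralConnectome(weights=np.zeros((5, 5)))
        with pytest.raises(DegenerateGeneratorError):
            simulate_cascades(sc, coupling=1.0, sigma_target=1.0, n_cascades=5, seed=0)

    @staticmethod
    def _edge_rank_corr(sc, coupling, seed, n_cascades=10_000):
        gt = simulate_cascades(
            sc, coupling, sigma_target=1.0, n_cascades=n_cascades,
            max_duration=30, seed=seed,
        )
        freq = brute_force_transition_freq(gt.rasters, sc.n_regions)
        freq = freq + freq.T
        iu = np.triu_indices(sc.n_regions, 1)
        r, p = stats.spearmanr(freq[iu], sc.weights[iu])
        return r, p

    def test_uncoupled_transitions_uncorrelated_with_weights(self):
        sc = gen_connectome(24, density=0.4, seed=5)
        r, p = self._edge_rank_corr(sc, coupling=0.0, seed=6)
        assert p > 0.01 and abs(r) < 0.15

    def test_fully_coupled_transitions_track_weights(self):
        sc = gen_connectome(24, density=0.4, seed=5)
        r, p = self._edge_rank_corr(sc, coupling=1.0, seed=7)
        assert r > 0.3 and p < 0.01

    def test_coupling_monotonicity(self):
        sc = gen_connectome(24, density=0.4, seed=5)
        rs = [
            self._edge_rank_corr(sc, coupling=c, seed=8)[0] for c in (0.0, 0.5, 1.0)
        ]
        assert rs[0] <= rs[1] <= rs[2]


class TestEmbedContinuous:
    def _cascades(self, seed=9, n=12):
        sc = gen_connectome(15, density=0.5, seed=4)
        gt = simulate_cascades(sc, 0.5, 1.2, n_cascades=n, max_duration=30, seed=seed)
        gt.rasters = [r for r in gt.rasters if r.shape[1] >= 3]
        return gt

    def test_seeded_determinism(self):
        gt = self._cascades()
        a = embed_continuous(gt, seed=1)
        b = embed_continuous(gt, seed=1)
        np.testing.assert_array_equal(a, b)

    def test_invalid_amplitude(self):
        with pytest.raises(ParameterError):
            embed_continuous(self._cascades(), event_amplitude=0.0)

    def test_round_trip_exact_at_amplitude_ten(self):
        for seed in range(5):
            gt = self._cascades(seed=20 + seed)
            sig = embed_continuous(gt, bin_size=3, event_amplitude=10, seed=seed)
            avs = detect_chain(sig, bin_size=3)
            assert len(avs) == len(gt.rasters)
            for av, truth in zip(avs, gt.rasters):
                np.testing.assert_array_equal(av.raster, truth)

    def test_pure_noise_yields_no_long_avalanches(self):
        empty = CascadeGroundTruth(rasters=[], coupling=0.0, sigma_target=1.0)
        survivors = 0
        for seed in range(30):
            sig = embed_continuous(empty, bin_size=3, seed=seed)
            sig = np.vstack([sig] * 10)  # 10 independent noise regions
            survivors += len(detect_chain(sig, bin_size=3, min_duration=10))
        assert survivors == 0


class TestBranchingProcess:
    def test_sigma_zero_single_event(self):
        avs = simulate_branching_process(0.0, 100, n_regions=8, seed=0)
        assert all(a.n_events == 1 and a.duration == 1 for a in avs)

    def test_supercritical_mostly_truncated(self):
        avs = simulate_branching_process(2.0, 1000, n_regions=32, max_events=10_000, seed=1)
        frac = np.mean([a.truncated for a in avs])
        assert frac > 0.5

    def test_offspring_conservation(self):
        """Mean offspring per reproducing event within 3 SE of sigma."""
        for sigma in (0.5, 1.0, 1.5):
            avs = simulate_branching_process(sigma, 4000, n_regions=32,
                                             max_events=2000, seed=2)
            offspring = parents = 0
            for a in avs:
                offspring += a.n_events - a.events_per_bin[0]
                parents += a.n_events if not a.truncated else (
                    a.n_events - a.events_per_bin[-1]
                )
            mean = offspring / parents
            se = np.sqrt(sigma / parents)
            assert abs(mean - sigma) < 3 * se

    def test_critical_per_bin_ratio_near_one(self):
        avs = simulate_branching_process(1.0, 3000, n_regions=32, max_events=5000, seed=3)
        anc = dec = 0
        for a in avs:
            n = a.events_per_bin
            anc += n[:-1].sum()
            dec += n[1:].sum()
        assert dec / anc == pytest.approx(1.0, abs=0.05)

    def test_seeded_determinism(self):
        a = simulate_branching_process(1.0, 50, seed=4)
        b = simulate_branching_process(1.0, 50, seed=4)
        assert all(np.array_equal(x.raster, y.raster) for x, y in zip(a, b))

    def test_estimator_separates_supercritical_dynamics(self):
        """The geometric-mean branching estimator telescopes to
        (n_last/n_first)^(1/(duration-1)), so on single-ancestor avalanches
        it reads near 1 for subcritical and critical processes alike (the
        last bin is conditioned on imminent extinction) but clearly above 1
        for supercritical ones.  This documents what the estimator can and
        cannot discriminate."""
        from avaconn.detect import branching_parameter

        estimates = {}
        for sigma in (0.5, 1.0, 1.5):
            avs = simulate_branching_process(
                sigma, 6000, n_regions=32, max_events=10_000, seed=6
            )
            estimates[sigma] = branching_parameter(avs).sigma
        assert estimates[1.5] > estimates[1.0] + 0.2
        assert abs(estimates[0.5] - 1.0) < 0.15
        assert abs(estimates[1.0] - 1.0) < 0.15

    def test_raster_collapses_duplicates_counts_do_not(self):
        avs = simulate_branching_process(2.5, 200, n_regions=4, max_events=500, seed=5)
        assert any(
            a.events_per_bin[j] > a.raster[:, j].sum()
            for a in avs
            for j in range(a.duration)
        )


class TestLeadfieldSurrogate:
    def test_seeded_determinism(self):
        spec = SurrogateSpec(n_perturbations=10, seed=0)
        a = gen_leadfield_surrogate(spec, n_sensors=80, n_samples=5000)
        b = gen_leadfield_surrogate(spec, n_sensors=80, n_samples=5000)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
        assert a[2].equals(b[2])

    def test_placement_respects_separation(self):
        spec = SurrogateSpec(seed=1)
        _, _, log = gen_leadfield_surrogate(spec, n_sensors=80, n_samples=30_000)
        log = log.sort_values("onset_sample").reset_index(drop=True)
        gaps = (
            log.onset_sample.values[1:]
            - (log.onset_sample.values[:-1] + log.length.values[:-1])
        )
        assert (gaps >= spec.min_separation).all()
        assert (log.onset_sample + log.length <= 30_000).all()

    def test_infeasible_placement_raises(self):
        with pytest.raises(PlacementError):
            gen_leadfield_surrogate(
                SurrogateSpec(seed=2), n_sensors=80, n_samples=2000
            )

    def test_perturbations_recovered_in_source_region(self):
        hits = total = 0
        for seed in range(3):
            spec = SurrogateSpec(seed=seed)
            _, recon, log = gen_leadfield_surrogate(
                spec, n_sensors=120, n_samples=50_000
            )
            active = binarize(zscore_series(recon, 1024.0), 3.0)
            for row in log.itertuples(index=False):
                window = active[row.region, row.onset_sample : row.onset_sample + row.length]
                hits += bool(window.any())
                total += 1
        assert hits / total >= 0.9

    def test_no_perturbations_no_long_excursions(self):
        survivors = 0
        for seed in range(5):
            spec = SurrogateSpec(n_perturbations=0, seed=seed)
            _, recon, log = gen_leadfield_surrogate(spec, n_sensors=100, n_samples=8000)
            assert log.empty
            survivors += len(detect_chain(recon, bin_size=3, min_duration=10))
        assert survivors == 0

    def test_invalid_spec(self):
        with pytest.raises(ParameterError):
            SurrogateSpec(min_separation=50)  # shorter than longest perturbation
        with pytest.raises(ParameterError):
            SurrogateSpec(snr=0)
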