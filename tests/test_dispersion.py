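"""Network dispersion formulas, covariate effects, and label-spin specificity."""

from itertools import combinations

import numpy as np
import pytest

from axisflux import (
    ValidationError,
    between_dispersion,
    dispersion_series,
    fit_dispersion_effects,
    spin_specificity,
    within_dispersion,
)
from axisflux import synth
from axisflux.spatial_null import generate_spins
from tests.test_effects import make_cov
from tests.test_variability import make_axes


def brute_force_dispersion(loadings, labels):
    """Independent plain-loop evaluation of D_w and D_b."""
    networks = sorted(set(labels), key=list(labels).index)
    from axisflux.data_model import NETWORK_ORDER

    networks = [n for n in NETWORK_ORDER if n in set(labels)]
    med = {}
    dw = []
    for net in networks:
        vals = [loadings[i] for i in range(len(labels)) if labels[i] == net]
        m = float(np.median(vals))
        med[net] = m
        total = 0.0
        for v in vals:
            total += (v - m) ** 2
        dw.append(total)
    db = []
    for a, b in combinations(networks, 2):
        db.append(abs(med[a] - med[b]))
    return np.array(dw), np.array(db)


class TestWithinDispersion:
    def test_hand_worked_value(self):
        # loadings {1,2,3}: median 2, D_w = (1-2)^2 + 0 + (3-2)^2 = 2
        labels = np.array(["visual"] * 3, dtype=object)
        out = within_dispersion(np.array([1.0, 2.0, 3.0]), labels)
        assert out[0] == pytest.approx(2.0)

    def test_all_equal_loadings_zero(self):
        labels = np.array(["visual"] * 4, dtype=object)
        assert within_dispersion(np.full(4, 3.3), labels)[0] == 0.0

    def test_translation_invariance(self, rng, meta100):
        g = rng.standard_normal(100)
        a = within_dispersion(g, meta100.network)
        b = within_dispersion(g + 17.0, meta100.network)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_single_parcel_network_zero(self):
        labels = np.array(["visual", "limbic", "limbic"], dtype=object)
        out = within_dispersion(np.array([5.0, 1.0, 2.0]), labels)
        assert out[0] == 0.0  # visual has one parcel


class TestBetweenDispersion:
    def test_hand_worked_value(self):
        # A {0, 0} median 0; B {1, 3} median 2 -> D_b = 2
        labels = np.array(["visual", "visual", "limbic", "limbic"], dtype=object)
        out = between_dispersion(np.array([0.0, 0.0, 1.0, 3.0]), labels)
        assert out[0] == pytest.approx(2.0)

    def test_identical_medians_zero(self):
        labels = np.array(["visual", "limbic"], dtype=object)
        assert between_dispersion(np.array([1.0, 1.0]), labels)[0] == 0.0

    def test_pair_count_for_seven_networks(self, meta100, rng):
        out = between_dispersion(rng.standard_normal(100), meta100.network)
        assert out.size == 21


class TestDispersionSeries:
    def test_identical_sessions_identical_rows(self, meta100, rng):
        g = rng.standard_normal(100)
        axes = make_axes(np.tile(g[:, None], (1, 5)))
        ser = dispersion_series(axes, meta100)
        for s in range(1, 5):
            np.testing.assert_array_equal(ser.within[s], ser.within[0])
            np.testing.assert_array_equal(ser.between[s], ser.between[0])

    def test_matches_brute_force(self, meta100, rng):
        for _ in range(100):
            g = rng.standard_normal(100)
            dw, db = brute_force_dispersion(g, list(meta100.network))
            np.testing.assert_allclose(
                within_dispersion(g, meta100.network), dw, atol=1e-12
            )
            np.testing.assert_allclose(
                between_dispersion(g, meta100.network), db, atol=1e-12
            )

    def test_scale_equivariance(self, meta100, rng):
        g = rng.standard_normal(100)
        c = 3.7
        np.testing.assert_allclose(
            within_dispersion(c * g, meta100.network),
            c**2 * within_dispersion(g, meta100.network),
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            between_dispersion(c * g, meta100.network),
            c * between_dispersion(g, meta100.network),
            rtol=1e-12,
        )

    def test_session_permutation_equivariance(self, meta100, rng):
        loadings = rng.standard_normal((100, 6))
        axes = make_axes(loadings)
        perm = [3, 1, 5, 0, 2, 4]
        axes_p = make_axes(loadings[:, perm])
        ser = dispersion_series(axes, meta100)
        ser_p = dispersion_series(axes_p, meta100)
        np.testing.assert_allclose(ser_p.within, ser.within[perm], atol=1e-14)

    def test_total_ss_bounds_within_sum(self, meta100, rng):
        # sum of within-network SS about medians cannot exceed the total SS
        # about the per-network means plus the median-vs-mean slack; checked
        # against the loose global inequality sum(D_w) <= total SS about
        # network means * (1 + slack) via brute force
        for _ in range(20):
            g = rng.standard_normal(100)
            dw = within_dispersion(g, meta100.network)
            total = 0.0
            for net in set(meta100.network):
                sub = g[meta100.network == net]
                total += np.sum((sub - sub.mean()) ** 2) + sub.size * (
                    np.median(sub) - sub.mean()
                ) ** 2
            assert dw.sum() <= total + 1e-10


class TestFitDispersionEffects:
    def test_bonferroni_thresholds_printed_values(self):
        assert round(0.025 / 7, 3) == 0.004
        assert round(0.025 / 21, 3) == 0.001

    def test_planted_effect_detected(self, meta100, cycle_cov):
        truth = synth.make_ground_truth(
            meta100,
            gamma_dispersion={"estradiol": {"default_mode": 0.6}},
            noise_sd=0.005,
            seed=4,
        )
        loadings = synth.simulate_session_loadings(meta100, truth, cycle_cov)
        ser = dispersion_series(make_axes(loadings), meta100)
        eff = fit_dispersion_effects(ser, cycle_cov, ["estradiol"])
        row = eff[
            (eff.measure == "default_mode") & (eff.covariate == "estradiol")
        ].iloc[0]
        assert row.t > 0
        assert row.bonferroni_significant

    def test_null_familywise_error_within_family(self):
        # Bonferroni at 0.025/7 keeps the within-family FWER at or below 0.025
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            meta = synth.make_parcellation(60, 7, seed=2)
            loadings = rng.standard_normal((60, 20))
            cov = make_cov({"h": rng.uniform(0, 1, 20)})
            ser = dispersion_series(make_axes(loadings), meta)
            eff = fit_dispersion_effects(ser, cov, ["h"])
            within = eff[eff.kind == "within"]
            hits += int(within.bonferroni_significant.any())
        # binomial 95% upper band around 0.025 with 60 draws
        assert hits / n_seeds <= 0.025 + 1.96 * np.sqrt(0.025 * 0.975 / n_seeds)

    def test_sign_convention_columns(self, meta100, cycle_cov, rng):
        loadings = rng.standard_normal((100, 29))
        ser = dispersion_series(make_axes(loadings), meta100)
        eff = fit_dispersion_effects(ser, cycle_cov, ["estradiol", "pss_score"])
        assert set(eff.kind) == {"within", "between"}
        assert len(eff) == (7 + 21) * 2


@pytest.fixture(scope="module")
def spins(meta100):
    return generate_spins(meta100, n_perm=100, seed=12)


class TestSpinSpecificity:
    def test_network_specific_effect_localized(self, meta100, cycle_cov, spins):
        # realistic measurement noise: with a near-deterministic signal the
        # t statistic saturates for any relabeling that clips the true
        # network, and localization is impossible by construction
        truth = synth.make_ground_truth(
            meta100,
            gamma_dispersion={"estradiol": {"default_mode": 0.6}},
            noise_sd=0.05,
            seed=4,
        )
        loadings = synth.simulate_session_loadings(meta100, truth, cycle_cov)
        axes = make_axes(loadings)
        p = spin_specificity(
            axes, meta100, cycle_cov, "default_mode", "estradiol", spins
        )
        assert p <= 0.05

    def test_global_effect_not_specific(self, meta100, cycle_cov):
        # a cortex-wide expansion (all loadings scaled about the global
        # median) survives network relabeling -> the spin p is not small
        spins = generate_spins(meta100, n_perm=50, seed=13)
        e2 = cycle_cov.data["estradiol"].to_numpy()
        z = (e2 - e2.mean()) / e2.std(ddof=1)
        ps = []
        for seed in (1, 2, 3):
            truth = synth.make_ground_truth(meta100, noise_sd=0.05, seed=seed)
            loadings = synth.simulate_session_loadings(
                meta100, truth, cycle_cov
            )
            m = np.median(loadings, axis=0)
            loadings = m + (loadings - m) * (1.0 + 0.3 * z)[None, :]
            p = spin_specificity(
                make_axes(loadings), meta100, cycle_cov, "default_mode",
                "estradiol", spins,
            )
            ps.append(p)
        assert np.median(ps) > 0.2

    def test_p_bounded_below(self, meta100, cycle_cov, spins):
        rng = np.random.default_rng(0)
        axes = make_axes(rng.standard_normal((100, 29)))
        p = spin_specificity(
            axes, meta100, cycle_cov, "visual", "estradiol", spins
        )
        assert p >= 1 / (spins.n_perm + 1)


class TestErrors:
    def test_empty_network_rejected(self):
        labels = np.array(["visual", "visual"], dtype=object)
        with pytest.raises(ValidationError):
            dispersion_series(
                make_axes(np.ones((3, 3))), None, labels=labels
            )
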