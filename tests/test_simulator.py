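import math

import numpy as np
import pytest
from scipy import stats as sps

from rhizomorph.morphometrics import (
    bifurcation_angles,
    count_tips_bifurcations,
    summarize,
    total_length,
)
from rhizomorph.simulator import (
    Bead,
    GrowthParams,
    bead_contact_split,
    preset,
    simulate,
)
from rhizomorph.swc import write_swc


class TestParams:
    def test_presets_encode_published_rates(self):
        p = preset("replete")
        assert p.angle_mu == 81.4
        assert p.elongation_budget == 110.8
        assert p.branch_rate == 4.6

    def test_starved_is_sparser_and_wider(self):
        r, s = preset("replete"), preset("starved")
        assert s.branch_rate < r.branch_rate
        assert s.angle_mu > r.angle_mu
        assert s.elongation_budget == r.elongation_budget  # searching keeps growing

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            preset("well-fed")

    def test_invalid_params_listed(self):
        p = GrowthParams(elongation_budget=-1, lateral_prob=1.5, angle_mu=200)
        with pytest.raises(ValueError) as err:
            p.validate()
        msg = str(err.value)
        assert "elongation_budget" in msg and "lateral_prob" in msg and "angle_mu" in msg

    def test_yaml_roundtrip(self, tmp_path):
        cfg = tmp_path / "params.yaml"
        cfg.write_text("preset: starved\nseed: 7\nduration: 2.0\n")
        p = GrowthParams.from_file(cfg)
        assert p.branch_rate == 2.3 and p.seed == 7 and p.duration == 2.0
        with pytest.raises(ValueError):
            GrowthParams.from_dict({"elongation_speed": 1.0})


class TestGrowthLaw:
    def test_branchless_growth_is_a_single_filament(self):
        params = GrowthParams(
            elongation_budget=10.0, branch_rate=1e-12, duration=1.0, seed=0
        )
        series, log = simulate(params)
        tree = series.trees[-1]
        assert len(log) == 0
        assert count_tips_bifurcations(tree) == (1, 0)
        assert total_length(tree) == pytest.approx(10.0, abs=1e-9)

    def test_length_conservation_under_branching(self):
        """Total length is V·T regardless of branching history."""
        for seed in (0, 1, 2):
            p = preset("replete")
            p.seed = seed
            p.duration = 5.0
            series, _ = simulate(p)
            expected = 110.8 * 5.0
            assert total_length(series.trees[-1]) == pytest.approx(
                expected, abs=110.8 * p.dt
            )

    def test_tip_count_is_poisson_shifted(self):
        """Across seeds, tips at T ~ 1 + Poisson(λT) (chi-square GOF, α=0.01)."""
        lam = 4.6 * 9.99  # no arrivals on the final step
        counts = []
        for seed in range(20):
            p = preset("replete")
            p.seed = 200 + seed
            counts.append(count_tips_bifurcations(simulate(p)[0].trees[-1])[0] - 1)
        counts = np.array(counts)
        # bin by Poisson quartiles and compare observed vs expected
        qs = sps.poisson.ppf([0.25, 0.5, 0.75], lam)
        edges = [-0.5, *qs, np.inf]
        obs, _ = np.histogram(counts, bins=edges)
        cdf = sps.poisson.cdf([e for e in edges[1:-1]], lam)
        probs = np.diff([0.0, *cdf, 1.0])
        chi2 = ((obs - 20 * probs) ** 2 / (20 * probs)).sum()
        assert chi2 < sps.chi2.ppf(0.99, df=3)

    def test_rgu_saturates_near_budget_over_rate(self):
        """Ratio-RGU rises early then plateaus near V/λ."""
        curves = []
        for seed in (301, 302, 303, 304, 305):
            p = preset("replete")
            p.seed = seed
            series, _ = simulate(p)
            curves.append([summarize(t).rgu_ratio for t in series.trees])
        m = np.nanmean(np.array(curves, dtype=float), axis=0)
        assert m[1] < m[4] <= max(m)  # early rise
        late = m[-3:]
        assert np.ptp(late) / late.mean() < 0.2  # plateau
        assert abs(late.mean() - 110.8 / 4.6) / (110.8 / 4.6) < 0.35

    def test_lateral_fraction_follows_probability(self):
        kinds = []
        for seed in (401, 402, 403, 404):
            p = preset("replete")
            p.seed = seed
            kinds += [e.kind for e in simulate(p)[1]]
        frac = np.mean([k == "branch_lateral" for k in kinds])
        lo, hi = sps.binom.interval(0.99, len(kinds), 0.85)
        assert lo / len(kinds) <= frac <= hi / len(kinds)

    def test_angle_distribution_mean(self):
        angles = []
        for seed in (501, 502, 503):
            p = preset("replete")
            p.seed = seed
            angles += bifurcation_angles(simulate(p)[0].trees[-1])
        assert len(angles) > 100
        assert np.mean(angles) == pytest.approx(81.4, abs=2.0)


class TestDeterminism:
    def test_identical_seed_bytes_identical(self, tmp_path):
        p = preset("replete")
        p.seed = 42
        p.duration = 3.0
        outs = []
        for run in (0, 1):
            series, log = simulate(p)
            blobs = []
            for i, (_, tree) in enumerate(series.frames):
                f = tmp_path / f"run{run}_f{i}.swc"
                write_swc(tree, f)
                blobs.append(f.read_bytes())
            outs.append((blobs, [(e.time, e.kind, e.node_id, e.angle_deg) for e in log]))
    # byte-identical frames and identical event logs
        assert outs[0] == outs[1]

    def test_different_seeds_differ(self):
        p1, p2 = preset("replete"), preset("replete")
        p1.seed, p2.seed = 1, 2
        p1.duration = p2.duration = 2.0
        t1 = simulate(p1)[0].trees[-1]
        t2 = simulate(p2)[0].trees[-1]
        assert len(t1) != len(t2) or not np.allclose(t1.coords, t2.coords)


class TestBeadMode:
    def test_contact_split_far_bead_is_empty(self, toy_y):
        contact, free = bead_contact_split(toy_y, Bead(centre=(1000, 0, 0), radius=5))
        assert contact.n_edges == 0 and contact.total_length == 0.0
        assert free.total_length == pytest.approx(30.0)

    def test_crossing_filament_splits_both_ways(self, toy_y):
        contact, free = bead_contact_split(
            toy_y, Bead(centre=(0.0, 14.0, 0.0), radius=3.0), contact_tolerance=1.0
        )
        assert contact.n_edges > 0 and free.n_edges > 0
        assert contact.total_length + free.total_length == pytest.approx(30.0)

    def test_requires_bead(self, toy_y):
        with pytest.raises(ValueError):
            bead_contact_split(toy_y, None)

    def test_feeding_contact_rhizoid_is_more_branched(self):
        """Particle-contact rhizoid has lower ratio-RGU than free rhizoid."""
        wins = total = 0
        for seed in (601, 602, 603, 604, 605):
            p = preset("bead")
            p.seed = seed
            series, _ = simulate(p)
            contact, free = bead_contact_split(series.trees[-1], p.bead, p.contact_tolerance)
            if contact.n_tips and free.n_tips:
                total += 1
                wins += contact.rgu_ratio < free.rgu_ratio
        assert total >= 4 and wins == total
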