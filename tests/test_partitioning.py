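"""Loss partitioning: component estimators, exact closure, closure test."""

import numpy as np
import pytest
from scipy import stats

from socbalance import (
    DataError,
    DegradationStage,
    SequenceScenario,
    StageEnsemble,
    closure_check,
    erosion_loss,
    generate_sequence,
    mineralization_loss,
    partition_sequence,
    percent_loss,
    total_loss,
)
from conftest import make_profile


def degraded_ensemble(stage="S5", crack=0.0, scale=1.0, n=4):
    """Degraded replicates built from the fixture reference layout."""
    layers = [
        ("Ah1", 0.0, 5.0, 60.0 * scale, 0.7),
        ("Ah2", 5.0, 15.0, 50.0 * scale, 0.85),
        ("Bw", 15.0, 35.0, 30.0 * scale, 1.1),
    ]
    if crack:
        layers = [
            (l, max(t - crack, 0.0), b - crack, c, d)
            for l, t, b, c, d in layers
            if b > crack
        ]
    return StageEnsemble(
        stage=DegradationStage.from_label(stage),
        profiles=[
            make_profile(stage=stage, replicate=f"r{i}", crack=crack, layers=layers)
            for i in range(1, n + 1)
        ],
    )


class TestTotalLoss:
    def test_identical_ensembles_lose_nothing(self, reference_ensemble):
        loss = total_loss(reference_ensemble, degraded_ensemble("S1"), 30.0)
        assert loss.mean == pytest.approx(0.0, abs=1e-12)

    def test_subtraction_of_means(self, reference_ensemble):
        # reference stock over 30 cm: 60*0.7*5 + 50*0.85*10 + 30*1.1*15 = 2.1+4.25+4.95
        deg = degraded_ensemble("S5", scale=0.5)
        loss = total_loss(reference_ensemble, deg, 30.0)
        assert loss.mean == pytest.approx(0.5 * 11.3)

    def test_gain_is_a_negative_loss_unclamped(self, reference_ensemble):
        deg = degraded_ensemble("S1", scale=1.2)
        assert total_loss(reference_ensemble, deg, 30.0).mean < 0


class TestErosionLoss:
    def test_zero_crack_depth_is_zero_everything(self, reference_ensemble):
        result = erosion_loss(reference_ensemble, 0.0)
        assert result.carbon.mean == 0.0
        assert result.soil_mass_mean == 0.0

    def test_single_horizon_closed_form(self):
        ens = StageEnsemble(
            stage=DegradationStage.S0,
            profiles=[
                make_profile(replicate=f"r{i}", layers=[("A", 0.0, 15.0, 60.0, 0.85)])
                for i in range(1, 4)
            ],
        )
        result = erosion_loss(ens, 10.0)
        assert result.carbon.mean == pytest.approx(5.1)  # 60*0.85*10*1e-2
        assert result.soil_mass_mean == pytest.approx(85.0)  # 0.85*10*10

    def test_crack_beyond_profile_depth_raises(self, reference_ensemble):
        with pytest.raises(DataError, match="exceeds"):
            erosion_loss(reference_ensemble, 50.0)

    def test_monotone_and_continuous_in_crack_depth(self, reference_ensemble):
        depths = np.linspace(0, 35, 351)
        values = [erosion_loss(reference_ensemble, d).carbon.mean for d in depths]
        diffs = np.diff(values)
        assert np.all(diffs >= -1e-12)
        # continuity: no jump larger than the densest horizon's contribution per step
        max_rate = max(h.soc_content * h.bulk_density for h in reference_ensemble.profiles[0].horizons)
        assert np.max(diffs) <= max_rate * 0.1 * 1e-2 + 1e-12


class TestMineralizationLoss:
    def test_identical_ensembles_lose_nothing(self, reference_ensemble):
        loss = mineralization_loss(reference_ensemble, degraded_ensemble("S1"), 30.0)
        assert loss.mean == pytest.approx(0.0, abs=1e-12)

    def test_single_horizon_closed_form(self):
        ref = StageEnsemble(
            stage=DegradationStage.S0,
            profiles=[
                make_profile(replicate=f"r{i}", layers=[("A", 0.0, 10.0, 60.0, 0.8)])
                for i in range(1, 3)
            ],
        )
        deg = StageEnsemble(
            stage=DegradationStage.S2,
            profiles=[
                make_profile(
                    stage="S2", replicate=f"r{i}", layers=[("A", 0.0, 10.0, 45.0, 0.8)]
                )
                for i in range(1, 3)
            ],
        )
        loss = mineralization_loss(ref, deg, 10.0)
        assert loss.mean == pytest.approx(4.8 - 3.6)

    def test_missing_matching_horizon_raises(self, reference_ensemble):
        deg = degraded_ensemble("S4")
        for p in deg.profiles:
            p.horizons = p.horizons[:1]
        with pytest.raises(DataError, match="horizon matching error"):
            mineralization_loss(reference_ensemble, deg, 30.0)


class TestPercentLoss:
    def test_zero_loss_is_zero_percent(self, reference_ensemble):
        assert percent_loss(0.0, reference_ensemble, 30.0) == 0.0

    def test_division_by_reference_mean(self, reference_ensemble):
        # reference mean stock is 11.3 kg C m^-2 over 30 cm
        assert percent_loss(11.3 * 0.45, reference_ensemble, 30.0) == pytest.approx(45.0)

    def test_loss_equal_to_reference_is_100_percent(self, reference_ensemble):
        assert percent_loss(11.3, reference_ensemble, 30.0) == pytest.approx(100.0)


class TestClosureCheck:
    def test_identical_vectors_close_with_p_one(self):
        stat, p, ns = closure_check([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0 and ns

    def test_strongly_offset_vectors_reject(self):
        rng = np.random.default_rng(7)
        a = rng.normal(5.0, 0.1, 8)
        b = a + 1.0  # 10 SD offset
        _, p, ns = closure_check(a, b)
        assert p < 0.05 and not ns

    def test_single_replicate_raises(self):
        with pytest.raises(DataError, match="insufficient replication"):
            closure_check([1.0], [1.0, 2.0])

    def test_decision_agrees_with_permutation_oracle(self):
        """Welch accept/reject matches a permutation test in >=95% of cases."""
        rng = np.random.default_rng(42)
        agree = 0
        n_cases = 100
        for _ in range(n_cases):
            shift = rng.uniform(0, 1.5)
            a = rng.normal(0.0, 1.0, 6)
            b = rng.normal(shift, 1.0, 6)
            _, p_w, ns_w = closure_check(a, b)
            perm = stats.permutation_test(
                (a, b),
                lambda x, y: np.mean(x) - np.mean(y),
                permutation_type="independent",
                n_resamples=2000,
                random_state=rng.integers(2**31),
            )
            agree += ns_w == (perm.pvalue >= 0.05)
        assert agree / n_cases >= 0.95


class TestPartitionSequence:
    def test_requires_reference_stage(self):
        with pytest.raises(DataError, match="no reference stage"):
            partition_sequence([degraded_ensemble("S3")])

    def test_erosion_only_scenario_has_no_mineralization(self):
        scenario = SequenceScenario(
            noise_cv=0.0, mineralization_intensity=(0.0,) * 5
        )
        ensembles, _ = generate_sequence(scenario)
        for r in partition_sequence(ensembles):
            assert r.mineralization.mean == pytest.approx(0.0, abs=1e-12)
            assert r.erosion.carbon.mean > 0

    def test_mineralization_only_scenario_has_no_erosion(self):
        scenario = SequenceScenario(noise_cv=0.0, erosion_depths=(0.0,) * 5)
        ensembles, _ = generate_sequence(scenario)
        for r in partition_sequence(ensembles):
            assert r.erosion.carbon.mean == 0.0
            assert r.mineralization.mean > 0

    def test_noiseless_sequence_recovers_ground_truth(self):
        ensembles, truth = generate_sequence(SequenceScenario(noise_cv=0.0))
        for r in partition_sequence(ensembles):
            st = truth.stages[r.stage]
            assert r.total_reference_frame.mean == pytest.approx(st.total, abs=1e-10)
            assert r.erosion.carbon.mean == pytest.approx(st.erosion, abs=1e-10)
            assert r.mineralization.mean == pytest.approx(st.mineralization, abs=1e-10)
            assert r.closure_ns

    def test_exact_closure_across_random_scenarios(self):
        """total = erosion + mineralization identically on noise-free data."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            scenario = SequenceScenario(
                c0=rng.uniform(40, 90),
                k=rng.uniform(0.0, 0.03),
                b0=rng.uniform(0.4, 0.9),
                bd_slope=rng.uniform(0.0, 0.025),
                erosion_depths=tuple(np.sort(rng.uniform(0, 14, 5))),
                mineralization_intensity=tuple(np.sort(rng.uniform(0, 0.5, 5))),
                noise_cv=0.0,
                seed=int(rng.integers(2**31)),
            )
            ensembles, _ = generate_sequence(scenario)
            for r in partition_sequence(ensembles):
                residual = abs(
                    r.total_reference_frame.mean
                    - r.erosion.carbon.mean
                    - r.mineralization.mean
                )
                assert residual <= 1e-10
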