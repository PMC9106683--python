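"""CSV round trips, schema enforcement and configuration parsing."""

import numpy as np
import pandas as pd
import pytest

from socbalance import (
    ConfigError,
    DataError,
    RunConfig,
    SchemaError,
    SequenceScenario,
    generate_literature_corpus,
    generate_sequence,
    read_literature,
    read_profiles,
    read_results,
    validate_profile,
    write_results,
)
from socbalance.tabular_io import profiles_to_frame


@pytest.fixture
def profile_csv(tmp_path):
    rows = []
    for stage, crack in (("S0", 0.0), ("S2", 4.0)):
        for rep in ("r1", "r2"):
            for label, top, bottom, soc, bd in (
                ("Ah", 0.0, 5.0, 60.0, 0.7),
                ("Bw1", 5.0, 15.0, 45.0, 0.9),
                ("Bw2", 15.0, 30.0, 25.0, 1.1),
            ):
                rows.append(
                    dict(stage=stage, replicate=rep, horizon=label, top_cm=top,
                         bottom_cm=bottom, soc_g_kg=soc, bd_g_cm3=bd, crack_cm=crack)
                )
    path = tmp_path / "profiles.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


class TestReadProfiles:
    def test_rows_group_into_stage_ensembles(self, profile_csv):
        ensembles = read_profiles(profile_csv)
        assert len(ensembles) == 2
        assert all(len(e.profiles) == 2 for e in ensembles)
        assert all(len(p.horizons) == 3 for e in ensembles for p in e.profiles)

    def test_missing_required_column_is_a_schema_error(self, profile_csv, tmp_path):
        frame = pd.read_csv(profile_csv).drop(columns=["bd_g_cm3"])
        bad = tmp_path / "bad.csv"
        frame.to_csv(bad, index=False)
        with pytest.raises(SchemaError, match="bd_g_cm3"):
            read_profiles(bad)

    def test_duplicate_horizon_row_is_a_data_error(self, profile_csv, tmp_path):
        frame = pd.read_csv(profile_csv)
        dup = tmp_path / "dup.csv"
        pd.concat([frame, frame.iloc[[0]]]).to_csv(dup, index=False)
        with pytest.raises(DataError, match="duplicate"):
            read_profiles(dup)

    def test_invariant_violation_names_the_profile(self, profile_csv, tmp_path):
        frame = pd.read_csv(profile_csv)
        frame.loc[0, "soc_g_kg"] = -5.0
        bad = tmp_path / "neg.csv"
        frame.to_csv(bad, index=False)
        with pytest.raises(DataError, match="S0/r1"):
            read_profiles(bad)

    def test_generated_sequence_round_trips_losslessly(self, tmp_path):
        ensembles, _ = generate_sequence(SequenceScenario(seed=4))
        path = tmp_path / "gen.csv"
        write_results(profiles_to_frame(ensembles), path)
        back = read_profiles(path)
        assert [e.stage for e in back] == [e.stage for e in ensembles]
        for ea, eb in zip(ensembles, back):
            for pa, pb in zip(ea.profiles, eb.profiles):
                assert validate_profile(pb) == []
                assert pb.crack_depth == pytest.approx(pa.crack_depth)
                for ha, hb in zip(pa.horizons, pb.horizons):
                    assert hb.soc_content == pytest.approx(ha.soc_content, rel=1e-5)
                    assert hb.bulk_density == pytest.approx(ha.bulk_density, rel=1e-5)
                    assert hb.delta13c == pytest.approx(ha.delta13c, rel=1e-5)


class TestReadLiterature:
    def test_corpus_round_trip_preserves_fields(self, tmp_path):
        corpus = generate_literature_corpus(4, seed=1)
        frame = pd.DataFrame(
            {
                "study_id": [r.study_id for r in corpus],
                "degradation_label": [r.original_label for r in corpus],
                "depth_top_cm": [r.depth_top for r in corpus],
                "depth_bottom_cm": [r.depth_bottom for r in corpus],
                "carbon_kind": [r.carbon_kind for r in corpus],
                "carbon_g_kg": [r.carbon_content for r in corpus],
                "n_g_kg": [r.n_content for r in corpus],
                "bd_g_cm3": [r.bulk_density for r in corpus],
                "year": [r.year for r in corpus],
            }
        )
        path = tmp_path / "lit.csv"
        frame.to_csv(path, index=False)
        back = read_literature(path)
        assert len(back) == len(corpus)
        for a, b in zip(corpus, back):
            assert b.carbon_kind == a.carbon_kind
            assert b.carbon_content == pytest.approx(a.carbon_content)
            assert (b.bulk_density is None) == (a.bulk_density is None)

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        assert read_literature(path) == []

    def test_unparseable_numeric_cell_names_the_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "study_id,degradation_label,depth_top_cm,depth_bottom_cm,carbon_g_kg\n"
            "s1,intact,0,10,abc\n"
        )
        with pytest.raises(DataError, match="row 0"):
            read_literature(path)

    def test_unflagged_carbon_defaults_to_soc(self, tmp_path):
        path = tmp_path / "soc.csv"
        path.write_text(
            "study_id,degradation_label,depth_top_cm,depth_bottom_cm,carbon_g_kg\n"
            "s1,intact,0,10,42\n"
        )
        (record,) = read_literature(path)
        assert record.carbon_kind == "SOC"


class TestWriteResults:
    def test_round_trip_at_declared_precision(self, tmp_path):
        frame = pd.DataFrame(
            {"stage": ["S1", "S2"], "total_loss": [1.234567, 2.5], "closure_p": [0.9, 1.0]}
        )
        path = tmp_path / "out.csv"
        write_results(frame, path, RunConfig())
        back = read_results(path)
        assert list(back.columns) == list(frame.columns)
        assert np.allclose(back.total_loss, frame.total_loss, rtol=1e-5)

    def test_header_carries_version_and_config(self, tmp_path):
        path = tmp_path / "out.csv"
        write_results(pd.DataFrame({"a": [1]}), path, RunConfig(alpha=0.01))
        text = path.read_text()
        assert text.startswith("# socbalance v")
        assert "alpha=0.01" in text

    def test_empty_result_set_is_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_results(pd.DataFrame(columns=["stage", "total_loss"]), path)
        back = read_results(path)
        assert back.empty and list(back.columns) == ["stage", "total_loss"]


class TestRunConfig:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("depth_limit: 20\nalpha: 0.01\nseed: 7\n")
        config = RunConfig.from_yaml(path)
        assert config.depth_limit == 20
        assert config.alpha == 0.01
        assert config.som_to_soc_factor == 2.0

    def test_stage_mapping_entries_are_parsed(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("stage_mapping:\n  totally gone: S5\n")
        config = RunConfig.from_yaml(path)
        from socbalance import DegradationStage

        assert config.stage_mapping["totally gone"] is DegradationStage.S5

    @pytest.mark.parametrize("text", ["depth_limit: -1", "alpha: 1.5", "bogus_key: 1"])
    def test_invalid_values_raise_config_errors(self, tmp_path, text):
        path = tmp_path / "config.yaml"
        path.write_text(text + "\n")
        with pytest.raises(ConfigError):
            RunConfig.from_yaml(path)
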