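import numpy as np
import pytest
from scipy.special import expit

from lekid.certainty import corrected_certainty_table
from lekid.consensus import aci_table
from lekid.data import UNKNOWN, write_dataset
from lekid.indices import photo_index_table
from lekid.simulate import GeneratorConfig, generate, scenario_library


class TestGeneratorConfig:
    def test_defaults_mirror_study_design(self):
        cfg = GeneratorConfig()
        assert cfg.n_fishers == 38
        assert cfg.n_photos == 30
        assert cfg.photos_per_interview == (8, 10)

    def test_invalid_config_lists_offending_fields(self):
        cfg = GeneratorConfig(p_marked=1.5, photos_per_interview=(0, 5))
        with pytest.raises(ValueError) as err:
            cfg.validate()
        assert "p_marked" in str(err.value)
        assert "photos_per_interview" in str(err.value)

    def test_proportions_must_sum_to_one(self):
        cfg = GeneratorConfig(learning_mode_proportions={
            "vertical": 0.5, "horizontal": 0.5, "individual": 0.5})
        with pytest.raises(ValueError, match="sum to 1"):
            cfg.validate()


class TestGenerate:
    def test_structural_bounds_default_config(self):
        ds, truth = generate(GeneratorConfig(seed=1))
        assert ds.n_fishers == 38
        assert ds.n_photos == 30
        assert 8 * 38 <= len(ds.responses) <= 10 * 38
        per_fisher = ds.responses.groupby("fisher_id").size()
        assert per_fisher.between(8, 10).all()
        assert len(truth.assignments) == len(ds.responses)

    def test_byte_identical_determinism(self, tmp_path):
        cfg = GeneratorConfig(seed=123)
        for sub in ("a", "b"):
            ds, _ = generate(cfg)
            write_dataset(ds, tmp_path / sub)
        for name in ("responses.csv", "fishers.csv", "photos.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        ds1, _ = generate(GeneratorConfig(seed=1))
        ds2, _ = generate(GeneratorConfig(seed=2))
        assert not ds1.responses.equals(ds2.responses)

    def test_recognition_frequency_matches_configured_probability(self):
        """Law of large numbers: empirical recognition rates converge to the
        inverse-logit probabilities for marked and unmarked photos."""
        cfg = GeneratorConfig(n_fishers=1200, n_photos=30, seed=21,
                              recognition_intercept=0.0, mark_effect=1.065)
        ds, truth = generate(cfg)
        merged = ds.responses.merge(truth.photos[["photo_id", "marked"]],
                                    on="photo_id")
        for marked, expected in ((False, expit(0.0)), (True, expit(1.065))):
            rate = merged.loc[merged["marked"] == marked, "recognized"].mean()
            assert rate == pytest.approx(expected, abs=0.02)

    def test_marked_ri_gap_matches_closed_form(self):
        cfg = GeneratorConfig(n_fishers=500, seed=33,
                              recognition_intercept=0.0, mark_effect=1.065)
        ds, truth = generate(cfg)
        frame = photo_index_table(ds).frame.merge(
            truth.photos[["photo_id", "marked"]], on="photo_id")
        gap = (frame.loc[frame["marked"], "RI"].mean()
               - frame.loc[~frame["marked"], "RI"].mean())
        assert gap == pytest.approx(expit(1.065) - expit(0.0), abs=0.05)

    def test_ground_truth_consistent_with_dataset(self):
        ds, truth = generate(GeneratorConfig(seed=4))
        assert list(truth.photos["photo_id"]) == list(ds.photos["photo_id"])
        assert (truth.photos["true_name"] == ds.photos["true_name"]).all()
        pairs_resp = set(map(tuple, ds.responses[["fisher_id", "photo_id"]].values))
        pairs_truth = set(map(tuple, truth.assignments.values))
        assert pairs_resp == pairs_truth


class TestScenarios:
    def test_library_ships_required_scenarios(self):
        lib = scenario_library()
        assert {"perfect_knowledge", "no_knowledge", "paper_like", "null"} <= set(lib)
        for cfg in lib.values():
            cfg.validate()

    def test_perfect_knowledge_pipeline_limit(self):
        ds, _ = generate(scenario_library()["perfect_knowledge"])
        photo = photo_index_table(ds)
        assert (photo.frame["RI"] == 1.0).all()
        assert (photo.frame["CDI"].dropna() == 1.0).all()
        aci = aci_table(ds)
        assert (aci.frame["ACI"] == 1.0).all()
        cert = corrected_certainty_table(ds)
        assert (cert.frame["CeI"] == 1.0).all()

    def test_no_knowledge_consensus_matches_zipf_collision(self):
        """Mean pairwise CI equals the analytic collision probability of two
        independent Zipf draws from the name pool."""
        cfg = scenario_library()["no_knowledge"].with_(n_fishers=150, seed=77)
        ds, truth = generate(cfg)
        pairs = aci_table(ds).pairwise
        observed = (pairs["n_match"].sum() / pairs["n_shared"].sum())
        assert observed == pytest.approx(truth.collision_probability, abs=0.02)

    def test_occupancy_formula_matches_exact_enumeration(self):
        """sum_k 1-(1-p_k)^n equals E[#distinct] enumerated over all draw
        sequences of length n <= 5 from a 5-name Zipf pool."""
        from itertools import product

        cfg = scenario_library()["no_knowledge"].with_(
            n_photos=5, photos_per_interview=(2, 3))
        _, truth = generate(cfg)
        p = truth.zipf_probs
        for n in range(1, 6):
            exact = 0.0
            for seq in product(range(5), repeat=n):
                prob = np.prod([p[k] for k in seq])
                exact += prob * len(set(seq))
            formula = float(np.sum(1.0 - (1.0 - p) ** n))
            assert formula == pytest.approx(exact, abs=1e-12)

    def test_no_knowledge_name_diversity_matches_occupancy_formula(self):
        """Across many small surveys, mean nN at each nR <= 5 tracks the
        occupancy expectation for iid Zipf draws from the 5-name pool."""
        base = scenario_library()["no_knowledge"].with_(
            n_fishers=8, n_photos=5, photos_per_interview=(2, 3))
        samples: dict[int, list[int]] = {}
        p = None
        for seed in range(150):
            ds, truth = generate(base.with_(seed=seed))
            p = truth.zipf_probs
            for row in photo_index_table(ds).frame.itertuples(index=False):
                if 1 <= row.nR <= 5:
                    samples.setdefault(row.nR, []).append(row.nN)
        for n_r, observed in samples.items():
            if len(observed) < 50:
                continue
            expected = float(np.sum(1.0 - (1.0 - p) ** n_r))
            assert np.mean(observed) == pytest.approx(expected, abs=0.15)

    def test_null_scenario_has_no_mark_effect(self):
        cfg = scenario_library()["null"].with_(n_fishers=800, seed=3)
        ds, truth = generate(cfg)
        merged = ds.responses.merge(truth.photos[["photo_id", "marked"]],
                                    on="photo_id")
        gap = (merged.loc[merged["marked"], "recognized"].mean()
               - merged.loc[~merged["marked"], "recognized"].mean())
        assert abs(gap) < 0.03
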