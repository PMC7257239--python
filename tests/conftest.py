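import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lekid.data import UNKNOWN, Dataset

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


def build_dataset(assignments, fishers=None, photos=None):
    """Construct a small Dataset from (fisher_id, photo_id, name) triples.

    ``name`` None means the photo was not recognized; the UNKNOWN sentinel
    means recognized without a name.  Fisher and photo covariates default to
    neutral values unless overridden via dicts keyed by id.
    """
    fishers = fishers or {}
    photos = photos or {}
    rows = []
    for fisher_id, photo_id, name in assignments:
        recognized = name is not None
        rows.append({
            "fisher_id": fisher_id, "photo_id": photo_id,
            "recognized": recognized,
            "name_given": name if recognized else UNKNOWN,
            "recognition_method": "marks" if recognized else "none",
            "perceived_sex": UNKNOWN, "perceived_age_years": np.nan,
            "perceived_behavior": UNKNOWN,
        })
    frame = pd.DataFrame(rows)
    fisher_ids = sorted(frame["fisher_id"].unique())
    photo_ids = sorted(frame["photo_id"].unique())
    fisher_frame = pd.DataFrame([
        {"fisher_id": fid, "age_years": 40, "fishing_site": "lagoon",
         "learning_mode": "vertical", "dependence": True,
         **fishers.get(fid, {})}
        for fid in fisher_ids])
    photo_frame = pd.DataFrame([
        {"photo_id": pid, "home_range": 10.0, "encounter_rate": 0.5,
         "behavior_class": "good", "true_name": UNKNOWN,
         **photos.get(pid, {})}
        for pid in photo_ids])
    return Dataset(responses=frame, fishers=fisher_frame, photos=photo_frame)


@pytest.fixture
def tiny_dataset():
    """Two fishers x three photos, fully crossed: six responses."""
    return build_dataset([
        ("F01", "P01", "scooby"),
        ("F01", "P02", "caroba"),
        ("F01", "P03", None),
        ("F02", "P01", "scooby"),
        ("F02", "P02", "figueiredo"),
        ("F02", "P03", UNKNOWN),
    ])


@pytest.fixture(scope="session")
def paper_like():
    from lekid.simulate import generate, scenario_library

    return generate(scenario_library()["paper_like"])
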