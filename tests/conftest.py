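import numpy as np
import pytest

from dsanet import preprocess as pp
from dsanet.synthetic import CohortConfig, PhantomConfig, generate_cohort


def build_seg_dataset(cohort: dict, size: int = 64) -> list[dict]:
    """Preprocess every patient of a rendered cohort into training entries."""
    dataset = []
    for e in cohort["patients"]:
        frames, box = pp.preprocess_video(e["video"], size=size)
        key = pp.select_key_frame(frames)
        bundle = pp.build_key_frame_bundle(frames, key)
        dataset.append({
            "patient_id": e["patient_id"],
            "bundle": bundle,
            "tumor_mask": pp.preprocess_mask(e["tumor_mask"].pixels, box, size=size),
            "liver_mask": pp.preprocess_mask(e["liver_mask"].pixels, box, size=size),
            "truth": e["truth"],
            "clinical": e["clinical"],
            "label": e["label"],
            "survival": e["survival"],
        })
    return dataset


@pytest.fixture(scope="session")
def small_phantom_config():
    return PhantomConfig(height=64, width=64)


@pytest.fixture(scope="session")
def easy_cohort_10():
    cfg = CohortConfig(n_patients=10, seed=3,
                       phantom=PhantomConfig(height=64, width=64))
    return generate_cohort(cfg, easy=True)


@pytest.fixture(scope="session")
def easy_seg_dataset_10(easy_cohort_10):
    return build_seg_dataset(easy_cohort_10, size=64)
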