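import numpy as np
import pytest

from improcoord import MusicianProfile, Segmentation, build_recording

# the study's 8-sequence segmentation (durations 225;45;135;130;215;135;95;179)
STUDY_BOUNDARIES = (0, 225, 270, 405, 535, 750, 885, 980, 1159)
STUDY_DURATIONS = (225, 45, 135, 130, 215, 135, 95, 179)


@pytest.fixture
def study_segmentation() -> Segmentation:
    return Segmentation(STUDY_BOUNDARIES)


def make_profiles(n: int, families=("winds", "strings", "inharmonic")):
    ids = [f"M{i + 1:02d}" for i in range(n)]
    return [
        MusicianProfile(
            musician_id=ids[i],
            instrument_family=families[i % len(families)],
            seat_index=i,
            years_in_ensemble=4.0 + i % 5,
            years_cfi=10.0 + i % 7,
            familiarity_ratings={ids[j]: (i + j) % 3 for j in range(n) if j != i},
        )
        for i in range(n)
    ]


@pytest.fixture
def tiny_recording():
    """Two musicians, 40 s, trivial segmentation."""
    rng = np.random.default_rng(0)
    profiles = make_profiles(2)
    actions = {p.musician_id: rng.integers(0, 2, 40) for p in profiles}
    intentions = {p.musician_id: rng.uniform(0, 1, 40) for p in profiles}
    return build_recording(profiles, actions, intentions, Segmentation((0, 20, 40)))
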