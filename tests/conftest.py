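import pytest
from hypothesis import settings

import boarmark as bm

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return bm.default_panel()


@pytest.fixture(scope="session")
def backbone(panel):
    return bm.build_backbone(seed=0, panel=panel)


@pytest.fixture(scope="session")
def cohort(backbone):
    return bm.generate_cohort(backbone=backbone, seed=0)


@pytest.fixture(scope="session")
def wildtype_amplicon(panel, backbone):
    return bm.extract_amplicon(backbone.mc1r_template,
                               panel.assays["MC1R"].primers, "MC1R")


@pytest.fixture(scope="session")
def cohort_diplotypes(cohort):
    """Ground-truth diplotypes (with the ED/EP3 split) of the full cohort."""
    class TruthDiplotype:
        def __init__(self, s):
            self.sample_id = s.sample_id
            self.breed_label = s.breed
            self.pair = s.diplotype
    return [TruthDiplotype(s) for s in cohort.samples]
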