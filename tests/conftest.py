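import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from iccmap.icc import make_gm_mask
from iccmap.synthetic import SyntheticCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small mid-noise cohort shared by read-only tests: 8 subjects,
    12^3 grid, 60 retained volumes, 4 networks."""
    spec = SyntheticCohortSpec(
        n_subjects=8,
        grid_shape=(12, 12, 12),
        n_timepoints=60,
        noise_sd=0.5,
        rng_seed=42,
    )
    bold, motion, gm_prob, templates, cov, truth = generate_cohort(spec)
    mask = make_gm_mask(gm_prob, spec.affine)
    return {
        "spec": spec,
        "bold": bold,
        "motion": motion,
        "gm_prob": gm_prob,
        "templates": templates,
        "covariates": cov,
        "truth": truth,
        "mask": mask,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
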