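"""Shared fixtures: toy gaze trials and reusable simulated twin datasets."""

import numpy as np
import pytest

import twinlook as tl

SAMPLE_MS = 1000.0 / 120.0


@pytest.fixture(scope="session")
def scene():
    return tl.default_scenes()[0]


@pytest.fixture
def make_trial(scene):
    """Build a GazeTrial from a per-sample AOI label sequence.

    Labels: an AOI name places the sample at that AOI's centre; "out"
    places it on-screen outside every AOI; "invalid" marks it missing.
    """

    def _build(labels, infant_id="i1", trial_index=1):
        n = len(labels)
        t = np.arange(n) * SAMPLE_MS
        x = np.empty(n)
        y = np.empty(n)
        valid = np.ones(n, dtype=bool)
        for i, lab in enumerate(labels):
            if lab == "invalid":
                valid[i] = False
                x[i] = y[i] = np.nan
            elif lab == "out":
                x[i], y[i] = scene.centre()  # centre is outside all AOIs
            else:
                x[i], y[i] = scene.aoi_centre(lab)
        return tl.GazeTrial(infant_id=infant_id, trial_index=trial_index,
                            stimulus_id=scene.stimulus_id, t_ms=t, x_px=x,
                            y_px=y, valid=valid, scene=scene)

    return _build


@pytest.fixture(scope="session")
def ae_dataset():
    """AE twin data with heritability 0.46, complete pairs, no covariates."""
    spec = tl.GenerativeSpec.univariate(a2=0.46)
    return tl.simulate_twin_phenotypes(spec, 1500, 1500, 0.0, seed=707)


@pytest.fixture(scope="session")
def small_mixed_dataset():
    """Modest ACE dataset with incomplete pairs and covariate effects."""
    spec = tl.GenerativeSpec(
        n_traits=1, path_A=((np.sqrt(0.3),),), path_C=((np.sqrt(0.2),),),
        path_E=((np.sqrt(0.5),),), trait_means=(0.4,),
        beta_age=(0.05,), beta_sex=(-0.1,), standardized=False)
    return tl.simulate_twin_phenotypes(spec, 160, 140, 0.1, seed=21)
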