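import numpy as np
import pytest

import urinmr as u

# coarser grid than the production default keeps the suite quick while
# preserving >=5 points per linewidth
FAST_STEP = 0.002


@pytest.fixture(scope="session")
def library():
    return u.build_default_library(seed=1)


def make_two_group_cohort(library, seed=3, n_subjects=6, periods=("T1", "T2"),
                          effects=None, noise=None, step=FAST_STEP,
                          groups=("NC", "TAA")):
    design = u.CohortDesign(groups=groups, n_subjects=n_subjects,
                            periods=periods)
    if noise is None:
        noise = u.NoiseModel(seed=seed)
    if effects is None:
        effects = []
    return u.generate_cohort(design, library, effects, noise, ppm_step=step)


@pytest.fixture(scope="session")
def planted_cohort(library):
    """NC vs TAA, citrate halved and glutamate raised in TAA."""
    effects = [
        u.EffectSpec("citrate", ("TAA",), {p: 0.5 for p in u.PERIODS}),
        u.EffectSpec("glutamate", ("TAA",), {p: 2.0 for p in u.PERIODS}),
    ]
    X, meta, truth = make_two_group_cohort(library, effects=effects)
    norm, scaled = u.standard_preprocess(X)
    cv = u.ClassVector.from_labels(
        scaled.sample_ids, meta.set_index("sample_id").loc[
            scaled.sample_ids, "group"], positive_label="TAA")
    return {"X": X, "meta": meta, "truth": truth, "norm": norm,
            "scaled": scaled, "cv": cv}


@pytest.fixture(scope="session")
def zero_noise_cohort(library):
    """Deterministic cohort: no noise, no dilution, no biological spread."""
    noise = u.NoiseModel(additive_sd=0, baseline_amplitude=0,
                         shift_jitter_sd=0, dilution_log_sd=0,
                         concentration_rsd=0, seed=0)
    effects = [u.EffectSpec("citrate", ("TAA",), {p: 2.0 for p in u.PERIODS})]
    return make_two_group_cohort(library, effects=effects, noise=noise,
                                 n_subjects=3, periods=("T1",))
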