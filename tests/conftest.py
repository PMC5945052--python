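import numpy as np
import pytest

import steatoscope as st


@pytest.fixture(scope="session")
def small_slide():
    """A 256x256 synthetic slide with fat, confusers and foamy foci."""
    params = st.GeneratorParams(dims=(256, 256), target_percent=12.0,
                                micro_focus_count=2, n_portal_triads=1,
                                n_central_veins=1, n_sinusoid_patches=2)
    return st.generate_slide(params, seed=42, slide_id="fixture-small")


@pytest.fixture(scope="session")
def small_analysis(small_slide):
    return st.analyze_slide(small_slide.image, slide_id=small_slide.slide_id,
                            annotations=small_slide.truth_annotations)


@pytest.fixture(scope="session")
def macro_bank20():
    return st.macro_bank()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
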