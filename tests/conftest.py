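import numpy as np
import pytest

from pazquant import ExperimentConfig, synth


@pytest.fixture
def cfg():
    return ExperimentConfig()


@pytest.fixture(scope="session")
def nmj_scene_clean():
    """Default-condition NMJ volume (K=20 units, Brp in half of them,
    Pak apposed everywhere), noise-free."""
    p = synth.SynthNmjParams(poisson_scale=0, read_noise_sd=0, seed=5)
    vol, truth = synth.generate_nmj_volume(p)
    return p, vol, truth


@pytest.fixture(scope="session")
def sted_sideview_scene_clean():
    """One noise-free side-view synapse with a +90.8 nm protein offset."""
    p = synth.SynthStedParams(
        n_sideview=1,
        n_enface=0,
        field_px=128,
        protein_offset_nm=90.8,
        angles_rad=(np.pi / 6,),
        poisson_scale=0,
        read_noise_sd=0,
        seed=1,
    )
    field, truth = synth.generate_sted_field(p)
    return p, field, truth


def match_units(labels, true_labels):
    """Hungarian matching of recovered to true unit labels by centroid
    distance; returns list of (recovered_label, true_label)."""
    from scipy.optimize import linear_sum_assignment
    from scipy.spatial.distance import cdist
    from skimage import measure

    rp = measure.regionprops(labels)
    tp = measure.regionprops(true_labels)
    rc = np.array([x.centroid for x in rp])
    tc = np.array([x.centroid for x in tp])
    ri, ti = linear_sum_assignment(cdist(rc, tc))
    return [(rp[a].label, tp[b].label) for a, b in zip(ri, ti)]
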