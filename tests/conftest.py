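import numpy as np
import pytest

import fibriq as fq


@pytest.fixture(scope="session")
def rendered_control():
    """Five well-separated control-preset chains with ground truth."""
    lengths = fq.sample_chain_lengths(*fq.CONTROL_LENGTH, 5, seed=7)
    cfg = fq.ChainRenderConfig(rng_seed=5)
    img, truth = fq.render_chain_image(fq.CONTROL_PERIODICITY, lengths, cfg)
    return img, truth, cfg


@pytest.fixture(scope="session")
def tissue_section():
    """A banded synthetic section at 31% stain coverage."""
    img, truth = fq.render_tissue_section(stain_fraction=31.0, seed=4)
    return img, truth


def match_detections(detected, truth_beads, tol_nm):
    """Count truth beads with a detection within tol_nm (greedy 1-1)."""
    det = detected[["x_nm", "y_nm"]].to_numpy(float)
    tru = truth_beads[["x_nm", "y_nm"]].to_numpy(float)
    used = np.zeros(len(det), bool)
    hits = 0
    for t in tru:
        if len(det) == 0:
            break
        d = np.hypot(det[:, 0] - t[0], det[:, 1] - t[1])
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_nm:
            used[j] = True
            hits += 1
    return hits
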