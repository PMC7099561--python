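import numpy as np
import pytest

from fazseg.datatypes import SubjectSpec
from fazseg.synthetic import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Six synthetic subjects (2 high myopes) at 128 x 128: 54 images."""
    return generate_cohort(6, 2, seed=42)


@pytest.fixture()
def circle_spec():
    """A subject whose FAZ is an unperturbed circle of radius 0.3 mm."""
    return SubjectSpec(
        subject_id="C1",
        myopia_class="low",
        faz_center=(0.5, 0.5),
        faz_radius_mm=0.3,
        boundary_harmonics=[],
        vessel_density=0.7,
        rng_seed=123,
    )


# ---------------------------------------------------------------------
# independent brute-force topology oracles (pure-python flood fill)


def flood_components(mask, connectivity=8):
    """Label foreground components by BFS; returns (n_components, labels)."""
    m = np.asarray(mask) > 0
    h, w = m.shape
    labels = np.zeros((h, w), dtype=int)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    n = 0
    for si in range(h):
        for sj in range(w):
            if m[si, sj] and labels[si, sj] == 0:
                n += 1
                stack = [(si, sj)]
                labels[si, sj] = n
                while stack:
                    i, j = stack.pop()
                    for di, dj in nbrs:
                        ni, nj = i + di, j + dj
                        if 0 <= ni < h and 0 <= nj < w and m[ni, nj] and labels[ni, nj] == 0:
                            labels[ni, nj] = n
                            stack.append((ni, nj))
    return n, labels


def count_holes(mask):
    """Interior background regions (4-connected, not touching the border)."""
    m = np.asarray(mask) > 0
    n_bg, labels = flood_components(~m, connectivity=4)
    border = set(labels[0, :]) | set(labels[-1, :]) | set(labels[:, 0]) | set(labels[:, -1])
    border.discard(0)
    return n_bg - len(border)


def fill_holes_oracle(mask):
    """Foreground plus every interior background region."""
    m = np.asarray(mask) > 0
    _, labels = flood_components(~m, connectivity=4)
    border = set(labels[0, :]) | set(labels[-1, :]) | set(labels[:, 0]) | set(labels[:, -1])
    border.discard(0)
    filled = m.copy()
    filled[(labels > 0) & ~np.isin(labels, sorted(border))] = True
    return filled
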