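import numpy as np
import pytest

from calcnet import CTStack, PhantomParams, generate_stack, segment_stack


@pytest.fixture(scope="session")
def stone_stack():
    """A mid-size stone phantom with a rim, fixed seed."""
    params = PhantomParams("stone", max_diameter_mm=6.0, peak_hu=700.0,
                           rim_present=True, seed=11)
    return generate_stack(params, id="stone11")


@pytest.fixture(scope="session")
def phlebolith_stack():
    """A phlebolith phantom with central lucency and comet tail."""
    params = PhantomParams("phlebolith", max_diameter_mm=6.0, peak_hu=650.0,
                           lucency_present=True, lucency_hu=100.0,
                           comet_present=True, seed=12)
    return generate_stack(params, id="phleb12")


@pytest.fixture(scope="session")
def stone_mask(stone_stack):
    return segment_stack(stone_stack)


@pytest.fixture(scope="session")
def phlebolith_mask(phlebolith_stack):
    return segment_stack(phlebolith_stack)


@pytest.fixture
def uniform_stack():
    def make(value, shape=(20, 20, 20), spacing=(1.0, 1.0, 1.0)):
        return CTStack(np.full(shape, float(value), dtype=np.float32),
                       spacing, "unknown", f"uniform{value}")
    return make


def flood_fill_holes(mask: np.ndarray) -> np.ndarray:
    """Independent hole-filling oracle: 6-connected BFS over the background
    from the grid border; any background voxel the BFS cannot reach is an
    interior cavity and gets filled."""
    from collections import deque

    bg = ~mask
    reached = np.zeros_like(bg)
    q = deque()
    nx, ny, nz = mask.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if (x in (0, nx - 1) or y in (0, ny - 1) or z in (0, nz - 1)) \
                        and bg[x, y, z] and not reached[x, y, z]:
                    reached[x, y, z] = True
                    q.append((x, y, z))
    while q:
        x, y, z = q.popleft()
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            u, v, w = x + dx, y + dy, z + dz
            if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz \
                    and bg[u, v, w] and not reached[u, v, w]:
                reached[u, v, w] = True
                q.append((u, v, w))
    return mask | (bg & ~reached)
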