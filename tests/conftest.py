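import numpy as np
import pytest

from resistscape import GridSpec, RasterGrid, ResistanceSurface


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_surface(values: np.ndarray, cell_size: float = 1.0,
                 mask: np.ndarray | None = None) -> ResistanceSurface:
    """A resistance surface on a unit grid from a raw value array."""
    values = np.asarray(values, dtype=float)
    nr, nc = values.shape
    spec = GridSpec(nr, nc, 0.0, nr * cell_size, cell_size)
    m = np.zeros_like(values, dtype=bool) if mask is None else mask
    return ResistanceSurface(RasterGrid(values, spec, mask=m))


def random_surface(rng, n: int, lo: float = 1.0, hi: float = 3.0,
                   cell_size: float = 1.0) -> ResistanceSurface:
    return make_surface(rng.uniform(lo, hi, size=(n, n)), cell_size=cell_size)


def laplacian_pseudoinverse(L: np.ndarray) -> np.ndarray:
    """Deflated inverse of a connected graph Laplacian: (L + J/n)^-1 - J/n."""
    n = L.shape[0]
    J = np.ones((n, n)) / n
    return np.linalg.inv(L + J) - J
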