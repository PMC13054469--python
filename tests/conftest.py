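import numpy as np
import pytest

import needletrack as nt


@pytest.fixture(scope="session")
def layout():
    """The default 256-element grid-snapped Fermat spiral."""
    return nt.default_layout()


@pytest.fixture(scope="session")
def layout13(layout):
    """The 13 outermost elements (the fast-tracking subset)."""
    return nt.sparsify(layout, 13)


@pytest.fixture(scope="session")
def chirp_spec():
    return nt.ExcitationSpec.chirp()


@pytest.fixture(scope="session")
def template(chirp_spec):
    return nt.waveform(chirp_spec)


@pytest.fixture(scope="session")
def fs(chirp_spec):
    return chirp_spec.sample_rate


def grid_search_oracle(transmitters, ranges, center, half=5.0, step=0.05):
    """Exhaustive minimiser of Σ(‖p−s_i‖−d_i)² over a cube grid around ``center``.

    Brute force, evaluated slice by slice in z to bound memory; independent of
    the package's solver.
    """
    ax = np.arange(-half, half + step / 2.0, step)
    best_ssr, best_p = np.inf, None
    X, Y = np.meshgrid(center[0] + ax, center[1] + ax, indexing="ij")
    for dz in ax:
        z = center[2] + dz
        ssr = np.zeros_like(X)
        for si, di in zip(transmitters, ranges):
            r = np.sqrt((X - si[0]) ** 2 + (Y - si[1]) ** 2 + (z - si[2]) ** 2) - di
            ssr += r * r
        i = np.unravel_index(np.argmin(ssr), ssr.shape)
        if ssr[i] < best_ssr:
            best_ssr, best_p = float(ssr[i]), np.array([X[i], Y[i], z])
    return best_p, best_ssr
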