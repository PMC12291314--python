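import numpy as np
import pytest

from ojiptools.io import FluorescenceTransient
from ojiptools.jip import OJIPLandmarks


def trace_through(knots: dict[float, float], *, n_extra: int = 100,
                  variety: str = "V1", treatment: str = "0h",
                  replicate: int = 1) -> FluorescenceTransient:
    """Build a trace that is piecewise log-linear through the given (t, F) knots.

    Sample times are the knots plus a log-spaced fill, so log-time linear
    interpolation at any knot time returns the knot value exactly.
    """
    kt = np.array(sorted(knots))
    kf = np.array([knots[t] for t in kt])
    times = np.unique(np.concatenate((np.geomspace(kt[0], kt[-1], n_extra), kt)))
    f = np.interp(np.log10(times), np.log10(kt), kf)
    return FluorescenceTransient(times=times, fluorescence=f, variety=variety,
                                 treatment=treatment, replicate=replicate)


@pytest.fixture
def worked_trace() -> FluorescenceTransient:
    """The worked example: passes through the canonical landmark values."""
    return trace_through(
        {20.0: 500.0, 150.0: 650.0, 300.0: 900.0, 2000.0: 1500.0,
         30000.0: 2200.0, 500000.0: 2500.0}
    )


@pytest.fixture
def worked_landmarks() -> OJIPLandmarks:
    return OJIPLandmarks(F0=500.0, FL=650.0, FK=900.0, FJ=1500.0, FI=2200.0,
                         Fm=2500.0, t_Fm=500000.0, t0=20.0)


def random_landmarks(rng: np.random.Generator) -> OJIPLandmarks:
    """A random strictly ordered landmark tuple 0 < F0 < FL < FK < FJ < FI < Fm."""
    f0 = rng.uniform(100.0, 1000.0)
    fm = f0 * rng.uniform(2.5, 6.0)
    cuts = np.sort(rng.uniform(0.02, 0.98, size=4))
    fl, fk, fj, fi = f0 + cuts * (fm - f0)
    return OJIPLandmarks(F0=f0, FL=fl, FK=fk, FJ=fj, FI=fi, Fm=fm,
                         t_Fm=3e5, t0=20.0)
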