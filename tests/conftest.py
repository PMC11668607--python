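import numpy as np
import pandas as pd
import pytest

from gediagb import FieldSpec, OrbitSpec, generate_field, sample_footprints, simulate_tracks


@pytest.fixture(scope="session")
def small_fields():
    """Three autocorrelated metric fields on a 12 km square at 60 m cells."""
    spec = FieldSpec(
        extent=(0.0, 0.0, 12000.0, 12000.0),
        means={"pai": 3.0, "rg": 40.0, "cover": 0.55},
        sills={"pai": 0.5, "rg": 90.0, "cover": 0.02},
        range_m=3000.0,
        nugget=0.01,
        seed=42,
    )
    return spec, generate_field(spec, 60.0)


@pytest.fixture(scope="session")
def small_scene(small_fields):
    """Clean (uncontaminated, noise-free) footprints over the small fields."""
    spec, fields = small_fields
    orbit = OrbitSpec(overpass_azimuths=(0.0, 60.0, 120.0), seed=1)
    tracks = simulate_tracks(orbit, spec.extent)
    table = sample_footprints(tracks, fields, noise_std=0.0, seed=7)
    return spec, fields, table


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_table():
    """20 footprints on one beam, all passing the quality screen."""
    n = 20
    return pd.DataFrame(
        {
            "shot_id": np.arange(n),
            "beam": "BEAM00",
            "track": "T0",
            "x": np.linspace(0, 1140, n),
            "y": 0.0,
            "pai": np.linspace(2, 4, n),
            "quality_flag": 1,
            "degrade_flag": 0,
            "sensitivity": 0.95,
        }
    )


def brute_force_idw(query, points, values, power=2.0, n_neighbors=0):
    """All-pairs IDW oracle, independent of the package implementation."""
    query = np.atleast_2d(query)
    out = np.empty(len(query))
    for i, q in enumerate(query):
        d = np.sqrt(((points - q) ** 2).sum(axis=1))
        if d.min() < 1e-9:
            out[i] = values[np.argmin(d)]
            continue
        order = np.argsort(d, kind="stable")
        if n_neighbors:
            order = order[:n_neighbors]
        w = d[order] ** (-power)
        out[i] = (w * values[order]).sum() / w.sum()
    return out
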