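import numpy as np
import pytest

from pollenmat import (
    CalibrationEntry,
    PFTVector,
    PollenSample,
    RasterGrid,
    WorldConfig,
    generate_world,
    synthetic_dictionary,
)


@pytest.fixture(scope="session")
def pft_dict():
    return synthetic_dictionary()


@pytest.fixture(scope="session")
def small_world():
    """A compact seeded world shared by read-only tests."""
    cfg = WorldConfig(
        n_modern=80,
        n_fossil_sites=6,
        samples_per_core=30,
        resolution_m=4000.0,
        seed=11,
    )
    return generate_world(cfg)


def make_entry(sample_id, pft_scores, cover, sigma=500.0, context="moss", ap=0.0):
    """Calibration entry over a 2-PFT toy space unless scores say otherwise."""
    scores = np.asarray(pft_scores, dtype=float)
    pfts = tuple(f"pft{i}" for i in range(len(scores)))
    return CalibrationEntry(
        sample_id=sample_id,
        pft_vector=PFTVector(pfts, scores),
        cover=cover,
        sigma=sigma,
        context=context,
        ap=ap,
    )


@pytest.fixture
def toy_pool():
    """Ten calibration entries on a 3-PFT simplex with covers tied to
    composition, small enough for exhaustive oracles."""
    rng = np.random.default_rng(42)
    entries = []
    for i in range(10):
        a = rng.dirichlet([2.0, 2.0, 2.0])
        cover = 100.0 * a[0]  # cover is a deterministic function of the vector
        entries.append(make_entry(f"cal{i:02d}", a, cover))
    return entries


def uniform_raster(value, n=21, res=0.01, lon0=10.0, lat0=45.0):
    """Square raster of a constant value with cell-center origin near
    (lon0, lat0); the sample point at the exact center is on a cell center."""
    vals = np.full((n, n), float(value))
    return RasterGrid(vals, lon_min=lon0 - res * (n // 2), lat_max=lat0 + res * (n // 2), res=res)


def make_sample(sid="s", lon=10.0, lat=45.0, context="moss", pct=None, count=300.0, **kw):
    pct = pct if pct is not None else {"Pinus": 50.0, "Poaceae": 50.0}
    defaults = dict(elevation=500.0, age=0.0)
    defaults.update(kw)
    return PollenSample(
        id=sid, lon=lon, lat=lat, context=context, percentages=pct, count_total=count, **defaults
    )


@pytest.fixture
def fixture12():
    """12 modern samples with one designed violation per quality rule plus
    clean samples; rasters and calibration entries arranged so the surviving
    set is known exactly."""
    from pollenmat.synthetic import CLASS_FOREST, CLASS_OPEN

    n = 12
    lons = [10.0 + 0.01 * i for i in range(n)]

    def _grid(values):
        return RasterGrid(np.asarray(values, dtype=float), lon_min=10.0, lat_max=45.0, res=0.01)

    dem = _grid([[500.0] * n])
    landclass = _grid([[CLASS_OPEN] * n])
    height = _grid([[5.0] * n])

    def sample(i, **kw):
        kw.setdefault("lon", lons[i])
        kw.setdefault("lat", 45.0)
        kw.setdefault("elevation", 500.0)
        kw.setdefault("location_error", 50.0)
        return make_sample(sid=f"s{i:02d}", **kw)

    samples = [
        sample(0, context="moss"),                                   # clean
        sample(1, lon=lons[0], context="moss"),                      # duplicate of s00
        sample(2, location_error=150.0),                             # location error
        sample(3, elevation=800.0),                                  # DEM says 500 -> diff 300
        sample(4, context="riverine"),                               # excluded context
        sample(5, count=100.0),                                      # count not > 100
        sample(6, context="treeless"),                               # open context, forest class
        sample(7, context="dense_forest"),                           # forest context, open class
        sample(8, context="moss"),                                   # AP 85, cover 20
        sample(9, context="tundra"),                                 # AP 85, cover 20 but exempt
        sample(10, context="soil", location_error=None),             # missing error -> retained
        sample(11, context="lake", lake_area_ha=100.0),              # clean lake
    ]
    # duplicate needs identical coordinates AND assemblage (the default pct)
    landclass.values[0, 6] = CLASS_FOREST
    covers = {0: 50.0, 1: 50.0, 2: 50.0, 3: 50.0, 4: 50.0, 5: 50.0,
              6: 30.0, 7: 5.0, 8: 20.0, 9: 20.0, 10: 50.0, 11: 50.0}
    aps = {8: 85.0, 9: 85.0}
    height.values[0, 7] = 0.0
    entries = {
        s.id: make_entry(s.id, [1.0, 0.0], covers[i], context=s.context, ap=aps.get(i, 40.0))
        for i, s in enumerate(samples)
    }
    return samples, entries, dem, landclass, height
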