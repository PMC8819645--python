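"""Shared fixtures: small fix tables and one cached eagle-like fit."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import flightmodes as fm
from flightmodes.cluster import fit_k_range
from flightmodes.selection import bootstrap_silhouette


def make_fixes(
    times,
    animal="a1",
    x=None,
    y=None,
    z=None,
    kph=None,
    hdop=1.0,
    vdop=1.0,
    fix_dim="3D",
    ground_elev=0.0,
):
    """Build a canonical fix table from per-fix values (scalars broadcast)."""
    n = len(times)

    def col(v, default):
        if v is None:
            v = default
        return np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy()

    return pd.DataFrame(
        {
            "animal_id": animal,
            "t": pd.to_datetime("2021-06-01", utc=True)
            + pd.to_timedelta(np.asarray(times, dtype=float), unit="s"),
            "x": col(x, np.arange(n, dtype=float) * 10.0),
            "y": col(y, 0.0),
            "z": col(z, 100.0),
            "kph": col(kph, 10.0),
            "hdop": col(hdop, 1.0),
            "vdop": col(vdop, 1.0),
            "fix_dim": np.broadcast_to(np.asarray(fix_dim, dtype=object), (n,)).copy(),
            "ground_elev": col(ground_elev, 0.0),
        }
    )


@pytest.fixture
def fixes_factory():
    return make_fixes


@pytest.fixture(scope="session")
def eagle_run():
    """One simulated deployment with fits at K=3..5 and silhouette bootstraps.

    Cached per session: several end-to-end checks (regime recovery,
    K-selection behavior, centroid ordering) share this single run.
    """
    seed = 1
    cfg = fm.default_eagle_config(n_fixes=20000, seed=seed)
    fixes, truth = fm.simulate_tracks(cfg)
    model = fm.FlightStateModel(fixes, fm.RunConfig(seed=seed))
    model.prepare()
    X = model.X.to_numpy()
    models = fit_k_range(X, (3, 4, 5), n_starts=10, seed=seed, scaling=model.scaling)
    boots = bootstrap_silhouette(
        X,
        {k: m.labels for k, m in models.items()},
        b=100,
        n_boot=2000,
        seed=seed,
    )
    return {
        "config": cfg,
        "fixes": fixes,
        "truth": truth,
        "model": model,
        "models": models,
        "bootstraps": boots,
        "seed": seed,
    }
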