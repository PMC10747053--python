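"""Great-circle geography and the Mantel permutation test.

Isolation by distance predicts a positive correlation between genetic and
geographic distance, so the Mantel test defaults to the one-sided upper-tail
alternative with the +1 permutation p-value convention:
p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from sojapop.errors import SojapopError

EARTH_RADIUS_KM = 6371.0088


def haversine_matrix(coords: pd.DataFrame) -> DistanceMatrix:
    """Great-circle distance matrix (km) from a location/latitude/longitude table.

    ``coords`` needs columns ``location``, ``latitude``, ``longitude`` in
    decimal degrees.
    """
    if len(coords) < 2:
        raise SojapopError("haversine_matrix needs >= 2 locations")
    lat = coords["latitude"].to_numpy(float)
    lon = coords["longitude"].to_numpy(float)
    names = coords["location"].astype(str).tolist()
    bad = ~(np.isfinite(lat) & np.isfinite(lon)
            & (np.abs(lat) <= 90.0) & (np.abs(lon) <= 180.0))
    if bad.any():
        raise SojapopError(f"invalid coordinates for location {names[int(np.argmax(bad))]!r}")
    la, lo = np.radians(lat), np.radians(lon)
    dlat = la[:, None] - la[None, :]
    dlon = lo[:, None] - lo[None, :]
    h = np.sin(dlat / 2.0) ** 2 + np.cos(la)[:, None] * np.cos(la)[None, :] * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=names)


def mantel_test(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 9999,
                seed: int = 0):
    """Mantel correlation between two labelled distance matrices.

    Returns ``(r, p)``: the Pearson correlation over the strict lower
    triangle and the one-sided (upper-tail) permutation p-value obtained by
    jointly permuting rows and columns of ``d2``.  Deterministic given
    ``seed``; p lies in [1/(1+n_perm), 1].
    """
    if list(d1.ids) != list(d2.ids):
        raise SojapopError("distance matrices must share labels and order")
    n = len(d1.ids)
    if n < 4:
        raise SojapopError("mantel_test needs >= 4 labels")
    a, b = d1.data, d2.data
    tri = np.tril_indices(n, k=-1)
    x = a[tri]
    xc = x - x.mean()
    sx = np.sqrt((xc ** 2).sum())
    y0 = b[tri]
    if sx == 0.0 or np.std(y0) == 0.0:
        raise SojapopError("constant distance matrix: Mantel r undefined")

    def corr(y):
        yc = y - y.mean()
        return float((xc * yc).sum() / (sx * np.sqrt((yc ** 2).sum())))

    r_obs = corr(y0)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)]
        if corr(bp[tri]) >= r_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return r_obs, p
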