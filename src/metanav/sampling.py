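"""Landmark-sampling analytics: accessibility, centrality and sampling PCA.

When navigators choose their own landmarks, where they put them can be
summarised by (1) the mean distance from every grid state to its
nearest landmark (accessibility), (2) the mean distance of the chosen
landmarks from the grid centre (centrality; chance level is exactly 4
grid steps for uniform placement on the 8x8 interior), and (3) mean
memory-probe error.  Individual differences in sampling strategy are
captured by a PCA over the subjects x 64-locations count matrix.

Distances are Manhattan grid steps by default — the only metric under
which the uniform-placement chance level is exactly 4 — with Euclidean
available behind a flag.  Metrics treat resampled cells as a single
landmark unless count weighting is requested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from metanav import gridworld as gw

CENTER = ((gw.INTERIOR_SIZE - 1) / 2.0, (gw.INTERIOR_SIZE - 1) / 2.0)


def _distance(a, b, metric: str) -> float:
    dr, dc = a[0] - b[0], a[1] - b[1]
    if metric == "manhattan":
        return abs(dr) + abs(dc)
    if metric == "euclidean":
        return float(np.hypot(dr, dc))
    raise ValueError(f"unknown metric {metric!r}")


def _unique_cells(landmark_cells, weights=None):
    cells = [tuple(c) for c in landmark_cells]
    if not cells:
        raise ValueError("empty landmark set")
    if weights is None:
        uniq = sorted(set(cells))
        return uniq, np.ones(len(uniq))
    return cells, np.asarray(weights, dtype=float)


def mean_nearest_landmark_distance(
    landmark_cells, metric: str = "manhattan"
) -> float:
    """Mean over all 64 interior cells of the distance to the nearest landmark."""
    cells, _ = _unique_cells(landmark_cells)
    size = gw.INTERIOR_SIZE
    total = 0.0
    for r in range(size):
        for c in range(size):
            total += min(_distance((r, c), lm, metric) for lm in cells)
    return total / size**2


def mean_center_distance(
    landmark_cells, metric: str = "manhattan", weights=None
) -> float:
    """Mean distance of the landmarks from the interior centre (3.5, 3.5).

    With ``weights`` (sampling counts) the mean is count-weighted;
    the default counts each sampled cell once.
    """
    cells, w = _unique_cells(landmark_cells, weights)
    d = np.array([_distance(cell, CENTER, metric) for cell in cells])
    return float(np.average(d, weights=w))


def chance_center_distance(
    interior_size: int = gw.INTERIOR_SIZE, metric: str = "manhattan"
) -> float:
    """Exact uniform-placement expectation of the centre distance.

    Enumerates all interior cells; equals 4 for the 8x8 interior under
    the Manhattan metric.
    """
    centre = ((interior_size - 1) / 2.0,) * 2
    total = sum(
        _distance((r, c), centre, metric)
        for r in range(interior_size)
        for c in range(interior_size)
    )
    return total / interior_size**2


def probe_error_summary(probe_records: pd.DataFrame, metric: str = "manhattan") -> float:
    """Mean distance between probe responses and true locations.

    ``probe_records`` needs columns ``resp_r, resp_c, true_r, true_c``.
    Error 0 corresponds to the maximum 30-point probe score band.
    """
    if len(probe_records) == 0:
        raise ValueError("no probe records")
    errs = [
        _distance((row.resp_r, row.resp_c), (row.true_r, row.true_c), metric)
        for row in probe_records.itertuples()
    ]
    return float(np.mean(errs))


def sampling_pca(matrix: np.ndarray, n_components: int | None = None):
    """PCA of the subjects x 64-locations sampling-count matrix.

    Columns are mean-centred only (no scaling).  Returns a dict with
    ``components`` (components x 64), ``loadings_maps`` (components x
    8 x 8, row-major reshape for display), ``scores`` (subjects x
    components) and ``explained_variance_ratio``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != gw.INTERIOR_SIZE**2:
        raise ValueError("matrix must be subjects x 64 locations")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("degenerate sampling matrix: no between-subject variance")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    comps = pca.components_
    return {
        "components": comps,
        "loadings_maps": comps.reshape(len(comps), gw.INTERIOR_SIZE, gw.INTERIOR_SIZE),
        "scores": scores,
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }


def landmark_set_metrics(landmark_cells, metric: str = "manhattan") -> dict:
    """Accessibility and centrality of one landmark set."""
    return {
        "mean_nearest_landmark_distance": mean_nearest_landmark_distance(
            landmark_cells, metric
        ),
        "mean_center_distance": mean_center_distance(landmark_cells, metric),
    }
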