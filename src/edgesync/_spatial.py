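"""Node-permutation nulls: uniform label shuffles and geometry-preserving spins."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation


def spatial_permutations(
    n_nodes: int,
    n_perm: int,
    rng: np.random.Generator,
    centroids: np.ndarray | None = None,
) -> np.ndarray:
    """(n_perm, n_nodes) array of node-index permutations.

    With ``centroids`` (unit-norm rows) each permutation is a random 3-D
    rotation of the centroid cloud followed by nearest-centroid
    reassignment — the "spin" null that preserves the spatial
    autocorrelation structure of a cortical map.  Without centroids,
    uniform random permutations are used.  Spin reassignments are not
    guaranteed to be bijections; duplicates are allowed, as is standard.
    """
    if centroids is None:
        return np.vstack([rng.permutation(n_nodes) for _ in range(n_perm)])
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape != (n_nodes, 3):
        raise ValueError("centroids must have shape (n_nodes, 3)")
    norms = np.linalg.norm(centroids, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("centroids must be unit-norm (on the sphere)")
    tree = cKDTree(centroids)
    perms = np.empty((n_perm, n_nodes), dtype=int)
    for k in range(n_perm):
        rot = Rotation.random(random_state=rng).as_matrix()
        rotated = centroids @ rot.T
        _, idx = tree.query(rotated)
        perms[k] = idx
    return perms
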