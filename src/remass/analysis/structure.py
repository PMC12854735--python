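"""Optimal-superposition RMSD (Kabsch) and all-against-all distributions."""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch_rmsd", "rmsd_distribution"]


def kabsch_rmsd(a, b) -> float:
    """Minimum RMSD between two conformations after optimal superposition.

    Centroids are removed, the optimal rotation is found by SVD of the
    covariance matrix, and a proper rotation (det = +1) is enforced.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.shape[0] < 3:
        raise ValueError("need two equal sets of at least 3 atoms")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    cov = ac.T @ bc
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    # explicit residual (rather than the e0 - 2*trace shortcut) avoids
    # catastrophic cancellation for near-identical structures
    resid = ac @ rot.T - bc
    return float(np.sqrt(np.sum(resid ** 2) / a.shape[0]))


def rmsd_distribution(frames, stride: int = 1, n_bins: int = 50):
    """All-against-all RMSD over frames taken at `stride`.

    Returns (pairwise rmsd array, histogram bin centres, density, mean).
    """
    sel = list(frames)[::stride]
    n = len(sel)
    if n < 2:
        raise ValueError("need at least two frames")
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            vals.append(kabsch_rmsd(sel[i], sel[j]))
    vals = np.array(vals)
    hist, edges = np.histogram(vals, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return vals, centers, hist, float(vals.mean())
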