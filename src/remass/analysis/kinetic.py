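"""Kinetic-energy diagnostics: Maxwell-Boltzmann reference and temperature.

For a system with n_dof quadratic momentum degrees of freedom the total
kinetic energy is gamma-distributed with shape n_dof/2 and scale Rc*T; its
mean is (n_dof/2) Rc T.  The instantaneous temperature follows from
equipartition, T = 2 E_k / (n_dof Rc).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .. import constants as C

__all__ = ["MBDReference", "mbd_reference", "mbd_rmsd", "instantaneous_temperature"]


@dataclass(frozen=True)
class MBDReference:
    n_dof: int
    T: float

    @property
    def shape(self) -> float:
        return self.n_dof / 2.0

    @property
    def scale(self) -> float:
        return C.KB * self.T

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    def pdf(self, e):
        return stats.gamma.pdf(e, a=self.shape, scale=self.scale)

    def rvs(self, n: int, rng: np.random.Generator):
        return stats.gamma.rvs(a=self.shape, scale=self.scale, size=n,
                               random_state=rng)

    def ks_statistic(self, samples) -> float:
        return float(stats.kstest(samples, "gamma",
                                  args=(self.shape, 0.0, self.scale)).statistic)


def mbd_reference(n_dof: int, T: float) -> MBDReference:
    if n_dof < 1:
        raise ValueError("n_dof must be >= 1")
    return MBDReference(n_dof=n_dof, T=T)


def mbd_rmsd(samples, reference: MBDReference, n_bins: int = 200) -> float:
    """RMSD between the sample histogram density and the reference pdf.

    The histogram spans [0, max(sample)] with n_bins equal bins; the
    reference is evaluated at the bin centres.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty sample")
    edges = np.linspace(0.0, samples.max(), n_bins + 1)
    hist, _ = np.histogram(samples, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(np.sqrt(np.mean((hist - reference.pdf(centers)) ** 2)))


def instantaneous_temperature(velocities, masses, n_dof: int) -> float:
    """T = 2 E_k / (n_dof Rc) with E_k = 0.5 sum m v^2 (v in Å/fs)."""
    if n_dof <= 0:
        raise ValueError("n_dof must be positive")
    v = np.asarray(velocities, dtype=float)
    m = np.asarray(masses, dtype=float)
    ek = 0.5 * np.sum(m[:, None] * v ** 2) / C.KE_CONV
    return float(2.0 * ek / (n_dof * C.KB))
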