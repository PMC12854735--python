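"""Synthetic-data generators with known ground truth.

Every analysis probe can be exercised without running any dynamics: angles
from a circular two-well density with an analytic log-density, kinetic
energies from the exact Maxwell-Boltzmann gamma form, relaxation curves from
a prescribed biexponential with binomial counting noise, and ideal-gas
configurations for the radial distribution function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import constants as C
from .analysis.equilibration import biexponential

__all__ = ["TwoWellDensity", "sample_angles", "sample_kinetic",
           "sample_relaxation", "place_ideal_gas"]


@dataclass(frozen=True)
class TwoWellDensity:
    """Mixture of two von Mises wells on the circle (angles in degrees).

    centers/kappas/weights define p(theta) = sum_k w_k VM(theta; mu_k, kappa_k);
    `log_density` is exposed for inverse-Boltzmann checks, and
    `free_energy(T)` gives the generating PMF -Rc T ln p, min-shifted.
    """

    centers: tuple[float, float] = (-70.0, 60.0)
    kappas: tuple[float, float] = (4.0, 4.0)
    weights: tuple[float, float] = (0.7, 0.3)

    def density(self, theta_deg):
        th = np.radians(np.asarray(theta_deg, dtype=float))
        p = np.zeros_like(th)
        for mu, kap, w in zip(self.centers, self.kappas, self.weights):
            p += w * stats.vonmises.pdf(th, kap, loc=np.radians(mu))
        return p / sum(self.weights)

    def log_density(self, theta_deg):
        return np.log(self.density(theta_deg))

    def free_energy(self, theta_deg, T: float = 310.0):
        g = -C.KB * T * self.log_density(theta_deg)
        return g - g.min()

    def sample(self, n: int, rng: np.random.Generator):
        comp = rng.choice(len(self.weights), size=n,
                          p=np.asarray(self.weights) / sum(self.weights))
        out = np.empty(n)
        for k, (mu, kap) in enumerate(zip(self.centers, self.kappas)):
            m = comp == k
            out[m] = stats.vonmises.rvs(kap, loc=np.radians(mu),
                                        size=int(m.sum()), random_state=rng)
        deg = np.degrees(out)
        return -((-deg + 180.0) % 360.0 - 180.0)   # wrap to (-180, 180]


def sample_angles(n: int, seed: int = 0,
                  density: TwoWellDensity | None = None):
    """Angle series (degrees) plus the generating density as ground truth."""
    density = density or TwoWellDensity()
    rng = np.random.default_rng(seed)
    return density.sample(n, rng), density


def sample_kinetic(n_dof: int, T: float, n: int, seed: int = 0):
    """Exact Maxwell-Boltzmann kinetic-energy draws (gamma distribution)."""
    rng = np.random.default_rng(seed)
    return stats.gamma.rvs(a=n_dof / 2.0, scale=C.KB * T, size=n,
                           random_state=rng)


def sample_relaxation(a0: float, a1: float, a2: float, tau1: float,
                      tau2: float, t, n_traj: int, seed: int = 0):
    """Noisy occupancy curve: Binomial(n_traj, p(t))/n_traj at each time."""
    rng = np.random.default_rng(seed)
    t = np.asarray(t, dtype=float)
    p = np.clip(biexponential(t, a0, a1, a2, tau1, tau2), 0.0, 1.0)
    return rng.binomial(n_traj, p) / n_traj


def place_ideal_gas(n: int, box_edge: float, seed: int = 0):
    """Uniform (Poisson) particle placement in a periodic cube."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, box_edge, size=(n, 3))
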