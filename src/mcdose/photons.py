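"""Photon interaction sampling.

Compton scattering uses the Klein-Nishina differential cross section for a
free electron at rest (no binding, no Doppler broadening), sampled with the
standard two-branch composition-rejection scheme in the energy ratio
``eps = E'/E``.  Photoelectric absorption transfers the full photon energy
to a photoelectron along the photon direction (relaxation neglected).  Pair
production splits the available kinetic energy uniformly between the
electron and the positron, both emitted forward; the positron annihilates
at rest into two back-to-back 0.511 MeV photons.
"""

from __future__ import annotations

import numpy as np

from .constants import MEC2, PAIR_THRESHOLD

__all__ = ["kn_dcs_eps", "sample_compton", "sample_interaction_channel",
           "photoelectric", "pair_production", "annihilation_directions"]


def kn_dcs_eps(E, eps):
    """Klein-Nishina differential cross section in eps = E'/E (unnormalized
    shape, per unit eps).  Used by the spectrum tests as the quadrature
    reference."""
    k = np.asarray(E, dtype=float) / MEC2
    eps = np.asarray(eps, dtype=float)
    cos_t = 1.0 - (1.0 / eps - 1.0) / k
    sin2 = 1.0 - cos_t**2
    return (eps + 1.0 / eps - sin2) * np.where(
        (eps >= 1.0 / (1.0 + 2.0 * k)) & (eps <= 1.0), 1.0, 0.0)


def sample_compton(E, rng):
    """Sample Compton scattering at photon energies ``E`` (array, MeV).

    Returns ``(E_out, cos_theta, E_e, cos_theta_e)``: scattered photon energy
    and polar cosine, recoil electron energy and polar cosine (azimuths are
    opposite; energy is conserved exactly, E_out + E_e = E).
    """
    E = np.atleast_1d(np.asarray(E, dtype=float))
    if np.any(E <= 0):
        raise ValueError("photon energy must be positive")
    k = E / MEC2
    eps0 = 1.0 / (1.0 + 2.0 * k)
    a1 = np.log(1.0 / eps0)
    a2 = 0.5 * (1.0 - eps0**2)
    n = len(E)
    eps = np.empty(n)
    todo = np.arange(n)
    while len(todo):
        kk, e0 = k[todo], eps0[todo]
        r1, r2, r3 = rng.random((3, len(todo)))
        use_log = r1 * (a1[todo] + a2[todo]) < a1[todo]
        cand = np.where(use_log, e0 * np.exp(a1[todo] * r2),
                        np.sqrt(e0**2 + (1.0 - e0**2) * r2))
        cos_t = 1.0 - (1.0 / cand - 1.0) / kk
        sin2 = np.clip(1.0 - cos_t**2, 0.0, 1.0)
        g = 1.0 - cand * sin2 / (1.0 + cand**2)
        acc = r3 <= g
        eps[todo[acc]] = cand[acc]
        todo = todo[~acc]
    E_out = eps * E
    cos_theta = np.clip(1.0 - (1.0 / eps - 1.0) / k, -1.0, 1.0)
    E_e = E - E_out
    p_e = np.sqrt(E_e * (E_e + 2.0 * MEC2))
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_e = np.where(p_e > 0, (E - E_out * cos_theta) / np.where(p_e > 0, p_e, 1.0), 1.0)
    return E_out, cos_theta, E_e, np.clip(cos_e, -1.0, 1.0)


def sample_interaction_channel(mu_compton, mu_photo, mu_pair, rng):
    """Draw the interaction channel (0=Compton, 1=photoelectric, 2=pair)
    proportionally to the per-channel attenuation coefficients."""
    mu_c = np.atleast_1d(np.asarray(mu_compton, dtype=float))
    mu_p = np.broadcast_to(np.asarray(mu_photo, dtype=float), mu_c.shape)
    mu_pp = np.broadcast_to(np.asarray(mu_pair, dtype=float), mu_c.shape)
    tot = mu_c + mu_p + mu_pp
    xi = rng.random(mu_c.shape) * tot
    return np.where(xi < mu_c, 0, np.where(xi < mu_c + mu_p, 1, 2)).astype(np.int8)


def photoelectric(E):
    """Photoelectric absorption: the photoelectron carries the full photon
    energy along the photon direction (binding/relaxation neglected)."""
    return np.asarray(E, dtype=float)


def pair_production(E, rng):
    """Split E - 1.022 MeV uniformly between electron and positron.

    Returns (E_electron, E_positron); raises below threshold.
    """
    E = np.atleast_1d(np.asarray(E, dtype=float))
    if np.any(E < PAIR_THRESHOLD * (1 - 1e-12)):
        raise ValueError("pair production below 1.022 MeV threshold")
    avail = np.maximum(E - PAIR_THRESHOLD, 0.0)
    xi = rng.random(E.shape)
    return avail * xi, avail * (1.0 - xi)


def annihilation_directions(n, rng):
    """Isotropic unit axes for positron annihilation at rest; the two 0.511
    MeV photons fly back-to-back along +/- the returned axis."""
    cos_t = 2.0 * rng.random(n) - 1.0
    phi = 2.0 * np.pi * rng.random(n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
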