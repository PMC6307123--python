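"""Charged-particle interaction sampling.

Hard inelastic collisions follow the Moller differential cross section for a
free electron at rest (identical-particle convention: the delta ray is the
slower outgoing electron, so transfers are capped at half the kinetic
energy).  Angular deflections over a condensed step are drawn from a single
small-angle distribution scaled by the characteristic angle
``theta0 = sqrt(T(E) * s)`` with T the material scattering power: the shape
is the plane-projected 2-D Gaussian (Rayleigh-distributed polar angle)
truncated at pi, which preserves the exact first moment <theta^2> = T*s.
Positrons reuse the electron model and annihilate at rest.
"""

from __future__ import annotations

import numpy as np

from .constants import MEC2, RE

__all__ = ["moller_dcs", "sample_moller", "moller_directions",
           "sample_multiple_scattering"]


def moller_dcs(T, W):
    """Moller differential cross section dsigma/dW per atomic electron
    (cm^2/MeV) for primary kinetic energy ``T`` and energy transfer ``W``.

    Valid for W in (0, T/2]; the identical-particle convention assigns the
    faster outgoing electron to the primary.
    """
    T = np.asarray(T, dtype=float)
    W = np.asarray(W, dtype=float)
    tau = T / MEC2
    beta2 = tau * (tau + 2.0) / (tau + 1.0) ** 2
    eps = W / T
    bracket = (1.0 / eps**2 + 1.0 / (1.0 - eps) ** 2
               + (tau / (tau + 1.0)) ** 2
               - (2.0 * tau + 1.0) / (tau + 1.0) ** 2 / (eps * (1.0 - eps)))
    return 2.0 * np.pi * RE**2 * MEC2 / (beta2 * T**2) * bracket


def _moller_shape(T, eps):
    """eps^2-reduced Moller shape g(eps) used for rejection sampling."""
    tau = T / MEC2
    return (1.0 + (eps / (1.0 - eps)) ** 2 + (tau / (tau + 1.0)) ** 2 * eps**2
            - (2.0 * tau + 1.0) / (tau + 1.0) ** 2 * eps**2 / (eps * (1.0 - eps)))


def sample_moller(T, wc, rng):
    """Sample delta-ray energies W from the restricted Moller spectrum.

    ``T`` is an array of primary kinetic energies (each must exceed 2*wc).
    Rejection sampling with a 1/W^2 envelope on [wc, T/2].
    Returns W with W <= T/2 elementwise.
    """
    T = np.atleast_1d(np.asarray(T, dtype=float))
    if np.any(T <= 2.0 * wc):
        raise ValueError("hard Moller collision requires T > 2*wc")
    n = len(T)
    W = np.empty(n)
    todo = np.arange(n)
    # envelope bound on the eps^2-reduced shape over [wc/T, 1/2]
    eps_lo = wc / T
    probes = eps_lo[None, :] + np.linspace(0.0, 1.0, 17)[:, None] * (0.5 - eps_lo[None, :])
    gmax = _moller_shape(T[None, :], probes).max(axis=0) * (1.0 + 1e-6)
    while len(todo):
        t = T[todo]
        xi = rng.random(len(todo))
        # inverse-CDF of the 1/W^2 envelope
        w = 1.0 / (1.0 / wc - xi * (1.0 / wc - 2.0 / t))
        acc = rng.random(len(todo)) * gmax[todo] <= _moller_shape(t, w / t)
        W[todo[acc]] = w[acc]
        todo = todo[~acc]
    return W


def moller_directions(T, W):
    """Polar cosines of the primary and the delta ray after a hard collision,
    from two-body kinematics on a free electron at rest."""
    T = np.asarray(T, dtype=float)
    W = np.asarray(W, dtype=float)
    cos_d = np.sqrt(np.clip((W / T) * (T + 2.0 * MEC2) / (W + 2.0 * MEC2), 0.0, 1.0))
    Tp = T - W
    cos_p = np.sqrt(np.clip((Tp / T) * (T + 2.0 * MEC2) / (Tp + 2.0 * MEC2), 0.0, 1.0))
    return cos_p, cos_d


def sample_multiple_scattering(E, material, s, rng):
    """Sample the polar deflection over a condensed step of length ``s`` (cm).

    Returns (theta, phi).  theta follows the small-angle 2-D Gaussian shape
    with <theta^2> = T(E)*s, truncated at pi; phi is uniform.
    """
    E = np.atleast_1d(np.asarray(E, dtype=float))
    s = np.broadcast_to(np.asarray(s, dtype=float), E.shape)
    theta0_sq = material.T_scatter(E) * s
    theta = np.sqrt(theta0_sq * -np.log(np.clip(1.0 - rng.random(E.shape), 1e-300, None)))
    theta = np.minimum(theta, np.pi)
    phi = 2.0 * np.pi * rng.random(E.shape)
    return theta, phi
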