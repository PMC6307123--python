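"""Small vector helpers shared by the transport modules."""

from __future__ import annotations

import numpy as np


def normalize(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def rotate_direction(d, cos_theta, phi):
    """Deflect unit vectors ``d`` (n,3) by polar angle theta (given as cos)
    and azimuth phi about each vector's own axis.  Vectorized, with the
    usual special-casing of directions (anti)parallel to z."""
    d = np.atleast_2d(np.asarray(d, dtype=float))
    ct = np.atleast_1d(np.asarray(cos_theta, dtype=float))
    ph = np.atleast_1d(np.asarray(phi, dtype=float))
    st = np.sqrt(np.clip(1.0 - ct**2, 0.0, None))
    cp, sp = np.cos(ph), np.sin(ph)
    u, v, w = d[:, 0], d[:, 1], d[:, 2]
    rho2 = u**2 + v**2
    out = np.empty_like(d)
    near_pole = rho2 < 1e-20
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.sqrt(rho2)
        a = st * (u * w * cp - v * sp) / rho
        b = st * (v * w * cp + u * sp) / rho
        out[:, 0] = u * ct + a
        out[:, 1] = v * ct + b
        out[:, 2] = w * ct - rho * st * cp
    if np.any(near_pole):
        sgn = np.sign(w[near_pole])
        out[near_pole, 0] = st[near_pole] * cp[near_pole] * sgn
        out[near_pole, 1] = st[near_pole] * sp[near_pole] * sgn
        out[near_pole, 2] = ct[near_pole] * sgn
    # renormalize to keep |d| = 1 to machine precision over long tracks
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out
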