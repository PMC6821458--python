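"""Periodic cardinal spline basis for circular (phase) predictors.

The low-frequency phase enters the coupling models through a periodic
cardinal-spline basis with ``n`` control points equally spaced on [0, 2*pi).
Basis function k interpolates the indicator of control point k (it equals 1
there and 0 at every other control point) and the basis functions sum to one
at every phase, so the models need no separate intercept. With tension 0.5
the cardinal spline is the Catmull-Rom spline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PeriodicSplineBasis", "spline_design_matrix"]


@dataclass(frozen=True)
class PeriodicSplineBasis:
    """Basis of ``n`` periodic cardinal splines with the given tension."""

    n: int = 10
    tension: float = 0.5

    def __post_init__(self):
        if self.n < 4:
            raise ValueError(
                f"need at least 4 control points for a cardinal spline basis, got {self.n}"
            )

    @property
    def control_phases(self) -> np.ndarray:
        """Control-point phases, equally spaced on [0, 2*pi)."""
        return np.arange(self.n) * (2.0 * np.pi / self.n)


def spline_design_matrix(phi: np.ndarray, basis: PeriodicSplineBasis) -> np.ndarray:
    """Evaluate the periodic spline basis at each phase.

    Parameters
    ----------
    phi : array_like
        Phases in radians; any real values are accepted and wrapped to
        [0, 2*pi).
    basis : PeriodicSplineBasis

    Returns
    -------
    ndarray of shape (len(phi), basis.n)
        Row t holds f_1(phi_t), ..., f_n(phi_t). Each row sums to one; at
        most four entries per row are non-zero.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    n, s = basis.n, basis.tension
    h = 2.0 * np.pi / n

    theta = np.mod(phi, 2.0 * np.pi)
    seg = np.floor(theta / h).astype(np.intp)
    # guard against theta/h == n from rounding at 2*pi
    seg = np.minimum(seg, n - 1)
    u = theta / h - seg
    u2 = u * u
    u3 = u2 * u

    # cardinal-spline blending weights for control points seg-1 .. seg+2
    w = np.empty((len(phi), 4))
    w[:, 0] = -s * u + 2.0 * s * u2 - s * u3
    w[:, 1] = 1.0 + (s - 3.0) * u2 + (2.0 - s) * u3
    w[:, 2] = s * u + (3.0 - 2.0 * s) * u2 + (s - 2.0) * u3
    w[:, 3] = -s * u2 + s * u3

    X = np.zeros((len(phi), n))
    rows = np.arange(len(phi))
    for k in range(4):
        np.add.at(X, (rows, (seg + k - 1) % n), w[:, k])
    return X
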