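"""Linear neuronal dynamics for resting-state effective connectivity.

The neuronal state of each region evolves as a linear stochastic system

    dx/dt = A x + C u + v(t)

where ``A`` (Hz) is the effective-connectivity Jacobian, ``C`` (Hz) routes
exogenous inputs ``u`` (identically zero at rest) and ``v(t)`` are the
endogenous neuronal fluctuations.  Self-connections are fixed at -0.5 Hz and
re-scaled through a log parameter, so the diagonal of ``A`` is
``-0.5 * exp(self_logscale)`` — strictly negative for any finite value, which
precludes run-away excitation.

Convention
----------
``A[i, j]`` is the coupling FROM region ``j`` TO region ``i`` (column =
source), matching the matrix-vector action on the state vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SELF_CONNECTION_HZ",
    "ConnectivityParams",
    "effective_jacobian",
    "stability_analysis",
    "StabilityResult",
    "four_node_benchmark",
]

#: Fixed intrinsic (within-region) rate constant, Hz.  Self-connections are
#: parameterised as ``SELF_CONNECTION_HZ * exp(self_logscale)``.
SELF_CONNECTION_HZ = -0.5


class InvalidParameterError(ValueError):
    """Raised when connectivity parameters violate their invariants."""


def _as_matrix(x, n, m, name):
    a = np.asarray(x, dtype=float)
    if a.shape != (n, m):
        raise InvalidParameterError(f"{name} must have shape {(n, m)}, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InvalidParameterError(f"{name} contains non-finite entries")
    return a


@dataclass(frozen=True)
class ConnectivityParams:
    """Parameterisation of the neuronal Jacobian.

    Parameters
    ----------
    extrinsic : (n, n) array
        Between-region couplings in Hz with an identically-zero diagonal;
        entry ``[i, j]`` is the influence of region ``j`` on region ``i``.
    self_logscale : (n,) array
        Unitless log-scaling of the fixed -0.5 Hz self-connections.
    driving : (n, m) array, optional
        Exogenous input weights in Hz; all-zero (shape ``(n, 0)``) at rest.
    """

    extrinsic: np.ndarray
    self_logscale: np.ndarray
    driving: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        ext = np.asarray(self.extrinsic, dtype=float)
        if ext.ndim != 2 or ext.shape[0] != ext.shape[1]:
            raise InvalidParameterError("extrinsic must be a square matrix")
        n = ext.shape[0]
        ext = _as_matrix(ext, n, n, "extrinsic")
        if np.any(np.diag(ext) != 0.0):
            raise InvalidParameterError("extrinsic diagonal must be identically zero")
        sls = np.asarray(self.self_logscale, dtype=float).reshape(-1)
        if sls.shape != (n,):
            raise InvalidParameterError(f"self_logscale must have length {n}")
        if not np.all(np.isfinite(sls)):
            raise InvalidParameterError("self_logscale contains non-finite entries")
        drv = self.driving
        if drv is None:
            drv = np.zeros((n, 0))
        drv = np.asarray(drv, dtype=float)
        if drv.ndim != 2 or drv.shape[0] != n or not np.all(np.isfinite(drv)):
            raise InvalidParameterError("driving must be a finite (n, m) matrix")
        object.__setattr__(self, "extrinsic", ext)
        object.__setattr__(self, "self_logscale", sls)
        object.__setattr__(self, "driving", drv)

    @property
    def n_regions(self) -> int:
        return self.extrinsic.shape[0]

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "extrinsic": self.extrinsic.tolist(),
            "self_logscale": self.self_logscale.tolist(),
            "driving": self.driving.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConnectivityParams":
        return cls(
            extrinsic=np.asarray(d["extrinsic"], dtype=float),
            self_logscale=np.asarray(d["self_logscale"], dtype=float),
            driving=np.asarray(d.get("driving", []), dtype=float).reshape(
                len(d["self_logscale"]), -1
            ),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path) -> "ConnectivityParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def effective_jacobian(params: ConnectivityParams) -> np.ndarray:
    """Effective-connectivity Jacobian ``A`` in Hz.

    Returns the extrinsic coupling matrix with its diagonal replaced by
    ``-0.5 * exp(self_logscale)``.
    """
    A = params.extrinsic.copy()
    np.fill_diagonal(A, SELF_CONNECTION_HZ * np.exp(params.self_logscale))
    return A


@dataclass(frozen=True)
class StabilityResult:
    eigenvalues: np.ndarray  # complex, Hz
    max_lyapunov: float  # largest real part, Hz
    stable: bool


def stability_analysis(params: ConnectivityParams) -> StabilityResult:
    """Eigenvalues of the neuronal Jacobian and the leading Lyapunov exponent.

    The real parts of the eigenvalues of ``A`` are the Lyapunov exponents of
    the linear system; the fixed point is stable iff all are negative.  A
    warning (not an error) is emitted for non-negative leading exponents.
    """
    import warnings

    A = effective_jacobian(params)
    eigvals = np.linalg.eigvals(A)
    max_lyap = float(np.max(eigvals.real))
    stable = max_lyap < 0.0
    if not stable:
        warnings.warn(
            f"neuronal system is not stable (max Lyapunov exponent {max_lyap:.4g} Hz)",
            RuntimeWarning,
            stacklevel=2,
        )
    return StabilityResult(eigenvalues=eigvals, max_lyapunov=max_lyap, stable=stable)


def four_node_benchmark() -> ConnectivityParams:
    """The directed, cyclic four-region validation network.

    Forward/lateral couplings are excitatory and backward couplings
    inhibitory; self-connections sit at their -0.5 Hz default
    (``self_logscale = 0``).  This is the network used throughout the
    package's simulation-based validation protocols.
    """
    extrinsic = np.array(
        [
            [0.0, 0.0, -0.3, -0.1],
            [0.4, 0.0, 0.2, 0.0],
            [0.0, 0.2, 0.0, -0.1],
            [0.1, 0.3, 0.0, 0.0],
        ]
    )
    return ConnectivityParams(extrinsic=extrinsic, self_logscale=np.zeros(4))
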