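"""Balloon-model haemodynamics and the BOLD observation function.

Each region carries four haemodynamic states downstream of its neuronal
activity ``x``: a vasodilatory signal ``s``, and log-transformed blood flow,
venous volume and deoxyhemoglobin content (log transforms guarantee
positivity of the physical quantities).  With ``f = exp(log_flow)``,
``v = exp(log_volume)``, ``q = exp(log_dhb)``:

    ds/dt  = x - kappa*s - gamma*(f - 1)
    df/dt  = s                                   (so  d log f/dt = s/f)
    tau dv/dt = f - v**(1/alpha)
    tau dq/dt = f*E(f, E0)/E0 - v**(1/alpha) * q/v

with the oxygen-extraction function ``E(f, E0) = 1 - (1 - E0)**(1/f)``, and
the static BOLD read-out (percent signal change)

    y = V0 * (k1*(1 - q) + k2*(1 - q/v) + k3*(1 - v)).

The resting fixed point is the all-zero state in this parameterisation.
The neurovascular efficacy ``epsilon`` scales how strongly neuronal activity
drives the vasodilatory signal; its default (1/16) calibrates the model so
that slow endogenous fluctuations of order-one neuronal amplitude produce
flow excursions of a few tens of percent and resting BOLD fluctuations
peaking near 2% — the canonical magnitudes — rather than the run-away
values the cascade yields with unit efficacy.
Only the transit time ``tau`` and the signal decay ``kappa`` are treated as
free (estimable) parameters during inversion, as per-region log-scaling
factors with tight shrinkage priors; the remaining constants are fixed but
config-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .connectivity import ConnectivityParams, effective_jacobian

__all__ = [
    "HemodynamicParams",
    "FullStateVector",
    "hemo_drift",
    "full_drift",
    "bold_readout",
    "linearise_full_system",
    "N_STATES_PER_REGION",
]

#: neuronal activity + (s, log f, log v, log q)
N_STATES_PER_REGION = 5


class IntegrationDomainError(ValueError):
    """Raised when a state vector leaves the integrable domain."""


@dataclass(frozen=True)
class HemodynamicParams:
    """Balloon-model constants.

    Per-region arrays of length ``n``: ``transit_time`` (s), ``signal_decay``
    (1/s), ``autoregulation`` (1/s), ``grubb_exponent`` (unitless, in (0,1)),
    ``oxygen_extraction`` (resting fraction, in (0,1)).  Scalars:
    ``echo_time`` (s), ``resting_venous_volume`` (%), and the field-dependent
    read-out coefficients ``k1, k2, k3``.
    """

    transit_time: np.ndarray
    signal_decay: np.ndarray
    autoregulation: np.ndarray
    grubb_exponent: np.ndarray
    oxygen_extraction: np.ndarray
    neural_efficacy: np.ndarray = None  # type: ignore[assignment]
    echo_time: float = 0.04
    resting_venous_volume: float = 4.0
    k1: float = 6.93 * 0.4
    k2: float = 1.5
    k3: float = 0.6

    def __post_init__(self):
        if self.neural_efficacy is None:
            object.__setattr__(
                self, "neural_efficacy", np.full(np.atleast_1d(self.transit_time).shape, 1.0 / 16.0)
            )
        for name in (
            "transit_time",
            "signal_decay",
            "autoregulation",
            "grubb_exponent",
            "oxygen_extraction",
            "neural_efficacy",
        ):
            a = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if not np.all(np.isfinite(a)):
                raise ValueError(f"{name} contains non-finite entries")
            object.__setattr__(self, name, a)
        if np.any(self.transit_time <= 0):
            raise ValueError("transit_time must be positive")
        for name in ("grubb_exponent", "oxygen_extraction"):
            a = getattr(self, name)
            if np.any(a <= 0) or np.any(a >= 1):
                raise ValueError(f"{name} must lie in (0, 1)")

    @property
    def n_regions(self) -> int:
        return self.transit_time.shape[0]

    @classmethod
    def defaults(cls, n_regions: int, **overrides) -> "HemodynamicParams":
        """Standard constants: tau=2 s, kappa=0.64/s, gamma=0.32/s,
        alpha=0.32, E0=0.4, epsilon=1/16, V0=4%, TE=0.04 s, 3T read-out
        coefficients."""
        base = dict(
            transit_time=np.full(n_regions, 2.0),
            signal_decay=np.full(n_regions, 0.64),
            autoregulation=np.full(n_regions, 0.32),
            grubb_exponent=np.full(n_regions, 0.32),
            oxygen_extraction=np.full(n_regions, 0.4),
            neural_efficacy=np.full(n_regions, 1.0 / 16.0),
        )
        base.update(overrides)
        return cls(**base)

    def rescaled(self, transit_logscale=None, decay_logscale=None) -> "HemodynamicParams":
        """Apply log-scaling factors to the free parameters (transit, decay)."""
        kw = {}
        if transit_logscale is not None:
            kw["transit_time"] = self.transit_time * np.exp(np.asarray(transit_logscale))
        if decay_logscale is not None:
            kw["signal_decay"] = self.signal_decay * np.exp(np.asarray(decay_logscale))
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "transit_time": self.transit_time.tolist(),
            "signal_decay": self.signal_decay.tolist(),
            "autoregulation": self.autoregulation.tolist(),
            "grubb_exponent": self.grubb_exponent.tolist(),
            "oxygen_extraction": self.oxygen_extraction.tolist(),
            "neural_efficacy": self.neural_efficacy.tolist(),
            "echo_time": self.echo_time,
            "resting_venous_volume": self.resting_venous_volume,
            "k1": self.k1,
            "k2": self.k2,
            "k3": self.k3,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HemodynamicParams":
        return cls(**{k: (np.asarray(v) if isinstance(v, list) else v) for k, v in d.items()})


@dataclass(frozen=True)
class FullStateVector:
    """Stacked neuronal + haemodynamic states for ``n`` regions.

    The flat layout used throughout is five blocks of length ``n``:
    ``[x, s, log_flow, log_volume, log_dhb]``.
    """

    x: np.ndarray
    s: np.ndarray
    log_flow: np.ndarray
    log_volume: np.ndarray
    log_dhb: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.x, self.s, self.log_flow, self.log_volume, self.log_dhb])

    @classmethod
    def from_array(cls, z: np.ndarray) -> "FullStateVector":
        z = np.asarray(z, dtype=float)
        n = z.size // N_STATES_PER_REGION
        b = z.reshape(N_STATES_PER_REGION, n)
        return cls(x=b[0], s=b[1], log_flow=b[2], log_volume=b[3], log_dhb=b[4])

    @classmethod
    def resting(cls, n_regions: int) -> "FullStateVector":
        z = np.zeros(N_STATES_PER_REGION * n_regions)
        return cls.from_array(z)


def _oxygen_extraction(f: np.ndarray, e0: np.ndarray) -> np.ndarray:
    return 1.0 - (1.0 - e0) ** (1.0 / f)


def _hemo_rates(s, lf, lv, lq, x, p: HemodynamicParams):
    """Time derivatives of (s, log f, log v, log q) given neuronal drive x."""
    f = np.exp(lf)
    v = np.exp(lv)
    q = np.exp(lq)
    e0 = p.oxygen_extraction
    inv_alpha = 1.0 / p.grubb_exponent
    ds = p.neural_efficacy * x - p.signal_decay * s - p.autoregulation * (f - 1.0)
    dlf = s / f
    dlv = (f - v**inv_alpha) / (p.transit_time * v)
    dlq = (f * _oxygen_extraction(f, e0) / (e0 * q) - v ** (inv_alpha - 1.0)) / p.transit_time
    return ds, dlf, dlv, dlq


def hemo_drift(
    state: FullStateVector, neural_input: np.ndarray, params: HemodynamicParams
) -> np.ndarray:
    """Derivatives of the four haemodynamic states per region, stacked as
    ``[ds, dlog_flow, dlog_volume, dlog_dhb]`` (shape ``(4, n)``).

    At the all-zero state with zero drive the derivative is exactly zero
    (the resting fixed point).
    """
    z = state.as_array()
    if not np.all(np.isfinite(z)):
        raise IntegrationDomainError("non-finite haemodynamic state")
    ds, dlf, dlv, dlq = _hemo_rates(
        state.s, state.log_flow, state.log_volume, state.log_dhb,
        np.asarray(neural_input, dtype=float), params,
    )
    return np.stack([ds, dlf, dlv, dlq])


def full_drift(
    z: np.ndarray,
    conn: ConnectivityParams,
    hemo: HemodynamicParams,
    fluctuation: np.ndarray | None = None,
    A: np.ndarray | None = None,
) -> np.ndarray:
    """Drift of the stacked neuronal + haemodynamic system (flat 5n vector).

    ``fluctuation`` is the endogenous neuronal noise path value v(t), added to
    the neuronal rows only.  ``A`` may be passed to avoid recomputing the
    effective Jacobian inside integration loops.
    """
    n = conn.n_regions
    b = np.asarray(z, dtype=float).reshape(N_STATES_PER_REGION, n)
    x, s, lf, lv, lq = b
    if A is None:
        A = effective_jacobian(conn)
    dx = A @ x
    if fluctuation is not None:
        dx = dx + fluctuation
    ds, dlf, dlv, dlq = _hemo_rates(s, lf, lv, lq, x, hemo)
    return np.concatenate([dx, ds, dlf, dlv, dlq])


def bold_readout(state: FullStateVector, params: HemodynamicParams) -> np.ndarray:
    """BOLD percent signal change per region; exactly 0 at the fixed point."""
    v = np.exp(state.log_volume)
    q = np.exp(state.log_dhb)
    v0 = params.resting_venous_volume
    return v0 * (
        params.k1 * (1.0 - q) + params.k2 * (1.0 - q / v) + params.k3 * (1.0 - v)
    )


def bold_from_flat(z: np.ndarray, n: int, params: HemodynamicParams) -> np.ndarray:
    """Fast path: read-out from a flat state array (or batch, shape (..., 5n))."""
    z = np.asarray(z)
    lv = z[..., 3 * n : 4 * n]
    lq = z[..., 4 * n : 5 * n]
    v = np.exp(lv)
    q = np.exp(lq)
    v0 = params.resting_venous_volume
    return v0 * (params.k1 * (1.0 - q) + params.k2 * (1.0 - q / v) + params.k3 * (1.0 - v))


def linearise_full_system(conn: ConnectivityParams, hemo: HemodynamicParams):
    """Exact Jacobian of the stacked system at the resting fixed point.

    Returns ``(J, noise_injection, readout_gradient)`` where ``J`` is the
    ``5n x 5n`` drift Jacobian, ``noise_injection`` (``5n x n``) routes state
    noise into the neuronal rows, and ``readout_gradient`` (``n x 5n``) is the
    gradient of the BOLD read-out — nonzero only in the volume and
    deoxyhemoglobin columns.

    The haemodynamic blocks are diagonal across regions; at the fixed point
    (f = v = q = 1) the nonzero partials reduce to closed forms, e.g.
    ``d(dlog q)/d(log f) = (1 + (1-E0) ln(1-E0)/E0) / tau``.
    """
    n = conn.n_regions
    if hemo.n_regions != n:
        raise ValueError("connectivity and haemodynamic parameters disagree on n_regions")
    A = effective_jacobian(conn)

    kappa = hemo.signal_decay
    gamma = hemo.autoregulation
    tau = hemo.transit_time
    alpha = hemo.grubb_exponent
    e0 = hemo.oxygen_extraction
    inv_alpha = 1.0 / alpha

    ns = N_STATES_PER_REGION * n
    J = np.zeros((ns, ns))
    ix = slice(0, n)
    i_s = slice(n, 2 * n)
    ilf = slice(2 * n, 3 * n)
    ilv = slice(3 * n, 4 * n)
    ilq = slice(4 * n, 5 * n)

    J[ix, ix] = A
    # ds/dt = epsilon x - kappa s - gamma (exp(lf) - 1)
    J[i_s, ix] = np.diag(hemo.neural_efficacy)
    J[i_s, i_s] = -np.diag(kappa)
    J[i_s, ilf] = -np.diag(gamma)
    # dlf/dt = s exp(-lf)
    J[ilf, i_s] = np.eye(n)
    # dlv/dt = (exp(lf - lv) - exp((1/alpha - 1) lv)) / tau
    J[ilv, ilf] = np.diag(1.0 / tau)
    J[ilv, ilv] = -np.diag(inv_alpha / tau)
    # dlq/dt = (phi(f) exp(-lq) - exp((1/alpha - 1) lv)) / tau,
    # phi(f) = f E(f)/E0, phi'(1) = 1 + (1 - E0) ln(1 - E0)/E0
    dphi = 1.0 + (1.0 - e0) * np.log(1.0 - e0) / e0
    J[ilq, ilf] = np.diag(dphi / tau)
    J[ilq, ilv] = -np.diag((inv_alpha - 1.0) / tau)
    J[ilq, ilq] = -np.diag(1.0 / tau)

    if not np.all(np.isfinite(J)):
        raise FloatingPointError("linearisation produced non-finite Jacobian")

    noise_injection = np.zeros((ns, n))
    noise_injection[ix, :] = np.eye(n)

    v0 = hemo.resting_venous_volume
    readout_gradient = np.zeros((n, ns))
    readout_gradient[:, ilv] = np.diag(np.full(n, v0 * (hemo.k2 - hemo.k3)))
    readout_gradient[:, ilq] = np.diag(np.full(n, -v0 * (hemo.k1 + hemo.k2)))

    return J, noise_injection, readout_gradient
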