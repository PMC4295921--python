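"""Deterministic generative model of observed BOLD cross spectra.

Endogenous neuronal fluctuations and observation noise are given scale-free
(power-law) spectral densities

    g_v(w) = alpha_v * w**(-beta_v),      g_e(w) = alpha_e * w**(-beta_e),

with amplitudes and exponents estimated as log-parameters (positive by
construction).  These pass through the first-order transfer function of the
linearised neuronal + haemodynamic system,

    K(w) = dg/dx . (i 2 pi w I - J)^{-1} . B,

(the Fourier transform of the system's first-order Volterra kernels; ``J``
the full-system Jacobian at the fixed point, ``B`` the injection of state
noise into the neuronal rows, ``dg/dx`` the BOLD read-out gradient), giving
the predicted cross-spectral density

    G_y(w) = K(w) diag(g_v(w)) K(w)^H + diag(g_e(w)).

This is the multi-region generalisation of the scalar form
``|K|^2 g_v + g_e``; for one region the two coincide.  Noise processes are
mutually independent and independent across regions, so both spectral
matrices are diagonal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .connectivity import ConnectivityParams
from .features import CrossSpectra, FrequencyGrid
from .hemodynamics import HemodynamicParams, linearise_full_system

__all__ = [
    "NoiseSpectralParams",
    "SpectralModel",
    "powerlaw_spectrum",
    "transfer_function",
    "predict_csd",
    "NEURAL_BASE_AMPLITUDE",
    "OBS_BASE_AMPLITUDE",
]

#: Unit calibration of the fluctuation spectra: with these base amplitudes a
#: prior-mean model (couplings at -0.5 Hz self-connections, unit log-scales)
#: predicts order-one spectral densities over the standard analysis band, and
#: observation noise is a priori an order of magnitude weaker than the
#: neuronally driven signal.  Data features are rescaled to the same overall
#: power during inversion, so these constants fix units, not fit quality.
NEURAL_BASE_AMPLITUDE = 1.0 / 4096.0
OBS_BASE_AMPLITUDE = NEURAL_BASE_AMPLITUDE / 8.0


@dataclass(frozen=True)
class NoiseSpectralParams:
    """Log-amplitudes (per region) and log-exponents (shared) of the
    power-law neuronal and observation noise spectra."""

    log_alpha_neural: np.ndarray  # (n,)
    log_beta_neural: float = 0.0
    log_alpha_obs: np.ndarray = None  # type: ignore[assignment]
    log_beta_obs: float = 0.0

    def __post_init__(self):
        la = np.atleast_1d(np.asarray(self.log_alpha_neural, dtype=float))
        lo = self.log_alpha_obs
        lo = np.zeros_like(la) if lo is None else np.atleast_1d(np.asarray(lo, dtype=float))
        if la.shape != lo.shape:
            raise ValueError("neural and observation amplitude vectors must match")
        vals = np.concatenate([la, lo, [self.log_beta_neural, self.log_beta_obs]])
        if not np.all(np.isfinite(vals)):
            raise ValueError("noise spectral parameters must be finite")
        object.__setattr__(self, "log_alpha_neural", la)
        object.__setattr__(self, "log_alpha_obs", lo)

    @property
    def n_regions(self) -> int:
        return self.log_alpha_neural.shape[0]

    @classmethod
    def defaults(cls, n_regions: int) -> "NoiseSpectralParams":
        return cls(log_alpha_neural=np.zeros(n_regions), log_alpha_obs=np.zeros(n_regions))

    def to_dict(self) -> dict:
        return {
            "log_alpha_neural": self.log_alpha_neural.tolist(),
            "log_beta_neural": self.log_beta_neural,
            "log_alpha_obs": self.log_alpha_obs.tolist(),
            "log_beta_obs": self.log_beta_obs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSpectralParams":
        return cls(
            log_alpha_neural=np.asarray(d["log_alpha_neural"], dtype=float),
            log_beta_neural=float(d["log_beta_neural"]),
            log_alpha_obs=np.asarray(d["log_alpha_obs"], dtype=float),
            log_beta_obs=float(d["log_beta_obs"]),
        )


@dataclass(frozen=True)
class SpectralModel:
    """A complete generative model of cross spectra on a frequency grid."""

    conn: ConnectivityParams
    hemo: HemodynamicParams
    noise: NoiseSpectralParams
    grid: FrequencyGrid

    def __post_init__(self):
        n = self.conn.n_regions
        if self.hemo.n_regions != n or self.noise.n_regions != n:
            raise ValueError("component parameter sets disagree on n_regions")

    @property
    def n_regions(self) -> int:
        return self.conn.n_regions

    def to_dict(self) -> dict:
        return {
            "conn": self.conn.to_dict(),
            "hemo": self.hemo.to_dict(),
            "noise": self.noise.to_dict(),
            "grid": {"frequencies": self.grid.frequencies.tolist(), "TR": self.grid.TR},
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralModel":
        return cls(
            conn=ConnectivityParams.from_dict(d["conn"]),
            hemo=HemodynamicParams.from_dict(d["hemo"]),
            noise=NoiseSpectralParams.from_dict(d["noise"]),
            grid=FrequencyGrid(
                np.asarray(d["grid"]["frequencies"], dtype=float), float(d["grid"]["TR"])
            ),
        )

    @classmethod
    def from_json(cls, path) -> "SpectralModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def powerlaw_spectrum(log_alpha: float, log_beta: float, grid: FrequencyGrid) -> np.ndarray:
    """``g(w) = exp(log_alpha) * w**(-exp(log_beta))`` per frequency bin.

    Strictly positive; strictly decreasing for any positive exponent (the
    grid excludes w = 0 by construction).
    """
    w = grid.frequencies
    return np.exp(log_alpha) * w ** (-np.exp(log_beta))


def transfer_function(
    conn: ConnectivityParams, hemo: HemodynamicParams, grid: FrequencyGrid
) -> np.ndarray:
    """First-order transfer function ``K(w)`` from neuronal fluctuations to
    BOLD, complex array of shape ``(n, n, F)``."""
    J, B, L = linearise_full_system(conn, hemo)
    w = grid.frequencies
    M = 1j * 2.0 * np.pi * w[:, None, None] * np.eye(J.shape[0])[None] - J[None]
    try:
        X = np.linalg.solve(M, np.broadcast_to(B, (w.size, *B.shape)))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "transfer function singular on the grid (resonance or instability)"
        ) from exc
    K = np.einsum("ij,fjk->ikf", L, X)
    if not np.all(np.isfinite(K)):
        raise FloatingPointError("transfer function is not finite on the grid")
    return K


def predict_csd(model: SpectralModel) -> CrossSpectra:
    """Predicted cross-spectral density ``K G_v K^H + G_e`` on the grid."""
    noise = model.noise
    g_v = NEURAL_BASE_AMPLITUDE * np.stack(
        [
            powerlaw_spectrum(la, noise.log_beta_neural, model.grid)
            for la in noise.log_alpha_neural
        ]
    )  # (n, F)
    g_e = OBS_BASE_AMPLITUDE * np.stack(
        [
            powerlaw_spectrum(la, noise.log_beta_obs, model.grid)
            for la in noise.log_alpha_obs
        ]
    )
    K = transfer_function(model.conn, model.hemo, model.grid)  # (n, n, F)
    G = np.einsum("ikf,kf,jkf->ijf", K, g_v, np.conj(K))
    idx = np.arange(model.n_regions)
    G[idx, idx, :] = G[idx, idx, :].real + g_e
    csd = CrossSpectra(G, model.grid).hermitised()
    return csd
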