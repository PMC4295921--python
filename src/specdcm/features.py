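"""Sample cross-spectral data features.

Observed multivariate BOLD series are summarised by smooth sample
cross-spectral densities: the series are detrended, a fourth-order
multivariate autoregression (MAR) is fitted by least squares, and the MAR's
rational spectrum is evaluated on a fixed frequency grid.  Cross-covariance
functions are obtained from the spectra by an inverse Fourier transform over
the band.

Spectral convention
-------------------
Cross spectra are *two-sided* densities per Hz evaluated on the positive
half-axis: for a univariate AR(1) with coefficient ``a`` and innovation
variance ``s2`` sampled at interval ``TR``,

    S(f) = s2 * TR / |1 - a exp(-i 2 pi f TR)|**2 .

Predictions from the continuous-time generative model use the same
convention, so features and predictions live in one unit system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal

__all__ = [
    "FrequencyGrid",
    "CrossSpectra",
    "MARModel",
    "default_grid",
    "detrend",
    "fit_mar",
    "mar_to_csd",
    "csd_to_ccf",
    "sample_csd",
]

#: Lower edge of the analysis band in Hz (1/128 Hz, the slowest fluctuation
#: typically retained in resting-state fMRI).
LOW_FREQUENCY_HZ = 1.0 / 128.0


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing analysis frequencies (Hz) for sampling interval TR."""

    frequencies: np.ndarray
    TR: float

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        if f.size < 2:
            raise ValueError("grid needs at least 2 frequencies")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if f[0] <= 0:
            raise ValueError("minimum frequency must be positive")
        nyquist = 0.5 / self.TR
        if f[-1] > nyquist + 1e-12:
            raise ValueError(f"maximum frequency exceeds Nyquist ({nyquist} Hz)")
        object.__setattr__(self, "frequencies", f)

    @property
    def n_bins(self) -> int:
        return self.frequencies.size


def default_grid(TR: float, n_bins: int = 32) -> FrequencyGrid:
    """Evenly spaced grid from 1/128 Hz to the Nyquist frequency 1/(2 TR)."""
    if TR <= 0:
        raise ValueError("TR must be positive")
    nyquist = 0.5 / TR
    if LOW_FREQUENCY_HZ >= nyquist:
        raise ValueError(
            f"empty band: 1/128 Hz is not below the Nyquist frequency {nyquist} Hz"
        )
    return FrequencyGrid(np.linspace(LOW_FREQUENCY_HZ, nyquist, n_bins), TR)


@dataclass(frozen=True)
class CrossSpectra:
    """Complex cross-spectral density array, shape ``(n, n, F)``.

    Hermitian at each frequency; diagonals real and non-negative.  Units:
    signal^2 * s (density per Hz).
    """

    values: np.ndarray
    grid: FrequencyGrid

    def __post_init__(self):
        v = np.asarray(self.values, dtype=complex)
        if v.ndim != 3 or v.shape[0] != v.shape[1] or v.shape[2] != self.grid.n_bins:
            raise ValueError("values must have shape (n, n, F) matching the grid")
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def validate(self, atol: float = 1e-10) -> None:
        """Assert Hermitian symmetry per bin and real non-negative diagonals."""
        v = self.values
        herm = np.conj(np.transpose(v, (1, 0, 2)))
        if not np.allclose(v, herm, atol=atol):
            raise ValueError("cross spectra are not Hermitian per frequency")
        d = np.einsum("iik->ik", v)
        if np.max(np.abs(d.imag)) > atol:
            raise ValueError("diagonal spectra are not real")
        if np.min(d.real) < -atol:
            raise ValueError("diagonal spectra are negative")

    def hermitised(self) -> "CrossSpectra":
        v = 0.5 * (self.values + np.conj(np.transpose(self.values, (1, 0, 2))))
        return CrossSpectra(v, self.grid)

    # -- serialisation ------------------------------------------------------
    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("frequencies", data=self.grid.frequencies)
            f.attrs["TR"] = self.grid.TR

    @classmethod
    def from_hdf5(cls, path) -> "CrossSpectra":
        import h5py

        with h5py.File(path, "r") as f:
            grid = FrequencyGrid(f["frequencies"][:], float(f.attrs["TR"]))
            return cls(f["values"][:], grid)

    def to_json(self, path) -> None:
        """Plain-text debug format (real/imaginary parts as nested lists)."""
        import json
        from pathlib import Path

        doc = {
            "real": self.values.real.tolist(),
            "imag": self.values.imag.tolist(),
            "frequencies": self.grid.frequencies.tolist(),
            "TR": self.grid.TR,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path) -> "CrossSpectra":
        import json
        from pathlib import Path

        doc = json.loads(Path(path).read_text())
        v = np.asarray(doc["real"]) + 1j * np.asarray(doc["imag"])
        return cls(v, FrequencyGrid(np.asarray(doc["frequencies"]), doc["TR"]))


@dataclass(frozen=True)
class MARModel:
    """Order-p multivariate autoregression ``y_t = sum_k A_k y_{t-k} + e_t``."""

    coefficients: np.ndarray  # (p, n, n), lag-k regression weights
    innovation_covariance: np.ndarray  # (n, n), symmetric PSD
    TR: float

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float)
        s = np.asarray(self.innovation_covariance, dtype=float)
        if c.ndim != 3 or c.shape[1] != c.shape[2]:
            raise ValueError("coefficients must have shape (p, n, n)")
        if s.shape != (c.shape[1], c.shape[1]):
            raise ValueError("innovation_covariance shape mismatch")
        if not np.allclose(s, s.T, atol=1e-10):
            raise ValueError("innovation_covariance must be symmetric")
        object.__setattr__(self, "coefficients", c)
        object.__setattr__(self, "innovation_covariance", 0.5 * (s + s.T))

    @property
    def order(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_regions(self) -> int:
        return self.coefficients.shape[1]


def detrend(Y: np.ndarray) -> np.ndarray:
    """Remove each row's mean and linear trend (minimal stationarity guard)."""
    return scipy.signal.detrend(np.asarray(Y, dtype=float), axis=-1, type="linear")


def fit_mar(Y: np.ndarray, p: int = 4, TR: float = 1.0, ridge: float = 1e-8) -> MARModel:
    """Least-squares MAR(p) fit to a detrended (n, T) series.

    A tiny ridge proportional to the design's mean squared amplitude is added
    if the normal equations are rank deficient (with a warning).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    n, T = Y.shape
    if T <= n * p + 1:
        raise ValueError(f"need T > n*p + 1 samples (T={T}, n={n}, p={p})")
    # lag-stacked design: predict Y[:, t] from [Y[:, t-1], ..., Y[:, t-p]]
    X = np.empty((T - p, n * p))
    for k in range(1, p + 1):
        X[:, (k - 1) * n : k * n] = Y[:, p - k : T - k].T
    Z = Y[:, p:].T  # (T-p, n)
    G = X.T @ X
    try:
        B = np.linalg.solve(G, X.T @ Z)
    except np.linalg.LinAlgError:
        B = None
    if B is None or not np.all(np.isfinite(B)):
        warnings.warn("rank-deficient MAR design; falling back to ridge", RuntimeWarning)
        lam = ridge * np.trace(G) / max(G.shape[0], 1)
        B = np.linalg.solve(G + lam * np.eye(G.shape[0]), X.T @ Z)
    resid = Z - X @ B
    sigma = resid.T @ resid / max(T - p - n * p, 1)
    coeffs = np.stack([B[(k - 1) * n : k * n, :].T for k in range(1, p + 1)])
    return MARModel(coefficients=coeffs, innovation_covariance=sigma, TR=TR)


def mar_to_csd(mar: MARModel, grid: FrequencyGrid) -> CrossSpectra:
    """Rational MAR spectrum on the grid.

    ``S(f) = TR * H(f) Sigma H(f)^H`` with
    ``H(f) = (I - sum_k A_k exp(-i 2 pi f k TR))^{-1}``.
    """
    p, n = mar.order, mar.n_regions
    f = grid.frequencies
    TR = mar.TR
    # (F, n, n) frequency response denominators
    phase = np.exp(-2j * np.pi * np.outer(f, np.arange(1, p + 1)) * TR)  # (F, p)
    Afreq = np.tensordot(phase, mar.coefficients, axes=(1, 0))  # (F, n, n)
    M = np.eye(n)[None, :, :] - Afreq
    try:
        H = np.linalg.inv(M)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "MAR transfer function singular at a grid frequency"
        ) from exc
    S = TR * np.einsum("fij,jk,flk->fil", H, mar.innovation_covariance, np.conj(H))
    csd = CrossSpectra(np.moveaxis(S, 0, -1), grid).hermitised()
    return csd


def csd_to_ccf(csd: CrossSpectra, n_lags: int) -> np.ndarray:
    """Cross-covariance function from band-limited spectra.

    Returns a real array of shape ``(n, n, 2*n_lags + 1)`` over lags
    ``-n_lags*TR ... +n_lags*TR``, computed as

        c_ij(tau) = 2 Re[ sum_k S_ij(f_k) exp(i 2 pi f_k tau) ] df,

    i.e. the inverse Fourier transform over the (Hermitian-extended) band.
    """
    f = csd.grid.frequencies
    df = f[1] - f[0]
    lags = np.arange(-n_lags, n_lags + 1) * csd.grid.TR
    phase = np.exp(2j * np.pi * np.outer(f, lags))  # (F, L)
    c = 2.0 * np.real(np.tensordot(csd.values, phase, axes=(2, 0))) * df
    return c


def mar_from_csd(csd: CrossSpectra, p: int = 4) -> MARModel:
    """The MAR(p) a Yule-Walker estimator would converge to for a process
    with the given band-limited spectrum.

    Band-limited autocovariances ``R(k) = 2 Re sum_f S(f) exp(i 2 pi f k TR) df``
    are formed from the spectrum, and the block-Toeplitz Yule-Walker system
    ``R(k) = sum_j A_j R(k - j)`` is solved for the lag matrices and the
    innovation covariance.  This is the population analogue of
    :func:`fit_mar`; composing it with :func:`mar_to_csd` projects an
    arbitrary spectrum onto the order-p rational family — the same bottleneck
    through which observed data pass.
    """
    n = csd.n_regions
    f = csd.grid.frequencies
    df = f[1] - f[0]
    TR = csd.grid.TR
    lags = np.arange(0, p + 1) * TR
    phase = np.exp(2j * np.pi * np.outer(f, lags))
    R = 2.0 * np.real(np.tensordot(csd.values, phase, axes=(2, 0))) * df
    Rk = [R[:, :, k] for k in range(p + 1)]
    M = np.zeros((n * p, n * p))
    for j in range(p):
        for k in range(p):
            m = k - j
            blk = Rk[m] if m >= 0 else Rk[-m].T
            M[j * n : (j + 1) * n, k * n : (k + 1) * n] = blk
    rhs = np.hstack([Rk[k + 1] for k in range(p)])  # (n, n*p)
    # R(k) = sum_j A_j M_{jk}  =>  rhs = [A_1 ... A_p] M
    A = np.linalg.solve(M.T, rhs.T).T
    Aj = [A[:, j * n : (j + 1) * n] for j in range(p)]
    sigma = Rk[0] - sum(Aj[j] @ Rk[j + 1].T for j in range(p))
    return MARModel(np.stack(Aj), 0.5 * (sigma + sigma.T), TR)


def sample_csd(
    Y: np.ndarray, grid: FrequencyGrid, p: int = 4, standardise: bool = False
) -> CrossSpectra:
    """Observed-data feature path: detrend -> MAR(p) -> rational spectrum."""
    Yd = detrend(Y)
    if standardise:
        s = Yd.std(axis=-1, ddof=0, keepdims=True)
        s[s == 0] = 1.0
        Yd = Yd / s
    mar = fit_mar(Yd, p=p, TR=grid.TR)
    return mar_to_csd(mar, grid)
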