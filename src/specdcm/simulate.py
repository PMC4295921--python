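"""Synthetic resting-state BOLD generation.

Endogenous neuronal fluctuations and observation noise are smooth AR(1)
processes (autoregressive coefficient 1/2 by default), each realisation
rescaled to a stated sample standard deviation (1/4 for the neuronal
fluctuations, 1/8 for observation noise, in the standard protocol).  The
fluctuations drive the stochastic neuronal + balloon system; BOLD is sampled
every TR and observation noise — generated at scan resolution, since it
corrupts measurements rather than dynamics — is added afterwards.

Integration
-----------
The default integrator (``method='rk4'``) is a fixed-step 4th-order
Runge-Kutta scheme on the full nonlinear drift at micro-steps of length
``dt`` (default TR/8), with the fluctuation path held piecewise-constant
within micro-steps.  ``method='linearised'`` instead propagates the
linearised state dynamics exactly (zero-order-hold:
``z[k+1] = exp(J dt) z[k] + J^{-1} (exp(J dt) - I) B v[k]`` with ``J`` the
full-system Jacobian at the resting fixed point) while keeping the nonlinear
BOLD read-out; it is faster and serves as a cross-check of the spectral
forward model.  Note the balloon model's log-flow state has a finite-time
singularity under sustained strong negative drive (flow reaching zero in
finite time); at physiological neurovascular efficacy the fluctuations stay
well clear of this regime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityParams, stability_analysis
from .hemodynamics import (
    N_STATES_PER_REGION,
    HemodynamicParams,
    bold_from_flat,
    full_drift,
    linearise_full_system,
)
from .connectivity import effective_jacobian

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "generate_ar1",
    "simulate_bold",
    "write_dataset",
    "read_dataset",
]


class NonstationarityError(ValueError):
    """AR coefficient outside the stationary region (|a| >= 1)."""


class DivergenceError(RuntimeError):
    """Integration produced a non-finite trajectory."""


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to generate one synthetic resting-state run."""

    conn: ConnectivityParams
    hemo: HemodynamicParams
    n_scans: int = 512
    TR: float = 2.0
    ar_coefficient: float = 0.5
    neural_sd: float = 0.25
    observation_sd: float = 0.125
    integration_dt: float | None = None  # default TR / 8
    seed: int = 0
    allow_unstable: bool = False
    method: str = "rk4"  # or "linearised" (exact ZOH of the linearised system)

    def __post_init__(self):
        if self.n_scans < 2:
            raise ValueError("n_scans must be >= 2")
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if abs(self.ar_coefficient) >= 1:
            raise NonstationarityError("|ar_coefficient| must be < 1")
        if self.neural_sd < 0 or self.observation_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        dt = self.integration_dt
        if dt is not None and not (0 < dt <= self.TR):
            raise ValueError("integration_dt must lie in (0, TR]")
        if self.method not in ("linearised", "rk4"):
            raise ValueError("method must be 'linearised' or 'rk4'")

    @property
    def dt(self) -> float:
        return self.TR / 8.0 if self.integration_dt is None else self.integration_dt

    def to_dict(self) -> dict:
        return {
            "conn": self.conn.to_dict(),
            "hemo": self.hemo.to_dict(),
            "n_scans": self.n_scans,
            "TR": self.TR,
            "ar_coefficient": self.ar_coefficient,
            "neural_sd": self.neural_sd,
            "observation_sd": self.observation_sd,
            "integration_dt": self.integration_dt,
            "seed": self.seed,
            "method": self.method,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        d = dict(d)
        d["conn"] = ConnectivityParams.from_dict(d["conn"])
        d["hemo"] = HemodynamicParams.from_dict(d["hemo"])
        return cls(**d)


@dataclass(frozen=True)
class SimulatedDataset:
    bold: np.ndarray  # (n_regions, n_scans), percent signal change
    hidden_states: np.ndarray  # (5n, T_fine)
    fluctuations: np.ndarray  # (n, T_fine) neuronal noise path
    observation_noise: np.ndarray  # (n, n_scans)
    ground_truth: SimulationSpec

    @property
    def n_regions(self) -> int:
        return self.bold.shape[0]


def generate_ar1(
    n_series: int, n_steps: int, coefficient: float, sd: float, seed
) -> np.ndarray:
    """Independent stationary AR(1) rows, each rescaled to sample sd ``sd``.

    ``seed`` may be an int or a ``numpy.random.Generator``.  The process is
    initialised from its stationary distribution; each row is then centred
    and rescaled so its *sample* standard deviation equals ``sd`` exactly
    (the 'scaled to a standard deviation of ...' reading).
    """
    if abs(coefficient) >= 1:
        raise NonstationarityError("|coefficient| must be < 1 for stationarity")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    innov = rng.standard_normal((n_series, n_steps))
    out = np.empty((n_series, n_steps))
    # stationary start: variance 1/(1-a^2) with unit innovations
    out[:, 0] = innov[:, 0] / np.sqrt(1.0 - coefficient**2)
    for t in range(1, n_steps):
        out[:, t] = coefficient * out[:, t - 1] + innov[:, t]
    if sd == 0.0:
        return np.zeros((n_series, n_steps))
    out -= out.mean(axis=1, keepdims=True)
    s = out.std(axis=1, ddof=0)
    s[s == 0] = 1.0
    return out * (sd / s)[:, None]


def simulate_bold(spec: SimulationSpec) -> SimulatedDataset:
    """Integrate the stochastic neuronal + haemodynamic system.

    Raises ``RuntimeWarning``-backed refusal for unstable systems unless
    ``spec.allow_unstable`` is set, and ``DivergenceError`` on non-finite
    trajectories.  Identical spec (including seed) gives bit-identical output.
    """
    conn, hemo = spec.conn, spec.hemo
    n = conn.n_regions
    stab = stability_analysis(conn)
    if not stab.stable and not spec.allow_unstable:
        raise RuntimeError(
            f"refusing to integrate unstable system (max Lyapunov "
            f"{stab.max_lyapunov:.4g} Hz); set allow_unstable to force"
        )

    dt = spec.dt
    steps_per_scan = max(1, int(round(spec.TR / dt)))
    dt = spec.TR / steps_per_scan
    t_fine = spec.n_scans * steps_per_scan

    ss = np.random.SeedSequence(spec.seed)
    rng_neural, rng_obs = [np.random.default_rng(s) for s in ss.spawn(2)]
    # fluctuations live at scan resolution (one AR(1) draw per TR, so the
    # 'scaled to sd ...' statement refers to the n_scans-length series) and
    # are held constant across the micro-steps within each scan
    fluct_scan = generate_ar1(
        n, spec.n_scans, spec.ar_coefficient, spec.neural_sd, rng_neural
    )
    fluct = np.repeat(fluct_scan, steps_per_scan, axis=1)
    obs_noise = generate_ar1(
        n, spec.n_scans, spec.ar_coefficient, spec.observation_sd, rng_obs
    )

    A = effective_jacobian(conn)
    ns = N_STATES_PER_REGION * n
    z = np.zeros(ns)
    hidden = np.empty((ns, t_fine))
    bold = np.empty((n, spec.n_scans))

    if spec.method == "linearised":
        import scipy.linalg

        J, B, _ = linearise_full_system(conn, hemo)
        E = scipy.linalg.expm(J * dt)
        # zero-order-hold input matrix: J^{-1} (E - I) B
        G = np.linalg.solve(J, (E - np.eye(ns)) @ B)
        k = 0
        for scan in range(spec.n_scans):
            for _ in range(steps_per_scan):
                z = E @ z + G @ fluct[:, k]
                hidden[:, k] = z
                k += 1
            if not np.all(np.isfinite(z)):
                raise DivergenceError(f"trajectory diverged at scan {scan}")
            bold[:, scan] = bold_from_flat(z, n, hemo)
    else:

        def f(state, v):
            return full_drift(state, conn, hemo, fluctuation=v, A=A)

        k = 0
        for scan in range(spec.n_scans):
            for _ in range(steps_per_scan):
                v = fluct[:, k]
                k1 = f(z, v)
                k2 = f(z + 0.5 * dt * k1, v)
                k3 = f(z + 0.5 * dt * k2, v)
                k4 = f(z + dt * k3, v)
                z = z + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                hidden[:, k] = z
                k += 1
            if not np.all(np.isfinite(z)):
                raise DivergenceError(f"trajectory diverged at scan {scan}")
            bold[:, scan] = bold_from_flat(z, n, hemo)

    bold = bold + obs_noise
    return SimulatedDataset(
        bold=bold,
        hidden_states=hidden,
        fluctuations=fluct,
        observation_noise=obs_noise,
        ground_truth=spec,
    )


def write_dataset(ds: SimulatedDataset, path) -> dict:
    """Write BOLD as CSV (scans as rows, one column per region) plus a JSON
    sidecar carrying TR, seed and the full ground-truth spec.

    Returns the paths written.  The round trip through ``read_dataset`` is
    bit-exact.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    labels = [f"region_{i + 1}" for i in range(ds.n_regions)]
    csv_path = path / "bold.csv"
    df = pd.DataFrame(ds.bold.T, columns=labels)
    df.to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "TR": ds.ground_truth.TR,
        "seed": ds.ground_truth.seed,
        "n_scans": int(ds.bold.shape[1]),
        "region_labels": labels,
        "orientation": "scans_by_regions",
        "ground_truth": ds.ground_truth.to_dict(),
    }
    json_path = path / "bold.json"
    json_path.write_text(json.dumps(sidecar, indent=1))
    return {"bold": csv_path, "sidecar": json_path}


def read_dataset(path):
    """Read a (bold.csv, bold.json) pair written by ``write_dataset``.

    Returns ``(bold, TR, sidecar)`` with ``bold`` of shape
    ``(n_regions, n_scans)``.
    """
    path = Path(path)
    csv_path = path / "bold.csv" if path.is_dir() else path
    json_path = csv_path.with_suffix(".json")
    df = pd.read_csv(csv_path, float_precision='round_trip')
    sidecar = json.loads(json_path.read_text()) if json_path.exists() else {}
    bold = df.to_numpy(dtype=float).T
    if sidecar.get("orientation") == "regions_by_scans":
        bold = bold.T
    return bold, sidecar.get("TR"), sidecar


def read_timeseries(csv_path, tr: float | None = None, transpose: bool = False):
    """Read an arbitrary region-by-time (or time-by-region) CSV/TSV matrix.

    Rows are taken as scans unless ``transpose`` is set.  ``tr`` overrides
    any sidecar value.
    """
    csv_path = Path(csv_path)
    sep = "\t" if csv_path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(csv_path, sep=sep, float_precision='round_trip')
    bold = df.to_numpy(dtype=float).T
    if transpose:
        bold = bold.T
    sidecar_path = csv_path.with_suffix(".json")
    if tr is None and sidecar_path.exists():
        tr = json.loads(sidecar_path.read_text()).get("TR")
    if tr is None:
        raise ValueError("repetition time not given and no sidecar found; pass tr=")
    return bold, float(tr)
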