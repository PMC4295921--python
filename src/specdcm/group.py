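"""Post-inversion statistics.

Root-mean-square estimation error, Bayesian parameter averaging (BPA) of
per-subject Gaussian posteriors, analytic Bayesian model reduction (post-hoc
model optimisation) and classical two-sample t-tests on posterior means.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .inversion import Posterior, PriorSpec

__all__ = [
    "rms_error",
    "bpa",
    "bmr_reduce",
    "bmr_search",
    "group_ttest",
    "GroupResult",
]


def rms_error(true_params: np.ndarray, estimated: np.ndarray) -> float:
    """Root mean squared error between true and estimated parameter vectors
    (Hz for coupling parameters): ``sqrt(mean((theta - theta_hat)**2))``."""
    t = np.asarray(true_params, dtype=float).reshape(-1)
    e = np.asarray(estimated, dtype=float).reshape(-1)
    if t.shape != e.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {e.shape}")
    if t.size < 1:
        raise ValueError("need at least one parameter")
    return float(np.sqrt(np.mean((t - e) ** 2)))


def _safe_inv(C: np.ndarray, what: str) -> np.ndarray:
    try:
        ev_min = np.min(np.linalg.eigvalsh(0.5 * (C + C.T)))
        if ev_min <= 0:
            raise np.linalg.LinAlgError
        return np.linalg.inv(C)
    except np.linalg.LinAlgError:
        warnings.warn(f"singular {what}; using ridge-regularised inverse", RuntimeWarning)
        lam = 1e-8 * max(np.trace(C) / C.shape[0], 1e-12)
        return np.linalg.inv(C + lam * np.eye(C.shape[0]))


def bpa(
    posteriors: list[Posterior],
    correct_prior: bool = True,
    diagonal: bool = False,
) -> Posterior:
    """Precision-weighted (fixed-effects) Bayesian parameter average.

    With ``correct_prior`` (default) the shared prior precision is counted
    once rather than k times: ``P_bpa = sum_i P_i - (k-1) P_0``.  With
    ``diagonal`` the subject covariances are reduced to their diagonals
    (posterior correlations ignored) before averaging.
    """
    if len(posteriors) == 0:
        raise ValueError("need at least one posterior")
    if len(posteriors) == 1:
        return posteriors[0]
    k = len(posteriors)
    covs = [p.covariance for p in posteriors]
    if diagonal:
        covs = [np.diag(np.diag(C)) for C in covs]
    precisions = [_safe_inv(C, "subject covariance") for C in covs]
    P_sum = np.sum(precisions, axis=0)
    b = np.sum([P @ p.mean for P, p in zip(precisions, posteriors)], axis=0)
    prior = posteriors[0].priors
    if correct_prior and prior is not None:
        P0 = _safe_inv(prior.covariance, "prior covariance")
        P_sum = P_sum - (k - 1) * P0
        b = b - (k - 1) * (P0 @ prior.mean)
    C_bpa = _safe_inv(P_sum, "pooled precision")
    mu_bpa = C_bpa @ b
    first = posteriors[0]
    return Posterior(
        mean=mu_bpa,
        covariance=0.5 * (C_bpa + C_bpa.T),
        free_energy=float(np.sum([p.free_energy for p in posteriors])),
        hyper_posterior={},
        n_iterations=0,
        converged=all(p.converged for p in posteriors),
        param_map=first.param_map,
        priors=first.priors,
        base_hemo=first.base_hemo,
        grid=first.grid,
    )


def replace_posterior(post: Posterior, priors: PriorSpec) -> Posterior:
    """A copy of ``post`` carrying a different prior specification."""
    import dataclasses

    return dataclasses.replace(post, priors=priors)


def bmr_reduce(
    full: Posterior, priors: PriorSpec, reduced_priors: PriorSpec
) -> tuple[float, Posterior]:
    """Analytic evidence change and posterior for a reduced model.

    Given the full model's Gaussian prior and posterior, the evidence and
    posterior of a model that differs only in its (typically shrunken) prior
    follow in closed form, without re-inversion:

        S  = qP + rP - pP            (reduced posterior precision)
        dF = (ln|qP| + ln|rP| - ln|pP| - ln|S|)/2 - (c - b' S^-1 b)/2

    with ``b = qP qE + rP rE - pP pE`` and
    ``c = qE' qP qE + rE' rP rE - pE' pP pE``.  ``dF = 0`` exactly when the
    reduced prior equals the full prior.
    """
    pE, pC = priors.mean, priors.covariance
    rE, rC = reduced_priors.mean, reduced_priors.covariance
    qE, qC = full.mean, full.covariance
    if np.array_equal(pE, rE) and np.array_equal(pC, rC):
        # identical priors: the identity is exact, no algebra needed
        return 0.0, replace_posterior(full, reduced_priors)
    pP = _safe_inv(pC, "prior covariance")
    rP = _safe_inv(rC, "reduced prior covariance")
    qP = _safe_inv(qC, "posterior covariance")
    S = qP + rP - pP
    ev = np.linalg.eigvalsh(0.5 * (S + S.T))
    if np.min(ev) <= 0:
        raise np.linalg.LinAlgError(
            "reduced posterior precision is not positive definite"
        )
    b = qP @ qE + rP @ rE - pP @ pE
    sE = np.linalg.solve(S, b)
    c = float(qE @ qP @ qE + rE @ rP @ rE - pE @ pP @ pE)
    logdet = lambda M: float(np.linalg.slogdet(M)[1])
    dF = 0.5 * (logdet(qP) + logdet(rP) - logdet(pP) - logdet(S)) - 0.5 * (
        c - float(b @ sE)
    )
    sC = np.linalg.inv(S)
    reduced = Posterior(
        mean=sE,
        covariance=0.5 * (sC + sC.T),
        free_energy=full.free_energy + dF,
        hyper_posterior=full.hyper_posterior,
        n_iterations=0,
        converged=full.converged,
        param_map=full.param_map,
        priors=reduced_priors,
        base_hemo=full.base_hemo,
        grid=full.grid,
        data_scale=full.data_scale,
    )
    return float(dF), reduced


def bmr_search(
    full: Posterior,
    priors: PriorSpec,
    candidate_indices,
    off_variance: float = 1e-8,
    exhaustive_limit: int = 12,
):
    """Search over models formed by switching off subsets of connections.

    Switching a connection off means shrinking its prior variance to
    ``off_variance`` (pinning it to the prior mean).  Exhaustive over all
    2^k subsets when ``k <= exhaustive_limit``; otherwise greedy backward
    pruning (best single removal, iterated while evidence improves).

    Returns ``(best_subset_off, best_dF, table)`` where ``table`` is a list
    of ``(subset_off, dF)`` for every model visited.
    """
    candidates = list(np.atleast_1d(candidate_indices))
    k = len(candidates)
    table = []
    if k <= exhaustive_limit:
        best = ((), 0.0)
        for r in range(k + 1):
            for subset in itertools.combinations(candidates, r):
                dF = 0.0 if not subset else bmr_reduce(
                    full, priors, priors.shrink(list(subset), off_variance)
                )[0]
                table.append((subset, dF))
                if dF > best[1]:
                    best = (subset, dF)
        return best[0], best[1], table
    # greedy backward pruning
    current: tuple = ()
    current_dF = 0.0
    table.append(((), 0.0))
    remaining = list(candidates)
    improved = True
    while improved and remaining:
        improved = False
        best_step = None
        for c in remaining:
            subset = tuple(sorted(current + (c,)))
            dF = bmr_reduce(full, priors, priors.shrink(list(subset), off_variance))[0]
            table.append((subset, dF))
            if dF > current_dF and (best_step is None or dF > best_step[1]):
                best_step = (c, dF)
        if best_step is not None:
            current = tuple(sorted(current + (best_step[0],)))
            current_dF = best_step[1]
            remaining.remove(best_step[0])
            improved = True
    return current, current_dF, table


@dataclass
class GroupResult:
    """Per-connection two-sample comparison summary."""

    mean_difference: np.ndarray  # group A - group B, per connection
    t_statistics: np.ndarray
    dof: int
    p_values: np.ndarray
    n_tests: int
    uncorrected_threshold: float  # |t| threshold at p = 0.05
    corrected_threshold: float  # Bonferroni over n_tests
    infinite_t: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    bpa_difference: np.ndarray | None = None
    bpa_ci: tuple | None = None

    @property
    def significant_uncorrected(self) -> np.ndarray:
        return np.abs(self.t_statistics) > self.uncorrected_threshold

    @property
    def significant_corrected(self) -> np.ndarray:
        return np.abs(self.t_statistics) > self.corrected_threshold


def group_ttest(
    groupA: np.ndarray,
    groupB: np.ndarray,
    n_tests: int | None = None,
    alpha: float = 0.05,
) -> GroupResult:
    """Univariate two-sample t-tests per connection.

    ``groupA``/``groupB`` are subjects-by-connections matrices of posterior
    means (summary statistics).  Thresholds are |t| criticals at ``alpha``
    two-sided, uncorrected and Bonferroni-corrected over ``n_tests``
    (defaults to the connection count, self-connections included).
    """
    A = np.atleast_2d(np.asarray(groupA, dtype=float))
    B = np.atleast_2d(np.asarray(groupB, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups disagree on connection count")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    m = A.shape[1]
    n_tests = m if n_tests is None else int(n_tests)
    dof = A.shape[0] + B.shape[0] - 2
    diff = A.mean(axis=0) - B.mean(axis=0)

    # pooled-variance two-sample t with an infinite-t guard
    ssA = ((A - A.mean(axis=0)) ** 2).sum(axis=0)
    ssB = ((B - B.mean(axis=0)) ** 2).sum(axis=0)
    sp2 = (ssA + ssB) / dof
    se = np.sqrt(sp2 * (1.0 / A.shape[0] + 1.0 / B.shape[0]))
    infinite = (se == 0) & (diff != 0)
    t = np.zeros(m)
    ok = se > 0
    t[ok] = diff[ok] / se[ok]
    t[infinite] = np.sign(diff[infinite]) * np.inf
    if np.any(infinite):
        warnings.warn("zero within-group variance: infinite t flagged", RuntimeWarning)
    p = 2.0 * scipy.stats.t.sf(np.abs(t), dof)
    return GroupResult(
        mean_difference=diff,
        t_statistics=t,
        dof=dof,
        p_values=p,
        n_tests=n_tests,
        uncorrected_threshold=float(scipy.stats.t.ppf(1 - alpha / 2, dof)),
        corrected_threshold=float(scipy.stats.t.ppf(1 - alpha / (2 * n_tests), dof)),
        infinite_t=infinite,
    )
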