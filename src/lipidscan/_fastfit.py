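"""Lightweight Newton solvers for logistic and Cox log-likelihoods.

Cross-validated stepwise selection evaluates thousands of candidate model
fits per fold; these solvers compute coefficients and log-likelihoods with
plain numpy so the selection and the 200-repeat replication evaluation run
in seconds.  They are validated in the test suite against statsmodels
(logistic) and lifelines (Cox, Efron ties, left truncation) on identical
data.  The public per-lipid association API (:mod:`lipidscan.stats`) stays
on statsmodels/lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["logistic_fit", "cox_fit", "CoxPrep"]

_MAX_ITER = 60
_TOL = 1e-9


def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, bool]:
    """Newton-Raphson MLE for logistic regression.

    ``X`` must include the intercept column.  Returns (beta, loglik,
    converged); step-halving guards against overshoot, and fits drifting
    toward separation report ``converged=False``.
    """
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.astype(float).copy()

    def loglik(b: np.ndarray) -> float:
        eta = X @ b
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    ll = loglik(beta)
    for _ in range(_MAX_ITER):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            return beta, ll, False
        t = 1.0
        for _ in range(20):
            cand = beta + t * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        else:
            return beta, ll, False
        moved = np.max(np.abs(t * step))
        beta, ll = cand, ll_new
        if moved < _TOL * (1.0 + np.max(np.abs(beta))):
            break
    converged = np.max(np.abs(beta)) < 30.0 and np.isfinite(ll)
    return beta, ll, bool(converged)


@dataclass
class CoxPrep:
    """Precomputed risk-set bookkeeping for one (entry, time, event) triplet.

    Risk sets at each event time t are {i : entry_i < t <= time_i}; their
    sums are evaluated as suffix sums over rows sorted by exit time minus
    suffix sums over rows sorted by entry time, which vectorises the
    partial-likelihood evaluation over event times.
    """

    death_rows: np.ndarray  # all event rows
    ev_times: np.ndarray  # unique event times
    order_time: np.ndarray
    order_entry: np.ndarray
    pos_time: np.ndarray  # per event time: first sorted-time row with time >= t
    pos_entry: np.ndarray  # per event time: first sorted-entry row with entry >= t
    single: np.ndarray  # boolean: event time has exactly one death
    tied_groups: list[np.ndarray]  # death rows per tied event time
    tied_pos: np.ndarray  # indices into ev_times of tied times


def cox_prep(entry: np.ndarray, time: np.ndarray, event: np.ndarray) -> CoxPrep:
    entry = np.asarray(entry, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    death_rows = np.flatnonzero(event)
    ev_times, counts = np.unique(time[event], return_counts=True)
    order_time = np.argsort(time, kind="stable")
    order_entry = np.argsort(entry, kind="stable")
    pos_time = np.searchsorted(time[order_time], ev_times, side="left")
    pos_entry = np.searchsorted(entry[order_entry], ev_times, side="left")
    single = counts == 1
    tied_pos = np.flatnonzero(~single)
    tied_groups = [
        np.flatnonzero(event & (time == ev_times[j])) for j in tied_pos
    ]
    return CoxPrep(
        death_rows, ev_times, order_time, order_entry, pos_time, pos_entry,
        single, tied_groups, tied_pos,
    )


def cox_fit(
    entry: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    beta0: np.ndarray | None = None,
    prep: CoxPrep | None = None,
) -> tuple[np.ndarray, float, bool]:
    """Newton MLE of the Cox partial likelihood (Efron ties, left truncation).

    ``prep`` may carry :func:`cox_prep` output so repeated fits on the same
    survival triplet (stepwise candidate loops) skip the sorting.  Returns
    (beta, partial loglik, converged).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.astype(float).copy()
    if prep is None:
        prep = cox_prep(entry, time, event)

    def quantities(b: np.ndarray, with_derivs: bool = True):
        eta = X @ b
        c = eta.max()
        r = np.exp(eta - c)  # rescaled; every log s0 gains +c, cancelled below
        rX = r[:, None] * X
        # suffix sums along the two sort orders
        sfx_t0 = np.concatenate([np.cumsum(r[prep.order_time][::-1])[::-1], [0.0]])
        sfx_e0 = np.concatenate([np.cumsum(r[prep.order_entry][::-1])[::-1], [0.0]])
        S0 = sfx_t0[prep.pos_time] - sfx_e0[prep.pos_entry]
        if with_derivs:
            sfx_t1 = np.vstack(
                [np.cumsum(rX[prep.order_time][::-1], axis=0)[::-1], np.zeros((1, p))]
            )
            sfx_e1 = np.vstack(
                [np.cumsum(rX[prep.order_entry][::-1], axis=0)[::-1], np.zeros((1, p))]
            )
            S1 = sfx_t1[prep.pos_time] - sfx_e1[prep.pos_entry]
            rXX = np.einsum("ni,nj->nij", rX, X)
            sfx_t2 = np.concatenate(
                [np.cumsum(rXX[prep.order_time][::-1], axis=0)[::-1],
                 np.zeros((1, p, p))]
            )
            sfx_e2 = np.concatenate(
                [np.cumsum(rXX[prep.order_entry][::-1], axis=0)[::-1],
                 np.zeros((1, p, p))]
            )
            S2 = sfx_t2[prep.pos_time] - sfx_e2[prep.pos_entry]

        # untied event times: a single Breslow(=Efron) denominator term each
        sg = prep.single
        ll = float(eta[prep.death_rows].sum() - np.log(S0[sg]).sum() - sg.sum() * c)
        if with_derivs:
            grad = X[prep.death_rows].sum(axis=0) - (S1[sg] / S0[sg, None]).sum(axis=0)
            H = (
                np.einsum("eij,e->ij", S2[sg], 1.0 / S0[sg])
                - np.einsum("ei,ej,e->ij", S1[sg], S1[sg], 1.0 / S0[sg] ** 2)
            )
        else:
            grad = H = None

        # tied event times: exact Efron terms
        for j, D in zip(prep.tied_pos, prep.tied_groups):
            d = D.size
            s0R, s0D = S0[j], r[D].sum()
            if with_derivs:
                s1R, s1D = S1[j], rX[D].sum(axis=0)
                s2R = S2[j]
                s2D = rX[D].T @ X[D]
            for l in range(d):
                f = l / d
                s0 = s0R - f * s0D
                ll -= np.log(s0) + c
                if with_derivs:
                    s1 = s1R - f * s1D
                    s2 = s2R - f * s2D
                    grad -= s1 / s0
                    H += s2 / s0 - np.outer(s1, s1) / s0**2
        return ll, grad, H

    ll, grad, H = quantities(beta)
    for _ in range(_MAX_ITER):
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            return beta, ll, False
        t = 1.0
        for _ in range(20):
            cand = beta + t * step
            ll_new, grad_new, H_new = quantities(cand)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        else:
            return beta, ll, False
        moved = np.max(np.abs(t * step))
        beta, ll, grad, H = cand, ll_new, grad_new, H_new
        if moved < _TOL * (1.0 + np.max(np.abs(beta))):
            break
    converged = np.max(np.abs(beta)) < 30.0 and np.isfinite(ll)
    return beta, ll, bool(converged)
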