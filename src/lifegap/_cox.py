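"""Newton solver for the Cox partial likelihood with a single categorical
covariate on a left-truncated (counting-process) time scale.

Episodes enter the risk set at ``start`` and leave at ``stop`` (at risk
at time t iff ``start < t <= stop``), which implements delayed entry on
the attained-age scale.  Because the covariate is categorical with a
handful of levels, the likelihood, gradient and Hessian reduce to
per-group sufficient statistics at each distinct event time: the
at-risk weight ``n_g(t)`` and the death weight ``d_g(t)`` per group.
One Newton iteration is therefore O(number of deaths x groups),
independent of the number of episodes, and tied event times (ubiquitous
with one-year episodes ending at integer ages) are handled exactly by
the Efron or Breslow correction.
"""

from __future__ import annotations

import numpy as np


class ConvergenceError(RuntimeError):
    """Partial-likelihood maximization failed to converge."""


def _risk_weights(start, stop, weights, group, n_groups, times):
    """At-risk weight per group at each time: sum of w over start < t <= stop."""
    K = len(times)
    n = np.zeros((K, n_groups))
    for g in range(n_groups):
        sel = group == g
        if not sel.any():
            continue
        ws = weights[sel]
        o_s = np.argsort(start[sel], kind="stable")
        o_e = np.argsort(stop[sel], kind="stable")
        s = start[sel][o_s]
        e = stop[sel][o_e]
        cw_s = np.concatenate([[0.0], np.cumsum(ws[o_s])])
        cw_e = np.concatenate([[0.0], np.cumsum(ws[o_e])])
        entered = cw_s[np.searchsorted(s, times, side="left")]
        left = cw_e[np.searchsorted(e, times, side="left")]
        n[:, g] = entered - left
    return n


def _suffstats(start, stop, event, group, weights, n_groups):
    times = np.unique(stop[event])
    K = len(times)
    n_at_risk = _risk_weights(start, stop, weights, group, n_groups, times)
    dw = np.zeros((K, n_groups))
    dc = np.zeros(K, dtype=np.int64)
    ev_t = stop[event]
    ev_g = group[event]
    ev_w = weights[event]
    k_idx = np.searchsorted(times, ev_t)
    np.add.at(dw, (k_idx, ev_g), ev_w)
    np.add.at(dc, k_idx, 1)
    return times, n_at_risk, dw, dc


def _loglik_grad_hess(beta, n_at_risk, dw, dc, frac, rep, wbar):
    eb = np.exp(beta)
    Rk = n_at_risk * eb
    Dk = dw * eb
    r = Rk[rep] - frac[:, None] * Dk[rep]
    phi = r.sum(axis=1)
    if np.any(phi <= 0):
        return -np.inf, None, None
    wp = wbar[rep] / phi
    ll = float(dw.sum(axis=0) @ beta - wbar[rep] @ np.log(phi))
    grad = dw.sum(axis=0) - wp @ r
    s1 = (wp[:, None] * r).sum(axis=0)
    M = r.T @ (r * (wp / phi)[:, None])
    hess = -(np.diag(s1) - M)
    return ll, grad, hess


def fit_cox_categorical(
    start,
    stop,
    event,
    group,
    n_groups: int,
    *,
    ties: str = "efron",
    weights=None,
    ref: int | None = None,
    gtol: float = 1e-9,
    max_iter: int = 100,
):
    """Maximize the partial likelihood for a categorical covariate.

    Parameters
    ----------
    start, stop, event, group
        Episode arrays; ``group`` holds integer codes in ``[0, n_groups)``.
    ties
        ``"efron"`` (default) or ``"breslow"`` correction for tied
        event times.
    weights
        Optional case weights (survey-weight hook); default 1.
    ref
        Reference group whose coefficient is fixed at 0; defaults to
        the group with the largest total weight.

    Returns
    -------
    dict with ``beta`` (length ``n_groups``, reference-coded),
    ``cov`` (observed-information covariance, reference row/col zero),
    ``loglik``, ``n_iter`` and ``ref``.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie correction {ties!r}")
    start = np.asarray(start, dtype=float)
    stop = np.asarray(stop, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group, dtype=np.int64)
    weights = (
        np.ones_like(start) if weights is None else np.asarray(weights, dtype=float)
    )
    if np.any(stop <= start):
        raise ValueError("episodes must satisfy stop > start")
    if not event.any():
        raise ValueError("no events: partial likelihood is undefined")

    times, n_at_risk, dw, dc = _suffstats(start, stop, event, group, weights, n_groups)
    K = len(times)
    offsets = np.cumsum(dc) - dc
    rep = np.repeat(np.arange(K), dc)
    j = np.arange(dc.sum()) - np.repeat(offsets, dc)
    frac = j / dc[rep] if ties == "efron" else np.zeros(len(rep))
    wbar = dw.sum(axis=1) / dc  # mean death weight per tied set

    if ref is None:
        ref = int(np.argmax(np.bincount(group, weights=weights, minlength=n_groups)))
    free = np.array([g for g in range(n_groups) if g != ref])

    beta = np.zeros(n_groups)
    ll, grad, hess = _loglik_grad_hess(beta, n_at_risk, dw, dc, frac, rep, wbar)
    n_iter = 0
    # gradient tolerance scales with the total death weight so tiny and
    # large strata converge to comparable relative precision
    thr = gtol * max(1.0, float(dw.sum()))
    if free.size:
        for n_iter in range(1, max_iter + 1):
            g_free = grad[free]
            if np.max(np.abs(g_free)) < thr:
                break
            H_free = hess[np.ix_(free, free)]
            try:
                delta = np.linalg.solve(-H_free, g_free)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(
                    f"singular information matrix at iteration {n_iter} "
                    f"(loglik={ll:.6g})"
                ) from exc
            step = 1.0
            stalled = False
            for _ in range(40):
                cand = beta.copy()
                cand[free] += step * delta
                ll_new, grad_new, hess_new = _loglik_grad_hess(
                    cand, n_at_risk, dw, dc, frac, rep, wbar
                )
                if ll_new > ll - 1e-12 * max(1.0, abs(ll)):
                    break
                step *= 0.5
            else:
                stalled = True
            if stalled:
                if np.max(np.abs(g_free)) < 1e3 * thr:
                    break  # at the optimum to floating-point precision
                raise ConvergenceError(
                    f"step halving failed at iteration {n_iter} (loglik={ll:.6g}, "
                    f"gradient norm {np.max(np.abs(g_free)):.3g})"
                )
            beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        else:
            raise ConvergenceError(
                f"no convergence in {max_iter} iterations "
                f"(gradient norm {np.max(np.abs(grad[free])):.3g})"
            )

    cov = np.zeros((n_groups, n_groups))
    if free.size:
        cov[np.ix_(free, free)] = np.linalg.inv(-hess[np.ix_(free, free)])
    return {"beta": beta, "cov": cov, "loglik": ll, "n_iter": n_iter, "ref": int(ref)}
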