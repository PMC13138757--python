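"""Numerical workhorses for the penalized screening step.

Two compiled solvers live here:

* a FISTA proximal-gradient solver for the rank-based (Gehan) AFT loss
  with an elastic-net penalty, using a Huber-smoothed hinge so the loss
  is differentiable (smoothing width ``h`` is fixed per fit, so the
  optimized objective is well defined);
* a cyclic coordinate-descent solver for penalized least squares with
  MCP, lasso or elastic-net penalties.

Both solve a whole descending lambda path with warm starts and return
exact zeros for inactive coefficients.  Inputs are expected to be
column-standardized; callers rescale coefficients afterwards.
"""

from __future__ import annotations

import numpy as np
from numba import njit

FAMILY_MCP = 0
FAMILY_ENET = 1  # includes lasso at alpha_mix = 1


@njit(cache=True)
def _smoothed_gehan_grad(e, delta, h, n):
    """Gradient weights of the smoothed Gehan loss wrt residuals.

    Returns the vector c with grad_beta = X.T @ c / n^2: with residuals
    e = y - X beta, pair (i, j) contributes s'(e_j - e_i) * (x_i - x_j).
    """
    c = np.zeros(n)
    for i in range(n):
        if delta[i] > 0.0:
            ei = e[i]
            for j in range(n):
                u = e[j] - ei
                if u > 0.0:
                    w = u / h if u < h else 1.0
                    c[j] -= w
                    c[i] += w
    return c


@njit(cache=True)
def smoothed_gehan_loss(e, delta, h, n):
    total = 0.0
    for i in range(n):
        if delta[i] > 0.0:
            ei = e[i]
            for j in range(n):
                u = e[j] - ei
                if u > 0.0:
                    total += 0.5 * u * u / h if u < h else u - 0.5 * h
    return total / (n * n)


@njit(cache=True)
def _smoothed_gehan_loss_grad_ref(X, beta, y, delta, h, ridge):
    """O(n^2) reference: smoothed Gehan loss (+ ridge) and gradient at beta."""
    n, d = X.shape
    e = y - X @ beta
    c = np.zeros(n)
    total = 0.0
    for i in range(n):
        if delta[i] > 0.0:
            ei = e[i]
            for j in range(n):
                u = e[j] - ei
                if u > 0.0:
                    if u < h:
                        total += 0.5 * u * u / h
                        w = u / h
                    else:
                        total += u - 0.5 * h
                        w = 1.0
                    c[j] -= w
                    c[i] += w
    n2 = float(n * n)
    loss = total / n2
    grad = (X.T @ c) / n2
    if ridge > 0.0:
        loss += 0.5 * ridge * (beta @ beta)
        grad += ridge * beta
    return loss, grad


@njit(cache=True)
def _bisect_left(a, v):
    lo, hi = 0, len(a)
    while lo < hi:
        mid = (lo + hi) // 2
        if a[mid] < v:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def _smoothed_gehan_loss_grad(X, beta, y, delta, h, ridge):
    """Smoothed Gehan loss (+ ridge term) and its gradient at beta.

    Sort-based O(n log n + mid-zone) evaluation: pairs separated by at
    least the smoothing width h carry weight exactly 1 and are counted
    with prefix sums; only pairs inside the narrow mid zone (residual
    difference in (0, h)) are visited explicitly.  Equivalent to the
    O(n^2) reference (checked in the test suite).
    """
    n, d = X.shape
    e = y - X @ beta
    order = np.argsort(e)
    es = np.empty(n)
    ev_sorted = np.empty(n)
    for k in range(n):
        es[k] = e[order[k]]
        ev_sorted[k] = delta[order[k]]
    # prefix sums over sorted residuals: all points, and event points only
    cnt_ev = np.zeros(n + 1)       # number of events among first k sorted points
    suf_sum = np.zeros(n + 1)      # suffix sum of es[k:]
    for k in range(n):
        cnt_ev[k + 1] = cnt_ev[k] + (1.0 if ev_sorted[k] > 0 else 0.0)
    for k in range(n - 1, -1, -1):
        suf_sum[k] = suf_sum[k + 1] + es[k]

    c_sorted = np.zeros(n)
    total = 0.0

    for k in range(n):
        ek = es[k]
        # A_k: sum over events i below, of w(ek - e_i); far zone e_i <= ek - h
        p = _bisect_left(es, ek - h)
        a_far = cnt_ev[p]
        a_mid = 0.0
        for m in range(p, k):
            if ev_sorted[m] > 0:
                u = ek - es[m]
                if u > 0.0:
                    a_mid += u / h
        c_sorted[k] -= a_far + a_mid
        if ev_sorted[k] > 0:
            # B_k: sum over points l above, of w(e_l - ek); far zone e_l >= ek + h
            q = _bisect_left(es, ek + h)
            b_far = float(n - q)
            b_mid = 0.0
            for m in range(k + 1, q):
                u = es[m] - ek
                if u > 0.0:
                    b_mid += u / h
            c_sorted[k] += b_far + b_mid
            # loss: far pairs contribute u - h/2, mid pairs u^2/(2h)
            total += (suf_sum[q] - ek * (n - q)) - 0.5 * h * (n - q)
            for m in range(k + 1, q):
                u = es[m] - ek
                if u > 0.0:
                    total += 0.5 * u * u / h

    c = np.zeros(n)
    for k in range(n):
        c[order[k]] = c_sorted[k]
    n2 = float(n * n)
    loss = total / n2
    grad = (X.T @ c) / n2
    if ridge > 0.0:
        loss += 0.5 * ridge * (beta @ beta)
        grad += ridge * beta
    return loss, grad


@njit(cache=True)
def _fast_smoothed_loss(e, delta, h):
    """Sort-based smoothed Gehan loss from residuals only (no gradient)."""
    n = len(e)
    es = np.sort(e)
    # mark which sorted entries are events by re-sorting pairs
    order = np.argsort(e)
    total = 0.0
    suf_sum = np.zeros(n + 1)
    for k in range(n - 1, -1, -1):
        suf_sum[k] = suf_sum[k + 1] + es[k]
    for k in range(n):
        if delta[order[k]] > 0.0:
            ek = es[k]
            q = _bisect_left(es, ek + h)
            total += (suf_sum[q] - ek * (n - q)) - 0.5 * h * (n - q)
            for m in range(k + 1, q):
                u = es[m] - ek
                if u > 0.0:
                    total += 0.5 * u * u / h
    return total / (n * n)


@njit(cache=True)
def _kkt_violation(X, beta, y, delta, h, ridge, thr):
    """Max KKT residual of the l1-penalized smoothed problem at beta."""
    _, grad = _smoothed_gehan_loss_grad(X, beta, y, delta, h, ridge)
    worst = 0.0
    for j in range(len(beta)):
        if beta[j] == 0.0:
            v = abs(grad[j]) - thr
            if v > worst:
                worst = v
        else:
            sgn = 1.0 if beta[j] > 0.0 else -1.0
            v = abs(grad[j] + thr * sgn)
            if v > worst:
                worst = v
    return worst


@njit(cache=True)
def fista_gehan_path(X, y, delta, lambdas, alpha_mix, h, lip, tol, max_iter, beta_init):
    """Elastic-net penalized smoothed-Gehan fits along a descending lambda path.

    FISTA with backtracking line search, Nesterov momentum, adaptive
    restart and warm starts; convergence is declared on the KKT residual
    of the penalized smoothed problem.  Returns (betas, n_iter, conv)
    with betas of shape (L, d).
    """
    n, d = X.shape
    L = len(lambdas)
    betas = np.zeros((L, d))
    iters = np.zeros(L, np.int64)
    conv = np.zeros(L, np.uint8)
    beta = beta_init.copy()
    lam_scale = lambdas[0] if lambdas[0] > 0 else 1.0
    step = 4.0 / lip if lip > 0 else 1.0
    for li in range(L):
        lam = lambdas[li]
        ridge = lam * (1.0 - alpha_mix)
        thr = lam * alpha_mix
        kkt_tol = tol * max(lam_scale, 1e-12) * 10.0
        z = beta.copy()
        cand = beta.copy()
        tk = 1.0
        ok = False
        fz, gz = _smoothed_gehan_loss_grad(X, z, y, delta, h, ridge)
        it = 0
        while it < max_iter:
            it += 1
            # backtracking: find step with f(cand) <= quadratic model at z
            for _bt in range(60):
                for jd in range(d):
                    v = z[jd] - step * gz[jd]
                    av = abs(v) - step * thr
                    cand[jd] = (av if av > 0.0 else 0.0) * (1.0 if v > 0.0 else -1.0)
                ec = y - X @ cand
                fc = _fast_smoothed_loss(ec, delta, h)
                if ridge > 0.0:
                    fc += 0.5 * ridge * (cand @ cand)
                q = fz
                sq = 0.0
                for jd in range(d):
                    dj = cand[jd] - z[jd]
                    q += gz[jd] * dj
                    sq += dj * dj
                q += sq / (2.0 * step)
                if fc <= q + 1e-12:
                    break
                step *= 0.5
            tk1 = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
            mom = (tk - 1.0) / tk1
            dot = 0.0
            for jd in range(d):
                dot += (z[jd] - cand[jd]) * (cand[jd] - beta[jd])
            if dot > 0.0:
                tk1 = 1.0
                for jd in range(d):
                    z[jd] = cand[jd]
            else:
                for jd in range(d):
                    z[jd] = cand[jd] + mom * (cand[jd] - beta[jd])
            tk = tk1
            for jd in range(d):
                beta[jd] = cand[jd]
            if it % 10 == 0 or it == 1:
                if _kkt_violation(X, beta, y, delta, h, ridge, thr) <= kkt_tol:
                    ok = True
                    break
            fz, gz = _smoothed_gehan_loss_grad(X, z, y, delta, h, ridge)
            step *= 1.25  # allow the step to grow back between iterations
        iters[li] = it
        conv[li] = 1 if ok else 0
        betas[li] = beta
    return betas, iters, conv


@njit(cache=True)
def cd_ls_path(X, y, lambdas, gamma, alpha_mix, family, tol, max_iter, beta_init):
    """Penalized least squares (1/2n)||y - Xb||^2 + penalty along a lambda path.

    X must have columns with mean 0 and variance 1 (x_j'x_j / n = 1).
    family: 0 = MCP (gamma > 1), 1 = elastic net / lasso.
    """
    n, d = X.shape
    L = len(lambdas)
    betas = np.zeros((L, d))
    conv = np.zeros(L, np.uint8)
    beta = beta_init.copy()
    r = y - X @ beta
    for li in range(L):
        lam = lambdas[li]
        ok = False
        for it in range(max_iter):
            move = 0.0
            size = 0.0
            for j in range(d):
                bj = beta[j]
                z = 0.0
                for i in range(n):
                    z += X[i, j] * r[i]
                z = z / n + bj
                if family == FAMILY_MCP:
                    az = abs(z)
                    if az <= gamma * lam:
                        s = az - lam
                        bnew = 0.0 if s <= 0.0 else (s / (1.0 - 1.0 / gamma)) * (
                            1.0 if z > 0.0 else -1.0
                        )
                    else:
                        bnew = z
                else:
                    s = abs(z) - lam * alpha_mix
                    bnew = (
                        0.0
                        if s <= 0.0
                        else (s / (1.0 + lam * (1.0 - alpha_mix))) * (1.0 if z > 0.0 else -1.0)
                    )
                if bnew != bj:
                    db = bnew - bj
                    for i in range(n):
                        r[i] -= X[i, j] * db
                    beta[j] = bnew
                    if abs(db) > move:
                        move = abs(db)
                if abs(beta[j]) > size:
                    size = abs(beta[j])
            if move < tol * (1.0 + size):
                ok = True
                break
        conv[li] = 1 if ok else 0
        betas[li] = beta
    return betas, conv
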