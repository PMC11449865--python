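"""Compiled inner loops for FOCE-I.

Each subject's conditional-mode problem is solved independently: the
conditional objective is evaluated on a small η grid (0 and ±1.6ω per
dimension), damped Gauss–Newton with analytic ∂f/∂η is run from the two
best grid points, and the better converged mode wins.  The double start
matters: with population variability near 100 %CV the conditional
objective can be bimodal, and following a single basin makes the outer
objective discontinuous wherever a subject's preferred mode flips.
Everything is cold-started, so the objective is a deterministic function
of the population parameters.

The per-subject OFV contribution is assembled with the rank-≤2
matrix-determinant lemma and Woodbury identity, so no dense linear algebra
is needed.

Array layout (padded): y, m (S,O); dtp, act (S,O,D); amt (S,D) in µg.
``codes`` maps η columns to structural parameters (0 = CL, 1 = V).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_DEG_RTOL = 1e-8
_W_FLOOR = 1e-12


@njit(cache=True)
def _subject_conc(cl, v, ka, dtp, act, amt, f, dfdcl, dfdv, want_grad):
    """Concentration and parameter gradients for one subject.

    dtp, act: (O, D); amt: (D,); outputs f, dfdcl, dfdv: (O,).
    """
    O, D = dtp.shape
    k = cl / v
    deg = abs(ka - k) < _DEG_RTOL * k
    for j in range(O):
        fj = 0.0
        dgdk = 0.0
        for d in range(D):
            if not act[j, d] or amt[d] == 0.0:
                continue
            t = dtp[j, d]
            e1 = np.exp(-k * t)
            if deg:
                a = amt[d]
                fj += a * k * t * e1 / v
                if want_grad:
                    dgdk += a * t * e1 * (1.0 - k * t) / v
            else:
                a = amt[d] * ka
                den = ka - k
                e2 = np.exp(-ka * t)
                fj += a / (v * den) * (e1 - e2)
                if want_grad:
                    dgdk += a / (v * den * den) * (e1 - e2) - a / (v * den) * t * e1
        f[j] = fj
        if want_grad:
            dfdcl[j] = dgdk / v
            dfdv[j] = -fj / v - dgdk * k / v


@njit(cache=True)
def _subject_value(eta, n_eta, codes, cl_t, v_t, ka, dtp, act, amt,
                   y, m, omega2, sigp2, siga2, f, dfdcl, dfdv):
    """Conditional objective l(η) for one subject (value only)."""
    cl = cl_t
    v = v_t
    for r in range(n_eta):
        if codes[r] == 0:
            cl = cl * np.exp(eta[r])
        else:
            v = v * np.exp(eta[r])
    _subject_conc(cl, v, ka, dtp, act, amt, f, dfdcl, dfdv, False)
    l = 0.0
    for j in range(y.shape[0]):
        if not m[j]:
            continue
        w = sigp2 * f[j] * f[j] + siga2
        if w < _W_FLOOR:
            w = _W_FLOOR
        e = y[j] - f[j]
        l += e * e / w + np.log(w)
    for r in range(n_eta):
        l += eta[r] * eta[r] / omega2[r]
    return l


@njit(cache=True)
def _subject_newton(eta, l0, n_eta, codes, cl_t, v_t, ka, dtp, act, amt,
                    y, m, omega2, sigp2, siga2, tol, max_iter):
    """Damped Gauss–Newton from the given start; updates eta in place and
    returns the final objective value."""
    O = y.shape[0]
    f = np.empty(O)
    dfdcl = np.empty(O)
    dfdv = np.empty(O)
    g = np.zeros(2)
    H = np.zeros((2, 2))
    trial = np.zeros(2)
    l = l0
    for _it in range(max_iter):
        cl = cl_t
        v = v_t
        for r in range(n_eta):
            if codes[r] == 0:
                cl = cl * np.exp(eta[r])
            else:
                v = v * np.exp(eta[r])
        _subject_conc(cl, v, ka, dtp, act, amt, f, dfdcl, dfdv, True)
        for r in range(n_eta):
            g[r] = 2.0 * eta[r] / omega2[r]
            for s in range(n_eta):
                H[r, s] = 0.0
            H[r, r] = 2.0 / omega2[r]
        for j in range(O):
            if not m[j]:
                continue
            w = sigp2 * f[j] * f[j] + siga2
            if w < _W_FLOOR:
                w = _W_FLOOR
            e = y[j] - f[j]
            for r in range(n_eta):
                fr = dfdcl[j] * cl if codes[r] == 0 else dfdv[j] * v
                wr = 2.0 * sigp2 * f[j] * fr
                g[r] += -2.0 * e * fr / w - e * e / (w * w) * wr + wr / w
                for s in range(r + 1):
                    fs = dfdcl[j] * cl if codes[s] == 0 else dfdv[j] * v
                    H[r, s] += 2.0 * fr * fs / w
                    if s != r:
                        H[s, r] = H[r, s]
        # solve (H + λI) step = −g for n_eta ≤ 2
        lam = 1e-10
        if n_eta == 1:
            s0 = -g[0] / (H[0, 0] + lam)
            s1 = 0.0
        else:
            det = (H[0, 0] + lam) * (H[1, 1] + lam) - H[0, 1] * H[1, 0]
            if det <= 0.0:
                det = 1e-10
            s0 = (-(H[1, 1] + lam) * g[0] + H[0, 1] * g[1]) / det
            s1 = (H[1, 0] * g[0] - (H[0, 0] + lam) * g[1]) / det
        if s0 > 2.0:
            s0 = 2.0
        if s0 < -2.0:
            s0 = -2.0
        if s1 > 2.0:
            s1 = 2.0
        if s1 < -2.0:
            s1 = -2.0
        if abs(s0) < tol and abs(s1) < tol:
            break
        alpha = 1.0
        accepted = False
        for _ls in range(14):
            trial[0] = eta[0] + alpha * s0
            trial[1] = eta[1] + alpha * s1
            lt = _subject_value(trial, n_eta, codes, cl_t, v_t, ka, dtp,
                                act, amt, y, m, omega2, sigp2, siga2,
                                f, dfdcl, dfdv)
            if lt < l - 1e-13:
                eta[0] = trial[0]
                eta[1] = trial[1]
                l = lt
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
    return l


@njit(cache=True)
def _subject_solve(n_eta, codes, cl_t, v_t, ka, dtp, act, amt, y, m,
                   omega2, sigp2, siga2, eta_out, f_out, G_out, w_out,
                   tol, max_iter):
    """Global-ish inner solve for one subject's η̂; fills f, G, w at the
    mode."""
    O = y.shape[0]
    f = np.empty(O)
    dfdcl = np.empty(O)
    dfdv = np.empty(O)
    eta = np.zeros(2)
    has_data = False
    for j in range(O):
        if m[j]:
            has_data = True
            break
    if n_eta > 0 and has_data:
        # rank the start grid (0, ±1.6ω per dimension)
        n0 = 3
        n1 = 3 if n_eta == 2 else 1
        best_l = 1e300
        second_l = 1e300
        best = np.zeros(2)
        second = np.zeros(2)
        trial = np.zeros(2)
        for i0 in range(n0):
            for i1 in range(n1):
                trial[0] = (0.0, -1.6, 1.6)[i0] * np.sqrt(omega2[0])
                trial[1] = 0.0
                if n_eta == 2:
                    trial[1] = (0.0, -1.6, 1.6)[i1] * np.sqrt(omega2[1])
                lt = _subject_value(trial, n_eta, codes, cl_t, v_t, ka, dtp,
                                    act, amt, y, m, omega2, sigp2, siga2,
                                    f, dfdcl, dfdv)
                if lt < best_l:
                    second_l = best_l
                    second[0] = best[0]
                    second[1] = best[1]
                    best_l = lt
                    best[0] = trial[0]
                    best[1] = trial[1]
                elif lt < second_l:
                    second_l = lt
                    second[0] = trial[0]
                    second[1] = trial[1]
        # refine the two best starts with full Newton; keep the better mode
        eta1 = best.copy()
        l1 = _subject_newton(eta1, best_l, n_eta, codes, cl_t, v_t, ka, dtp,
                             act, amt, y, m, omega2, sigp2, siga2, tol, max_iter)
        eta[0] = eta1[0]
        eta[1] = eta1[1]
        if second_l < 1e300:
            eta2 = second.copy()
            l2 = _subject_newton(eta2, second_l, n_eta, codes, cl_t, v_t, ka,
                                 dtp, act, amt, y, m, omega2, sigp2, siga2,
                                 tol, max_iter)
            if l2 < l1:
                eta[0] = eta2[0]
                eta[1] = eta2[1]
    # final structural values, Jacobian and residual variance at the mode
    cl = cl_t
    v = v_t
    for r in range(n_eta):
        if codes[r] == 0:
            cl = cl * np.exp(eta[r])
        else:
            v = v * np.exp(eta[r])
        eta_out[r] = eta[r]
    _subject_conc(cl, v, ka, dtp, act, amt, f, dfdcl, dfdv, True)
    for j in range(O):
        f_out[j] = f[j]
        w = sigp2 * f[j] * f[j] + siga2
        w_out[j] = w if w > _W_FLOOR else _W_FLOOR
        for r in range(n_eta):
            G_out[j, r] = dfdcl[j] * cl if codes[r] == 0 else dfdv[j] * v


@njit(cache=True)
def _subject_ofv(n_eta, y, m, eta, f, G, w, omega2):
    """FOCE-I OFV contribution via determinant lemma + Woodbury (n_eta ≤ 2)."""
    O = y.shape[0]
    logdet = 0.0
    quad = 0.0
    A = np.zeros((2, 2))
    b = np.zeros(2)
    for j in range(O):
        if not m[j]:
            continue
        r_j = y[j] - f[j]
        for r in range(n_eta):
            r_j += G[j, r] * eta[r]
        logdet += np.log(w[j])
        quad += r_j * r_j / w[j]
        for r in range(n_eta):
            b[r] += G[j, r] * r_j / w[j]
            for s in range(r + 1):
                A[r, s] += G[j, r] * G[j, s] / w[j]
    if n_eta == 0:
        return logdet + quad
    A[0, 1] = A[1, 0]
    if n_eta == 1:
        detM = 1.0 + omega2[0] * A[0, 0]
        if detM <= 0.0:
            return np.nan
        logdet += np.log(detM)
        quad -= b[0] * b[0] / (1.0 / omega2[0] + A[0, 0])
        return logdet + quad
    m00 = 1.0 + omega2[0] * A[0, 0]
    m01 = omega2[0] * A[0, 1]
    m10 = omega2[1] * A[1, 0]
    m11 = 1.0 + omega2[1] * A[1, 1]
    detM = m00 * m11 - m01 * m10
    if detM <= 0.0:
        return np.nan
    logdet += np.log(detM)
    b00 = 1.0 / omega2[0] + A[0, 0]
    b01 = A[0, 1]
    b11 = 1.0 / omega2[1] + A[1, 1]
    detB = b00 * b11 - b01 * b01
    if detB <= 0.0:
        return np.nan
    quad -= (b11 * b[0] * b[0] - 2.0 * b01 * b[0] * b[1] + b00 * b[1] * b[1]) / detB
    return logdet + quad


@njit(cache=True)
def solve_cohort(codes, cl_t, v_t, ka_t, dtp, act, amt, y, m,
                 omega2, sigp2, siga2, tol=1e-10, max_iter=50):
    """Solve every subject's inner problem and assemble OFV contributions.

    Returns (eta (S,2), f (S,O), G (S,O,2), w (S,O), ofv_i (S,)).
    """
    S, O = y.shape
    n_eta = codes.shape[0]
    eta = np.zeros((S, 2))
    f = np.zeros((S, O))
    G = np.zeros((S, O, 2))
    w = np.ones((S, O))
    ofv_i = np.zeros(S)
    for i in range(S):
        _subject_solve(n_eta, codes, cl_t[i], v_t[i], ka_t[i],
                       dtp[i], act[i], amt[i], y[i], m[i],
                       omega2, sigp2, siga2,
                       eta[i], f[i], G[i], w[i], tol, max_iter)
        ofv_i[i] = _subject_ofv(n_eta, y[i], m[i], eta[i], f[i], G[i], w[i],
                                omega2)
    return eta, f, G, w, ofv_i
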