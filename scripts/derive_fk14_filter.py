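"""Regenerate the length-14 scaling filter frozen in croaker.wavelets.

Construction:
1.  Parameterize valid orthogonal half-band magnitude responses
    ``P(xi) = |m0(xi)|^2 = 1 + sum_{k odd <= 13} p_k cos(k xi)`` with
    ``sum p_k = 1`` (so P(0)=2, P(pi)=0) and ``P >= 0``.
2.  Maximize the passband energy concentration
    ``(1/2pi) * integral_{-pi/2}^{pi/2} P`` — a linear program in the p_k
    solved on a dense frequency grid.
3.  Spectral-factorize the optimal P (roots of the degree-26 Laurent
    polynomial); unit-circle double zeros contribute one copy each, and
    for the three off-circle conjugate quadruples the inside/outside
    choice is the one minimizing ||h - reversed(h)|| (most nearly
    symmetric factor) with a positive main lobe.
4.  Newton-polish the 14 coefficients onto the conjugate-quadrature
    constraints (unit energy, shift orthogonality, sum = sqrt 2).

Usage:  python scripts/derive_fk14_filter.py
Prints the polished coefficients and the maximum deviation from the
values frozen in the package.
"""

import itertools

import numpy as np
from scipy.optimize import linprog

from croaker.wavelets import FK14_FILTER

L = 14
K = L // 2


def solve_halfband_lp(ngrid: int = 60001) -> np.ndarray:
    ks = np.arange(1, L, 2)
    xi = np.linspace(0, np.pi, ngrid)
    cost = -np.sin(ks * np.pi / 2) / ks  # passband concentration
    res = linprog(cost, A_ub=-np.cos(np.outer(xi, ks)),
                  b_ub=np.ones(ngrid), A_eq=np.ones((1, K)), b_eq=[1.0],
                  bounds=[(None, None)] * K, method="highs")
    assert res.success, res.message
    return res.x


def cqf_residual(h: np.ndarray) -> np.ndarray:
    r = [h @ h - 1, h.sum() - np.sqrt(2)]
    for m in range(1, K):
        r.append(h[:-2 * m] @ h[2 * m:])
    return np.array(r)


def polish(h: np.ndarray) -> np.ndarray:
    for _ in range(80):
        r = cqf_residual(h)
        if np.max(np.abs(r)) < 2e-16:
            break
        J = np.zeros((len(r), L))
        J[0] = 2 * h
        J[1] = 1.0
        for m in range(1, K):
            g = np.zeros(L)
            for k in range(L - 2 * m):
                g[k] += h[k + 2 * m]
                g[k + 2 * m] += h[k]
            J[m + 1] = g
        h = h + np.linalg.lstsq(J, -r, rcond=None)[0]
    return h


def factor_candidates(p: np.ndarray):
    deg = L - 1
    a = np.zeros(2 * deg + 1)
    a[deg] = 1.0
    for k, pk in zip(np.arange(1, L, 2), p):
        a[deg + k] += pk / 2
        a[deg - k] += pk / 2
    roots = np.roots(a[::-1])
    mod = np.abs(roots)
    tol = 2e-4
    on_circle = roots[np.abs(mod - 1) < tol]
    inside = roots[(mod < 1 - tol)]
    # collapse double circle zeros to one representative each
    reps = []
    used = np.zeros(len(on_circle), bool)
    order = np.argsort(np.angle(on_circle))
    on_circle = on_circle[order]
    for i in range(len(on_circle)):
        if used[i]:
            continue
        d = np.abs(on_circle - on_circle[i])
        d[i] = np.inf
        d[used] = np.inf
        j = int(np.argmin(d))
        used[i] = used[j] = True
        reps.append(np.exp(1j * np.angle((on_circle[i] + on_circle[j]) / 2)))
    quads = inside[np.imag(inside) >= 0]
    for flags in itertools.product([0, 1], repeat=len(quads)):
        roots_sel = list(reps)
        for f, z in zip(flags, quads):
            zz = z if f == 0 else 1 / np.conj(z)
            roots_sel += [zz, np.conj(zz)]
        h = np.real(np.poly(roots_sel))
        h = h / np.linalg.norm(h)
        if h.sum() < 0:
            h = -h
        yield polish(h)


def main() -> None:
    p = solve_halfband_lp()
    best = min(factor_candidates(p),
               key=lambda h: np.linalg.norm(h - h[::-1]))
    print("coefficients:")
    for v in best:
        print(f"  {v:+.17f}")
    print("max |residual|:", np.max(np.abs(cqf_residual(best))))
    print("max deviation from frozen values:",
          np.max(np.abs(best - FK14_FILTER)))


if __name__ == "__main__":
    main()
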