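"""One-off generator for the frozen mean-BR probit oracle values.

Independent route: the mean bias-reducing adjustment is evaluated from the
generic adjusted-score theory, ``A_t = tr[F^{-1}(P_t + Q_t)] / 2`` with
``P_t = E[U U' U_t]`` and ``Q_t = -E[J U_t]`` computed from exact Bernoulli
moments (third central moment ``v (1 - 2 mu)``), and the adjusted equations
are solved with a general-purpose root finder with numerical Jacobian -- no
shared code or iteration scheme with the package's closed-form quasi-Fisher
implementation.  Sanity anchor: on the logit link the same generic route
reproduces the Jeffreys-prior penalised mode (the classical equivalence).

Run from the repository root:  python tests/oracles/generate_meanbr_oracle.py
"""

import json
from pathlib import Path

import numpy as np
from scipy.optimize import root
from scipy.special import ndtr
from scipy.stats import norm


def adjusted_score(beta, X, y):
    # clip the linear predictor so the root search cannot wander into
    # double-precision underflow; every mean-BR solution here has |eta| << 12
    eta = np.clip(X @ beta, -12.0, 12.0)
    mu = ndtr(eta)
    mu_c = ndtr(-eta)  # 1 - mu without cancellation
    d = norm.pdf(eta)
    v = mu * mu_c
    u = d / v
    dd = -eta * d  # d'(eta)
    one_m_2mu = mu_c - mu  # 1 - 2 mu, stable
    up = (dd * v - d * d * one_m_2mu) / v**2  # u'(eta)
    w = d * u
    F = X.T @ (w[:, None] * X)
    Finv = np.linalg.inv(F)
    k3 = v * one_m_2mu  # E[(y - mu)^3]
    P = np.einsum("i,ip,iq,it->pqt", u**3 * k3, X, X, X)
    Q = np.einsum("i,ip,iq,it->pqt", up * u * v, X, X, X)
    A = 0.5 * np.einsum("pq,pqt->t", Finv, P + Q)
    resid = np.where(y > 0.5, mu_c, -mu)  # y - mu, stable per branch
    return X.T @ (u * resid) + A


def solve(X, y):
    sol = root(lambda b: adjusted_score(b, X, y), np.zeros(X.shape[1]), tol=1e-13)
    assert sol.success, sol.message
    # polish and verify the residual
    resid = np.abs(adjusted_score(sol.x, X, y)).max()
    assert resid < 1e-9, resid
    return sol.x


def main() -> None:
    rng = np.random.default_rng(20240917)
    fixtures = []
    # 12 small random designs (some will be quasi-separated by chance)
    for k in range(12):
        n = int(rng.integers(10, 25))
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        if k % 3 == 2:
            X = np.column_stack([X, rng.binomial(1, 0.5, n).astype(float)])
        p = ndtr(X @ rng.uniform(-1.0, 1.0, X.shape[1]))
        y = (rng.random(n) < p).astype(float)
        if y.std() == 0:  # keep intercept-only separation out of the random set
            y[0] = 1.0 - y[0]
        fixtures.append((X, y))
    # 4 perfectly separated continuous designs
    for k in range(4):
        n = 16
        x2 = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x2])
        y = (x2 > np.median(x2)).astype(float)
        fixtures.append((X, y))
    # 4 two-by-two tabular designs (binary x, small counts incl. a zero cell)
    for counts in ([3, 1, 2, 4], [5, 0, 3, 2], [1, 1, 6, 2], [2, 5, 4, 1]):
        n11, n10, n01, n00 = counts  # (x=1,y=1), (x=1,y=0), (x=0,y=1), (x=0,y=0)
        x = np.r_[np.ones(n11 + n10), np.zeros(n01 + n00)]
        y = np.r_[np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)]
        fixtures.append((np.column_stack([np.ones_like(x), x]), y))

    records = []
    for X, y in fixtures:
        est = solve(X, y)
        records.append({
            "X": X.tolist(),
            "y": y.tolist(),
            "estimates": est.tolist(),
        })
    out = Path(__file__).resolve().parent.parent / "data" / "meanbr_oracle.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(records, indent=1))
    print(f"wrote {len(records)} oracle fixtures to {out}")


if __name__ == "__main__":
    main()
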