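"""Calibration primitives: cross-entropy SAM balancing and regularity-constrained
Almost Ideal Demand System (AIDS) parameter estimation.

A social accounting matrix (SAM) records inter-account currency flows; it is
balanced when each account's receipts (row sum) equal its outlays (column sum).
Balancing minimally adjusts a noisy prior matrix, here by the generalized
Kullback-Leibler divergence ``sum(a*log(a/q) - a + q)`` subject to balance,
solved exactly on the entropy dual.

AIDS budget-share equations are ``w_i = alpha_i + sum_j gamma_ij ln p_j +
beta_i ln(E/P*)`` with the translog price index ``ln P* = a0 + sum alpha_i ln
p_i + 1/2 sum_ij gamma_ij ln p_i ln p_j``.  Regularity requires adding-up
(``sum alpha = 1``, ``sum beta = 0``, column sums of gamma zero), homogeneity
(row sums of gamma zero) and Slutsky symmetry (``gamma_ij = gamma_ji``).
Posterior parameters are the weighted least-divergence projection of noisy
priors onto that affine constraint set, computed from the KKT system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceError, InfeasibleBalanceError

BALANCE_TOL = 1e-8
CONSTRAINT_TOL = 1e-8
MAX_ITER = 500


# ---------------------------------------------------------------------------
# SAM container
# ---------------------------------------------------------------------------

@dataclass
class SAM:
    """Square matrix of non-negative inter-account currency flows.

    Base-year prices are normalised to one, so flows double as quantities at
    benchmark.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if t.shape[0] != t.shape[1] or list(t.index) != list(t.columns):
            raise ValueError("SAM must be square with identical row/column account labels")
        if (t.values < -1e-12).any():
            raise ValueError("SAM flows must be non-negative")

    @property
    def accounts(self) -> list[str]:
        return list(self.table.index)

    @property
    def values(self) -> np.ndarray:
        return self.table.values

    def row_sums(self) -> np.ndarray:
        return self.table.values.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        return self.table.values.sum(axis=0)

    def max_imbalance(self) -> float:
        """Largest relative row/column discrepancy across accounts."""
        r, c = self.row_sums(), self.col_sums()
        scale = np.maximum(np.maximum(np.abs(r), np.abs(c)), 1e-12 * max(self.values.sum(), 1.0))
        return float(np.max(np.abs(r - c) / scale))

    def is_balanced(self, tol: float = BALANCE_TOL) -> bool:
        return self.max_imbalance() <= tol

    def copy(self) -> "SAM":
        return SAM(self.table.copy())

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SAM":
        return cls(pd.read_csv(path, index_col=0))


# ---------------------------------------------------------------------------
# Cross-entropy SAM balancing
# ---------------------------------------------------------------------------

def _check_feasible_pattern(q: np.ndarray, accounts: list[str]) -> None:
    row_has = (q > 0).any(axis=1)
    col_has = (q > 0).any(axis=0)
    for k, name in enumerate(accounts):
        if row_has[k] != col_has[k]:
            raise InfeasibleBalanceError(name)


def balance_sam(prior: SAM, targets: dict[str, float] | None = None,
                tol: float = 1e-12, max_iter: int = MAX_ITER) -> SAM:
    """Balance a prior SAM by minimum cross-entropy.

    Solves ``min sum a*log(a/q) - a + q`` over the prior's positive cells
    subject to row sum = column sum per account (and, if ``targets`` gives
    per-account totals, to those margins).  The solution has the exponential
    form ``a_ij = q_ij * exp(lam_j - lam_i)`` (``exp(r_i + s_j)`` with
    margins) and is found by Newton iteration on the dual multipliers, which
    is exact to solver precision.  Structural zeros are preserved; a balanced
    prior is returned unchanged.
    """
    q = np.asarray(prior.values, dtype=float).copy()
    accounts = prior.accounts
    n = q.shape[0]
    _check_feasible_pattern(q, accounts)

    if targets is not None:
        a = _balance_to_margins(q, accounts, targets, tol, max_iter)
    else:
        a = _balance_dual_newton(q, accounts, tol, max_iter)

    out = SAM(pd.DataFrame(a, index=accounts, columns=accounts))
    if not out.is_balanced(BALANCE_TOL):
        raise ConvergenceError("SAM balancing did not reach tolerance",
                               residuals=out.row_sums() - out.col_sums())
    return out


def _balance_dual_newton(q: np.ndarray, accounts: list[str],
                         tol: float, max_iter: int) -> np.ndarray:
    n = q.shape[0]
    active = (q > 0).any(axis=1) | (q > 0).any(axis=0)
    idx = np.where(active)[0]
    if idx.size == 0:
        return q
    lam = np.zeros(n)
    total = q.sum()
    # gauge: last active account's multiplier fixed at zero; its balance
    # equation is redundant (residuals sum to zero identically)
    free = idx[:-1]
    for _ in range(max_iter):
        a = q * np.exp(lam[None, :] - lam[:, None])
        res = a.sum(axis=1) - a.sum(axis=0)
        if np.max(np.abs(res)) <= tol * max(total, 1.0):
            return a
        if free.size == 0:
            break
        off = a + a.T
        J = off[np.ix_(free, free)].copy()
        diag = -(a.sum(axis=1) - np.diag(a)) - (a.sum(axis=0) - np.diag(a))
        J[np.diag_indices_from(J)] = diag[free]
        try:
            step = np.linalg.solve(J, -res[free])
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -res[free], rcond=None)[0]
        smax = np.max(np.abs(step))
        if smax > 5.0:
            step *= 5.0 / smax
        lam[free] += step
    a = q * np.exp(lam[None, :] - lam[:, None])
    raise ConvergenceError("cross-entropy balancing failed to converge",
                           residuals=a.sum(axis=1) - a.sum(axis=0))


def _balance_to_margins(q: np.ndarray, accounts: list[str],
                        targets: dict[str, float], tol: float,
                        max_iter: int) -> np.ndarray:
    """Biproportional (RAS) scaling: the cross-entropy solution for fixed
    row and column totals."""
    t = np.array([targets.get(acc, np.nan) for acc in accounts])
    if np.isnan(t).any():
        missing = [a for a, v in zip(accounts, t) if np.isnan(v)]
        raise ValueError(f"targets must cover every account; missing {missing}")
    a = q.copy()
    row_pos = a.sum(axis=1) > 0
    col_pos = a.sum(axis=0) > 0
    for k, acc in enumerate(accounts):
        if t[k] > 0 and not (row_pos[k] and col_pos[k]):
            raise InfeasibleBalanceError(acc)
    for _ in range(max_iter * 10):
        r = a.sum(axis=1)
        a *= np.where(r > 0, t / np.where(r > 0, r, 1.0), 1.0)[:, None]
        c = a.sum(axis=0)
        a *= np.where(c > 0, t / np.where(c > 0, c, 1.0), 1.0)[None, :]
        r = a.sum(axis=1)
        if max(np.max(np.abs(r - t)), np.max(np.abs(a.sum(axis=0) - t))) <= tol * max(t.sum(), 1.0):
            return a
    raise ConvergenceError("RAS scaling to margins failed to converge",
                           residuals=a.sum(axis=1) - t)


# ---------------------------------------------------------------------------
# AIDS parameters
# ---------------------------------------------------------------------------

@dataclass
class ElasticityPriors:
    """Per-household uncompensated price/income elasticities and base shares."""

    commodities: list[str]
    households: list[str]
    epsilon: np.ndarray      # (H, n, n) uncompensated cross-price elasticities
    eta: np.ndarray          # (H, n) income elasticities
    shares: np.ndarray       # (H, n) base budget shares, rows sum to 1

    def __post_init__(self):
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        self.shares = np.asarray(self.shares, dtype=float)
        if (self.shares <= 0).any() or (self.shares >= 1).any():
            raise ValueError("budget shares must lie strictly in (0, 1)")
        if not np.allclose(self.shares.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("budget shares must sum to one per household")


@dataclass
class AIDSParameters:
    """AIDS coefficients per household plus the price-index anchor constant.

    ``anchor`` is the translog constant a0, set so that base-year budget
    shares are reproduced at unit prices and base expenditure.
    """

    commodities: list[str]
    households: list[str]
    alpha: np.ndarray        # (H, n)
    beta: np.ndarray         # (H, n)
    gamma: np.ndarray        # (H, n, n)
    anchor: np.ndarray       # (H,)

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.anchor = np.asarray(self.anchor, dtype=float)

    # -- demand evaluation ---------------------------------------------------

    def budget_shares(self, h: int, prices: np.ndarray, expenditure: float) -> np.ndarray:
        """Budget shares at given positive prices and total expenditure."""
        lnp = np.log(np.asarray(prices, dtype=float))
        lnP = self.anchor[h] + self.alpha[h] @ lnp + 0.5 * lnp @ self.gamma[h] @ lnp
        return self.alpha[h] + self.gamma[h] @ lnp + self.beta[h] * (np.log(expenditure) - lnP)

    def quantities(self, h: int, prices: np.ndarray, expenditure: float) -> np.ndarray:
        w = self.budget_shares(h, prices, expenditure)
        return w * expenditure / np.asarray(prices, dtype=float)

    # -- regularity ------------------------------------------------------------

    def constraint_residuals(self) -> dict[str, float]:
        """Max absolute violation of adding-up, homogeneity and symmetry."""
        return {
            "adding_up_alpha": float(np.max(np.abs(self.alpha.sum(axis=1) - 1.0))),
            "adding_up_beta": float(np.max(np.abs(self.beta.sum(axis=1)))),
            "adding_up_gamma": float(np.max(np.abs(self.gamma.sum(axis=1)))),
            "homogeneity": float(np.max(np.abs(self.gamma.sum(axis=2)))),
            "symmetry": float(np.max(np.abs(self.gamma - np.transpose(self.gamma, (0, 2, 1))))),
        }

    def is_regular(self, tol: float = CONSTRAINT_TOL) -> bool:
        return max(self.constraint_residuals().values()) <= tol

    # -- serialisation ---------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "commodities": self.commodities,
            "households": self.households,
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "gamma": self.gamma.tolist(),
            "anchor": self.anchor.tolist(),
            "constraint_residuals": self.constraint_residuals(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AIDSParameters":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["commodities"], d["households"], np.array(d["alpha"]),
                   np.array(d["beta"]), np.array(d["gamma"]), np.array(d["anchor"]))


# ---------------------------------------------------------------------------
# Elasticity <-> parameter maps
# ---------------------------------------------------------------------------

def aids_elasticities(params: AIDSParameters, shares: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward linear-approximate (Stone index) elasticity formulas at base shares.

    eps_ij = -delta_ij + (gamma_ij - beta_i w_j) / w_i ;  eta_i = 1 + beta_i / w_i
    """
    w = np.asarray(shares, dtype=float)
    H, n = w.shape
    eye = np.eye(n)
    eps = np.empty((H, n, n))
    for h in range(H):
        eps[h] = -eye + (params.gamma[h] - np.outer(params.beta[h], w[h])) / w[h][:, None]
    eta = 1.0 + params.beta / w
    return eps, eta


def elasticities_to_aids(priors: ElasticityPriors,
                         base_expenditure: np.ndarray | None = None) -> AIDSParameters:
    """Invert the textbook elasticity formulas at base shares to prior AIDS
    parameters (unconstrained; regularity is not imposed here).

    With unit base prices the anchor a0 = ln(E0) makes base shares equal alpha.
    """
    w = priors.shares
    H, n = w.shape
    if (w == 0).any():
        bad = [priors.commodities[j] for j in np.where((w == 0).any(axis=0))[0]]
        raise ZeroDivisionError(f"zero budget share for commodities {bad}")
    beta = w * (priors.eta - 1.0)
    gamma = np.empty((H, n, n))
    eye = np.eye(n)
    for h in range(H):
        gamma[h] = w[h][:, None] * (priors.epsilon[h] + eye) + np.outer(beta[h], w[h])
    alpha = w.copy()
    if base_expenditure is None:
        anchor = np.zeros(H)
    else:
        anchor = np.log(np.asarray(base_expenditure, dtype=float))
    return AIDSParameters(priors.commodities, priors.households, alpha, beta, gamma, anchor)


# ---------------------------------------------------------------------------
# Regularity-constrained posterior estimation
# ---------------------------------------------------------------------------

@dataclass
class AIDSWeights:
    """Precision (inverse-variance) weights per parameter; defaults to ones."""

    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None
    gamma: np.ndarray | None = None


def _constraint_matrix(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Equality constraints A x = b on x = [alpha, beta, vec(gamma)]."""
    nv = 2 * n + n * n
    rows, b = [], []

    r = np.zeros(nv); r[:n] = 1.0
    rows.append(r); b.append(1.0)                       # sum alpha = 1
    r = np.zeros(nv); r[n:2 * n] = 1.0
    rows.append(r); b.append(0.0)                       # sum beta = 0
    for j in range(n):                                  # column sums of gamma
        r = np.zeros(nv)
        r[2 * n + j::n] = 1.0
        rows.append(r); b.append(0.0)
    for i in range(n):                                  # row sums of gamma
        r = np.zeros(nv)
        r[2 * n + i * n: 2 * n + (i + 1) * n] = 1.0
        rows.append(r); b.append(0.0)
    for i in range(n):                                  # symmetry
        for j in range(i + 1, n):
            r = np.zeros(nv)
            r[2 * n + i * n + j] = 1.0
            r[2 * n + j * n + i] = -1.0
            rows.append(r); b.append(0.0)
    return np.array(rows), np.array(b)


def estimate_aids(prior_params: AIDSParameters,
                  weights: AIDSWeights | None = None) -> AIDSParameters:
    """Project prior AIDS parameters onto the regularity constraint set.

    Minimises the precision-weighted squared deviation from the prior subject
    to adding-up, homogeneity and symmetry, via the exact KKT linear system
    (Gaussian cross-entropy for signed parameters).  A prior that already
    satisfies the constraints is returned unchanged.
    """
    H, n = prior_params.alpha.shape
    weights = weights or AIDSWeights()
    wa = np.ones((H, n)) if weights.alpha is None else np.asarray(weights.alpha, float)
    wb = np.ones((H, n)) if weights.beta is None else np.asarray(weights.beta, float)
    wg = np.ones((H, n, n)) if weights.gamma is None else np.asarray(weights.gamma, float)
    if (wa <= 0).any() or (wb <= 0).any() or (wg <= 0).any():
        raise ValueError("precision weights must be strictly positive")

    A, b = _constraint_matrix(n)
    nv = 2 * n + n * n
    alpha = np.empty((H, n)); beta = np.empty((H, n)); gamma = np.empty((H, n, n))
    for h in range(H):
        x0 = np.concatenate([prior_params.alpha[h], prior_params.beta[h],
                             prior_params.gamma[h].ravel()])
        if not np.all(np.isfinite(x0)):
            raise ValueError(f"non-finite prior parameters for household "
                             f"{prior_params.households[h]!r}")
        W = np.concatenate([wa[h], wb[h], wg[h].ravel()])
        m = A.shape[0]
        K = np.zeros((nv + m, nv + m))
        K[:nv, :nv] = np.diag(W)
        K[:nv, nv:] = A.T
        K[nv:, :nv] = A
        rhs = np.concatenate([W * x0, b])
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
        x = sol[:nv]
        alpha[h], beta[h] = x[:n], x[n:2 * n]
        gamma[h] = x[2 * n:].reshape(n, n)

    post = AIDSParameters(prior_params.commodities, prior_params.households,
                          alpha, beta, gamma, prior_params.anchor.copy())
    res = post.constraint_residuals()
    if max(res.values()) > CONSTRAINT_TOL:
        raise ConvergenceError("AIDS posterior violates regularity constraints",
                               residuals=res)
    return post


# ---------------------------------------------------------------------------
# Targeted elasticity adjustments (regularity-preserving)
# ---------------------------------------------------------------------------

def set_own_price_elasticity(aids: AIDSParameters, shares: np.ndarray,
                             commodity_index: int, target: float) -> AIDSParameters:
    """Move a commodity's own-price elasticity to ``target`` per household.

    Uses a symmetric doubly-centred rank-one adjustment of gamma, so
    adding-up, homogeneity and symmetry are preserved exactly.
    """
    from dataclasses import replace
    n = len(aids.commodities)
    p = commodity_index
    u = -np.ones(n) / n
    u[p] += 1.0
    U = np.outer(u, u)
    gamma = aids.gamma.copy()
    for h in range(gamma.shape[0]):
        w = shares[h]
        eps_pp = -1.0 + (gamma[h, p, p] - aids.beta[h, p] * w[p]) / w[p]
        d = w[p] * (target - eps_pp) / U[p, p]
        gamma[h] += d * U
    return replace(aids, gamma=gamma)


def set_cross_price_elasticity(aids: AIDSParameters, shares: np.ndarray,
                               i: int, j: int, target: float) -> AIDSParameters:
    """Set the uncompensated cross-price elasticity eps_ij (quantity i with
    respect to price j) via a symmetric doubly-centred rank-two adjustment."""
    from dataclasses import replace
    n = len(aids.commodities)
    x = -np.ones(n) / n
    x[i] += 1.0
    y = -np.ones(n) / n
    y[j] += 1.0
    M = np.outer(x, y) + np.outer(y, x)
    gamma = aids.gamma.copy()
    for h in range(gamma.shape[0]):
        w = shares[h]
        eps_ij = (gamma[h, i, j] - aids.beta[h, i] * w[j]) / w[i]
        d = w[i] * (target - eps_ij) / M[i, j]
        gamma[h] += d * M
    return replace(aids, gamma=gamma)


def set_income_elasticity(aids: AIDSParameters, shares: np.ndarray,
                          commodity_index: int, target: float) -> AIDSParameters:
    """Set a commodity's income elasticity, rebalancing the other
    expenditure coefficients so they keep summing to zero."""
    from dataclasses import replace
    p = commodity_index
    beta = aids.beta.copy()
    for h in range(beta.shape[0]):
        w = shares[h]
        new_bp = w[p] * (target - 1.0)
        diff = new_bp - beta[h, p]
        others = np.arange(len(w)) != p
        beta[h, p] = new_bp
        beta[h, others] -= diff * w[others] / w[others].sum()
    return replace(aids, beta=beta)
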