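"""Strictly convex quadratic programme for diet optimisation.

The model minimises the sum of squared relative deviations from the observed
average diet,

    f(x) = sum_i ((x_i - xbar_i) / xbar_i)^2,

subject to linear equality and inequality constraints and per-food box bounds.
In the scaled variables z_i = x_i / xbar_i the objective is ``sum (z_i - 1)^2``
with identity Hessian, so the problem is strictly convex and the minimiser is
unique; the solver works in z-space for conditioning and reports results in
original units.

The solver is an active-set method started from the unconstrained optimum
(z = 1): at each step the equality-constrained KKT system of the current
working set is solved exactly, then the most violated constraint is added or
the constraint with the most negative multiplier is dropped.  A fallback route
through :func:`scipy.optimize.minimize` (trust-constr) followed by the same
KKT polish covers the rare case where the working-set iteration stalls.
Feasibility is certified up front with a phase-1 linear programme (HiGHS).

Sign convention: with inequalities written ``a.x <= b``, optimality is
``grad f + A_eq' nu + A_ub' lambda = 0`` with ``lambda >= 0``; a positive
multiplier is the marginal objective cost of tightening the constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import LinearConstraint as _ScipyLinCon
from scipy.optimize import linprog, minimize

__all__ = [
    "LinearConstraint",
    "QPProblem",
    "Solution",
    "solve",
    "verify_kkt",
    "brute_force_oracle",
    "random_problem",
]

_EQ = "="
_LE = "<="
_GE = ">="


@dataclass(frozen=True)
class LinearConstraint:
    """A single linear constraint ``coeffs . x  sense  rhs`` over foods.

    ``coeffs`` is indexed by food id; ``sense`` is one of ``"="``, ``"<="``,
    ``">="``; ``label`` identifies the constraint in dual/binding reports
    (e.g. ``"energy"``, ``"nut:fibre:min"``, ``"ghge_cap"``).
    """

    coeffs: pd.Series
    sense: str
    rhs: float
    label: str

    def __post_init__(self) -> None:
        if self.sense not in (_EQ, _LE, _GE):
            raise ValueError(f"{self.label}: sense must be =, <= or >=, got {self.sense!r}")
        if not np.isfinite(self.coeffs.to_numpy()).all() or not np.isfinite(self.rhs):
            raise ValueError(f"{self.label}: non-finite coefficients or rhs")

    def restrict(self, foods: pd.Index, fixed: pd.Series) -> "LinearConstraint":
        """Project onto the decision foods, folding fixed foods into the rhs."""
        rhs = self.rhs
        if len(fixed):
            common = fixed.index.intersection(self.coeffs.index)
            rhs -= float(self.coeffs[common].to_numpy() @ fixed[common].to_numpy())
        return LinearConstraint(self.coeffs.reindex(foods, fill_value=0.0), self.sense, rhs, self.label)

    def value(self, diet: pd.Series) -> float:
        return float(self.coeffs.reindex(diet.index, fill_value=0.0).to_numpy() @ diet.to_numpy())

    def satisfied(self, diet: pd.Series, tol: float = 1e-7) -> bool:
        v = self.value(diet)
        scale = max(1.0, abs(self.rhs))
        if self.sense == _EQ:
            return abs(v - self.rhs) <= tol * scale
        if self.sense == _LE:
            return v <= self.rhs + tol * scale
        return v >= self.rhs - tol * scale


@dataclass
class QPProblem:
    """Assembled optimisation instance over the decision foods.

    Decision foods are those with positive anchor and a non-degenerate habit
    box (p10 < p90); the remaining foods are carried in ``fixed`` and their
    contributions are already folded into every constraint's rhs at solve time.
    Objective weights are ``w_i = 1 / xbar_i**2``.
    """

    anchor: pd.Series                      # xbar over decision foods, strictly > 0
    lower: pd.Series                       # box lower bounds (p10)
    upper: pd.Series                       # box upper bounds (p90)
    constraints: list[LinearConstraint]    # general constraints, over decision foods
    fixed: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        a = self.anchor.to_numpy(dtype=float)
        if (a <= 0).any() or not np.isfinite(a).all():
            raise ValueError("anchor must be strictly positive and finite on decision foods")
        for s in (self.lower, self.upper):
            if not s.index.equals(self.anchor.index):
                raise ValueError("bounds must share the anchor's food index")
        if (self.lower.to_numpy() > self.upper.to_numpy()).any():
            raise ValueError("lower bound exceeds upper bound")

    @property
    def foods(self) -> pd.Index:
        return self.anchor.index

    @property
    def all_foods(self) -> pd.Index:
        return self.anchor.index.append(self.fixed.index)

    @property
    def n(self) -> int:
        return len(self.anchor)

    @property
    def weights(self) -> pd.Series:
        return 1.0 / self.anchor**2

    def objective(self, diet: pd.Series) -> float:
        """f(x) on the decision foods (sum form)."""
        x = diet.reindex(self.foods).to_numpy()
        xb = self.anchor.to_numpy()
        return float(np.sum(((x - xb) / xb) ** 2))

    def full_diet(self, x: pd.Series) -> pd.Series:
        """Decision solution + fixed foods, in problem food order."""
        return pd.concat([x, self.fixed]).reindex(self.all_foods)

    def labels(self) -> list[str]:
        return [c.label for c in self.constraints]


@dataclass
class Solution:
    """Solved diet with duals and optimality diagnostics."""

    status: str                            # "optimal" | "infeasible" | "numerical_failure"
    x: pd.Series | None                    # full diet incl. fixed foods, g/cap/day
    objective: float | None
    duals: pd.Series | None                # per labelled constraint (>=0 for inequalities)
    slacks: pd.Series | None               # rhs - value for <=, value - rhs for >=, 0 for =
    active: pd.Series | None               # |slack| <= tol per labelled constraint
    bound_duals: pd.DataFrame | None       # per decision food: lower/upper multipliers
    kkt: dict | None
    diagnosis: str | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


# ---------------------------------------------------------------------------
# internal dense form
# ---------------------------------------------------------------------------

class _Dense:
    """z-space arrays: equalities, row-normalised inequalities (<=), boxes."""

    def __init__(self, p: QPProblem):
        self.p = p
        xb = p.anchor.to_numpy(dtype=float)
        self.xb = xb
        n = p.n
        rows_eq, beq, self.eq_meta = [], [], []
        rows_ub, bub, self.ub_meta = [], [], []
        for k, c in enumerate(p.constraints):
            cr = c.restrict(p.foods, p.fixed)
            a = cr.coeffs.to_numpy(dtype=float) * xb     # to z-space
            if c.sense == _EQ:
                rows_eq.append(a)
                beq.append(cr.rhs)
                self.eq_meta.append(k)
            else:
                sgn = 1.0 if c.sense == _LE else -1.0
                rows_ub.append(sgn * a)
                bub.append(sgn * cr.rhs)
                self.ub_meta.append(k)
        self.A_eq = np.array(rows_eq, dtype=float).reshape(len(rows_eq), n)
        self.b_eq = np.array(beq, dtype=float)
        self.A_ub = np.array(rows_ub, dtype=float).reshape(len(rows_ub), n)
        self.b_ub = np.array(bub, dtype=float)
        # row normalisation for conditioning; duals mapped back via the scales
        self.s_eq = np.maximum(np.abs(self.A_eq).max(axis=1, initial=0.0), 1e-300)
        self.s_ub = np.maximum(np.abs(self.A_ub).max(axis=1, initial=0.0), 1e-300)
        self.A_eq = self.A_eq / self.s_eq[:, None]
        self.b_eq = self.b_eq / self.s_eq
        self.A_ub = self.A_ub / self.s_ub[:, None]
        self.b_ub = self.b_ub / self.s_ub
        self.lz = p.lower.to_numpy(dtype=float) / xb
        self.uz = p.upper.to_numpy(dtype=float) / xb

    # stacked system: equalities, inequalities, then -z <= -lz and z <= uz
    def stacked(self):
        n = self.p.n
        I = np.eye(n)
        A = np.vstack([self.A_ub, -I, I]) if n else np.zeros((0, 0))
        b = np.concatenate([self.b_ub, -self.lz, self.uz])
        return A, b


def _kkt_solve(dense: _Dense, work: list[int]):
    """Exact minimiser of sum (z-1)^2 subject to equalities + working-set rows.

    Returns (z, mu_eq, mu_work) where stationarity reads
    2(z - 1) + A_eq' (2 mu_eq) + A_w' (2 mu_w) = 0.
    """
    A_in, b_in = dense.stacked()
    A = np.vstack([dense.A_eq, A_in[work]]) if len(work) else dense.A_eq
    b = np.concatenate([dense.b_eq, b_in[work]]) if len(work) else dense.b_eq
    if A.shape[0] == 0:
        return np.ones(dense.p.n), np.zeros(0), np.zeros(0)
    M = A @ A.T
    r = A @ np.ones(dense.p.n) - b
    try:
        mu = np.linalg.solve(M, r)
    except np.linalg.LinAlgError:
        mu = np.linalg.lstsq(M, r, rcond=None)[0]
    # guard against ill-conditioned M: fall back to least squares if residual poor
    if not np.allclose(M @ mu, r, atol=1e-9 * (1 + np.abs(r).max(initial=0.0))):
        mu = np.linalg.lstsq(M, r, rcond=None)[0]
    z = np.ones(dense.p.n) - A.T @ mu
    ne = len(dense.b_eq)
    return z, mu[:ne], mu[ne:]


def _active_set(dense: _Dense, tol: float, max_iter: int | None = None):
    """Working-set iteration from the unconstrained optimum z = 1."""
    A_in, b_in = dense.stacked()
    m = len(b_in)
    if max_iter is None:
        max_iter = 40 + 6 * (m + dense.p.n)
    work: list[int] = []
    for _ in range(max_iter):
        z, mu_eq, mu_w = _kkt_solve(dense, work)
        # drop: inequality in the working set with negative multiplier
        if len(work):
            neg = np.where(mu_w < -tol)[0]
            if len(neg):
                j = neg[np.argmin(mu_w[neg])]
                work.pop(int(j))
                continue
        # add: most violated inactive inequality
        if m:
            viol = A_in @ z - b_in
            viol[work] = -np.inf
            j = int(np.argmax(viol))
            if viol[j] > tol:
                work.append(j)
                continue
        return z, mu_eq, mu_w, work, True
    z, mu_eq, mu_w = _kkt_solve(dense, work)  # work changed after last solve
    return z, mu_eq, mu_w, work, False


def _polish_from_point(dense: _Dense, z0: np.ndarray, tol: float):
    """Derive a working set from a near-optimal point and run the iteration."""
    A_in, b_in = dense.stacked()
    slack = b_in - A_in @ z0 if len(b_in) else np.zeros(0)
    work = [int(i) for i in np.where(slack <= 1e-6 * (1 + np.abs(b_in)))[0]]
    m = len(b_in)
    max_iter = 40 + 6 * (m + dense.p.n)
    for _ in range(max_iter):
        z, mu_eq, mu_w = _kkt_solve(dense, work)
        if len(work):
            neg = np.where(mu_w < -tol)[0]
            if len(neg):
                j = neg[np.argmin(mu_w[neg])]
                work.pop(int(j))
                continue
        if m:
            viol = A_in @ z - b_in
            viol[work] = -np.inf
            j = int(np.argmax(viol))
            if viol[j] > tol:
                work.append(j)
                continue
        return z, mu_eq, mu_w, work, True
    z, mu_eq, mu_w = _kkt_solve(dense, work)
    return z, mu_eq, mu_w, work, False


def _primal_active_set(dense: _Dense, z0: np.ndarray, tol: float):
    """Textbook primal active-set method from a feasible starting point.

    Maintains primal feasibility with step-length control: at each iterate the
    equality-constrained minimiser over the working set defines a direction;
    either the full step is taken, or the nearest blocking constraint is added;
    at a working-set optimum the most negative multiplier is dropped.  The
    heuristic warm-start loop can cycle on degenerate geometry; this routine
    cannot (up to its iteration cap, which guards pathological degeneracy).
    """
    A_in, b_in = dense.stacked()
    m = len(b_in)
    n = dense.p.n
    z = z0.copy()
    act = A_in @ z - b_in if m else np.zeros(0)
    work = [int(i) for i in np.where(act >= -1e-10 * (1 + np.abs(b_in)))[0]]
    max_iter = 80 + 10 * (m + n)
    for _ in range(max_iter):
        z_star, mu_eq, mu_w = _kkt_solve(dense, work)
        p = z_star - z
        if np.abs(p).max(initial=0.0) <= 1e-13 * (1 + np.abs(z).max()):
            if len(work):
                neg = np.where(mu_w < -tol)[0]
                if len(neg):
                    j = neg[np.argmin(mu_w[neg])]
                    work.pop(int(j))
                    continue
            return z_star, mu_eq, mu_w, work, True
        # step length to the nearest blocking constraint
        alpha = 1.0
        block = None
        if m:
            Ap = A_in @ p
            resid = b_in - A_in @ z
            for i in range(m):
                if i in work or Ap[i] <= 1e-14:
                    continue
                a = resid[i] / Ap[i]
                if a < alpha - 1e-14:
                    alpha, block = a, i
        z = z + max(alpha, 0.0) * p
        if block is not None:
            work.append(block)
        elif alpha >= 1.0:
            z = z_star  # full step: at the working-set minimiser next round
    z_star, mu_eq, mu_w = _kkt_solve(dense, work)
    return z_star, mu_eq, mu_w, work, False


def _feasible(dense: _Dense) -> np.ndarray | None:
    """Phase-1 LP: a feasible z-point, or None when the instance is infeasible."""
    n = dense.p.n
    res = linprog(
        c=np.zeros(n),
        A_ub=dense.A_ub if len(dense.b_ub) else None,
        b_ub=dense.b_ub if len(dense.b_ub) else None,
        A_eq=dense.A_eq if len(dense.b_eq) else None,
        b_eq=dense.b_eq if len(dense.b_eq) else None,
        bounds=list(zip(dense.lz, dense.uz)),
        method="highs",
    )
    return np.asarray(res.x, dtype=float) if res.status == 0 else None


def diagnose_infeasibility(problem: QPProblem) -> str:
    """Interval-arithmetic report: constraints unreachable over the habit boxes."""
    lines = []
    lo_full = pd.concat([problem.lower, problem.fixed])
    hi_full = pd.concat([problem.upper, problem.fixed])
    for c in problem.constraints:
        a = c.coeffs.reindex(lo_full.index, fill_value=0.0).to_numpy()
        lo = lo_full.to_numpy()
        hi = hi_full.to_numpy()
        vmin = float(np.minimum(a * lo, a * hi).sum())
        vmax = float(np.maximum(a * lo, a * hi).sum())
        bad = (
            (c.sense == _LE and vmin > c.rhs)
            or (c.sense == _GE and vmax < c.rhs)
            or (c.sense == _EQ and not (vmin <= c.rhs <= vmax))
        )
        if bad:
            lines.append(
                f"{c.label}: attainable range over habit boxes is [{vmin:.6g}, {vmax:.6g}] "
                f"but constraint requires {c.sense} {c.rhs:.6g}"
            )
    if not lines:
        lines.append(
            "no single constraint is unreachable over the habit boxes; "
            "infeasibility arises from a conflict between two or more constraints"
        )
    return "; ".join(lines)


def _build_solution(problem: QPProblem, dense: _Dense, z, mu_eq, mu_w, work, tol) -> Solution:
    xb = dense.xb
    # snap float dust onto the box (active bounds can land at e.g. -1e-16)
    z = np.clip(z, dense.lz, dense.uz)
    x = pd.Series(z * xb, index=problem.foods)
    full = problem.full_diet(x)
    # multipliers: stationarity uses lambda = 2*mu (z-space), mapped back through
    # row scales; bound rows map with the anchor scaling of z-space boxes.
    n = problem.n
    m_ub = len(dense.b_ub)
    lam_stack = np.zeros(m_ub + 2 * n)
    for j, idx in enumerate(work):
        lam_stack[idx] = 2.0 * mu_w[j]
    lam_stack = np.maximum(lam_stack, 0.0)
    duals = pd.Series(0.0, index=problem.labels())
    for r, k in enumerate(dense.eq_meta):
        duals.iloc[k] = 2.0 * mu_eq[r] / dense.s_eq[r]
    for r, k in enumerate(dense.ub_meta):
        duals.iloc[k] = lam_stack[r] / dense.s_ub[r]
    lo_mult = lam_stack[m_ub:m_ub + n] / xb
    hi_mult = lam_stack[m_ub + n:] / xb
    bound_duals = pd.DataFrame({"lower": lo_mult, "upper": hi_mult}, index=problem.foods)
    slacks = pd.Series(0.0, index=problem.labels())
    active = pd.Series(False, index=problem.labels())
    for k, c in enumerate(problem.constraints):
        v = c.value(full)
        if c.sense == _EQ:
            s = 0.0
        elif c.sense == _LE:
            s = c.rhs - v
        else:
            s = v - c.rhs
        slacks.iloc[k] = s
        active.iloc[k] = c.sense == _EQ or abs(s) <= max(tol, 1e-7 * (1 + abs(c.rhs)))
    sol = Solution(
        status="optimal",
        x=full,
        objective=problem.objective(full),
        duals=duals,
        slacks=slacks,
        active=active,
        bound_duals=bound_duals,
        kkt=None,
    )
    sol.kkt = verify_kkt(problem, sol, tol=max(tol, 1e-8))
    return sol


def solve(problem: QPProblem, tol: float = 1e-9) -> Solution:
    """Globally solve the diet QP; never returns a silently wrong answer.

    Returns an optimal :class:`Solution` with duals and KKT residuals, an
    infeasible one with a textual diagnosis, or a numerical-failure one with
    the best residual report achieved.
    """
    if problem.n == 0:
        full = problem.full_diet(pd.Series(dtype=float))
        ok = all(c.satisfied(full) for c in problem.constraints)
        if ok:
            return Solution("optimal", full, 0.0, pd.Series(dtype=float),
                            pd.Series(dtype=float), pd.Series(dtype=bool), None,
                            {"max_residual": 0.0, "ok": True})
        return Solution("infeasible", None, None, None, None, None, None, None,
                        diagnosis="all foods fixed and fixed diet violates constraints")
    dense = _Dense(problem)
    z_feas = _feasible(dense)
    if z_feas is None:
        return Solution("infeasible", None, None, None, None, None, None, None,
                        diagnosis=diagnose_infeasibility(problem))
    # fast path: warm-start working-set iteration from the unconstrained optimum
    z, mu_eq, mu_w, work, ok = _active_set(dense, tol)
    if ok:
        sol = _build_solution(problem, dense, z, mu_eq, mu_w, work, tol)
        if sol.kkt["ok"]:
            return sol
    # rigorous path: primal active set from the phase-1 feasible point
    z, mu_eq, mu_w, work, ok = _primal_active_set(dense, z_feas, tol)
    if ok:
        sol = _build_solution(problem, dense, z, mu_eq, mu_w, work, tol)
        if sol.kkt["ok"]:
            return sol
    # last resort: interior-point-style solve, then KKT polish
    z0 = _trust_constr_solve(dense)
    z, mu_eq, mu_w, work, ok = _polish_from_point(dense, z0, tol)
    sol = _build_solution(problem, dense, z, mu_eq, mu_w, work, tol)
    if ok and sol.kkt["ok"]:
        return sol
    sol.status = "numerical_failure"
    sol.diagnosis = f"KKT residuals not within tolerance: {sol.kkt}"
    return sol


def _trust_constr_solve(dense: _Dense) -> np.ndarray:
    n = dense.p.n
    cons = []
    if len(dense.b_eq):
        cons.append(_ScipyLinCon(dense.A_eq, dense.b_eq, dense.b_eq))
    if len(dense.b_ub):
        cons.append(_ScipyLinCon(dense.A_ub, -np.inf, dense.b_ub))
    z0 = np.clip(np.ones(n), dense.lz, dense.uz)
    res = minimize(
        lambda z: float(np.sum((z - 1.0) ** 2)),
        z0,
        jac=lambda z: 2.0 * (z - 1.0),
        hess=lambda z: 2.0 * np.eye(n),
        method="trust-constr",
        bounds=list(zip(dense.lz, dense.uz)),
        constraints=cons,
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 3000, "verbose": 0},
    )
    return np.asarray(res.x, dtype=float)


def verify_kkt(problem: QPProblem, solution: Solution, tol: float = 1e-8) -> dict:
    """First-order optimality report for an (allegedly) optimal solution.

    Residual blocks, all computed in the scaled z-space where the objective has
    identity Hessian: stationarity, primal feasibility, dual sign and
    complementary slackness.  ``ok`` is True when every block is <= ``tol``.
    """
    if solution.x is None:
        raise ValueError("verify_kkt requires a solution with a diet")
    dense = _Dense(problem)
    xb = dense.xb
    z = solution.x.reindex(problem.foods).to_numpy() / xb
    grad = 2.0 * (z - 1.0)
    duals = solution.duals if solution.duals is not None else pd.Series(dtype=float)
    stat = grad.copy()
    for r, k in enumerate(dense.eq_meta):
        stat += duals.iloc[k] * dense.s_eq[r] * dense.A_eq[r]
    for r, k in enumerate(dense.ub_meta):
        stat += duals.iloc[k] * dense.s_ub[r] * dense.A_ub[r]
    dual_sign = 0.0
    comp = 0.0
    if solution.bound_duals is not None:
        lo_m = solution.bound_duals["lower"].to_numpy() * xb
        hi_m = solution.bound_duals["upper"].to_numpy() * xb
        stat += hi_m - lo_m
        dual_sign = max(dual_sign, float(np.maximum(-lo_m, 0).max(initial=0.0)),
                        float(np.maximum(-hi_m, 0).max(initial=0.0)))
        comp = max(comp,
                   float(np.abs(lo_m * (z - dense.lz)).max(initial=0.0)),
                   float(np.abs(hi_m * (dense.uz - z)).max(initial=0.0)))
    primal = 0.0
    if len(dense.b_eq):
        primal = max(primal, float(np.abs(dense.A_eq @ z - dense.b_eq).max()))
    if len(dense.b_ub):
        primal = max(primal, float(np.maximum(dense.A_ub @ z - dense.b_ub, 0).max()))
    primal = max(primal,
                 float(np.maximum(dense.lz - z, 0).max(initial=0.0)),
                 float(np.maximum(z - dense.uz, 0).max(initial=0.0)))
    for r, k in enumerate(dense.ub_meta):
        lam = duals.iloc[k] * dense.s_ub[r]
        dual_sign = max(dual_sign, max(-lam, 0.0))
        comp = max(comp, abs(lam * (dense.b_ub[r] - dense.A_ub[r] @ z)))
    stationarity = float(np.abs(stat).max(initial=0.0))
    worst = max(stationarity, primal, dual_sign, comp)
    return {
        "stationarity": stationarity,
        "primal": primal,
        "dual_sign": dual_sign,
        "complementary_slackness": comp,
        "max_residual": worst,
        "ok": worst <= tol,
    }


# ---------------------------------------------------------------------------
# brute-force oracle (tests only)
# ---------------------------------------------------------------------------

def random_problem(rng: np.random.Generator, n: int | None = None) -> QPProblem:
    """Random small instance, feasible by construction (QA/diagnostics helper).

    A random interior point x0 of the habit box defines the right-hand sides:
    the energy equality passes through x0 and the side inequalities leave
    slack at x0, so x0 is always feasible; the anchor may lie inside or
    outside the feasible region.
    """
    n = int(rng.integers(2, 5)) if n is None else n
    idx = pd.Index([f"f{i}" for i in range(n)], name="food_id")
    anchor = pd.Series(rng.uniform(50, 200, n), index=idx)
    lo = anchor * rng.uniform(0.1, 0.6, n)
    hi = anchor * rng.uniform(1.2, 2.5, n)
    x0 = pd.Series(rng.uniform(lo, hi), index=idx)
    c = pd.Series(rng.uniform(1, 10, n), index=idx)
    cons = [LinearConstraint(c, "=", float(c @ x0), "energy")]
    for k in range(int(rng.integers(0, 3))):
        a = pd.Series(rng.uniform(0, 5, n), index=idx)
        sense = "<=" if rng.random() < 0.5 else ">="
        slack = rng.uniform(0.0, 0.3) * abs(float(a @ x0))
        rhs = float(a @ x0) + (slack if sense == "<=" else -slack)
        cons.append(LinearConstraint(a, sense, rhs, f"side{k}"))
    return QPProblem(anchor=anchor, lower=lo, upper=hi, constraints=cons)


def brute_force_oracle(problem: QPProblem, feas_tol: float = 1e-9) -> Solution:
    """Exact global minimiser by exhaustive active-subset enumeration.

    Intended purely as an independent test oracle for instances with at most
    five decision foods.  For a strictly convex QP the minimiser lies on some
    face of the feasible polytope, i.e. it is the minimiser of the objective
    restricted to *some* subset of constraints treated as equalities.  The
    oracle therefore tries every subset of at most ``n`` inequality/bound
    rows (plus all equality constraints), computes the restricted minimiser
    in closed form as a minimum-norm least-squares solution in the relative
    deviations, discards candidates that violate any constraint, and returns
    the best survivor.  No gradients, multipliers or working-set logic are
    involved, so the route is fully independent of :func:`solve`.
    """
    from itertools import combinations

    n = problem.n
    if n > 5:
        raise ValueError("brute-force oracle limited to <= 5 decision foods")
    xb = problem.anchor.to_numpy(dtype=float)
    lo = problem.lower.to_numpy(dtype=float)
    hi = problem.upper.to_numpy(dtype=float)

    A_eq, b_eq, A_le, b_le = [], [], [], []
    for c in problem.constraints:
        cr = c.restrict(problem.foods, problem.fixed)
        a = cr.coeffs.to_numpy(dtype=float)
        if c.sense == _EQ:
            A_eq.append(a)
            b_eq.append(cr.rhs)
        else:
            sgn = 1.0 if c.sense == _LE else -1.0
            A_le.append(sgn * a)
            b_le.append(sgn * cr.rhs)
    I = np.eye(n)
    for i in range(n):
        A_le.append(-I[i]); b_le.append(-lo[i])
        A_le.append(I[i]);  b_le.append(hi[i])
    A_eq = np.array(A_eq).reshape(len(b_eq), n)
    b_eq = np.array(b_eq)
    A_le = np.array(A_le).reshape(len(b_le), n)
    b_le = np.array(b_le)
    scale_le = 1.0 + np.abs(b_le)
    scale_eq = 1.0 + np.abs(b_eq)

    def restricted_minimiser(rows: tuple[int, ...]) -> np.ndarray | None:
        # min sum u_i^2 with u = (x - xb)/xb subject to the selected rows as
        # equalities: B u = r with B = A diag(xb), r = b - A xb
        A = np.vstack([A_eq, A_le[list(rows)]]) if rows else A_eq
        b = np.concatenate([b_eq, b_le[list(rows)]]) if rows else b_eq
        if A.shape[0] == 0:
            return xb.copy()
        B = A * xb
        r = b - A @ xb
        u, *_ = np.linalg.lstsq(B, r, rcond=None)
        if not np.allclose(B @ u, r, atol=1e-8 * (1.0 + np.abs(r).max(initial=0.0))):
            return None  # inconsistent subset
        return xb * (1.0 + u)

    def feasible(x: np.ndarray) -> bool:
        if len(b_eq) and (np.abs(A_eq @ x - b_eq) > feas_tol * scale_eq).any():
            return False
        return not (A_le @ x - b_le > feas_tol * scale_le).any()

    best_x, best_f = None, np.inf
    m = len(b_le)
    for k in range(0, n + 1):
        for rows in combinations(range(m), k):
            x = restricted_minimiser(rows)
            if x is None or not feasible(x):
                continue
            f = float(np.sum(((x - xb) / xb) ** 2))
            if f < best_f:
                best_f, best_x = f, x
    if best_x is None:
        return Solution("infeasible", None, None, None, None, None, None, None,
                        diagnosis="no candidate face yields a feasible point")
    full = problem.full_diet(pd.Series(best_x, index=problem.foods))
    return Solution("optimal", full, best_f, None, None, None, None, None)
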