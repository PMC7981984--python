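"""Uniform sampling of TFA solution spaces and PCA-based representative states.

With direction binaries fixed, the feasible set of a TFA problem is a convex
polytope over the continuous variables (net fluxes, one-way fluxes, log
concentrations, Gibbs energies).  We sample it with an artificial-centering
hit-and-run (ACHR) walk expressed in the null space of the equality
constraints: equalities (mass balance, dG definitions, fixed variables) are
eliminated exactly, and the walk only ever moves along feasible chords of the
inequality system.

A single representative steady state is then selected from a pool by principal
component analysis: samples are standardised, components are retained until a
requested fraction of the variance is covered, and the pool member closest to
the projected pool mean is returned (always an actual sample, never a
synthetic average).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import linprog

from .errors import ConfigurationError, InfeasibleProblemError
from .milp import LinearModel
from .thermo import TFAProblem, compute_gamma


@dataclass
class SteadyState:
    """A paired net-flux / log-concentration point satisfying all constraints."""

    nf: pd.Series  # net fluxes, mmol/gDW/h, indexed by reaction id
    ln_x: pd.Series  # ln(mol/L), indexed by metabolite id
    gamma: pd.Series  # thermodynamic displacement, indexed by reaction id
    model_name: str = ""
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model_name,
                "provenance": self.provenance,
                "nf": self.nf.to_dict(),
                "ln_x": self.ln_x.to_dict(),
                "gamma": self.gamma.to_dict(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SteadyState":
        d = json.loads(text)
        return cls(
            nf=pd.Series(d["nf"], name="NF"),
            ln_x=pd.Series(d["ln_x"], name="ln_x"),
            gamma=pd.Series(d["gamma"], name="gamma"),
            model_name=d.get("model", ""),
            provenance=d.get("provenance", {}),
        )


@dataclass
class SamplePool:
    """A matrix of feasible samples (rows) over named variables (columns)."""

    df: pd.DataFrame
    seed: int
    sampler: str = "achr"
    settings: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.df)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.df.to_parquet(path)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "variables": list(self.df.columns),
                    "n_samples": self.n_samples,
                    "seed": self.seed,
                    "sampler": self.sampler,
                    "settings": self.settings,
                },
                indent=2,
            )
        )


# ---------------------------------------------------------------------------
# Polytope extraction and hit-and-run
# ---------------------------------------------------------------------------


@dataclass
class Polytope:
    """A_ub x <= b_ub intersected with A_eq x = b_eq (bounds already folded in)."""

    A_ub: np.ndarray
    b_ub: np.ndarray
    A_eq: np.ndarray
    b_eq: np.ndarray
    names: list[str]


def polytope_from_linear_model(lm: LinearModel) -> Polytope:
    """Extract the continuous polytope; all integer variables must be fixed."""
    n = lm.n_vars
    for i in range(n):
        if lm.integer[i] and lm.lb[i] != lm.ub[i]:
            raise ConfigurationError(
                "integer variables must be fixed before sampling "
                "(fix directionality first)"
            )
    eq_rows, eq_rhs, ub_rows, ub_rhs = [], [], [], []
    fixed = np.array([lm.lb[i] == lm.ub[i] for i in range(n)])
    fixed_val = np.where(fixed, np.asarray(lm.lb), 0.0)

    def dense(coeffs: dict[int, float]) -> np.ndarray:
        row = np.zeros(n)
        for j, v in coeffs.items():
            row[j] = v
        return row

    for name, coeffs, lo, hi in lm.constraints:
        row = dense(coeffs)
        if all(fixed[j] for j in coeffs):
            # constant row: verify and drop (keeping it would pin the
            # interior-point slack at zero)
            value = float(row @ fixed_val)
            if not (lo - 1e-7 <= value <= hi + 1e-7):
                raise InfeasibleProblemError(
                    f"fixed variables violate constraint {name!r}"
                )
            continue
        if lo == hi:
            eq_rows.append(row)
            eq_rhs.append(lo)
        else:
            if np.isfinite(hi):
                ub_rows.append(row)
                ub_rhs.append(hi)
            if np.isfinite(lo):
                ub_rows.append(-row)
                ub_rhs.append(-lo)
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        if lm.lb[i] == lm.ub[i]:
            eq_rows.append(e)
            eq_rhs.append(lm.lb[i])
        else:
            if np.isfinite(lm.ub[i]):
                ub_rows.append(e)
                ub_rhs.append(lm.ub[i])
            if np.isfinite(lm.lb[i]):
                ub_rows.append(-e)
                ub_rhs.append(-lm.lb[i])
    return Polytope(
        A_ub=np.array(ub_rows) if ub_rows else np.zeros((0, n)),
        b_ub=np.array(ub_rhs),
        A_eq=np.array(eq_rows) if eq_rows else np.zeros((0, n)),
        b_eq=np.array(eq_rhs),
        names=list(lm.names),
    )


def _affine_hull(poly: Polytope) -> tuple[np.ndarray, np.ndarray]:
    """Particular solution and orthonormal null-space basis of A_eq x = b_eq."""
    dim = poly.A_ub.shape[1]
    if poly.A_eq.size:
        x_p, _, _, _ = np.linalg.lstsq(poly.A_eq, poly.b_eq, rcond=None)
        resid = np.abs(poly.A_eq @ x_p - poly.b_eq).max()
        if resid > 1e-6:
            raise InfeasibleProblemError(
                f"equality constraints are inconsistent (residual {resid:.2e})"
            )
        N = null_space(poly.A_eq)
    else:
        x_p = np.zeros(dim)
        N = np.eye(dim)
    return x_p, N


def _projected_inequalities(
    poly: Polytope, x_p: np.ndarray, N: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inequalities expressed in hull coordinates, constant rows dropped.

    A row orthogonal to the hull is constant over the feasible set; it is
    checked once and removed (such rows would otherwise pin the interior-point
    slack at zero).  Returns (W, c, row_norms) for W z <= c with x = x_p + N z.
    """
    W = poly.A_ub @ N
    c = poly.b_ub - poly.A_ub @ x_p
    norms = np.linalg.norm(W, axis=1)
    constant = norms <= 1e-10
    if np.any(c[constant] < -1e-6):
        raise InfeasibleProblemError(
            "a constraint constant over the affine hull is violated"
        )
    keep = ~constant
    return W[keep], c[keep], norms[keep]


def interior_point(poly: Polytope) -> np.ndarray:
    """A point strictly inside the inequalities, on the equality hull."""
    x_p, N = _affine_hull(poly)
    z0 = _interior_z(poly, x_p, N)
    return x_p + N @ z0


def _interior_z(poly: Polytope, x_p: np.ndarray, N: np.ndarray) -> np.ndarray:
    k = N.shape[1]
    if k == 0:
        return np.zeros(0)
    W, c, norms = _projected_inequalities(poly, x_p, N)
    if W.shape[0] == 0:
        return np.zeros(k)
    # variables (z, r): maximize r subject to W z + r * norms <= c
    A = np.hstack([W, norms[:, None]])
    obj = np.zeros(k + 1)
    obj[-1] = -1.0
    res = linprog(
        obj,
        A_ub=A,
        b_ub=c,
        bounds=[(None, None)] * k + [(0, 1.0)],
        method="highs",
    )
    if res.status != 0:
        raise InfeasibleProblemError(f"no interior point: {res.message}")
    return res.x[:k]


def achr_sample(
    poly: Polytope,
    n: int,
    seed: int,
    warmup: int = 1000,
    thin: int = 10,
) -> np.ndarray:
    """Artificial-centering hit-and-run over the polytope; returns (n, dim)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x_p, N = _affine_hull(poly)
    k = N.shape[1]
    x0 = x_p + N @ _interior_z(poly, x_p, N) if k else x_p
    if k == 0:
        # fully determined: the polytope is a single point
        return np.tile(x0, (n, 1))
    W, c, _ = _projected_inequalities(poly, x0, N)
    z = np.zeros(k)
    center = z.copy()
    n_seen = 1
    history: list[np.ndarray] = [z.copy()]
    samples = np.empty((n, len(x0)))
    collected = 0
    step = 0
    max_steps = warmup + thin * n * 50  # hard safety cap
    while collected < n:
        step += 1
        if step > max_steps:
            raise RuntimeError("hit-and-run failed to mix (too many degenerate chords)")
        if step <= warmup or len(history) < 10:
            d = rng.standard_normal(k)
        else:
            d = history[rng.integers(len(history))] - center
            if np.linalg.norm(d) < 1e-12:
                d = rng.standard_normal(k)
        d /= np.linalg.norm(d)
        s = W @ d
        r = c - W @ z
        r = np.maximum(r, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = r / s
        pos = s > 1e-12
        neg = s < -1e-12
        t_hi = ratios[pos].min() if pos.any() else np.inf
        t_lo = ratios[neg].max() if neg.any() else -np.inf
        if not np.isfinite(t_hi) or not np.isfinite(t_lo):
            raise InfeasibleProblemError(
                "unbounded direction in sampling polytope; close the open bounds"
            )
        t_lo, t_hi = min(t_lo, 0.0), max(t_hi, 0.0)
        width = t_hi - t_lo
        if width < 1e-13:
            continue
        t = t_lo + rng.uniform(1e-9, 1.0 - 1e-9) * width
        z = z + t * d
        n_seen += 1
        center += (z - center) / n_seen
        if len(history) < 1000:
            history.append(z.copy())
        else:
            history[rng.integers(1000)] = z.copy()
        if step > warmup and (step - warmup) % thin == 0:
            samples[collected] = x0 + N @ z
            collected += 1
    return samples


# ---------------------------------------------------------------------------
# High-level sampling operations
# ---------------------------------------------------------------------------


def _sample_problem(
    problem: TFAProblem, n: int, seed: int, warmup: int, thin: int
) -> np.ndarray:
    poly = polytope_from_linear_model(problem.lm)
    return achr_sample(poly, n=n, seed=seed, warmup=warmup, thin=thin)


def sample_flux_space(
    problem: TFAProblem,
    n: int = 10000,
    seed: int = 0,
    warmup: int = 1000,
    thin: int = 10,
) -> SamplePool:
    """Sample net-flux vectors from the (direction-fixed) TFA polytope."""
    X = _sample_problem(problem, n, seed, warmup, thin)
    cols = {f"NF_{rid}": X[:, i] for rid, i in problem.nf.items()}
    return SamplePool(
        df=pd.DataFrame(cols),
        seed=seed,
        settings={"warmup": warmup, "thin": thin, "space": "flux"},
    )


def sample_concentration_space(
    problem: TFAProblem,
    fixed_flux: pd.Series,
    n: int = 10000,
    seed: int = 0,
    warmup: int = 1000,
    thin: int = 10,
) -> SamplePool:
    """Sample log-concentrations consistent with a fixed net-flux profile."""
    prob = problem.copy()
    for rid, idx in prob.nf.items():
        if rid in fixed_flux.index:
            v = float(fixed_flux[rid])
            prob.lm.fix(idx, v)
            if rid in prob.vp:
                prob.lm.fix(prob.vp[rid], max(v, 0.0))
                prob.lm.fix(prob.vn[rid], max(-v, 0.0))
    try:
        prob.solve_feasibility()
    except InfeasibleProblemError as exc:
        raise InfeasibleProblemError(
            "fixed flux profile admits no feasible concentration vector "
            f"(thermodynamic constraints binding): {exc}"
        )
    X = _sample_problem(prob, n, seed, warmup, thin)
    cols = {f"LNX_{m}": X[:, i] for m, i in prob.lnx.items()}
    return SamplePool(
        df=pd.DataFrame(cols),
        seed=seed,
        settings={"warmup": warmup, "thin": thin, "space": "concentration"},
    )


def select_representative(
    pool: SamplePool, variance_coverage: float = 0.9
) -> tuple[int, pd.Series]:
    """PCA-select the pool sample nearest the projected pool mean.

    Columns are standardised (constant columns dropped); principal components
    are retained until the cumulative explained variance reaches
    ``variance_coverage``; the returned sample minimises Euclidean distance to
    the projected mean in component space (ties: lowest sample index).
    """
    if pool.n_samples < 2:
        raise ValueError("need at least 2 samples to select a representative")
    X = pool.df.to_numpy(dtype=float)
    std = X.std(axis=0, ddof=0)
    keep = std > 1e-12
    if not keep.any():
        return 0, pool.df.iloc[0]
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / std[keep]
    _, svals, Vt = np.linalg.svd(Z, full_matrices=False)
    var = svals**2
    ratio = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(ratio, variance_coverage) + 1)
    T = Z @ Vt[:k].T
    dist = np.linalg.norm(T - T.mean(axis=0), axis=1)
    idx = int(np.argmin(dist))  # argmin takes the lowest index on ties
    return idx, pool.df.iloc[idx]


def assemble_steady_state(
    problem: TFAProblem,
    nf: pd.Series,
    ln_x: pd.Series,
    provenance: dict | None = None,
) -> SteadyState:
    """Bundle a flux profile and concentration vector, recomputing Gamma."""
    params = problem.params
    nf = nf.copy()
    nf.index = [i.removeprefix("NF_") for i in nf.index]
    ln_x = ln_x.copy()
    ln_x.index = [i.removeprefix("LNX_") for i in ln_x.index]
    gammas = {}
    for rid in problem.thermo_reactions:
        r = problem.model.reaction(rid)
        dg = r.delta_g0 + params.RT * sum(
            float(c) * ln_x[m] for m, c in r.stoichiometry.items() if m in ln_x.index
        )
        gammas[rid] = float(compute_gamma(dg, params.RT))
    return SteadyState(
        nf=nf,
        ln_x=ln_x,
        gamma=pd.Series(gammas, name="gamma", dtype=float),
        model_name=problem.model.name,
        provenance=provenance or {},
    )
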