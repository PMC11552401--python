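"""Covariance-structure SEM core: symbolic model specification, maximum-likelihood
estimation, fit statistics, standard errors, and effect decompositions.

The engine uses an all-latent ("all-y") representation: a model is described by

* a loading matrix ``Lambda`` (observed on latent),
* a structural matrix ``B`` of directed latent-to-latent effects (acyclic),
* ``Psi``, the (co)variances of exogenous latents and structural disturbances,
* ``Theta``, the measurement-error (co)variances of the observed variables,

so that the implied covariance of the observed variables is

    Sigma(theta) = Lambda (I - B)^-1 Psi (I - B)^-T Lambda^T + Theta.

Free parameters are named; fixed entries carry numeric values.  Estimation
minimises the normal-theory ML discrepancy

    F(S, Sigma) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

and reports chi_square = (n - 1) * F_min (the classic LISREL scaling; an
``n``-scaling switch is provided) with df = p(p+1)/2 minus the number of free
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import linalg as sla
from scipy import optimize
from scipy import stats

__all__ = [
    "Fixed",
    "Free",
    "SemModelSpec",
    "FitResult",
    "SemSpecError",
    "SemInputError",
    "SemEvalError",
    "implied_covariance",
    "ml_discrepancy",
    "fit_ml",
    "chi_square_stat",
    "chisq_pvalue",
    "standard_errors",
    "standardize_solution",
    "total_effects",
]

# Convergence thresholds for the ML fit (gradient of F and change in F).
GRAD_TOL = 1e-6
FTOL = 1e-10
MAX_SCORING_ITER = 200


class SemSpecError(ValueError):
    """Malformed model specification (duplicate parameters, cycles, bad df)."""


class SemInputError(ValueError):
    """Invalid data input (dimension mismatch, non-PD sample covariance)."""


class SemEvalError(RuntimeError):
    """Numerical failure while evaluating a model (singular I-B, non-PD Sigma)."""


@dataclass(frozen=True)
class Fixed:
    """A parameter entry fixed at a finite numeric value."""

    value: float

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise SemSpecError("fixed entries must carry a finite numeric value")


@dataclass(frozen=True)
class Free:
    """A named free parameter with an optional starting value."""

    name: str
    start: float | None = None


Status = Fixed | Free


@dataclass(frozen=True)
class SemModelSpec:
    """Symbolic specification of an all-latent covariance-structure model.

    Entries are ``(row-label, col-label, status)`` triples; symmetric matrices
    (``psi``, ``theta``) store each off-diagonal pair once.  Omitted entries
    are fixed at zero.
    """

    observed_names: tuple[str, ...]
    latent_names: tuple[str, ...]
    loadings: tuple[tuple[str, str, Status], ...]
    paths: tuple[tuple[str, str, Status], ...] = ()  # (cause, effect, status)
    psi: tuple[tuple[str, str, Status], ...] = ()
    theta: tuple[tuple[str, str, Status], ...] = ()

    def __post_init__(self):
        obs, lat = set(self.observed_names), set(self.latent_names)
        if len(obs) != len(self.observed_names):
            raise SemSpecError("duplicate observed variable names")
        if len(lat) != len(self.latent_names):
            raise SemSpecError("duplicate latent variable names")
        seen: set[str] = set()
        for o, l, st in self.loadings:
            if o not in obs or l not in lat:
                raise SemSpecError(f"loading ({o}, {l}) references unknown variable")
            _register_free(st, seen)
        for c, e, st in self.paths:
            if c not in lat or e not in lat:
                raise SemSpecError(f"path ({c}, {e}) references unknown latent")
            if c == e:
                raise SemSpecError(f"latent {c!r} cannot cause itself")
            _register_free(st, seen)
        for a, b, st in self.psi:
            if a not in lat or b not in lat:
                raise SemSpecError(f"psi ({a}, {b}) references unknown latent")
            _register_free(st, seen)
        for a, b, st in self.theta:
            if a not in obs or b not in obs:
                raise SemSpecError(f"theta ({a}, {b}) references unknown observed")
            _register_free(st, seen)
        _check_acyclic(self.latent_names, [(c, e) for c, e, _ in self.paths])

    @property
    def n_observed(self) -> int:
        return len(self.observed_names)

    @property
    def free_names(self) -> tuple[str, ...]:
        names = []
        for group in (self.loadings, self.paths, self.psi, self.theta):
            for _, _, st in group:
                if isinstance(st, Free):
                    names.append(st.name)
        return tuple(names)

    @property
    def df(self) -> int:
        p = self.n_observed
        return p * (p + 1) // 2 - len(self.free_names)


def _register_free(st: Status, seen: set[str]) -> None:
    if isinstance(st, Free):
        if st.name in seen:
            raise SemSpecError(f"free parameter {st.name!r} appears twice")
        seen.add(st.name)
    elif not isinstance(st, Fixed):
        raise SemSpecError(f"entry status must be Fixed or Free, got {st!r}")


def _check_acyclic(nodes: Iterable[str], edges: list[tuple[str, str]]) -> None:
    # Kahn's algorithm on the cause -> effect graph.
    nodes = list(nodes)
    out: dict[str, list[str]] = {v: [] for v in nodes}
    indeg = {v: 0 for v in nodes}
    for c, e in edges:
        out[c].append(e)
        indeg[e] += 1
    queue = [v for v in nodes if indeg[v] == 0]
    seen = 0
    while queue:
        v = queue.pop()
        seen += 1
        for w in out[v]:
            indeg[w] -= 1
            if indeg[w] == 0:
                queue.append(w)
    if seen != len(nodes):
        raise SemSpecError("structural path matrix contains a cycle")


# ---------------------------------------------------------------------------
# Compiled model: matrix templates plus per-parameter slot bookkeeping.
# ---------------------------------------------------------------------------

_KINDS = ("lambda", "beta", "psi", "theta")


class CompiledModel:
    """Matrix-level view of a :class:`SemModelSpec` used by the fitter."""

    def __init__(self, spec: SemModelSpec):
        self.spec = spec
        self.obs_index = {v: i for i, v in enumerate(spec.observed_names)}
        self.lat_index = {v: i for i, v in enumerate(spec.latent_names)}
        p, m = len(spec.observed_names), len(spec.latent_names)
        self.p, self.m = p, m
        self.lambda0 = np.zeros((p, m))
        self.beta0 = np.zeros((m, m))
        self.psi0 = np.zeros((m, m))
        self.theta0 = np.zeros((p, p))
        self.free_names: list[str] = []
        self.slots: list[tuple[str, int, int]] = []  # aligned with free_names
        self._start: list[float | None] = []

        def handle(kind, i, j, st):
            if isinstance(st, Fixed):
                mat = {"lambda": self.lambda0, "beta": self.beta0,
                       "psi": self.psi0, "theta": self.theta0}[kind]
                mat[i, j] = st.value
                if kind in ("psi", "theta") and i != j:
                    mat[j, i] = st.value
            else:
                self.free_names.append(st.name)
                self.slots.append((kind, i, j))
                self._start.append(st.start)

        for o, l, st in spec.loadings:
            handle("lambda", self.obs_index[o], self.lat_index[l], st)
        for c, e, st in spec.paths:
            # B[effect, cause]
            handle("beta", self.lat_index[e], self.lat_index[c], st)
        for a, b, st in spec.psi:
            handle("psi", self.lat_index[a], self.lat_index[b], st)
        for a, b, st in spec.theta:
            handle("theta", self.obs_index[a], self.obs_index[b], st)
        self.q = len(self.free_names)
        self.name_index = {nm: k for k, nm in enumerate(self.free_names)}

    # -- starting values ----------------------------------------------------
    def start_vector(self, S: np.ndarray | None = None) -> np.ndarray:
        """Default starts: paths/covariances 0, loadings 1, free variances at
        half the corresponding sample variance (1.0 without data); explicit
        ``Free.start`` values override."""
        x0 = np.zeros(self.q)
        # map each latent to the observed variable loading on it (for variance starts)
        lat_obs: dict[int, int] = {}
        lam_rows = {}
        for o, l, st in self.spec.loadings:
            lat_obs.setdefault(self.lat_index[l], self.obs_index[o])
        for k, (kind, i, j) in enumerate(self.slots):
            if self._start[k] is not None:
                x0[k] = self._start[k]
                continue
            if kind == "lambda":
                x0[k] = 1.0
            elif kind == "beta":
                x0[k] = 0.0
            elif kind in ("psi", "theta") and i == j:
                if S is not None:
                    oi = i if kind == "theta" else lat_obs.get(i)
                    x0[k] = 0.5 * S[oi, oi] if oi is not None else 1.0
                else:
                    x0[k] = 1.0
            else:
                x0[k] = 0.0
        return x0

    # -- matrix assembly ----------------------------------------------------
    def matrices(self, x: np.ndarray):
        lam = self.lambda0.copy()
        bet = self.beta0.copy()
        psi = self.psi0.copy()
        the = self.theta0.copy()
        for k, (kind, i, j) in enumerate(self.slots):
            v = x[k]
            if kind == "lambda":
                lam[i, j] = v
            elif kind == "beta":
                bet[i, j] = v
            elif kind == "psi":
                psi[i, j] = v
                psi[j, i] = v
            else:
                the[i, j] = v
                the[j, i] = v
        return lam, bet, psi, the

    def implied(self, x: np.ndarray):
        lam, bet, psi, the = self.matrices(x)
        ident = np.eye(self.m)
        try:
            C = sla.solve(ident - bet, ident)
        except sla.LinAlgError as exc:  # pragma: no cover - acyclicity prevents this
            raise SemEvalError("singular (I - B): structural specification error") from exc
        A = lam @ C
        sigma = A @ psi @ A.T + the
        sigma = 0.5 * (sigma + sigma.T)
        return sigma, A, C, psi

    # -- derivative matrices -------------------------------------------------
    def delta_stack(self, A: np.ndarray, C: np.ndarray, psi: np.ndarray) -> np.ndarray:
        """Stack of dSigma/dtheta_k, shape (q, p, p)."""
        R = C @ psi @ A.T  # m x p
        out = np.zeros((self.q, self.p, self.p))
        for k, (kind, i, j) in enumerate(self.slots):
            D = out[k]
            if kind == "lambda":
                D[i, :] += R[j]
                D[:, i] += R[j]
            elif kind == "beta":
                u, r = A[:, i], R[j]  # slot (effect=i row, cause=j col)
                D += np.outer(u, r)
                D += np.outer(r, u)
            elif kind == "psi":
                if i == j:
                    D += np.outer(A[:, i], A[:, i])
                else:
                    D += np.outer(A[:, i], A[:, j])
                    D += np.outer(A[:, j], A[:, i])
            else:
                D[i, j] += 1.0
                if i != j:
                    D[j, i] += 1.0
        return out

    def gradient(self, x: np.ndarray, S: np.ndarray):
        """F and its gradient; barrier values outside the PD region."""
        sigma, A, C, psi = self.implied(x)
        try:
            cf = sla.cho_factor(sigma, lower=True)
        except (sla.LinAlgError, ValueError):
            return self._barrier(sigma, A, C, psi)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        sigma_inv = sla.cho_solve(cf, np.eye(self.p))
        f = logdet + float(np.sum(sigma_inv * S)) - self._logdet_s - self.p
        G = sigma_inv - sigma_inv @ S @ sigma_inv  # dF = tr(G dSigma)
        grad = self._contract(G, A, C, psi)
        return f, grad, sigma, sigma_inv, A, C, psi

    def _contract(self, G: np.ndarray, A, C, psi) -> np.ndarray:
        R = C @ psi @ A.T
        GA = G @ A
        RG = R @ G  # m x p
        grad = np.empty(self.q)
        for k, (kind, i, j) in enumerate(self.slots):
            if kind == "lambda":
                grad[k] = 2.0 * RG[j, i]
            elif kind == "beta":
                grad[k] = 2.0 * float(R[j] @ GA[:, i])
            elif kind == "psi":
                AGA_ij = float(A[:, i] @ GA[:, j])
                grad[k] = AGA_ij if i == j else 2.0 * AGA_ij
            else:
                grad[k] = G[i, j] if i == j else 2.0 * G[i, j]
        return grad

    def _barrier(self, sigma, A, C, psi):
        """Smooth exit from the non-PD region: penalise the negative spectrum."""
        w, V = sla.eigh(sigma)
        neg = np.minimum(w, 1e-8)
        f = 1e8 + float(np.sum((1e-8 - neg) ** 2)) * 1e8
        # gradient of sum (eps - lambda_min)^2 via dlambda/dtheta = v' dSigma v
        grad = np.zeros(self.q)
        stack = self.delta_stack(A, C, psi)
        for idx in np.where(w < 1e-8)[0]:
            v = V[:, idx]
            coeff = -2e8 * (1e-8 - w[idx])
            grad += coeff * np.einsum("kij,i,j->k", stack, v, v)
        return f, grad, sigma, None, A, C, psi

    def information(self, sigma_inv: np.ndarray, A, C, psi) -> np.ndarray:
        """Expected-information Hessian of F: I_jk = tr(Sigma^-1 Dj Sigma^-1 Dk)."""
        stack = self.delta_stack(A, C, psi)
        M = np.einsum("ab,kbc->kac", sigma_inv, stack)
        return np.einsum("jab,kba->jk", M, M)

    def set_logdet_s(self, S: np.ndarray):
        try:
            cf = sla.cho_factor(S, lower=True)
        except (sla.LinAlgError, ValueError) as exc:
            raise SemInputError("sample covariance matrix is not positive definite") from exc
        self._logdet_s = 2.0 * np.sum(np.log(np.diag(cf[0])))


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def implied_covariance(spec: SemModelSpec, values: Mapping[str, float]) -> np.ndarray:
    """Model-implied covariance Lambda (I-B)^-1 Psi (I-B)^-T Lambda^T + Theta."""
    cm = CompiledModel(spec)
    missing = [nm for nm in cm.free_names if nm not in values]
    if missing:
        raise SemInputError(f"no value assigned to free parameters: {missing}")
    x = np.array([values[nm] for nm in cm.free_names])
    sigma, *_ = cm.implied(x)
    return sigma


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Normal-theory ML discrepancy F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p."""
    S = np.asarray(S, float)
    Sigma = np.asarray(Sigma, float)
    if S.shape != Sigma.shape or S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise SemInputError("S and Sigma must be square matrices of equal dimension")
    p = S.shape[0]
    try:
        cf = sla.cho_factor(Sigma, lower=True)
    except (sla.LinAlgError, ValueError) as exc:
        raise SemEvalError("implied covariance is not positive definite") from exc
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(cf[0])))
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise SemInputError("sample covariance matrix is not positive definite")
    trace = float(np.trace(sla.cho_solve(cf, S)))
    return float(logdet_sigma + trace - logdet_s - p)


def chisq_pvalue(x: float, df: int) -> float:
    """Right-tail chi-square probability P(X >= x)."""
    if df < 1:
        raise SemInputError("df must be a positive integer")
    if x < 0:
        raise SemInputError("chi-square statistic must be nonnegative")
    return float(stats.chi2.sf(x, df))


def chi_square_stat(f_min: float, n: int, df: int, *, scale: str = "n-1"):
    """Likelihood-ratio test statistic from the minimised discrepancy.

    ``scale='n-1'`` gives the classic (N-1)*F_min convention; ``scale='n'``
    uses N*F_min.
    """
    if f_min < 0:
        raise SemInputError("f_min must be nonnegative")
    if n < 2:
        raise SemInputError("sample size must be at least 2")
    mult = (n - 1) if scale == "n-1" else n
    chi2 = mult * f_min
    p = 1.0 if df == 0 else chisq_pvalue(chi2, df)
    return chi2, df, p


@dataclass
class FitResult:
    """Maximum-likelihood fit of a :class:`SemModelSpec` to a sample covariance."""

    spec: SemModelSpec
    estimates: dict[str, float]
    sigma_hat: np.ndarray
    f_min: float
    chi_square: float
    df: int
    p_value: float
    n: int
    std_errors: dict[str, float]
    standardized: dict[tuple[str, str], float]
    converged: bool
    admissible: bool
    S: np.ndarray = field(repr=False, default=None)
    warnings: tuple[str, ...] = ()
    n_iter: int = 0
    _compiled: CompiledModel = field(repr=False, default=None)
    _x: np.ndarray = field(repr=False, default=None)


def fit_ml(spec: SemModelSpec, S: np.ndarray, n: int, *,
           chi2_scale: str = "n-1") -> FitResult:
    """Fit ``spec`` to sample covariance ``S`` (sample size ``n``) by ML.

    Quasi-Newton (L-BFGS with analytic gradient) followed by Fisher-scoring
    polish; convergence requires max|grad F| < 1e-6 and a function change
    below 1e-10.
    """
    S = np.asarray(S, float)
    p = spec.n_observed
    if S.shape != (p, p):
        raise SemInputError(f"S has shape {S.shape}, expected ({p}, {p})")
    if not np.allclose(S, S.T, atol=1e-8):
        raise SemInputError("sample covariance matrix is not symmetric")
    if n <= p:
        raise SemInputError("sample size must exceed the number of observed variables")
    if spec.df < 0:
        raise SemSpecError(f"negative degrees of freedom ({spec.df})")

    cm = CompiledModel(spec)
    cm.set_logdet_s(S)
    x = cm.start_vector(S)
    warnings: list[str] = []

    def fg(xv):
        f, g, *_ = cm.gradient(xv, S)
        return f, g

    if cm.q > 0:
        res = optimize.minimize(fg, x, jac=True, method="L-BFGS-B",
                                options={"maxiter": 150, "ftol": 1e-14,
                                         "gtol": 1e-8, "maxcor": 30})
        x = res.x
        n_iter = int(res.nit)
    else:
        n_iter = 0

    # Fisher-scoring polish for high-precision convergence.
    f_prev, g, sigma, sigma_inv, A, C, psi = cm.gradient(x, S)
    delta_f = np.inf
    converged = cm.q == 0
    for it in range(MAX_SCORING_ITER if cm.q else 0):
        if np.max(np.abs(g)) < GRAD_TOL and delta_f < FTOL:
            converged = True
            break
        if sigma_inv is None:
            break
        info = cm.information(sigma_inv, A, C, psi)
        try:
            step = sla.solve(info + 1e-12 * np.eye(cm.q), g, assume_a="pos")
        except (sla.LinAlgError, ValueError):
            step, *_ = np.linalg.lstsq(info, g, rcond=None)
        # backtracking line search on F
        t = 1.0
        improved = False
        for _ in range(40):
            cand = x - t * step
            f_new, g_new, s_new, si_new, A_new, C_new, psi_new = cm.gradient(cand, S)
            if f_new <= f_prev - 1e-16:
                x, delta_f = cand, f_prev - f_new
                f_prev, g, sigma, sigma_inv = f_new, g_new, s_new, si_new
                A, C, psi = A_new, C_new, psi_new
                improved = True
                break
            t *= 0.5
        n_iter += 1
        if not improved:
            converged = np.max(np.abs(g)) < 1e-4  # stalled at a flat point
            break
    else:  # pragma: no cover
        pass
    if not converged and cm.q and np.max(np.abs(g)) < GRAD_TOL:
        converged = True

    f_min = max(float(f_prev), 0.0)
    if f_prev < -1e-8:
        warnings.append(f"negative discrepancy {f_prev:.2e} clipped to 0")
    estimates = {nm: float(v) for nm, v in zip(cm.free_names, x)}
    chi2, df, pval = chi_square_stat(f_min, n, spec.df, scale=chi2_scale)

    # admissibility: no negative free variance estimates, PD implied covariance
    admissible = True
    for k, (kind, i, j) in enumerate(cm.slots):
        if kind in ("psi", "theta") and i == j and x[k] < 0:
            admissible = False
    try:
        sla.cho_factor(sigma)
    except (sla.LinAlgError, ValueError):
        admissible = False

    fit = FitResult(
        spec=spec, estimates=estimates, sigma_hat=sigma, f_min=f_min,
        chi_square=float(chi2), df=df, p_value=float(pval), n=n,
        std_errors={}, standardized={}, converged=bool(converged),
        admissible=bool(admissible), S=S, warnings=tuple(warnings),
        n_iter=n_iter, _compiled=cm, _x=x.copy(),
    )
    if cm.q > 0 and sigma_inv is not None:
        try:
            fit.std_errors, _ = standard_errors(fit)
        except SemEvalError as exc:
            fit.warnings = fit.warnings + (str(exc),)
    if admissible:
        try:
            fit.standardized = standardize_solution(fit)
        except SemEvalError as exc:
            fit.warnings = fit.warnings + (str(exc),)
    return fit


def _fit_internals(fit: FitResult):
    cm = fit._compiled
    if cm is None:
        cm = CompiledModel(fit.spec)
        cm.set_logdet_s(fit.S)
    x = fit._x
    if x is None:
        x = np.array([fit.estimates[nm] for nm in cm.free_names])
    return cm, x


def standard_errors(fit: FitResult):
    """Asymptotic standard errors from the expected information.

    acov(theta_hat) = (2 / (n - 1)) * I^-1 with I_jk = tr(Sigma^-1 Dj Sigma^-1 Dk)
    at the solution.  Returns ``(se_map, band_map)`` where the band is 3 if
    |estimate| >= 3 SE, 2 if >= 2 SE, else 0 (Table-style significance marks).
    """
    cm, x = _fit_internals(fit)
    if cm.q == 0:
        return {}, {}
    sigma, A, C, psi = cm.implied(x)
    try:
        sigma_inv = sla.inv(sigma)
    except sla.LinAlgError as exc:
        raise SemEvalError("implied covariance singular; no standard errors") from exc
    info = cm.information(sigma_inv, A, C, psi)
    try:
        acov = (2.0 / (fit.n - 1)) * sla.inv(info)
    except sla.LinAlgError as exc:
        w, V = sla.eigh(info)
        nullspace = V[:, w < 1e-10 * max(w.max(), 1.0)]
        null = [cm.free_names[i] for i in range(cm.q)
                if nullspace.size and np.max(np.abs(nullspace[i])) > 1e-6]
        raise SemEvalError(
            f"singular information matrix; model not identified (null-space "
            f"parameters: {null})") from exc
    diag = np.diag(acov)
    if np.any(diag < -1e-10):
        raise SemEvalError("negative variance in the inverse information matrix")
    se = {nm: float(np.sqrt(max(v, 0.0))) for nm, v in zip(cm.free_names, diag)}
    bands = {}
    for nm in cm.free_names:
        est, s = fit.estimates[nm], se[nm]
        if s <= 0:
            bands[nm] = 0
        elif abs(est) >= 3 * s:
            bands[nm] = 3
        elif abs(est) >= 2 * s:
            bands[nm] = 2
        else:
            bands[nm] = 0
    return se, bands


def _latent_cov(cm: CompiledModel, x: np.ndarray) -> np.ndarray:
    _, bet, psi, _ = cm.matrices(x)
    ident = np.eye(cm.m)
    C = sla.solve(ident - bet, ident)
    return C @ psi @ C.T


def standardize_solution(fit: FitResult) -> dict[tuple[str, str], float]:
    """Standardized coefficients keyed by (cause, effect).

    Structural paths and loadings are rescaled by SD(cause)/SD(effect) using
    model-implied variances; free exogenous covariances are reported as
    correlations under the same key convention.
    """
    cm, x = _fit_internals(fit)
    V = _latent_cov(cm, x)
    sigma, *_ = cm.implied(x)
    lat_sd = np.sqrt(np.maximum(np.diag(V), 0.0))
    obs_sd = np.sqrt(np.maximum(np.diag(sigma), 0.0))
    if np.any(lat_sd == 0) or np.any(obs_sd == 0):
        bad = [nm for nm, s in zip(cm.spec.latent_names, lat_sd) if s == 0]
        bad += [nm for nm, s in zip(cm.spec.observed_names, obs_sd) if s == 0]
        raise SemEvalError(f"zero implied variance for: {bad}")
    out: dict[tuple[str, str], float] = {}
    lam, bet, psi, the = cm.matrices(x)
    lat, obs = cm.spec.latent_names, cm.spec.observed_names
    for c, e, st in cm.spec.paths:
        b = bet[cm.lat_index[e], cm.lat_index[c]]
        out[(c, e)] = float(b * lat_sd[cm.lat_index[c]] / lat_sd[cm.lat_index[e]])
    for a, b_, st in cm.spec.psi:
        if a != b_:
            ia, ib = cm.lat_index[a], cm.lat_index[b_]
            out[(a, b_)] = float(V[ia, ib] / (lat_sd[ia] * lat_sd[ib]))
    for o, l, st in cm.spec.loadings:
        io_, il = cm.obs_index[o], cm.lat_index[l]
        out[(l, o)] = float(lam[io_, il] * lat_sd[il] / obs_sd[io_])
    return out


def total_effects(fit: FitResult):
    """Standardized total effects among latents: (I - B_std)^-1 - I.

    Returns a pandas DataFrame with rows = causes, columns = effects.
    """
    import pandas as pd

    cm, x = _fit_internals(fit)
    _, bet, _, _ = cm.matrices(x)
    V = _latent_cov(cm, x)
    sd = np.sqrt(np.maximum(np.diag(V), 1e-300))
    # B_std[e, c] = B[e, c] * sd_c / sd_e
    b_std = bet * (sd[None, :] / sd[:, None])
    total = sla.solve(np.eye(cm.m) - b_std, np.eye(cm.m)) - np.eye(cm.m)
    # total[e, c] is cause c -> effect e; transpose to rows = cause
    return pd.DataFrame(total.T, index=cm.spec.latent_names,
                        columns=cm.spec.latent_names)
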