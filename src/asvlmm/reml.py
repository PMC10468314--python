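"""Multi-kernel REML engine for Gaussian linear mixed models.

Fits models of the form

    y = X b + sum_i Z_i u_i + e,      u_i ~ N(0, K_i s2_i),   e ~ N(0, R0 s2_e)

by restricted maximum likelihood, where each random term carries an arbitrary
covariance ``K_i`` over its levels (a genomic relationship kernel, a scaled
identity, or the identity) and the residual base structure ``R0`` may be the
identity, a diagonal weight structure, or a full covariance (the inverse of a
supplied weight matrix).  Any component, including the residual, may be fixed
at a known value — the device that lets stage-two fits carry a unit residual
with a fixed inverse-covariance weight matrix from stage one.

The optimizer runs a short expectation-maximization warm-up followed by
average-information (AI) updates, with step-halving back to an EM step
whenever an AI step fails to increase the restricted likelihood.  Components
driven negative are bent to a small positive boundary and constrained there
if they return.  All computations use the marginal covariance V directly;
singular kernels are handled naturally (V stays positive definite through the
residual) with the kernel's retained spectral rank used as the effective
dimension in EM updates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg as sla
from scipy import sparse
from scipy import stats

from .kernels import Kernel

__all__ = [
    "RandomTerm",
    "ResidualSpec",
    "ModelSpec",
    "FitResult",
    "fit_reml",
    "reml_loglik",
    "compute_blups",
    "lr_test",
]

#: lower bound for a bent variance component, as a fraction of var(y)
BOUNDARY_FRACTION = 1e-10
#: default convergence tolerance on the max relative component change
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 200


# ---------------------------------------------------------------------------
# model description
# ---------------------------------------------------------------------------


@dataclass
class RandomTerm:
    """One random term of a mixed model.

    Exactly one of ``codes`` (observation -> level index, factor incidence)
    or ``Z`` (dense incidence matrix) must be given.  ``kernel`` is the
    covariance over levels; ``None`` means identity.  ``fixed_value`` pins the
    variance component; ``init`` overrides the default initial value.
    """

    name: str
    codes: Optional[np.ndarray] = None
    Z: Optional[np.ndarray] = None
    kernel: Optional[Kernel | np.ndarray] = None
    fixed_value: Optional[float] = None
    init: Optional[float] = None
    levels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if (self.codes is None) == (self.Z is None):
            raise ValueError(f"term {self.name}: give exactly one of codes or Z")
        if self.codes is not None:
            self.codes = np.asarray(self.codes, dtype=int)

    def kernel_values(self) -> Optional[np.ndarray]:
        if self.kernel is None:
            return None
        if isinstance(self.kernel, Kernel):
            return self.kernel.values
        return np.asarray(self.kernel, dtype=float)

    def n_levels(self) -> int:
        K = self.kernel_values()
        if K is not None:
            return K.shape[0]
        if self.codes is not None:
            return int(self.codes.max()) + 1
        return self.Z.shape[1]

    def build_G(self, n_obs: int) -> np.ndarray:
        """Dense marginal contribution Z K Z^T (unit variance)."""
        K = self.kernel_values()
        if self.codes is not None:
            if len(self.codes) != n_obs:
                raise ValueError(f"term {self.name}: codes length mismatch")
            if K is None:
                return (self.codes[:, None] == self.codes[None, :]).astype(float)
            return K[np.ix_(self.codes, self.codes)]
        Z = np.asarray(self.Z, dtype=float)
        if Z.shape[0] != n_obs:
            raise ValueError(f"term {self.name}: Z row mismatch")
        return Z @ Z.T if K is None else Z @ K @ Z.T

    def effective_rank(self, n_obs: int) -> int:
        K = self.kernel_values()
        if K is None:
            if self.codes is not None:
                return int(len(np.unique(self.codes)))
            return int(np.linalg.matrix_rank(self.Z))
        ev = np.linalg.eigvalsh(K)
        return int((ev > 1e-10 * max(ev[-1], 0.0)).sum())


@dataclass
class ResidualSpec:
    """Residual structure: base covariance R0 and its variance constraint.

    ``kind`` is one of ``identity``, ``diagonal`` (per-observation weights
    ``w``, R0 = diag(1/w)) or ``full`` (weight matrix W = Omega^{-1}, so
    R0 = Omega).  Either ``omega`` or ``weight`` may be supplied for the full
    kind; whichever is missing is computed once by inversion.
    """

    kind: str = "identity"
    weights: Optional[np.ndarray] = None
    omega: Optional[np.ndarray] = None
    weight_matrix: Optional[np.ndarray] = None
    fixed_value: Optional[float] = None
    init: Optional[float] = None

    def base_covariance(self, n_obs: int) -> np.ndarray:
        if self.kind == "identity":
            return np.eye(n_obs)
        if self.kind == "diagonal":
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (n_obs,):
                raise ValueError("diagonal residual weights must have one entry per observation")
            if (w <= 0).any():
                raise ValueError("residual weights must be positive")
            return np.diag(1.0 / w)
        if self.kind == "full":
            if self.omega is not None:
                R0 = np.asarray(self.omega, dtype=float)
            elif self.weight_matrix is not None:
                W = np.asarray(self.weight_matrix, dtype=float)
                try:
                    R0 = _chol_inverse(W)[0]
                except np.linalg.LinAlgError as exc:
                    raise ValueError("residual weight matrix is not positive definite") from exc
            else:
                raise ValueError("full residual structure requires omega or weight_matrix")
            if R0.shape != (n_obs, n_obs):
                raise ValueError("residual structure dimension mismatch")
            ev_min = float(np.linalg.eigvalsh(R0)[0])
            if ev_min <= 0:
                raise ValueError("residual covariance structure must be positive definite")
            return 0.5 * (R0 + R0.T)
        raise ValueError(f"unknown residual kind {self.kind!r}")


@dataclass
class ModelSpec:
    """Declarative mixed-model description.

    ``fixed`` may be "intercept" (default), "none" (no fixed effects), or a
    dense design matrix.  Random terms are fitted in order; the residual is
    described by ``residual``.
    """

    terms: list[RandomTerm]
    fixed: object = "intercept"
    residual: ResidualSpec = field(default_factory=ResidualSpec)

    def fixed_design(self, n_obs: int) -> np.ndarray:
        if isinstance(self.fixed, str):
            if self.fixed == "intercept":
                return np.ones((n_obs, 1))
            if self.fixed == "none":
                return np.zeros((n_obs, 0))
            raise ValueError(f"unknown fixed-effect spec {self.fixed!r}")
        X = np.asarray(self.fixed, dtype=float)
        if X.ndim != 2 or X.shape[0] != n_obs:
            raise ValueError("fixed design matrix has wrong shape")
        return X

    def free_names(self) -> list[str]:
        names = [t.name for t in self.terms if t.fixed_value is None]
        if self.residual.fixed_value is None:
            names.append("residual")
        return names


@dataclass
class FitResult:
    """REML estimates plus everything downstream scaling and staging need."""

    components: dict[str, float]
    constraints: dict[str, str]  # free | fixed | boundary
    beta: np.ndarray
    var_beta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    trace: list[dict]
    n_obs: int
    blups: dict[str, np.ndarray] = field(default_factory=dict)
    fixed_signature: tuple = ()
    py: Optional[np.ndarray] = None  # V^{-1}(y - X beta), cached for BLUPs


# ---------------------------------------------------------------------------
# linear algebra helpers
# ---------------------------------------------------------------------------


def _chol_inverse(A: np.ndarray) -> tuple[np.ndarray, float]:
    """(A^{-1}, log|A|) via Cholesky; raises LinAlgError if not PD."""
    c, info = sla.lapack.dpotrf(A, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError(f"matrix not positive definite (dpotrf info={info})")
    logdet = 2.0 * float(np.log(np.diag(c)).sum())
    inv, info = sla.lapack.dpotri(c, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("dpotri failed")
    inv = np.tril(inv) + np.tril(inv, -1).T
    return inv, logdet


class _TermOps:
    """Per-term products that exploit the factor incidence when available.

    ``G`` (the dense marginal contribution Z K Z^T) is kept for assembling V;
    matrix products and traces against other dense matrices go through the
    sparse incidence so an iteration costs one Cholesky factorization plus
    O(n^2) bookkeeping rather than repeated n^2 q matmuls.
    """

    def __init__(self, n: int, codes=None, Z=None, K=None, R0=None):
        self.n = n
        self.K = K
        self.identity = False
        if R0 is not None:  # residual base covariance: no incidence structure
            self.G = R0
            self.Zs = None
            self.identity = R0.shape == (n, n) and np.array_equal(R0, np.eye(n))
        elif codes is not None and K is None and len(np.unique(codes)) == n:
            # observation-level identity term (e.g. G-by-E over cells)
            self.G = np.eye(n)
            self.Zs = None
            self.identity = True
        elif codes is not None:
            q = K.shape[0] if K is not None else int(codes.max()) + 1
            self.Zs = sparse.csr_matrix(
                (np.ones(n), (np.arange(n), codes)), shape=(n, q)
            )
            if K is None:
                self.G = (codes[:, None] == codes[None, :]).astype(float)
            else:
                self.G = K[np.ix_(codes, codes)]
        else:
            Z = np.asarray(Z, dtype=float)
            self.Zs = sparse.csr_matrix(Z)
            self.G = Z @ Z.T if K is None else Z @ K @ Z.T

    def apply(self, M: np.ndarray) -> np.ndarray:
        """G @ M through the incidence structure."""
        if self.identity:
            return M
        if self.Zs is None:
            return self.G @ M
        t = self.Zs.T @ M
        if self.K is not None:
            t = self.K @ t
        return self.Zs @ t

    def trace_with(self, S: np.ndarray) -> float:
        """tr(S G) = sum(S * G) for symmetric dense S."""
        if self.identity:
            return float(np.trace(S))
        if self.Zs is None:
            return float(np.sum(S * self.G))
        B = self.Zs.T @ S  # q x n
        A = (self.Zs.T @ B.T).T  # q x q = Z' S Z
        if self.K is None:
            return float(np.trace(A))
        return float(np.sum(self.K * A))


class _Workspace:
    """Precomputed marginal contributions for one model/data pair."""

    def __init__(self, spec: ModelSpec, y: np.ndarray):
        y = np.asarray(y, dtype=float).ravel()
        self.y = y
        self.n = len(y)
        self.X = spec.fixed_design(self.n)
        self.p = self.X.shape[1]
        if self.n <= self.p:
            raise ValueError("more fixed-effect columns than observations")
        self.names = [t.name for t in spec.terms] + ["residual"]
        self.ops = {
            t.name: _TermOps(self.n, codes=t.codes, Z=t.Z, K=t.kernel_values())
            for t in spec.terms
        }
        self.ops["residual"] = _TermOps(self.n, R0=spec.residual.base_covariance(self.n))
        self.rank = {t.name: t.effective_rank(self.n) for t in spec.terms}
        self.rank["residual"] = self.n
        self.fixed_values = {
            t.name: t.fixed_value for t in spec.terms if t.fixed_value is not None
        }
        if spec.residual.fixed_value is not None:
            self.fixed_values["residual"] = spec.residual.fixed_value
        self.free = [nm for nm in self.names if nm not in self.fixed_values]
        self.spec = spec

    def build_V(self, sigma: dict[str, float]) -> np.ndarray:
        V = np.zeros((self.n, self.n))
        for nm in self.names:
            V += sigma[nm] * self.ops[nm].G
        return V

    def initial(self, init: Optional[dict[str, float]]) -> dict[str, float]:
        sigma = dict(self.fixed_values)
        vy = float(np.var(self.y, ddof=1))
        fixed_part = sum(
            v * float(np.mean(np.diag(self.ops[nm].G)))
            for nm, v in self.fixed_values.items()
        )
        base = max(vy - fixed_part, 0.05 * vy)
        for nm in self.free:
            start = base / max(len(self.free), 1)
            if init and nm in init:
                start = float(init[nm])
            else:
                term_init = None
                if nm == "residual":
                    term_init = self.spec.residual.init
                else:
                    term = next(t for t in self.spec.terms if t.name == nm)
                    term_init = term.init
                if term_init is not None:
                    start = float(term_init)
            sigma[nm] = max(start, BOUNDARY_FRACTION * vy)
        return sigma


def _restricted_loglik_pieces(ws: _Workspace, sigma: dict[str, float]):
    """V^{-1}, Py, loglik and fixed-effect pieces at the given components."""
    V = ws.build_V(sigma)
    Vinv, logdetV = _chol_inverse(V)
    y, X, n, p = ws.y, ws.X, ws.n, ws.p
    if p:
        WX = Vinv @ X
        C = X.T @ WX
        Cinv, logdetC = _chol_inverse(C)
        beta = Cinv @ (WX.T @ y)
        Py = Vinv @ y - WX @ beta
    else:
        WX = np.zeros((n, 0))
        Cinv = np.zeros((0, 0))
        logdetC = 0.0
        beta = np.zeros(0)
        Py = Vinv @ y
    ll = -0.5 * (logdetV + logdetC + float(y @ Py) + (n - p) * math.log(2.0 * math.pi))
    return Vinv, WX, Cinv, beta, Py, ll


def _loglik_value(ws: _Workspace, sigma: dict[str, float]) -> float:
    """Restricted log-likelihood only (Cholesky solves, no explicit inverse)."""
    V = ws.build_V(sigma)
    c, info = sla.lapack.dpotrf(V, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("matrix not positive definite")
    logdetV = 2.0 * float(np.log(np.diag(c)).sum())
    y, X, n, p = ws.y, ws.X, ws.n, ws.p
    Viy = sla.cho_solve((c, True), y)
    if p:
        ViX = sla.cho_solve((c, True), X)
        C = X.T @ ViX
        cc, info2 = sla.lapack.dpotrf(C, lower=1)
        if info2 != 0:
            raise np.linalg.LinAlgError("X'V^{-1}X not positive definite")
        logdetC = 2.0 * float(np.log(np.diag(cc)).sum())
        xv_y = ViX.T @ y
        beta = sla.cho_solve((cc, True), xv_y)
        ypy = float(y @ Viy) - float(xv_y @ beta)
    else:
        logdetC = 0.0
        ypy = float(y @ Viy)
    return -0.5 * (logdetV + logdetC + ypy + (n - p) * math.log(2.0 * math.pi))


def reml_loglik(spec: ModelSpec, y: np.ndarray, components: dict[str, float]) -> float:
    """Restricted log-likelihood at the supplied variance components.

    Raises ``LinAlgError`` if the implied marginal covariance is not positive
    definite.
    """
    ws = _Workspace(spec, y)
    sigma = dict(components)
    for nm, v in ws.fixed_values.items():
        sigma.setdefault(nm, v)
    missing = [nm for nm in ws.names if nm not in sigma]
    if missing:
        raise ValueError(f"components missing for terms: {missing}")
    return _loglik_value(ws, sigma)


# ---------------------------------------------------------------------------
# the fit
# ---------------------------------------------------------------------------


def fit_reml(
    spec: ModelSpec,
    y: np.ndarray,
    *,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    em_warmup: int = 2,
    algorithm: str = "ai",
    init: Optional[dict[str, float]] = None,
    compute_blups_flag: bool = True,
) -> FitResult:
    """Maximize the restricted likelihood over the free variance components.

    Parameters
    ----------
    spec, y
        Model description and response vector.
    algorithm
        ``"ai"`` (default): EM warm-up then average-information updates with
        an EM fallback whenever an AI step does not improve the likelihood.
        ``"em"``: pure expectation-maximization, monotone in the likelihood.
    em_warmup
        Number of leading EM iterations in the ``"ai"`` schedule.
    init
        Optional starting values per component name; defaults to an equal
        split of the response variance across free components.

    Returns a :class:`FitResult`; non-convergence within ``max_iter`` is
    flagged, not raised.
    """
    ws = _Workspace(spec, y)
    sigma = ws.initial(init)
    vy = float(np.var(ws.y, ddof=1))
    boundary = BOUNDARY_FRACTION * max(vy, np.finfo(float).tiny)
    bend_counts = {nm: 0 for nm in ws.free}
    constrained: set[str] = set()

    trace: list[dict] = []
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        free = [nm for nm in ws.free if nm not in constrained]
        if not free:
            break
        Vinv, WX, Cinv, beta, Py, ll = _restricted_loglik_pieces(ws, sigma)

        # score pieces: tr(P G_i) and y'P G_i P y per free component
        tr_pg = {}
        quad = {}
        u = {}
        for nm in free:
            op = ws.ops[nm]
            t = op.trace_with(Vinv)
            if ws.p:
                GWX = op.apply(WX)
                t -= float(np.sum(Cinv * (WX.T @ GWX)))
            tr_pg[nm] = t
            u[nm] = op.apply(Py)
            quad[nm] = float(Py @ u[nm])

        use_em = algorithm == "em" or it <= em_warmup
        new_sigma = dict(sigma)
        if use_em:
            for nm in free:
                s = sigma[nm]
                upd = s + (s * s / ws.rank[nm]) * (quad[nm] - tr_pg[nm])
                new_sigma[nm] = max(upd, boundary)
        else:
            score = np.array([-0.5 * (tr_pg[nm] - quad[nm]) for nm in free])
            k = len(free)
            AI = np.empty((k, k))
            pu = {}
            for nm in free:
                if ws.p:
                    pu[nm] = Vinv @ u[nm] - WX @ (Cinv @ (WX.T @ u[nm]))
                else:
                    pu[nm] = Vinv @ u[nm]
            for a, na in enumerate(free):
                for b in range(a, k):
                    AI[a, b] = AI[b, a] = 0.5 * float(u[na] @ pu[free[b]])
            ridge = 1e-10 * max(np.abs(np.diag(AI)).max(), 1.0)
            try:
                delta = np.linalg.solve(AI + ridge * np.eye(k), score)
            except np.linalg.LinAlgError:
                delta = None
            stepped = False
            if delta is not None and np.isfinite(delta).all():
                step = 1.0
                for half in range(6):  # step halving against likelihood decreases
                    cand = dict(sigma)
                    rel = 0.0
                    for nm, d in zip(free, delta):
                        cand[nm] = max(sigma[nm] + step * d, boundary)
                        rel = max(rel, abs(cand[nm] - sigma[nm]) / max(sigma[nm], boundary))
                    if half == 0 and rel < 0.2:
                        # small AI step near the optimum: accept without the
                        # extra factorization (monotonicity guarded by the
                        # next iteration's likelihood evaluation)
                        new_sigma = cand
                        stepped = True
                        break
                    try:
                        cand_ll = _loglik_value(ws, cand)
                    except np.linalg.LinAlgError:
                        cand_ll = -np.inf
                    if cand_ll >= ll - 1e-10 * max(abs(ll), 1.0):
                        new_sigma = cand
                        stepped = True
                        break
                    step *= 0.5
            if not stepped:  # EM fallback keeps the ascent property
                for nm in free:
                    s = sigma[nm]
                    upd = s + (s * s / ws.rank[nm]) * (quad[nm] - tr_pg[nm])
                    new_sigma[nm] = max(upd, boundary)

        # bend-and-fix rule for components pinned at the boundary
        for nm in free:
            if new_sigma[nm] <= boundary * (1.0 + 1e-12):
                bend_counts[nm] += 1
                if bend_counts[nm] >= 2:
                    constrained.add(nm)
                    new_sigma[nm] = boundary

        rel_change = max(
            abs(new_sigma[nm] - sigma[nm]) / max(abs(sigma[nm]), boundary) for nm in free
        )
        trace.append(
            {"iter": it, "loglik": ll, "components": dict(sigma), "rel_change": rel_change}
        )
        sigma = new_sigma
        prev_ll = ll
        if rel_change < tol:
            converged = True
            break

    Vinv, WX, Cinv, beta, Py, ll = _restricted_loglik_pieces(ws, sigma)
    trace.append({"iter": it + 1, "loglik": ll, "components": dict(sigma), "rel_change": 0.0})

    constraints = {}
    for nm in ws.names:
        if nm in ws.fixed_values:
            constraints[nm] = "fixed"
        elif nm in constrained:
            constraints[nm] = "boundary"
        else:
            constraints[nm] = "free"

    Xsig = (ws.p, float(np.abs(ws.X).sum()), float((ws.X * ws.X).sum()))
    fit = FitResult(
        components={nm: float(sigma[nm]) for nm in ws.names},
        constraints=constraints,
        beta=beta,
        var_beta=Cinv,
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        trace=trace,
        n_obs=ws.n,
        fixed_signature=Xsig,
        py=Py,
    )
    if compute_blups_flag:
        fit.blups = compute_blups(fit, spec, y)
    return fit


def compute_blups(fit: FitResult, spec: ModelSpec, y: np.ndarray) -> dict[str, np.ndarray]:
    """Best linear unbiased predictors u_i = s2_i K_i Z_i' V^{-1}(y - X b).

    Terms with a zero (boundary) component return all-zero predictions; terms
    with centered ASV kernels return effects summing to approximately zero.
    """
    if fit.py is None:
        ws = _Workspace(spec, y)
        py = _restricted_loglik_pieces(ws, fit.components)[4]
    else:
        py = fit.py
    out: dict[str, np.ndarray] = {}
    for term in spec.terms:
        q = term.n_levels()
        if term.codes is not None:
            agg = np.bincount(term.codes, weights=py, minlength=q)
        else:
            agg = np.asarray(term.Z, dtype=float).T @ py
        K = term.kernel_values()
        u = agg if K is None else K @ agg
        out[term.name] = fit.components[term.name] * u
    return out


def lr_test(
    fit_null: FitResult, fit_alt: FitResult, df_boundary: int = 1
) -> tuple[float, float]:
    """Likelihood-ratio test between nested REML fits.

    The statistic is clipped at zero and referred to a 50:50 mixture of a
    point mass at zero and chi-square(df_boundary), the standard boundary
    correction for testing extra variance components.  REML likelihoods are
    only comparable across models with identical fixed effects; differing
    fixed designs raise a ``ValueError``.
    """
    if fit_null.n_obs != fit_alt.n_obs or fit_null.fixed_signature != fit_alt.fixed_signature:
        raise ValueError("REML likelihoods are not comparable: fixed effects differ")
    lr = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    p = 0.5 * float(stats.chi2.sf(lr, df_boundary))
    if lr <= 0.0:
        p += 0.5
    return lr, min(p, 1.0)
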