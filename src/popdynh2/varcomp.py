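"""Genetic relatedness matrices and REML variance-component estimation.

The mixed model is ``y = X b + g + e`` with ``cov(g) = sigma2_g * GRM`` and
``cov(e) = sigma2_e * I``; SNP heritability is ``sigma2_g / (sigma2_g +
sigma2_e)``.  The bivariate model adds a genetic covariance between two
traits, and the genetic correlation is ``cov_g / sqrt(var_gA * var_gB)``.

Fitting exploits the single-GRM structure: after an eigendecomposition
``GRM = U diag(lam) U'`` the rotated observations decouple into independent
1x1 (univariate) or 2x2 (bivariate) blocks with covariance
``lam_i * G + E``, so every likelihood, gradient and average-information
quantity is O(n) per evaluation.  Updates are a small number of EM-REML
warm-up steps followed by average-information steps with step-halving, so
the restricted log-likelihood never decreases across accepted iterations.

Haseman-Elston regression (phenotype cross-products on GRM off-diagonals)
is provided as an independent method-of-moments estimator of the same
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy import stats

from .exceptions import DataError, NonIdentifiableError

__all__ = [
    "GRMatrix",
    "VarianceFit",
    "compute_grm",
    "compute_pcs",
    "inverse_normal_transform",
    "reml_univariate",
    "reml_bivariate",
    "he_regression",
    "he_regression_cross",
    "prune_related",
]


@dataclass
class GRMatrix:
    """Symmetric relatedness matrix with individual ids and per-pair SNP counts."""

    ids: list[str]
    values: np.ndarray
    n_snps_per_pair: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise DataError("GRM dimensions do not match id count")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise DataError("GRM must be symmetric")
        if np.any(np.diag(self.values) <= 0):
            raise DataError("GRM diagonal entries must be positive")

    def subset(self, idx: np.ndarray) -> "GRMatrix":
        return GRMatrix(
            ids=[self.ids[i] for i in idx],
            values=self.values[np.ix_(idx, idx)],
            n_snps_per_pair=self.n_snps_per_pair[np.ix_(idx, idx)],
        )


@dataclass
class VarianceFit:
    """REML estimates for one (or a pair of) trait(s)."""

    sigma2_g: float
    sigma2_e: float
    h2: float
    se_h2: float
    loglik: float
    n_iter: int
    converged: bool
    n: int
    beta: np.ndarray
    boundary: bool = False
    se_sigma2_g: float = np.nan
    se_sigma2_e: float = np.nan
    # bivariate extras
    sigma2_g_A: float = np.nan
    sigma2_g_B: float = np.nan
    sigma2_e_A: float = np.nan
    sigma2_e_B: float = np.nan
    cov_g: float = np.nan
    cov_e: float = np.nan
    rg: float = np.nan
    se_rg: float = np.nan
    h2_A: float = np.nan
    se_h2_A: float = np.nan
    h2_B: float = np.nan
    se_h2_B: float = np.nan
    r_p: float = np.nan
    se_rp: float = np.nan
    loglik_trace: list = field(default_factory=list)


# ------------------------------------------------------------------ GRM / PCs
def compute_grm(
    dosages: np.ndarray,
    ids: list[str] | None = None,
    allele_freqs: np.ndarray | None = None,
) -> GRMatrix:
    """Standardized-dosage GRM: mean over variants of
    ``(x_ij - 2 p_j)(x_ik - 2 p_j) / (2 p_j (1 - p_j))``.

    Frequencies default to sample estimates; monomorphic variants are
    excluded.
    """
    dosages = np.asarray(dosages, dtype=np.float32)
    n, m = dosages.shape
    if n < 2:
        raise DataError("GRM requires at least two individuals")
    p = allele_freqs if allele_freqs is not None else dosages.mean(axis=0) / 2.0
    p = np.asarray(p, dtype=np.float64)
    poly = (p > 0.0) & (p < 1.0)
    if not np.any(poly):
        raise DataError("all variants are monomorphic; GRM undefined")
    Z = (dosages[:, poly] - 2.0 * p[poly]) / np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
    Z = Z.astype(np.float32)
    m_used = int(poly.sum())
    vals = (Z @ Z.T).astype(np.float64) / m_used
    vals = 0.5 * (vals + vals.T)
    if ids is None:
        ids = [f"I{i:06d}" for i in range(n)]
    return GRMatrix(
        ids=list(ids),
        values=vals,
        n_snps_per_pair=np.full((n, n), m_used, dtype=int),
    )


def compute_pcs(grm_or_dosages, k: int) -> np.ndarray:
    """Leading principal-component scores (n x k) of the genotype covariance.

    Deterministic up to sign; the sign is fixed so the largest-magnitude
    loading of each component is positive.
    """
    if k <= 0:
        raise DataError("k must be a positive integer")
    if isinstance(grm_or_dosages, GRMatrix):
        G = grm_or_dosages.values
    else:
        G = compute_grm(np.asarray(grm_or_dosages)).values
    n = G.shape[0]
    if k >= n:
        raise DataError("k must be smaller than the number of individuals")
    lam, vec = scipy.linalg.eigh(G, subset_by_index=(n - k, n - 1))
    lam, vec = lam[::-1], vec[:, ::-1]
    scores = vec * np.sqrt(np.maximum(lam, 0.0))
    for j in range(k):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    Output is the standard-normal quantile of ``(rank - 3/8) / (n + 1/4)``;
    ties share their mean rank, missing values stay missing.
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    ok = ~np.isnan(x)
    n = int(ok.sum())
    if n < 2:
        raise DataError("inverse normal transform needs >= 2 non-missing values")
    if np.ptp(x[ok]) == 0:
        raise DataError("inverse normal transform undefined for constant input")
    ranks = stats.rankdata(x[ok], method="average")
    out[ok] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


# ------------------------------------------------------------------ REML core
def _prep_xy(y, X, grm: GRMatrix):
    """Complete-case filter, covariate checks, shared eigendecomposition."""
    Y = np.column_stack([np.asarray(v, dtype=float) for v in y])
    n_all = Y.shape[0]
    if X is None:
        X = np.ones((n_all, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.allclose(X[:, 0], 1.0):
        X = np.column_stack([np.ones(n_all), X])
    keep = ~(np.isnan(Y).any(axis=1) | np.isnan(X).any(axis=1))
    idx = np.flatnonzero(keep)
    Y, X = Y[idx], X[idx]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError("covariate matrix is singular")
    G = grm.values[np.ix_(idx, idx)]
    lam, U = scipy.linalg.eigh(G)
    lam = np.maximum(lam, 0.0)
    if np.ptp(lam) < 1e-8:
        raise NonIdentifiableError(
            "GRM eigenvalues are constant (e.g. identity): genetic and residual "
            "variance are not separately identifiable"
        )
    return U.T @ Y, U.T @ X, lam, idx, X.shape[1]


class _BlockREML:
    """AI-REML over independent t x t blocks with covariance lam_i*G + E."""

    def __init__(self, Yr, Xr, lam, n_traits):
        self.Y = Yr
        self.X = Xr
        self.lam = lam
        self.t = n_traits
        self.n, self.k = Xr.shape
        # parameter layout: vech(G) then vech(E), diagonal first
        if n_traits == 1:
            self.basis = [("g", np.array([[1.0]])), ("e", np.array([[1.0]]))]
        else:
            b = [np.array([[1.0, 0], [0, 0]]), np.array([[0, 0], [0, 1.0]]),
                 np.array([[0, 1.0], [1.0, 0]])]
            self.basis = [("g", m) for m in b] + [("e", m) for m in b]

    # -- parameter packing
    def unpack(self, theta):
        t = self.t
        if t == 1:
            G = np.array([[theta[0]]])
            E = np.array([[theta[1]]])
        else:
            G = np.array([[theta[0], theta[2]], [theta[2], theta[1]]])
            E = np.array([[theta[3], theta[5]], [theta[5], theta[4]]])
        return G, E

    def pack(self, G, E):
        if self.t == 1:
            return np.array([G[0, 0], E[0, 0]])
        return np.array([G[0, 0], G[1, 1], G[0, 1], E[0, 0], E[1, 1], E[0, 1]])

    def _state(self, theta):
        """All shared quantities at theta; None if V is not positive definite."""
        G, E = self.unpack(theta)
        V = self.lam[:, None, None] * G + E[None]  # (n, t, t)
        if self.t == 1:
            d = V[:, 0, 0]
            if np.any(d <= 0):
                return None
            Vinv = (1.0 / d)[:, None, None]
            logdetV = float(np.sum(np.log(d)))
        else:
            det = V[:, 0, 0] * V[:, 1, 1] - V[:, 0, 1] ** 2
            if np.any(det <= 0) or np.any(V[:, 0, 0] <= 0):
                return None
            Vinv = np.empty_like(V)
            Vinv[:, 0, 0] = V[:, 1, 1] / det
            Vinv[:, 1, 1] = V[:, 0, 0] / det
            Vinv[:, 0, 1] = Vinv[:, 1, 0] = -V[:, 0, 1] / det
            logdetV = float(np.sum(np.log(det)))

        X, Y = self.X, self.Y
        t, k = self.t, self.k
        # C = X' V^-1 X assembled from k x k blocks per trait pair
        C = np.empty((t * k, t * k))
        for a in range(t):
            for b in range(t):
                C[a * k:(a + 1) * k, b * k:(b + 1) * k] = X.T @ (Vinv[:, a, b, None] * X)
        c = np.concatenate([
            X.T @ np.sum(Vinv[:, a, :] * Y, axis=1) for a in range(t)
        ])
        try:
            Cf = scipy.linalg.cho_factor(C)
        except scipy.linalg.LinAlgError:
            return None
        beta = scipy.linalg.cho_solve(Cf, c)
        fitted = np.column_stack([X @ beta[a * k:(a + 1) * k] for a in range(t)])
        R = Y - fitted
        Py = np.einsum("iab,ib->ia", Vinv, R)
        yPy = float(np.sum(R * Py))
        logdetC = 2.0 * float(np.sum(np.log(np.diag(Cf[0]))))
        ll = -0.5 * (logdetV + logdetC + yPy)
        return dict(G=G, E=E, Vinv=Vinv, Cf=Cf, beta=beta, Py=Py, ll=ll)

    def _weights(self, kind):
        return self.lam if kind == "g" else np.ones(self.n)

    def _xtvinv_u(self, Vinv, Cf, u):
        """Project u through P: returns u'Pu-ready pieces (V^-1 u and X'V^-1 u)."""
        X, t, k = self.X, self.t, self.k
        Vu = np.einsum("iab,ib->ia", Vinv, u)
        xv = np.concatenate([X.T @ Vu[:, a] for a in range(t)])
        return Vu, xv

    def score_and_ai(self, st):
        Vinv, Cf, Py = st["Vinv"], st["Cf"], st["Py"]
        X, t, k = self.X, self.t, self.k
        p = len(self.basis)
        score = np.empty(p)
        us, Vus, xvs = [], [], []
        for j, (kind, B) in enumerate(self.basis):
            w = self._weights(kind)
            VB = np.einsum("iab,bc->iac", Vinv, B)
            trV = np.sum(w * np.trace(VB, axis1=1, axis2=2))
            VBV = np.einsum("iab,ibc->iac", VB, Vinv)
            M = np.empty((t * k, t * k))
            for a in range(t):
                for b in range(t):
                    M[a * k:(a + 1) * k, b * k:(b + 1) * k] = X.T @ (
                        (w * VBV[:, a, b])[:, None] * X
                    )
            trP = trV - float(np.trace(scipy.linalg.cho_solve(Cf, M)))
            u = w[:, None] * (Py @ B.T)
            q = float(np.sum(Py * u))
            score[j] = -0.5 * (trP - q)
            Vu, xv = self._xtvinv_u(Vinv, Cf, u)
            us.append(u)
            Vus.append(Vu)
            xvs.append(xv)
        ai = np.empty((p, p))
        for j in range(p):
            for l in range(j, p):
                val = 0.5 * (
                    float(np.sum(us[j] * Vus[l]))
                    - float(xvs[j] @ scipy.linalg.cho_solve(Cf, xvs[l]))
                )
                ai[j, l] = ai[l, j] = val
        return score, ai

    def em_step(self, theta, st):
        """Matrix EM-REML update of G and E (the GCTA EM step when t = 1)."""
        Vinv, Cf, Py = st["Vinv"], st["Cf"], st["Py"]
        X, t, k, n = self.X, self.t, self.k, self.n
        Cinv_blocks = scipy.linalg.cho_solve(Cf, np.eye(t * k))
        # s[i] = X_i Cinv X_i' (t x t); correction = Vinv s Vinv
        s = np.empty((n, t, t))
        for a in range(t):
            for b in range(t):
                s[:, a, b] = np.einsum(
                    "ip,pq,iq->i", X, Cinv_blocks[a * k:(a + 1) * k, b * k:(b + 1) * k], X
                )
        Pblock = Vinv - np.einsum("iac,icd,idb->iab", Vinv, s, Vinv)
        outer = np.einsum("ia,ib->iab", Py, Py)
        G, E = st["G"], st["E"]
        Sg = np.einsum("i,iab->ab", self.lam, outer - Pblock)
        Se = np.sum(outer - Pblock, axis=0)
        G_new = G + (G @ Sg @ G) / n
        E_new = E + (E @ Se @ E) / n
        return self.pack(G_new, E_new)


def _project_theta(theta, t, floor):
    """Clamp variances to the floor and keep covariance matrices valid."""
    theta = theta.copy()
    if t == 1:
        theta[0] = max(theta[0], floor[0])
        theta[1] = max(theta[1], floor[0])
        return theta
    for i, f in zip((0, 1, 3, 4), (floor[0], floor[1], floor[0], floor[1])):
        theta[i] = max(theta[i], f)
    cap_g = (1.0 - 1e-6) * np.sqrt(theta[0] * theta[1])
    theta[2] = np.clip(theta[2], -cap_g, cap_g)
    cap_e = (1.0 - 1e-6) * np.sqrt(theta[3] * theta[4])
    theta[5] = np.clip(theta[5], -cap_e, cap_e)
    return theta


def _fit_blocked(engine: _BlockREML, theta0, floor, max_iter=100, tol=1e-6, n_em=2):
    """EM warm-up then AI iterations with step-halving; returns (theta, state,
    covariance of theta, trace, n_iter, converged)."""
    t = engine.t
    theta = _project_theta(theta0, t, floor)
    st = engine._state(theta)
    if st is None:
        raise NonIdentifiableError("could not evaluate restricted likelihood at start")
    trace = [st["ll"]]
    n_iter = 0
    converged = False
    for it in range(max_iter):
        n_iter = it + 1
        if it < n_em:
            prop = _project_theta(engine.em_step(theta, st), t, floor)
            st_new = engine._state(prop)
            if st_new is None or st_new["ll"] < st["ll"] - 1e-10:
                st_new = st  # EM proposal rejected; fall through to AI next round
                prop = theta
            theta, st = prop, st_new
            trace.append(st["ll"])
            continue
        score, ai = engine.score_and_ai(st)
        try:
            delta = np.linalg.solve(ai + 1e-10 * np.eye(len(score)), score)
        except np.linalg.LinAlgError:
            raise NonIdentifiableError("average-information matrix is singular")
        step = 1.0
        for _ in range(12):
            prop = _project_theta(theta + step * delta, t, floor)
            st_new = engine._state(prop)
            if st_new is not None and st_new["ll"] >= st["ll"] - 1e-10:
                break
            step *= 0.5
        else:
            break  # cannot improve: treat current point as the optimum
        rel = abs(st_new["ll"] - st["ll"]) / max(1.0, abs(st["ll"]))
        theta, st = prop, st_new
        trace.append(st["ll"])
        if rel < tol:
            converged = True
            break
    score, ai = engine.score_and_ai(st)
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov = np.full((len(theta), len(theta)), np.nan)
    return theta, st, cov, trace, n_iter, converged


def reml_univariate(
    y,
    X,
    grm: GRMatrix,
    max_iter: int = 100,
    tol: float = 1e-6,
    n_em: int = 2,
) -> VarianceFit:
    """Univariate AI-REML fit of ``(sigma2_g, sigma2_e)`` and h2 with its SE.

    The SE of h2 is obtained by the delta method from the inverse
    average-information matrix.  Missing phenotype/covariate rows are
    dropped (complete-case).  Components are floored at 1e-6 times the
    phenotypic variance; a fit at the floor is flagged ``boundary``.
    """
    Yr, Xr, lam, idx, k = _prep_xy([y], X, grm)
    vary = float(np.var(Yr[:, 0]))
    floor = (1e-6 * vary,)
    engine = _BlockREML(Yr, Xr, lam, 1)
    theta0 = np.array([vary / 2.0, vary / 2.0])
    theta, st, cov, trace, n_iter, converged = _fit_blocked(
        engine, theta0, floor, max_iter=max_iter, tol=tol, n_em=n_em
    )
    sg, se_ = theta
    tot = sg + se_
    h2 = sg / tot
    grad = np.array([se_, -sg]) / tot**2
    se_h2 = float(np.sqrt(max(0.0, grad @ cov @ grad)))
    return VarianceFit(
        sigma2_g=float(sg),
        sigma2_e=float(se_),
        h2=float(np.clip(h2, 0.0, 1.0)),
        se_h2=se_h2,
        loglik=st["ll"],
        n_iter=n_iter,
        converged=converged,
        n=len(idx),
        beta=st["beta"],
        boundary=bool(sg <= floor[0] * 1.01 or se_ <= floor[0] * 1.01),
        se_sigma2_g=float(np.sqrt(max(0.0, cov[0, 0]))),
        se_sigma2_e=float(np.sqrt(max(0.0, cov[1, 1]))),
        loglik_trace=trace,
    )


def reml_bivariate(
    yA,
    yB,
    X,
    grm: GRMatrix,
    max_iter: int = 100,
    tol: float = 1e-6,
    n_em: int = 2,
) -> VarianceFit:
    """Bivariate AI-REML: genetic/residual (co)variances, rg, and r_p.

    Individuals missing either trait are dropped (complete-case on the
    pair).  ``r_p`` is the correlation of the covariate-residualized
    traits.  If either genetic variance sits at its floor, ``rg`` is
    reported as missing.
    """
    Yr, Xr, lam, idx, k = _prep_xy([yA, yB], X, grm)
    vA = float(np.var(Yr[:, 0]))
    vB = float(np.var(Yr[:, 1]))
    cAB = float(np.cov(Yr[:, 0], Yr[:, 1])[0, 1])
    floor = (1e-6 * vA, 1e-6 * vB)
    engine = _BlockREML(Yr, Xr, lam, 2)
    theta0 = np.array([vA / 2, vB / 2, cAB / 2, vA / 2, vB / 2, cAB / 2])
    theta, st, cov, trace, n_iter, converged = _fit_blocked(
        engine, theta0, floor, max_iter=max_iter, tol=tol, n_em=n_em
    )
    gA, gB, cg, eA, eB, ce = theta
    boundary = bool(gA <= floor[0] * 1.01 or gB <= floor[1] * 1.01)
    h2A = gA / (gA + eA)
    h2B = gB / (gB + eB)

    def h2_se(gi, ei, ig, ie):
        tot = gi + ei
        grad = np.zeros(6)
        grad[ig] = ei / tot**2
        grad[ie] = -gi / tot**2
        return float(np.sqrt(max(0.0, grad @ cov @ grad)))

    if boundary:
        rg, se_rg = np.nan, np.nan
    else:
        rg = cg / np.sqrt(gA * gB)
        grad = np.zeros(6)
        grad[0] = -rg / (2 * gA)
        grad[1] = -rg / (2 * gB)
        grad[2] = 1.0 / np.sqrt(gA * gB)
        se_rg = float(np.sqrt(max(0.0, grad @ cov @ grad)))

    # phenotypic correlation of covariate-residualized traits
    Q, _ = np.linalg.qr(Xr)
    RA = Yr[:, 0] - Q @ (Q.T @ Yr[:, 0])
    RB = Yr[:, 1] - Q @ (Q.T @ Yr[:, 1])
    r_p = float(np.corrcoef(RA, RB)[0, 1])
    n = len(idx)
    se_rp = float(np.sqrt((1.0 - r_p**2) / max(n - 2, 1)))

    return VarianceFit(
        sigma2_g=float(gA),
        sigma2_e=float(eA),
        h2=float(np.clip(h2A, 0, 1)),
        se_h2=h2_se(gA, eA, 0, 3),
        loglik=st["ll"],
        n_iter=n_iter,
        converged=converged,
        n=n,
        beta=st["beta"],
        boundary=boundary,
        sigma2_g_A=float(gA),
        sigma2_g_B=float(gB),
        sigma2_e_A=float(eA),
        sigma2_e_B=float(eB),
        cov_g=float(cg),
        cov_e=float(ce),
        rg=float(rg) if np.isfinite(rg) else np.nan,
        se_rg=se_rg,
        h2_A=float(np.clip(h2A, 0, 1)),
        se_h2_A=h2_se(gA, eA, 0, 3),
        h2_B=float(np.clip(h2B, 0, 1)),
        se_h2_B=h2_se(gB, eB, 1, 4),
        r_p=r_p,
        se_rp=se_rp,
        loglik_trace=trace,
    )


# ------------------------------------------------------------------ HE / pruning
def _residualize(y, X):
    y = np.asarray(y, dtype=float)
    if X is None:
        return y - y.mean()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    X = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def he_regression(y, grm: GRMatrix, X=None) -> tuple[float, float]:
    """Haseman-Elston h2: regress standardized phenotype cross-products on
    GRM off-diagonals.  Returns (h2, SE of the slope)."""
    y = _residualize(y, X)
    n = len(y)
    if n < 50:
        raise DataError("Haseman-Elston regression needs n >= 50")
    z = y / y.std()
    iu, ju = np.triu_indices(n, k=1)
    a = grm.values[iu, ju]
    if a.std() == 0:
        raise DataError("GRM off-diagonals have zero variance")
    prod = z[iu] * z[ju]
    slope, intercept = np.polyfit(a, prod, 1)
    resid = prod - (slope * a + intercept)
    se = float(np.sqrt(np.sum(resid**2) / (len(a) - 2) / np.sum((a - a.mean()) ** 2)))
    return float(slope), se


def he_regression_cross(yA, yB, grm: GRMatrix, X=None) -> tuple[float, float]:
    """Cross-trait Haseman-Elston: slope estimates the genetic covariance of
    standardized traits (co-heritability)."""
    zA = _residualize(yA, X)
    zB = _residualize(yB, X)
    n = len(zA)
    if n < 50:
        raise DataError("Haseman-Elston regression needs n >= 50")
    zA = zA / zA.std()
    zB = zB / zB.std()
    iu, ju = np.triu_indices(n, k=1)
    a = grm.values[iu, ju]
    if a.std() == 0:
        raise DataError("GRM off-diagonals have zero variance")
    prod = 0.5 * (zA[iu] * zB[ju] + zB[iu] * zA[ju])
    slope, intercept = np.polyfit(a, prod, 1)
    resid = prod - (slope * a + intercept)
    se = float(np.sqrt(np.sum(resid**2) / (len(a) - 2) / np.sum((a - a.mean()) ** 2)))
    return float(slope), se


def prune_related(grm: GRMatrix, threshold: float = 0.1) -> np.ndarray:
    """Greedy pruning: repeatedly drop the individual involved in the most
    pairs with relatedness above ``threshold``; returns kept indices."""
    A = np.abs(grm.values.copy())
    np.fill_diagonal(A, 0.0)
    keep = np.ones(A.shape[0], dtype=bool)
    while True:
        over = (A > threshold) & keep[:, None] & keep[None, :]
        counts = over.sum(axis=1)
        if counts.max() == 0:
            break
        keep[np.argmax(counts)] = False
    return np.flatnonzero(keep)
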