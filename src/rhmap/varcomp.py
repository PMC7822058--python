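"""Multi-kernel REML, BLUP back-solving, and likelihood-ratio tests.

The model is

    y = X beta + sum_k Z u_k + e,    u_k ~ N(0, sigma2_k K_k),  e ~ N(0, sigma2_e I)

with y the plot-level trait vector, X the fixed design (grand mean plus
trial-within-year-within-location cells), Z the plot-to-clone incidence,
and each K_k a clone-level kernel (a genomic relationship matrix, or the
identity for unrelated clones).

Variance components are estimated by EM-REML — guaranteed monotone in the
restricted log-likelihood and well behaved near the zero boundary — with an
average-information (AI) Newton step attempted after a short burn-in and
accepted only when it stays feasible and improves the likelihood.  The
restricted log-likelihood is reported without its data-independent constant,
identically for every model on the same data, so differences between nested
fits are exact LRT statistics.

EM update (valid for singular PSD kernels, via the factorization u = L a
with a ~ N(0, sigma2 I_q)):

    sigma2_k <- sigma2_k + sigma2_k^2 (y'P G_k P y - tr(P G_k)) / q_k

with G_k = Z K_k Z', q_k the kernel dimension (n for the residual), and
P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

log = logging.getLogger(__name__)

__all__ = ["ModelDesign", "VarCompFit", "LRTResult", "fit_reml", "blup", "lrt"]

_MONOTONE_SLACK = 1e-5


@dataclass
class ModelDesign:
    """Response, fixed design, clone incidence, and an ordered kernel list.

    ``kernels`` is a list of (label, K) with K a clone x clone PSD matrix
    or None for the identity.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    kernels: list

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        n = self.y.shape[0]
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError(
                f"row mismatch: y has {n}, X has {self.X.shape[0]}, Z has {self.Z.shape[0]}"
            )
        q = self.Z.shape[1]
        labels = [lab for lab, _ in self.kernels]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate kernel labels: {labels}")
        for lab, K in self.kernels:
            if K is not None and np.asarray(K).shape != (q, q):
                raise ValueError(f"kernel {lab!r} has shape {np.asarray(K).shape}, expected ({q}, {q})")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_clones(self) -> int:
        return self.Z.shape[1]

    def kernel_labels(self) -> list[str]:
        return [lab for lab, _ in self.kernels]


@dataclass
class VarCompFit:
    """A fitted multi-kernel model at the REML estimates."""

    variance_components: dict  # label -> sigma2, plus "residual"
    beta_hat: np.ndarray
    restricted_loglik: float
    blups: dict  # label -> clone-effect vector
    converged: bool
    n_iterations: int
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    def total_variance(self) -> float:
        return float(sum(self.variance_components.values()))

    def h2(self, label: str) -> float:
        """Fraction of variance attributed to one kernel."""
        return self.variance_components[label] / self.total_variance()


@dataclass
class LRTResult:
    """Likelihood-ratio test between nested variance-component models."""

    statistic: float
    df: int
    p_value: float


def _plot_kernels(design: ModelDesign) -> list[np.ndarray]:
    Z = design.Z
    out = []
    for _, K in design.kernels:
        out.append(Z @ Z.T if K is None else Z @ np.asarray(K, dtype=float) @ Z.T)
    return out


def _reml_pieces(y, X, V):
    """Return (loglik, P y, Vinv_X, XtViX_factor, Vfactor) for one V."""
    n, p = X.shape
    cf = cho_factor(V, lower=True)
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    Vi_X = cho_solve(cf, X)
    Vi_y = cho_solve(cf, y)
    XtViX = X.T @ Vi_X
    cfx = cho_factor(XtViX, lower=True)
    logdet_X = 2.0 * float(np.sum(np.log(np.diag(cfx[0]))))
    beta = cho_solve(cfx, X.T @ Vi_y)
    Py = Vi_y - Vi_X @ cho_solve(cfx, Vi_X.T @ y)
    yPy = float(y @ Py)
    ll = -0.5 * (logdet_V + logdet_X + yPy)
    return ll, Py, Vi_X, cfx, cf, beta


def _fit_single_kernel(design: ModelDesign, tol: float) -> VarCompFit:
    """Exact REML for one kernel + residual via eigen-rotation.

    V = sigma2_e (I + lam * G): rotate into the eigenbasis of G = Z K Z',
    profile out sigma2_e, and optimize the restricted likelihood over
    log(lam) with a bounded scalar search.  Returns the same constant-free
    log-likelihood as the multi-kernel path.
    """
    y, X = design.y, design.X
    n, p = X.shape
    label, _ = design.kernels[0]
    G = _plot_kernels(design)[0]
    d, U = np.linalg.eigh(G)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    def neg_profile(t: float) -> float:
        lam = np.exp(t)
        W = 1.0 + lam * d
        Xw = Xt / W[:, None]
        A = Xt.T @ Xw
        cfa = cho_factor(A, lower=True)
        beta = cho_solve(cfa, Xw.T @ yt)
        r = yt - Xt @ beta
        q = float(np.sum(r * r / W))
        sig_e = q / (n - p)
        logdet_A = 2.0 * float(np.sum(np.log(np.diag(cfa[0]))))
        ll = -0.5 * (float(np.sum(np.log(W))) + (n - p) * np.log(sig_e) + logdet_A + (n - p))
        return -ll

    # lam capped at 1e6: below sigma2_e ~ 1e-6 Var(y) the likelihood is flat
    # for PSD kernels and the covariance turns numerically singular
    res = optimize.minimize_scalar(neg_profile, bounds=(-25.0, np.log(1e6)),
                                   method="bounded", options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    W = 1.0 + lam * d
    Xw = Xt / W[:, None]
    A = Xt.T @ Xw
    cfa = cho_factor(A, lower=True)
    beta = cho_solve(cfa, Xw.T @ yt)
    r = yt - Xt @ beta
    sig_e = float(np.sum(r * r / W)) / (n - p)
    sig_u = lam * sig_e
    ll = -float(res.fun)
    fit = VarCompFit(
        variance_components={label: sig_u, "residual": sig_e},
        beta_hat=beta,
        restricted_loglik=ll,
        blups={},
        converged=True,
        n_iterations=int(res.nfev),
        loglik_path=np.array([ll]),
    )
    fit.blups = {label: blup(fit, design, label)}
    return fit


def fit_reml(
    design: ModelDesign,
    tol: float = 1e-8,
    max_iter: int = 1000,
    init: dict | None = None,
    use_ai: bool = True,
    ai_burn_in: int = 3,
) -> VarCompFit:
    """Estimate variance components by EM-REML with AI acceleration.

    Convergence is declared when the relative change in the restricted
    log-likelihood falls below ``tol``.  Components are floored at
    1e-10 x Var(y) rather than allowed negative.  Non-convergence is
    reported through ``converged``/``n_iterations``, never hidden.
    """
    y, X, Z = design.y, design.X, design.Z
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design X is singular")
    vy = float(np.var(y))
    if vy <= 0.0:
        raise ValueError("response has zero variance; nothing to partition")
    if n < p + 2:
        raise ValueError(f"too few records ({n}) for {p} fixed effects")

    if len(design.kernels) == 1 and init is None:
        return _fit_single_kernel(design, tol)

    labels = design.kernel_labels()
    Gs = _plot_kernels(design)
    q_clone = design.n_clones
    # kernel components may go to ~0; the residual keeps V numerically PD
    # (below 1e-6 Var(y) the restricted likelihood is flat anyway)
    k = len(Gs)
    floor = np.array([1e-10 * vy] * k + [1e-6 * vy])

    # start: equal split across kernels and residual (or caller-supplied)
    if init is None:
        sig = np.full(k + 1, vy / (k + 1))
    else:
        sig = np.array([init.get(lab, vy / (k + 1)) for lab in labels]
                       + [init.get("residual", vy / (k + 1))])
    sig = np.maximum(sig, floor)
    divisors = np.array([q_clone] * k + [n], dtype=float)

    def build_V(s):
        V = s[-1] * np.eye(n)
        for j in range(k):
            V += s[j] * Gs[j]
        return V

    ll_path = []
    converged = False
    it = 0
    ll, Py, Vi_X, cfx, cf, beta = _reml_pieces(y, X, build_V(sig))
    for it in range(1, max_iter + 1):
        # gradient pieces at the current V; with symmetric V^-1 and G_k,
        # tr(V^-1 G_k) is an elementwise product (n^2, not a full solve)
        GPy = [G @ Py for G in Gs] + [Py]
        Vi = cho_solve(cf, np.eye(n))
        trPG = []
        for j in range(k):
            GVi_X = Gs[j] @ Vi_X
            corr = cho_solve(cfx, Vi_X.T @ GVi_X)
            trPG.append(float(np.sum(Vi * Gs[j])) - float(np.trace(corr)))
        trPG.append(float(np.trace(Vi)) - float(np.trace(cho_solve(cfx, Vi_X.T @ Vi_X))))

        yPGPy = np.array([float(Py @ g) for g in GPy])
        trPG = np.array(trPG)
        score = 0.5 * (yPGPy - trPG)

        # components pinned at the floor with a negative gradient are held
        # fixed; Newton/AI steps act on the active set only
        active = (sig > floor * (1 + 1e-9)) | (score > 0)
        accepted = False
        if use_ai and it > ai_burn_in and active.any():
            PGPy_vec = [cho_solve(cf, g) - Vi_X @ cho_solve(cfx, Vi_X.T @ g) for g in GPy]
            AI = 0.5 * np.array([[float(GPy[i] @ PGPy_vec[j]) for j in range(k + 1)]
                                 for i in range(k + 1)])
            idx = np.flatnonzero(active)
            try:
                delta = np.linalg.solve(AI[np.ix_(idx, idx)], score[idx])
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None:
                for step_frac in (1.0, 0.5, 0.25, 0.1, 0.01):
                    cand = sig.copy()
                    cand[idx] = sig[idx] + step_frac * delta
                    cand = np.maximum(cand, floor)
                    try:
                        ll_c, Py_c, Vi_X_c, cfx_c, cf_c, beta_c = _reml_pieces(y, X, build_V(cand))
                    except np.linalg.LinAlgError:
                        continue  # overshoot made V or X'V^-1X numerically indefinite
                    if np.isfinite(ll_c) and ll_c >= ll - 1e-10:
                        sig, ll_new = cand, ll_c
                        Py, Vi_X, cfx, cf, beta = Py_c, Vi_X_c, cfx_c, cf_c, beta_c
                        accepted = True
                        break
        if not accepted:
            prev_sig, prev_beta = sig.copy(), beta
            sig = np.maximum(sig + sig**2 * (yPGPy - trPG) / divisors, floor)
            ll_new, Py, Vi_X, cfx, cf, beta = _reml_pieces(y, X, build_V(sig))
            if ll_new < ll - _MONOTONE_SLACK * (1.0 + abs(ll)):
                # near-stationary float wobble on an ill-conditioned V:
                # keep the best iterate rather than walking downhill
                log.warning(
                    "log-likelihood wobble at iteration %d (%.6f -> %.6f); "
                    "stopping at the previous iterate", it, ll, ll_new,
                )
                sig, beta = prev_sig, prev_beta
                converged = True
                break

        ll_path.append(ll_new)
        # never declare convergence before the first Newton attempt: tiny EM
        # steps from a near-boundary warm start would stall a weak signal
        min_it = ai_burn_in + 1 if use_ai else 1
        if abs(ll_new - ll) < tol * (1.0 + abs(ll_new)) and it > min_it:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    fit = VarCompFit(
        variance_components={**{lab: float(s) for lab, s in zip(labels, sig[:-1])},
                             "residual": float(sig[-1])},
        beta_hat=beta,
        restricted_loglik=float(ll),
        blups={},
        converged=converged,
        n_iterations=it,
        loglik_path=np.array(ll_path),
    )
    fit.blups = {lab: blup(fit, design, lab) for lab in labels}
    return fit


def blup(fit: VarCompFit, design: ModelDesign, kernel_label: str) -> np.ndarray:
    """Posterior-mean clone effects u_hat_k = sigma2_k K_k Z' V^-1 (y - X beta_hat)."""
    labels = design.kernel_labels()
    if kernel_label not in labels:
        raise KeyError(f"unknown kernel label {kernel_label!r}; model has {labels}")
    y, X, Z = design.y, design.X, design.Z
    n = design.n
    V = fit.variance_components["residual"] * np.eye(n)
    for (lab, K), G in zip(design.kernels, _plot_kernels(design)):
        V += fit.variance_components[lab] * G
    cf = cho_factor(V, lower=True)
    r = y - X @ fit.beta_hat
    Vir = cho_solve(cf, r)
    j = labels.index(kernel_label)
    K = design.kernels[j][1]
    s2 = fit.variance_components[kernel_label]
    KZt = Z.T if K is None else np.asarray(K, dtype=float) @ Z.T
    return s2 * (KZt @ Vir)


def lrt(fit_alt: VarCompFit, fit_null: VarCompFit, df: int = 1, mixture: bool = False) -> LRTResult:
    """LRT of nested fits: statistic = 2 * (llik_alt - llik_null), clamped at 0.

    ``mixture=True`` uses the boundary-correct 50:50 chi2_0/chi2_1 mixture
    instead of the plain upper-tail chi-square with ``df`` degrees of
    freedom.
    """
    stat = 2.0 * (fit_alt.restricted_loglik - fit_null.restricted_loglik)
    if stat < -0.05:
        raise ValueError(
            f"alternative log-likelihood below null by {stat / 2:.3g}: models are not "
            "nested on the same data, or a fit failed"
        )
    if stat < -1e-6:
        # optimizer slack on a boundary-null fit; clamping is conservative
        log.warning("clamping slightly negative LRT statistic %.3g to 0", stat)
    stat = max(stat, 0.0)
    if mixture:
        p = 1.0 if stat == 0.0 else 0.5 * float(stats.chi2.sf(stat, 1))
    else:
        p = float(stats.chi2.sf(stat, df))
    return LRTResult(statistic=float(stat), df=df, p_value=p)
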