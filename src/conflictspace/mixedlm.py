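"""Linear mixed models with crossed random effects and Satterthwaite df.

Implements the profiled-deviance formulation of Bates et al. (penalized
least squares on the spherical random effects) for models of the form

    y = X beta + sum_k Z_k b_k + e,   b_k ~ N(0, s2_k I),   e ~ N(0, s2 I)

where each random term is a grouping factor crossed with a small covariate
design (e.g. intercept + slope per subject) and the per-covariate variances
are independent (diagonal G).  This covers the crossed row/column random
effects needed for pairwise-cell regressions as well as ordinary
subject-level intercept+slope models.

Degrees of freedom for fixed-effect t-tests use the Satterthwaite
approximation: df = 2 f^2 / Var(f) with f = Var(c' beta_hat), the variance
of f propagated from the finite-difference Hessian of the (RE)ML deviance
with respect to the variance components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, sparse, stats

__all__ = ["RandomTerm", "MixedLM", "MixedLMResult"]


@dataclass
class RandomTerm:
    """One random-effects term: a grouping factor with covariate columns."""

    name: str
    groups: np.ndarray  # (n,) integer group codes in [0, n_groups)
    design: np.ndarray  # (n, m) covariate values
    colnames: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.groups = np.asarray(self.groups)
        if self.groups.dtype.kind not in "iu":
            _, self.groups = np.unique(self.groups, return_inverse=True)
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        if self.design.shape[0] != self.groups.shape[0]:
            self.design = self.design.T
        self.n_groups = int(self.groups.max()) + 1
        self.m = self.design.shape[1]
        if not self.colnames:
            self.colnames = [f"{self.name}[{j}]" for j in range(self.m)]


@dataclass
class MixedLMResult:
    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    df: np.ndarray
    pvalues: np.ndarray  # two-tailed
    llf: float
    bic: float
    aic: float
    nobs: int
    sigma2: float
    varcomps: dict
    method: str
    converged: bool
    simplified: bool
    random_effects: dict
    cov_params: np.ndarray

    def __getitem__(self, name: str) -> dict:
        i = self.names.index(name)
        return {
            "beta": self.params[i],
            "se": self.bse[i],
            "t": self.tvalues[i],
            "df": self.df[i],
            "p": self.pvalues[i],
            "p_one_tailed": self.p_one_tailed(name),
            "eta_p2": self.eta_p2(name),
        }

    def p_one_tailed(self, name: str, direction: int = 1) -> float:
        """One-tailed p for the named coefficient (default: positive)."""
        i = self.names.index(name)
        return float(stats.t.sf(direction * self.tvalues[i], self.df[i]))

    def eta_p2(self, name: str) -> float:
        """Approximate partial eta squared, t^2 / (t^2 + df)."""
        i = self.names.index(name)
        t2 = self.tvalues[i] ** 2
        return float(t2 / (t2 + self.df[i]))


class MixedLM:
    """Gaussian linear mixed model with independent-variance random terms."""

    def __init__(self, y, X, terms: list[RandomTerm], names: list[str] | None = None):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            self.X = self.X.T
        self.terms = terms
        self.n, self.p = self.X.shape
        self.names = names or [f"x{j}" for j in range(self.p)]
        self._build()

    # -- assembly ---------------------------------------------------------
    def _build(self):
        n = self.n
        blocks = []
        self.block_slices = []  # per (term, covariate): slice into theta
        self.col_block = []  # per Z column: which theta parameter scales it
        self.param_names = []
        q0 = 0
        k = 0
        for term in self.terms:
            rows = np.arange(n)
            for j in range(term.m):
                cols = term.groups
                data = term.design[:, j]
                Zj = sparse.csr_matrix(
                    (data, (rows, cols)), shape=(n, term.n_groups)
                )
                blocks.append(Zj)
                self.col_block.extend([k] * term.n_groups)
                self.param_names.append(f"{term.name}:{term.colnames[j]}")
                k += 1
            q0 += term.n_groups * term.m
        self.K = k
        self.Z = sparse.hstack(blocks, format="csr") if blocks else None
        self.q = self.Z.shape[1] if self.Z is not None else 0
        self.col_block = np.asarray(self.col_block)
        # fixed cross-products
        self.ZtZ = np.asarray((self.Z.T @ self.Z).todense()) if self.q else None
        self.ZtX = self.Z.T @ self.X if self.q else None
        self.Zty = self.Z.T @ self.y if self.q else None
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

    # -- profiled deviance -------------------------------------------------
    def _solve(self, lam: np.ndarray):
        """Penalized least squares at relative sds `lam` (per theta param)."""
        d = lam[self.col_block]  # per Z column
        A = (d[:, None] * self.ZtZ) * d[None, :]
        A[np.diag_indices_from(A)] += 1.0
        L, low = linalg.cho_factor(A, lower=True, check_finite=False)
        DZtX = d[:, None] * self.ZtX
        DZty = d * self.Zty
        RZX = linalg.solve_triangular(L, DZtX, lower=True, check_finite=False)
        cu = linalg.solve_triangular(L, DZty, lower=True, check_finite=False)
        Sxx = self.XtX - RZX.T @ RZX
        RX, _ = linalg.cho_factor(Sxx, lower=True, check_finite=False)
        cb = linalg.solve_triangular(
            RX, self.Xty - RZX.T @ cu, lower=True, check_finite=False
        )
        pwrss = max(self.yty - cu @ cu - cb @ cb, 1e-12)
        logdet_L = 2.0 * np.sum(np.log(np.diag(L)))
        logdet_RX = 2.0 * np.sum(np.log(np.diag(RX)))
        beta = linalg.solve_triangular(RX.T, cb, lower=False, check_finite=False)
        return dict(
            L=L, RX=RX, RZX=RZX, cu=cu, beta=beta, pwrss=pwrss,
            logdet_L=logdet_L, logdet_RX=logdet_RX, Sxx=Sxx, d=d,
        )

    def _profiled_deviance(self, theta: np.ndarray, reml: bool):
        lam = np.abs(theta)
        if self.q == 0:
            resid = self.y - self.X @ np.linalg.lstsq(self.X, self.y, rcond=None)[0]
            pwrss = float(resid @ resid)
            nd = self.n - self.p if reml else self.n
            s2 = pwrss / nd
            dev = nd * (1.0 + math.log(2 * math.pi * s2))
            if reml:
                dev += 2.0 * np.sum(np.log(np.abs(np.diag(
                    np.linalg.cholesky(self.XtX)))))
            return dev
        try:
            sol = self._solve(lam)
        except (linalg.LinAlgError, np.linalg.LinAlgError, ValueError):
            # infeasible theta proposed by the optimizer: steep penalty
            return 1e12 * (1.0 + float(np.sum(lam)))
        if reml:
            nd = self.n - self.p
            s2 = sol["pwrss"] / nd
            return sol["logdet_L"] + sol["logdet_RX"] + nd * (
                1.0 + math.log(2 * math.pi * s2)
            )
        s2 = sol["pwrss"] / self.n
        return sol["logdet_L"] + self.n * (1.0 + math.log(2 * math.pi * s2))

    def _deviance_at_variances(self, v: np.ndarray, reml: bool) -> float:
        """-2 log likelihood at explicit variances v = (s2_1..s2_K, s2_e)."""
        s2e = max(v[-1], 1e-12)
        lam = np.sqrt(np.maximum(v[:-1], 0.0) / s2e)
        sol = self._solve(lam)
        dev = (
            sol["logdet_L"]
            + self.n * math.log(s2e)
            + sol["pwrss"] / s2e
            + self.n * math.log(2 * math.pi)
        )
        if reml:
            dev += sol["logdet_RX"] - self.p * math.log(s2e) - self.p * math.log(
                2 * math.pi
            )
        return dev

    # -- fitting -----------------------------------------------------------
    def fit(self, reml: bool = True, start: np.ndarray | None = None) -> MixedLMResult:
        theta0 = np.ones(self.K) if start is None else np.asarray(start, float)
        converged = True
        if self.K > 0:
            obj = lambda th: self._profiled_deviance(th, reml)
            best = None
            for x0 in (theta0, 0.1 * np.ones(self.K), 2.0 * np.ones(self.K)):
                res = optimize.minimize(
                    obj, x0, method="L-BFGS-B",
                    bounds=[(0.0, None)] * self.K,
                    options={"maxiter": 500, "ftol": 1e-11},
                )
                if best is None or res.fun < best.fun - 1e-8:
                    best = res
                if res.success and best is res:
                    break
            converged = bool(best.success)
            theta = np.abs(best.x)
        else:
            theta = np.zeros(0)
        return self._finalize(theta, reml, converged)

    def _finalize(self, theta, reml, converged) -> MixedLMResult:
        sol = self._solve(theta) if self.q else None
        nd = self.n - self.p if reml else self.n
        if sol is not None:
            s2 = sol["pwrss"] / nd
            beta = sol["beta"]
            Sxx = sol["Sxx"]
        else:
            beta, _, _, _ = np.linalg.lstsq(self.X, self.y, rcond=None)
            resid = self.y - self.X @ beta
            s2 = float(resid @ resid) / nd
            Sxx = self.XtX
        cov_beta = s2 * linalg.inv(Sxx)
        bse = np.sqrt(np.diag(cov_beta))
        tvals = beta / bse
        v_hat = np.concatenate([s2 * theta**2, [s2]])
        df = self._satterthwaite(v_hat, Sxx, reml)
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
        dev = self._profiled_deviance(theta, reml)
        llf = -0.5 * dev
        k_params = self.p + self.K + 1
        bic = dev + k_params * math.log(self.n)
        aic = dev + 2 * k_params
        varcomps = dict(zip(self.param_names, v_hat[:-1]))
        varcomps["residual"] = s2
        re = self._blups(theta, sol, s2) if sol is not None else {}
        return MixedLMResult(
            names=list(self.names), params=beta, bse=bse, tvalues=tvals,
            df=df, pvalues=pvals, llf=llf, bic=bic, aic=aic, nobs=self.n,
            sigma2=s2, varcomps=varcomps, method="REML" if reml else "ML",
            converged=converged, simplified=False, random_effects=re,
            cov_params=cov_beta,
        )

    def _blups(self, theta, sol, s2):
        """Conditional modes of the random effects, per term."""
        d = sol["d"]
        cu = sol["cu"] - sol["RZX"] @ sol["beta"]
        u = linalg.solve_triangular(sol["L"].T, cu, lower=False, check_finite=False)
        b = d * u
        out = {}
        off = 0
        for term in self.terms:
            mat = np.empty((term.n_groups, term.m))
            for j in range(term.m):
                mat[:, j] = b[off : off + term.n_groups]
                off += term.n_groups
            out[term.name] = mat
        return out

    # -- Satterthwaite -----------------------------------------------------
    def _satterthwaite(self, v_hat, Sxx, reml) -> np.ndarray:
        n_coef = self.p
        fallback = np.full(n_coef, max(self.n - self.p - self.q, 1), dtype=float)
        if self.q == 0:
            return np.full(n_coef, self.n - self.p, dtype=float)
        try:
            # keep parameters away from the boundary in the Hessian
            active = [k for k in range(self.K) if v_hat[k] > 1e-8 * v_hat[-1]]
            idx = active + [self.K]
            v0 = v_hat[idx]
            scale = np.maximum(np.abs(v0), 1e-8 * v_hat[-1])
            h = 1e-4 * scale

            def dev_of(vv):
                v_full = v_hat.copy()
                v_full[idx] = np.maximum(vv, 0.0)
                return self._deviance_at_variances(v_full, reml)

            m = len(idx)
            H = np.zeros((m, m))
            f0 = dev_of(v0)
            for a in range(m):
                for b_ in range(a, m):
                    ea = np.zeros(m); ea[a] = h[a]
                    eb = np.zeros(m); eb[b_] = h[b_]
                    if a == b_:
                        H[a, a] = (dev_of(v0 + ea) - 2 * f0 + dev_of(v0 - ea)) / h[a] ** 2
                    else:
                        H[a, b_] = H[b_, a] = (
                            dev_of(v0 + ea + eb)
                            - dev_of(v0 + ea - eb)
                            - dev_of(v0 - ea + eb)
                            + dev_of(v0 - ea - eb)
                        ) / (4 * h[a] * h[b_])
            W = 2.0 * linalg.pinvh(H)

            # variance of each fixed effect as a function of the components
            def var_beta(vv):
                v_full = v_hat.copy()
                v_full[idx] = np.maximum(vv, 0.0)
                s2e = v_full[-1]
                lam = np.sqrt(np.maximum(v_full[:-1], 0.0) / s2e)
                sol = self._solve(lam)
                return s2e * np.diag(linalg.inv(sol["Sxx"]))

            grads = np.zeros((m, n_coef))
            for a in range(m):
                ea = np.zeros(m); ea[a] = h[a]
                grads[a] = (var_beta(v0 + ea) - var_beta(v0 - ea)) / (2 * h[a])
            f_val = v_hat[-1] * np.diag(linalg.inv(Sxx))
            df = np.empty(n_coef)
            for c in range(n_coef):
                g = grads[:, c]
                denom = float(g @ W @ g)
                if denom <= 0 or not np.isfinite(denom):
                    df[c] = fallback[c]
                else:
                    df[c] = 2.0 * f_val[c] ** 2 / denom
            return np.clip(df, 1.0, 10.0 * self.n)
        except Exception:
            return fallback

    def contrast_F(self, result: MixedLMResult, L: np.ndarray):
        """Wald F test of L beta = 0 with a Satterthwaite-style df2.

        df2 follows the multi-contrast recipe: per-eigenvector Satterthwaite
        dfs nu_i combined as df2 = 2 E / (E - rank) with
        E = sum nu_i / (nu_i - 2).
        """
        L = np.atleast_2d(np.asarray(L, float))
        rank = np.linalg.matrix_rank(L)
        V = result.cov_params
        M = L @ V @ L.T
        Lb = L @ result.params
        F = float(Lb @ linalg.solve(M, Lb)) / rank
        # per-row Satterthwaite via the eigen-decomposition of M
        w, P = linalg.eigh(M)
        keep = w > 1e-12 * w.max()
        nus = []
        for vec in (P[:, keep]).T:
            c = vec @ L
            # single-contrast df via the same machinery as coefficient dfs
            nus.append(self._contrast_df(c, result))
        nus = np.array(nus)
        good = nus > 2.0
        E = float(np.sum(nus[good] / (nus[good] - 2.0)))
        if good.sum() == 0 or E <= rank:
            df2 = float(result.nobs - self.p)
        else:
            df2 = 2.0 * E / (E - rank)
        p = float(stats.f.sf(F, rank, max(df2, 1.0)))
        return F, rank, df2, p

    def _contrast_df(self, c: np.ndarray, result: MixedLMResult) -> float:
        v_hat = np.concatenate(
            [[result.varcomps[nm] for nm in self.param_names], [result.sigma2]]
        )
        reml = result.method == "REML"
        try:
            active = [k for k in range(self.K) if v_hat[k] > 1e-8 * v_hat[-1]]
            idx = active + [self.K]
            v0 = v_hat[idx]
            h = 1e-4 * np.maximum(np.abs(v0), 1e-8 * v_hat[-1])
            m = len(idx)

            def dev_of(vv):
                v_full = v_hat.copy()
                v_full[idx] = np.maximum(vv, 0.0)
                return self._deviance_at_variances(v_full, reml)

            H = np.zeros((m, m))
            f0 = dev_of(v0)
            for a in range(m):
                for b_ in range(a, m):
                    ea = np.zeros(m); ea[a] = h[a]
                    eb = np.zeros(m); eb[b_] = h[b_]
                    if a == b_:
                        H[a, a] = (dev_of(v0 + ea) - 2 * f0 + dev_of(v0 - ea)) / h[a] ** 2
                    else:
                        H[a, b_] = H[b_, a] = (
                            dev_of(v0 + ea + eb) - dev_of(v0 + ea - eb)
                            - dev_of(v0 - ea + eb) + dev_of(v0 - ea - eb)
                        ) / (4 * h[a] * h[b_])
            W = 2.0 * linalg.pinvh(H)

            def var_c(vv):
                v_full = v_hat.copy()
                v_full[idx] = np.maximum(vv, 0.0)
                s2e = v_full[-1]
                lam = np.sqrt(np.maximum(v_full[:-1], 0.0) / s2e)
                sol = self._solve(lam)
                return s2e * float(c @ linalg.solve(sol["Sxx"], c))

            g = np.zeros(m)
            for a in range(m):
                ea = np.zeros(m); ea[a] = h[a]
                g[a] = (var_c(v0 + ea) - var_c(v0 - ea)) / (2 * h[a])
            f_val = float(c @ result.cov_params @ c)
            denom = float(g @ W @ g)
            if denom <= 0 or not np.isfinite(denom):
                return float(self.n - self.p)
            return float(np.clip(2.0 * f_val**2 / denom, 1.0, 10.0 * self.n))
        except Exception:
            return float(self.n - self.p)
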