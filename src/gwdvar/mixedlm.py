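"""Gaussian linear mixed models with crossed and nested random effects.

This module provides the estimation engine used throughout the package: a
Gaussian mixed model

    y = X beta + sum_t Z_t u_t + eps,   u_t ~ N(0, sigma_t^2 I),  eps ~ N(0, sigma^2 I)

where every random term *t* is either a random intercept or a random slope for
one grouping factor (possibly a nested combination such as
``family:genus:species``).  Terms are mutually independent with isotropic
(per-term scalar) variances, which is the structure every analysis in this
package relies on: variance partitioning over nested taxonomic levels with a
crossed study ("source") effect, species-level random slopes for tissue
contrasts, and within-species environmental slopes.

Estimation maximises the restricted (REML, default) or full (ML) Gaussian
likelihood with an expectation–conditional-maximisation scheme over the
variance components, with the residual variance profiled in the same sweep.
Each iteration solves Henderson's mixed-model equations once; the EM update
never decreases the objective, which is asserted at every step.  A SQUAREM-type
extrapolation (with a monotonicity safeguard that falls back to the plain EM
step) accelerates convergence.

The model class follows the statsmodels convention: build a :class:`MixedModel`
from a DataFrame (usually via :meth:`MixedModel.from_formula` with an
lme4-style formula such as ``"wsg ~ 1 + (1 | family/genus/species) + (1 | source)"``),
call :meth:`~MixedModel.fit`, and work with the returned
:class:`MixedModelResults` (estimates, BLUPs, standard errors, ``summary()``).
"""
from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, sparse
from scipy.linalg import lapack

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "MixedModel",
    "MixedModelResults",
    "CenteredDesign",
    "center_within_between",
    "ConvergenceWarning",
]

_log = logging.getLogger("gwdvar.mixedlm")

# components whose SD falls below this are clamped to zero and frozen
ZERO_SD = 1e-8
_LOG2PI = float(np.log(2.0 * np.pi))


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class RandomTerm:
    """One independent random-effect term.

    factors : tuple of column names whose value combination defines the groups
              (("family", "genus") means groups are distinct family:genus pairs).
    slope   : optional numeric column; if None the term is a random intercept,
              otherwise a random slope on that column.
    """

    factors: tuple
    slope: Optional[str] = None

    @property
    def label(self) -> str:
        lhs = "1" if self.slope is None else f"0 + {self.slope}"
        return f"({lhs} | {':'.join(self.factors)})"


@dataclass
class ModelSpec:
    """Response, fixed terms and random terms of a mixed model."""

    response: str
    fixed: list = field(default_factory=list)
    intercept: bool = True
    random: list = field(default_factory=list)
    method: str = "reml"

    def __post_init__(self):
        if self.method.lower() not in ("reml", "ml"):
            raise ValueError(f"method must be 'reml' or 'ml', got {self.method!r}")
        self.method = self.method.lower()
        labels = [t.label for t in self.random]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicated random term in model specification")

    # -- formula grammar -----------------------------------------------------
    _RE_RANDOM = re.compile(r"\(([^|()]+)\|([^|()]+)\)")

    @classmethod
    def from_formula(cls, formula: str, method: str = "reml") -> "ModelSpec":
        """Parse an lme4-style formula.

        Supported grammar::

            response ~ 1 + x + (1 | family/genus/species) + (1 | source)
            response ~ 1 + branch + (1 + branch | species)

        ``a/b/c`` expands to nested terms ``a``, ``a:b``, ``a:b:c``;
        ``(1 + x | g)`` expands to an independent intercept and slope term
        (intercept–slope correlations are not modelled).
        """
        try:
            lhs, rhs = formula.split("~")
        except ValueError as exc:
            raise ValueError(f"formula must contain a single '~': {formula!r}") from exc
        random_specs: list = []

        def _grab(m: re.Match) -> str:
            random_specs.append((m.group(1).strip(), m.group(2).strip()))
            return ""

        fixed_part = cls._RE_RANDOM.sub(_grab, rhs)
        intercept = True
        fixed = []
        for tok in (t.strip() for t in fixed_part.split("+")):
            if not tok or tok == "1":
                continue
            if tok in ("0", "-1"):
                intercept = False
            else:
                fixed.append(tok)
        random_terms = []
        for expr, grouping in random_specs:
            parts = [p.strip() for p in expr.split("+") if p.strip()]
            has_intercept = not any(p in ("0", "-1") for p in parts)
            slopes = [p for p in parts if p not in ("0", "1", "-1")]
            path = [g.strip() for g in grouping.split("/") if g.strip()]
            if not path:
                raise ValueError(f"empty grouping in random term ({expr} | {grouping})")
            for depth in range(1, len(path) + 1):
                cols = tuple(path[:depth])
                if has_intercept:
                    random_terms.append(RandomTerm(cols, None))
                for s in slopes:
                    random_terms.append(RandomTerm(cols, s))
        return cls(response=lhs.strip(), fixed=fixed, intercept=intercept,
                   random=random_terms, method=method)

    @property
    def formula(self) -> str:
        parts = ["1"] if self.intercept else ["0"]
        parts += list(self.fixed)
        for t in self.random:
            lhs = "1" if t.slope is None else f"0 + {t.slope}"
            parts.append(f"({lhs} | {':'.join(t.factors)})")
        return f"{self.response} ~ " + " + ".join(parts)

    def to_dict(self) -> dict:
        return {"formula": self.formula, "method": self.method}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls.from_formula(d["formula"], method=d.get("method", "reml"))


# ---------------------------------------------------------------------------
# solvers for Henderson's mixed-model equations
# ---------------------------------------------------------------------------


class _SolveState:
    """Quantities produced by one solve of the mixed-model equations."""

    __slots__ = ("beta", "u", "ress", "yPe", "tr_c", "tr_uu", "logdetC",
                 "logdetDuu", "Sinv", "u_norm2", "resid")

    def __init__(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)


class _DenseSolver:
    """General solver: forms the (p+q) x (p+q) coefficient matrix densely.

    Handles any combination of crossed and nested terms; adequate up to a few
    thousand total random-effect levels.
    """

    def __init__(self, y, X, Zs):
        self.n, self.p = X.shape
        self.y = y
        blocks = [sparse.csr_matrix(X)] + [Z.tocsr() for Z in Zs]
        self.A = sparse.hstack(blocks, format="csc")
        self.qs = [Z.shape[1] for Z in Zs]
        offs = np.cumsum([self.p] + self.qs)
        self.slices = [slice(int(offs[i + 1] - self.qs[i]), int(offs[i + 1]))
                       for i in range(len(Zs))]
        AtA = (self.A.T @ self.A).toarray()
        self.AtA = np.asarray(AtA, dtype=float)
        self.Aty = np.asarray(self.A.T @ y).ravel()
        self.yty = float(y @ y)

    def solve(self, pen, active, need_uu=False):
        """pen: per-active-term penalty sigma^2/sigma_t^2; active: bool mask."""
        idx = [np.arange(self.p)]
        pen_full = []
        for t, a in enumerate(active):
            if a:
                idx.append(np.arange(self.slices[t].start, self.slices[t].stop))
                pen_full.append(np.full(self.qs[t], pen[t]))
        idx = np.concatenate(idx)
        penv = np.concatenate([np.zeros(self.p)] + pen_full) if pen_full else np.zeros(self.p)
        C = self.AtA[np.ix_(idx, idx)].copy()
        C[np.diag_indices_from(C)] += penv
        L = linalg.cholesky(C, lower=True, check_finite=False)
        rhs = self.Aty[idx]
        sol = linalg.cho_solve((L, True), rhs, check_finite=False)
        Linv, info = lapack.dtrtri(L, lower=1)
        if info != 0:  # pragma: no cover - C is SPD by construction
            raise linalg.LinAlgError("triangular inversion failed")
        diag_cinv = np.einsum("ij,ij->j", Linv, Linv)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(L))))
        yPe = self.yty - float(rhs @ sol)
        beta = sol[: self.p]
        u, u_norm2, tr_c = {}, {}, {}
        pos = self.p
        ress = yPe
        for t, a in enumerate(active):
            if not a:
                continue
            q_t = self.qs[t]
            u_t = sol[pos: pos + q_t]
            u[t] = u_t
            u_norm2[t] = float(u_t @ u_t)
            tr_c[t] = float(np.sum(diag_cinv[pos: pos + q_t]))
            ress -= pen[t] * u_norm2[t]
            pos += q_t
        state = _SolveState(beta=beta, u=u, ress=ress, yPe=yPe, tr_c=tr_c,
                            tr_uu=None, logdetC=logdetC, logdetDuu=None,
                            Sinv=None, u_norm2=u_norm2, resid=None)
        state.Sinv = (Linv[:, : self.p].T @ Linv[:, : self.p])
        if need_uu:
            # ML path: conditional covariance of u given beta fixed uses the
            # u-block (Z'Z + Lambda) alone.
            Cuu = C[self.p:, self.p:]
            Luu = linalg.cholesky(Cuu, lower=True, check_finite=False)
            Luinv, _ = lapack.dtrtri(Luu, lower=1)
            duu = np.einsum("ij,ij->j", Luinv, Luinv)
            state.logdetDuu = 2.0 * float(np.sum(np.log(np.diag(Luu))))
            tr_uu, pos = {}, 0
            for t, a in enumerate(active):
                if a:
                    tr_uu[t] = float(np.sum(duu[pos: pos + self.qs[t]]))
                    pos += self.qs[t]
            state.tr_uu = tr_uu
        return state


class _GroupedSolver:
    """Fast path when every random term shares one grouping factor.

    The u-block of the coefficient matrix is then block-diagonal over groups
    (one k x k block per group, k = number of terms), so a p x p Schur
    complement solves the system in O(n k^2 + G k^3) per iteration.  Used for
    the within/between environmental models (species intercept + slopes).
    """

    def __init__(self, y, X, codes, weights, n_groups):
        self.n, self.p = X.shape
        self.k = weights.shape[1]
        self.G = n_groups
        self.y = y
        self.X = X
        self.codes = codes
        self.W = weights
        G, p, k = n_groups, self.p, self.k
        self.WtW = np.zeros((G, k, k))
        for i in range(k):
            for j in range(i, k):
                s = np.bincount(codes, weights=weights[:, i] * weights[:, j], minlength=G)
                self.WtW[:, i, j] = s
                self.WtW[:, j, i] = s
        self.XtW = np.zeros((G, p, k))
        for a in range(p):
            for i in range(k):
                self.XtW[:, a, i] = np.bincount(
                    codes, weights=X[:, a] * weights[:, i], minlength=G)
        self.Wty = np.zeros((G, k))
        for i in range(k):
            self.Wty[:, i] = np.bincount(codes, weights=y * weights[:, i], minlength=G)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def solve(self, pen, active, need_uu=False):
        act = np.flatnonzero(active)
        ka = len(act)
        if ka == 0:
            Ls = linalg.cholesky(self.XtX, lower=True, check_finite=False)
            beta = linalg.cho_solve((Ls, True), self.Xty, check_finite=False)
            Lsinv, _ = lapack.dtrtri(Ls, lower=1)
            yPe = self.yty - float(self.Xty @ beta)
            return _SolveState(beta=beta, u={}, ress=yPe, yPe=yPe, tr_c={},
                               tr_uu={}, logdetC=2.0 * float(np.sum(np.log(np.diag(Ls)))),
                               logdetDuu=0.0, Sinv=Lsinv.T @ Lsinv,
                               u_norm2={}, resid=None)
        D = self.WtW[np.ix_(np.arange(self.G), act, act)].copy()
        D[:, np.arange(ka), np.arange(ka)] += np.asarray(pen, float)[act]
        Dinv = np.linalg.inv(D)
        E = self.XtW[:, :, act]                       # (G, p, ka)
        ED = np.einsum("gpi,gij->gpj", E, Dinv)       # E D^-1
        S = self.XtX - np.einsum("gpi,gqi->pq", ED, E)
        rhs = self.Xty - np.einsum("gpi,gi->p", ED, self.Wty[:, act])
        Ls = linalg.cholesky(S, lower=True, check_finite=False)
        beta = linalg.cho_solve((Ls, True), rhs, check_finite=False)
        resid_rhs = self.Wty[:, act] - np.einsum("gpi,p->gi", E, beta)
        U = np.einsum("gij,gj->gi", Dinv, resid_rhs)  # (G, ka)
        Lsinv, _ = lapack.dtrtri(Ls, lower=1)
        Sinv = Lsinv.T @ Lsinv
        # diagonal of C^{-1} over u: D^-1 + (D^-1 E') Sinv (E D^-1)
        F = np.transpose(ED, (0, 2, 1))               # (G, ka, p)
        extra = np.einsum("gip,pq,giq->gi", F, Sinv, F)
        ddiag = np.einsum("gii->gi", Dinv) + extra
        sign, logdetD = np.linalg.slogdet(D)
        if np.any(sign <= 0):  # pragma: no cover
            raise linalg.LinAlgError("non-SPD group block")
        logdetC = float(np.sum(logdetD)) + 2.0 * float(np.sum(np.log(np.diag(Ls))))
        yPe = self.yty - float(self.Xty @ beta) - float(np.sum(self.Wty[:, act] * U))
        u, u_norm2, tr_c = {}, {}, {}
        ress = yPe
        for j, t in enumerate(act):
            u_t = U[:, j]
            u[t] = u_t
            u_norm2[t] = float(u_t @ u_t)
            tr_c[t] = float(np.sum(ddiag[:, j]))
            ress -= pen[t] * u_norm2[t]
        state = _SolveState(beta=beta, u=u, ress=ress, yPe=yPe, tr_c=tr_c,
                            tr_uu=None, logdetC=logdetC, logdetDuu=None,
                            Sinv=Sinv, u_norm2=u_norm2, resid=None)
        if need_uu:
            duu = np.einsum("gii->gi", Dinv)
            state.tr_uu = {t: float(np.sum(duu[:, j])) for j, t in enumerate(act)}
            sgn, ld = np.linalg.slogdet(D)
            state.logdetDuu = float(np.sum(ld))
        return state


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class MixedModel:
    """Gaussian mixed model over a DataFrame.

    Parameters
    ----------
    data : DataFrame with the response, fixed covariates and grouping columns.
        Rows with missing values in any used column are dropped (count kept in
        ``n_dropped``).
    spec : ModelSpec

    Use :meth:`from_formula` for the common case.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec,
                 allow_single_group: bool = False):
        self.spec = spec
        used = {spec.response, *spec.fixed}
        for t in spec.random:
            used.update(t.factors)
            if t.slope is not None:
                used.add(t.slope)
        missing = sorted(used - set(data.columns))
        if missing:
            raise KeyError(f"columns not in data: {missing}")
        sub = data[sorted(used)].copy()
        keep = sub.notna().all(axis=1).to_numpy()
        self.n_dropped = int((~keep).sum())
        sub = sub.loc[keep]
        self.data = sub
        self.nobs = len(sub)
        if self.nobs == 0:
            raise ValueError("no complete rows available for the model")
        y = sub[spec.response].to_numpy(dtype=float)
        cols = [np.ones(self.nobs)] if spec.intercept else []
        names = ["Intercept"] if spec.intercept else []
        for f in spec.fixed:
            cols.append(sub[f].to_numpy(dtype=float))
            names.append(f)
        if not cols:
            raise ValueError("model must have at least one fixed term")
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")
        self.y, self.X, self.exog_names = y, X, names
        self.term_codes, self.term_groups, self.term_weights = [], [], []
        for t in spec.random:
            if len(t.factors) == 1:
                codes, uniq = pd.factorize(sub[t.factors[0]], sort=True)
                labels = list(uniq)
            else:
                mi = pd.MultiIndex.from_frame(sub[list(t.factors)])
                codes, uniq = mi.factorize(sort=True)
                labels = list(uniq)
            if (codes < 0).any():  # pragma: no cover - NA rows already dropped
                raise ValueError(f"missing group labels in {t.label}")
            nlev = len(labels)
            if nlev < 2 and not allow_single_group:
                raise ValueError(
                    f"grouping factor {':'.join(t.factors)} has a single level; "
                    "drop the term or pass allow_single_group=True")
            w = np.ones(self.nobs) if t.slope is None \
                else sub[t.slope].to_numpy(dtype=float)
            self.term_codes.append(np.asarray(codes))
            self.term_groups.append(labels)
            self.term_weights.append(w)
        self._solver = self._build_solver()

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame, method: str = "reml",
                     **kw) -> "MixedModel":
        return cls(data, ModelSpec.from_formula(formula, method=method), **kw)

    # -- design ---------------------------------------------------------------
    def _build_solver(self):
        terms = self.spec.random
        if terms and all(t.factors == terms[0].factors for t in terms):
            codes = self.term_codes[0]
            W = np.column_stack(self.term_weights)
            return _GroupedSolver(self.y, self.X, codes, W,
                                  len(self.term_groups[0]))
        Zs = []
        for codes, w, labels in zip(self.term_codes, self.term_weights,
                                    self.term_groups):
            Zs.append(sparse.csr_matrix(
                (w, (np.arange(self.nobs), codes)),
                shape=(self.nobs, len(labels))))
        return _DenseSolver(self.y, self.X, Zs)

    # -- likelihood ------------------------------------------------------------
    def loglike(self, sd_components: Sequence[float], sigma: float,
                method: Optional[str] = None):
        """(Restricted) log-likelihood at given component SDs and residual SD.

        Components with SD 0 are treated as dropped terms.
        """
        method = (method or self.spec.method).lower()
        sd = np.asarray(sd_components, float)
        sigma2 = float(sigma) ** 2
        active = sd > 0
        pen = np.where(active, sigma2 / np.where(active, sd, 1.0) ** 2, 0.0)
        state = self._solver.solve(pen, active, need_uu=(method == "ml"))
        return self._ll_from_state(state, sd ** 2, sigma2, active, method), state

    def _ll_from_state(self, state, sigma2_t, sigma2, active, method):
        n, p = self.nobs, self.X.shape[1]
        q_act = sum(len(self.term_groups[t]) for t in range(len(active)) if active[t])
        sum_q_log = sum(len(self.term_groups[t]) * np.log(sigma2_t[t])
                        for t in range(len(active)) if active[t])
        if method == "reml":
            return -0.5 * ((n - p - q_act) * np.log(sigma2) + sum_q_log
                           + state.logdetC + state.yPe / sigma2
                           + (n - p) * _LOG2PI)
        # ML: profile beta via GLS (already the MME solution)
        quad = state.yPe
        # (y - X beta)' V^-1 (y - X beta) = [y'e - beta' X'e]/sigma2 ; X'e = X'y - X'A s
        # cheaper: y'Py equals quad only under REML; recompute directly:
        Xb = self.X @ state.beta
        e = self._residual_vector(state)
        quad = float((self.y - Xb) @ e)
        return -0.5 * ((n - q_act) * np.log(sigma2) + sum_q_log
                       + state.logdetDuu + quad / sigma2 + n * _LOG2PI)

    def _residual_vector(self, state):
        e = self.y - self.X @ state.beta
        for t, u_t in state.u.items():
            e = e - self.term_weights[t] * u_t[self.term_codes[t]]
        return e

    # -- fitting ---------------------------------------------------------------
    def fit(self, method: Optional[str] = None, maxiter: int = 2000,
            rtol: float = 1e-8, accelerate: bool = True,
            start: Optional[dict] = None,
            fixed_components: Optional[dict] = None) -> "MixedModelResults":
        """Estimate variance components, fixed effects and BLUPs.

        Parameters
        ----------
        method : "reml" (default, taken from the spec) or "ml".
        fixed_components : optional {term label: SD} pinning components during
            optimisation (used by the likelihood profiler).
        """
        method = (method or self.spec.method).lower()
        T = len(self.spec.random)
        n, p = self.nobs, self.X.shape[1]
        labels = [t.label for t in self.spec.random]
        pinned = np.full(T, np.nan)
        if fixed_components:
            for lab, val in fixed_components.items():
                if lab not in labels:
                    raise KeyError(f"unknown component {lab!r}")
                pinned[labels.index(lab)] = float(val) ** 2
        vary = float(np.var(self.y))
        if vary < 1e-28 or (T == 0):
            return self._fit_degenerate(method, vary, pinned)
        # deterministic initialisation: equal split of half the variance
        sigma2_t = np.full(T, 0.5 * vary / max(T, 1))
        sigma2 = 0.5 * vary
        ok = ~np.isnan(pinned)
        sigma2_t[ok] = pinned[ok]
        active = sigma2_t > ZERO_SD ** 2

        def em_step(s2t, s2, act):
            pen = np.where(act, s2 / np.where(act, s2t, 1.0), 0.0)
            state = self._solver.solve(pen, act, need_uu=(method == "ml"))
            ll = self._ll_from_state(state, s2t, s2, act, method)
            new_t = s2t.copy()
            tr = state.tr_c if method == "reml" else state.tr_uu
            q_tot = 0
            tr_pen = 0.0
            for t in range(T):
                if not act[t]:
                    continue
                q_t = len(self.term_groups[t])
                q_tot += q_t
                tr_pen += (s2 / s2t[t]) * tr[t]
                if np.isnan(pinned[t]):
                    new_t[t] = (state.u_norm2[t] + s2 * tr[t]) / q_t
            if method == "reml":
                e_eps = state.ress + s2 * ((p + q_tot) - tr_pen)
            else:
                e2 = float(self._residual_vector(state) @ self._residual_vector(state))
                e_eps = e2 + s2 * (q_tot - tr_pen)
            new_s2 = max(e_eps / n, 1e-300)
            return new_t, new_s2, ll, state

        ll_prev = -np.inf
        state = None
        converged = False
        it = 0
        while it < maxiter:
            s2t_1, s2_1, ll0, state = em_step(sigma2_t, sigma2, active)
            it += 1
            if not np.isfinite(ll0):
                raise linalg.LinAlgError("non-finite objective")
            if ll0 < ll_prev - 1e-6 * (1.0 + abs(ll_prev)):
                raise AssertionError(
                    "EM objective decreased; this indicates a numerical fault")
            if abs(ll0 - ll_prev) < rtol * (1.0 + abs(ll0)) and it > 1:
                sigma2_t, sigma2 = s2t_1, s2_1
                converged = True
                break
            ll_prev = ll0
            if accelerate and it + 1 < maxiter:
                s2t_2, s2_2, ll1, _ = em_step(s2t_1, s2_1, active)
                it += 1
                th0 = np.log(np.append(sigma2_t[active], sigma2))
                th1 = np.log(np.append(s2t_1[active], s2_1))
                th2 = np.log(np.append(s2t_2[active], s2_2))
                r = th1 - th0
                v = th2 - th1 - r
                nv = float(v @ v)
                accepted = False
                if nv > 0:
                    alpha = -np.sqrt(float(r @ r) / nv)
                    alpha = min(alpha, -1.0)
                    th_acc = th0 - 2 * alpha * r + alpha * alpha * v
                    cand_t = sigma2_t.copy()
                    cand_t[active] = np.exp(th_acc[:-1])
                    ok = ~np.isnan(pinned)
                    cand_t[ok] = pinned[ok]
                    cand_s = float(np.exp(th_acc[-1]))
                    try:
                        ll_acc, _ = self._ll_at(cand_t, cand_s, active, method)
                    except linalg.LinAlgError:
                        ll_acc = -np.inf
                    ll2, _ = self._ll_at(s2t_2, s2_2, active, method)
                    it += 1
                    if ll_acc >= ll2:
                        sigma2_t, sigma2 = cand_t, cand_s
                        accepted = True
                        ll_prev = ll2
                if not accepted:
                    sigma2_t, sigma2 = s2t_2, s2_2
                    ll_prev = ll1
            else:
                sigma2_t, sigma2 = s2t_1, s2_1
            # clamp vanished components to zero and freeze them
            for t in range(T):
                if active[t] and np.isnan(pinned[t]) and sigma2_t[t] < ZERO_SD ** 2:
                    sigma2_t[t] = 0.0
                    active[t] = False
                    ll_prev = -np.inf  # objective changes support; restart test
        if not converged:
            warnings.warn("mixed model did not converge within "
                          f"{maxiter} iterations", ConvergenceWarning)
        # final solve at the estimate
        pen = np.where(active, sigma2 / np.where(active, sigma2_t, 1.0), 0.0)
        state = self._solver.solve(pen, active, need_uu=(method == "ml"))
        ll = self._ll_from_state(state, sigma2_t, sigma2, active, method)
        _log.info("fit %s nobs=%d groups=%s iter=%d converged=%s loglik=%.3f",
                  method, n, {t.label: len(g) for t, g in
                              zip(self.spec.random, self.term_groups)},
                  it, converged, ll)
        return MixedModelResults(self, method, np.sqrt(sigma2_t),
                                 float(np.sqrt(sigma2)), ll, state, converged, it)

    def _ll_at(self, sigma2_t, sigma2, active, method):
        pen = np.where(active, sigma2 / np.where(active, sigma2_t, 1.0), 0.0)
        state = self._solver.solve(pen, active, need_uu=(method == "ml"))
        return self._ll_from_state(state, sigma2_t, sigma2, active, method), state

    def _fit_degenerate(self, method, vary, pinned):
        # constant response (or no random terms): OLS with all components at
        # zero; sigma floored at numerical epsilon for a constant response.
        T = len(self.spec.random)
        beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ beta
        dof = max(self.nobs - self.X.shape[1], 1)
        sigma2 = float(resid @ resid) / (dof if method == "reml" else self.nobs)
        sigma = float(np.sqrt(max(sigma2, np.finfo(float).eps ** 2)))
        sd = np.zeros(T)
        ok = ~np.isnan(pinned)
        sd[ok] = np.sqrt(pinned[ok])
        if T and np.any(sd > 0):
            # pinned positive components: single constrained solve
            ll, state = self._ll_at(sd ** 2, sigma ** 2, sd > 0, method)
            return MixedModelResults(self, method, sd, sigma, ll, state, True, 1)
        n, p = self.nobs, self.X.shape[1]
        with np.errstate(divide="ignore"):
            if method == "reml":
                ll = -0.5 * ((n - p) * np.log(sigma ** 2)
                             + float(resid @ resid) / sigma ** 2
                             + (n - p) * _LOG2PI
                             + 2 * np.sum(np.log(np.diag(
                                 linalg.cholesky(self.X.T @ self.X)))))
            else:
                ll = -0.5 * (n * np.log(sigma ** 2)
                             + float(resid @ resid) / sigma ** 2 + n * _LOG2PI)
        state = _SolveState(beta=beta, u={}, ress=float(resid @ resid),
                            yPe=float(resid @ resid), tr_c={}, tr_uu={},
                            logdetC=0.0, logdetDuu=0.0,
                            Sinv=np.linalg.inv(self.X.T @ self.X),
                            u_norm2={}, resid=resid)
        return MixedModelResults(self, method, sd, sigma, ll, state, True, 0)


class MixedModelResults:
    """Fit results: fixed coefficients, component SDs, BLUPs, diagnostics."""

    def __init__(self, model, method, sd_components_arr, sigma, llf, state,
                 converged, n_iter):
        self.model = model
        self.method = method
        self._sd_arr = np.asarray(sd_components_arr, float)
        self.sigma = float(sigma)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self._state = state
        self.fe_params = pd.Series(state.beta, index=model.exog_names)
        self.nobs = model.nobs

    # -- parameters ------------------------------------------------------------
    @property
    def sd_components(self) -> pd.Series:
        """Random-effect SDs per term, in response units (g cm^-3 here)."""
        return pd.Series(self._sd_arr, index=[t.label for t in self.model.spec.random])

    @property
    def random_effects(self) -> dict:
        """Per-term conditional modes (BLUPs): {term label: Series group -> mode}."""
        out = {}
        for t, term in enumerate(self.model.spec.random):
            labels = self.model.term_groups[t]
            vals = self._state.u.get(t)
            if vals is None:
                vals = np.zeros(len(labels))
            idx = pd.Index(labels)
            out[term.label] = pd.Series(np.asarray(vals), index=idx)
        return out

    @property
    def bse_fe(self) -> pd.Series:
        cov = self.sigma ** 2 * self._state.Sinv
        return pd.Series(np.sqrt(np.diag(cov)), index=self.model.exog_names)

    def cov_fe(self) -> pd.DataFrame:
        return pd.DataFrame(self.sigma ** 2 * self._state.Sinv,
                            index=self.model.exog_names,
                            columns=self.model.exog_names)

    @property
    def resid(self) -> np.ndarray:
        return self.model._residual_vector(self._state)

    def bse_sd_components(self, rel_step: float = 1e-3) -> pd.Series:
        """Asymptotic SEs of the component SDs (and residual SD).

        Numerical observed information on the log-SD scale, delta method back
        to the SD scale.  Components estimated at the zero boundary get NaN.
        """
        sd = self._sd_arr
        free = np.flatnonzero(sd > 0)
        eta0 = np.log(np.concatenate([sd[free], [self.sigma]]))
        m = len(eta0)

        def f(eta):
            s = sd.copy()
            s[free] = np.exp(eta[:-1])
            ll, _ = self.model.loglike(s, float(np.exp(eta[-1])), method=self.method)
            return ll

        H = np.zeros((m, m))
        h = rel_step
        f0 = f(eta0)
        for i in range(m):
            for j in range(i, m):
                ei = np.zeros(m); ei[i] = h
                ej = np.zeros(m); ej[j] = h
                if i == j:
                    H[i, i] = (f(eta0 + ei) - 2 * f0 + f(eta0 - ei)) / h ** 2
                else:
                    H[i, j] = H[j, i] = (
                        f(eta0 + ei + ej) - f(eta0 + ei - ej)
                        - f(eta0 - ei + ej) + f(eta0 - ei - ej)) / (4 * h ** 2)
        try:
            cov = np.linalg.inv(-H)
            se_eta = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:  # pragma: no cover
            se_eta = np.full(m, np.nan)
        out = np.full(len(sd) + 1, np.nan)
        out[free] = sd[free] * se_eta[:-1]
        out[-1] = self.sigma * se_eta[-1]
        idx = [t.label for t in self.model.spec.random] + ["Residual"]
        return pd.Series(out, index=idx)

    # -- prediction ------------------------------------------------------------
    def conditional_modes(self, label: str, groups: Sequence) -> np.ndarray:
        """Conditional modes for requested groups; unseen groups get 0."""
        re = self.random_effects[label]
        return np.asarray([re.get(g, 0.0) for g in groups], dtype=float)

    def predict(self, data: pd.DataFrame, include_re: Optional[Sequence[str]] = None
                ) -> np.ndarray:
        """Fixed-effect prediction plus selected (default: all) random terms.

        Unseen groups contribute zero, so predictions fall back to the higher
        levels that are present — the shrinkage behaviour that makes the
        hierarchical estimator usable for unsampled species.
        """
        spec = self.model.spec
        n = len(data)
        yhat = np.zeros(n)
        if spec.intercept:
            yhat += self.fe_params["Intercept"]
        for fcol in spec.fixed:
            yhat += self.fe_params[fcol] * data[fcol].to_numpy(dtype=float)
        wanted = set(include_re) if include_re is not None \
            else {t.label for t in spec.random}
        res = self.random_effects
        for term in spec.random:
            if term.label not in wanted:
                continue
            re = res[term.label]
            if len(term.factors) == 1:
                keys = data[term.factors[0]]
                vals = keys.map(re).fillna(0.0).to_numpy(dtype=float)
            else:
                mi = pd.MultiIndex.from_frame(data[list(term.factors)])
                vals = np.asarray(
                    [re.get(k, 0.0) for k in mi], dtype=float)
            if term.slope is not None:
                vals = vals * data[term.slope].to_numpy(dtype=float)
            yhat += vals
        return yhat

    def reestimate(self, data: pd.DataFrame) -> "MixedModelResults":
        """Re-solve fixed effects and BLUPs on new data, components frozen.

        This is the component-freezing device used by the cross-validation
        experiments: the variance components act as hyper-parameters while
        Henderson's equations are re-solved on the (masked) training rows.
        """
        model = MixedModel(data, self.spec_copy(), allow_single_group=True)
        ll, state = model.loglike(self._sd_arr, self.sigma, method=self.method)
        return MixedModelResults(model, self.method, self._sd_arr, self.sigma,
                                 ll, state, True, 0)

    def spec_copy(self) -> ModelSpec:
        s = self.model.spec
        return ModelSpec(response=s.response, fixed=list(s.fixed),
                         intercept=s.intercept, random=list(s.random),
                         method=s.method)

    # -- profiling -------------------------------------------------------------
    def profile(self, label: str, grid: Sequence[float]) -> pd.DataFrame:
        """Profile the objective over one component SD.

        Other components are re-optimised at each grid point (warm started at
        the fitted values).  Returns a DataFrame (sd, loglik).
        """
        grid = np.asarray(list(grid), float)
        if grid.size == 0:
            raise ValueError("empty profile grid")
        lls = []
        for v in grid:
            res = self.model.fit(method=self.method,
                                 fixed_components={label: float(v)},
                                 maxiter=500)
            lls.append(res.llf)
        return pd.DataFrame({"sd": grid, "loglik": lls})

    # -- reporting -------------------------------------------------------------
    def variance_shares(self, include_residual: bool = True) -> pd.Series:
        sds = list(self._sd_arr) + ([self.sigma] if include_residual else [])
        idx = [t.label for t in self.model.spec.random] \
            + (["Residual"] if include_residual else [])
        v = np.asarray(sds) ** 2
        return pd.Series(v / v.sum(), index=idx)

    def summary(self) -> str:
        lines = [
            "Mixed model fit ({})".format(self.method.upper()),
            f"  formula:   {self.model.spec.formula}",
            f"  nobs: {self.nobs}   loglik: {self.llf:.3f}   "
            f"converged: {self.converged} (iter {self.n_iter})",
            "",
            "Fixed effects:",
        ]
        bse = self.bse_fe
        for name in self.model.exog_names:
            b = self.fe_params[name]
            se = bse[name]
            z = b / se if se > 0 else np.nan
            lines.append(f"  {name:<28s} {b:10.4f}  (SE {se:.4f}, z {z:7.2f})")
        lines.append("")
        lines.append("Random effects (SD scale, %Var in brackets):")
        shares = self.variance_shares()
        for t, term in enumerate(self.model.spec.random):
            lines.append(
                f"  {term.label:<28s} {self._sd_arr[t]:8.4f}  "
                f"({100 * shares[term.label]:5.1f}%)  "
                f"groups: {len(self.model.term_groups[t])}")
        lines.append(f"  {'Residual':<28s} {self.sigma:8.4f}  "
                     f"({100 * shares['Residual']:5.1f}%)")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# within/between (group-mean-centred) design
# ---------------------------------------------------------------------------


@dataclass
class CenteredDesign:
    """Group-mean-centred covariates for the within/between decomposition.

    data : copy of the modelled rows with, per covariate ``v``, the columns
        ``v_between`` (group mean of the standardised covariate, constant
        within group) and ``v_within`` (deviation from that mean, averaging to
        zero exactly within each group).
    standardizers : {covariate: (mean, sd)} used for the global z-scoring.
    group_ranges : per group and covariate, realized ranges of the
        standardised values (95% interval by default), for effect rescaling.
    excluded : {covariate: n rows dropped because the covariate was entirely
        missing for their group}.
    """

    data: pd.DataFrame
    grouping: str
    covariates: list
    standardizers: dict
    group_ranges: pd.DataFrame
    excluded: dict


def center_within_between(data: pd.DataFrame, covariates: Sequence[str],
                          grouping: str = "species",
                          range_quantile: float = 0.95,
                          min_records_for_range: int = 3) -> CenteredDesign:
    """Split covariates into group means and within-group deviations.

    Covariates are z-scored over the modelled records *before* splitting, so
    both parts are on the same global-SD scale and the fitted between/within
    coefficients are directly comparable.  Rows whose group has no observed
    value for some covariate are excluded (per-covariate counts reported).
    """
    covariates = list(covariates)
    df = data.copy()
    excluded = {}
    for v in covariates:
        grp_ok = df.groupby(grouping)[v].transform(lambda s: s.notna().any())
        n_bad = int((~grp_ok).sum())
        if n_bad:
            excluded[v] = n_bad
            df = df.loc[grp_ok]
    df = df.dropna(subset=covariates)
    standardizers = {}
    lo_q = (1.0 - range_quantile) / 2.0
    for v in covariates:
        mu = float(df[v].mean())
        sd = float(df[v].std(ddof=0))
        if sd == 0:
            raise ValueError(f"covariate {v!r} has zero variance")
        standardizers[v] = (mu, sd)
        z = (df[v] - mu) / sd
        between = z.groupby(df[grouping]).transform("mean")
        df[f"{v}_between"] = between
        df[f"{v}_within"] = z - between
        df[f"_{v}_z"] = z
    counts = df.groupby(grouping).size()
    rows = []
    for g, sub in df.groupby(grouping):
        rec = {"group": g, "n": len(sub)}
        for v in covariates:
            if len(sub) >= min_records_for_range:
                zv = sub[f"_{v}_z"]
                rec[f"{v}_range"] = float(zv.quantile(1 - lo_q) - zv.quantile(lo_q))
            else:
                rec[f"{v}_range"] = np.nan
        rows.append(rec)
    ranges = pd.DataFrame(rows).set_index("group")
    df = df.drop(columns=[f"_{v}_z" for v in covariates])
    return CenteredDesign(data=df, grouping=grouping, covariates=covariates,
                          standardizers=standardizers, group_ranges=ranges,
                          excluded=excluded)
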