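"""Multi-kernel linear mixed models: REML variance components and BLUP.

The model is

    y = X b + sum_k Z g_k + e,   g_k ~ N(0, s2_k K_k),   e ~ N(0, s2_e I),

with X the fixed-effect design (intercept plus environment contrasts), Z the
observation-to-line incidence, and each K_k a dense line-by-line kinship.
Restricted maximum likelihood is maximized over the nonnegative variance
components by monotone EM steps (rank-aware, so each step provably does not
decrease the restricted likelihood) accelerated by average-information (AI)
updates with step halving; components whose updates go negative are projected
to a small floor and flagged as boundary estimates at convergence.

All per-iteration linear algebra is carried out at the line level (m lines)
rather than the observation level (n >= m) via the Woodbury identity

    V^-1 = s2_e^-1 (I_n - Z G (s2_e I_m + D G)^-1 Z'),  G = sum_k s2_k K_k,

where D = Z'Z is the diagonal matrix of per-line observation counts, so a
fit costs O(m^3) per iteration regardless of replication across
environments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .kinship import KinshipMatrix

__all__ = [
    "ModelSpec",
    "FitOptions",
    "MixedModelFit",
    "build_design",
    "fit",
    "blup_product",
]

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class ModelSpec:
    """Data and design for one mixed model: y, X, line incidence and kernels."""

    y: np.ndarray
    X: np.ndarray
    line_index: np.ndarray  # per observation, index into line_ids
    line_ids: tuple[str, ...]
    kernels: dict[str, KinshipMatrix]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        self.line_index = np.asarray(self.line_index, dtype=int)
        self.line_ids = tuple(self.line_ids)
        n = self.y.size
        if not np.all(np.isfinite(self.y)):
            raise ValueError("phenotype vector contains non-finite values")
        if self.X.shape[0] != n or self.line_index.shape[0] != n:
            raise ValueError("rows of y, X and line incidence disagree")
        m = len(self.line_ids)
        if self.line_index.min(initial=0) < 0 or (n and self.line_index.max() >= m):
            raise ValueError("line index out of range")
        for name, k in self.kernels.items():
            if k.n_lines != m:
                raise ValueError(f"kernel {name!r} dimension {k.n_lines} != {m} lines")
            if k.line_ids != self.line_ids:
                raise ValueError(f"kernel {name!r} line ids/order differ from the model's")
        if len(set(self.line_index.tolist())) < 2:
            raise ValueError("need at least 2 distinct lines")

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)


@dataclass
class FitOptions:
    max_iter: int = 200
    tol: float = 1e-6            # convergence on |delta logREML|
    use_ai: bool = True          # average-information acceleration after EM warmup
    n_em_start: int = 3
    boundary_eps: float = 1e-8   # x var(y): below this a component is "on the boundary"
    floor: float = 1e-12         # x var(y): projection floor during iteration
    init: Mapping[str, float] | None = None  # warm-start variance components


@dataclass
class MixedModelFit:
    """REML variance components, restricted log-likelihood and per-kernel BLUPs."""

    variance_components: dict[str, float]
    logREML: float
    blups: dict[str, np.ndarray]
    converged: bool
    boundary_flags: dict[str, bool]
    n_iter: int
    fixed_effects: np.ndarray
    line_ids: tuple[str, ...]
    history: list[float] = field(default_factory=list)

    def to_report(self) -> dict:
        return {
            "variance_components": {k: float(v) for k, v in self.variance_components.items()},
            "logREML": float(self.logREML),
            "converged": bool(self.converged),
            "boundary_flags": {k: bool(v) for k, v in self.boundary_flags.items()},
            "n_iter": int(self.n_iter),
        }


def build_design(
    pheno: pd.DataFrame, line_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observation vector, fixed design and line incidence from a phenotype table.

    X holds an intercept plus treatment contrasts for environments (first
    environment, in sorted order, as the reference).
    """
    lookup = {l: i for i, l in enumerate(line_ids)}
    unknown = set(pheno["line_id"]) - set(lookup)
    if unknown:
        raise ValueError(f"phenotyped lines missing from line ids: {sorted(unknown)[:5]}")
    y = pheno["value"].to_numpy(dtype=float)
    line_index = np.array([lookup[l] for l in pheno["line_id"]], dtype=int)
    envs = sorted(pheno["env_id"].unique())
    X = np.ones((len(pheno), 1))
    if len(envs) > 1:
        dummies = np.column_stack(
            [(pheno["env_id"] == e).to_numpy(dtype=float) for e in envs[1:]]
        )
        X = np.hstack([X, dummies])
    return y, X, line_index


def _drop_rank_deficient(X: np.ndarray) -> np.ndarray:
    """Keep a maximal independent column subset of X (warn if any dropped)."""
    q, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        keep = np.sort(piv[:rank])
        warnings.warn(f"dropping {X.shape[1] - rank} rank-deficient fixed-effect columns")
        return X[:, keep]
    return X


class _State:
    """All REML quantities at one point in variance-component space."""

    def __init__(self, model: ModelSpec, Ks: list[np.ndarray], sig: np.ndarray, sig_e: float):
        y, X, li = model.y, model.X, model.line_index
        n, m = y.size, model.n_lines
        D = np.bincount(li, minlength=m).astype(float)

        if Ks:
            G = sum(s * K for s, K in zip(sig, Ks))
        else:
            G = np.zeros((m, m))
        A = sig_e * np.eye(m) + D[:, None] * G
        lu, piv = scipy.linalg.lu_factor(A)
        # C = G A^-1 (symmetric); solve A' C' = G'
        C = scipy.linalg.lu_solve((lu, piv), G, trans=1).T
        C = (C + C.T) / 2.0

        def vinv(M: np.ndarray) -> np.ndarray:
            Mz = np.zeros((m,) + M.shape[1:])
            np.add.at(Mz, li, M)
            return (M - (C @ Mz)[li]) / sig_e

        ViX = vinv(X)
        Viy = vinv(y)
        B = X.T @ ViX
        Bc = scipy.linalg.cho_factor((B + B.T) / 2.0)
        beta = scipy.linalg.cho_solve(Bc, X.T @ Viy)
        Py = Viy - ViX @ beta
        ZtPy = np.bincount(li, weights=Py, minlength=m)

        # Z' V^-1 Z and Z' P Z for trace terms
        S = (np.diag(D) - (D[:, None] * C) * D[None, :]) / sig_e
        T = np.zeros((m, X.shape[1]))
        np.add.at(T, li, ViX)
        SP = S - T @ scipy.linalg.cho_solve(Bc, T.T)

        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            raise np.linalg.LinAlgError("V is not positive definite")
        logdetV = (n - m) * np.log(sig_e) + logdetA
        logdetB = 2.0 * float(np.sum(np.log(np.diag(Bc[0]))))
        yPy = float(y @ Py)
        p = X.shape[1]
        self.ll = -0.5 * (logdetV + logdetB + yPy + (n - p) * _LOG2PI)

        self.tr_PM = np.array([float(np.sum(SP * K)) for K in Ks])
        self.yPMPy = np.array([float(ZtPy @ (K @ ZtPy)) for K in Ks])
        # residual analogues: tr(P) and y'PPy
        trVinv = (n - float(np.sum(np.diag(C) * D))) / sig_e
        X2 = ViX.T @ ViX
        self.tr_P = trVinv - float(np.trace(scipy.linalg.cho_solve(Bc, X2)))
        self.yPPy = float(Py @ Py)

        self.Py, self.ZtPy, self.beta = Py, ZtPy, beta
        self._vinv, self._ViX, self._Bc, self._li = vinv, ViX, Bc, li

    def apply_P(self, u: np.ndarray) -> np.ndarray:
        Viu = self._vinv(u)
        return Viu - self._ViX @ scipy.linalg.cho_solve(self._Bc, self._ViX.T @ u)


def fit(model: ModelSpec, opts: FitOptions | None = None) -> MixedModelFit:
    """Maximize the restricted likelihood over nonnegative variance components.

    Returns the restricted log-likelihood at the optimum, the estimated
    components (kernels first, then ``residual``), per-kernel BLUPs (all-zero
    for boundary components), and convergence/boundary flags.
    """
    opts = opts or FitOptions()
    X = _drop_rank_deficient(model.X)
    if X is not model.X:
        model = ModelSpec(model.y, X, model.line_index, model.line_ids, model.kernels)
    n, p = model.n_obs, model.X.shape[1]
    if n <= p:
        raise ValueError("residual variance not identifiable: n_obs <= rank(X)")

    names = list(model.kernels)
    Ks = [model.kernels[k].values for k in names]
    ranks = np.array([model.kernels[k].rank() for k in names], dtype=float)
    vary = float(np.var(model.y)) or 1.0
    floor = opts.floor * vary

    # initial values: split the OLS residual variance across components
    beta0, *_ = np.linalg.lstsq(model.X, model.y, rcond=None)
    v0 = float(np.sum((model.y - model.X @ beta0) ** 2)) / max(n - p, 1)
    sig = np.empty(len(Ks))
    for j, K in enumerate(Ks):
        scale = float(np.mean(np.diag(K))) or 1.0
        sig[j] = 0.5 * v0 / (len(Ks) * scale)
    sig_e = 0.5 * v0 if Ks else v0
    if opts.init:
        for j, name in enumerate(names):
            if name in opts.init:
                sig[j] = max(float(opts.init[name]), floor)
        if "residual" in opts.init:
            sig_e = max(float(opts.init["residual"]), floor)
    sig = np.maximum(sig, floor)
    sig_e = max(sig_e, floor)

    state = _State(model, Ks, sig, sig_e)
    history = [state.ll]
    converged = False
    it = 0

    def em_step(st: _State, s: np.ndarray, se: float) -> tuple[np.ndarray, float]:
        s_new = s + (s**2 / ranks) * (st.yPMPy - st.tr_PM) if len(s) else s
        se_new = se + (se**2 / n) * (st.yPPy - st.tr_P)
        return np.maximum(s_new, floor), max(se_new, floor)

    for it in range(1, opts.max_iter + 1):
        accepted = False
        if opts.use_ai and it > opts.n_em_start:
            # average-information step over the active components (residual
            # last); components pinned at the floor with a non-positive
            # score are held fixed so the AI system stays well conditioned
            score_full = np.append(
                0.5 * (state.yPMPy - state.tr_PM), 0.5 * (state.yPPy - state.tr_P)
            )
            cur = np.append(sig, sig_e)
            active = (cur > 2.0 * floor) | (score_full > 0.0)
            active[-1] = True  # residual always free
            idx = np.nonzero(active)[0]
            us_all = [(K @ state.ZtPy)[model.line_index] for K in Ks] + [state.Py]
            us = [us_all[a] for a in idx]
            Pus = [state.apply_P(u) for u in us]
            q = len(us)
            AI = np.empty((q, q))
            for a in range(q):
                for b in range(a, q):
                    AI[a, b] = AI[b, a] = 0.5 * float(us[a] @ Pus[b])
            ridge = 1e-8 * max(np.trace(AI) / q, 1.0)
            try:
                delta_act = np.linalg.solve(AI + ridge * np.eye(q), score_full[idx])
            except np.linalg.LinAlgError:
                delta_act = None
            if delta_act is not None:
                delta = np.zeros_like(cur)
                delta[idx] = delta_act
                step = 1.0
                for _ in range(8):
                    cand = np.maximum(cur + step * delta, floor)
                    try:
                        st_new = _State(model, Ks, cand[:-1], cand[-1])
                    except np.linalg.LinAlgError:
                        step /= 2.0
                        continue
                    if st_new.ll >= state.ll - 1e-10:
                        sig, sig_e, state = cand[:-1], cand[-1], st_new
                        accepted = True
                        break
                    step /= 2.0
        if not accepted:
            sig, sig_e = em_step(state, sig, sig_e)
            state = _State(model, Ks, sig, sig_e)
        history.append(state.ll)
        if abs(history[-1] - history[-2]) < opts.tol:
            converged = True
            break

    if not converged:
        warnings.warn(f"REML did not converge in {opts.max_iter} iterations")

    eps = opts.boundary_eps * vary
    boundary = {name: bool(s < eps) for name, s in zip(names, sig)}
    boundary["residual"] = bool(sig_e < eps)
    components = {name: (0.0 if boundary[name] else float(s)) for name, s in zip(names, sig)}
    components["residual"] = float(sig_e)

    blups: dict[str, np.ndarray] = {}
    for name, s, K in zip(names, sig, Ks):
        if boundary[name]:
            blups[name] = np.zeros(model.n_lines)
        else:
            blups[name] = s * (K @ state.ZtPy)

    return MixedModelFit(
        variance_components=components,
        logREML=float(state.ll),
        blups=blups,
        converged=converged,
        boundary_flags=boundary,
        n_iter=it,
        fixed_effects=state.beta,
        line_ids=model.line_ids,
        history=history,
    )


def blup_product(fit_result: MixedModelFit, term_i: str, term_j: str) -> np.ndarray:
    """Elementwise product of two BLUP vectors (e.g. the two arm additive effects)."""
    for t in (term_i, term_j):
        if t not in fit_result.blups:
            raise KeyError(f"no BLUP term {t!r} in fit (have {sorted(fit_result.blups)})")
    return fit_result.blups[term_i] * fit_result.blups[term_j]
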