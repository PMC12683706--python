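"""Integrated step-selection analysis.

Each observed step is matched with K control steps whose lengths and turns
are drawn from movement kernels (gamma step lengths, von Mises turns) fitted
to the data. Selection for the log habitat resource index is then estimated
by maximizing the stratified conditional (multinomial) log-likelihood

    sum_s log[ exp(eta_case) / sum_choices exp(eta) ],

with eta = b_sl*length + b_lsl*log(length) + b_cos*cos(turn) +
b_HRI*log(HRI) and optional ridge-shrunk per-individual / per-year
deviations on the HRI slope. This is exactly the partial likelihood of the
constant-event-time Cox construction used for step-selection models, so the
coefficient on log(HRI) is the log relative selection strength per unit
log(HRI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .escape_map import EScape, sample_hri

logger = logging.getLogger(__name__)

__all__ = [
    "MovementKernel",
    "SSFFit",
    "StepSelectionFunction",
    "fit_kernel",
    "make_controls",
    "fit_issf",
    "rss",
]

FIXED_TERMS = ("length", "log_length", "cos_turn", "log_hri")


@dataclass(frozen=True)
class MovementKernel:
    """Gamma step-length and von Mises turn-angle kernels."""

    shape: float
    scale: float
    mu: float
    kappa: float

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be > 0")
        if self.kappa < 0:
            raise ValueError("von Mises kappa must be >= 0")

    @property
    def mean_length(self) -> float:
        return self.shape * self.scale


def fit_kernel(steps: pd.DataFrame) -> MovementKernel:
    """Maximum-likelihood movement kernels from an observed step series.

    Positive lengths feed the gamma fit (zero-length steps are excluded with
    a logged count); defined turns feed the von Mises fit.
    """
    turns = steps["turn"].to_numpy(dtype=float)
    turns = turns[np.isfinite(turns)]
    if turns.size < 10:
        raise ValueError("need at least 10 steps with defined turns")
    lengths = steps["length"].to_numpy(dtype=float)
    lengths = lengths[np.isfinite(lengths)]
    n_zero = int(np.sum(lengths <= 0))
    if n_zero:
        logger.info("fit_kernel: excluded %d zero-length steps from gamma fit", n_zero)
    lengths = lengths[lengths > 0]
    if lengths.size < 2 or np.ptp(lengths) == 0:
        raise ValueError("degenerate step lengths: cannot fit a gamma kernel")
    shape, _, scale = stats.gamma.fit(lengths, floc=0)
    kappa, mu, _ = stats.vonmises.fit(turns, fscale=1)
    return MovementKernel(shape=float(shape), scale=float(scale), mu=float(mu), kappa=float(max(kappa, 0.0)))


def make_controls(
    steps: pd.DataFrame,
    kernel: MovementKernel,
    K: int = 50,
    escape: EScape | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Matched case-control step sets for the conditional likelihood.

    For every observed step with a defined turn, K alternative endpoints are
    drawn by sampling a length from the gamma kernel and a turn from the von
    Mises kernel applied to the previous heading. The log(HRI) covariate is
    attached at each endpoint from ``escape``; any stratum whose case or
    control endpoint has a missing covariate (outside the E-scape, nodata, or
    HRI <= 0) is dropped entirely, with the count logged.

    Returns a long DataFrame: stratum, case (0/1), length, log_length,
    cos_turn, log_hri, x, y, bird_id, year.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    obs = steps[np.isfinite(steps["turn"]) & (steps["length"] > 0)].reset_index(drop=True)
    n = len(obs)
    if n == 0:
        raise ValueError("no usable observed steps (need defined turns and positive lengths)")
    rng = np.random.default_rng(seed)

    prev_heading = (obs["heading"] - obs["turn"]).to_numpy(dtype=float)
    x0 = obs["x0"].to_numpy(dtype=float)
    y0 = obs["y0"].to_numpy(dtype=float)

    ctrl_len = rng.gamma(kernel.shape, kernel.scale, size=(n, K))
    if kernel.kappa > 0:
        ctrl_turn = rng.vonmises(kernel.mu, kernel.kappa, size=(n, K))
    else:
        ctrl_turn = rng.uniform(-np.pi, np.pi, size=(n, K))
    ctrl_head = prev_heading[:, None] + ctrl_turn
    cx = x0[:, None] + ctrl_len * np.cos(ctrl_head)
    cy = y0[:, None] + ctrl_len * np.sin(ctrl_head)

    # interleave case + controls: rows (n, K+1)
    all_len = np.column_stack([obs["length"].to_numpy(dtype=float), ctrl_len])
    all_turn = np.column_stack([obs["turn"].to_numpy(dtype=float), ctrl_turn])
    all_x = np.column_stack([obs["x1"].to_numpy(dtype=float), cx])
    all_y = np.column_stack([obs["y1"].to_numpy(dtype=float), cy])

    if escape is not None:
        hri = sample_hri(escape, np.column_stack([all_x.ravel(), all_y.ravel()])).reshape(n, K + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_hri = np.where(hri > 0, np.log(hri), np.nan)
    else:
        log_hri = np.zeros((n, K + 1))

    ok = np.all(np.isfinite(log_hri), axis=1)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("make_controls: dropped %d/%d strata with missing covariates", n_drop, n)
    if not np.any(ok):
        raise ValueError("all strata dropped: E-scape does not cover the step endpoints")

    idx = np.nonzero(ok)[0]
    m = idx.size
    stratum = np.repeat(obs.loc[idx, "stratum"].to_numpy() if "stratum" in obs else idx, K + 1)
    out = pd.DataFrame(
        {
            "stratum": stratum,
            "case": np.tile(np.r_[1, np.zeros(K, dtype=int)], m),
            "length": all_len[idx].ravel(),
            "cos_turn": np.cos(all_turn[idx]).ravel(),
            "log_hri": log_hri[idx].ravel(),
            "x": all_x[idx].ravel(),
            "y": all_y[idx].ravel(),
            "bird_id": np.repeat(obs.loc[idx, "bird_id"].to_numpy(), K + 1),
            "year": np.repeat(obs.loc[idx, "year"].to_numpy(), K + 1),
        }
    )
    out["log_length"] = np.log(out["length"])
    return out


@dataclass
class SSFFit:
    """Fitted conditional-likelihood step-selection model."""

    coef: dict[str, float]
    se: dict[str, float]
    loglik: float
    n_strata: int
    converged: bool
    ridge: float = 0.0
    individual_dev: dict[str, float] = field(default_factory=dict)
    year_dev: dict[str, float] = field(default_factory=dict)
    vcov: np.ndarray | None = None
    terms: tuple[str, ...] = FIXED_TERMS

    @property
    def z(self) -> dict[str, float]:
        return {k: self.coef[k] / self.se[k] if self.se[k] > 0 else np.nan for k in self.coef}

    @property
    def p(self) -> dict[str, float]:
        return {k: 2 * stats.norm.sf(abs(z)) for k, z in self.z.items()}

    def report(self) -> dict:
        return {
            "coef": self.coef,
            "se": self.se,
            "z": self.z,
            "p": self.p,
            "loglik": self.loglik,
            "n_strata": self.n_strata,
            "converged": self.converged,
            "ridge": self.ridge,
            "individual_dev": self.individual_dev,
            "year_dev": self.year_dev,
        }


class StepSelectionFunction:
    """Conditional-logit step-selection estimator (sklearn-style).

    Parameters
    ----------
    individual_deviations, year_deviations : bool
        Add ridge-shrunk per-individual / per-year deviations to the HRI
        slope (random-slope analogue).
    ridge : float or "auto"
        Penalty weight on the deviations; "auto" selects it by a Laplace
        marginal-likelihood grid search.
    ridge_grid : array-like
        Candidate penalties for "auto".

    Attributes
    ----------
    fit_ : SSFFit
    coef_, se_ : dict per term
    loglik_ : float
    converged_ : bool
    """

    _param_names = ("individual_deviations", "year_deviations", "ridge", "ridge_grid", "tol", "max_iter")

    def __init__(
        self,
        individual_deviations: bool = False,
        year_deviations: bool = False,
        ridge="auto",
        ridge_grid=(0.01, 0.1, 1.0, 10.0, 100.0),
        tol: float = 1e-10,
        max_iter: int = 200,
    ):
        self.individual_deviations = individual_deviations
        self.year_deviations = year_deviations
        self.ridge = ridge
        self.ridge_grid = ridge_grid
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- likelihood machinery ------------------------------------------
    @staticmethod
    def _group_structures(strata: np.ndarray):
        codes, uniques = pd.factorize(strata)
        order = np.argsort(codes, kind="stable")
        return codes, order, len(uniques)

    def _loglik_parts(self, beta, X, case, codes, n_strata, lam, n_dev):
        eta = X @ beta
        # per-stratum log-sum-exp
        m = np.full(n_strata, -np.inf)
        np.maximum.at(m, codes, eta)
        z = np.exp(eta - m[codes])
        denom = np.bincount(codes, weights=z, minlength=n_strata)
        logZ = m + np.log(denom)
        pi = z / denom[codes]
        ll = float(eta[case].sum() - logZ.sum())
        grad = X.T @ (case.astype(float) - pi)
        # Hessian of ll: -(X' diag(pi) X - sum_s m_s m_s')
        Xw = X * pi[:, None]
        A = X.T @ Xw
        M = np.zeros((n_strata, X.shape[1]))
        np.add.at(M, codes, Xw)
        H = -(A - M.T @ M)
        if lam > 0 and n_dev:
            ll_pen = ll - 0.5 * lam * np.sum(beta[-n_dev:] ** 2)
            grad = grad.copy()
            grad[-n_dev:] -= lam * beta[-n_dev:]
            H = H.copy()
            H[np.arange(X.shape[1] - n_dev, X.shape[1]), np.arange(X.shape[1] - n_dev, X.shape[1])] -= lam
        else:
            ll_pen = ll
        return ll, ll_pen, grad, H

    def _newton(self, X, case, codes, n_strata, lam, n_dev):
        beta = np.zeros(X.shape[1])
        # scale columns for conditioning; coefficients rescaled at the end
        scales = X.std(axis=0)
        scales[scales == 0] = 1.0
        Xs = X / scales
        ll_prev = -np.inf
        converged = False
        for _ in range(self.max_iter):
            ll, ll_pen, grad, H = self._loglik_parts(beta, Xs, case, codes, n_strata, lam, n_dev)
            try:
                delta = np.linalg.solve(-H + 1e-12 * np.eye(len(beta)), grad)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(-H, grad, rcond=None)[0]
            # backtracking line search on the penalized objective
            step = 1.0
            for _ in range(30):
                cand = beta + step * delta
                _, ll_new, _, _ = self._loglik_parts(cand, Xs, case, codes, n_strata, lam, n_dev)
                if ll_new >= ll_pen - 1e-12:
                    break
                step *= 0.5
            beta = beta + step * delta
            if abs(ll_new - ll_prev) < self.tol * (1 + abs(ll_new)) and np.max(np.abs(grad)) < 1e-6 * n_strata:
                converged = True
                break
            ll_prev = ll_new
        ll, ll_pen, grad, H = self._loglik_parts(beta, Xs, case, codes, n_strata, lam, n_dev)
        # back-transform to the original scale
        beta_o = beta / scales
        H_o = H * np.outer(scales, scales)
        return beta_o, ll, ll_pen, H_o, converged

    def fit(self, data: pd.DataFrame, y=None):
        """Fit from a long case-control table (see :func:`make_controls`)."""
        need = {"stratum", "case", "length", "log_length", "cos_turn", "log_hri"}
        missing = need - set(data.columns)
        if missing:
            raise ValueError(f"control set missing columns: {sorted(missing)}")
        strata = data["stratum"].to_numpy()
        codes, order, n_strata = self._group_structures(strata)
        if n_strata < 2:
            raise ValueError("need at least 2 strata")
        case = data["case"].to_numpy().astype(bool)
        counts = np.bincount(codes[case], minlength=n_strata)
        if np.any(counts != 1):
            raise ValueError("every stratum must contain exactly one case")

        cols = [data[c].to_numpy(dtype=float) for c in FIXED_TERMS]
        names = list(FIXED_TERMS)
        dev_names: list[str] = []
        if self.individual_deviations:
            for b in pd.unique(data["bird_id"]):
                cols.append(np.where(data["bird_id"] == b, data["log_hri"], 0.0))
                dev_names.append(f"dev_bird:{b}")
        if self.year_deviations:
            for yr in pd.unique(data["year"]):
                cols.append(np.where(data["year"] == yr, data["log_hri"], 0.0))
                dev_names.append(f"dev_year:{yr}")
        X = np.column_stack(cols)
        n_dev = len(dev_names)

        if n_dev and self.ridge == "auto":
            lam = self._select_ridge(X, case, codes, n_strata, n_dev)
        else:
            lam = float(self.ridge) if (n_dev and self.ridge != "auto") else 0.0

        beta, ll, ll_pen, H, converged = self._newton(X, case, codes, n_strata, lam, n_dev)
        if not converged and lam == 0.0:
            logger.warning("SSF fit did not converge unpenalized; retrying with a small ridge")
            lam = 1e-4
            beta, ll, ll_pen, H, converged = self._newton(X, case, codes, n_strata, lam, n_dev)

        try:
            vcov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(-H)
        se_all = np.sqrt(np.clip(np.diag(vcov), 0, None))

        coef = {n: float(beta[i]) for i, n in enumerate(names)}
        se = {n: float(se_all[i]) for i, n in enumerate(names)}
        p0 = len(names)
        ind_dev = {n.split(":", 1)[1]: float(beta[p0 + i]) for i, n in enumerate(dev_names) if n.startswith("dev_bird")}
        yr_dev = {
            n.split(":", 1)[1]: float(beta[p0 + i]) for i, n in enumerate(dev_names) if n.startswith("dev_year")
        }
        self.fit_ = SSFFit(
            coef=coef,
            se=se,
            loglik=float(ll),
            n_strata=int(n_strata),
            converged=bool(converged),
            ridge=lam,
            individual_dev=ind_dev,
            year_dev=yr_dev,
            vcov=vcov,
        )
        self.coef_ = coef
        self.se_ = se
        self.loglik_ = float(ll)
        self.converged_ = bool(converged)
        return self

    def _select_ridge(self, X, case, codes, n_strata, n_dev) -> float:
        """Laplace-approximate marginal likelihood grid search for the
        deviation penalty (random-slope variance analogue)."""
        best_lam, best_score = None, -np.inf
        for lam in self.ridge_grid:
            beta, ll, ll_pen, H, _ = self._newton(X, case, codes, n_strata, lam, n_dev)
            Hbb = -H[-n_dev:, -n_dev:] - lam * np.eye(n_dev)  # unpenalized block
            sign, logdet = np.linalg.slogdet(Hbb + lam * np.eye(n_dev))
            if sign <= 0:
                continue
            score = ll_pen + 0.5 * n_dev * np.log(lam) - 0.5 * logdet
            if score > best_score:
                best_lam, best_score = lam, score
        return float(best_lam if best_lam is not None else 1.0)


def fit_issf(data: pd.DataFrame, options: dict | None = None) -> SSFFit:
    """Functional wrapper over :class:`StepSelectionFunction`."""
    options = options or {}
    model = StepSelectionFunction(**options)
    model.fit(data)
    return model.fit_


def rss(fit: SSFFit, delta_log_hri, group: str | None = None) -> np.ndarray | dict:
    """Relative selection strength exp(beta_HRI * delta) for a change in
    log(HRI); with deviations, per-group curves add the group's slope
    deviation."""
    if not fit.converged:
        raise RuntimeError("RSS requires a converged fit")
    delta = np.asarray(delta_log_hri, dtype=float)
    base = fit.coef["log_hri"]
    if group is None:
        return np.exp(base * delta)
    devs = fit.individual_dev if group == "individual" else fit.year_dev
    return {g: np.exp((base + d) * delta) for g, d in devs.items()}
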