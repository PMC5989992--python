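"""L1-penalized regression of a response on component scores plus ICV.

The model is LASSO-PCR: a response ``y`` is regressed on the subjects'
component scores ``Z = U S`` together with intracranial volume (ICV), under
an L1 penalty that drives most component coefficients to exactly zero,

    beta_hat = argmin_beta { ||y - Z beta||^2 + lambda * ||beta||_1 }.

ICV enters every model so that head size can never masquerade as fingerprint
signal; for linear models its coefficient is afterwards *truncated* away so
predictions derive from the fingerprint alone. Penalty strength is chosen by
inner cross-validation on a log-spaced path, with either the deviance-minimum
or the conservative one-standard-error rule.

The linear solver is scikit-learn's coordinate descent
(``lasso_path``/``Lasso``); the logistic path is solved here by proximal
Newton (IRLS) with warm starts, strong-rule screening and KKT checks, using
the same coordinate-descent core for each weighted subproblem. Path
construction, deviance scoring and the selection rules follow the glmnet
conventions (objective scaled by 1/(2n), predictors standardized internally,
intercept unpenalized, coefficients reported on the original predictor
scale).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso
from sklearn.linear_model import _cd_fast as cd_fast
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "SparseModel",
    "select_penalty",
    "fit_sparse_model",
    "truncate_confound",
    "lambda_max",
    "lambda_path",
    "PenaltySelector",
]

# standardization guard: columns whose SD is below this fraction of the
# largest column SD are numerically degenerate and excluded from the fit
_SD_RTOL = 1e-12
# IRLS controls for the logistic path: weight floor, linear-predictor clip
# (guards quasi-separation at tiny penalties), coefficient-change tolerance
_IRLS_WEIGHT_FLOOR = 1e-5
_IRLS_ETA_CLIP = 30.0
_IRLS_TOL = 1e-7
_IRLS_MAX_ITER = 12
# mean binomial deviance below which the fit is saturated and the path stops
_IRLS_DEV_FLOOR = 1e-6


@dataclass
class SparseModel:
    """A fitted sparse component regression.

    ``beta`` holds the component coefficients on the original score scale,
    ``beta_icv`` the ICV coefficient, both with the unpenalized intercept.
    ``lam`` is the L1 penalty used (glmnet scale) and ``selection_rule``
    records how it was chosen.
    """

    family: str
    beta: np.ndarray
    beta_icv: float
    intercept: float
    lam: float
    selection_rule: str = "fixed"

    def __post_init__(self) -> None:
        if self.family not in ("linear", "logistic"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        self.beta = np.asarray(self.beta, dtype=float)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.beta)) + int(self.beta_icv != 0)

    @property
    def is_intercept_only(self) -> bool:
        return self.n_nonzero == 0

    def to_json(self, path: str | Path | None = None) -> str:
        nz = np.flatnonzero(self.beta)
        payload = {
            "family": self.family,
            "lambda": self.lam,
            "selection_rule": self.selection_rule,
            "n_components": int(len(self.beta)),
            "coefficients": [[int(j), float(self.beta[j])] for j in nz],
            "beta_icv": float(self.beta_icv),
            "intercept": float(self.intercept),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SparseModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        beta = np.zeros(d["n_components"])
        for j, v in d["coefficients"]:
            beta[j] = v
        return cls(d["family"], beta, d["beta_icv"], d["intercept"],
                   d["lambda"], d["selection_rule"])


def _augment(Z: np.ndarray | None, icv: np.ndarray | None) -> np.ndarray:
    parts = []
    if Z is not None and np.size(Z):
        parts.append(np.atleast_2d(np.asarray(Z, dtype=float)))
    if icv is not None:
        parts.append(np.asarray(icv, dtype=float).reshape(-1, 1))
    if not parts:
        raise ValueError("no predictors: need component scores and/or ICV")
    return np.hstack(parts)


def _standardize(Z_aug: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale columns to unit SD; returns (scaled, sd, active-column mask)."""
    sd = Z_aug.std(axis=0, ddof=0)
    active = sd > _SD_RTOL * max(sd.max(), 1.0)
    scaled = Z_aug[:, active] / sd[active]
    return scaled, sd, active


def _check_response(y: np.ndarray, family: str) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if family == "linear":
        if y.std() == 0:
            raise ValueError("degenerate response: y is constant")
    elif family == "logistic":
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("degenerate response: single class")
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("logistic response must be coded {0, 1}")
    else:
        raise ValueError(f"unknown family {family!r}")
    return y


def lambda_max(Xs: np.ndarray, y: np.ndarray, family: str) -> float:
    """Smallest penalty at which every slope is exactly zero (KKT bound).

    ``Xs`` must already be standardized. For the linear family this is
    ``max_j |<x_j - mean, y - mean>| / n``; for logistic the working response
    is ``y - base_rate``.
    """
    n = len(y)
    Xc = Xs - Xs.mean(axis=0)
    resid = y - y.mean()
    lm = float(np.max(np.abs(Xc.T @ resid)) / n)
    return max(lm, 1e-12)


def lambda_path(
    lmax: float, n_lambda: int = 100, lambda_min_ratio: float = 1e-4
) -> np.ndarray:
    """Log-spaced penalty path from ``lmax`` down ``-log10(ratio)`` decades."""
    return np.logspace(np.log10(lmax), np.log10(lmax * lambda_min_ratio), n_lambda)


class PenaltySelector:
    """Inner-CV penalty selection with reusable design-side precomputation.

    Everything derived from the predictors alone — standardization, inner
    fold splits, per-fold centered design matrices and Gram matrices — is
    computed once at construction, so repeated selections against different
    responses (permutation trials) cost only the response-side work. This
    reuse is exact: permuting ``y`` cannot change any of the cached
    quantities.
    """

    def __init__(
        self,
        Z_aug: np.ndarray,
        family: str,
        n_inner_folds: int = 10,
        seed: int = 0,
        n_lambda: int = 100,
        lambda_min_ratio: float = 1e-4,
        stratify_labels: np.ndarray | None = None,
    ):
        self.family = family
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        Z_aug = np.asarray(Z_aug, dtype=float)
        n = Z_aug.shape[0]
        if n < 2 * n_inner_folds:
            raise ValueError(
                f"n={n} too small for {n_inner_folds}-fold inner cross-validation"
            )
        self.Xs, self.sd, self.active = _standardize(Z_aug)
        if family == "logistic" and stratify_labels is not None:
            splitter = StratifiedKFold(n_inner_folds, shuffle=True, random_state=seed)
            splits = list(splitter.split(self.Xs, stratify_labels))
        else:
            splitter = KFold(n_inner_folds, shuffle=True, random_state=seed)
            splits = list(splitter.split(self.Xs))
        self.splits = splits
        self._full_gram = None
        self._fold_cache = []
        if family == "linear":
            for tr, va in splits:
                Xtr = self.Xs[tr]
                mu = Xtr.mean(axis=0)
                Xtr_c = Xtr - mu
                gram = np.ascontiguousarray(Xtr_c.T @ Xtr_c)
                self._fold_cache.append((Xtr_c, mu, gram, self.Xs[va] - mu))

    def _cv_deviance(self, y: np.ndarray, path: np.ndarray) -> np.ndarray:
        """Mean held-out deviance per penalty, over inner folds (rows)."""
        dev = np.empty((len(self.splits), len(path)))
        if self.family == "linear":
            dev[:] = np.inf
            states = [_GramPathState(self._fold_cache[f], y[tr])
                      for f, (tr, va) in enumerate(self.splits)]
            start = 0
            while start < len(path):
                # the cheap sparse top of the path is taken in one block;
                # the expensive dense tail in small ones so the stop rule
                # can cut it as soon as it is hopeless
                chunk = 10 if start < 10 else 5
                lams = path[start:start + chunk]
                for f, (tr, va) in enumerate(self.splits):
                    pred = states[f].advance(lams)
                    dev[f, start:start + len(lams)] = (
                        (y[va][:, None] - pred) ** 2
                    ).mean(axis=0)
                start += len(lams)
                if self._path_done(dev, start):
                    break
        else:
            # held-out deviance tolerates a looser subproblem tol; the
            # selected-penalty refit is done tightly elsewhere
            states = []
            for tr, va in self.splits:
                if len(np.unique(y[tr])) < 2:
                    raise ValueError("single-class inner training fold")
                states.append(_LogisticPathState(self.Xs[tr], y[tr], cd_tol=1e-5))
            dev[:] = np.inf
            start = 0
            while start < len(path):
                chunk = 10 if start < 10 else 5
                lams = path[start:start + chunk]
                for f, (tr, va) in enumerate(self.splits):
                    coefs, b0s = states[f].advance(lams)
                    eta = self.Xs[va] @ coefs + b0s
                    # binomial deviance, numerically safe
                    dev[f, start:start + len(lams)] = 2 * np.mean(
                        np.logaddexp(0.0, eta) - y[va][:, None] * eta, axis=0
                    )
                start += len(lams)
                if self._path_done(dev, start):
                    break
        return dev

    def fit_at(self, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
        """Exact penalized fit at one penalty on the full training design.

        Linear family only. Returns ``(coef, intercept)`` with ``coef`` on
        the original (unstandardized) predictor scale, zeros for dropped
        degenerate columns — the same solution :func:`fit_sparse_model`
        produces, computed through the compiled Gram path for speed.
        """
        if self.family != "linear":
            raise ValueError("fit_at supports the linear family only")
        if self._full_gram is None:
            Xc = self.Xs - self.Xs.mean(axis=0)
            self._full_gram = (np.ascontiguousarray(Xc.T @ Xc), Xc)
        gram, Xc = self._full_gram
        ym = y.mean()
        yc = y - ym
        Xy = Xc.T @ yc
        n = len(y)
        lmax = max(np.max(np.abs(Xy)) / n, lam)
        sub = np.geomspace(lmax, lam, 12) if lam < lmax else np.array([lam])
        coefs = _gram_cd_path_warm(gram, Xy, np.zeros(Xc.shape[1]), sub * n,
                                   np.ascontiguousarray(yc), tol=1e-8,
                                   max_iter=5000)
        beta_std = coefs[:, -1]
        coef = np.zeros(len(self.active))
        coef[self.active] = beta_std / self.sd[self.active]
        intercept = float(ym - self.Xs.mean(axis=0) @ beta_std)
        return coef, intercept

    @staticmethod
    def _path_done(dev: np.ndarray, done: int) -> bool:
        """Abandon the path once the whole last chunk sits far above the
        running deviance minimum: those penalties can no longer win under
        either selection rule (the 1se threshold is min + 1 SE, well inside
        the 4-SE margin used here)."""
        mean = dev[:, :done].mean(axis=0)
        best = int(np.argmin(mean))
        se = dev[:, best].std(ddof=1) / np.sqrt(dev.shape[0])
        margin = max(4.0 * se, 1e-3 * abs(mean[best]))
        start = max(done - 10, 0)
        return bool(np.all(mean[start:done] > mean[best] + margin))

    def select(self, y: np.ndarray, rule: str = "1se") -> float:
        """Pick the penalty by inner-CV deviance under ``rule`` (min | 1se)."""
        if rule not in ("min", "1se"):
            raise ValueError(f"unknown selection rule {rule!r}")
        y = _check_response(y, self.family)
        lmax = lambda_max(self.Xs, y, self.family)
        path = lambda_path(lmax, self.n_lambda, self.lambda_min_ratio)
        dev = self._cv_deviance(y, path)
        mean = dev.mean(axis=0)
        best = int(np.argmin(mean))
        if rule == "min":
            return float(path[best])
        se = dev[:, best].std(ddof=1) / np.sqrt(dev.shape[0])
        # path is descending, so the first index within one SE of the
        # minimum is the largest (most conservative) admissible penalty
        ok = np.flatnonzero(mean <= mean[best] + se)
        return float(path[ok[0]])


class _LogisticPathState:
    """Resumable warm-started L1 logistic path (proximal Newton / IRLS).

    At each penalty the logistic deviance is majorized by its weighted
    least-squares expansion around the current estimate and the resulting
    weighted lasso subproblem is solved by coordinate descent, warm-started
    from the previous penalty (the glmnet algorithm). Strong-rule screening
    restricts each solve to the plausible active set, with a KKT check over
    the excluded coordinates. The intercept is unpenalized (absorbed through
    weighted centering); the objective is
    ``(1/n) * sum(-loglik) + lam * ||beta||_1``.

    ``advance`` may be called repeatedly with successive descending penalty
    chunks, preserving warm state — the basis for validation-driven early
    termination of the path.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, cd_tol: float = 1e-8):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float).ravel()
        self.n, self.d = self.X.shape
        self.beta = np.zeros(self.d)
        base = float(np.clip(self.y.mean(), 1e-9, 1 - 1e-9))
        self.b0 = float(np.log(base / (1 - base)))
        self.p = np.full(self.n, base)
        self.lam_prev: float | None = None
        self.saturated = False
        self.solver = Lasso(alpha=1.0, fit_intercept=False, warm_start=True,
                            tol=cd_tol, max_iter=5000)

    def _irls(self, cand: np.ndarray, lam: float) -> float:
        """Proximal-Newton iterations on the candidate columns; returns deviance/2."""
        X, y, n = self.X, self.y, self.n
        Xc = X[:, cand]
        bc = self.beta[cand]
        b0 = self.b0
        self.solver.alpha = lam
        if Xc.shape[1] == 0:
            # intercept-only Newton: fixed point is the base-rate log-odds
            for _ in range(_IRLS_MAX_ITER):
                pr = expit(np.clip(b0, -_IRLS_ETA_CLIP, _IRLS_ETA_CLIP))
                w0 = max(pr * (1 - pr), _IRLS_WEIGHT_FLOOR)
                new_b0 = b0 + float(np.mean(y - pr)) / w0
                converged = abs(new_b0 - b0) < _IRLS_TOL
                b0 = new_b0
                if converged:
                    break
            self.beta = np.zeros(self.d)
            self.b0 = b0
            eta = np.full(n, np.clip(b0, -_IRLS_ETA_CLIP, _IRLS_ETA_CLIP))
            self.p = expit(eta)
            return float(np.mean(np.logaddexp(0.0, eta) - y * eta))
        prev_dev = np.inf
        for _ in range(_IRLS_MAX_ITER):
            eta = np.clip(b0 + Xc @ bc, -_IRLS_ETA_CLIP, _IRLS_ETA_CLIP)
            p = expit(eta)
            w = np.maximum(p * (1 - p), _IRLS_WEIGHT_FLOOR)
            z = eta + (y - p) / w
            wsum = w.sum()
            xm = (w @ Xc) / wsum
            zm = (w @ z) / wsum
            sw = np.sqrt(w)
            self.solver.coef_ = bc  # warm start the subproblem too
            self.solver.fit(sw[:, None] * (Xc - xm), sw * (z - zm))
            new_bc = self.solver.coef_.copy()
            new_b0 = zm - xm @ new_bc
            delta = max(np.max(np.abs(new_bc - bc), initial=0.0), abs(new_b0 - b0))
            bc, b0 = new_bc, new_b0
            if delta < _IRLS_TOL * max(1.0, np.max(np.abs(bc), initial=1.0)):
                break
            # near quasi-separation the coefficients drift while the fit
            # itself is flat: a plateaued deviance is converged too
            eta = np.clip(b0 + Xc @ bc, -_IRLS_ETA_CLIP, _IRLS_ETA_CLIP)
            dev = float(np.mean(np.logaddexp(0.0, eta) - y * eta))
            if abs(prev_dev - dev) < 1e-5 * max(abs(dev), 1e-3):
                break
            prev_dev = dev
        self.beta = np.zeros(self.d)
        self.beta[cand] = bc
        self.b0 = b0
        eta = np.clip(b0 + Xc @ bc, -_IRLS_ETA_CLIP, _IRLS_ETA_CLIP)
        self.p = expit(eta)
        return float(np.mean(np.logaddexp(0.0, eta) - y * eta))

    def advance(self, lambdas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fit the next (descending) penalty chunk; returns (coefs, intercepts)."""
        lambdas = np.atleast_1d(np.asarray(lambdas, dtype=float))
        coefs = np.empty((self.d, len(lambdas)))
        b0s = np.empty(len(lambdas))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for idx, lam in enumerate(lambdas):
                if self.saturated:
                    coefs[:, idx] = self.beta
                    b0s[idx] = self.b0
                    continue
                lam_prev = lam if self.lam_prev is None else self.lam_prev
                # sequential strong rule: candidates whose gradient at the
                # previous solution comes close to the new threshold
                grad = np.abs(self.X.T @ (self.y - self.p)) / self.n
                cand = (grad >= 2 * lam - lam_prev) | (self.beta != 0)
                while True:
                    half_dev = self._irls(cand, lam)
                    grad = np.abs(self.X.T @ (self.y - self.p)) / self.n
                    violators = (grad > lam * (1 + 1e-3) + 1e-8) & ~cand
                    if not violators.any():
                        break
                    cand = cand | violators
                coefs[:, idx] = self.beta
                b0s[idx] = self.b0
                self.lam_prev = float(lam)
                if 2 * half_dev < _IRLS_DEV_FLOOR:
                    # saturated fit: smaller penalties cannot improve it
                    self.saturated = True
        return coefs, b0s


def _logistic_lasso_path(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray, cd_tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Full L1 logistic path (see :class:`_LogisticPathState`)."""
    return _LogisticPathState(X, y, cd_tol=cd_tol).advance(lambdas)


def select_penalty(
    Z_aug: np.ndarray,
    y: np.ndarray,
    family: str = "linear",
    rule: str = "1se",
    n_inner_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
) -> float:
    """Choose the L1 penalty by inner cross-validated deviance.

    ``Z_aug`` is the full predictor matrix of the training split (component
    scores with ICV as the last column). The penalty path is log-spaced over
    four decades below the smallest all-zero penalty; ``rule`` is ``"min"``
    (deviance minimum) or ``"1se"`` (largest penalty within one standard
    error of the minimum, the conservative default). Deterministic given
    ``seed``.
    """
    y = _check_response(np.asarray(y, dtype=float).ravel(), family)
    strat = y if family == "logistic" else None
    sel = PenaltySelector(
        Z_aug, family, n_inner_folds=n_inner_folds, seed=seed,
        n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio,
        stratify_labels=strat,
    )
    return sel.select(y, rule=rule)


def fit_sparse_model(
    Z: np.ndarray | None,
    icv: np.ndarray | None,
    y: np.ndarray,
    family: str = "linear",
    lam: float = 0.0,
    selection_rule: str = "fixed",
) -> SparseModel:
    """Fit the penalized model at a given penalty.

    Minimizes ``(1/2n)||y - Z_aug b||^2 + lam * ||b||_1`` (linear) or the
    equivalently scaled logistic deviance, with the intercept unpenalized.
    Predictors are standardized to unit SD internally and the coefficients
    back-transformed, so ICV's raw mm^3 scale does not distort its penalty.
    ``Z`` may be None/empty to fit an ICV-only model.
    """
    Z_aug = _augment(Z, icv)
    y = _check_response(y, family)
    if Z_aug.shape[0] != len(y):
        raise ValueError("predictor and response row counts differ")
    if not np.all(np.isfinite(Z_aug)):
        raise ValueError("predictors contain non-finite values")
    Xs, sd, active = _standardize(Z_aug)
    n = len(y)
    coef_std = np.zeros(Z_aug.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if family == "linear":
            if lam == 0:
                # unpenalized least squares on the active columns
                Xc = Xs - Xs.mean(axis=0)
                bc, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
                coef_std[active] = bc
                intercept = float(y.mean() - (Xs.mean(axis=0) @ bc))
            else:
                model = Lasso(alpha=lam, fit_intercept=True, tol=1e-8, max_iter=10000)
                model.fit(Xs, y)
                coef_std[active] = model.coef_
                intercept = float(model.intercept_)
        else:
            if lam == 0:
                raise ValueError("logistic fit requires a positive penalty")
            # warm-started descent from the all-zero penalty to the target
            lmax = lambda_max(Xs, y, "logistic")
            if lam >= lmax:
                sub_path = np.array([lam])
            else:
                sub_path = np.geomspace(lmax, lam, 25)
            coefs, b0s = _logistic_lasso_path(Xs, y, sub_path)
            coef_std[active] = coefs[:, -1]
            intercept = float(b0s[-1])
    coef = np.zeros_like(coef_std)
    coef[active] = coef_std[active] / sd[active]
    n_comp = Z_aug.shape[1] - (1 if icv is not None else 0)
    beta = coef[:n_comp]
    beta_icv = float(coef[n_comp]) if icv is not None else 0.0
    return SparseModel(family, beta, beta_icv, intercept, float(lam), selection_rule)


def truncate_confound(m: SparseModel) -> np.ndarray:
    """Drop the ICV coefficient (and intercept) from a fitted linear model.

    Returns ``beta_star``, the component coefficients alone, so downstream
    predictions derive only from the fingerprint. Invalid for logistic
    models: removing a coefficient inside the nonlinear link distorts the
    predicted class probabilities, so binary models are instead compared
    against an ICV-only benchmark.
    """
    if m.family != "linear":
        raise ValueError(
            "confound truncation is only defined for linear models; compare "
            "logistic models against an ICV-only fit instead"
        )
    return m.beta.copy()

class _GramPathState:
    """Warm CD state for one inner fold's descending penalty path."""

    def __init__(self, fold_cache, ytr: np.ndarray):
        self.Xtr_c, self.mu, self.gram, self.Xva_c = fold_cache
        self.n_tr = self.Xtr_c.shape[0]
        self.ym = ytr.mean()
        self.ytr_c = np.ascontiguousarray(ytr - self.ym)
        self.Xy = self.Xtr_c.T @ self.ytr_c
        self.beta = np.zeros(self.Xtr_c.shape[1])

    def advance(self, lams: np.ndarray) -> np.ndarray:
        """Fit the next penalty chunk; returns validation predictions.

        Held-out deviance only ranks penalties, so the solves run at a
        selection-grade tolerance; the refit at the chosen penalty is done
        tightly elsewhere.
        """
        coefs = _gram_cd_path_warm(self.gram, self.Xy, self.beta,
                                   np.asarray(lams) * self.n_tr, self.ytr_c,
                                   tol=1e-3)
        self.beta = coefs[:, -1].copy()
        return self.Xva_c @ coefs + self.ym


def _gram_cd_path_warm(G, Xy, beta0, alphas_scaled, y_c, tol=1e-4, max_iter=2000):
    """Warm-started lasso solves along a descending penalty grid, Gram form.

    Thin loop over scikit-learn's screened coordinate-descent kernel
    (``enet_coordinate_descent_gram``): ``G = Xc'Xc``, ``Xy = Xc'yc``,
    ``alphas_scaled = lam * n``. ``y_c`` enters only the kernel's duality-gap
    convergence test. Returns coefficients of shape ``(d, len(alphas))``.
    Bypassing the public path API removes per-call validation overhead,
    which dominates at permutation-trial volumes.
    """
    rng = np.random.RandomState(0)
    coef = np.array(beta0, dtype=float, copy=True)
    coefs = np.empty((len(coef), len(alphas_scaled)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for a, alpha in enumerate(alphas_scaled):
            coef, *_ = cd_fast.enet_coordinate_descent_gram(
                coef, alpha, 0.0, G, Xy, y_c, max_iter, tol, rng, 0, 0, 1,
            )
            coefs[:, a] = coef
    return coefs
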