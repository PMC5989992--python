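"""Cross-validated prediction, permutation nulls, bootstrap CIs, and FDR.

The evaluation scheme is fivefold cross-validation: a unique 20% of the
subjects is held out in each fold, the entire training pipeline (economical
SVD, penalty selection, sparse fit, confound truncation, back-projection) is
run on the remaining 80%, and the held-out subjects are scored against the
resulting phenotype map. Continuous responses are summarized by the Pearson
correlation between observation and held-out prediction; binary responses by
classification accuracy, reported both for an ICV-only benchmark and for the
full ICV + fingerprint-component model.

Inference is nonparametric throughout: significance from a permutation test
that reruns the full pipeline on shuffled responses (trials whose null model
is intercept-only leave the correlation undefined and are excluded from the
p-value denominator), confidence intervals from percentile bootstrap over
prediction-observation pairs, and multiplicity control by Benjamini-Hochberg
FDR.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decomposition import Decomposition, component_scores, economical_svd
from .phenotype import LCPMap, build_phenotype_map
from .regression import PenaltySelector, SparseModel, fit_sparse_model, truncate_confound

__all__ = [
    "CVConfig",
    "FoldAssignment",
    "CVResult",
    "PermutationResult",
    "derive_seed",
    "assign_folds",
    "run_cv_continuous",
    "run_cv_binary",
    "fit_full_sample",
    "bootstrap_ci",
    "permutation_test",
    "fdr_adjust",
    "pairwise_similarity",
    "icv_response_association",
]


def derive_seed(seed: int, *tags) -> int:
    """Derive a stream-specific child seed from one top-level seed.

    One run seed fans out to fold assignment, per-fold inner CV, permutation
    trials and the bootstrap through stable string tags, so every stochastic
    stage is reproducible yet decorrelated. Result is below 2**31.
    """
    parts = [int(seed) & 0xFFFFFFFF] + [zlib.crc32(str(t).encode()) for t in tags]
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31 - 1))


@dataclass
class CVConfig:
    """Run configuration for the cross-validated pipeline.

    ``k`` outer folds (fivefold by default, each holding out 20%);
    ``rule`` is the inner-CV penalty selection rule (``"1se"`` conservative
    default, or ``"min"``); ``n_inner_folds``/``n_lambda``/
    ``lambda_min_ratio`` shape the inner penalty search; ``seed`` is the one
    top-level seed. ``pooled_decomposition`` reuses a single cohort SVD for
    all folds (exploration only — it leaks held-out rows into the axes);
    ``center_columns`` switches to conventional centered PCA.
    """

    k: int = 5
    rule: str = "1se"
    n_inner_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    seed: int = 0
    pooled_decomposition: bool = False
    center_columns: bool = False
    balance_tolerance: float = 0.25


@dataclass
class FoldAssignment:
    """A partition of subjects into ``k`` cross-validation folds."""

    k: int
    fold_of: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.fold_of = np.asarray(self.fold_of, dtype=int)
        sizes = np.bincount(self.fold_of, minlength=self.k)
        if len(sizes) != self.k or sizes.max() - sizes.min() > 1:
            raise ValueError("folds must partition subjects with sizes differing by <= 1")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


@dataclass
class CVResult:
    """Held-out predictions and summary metric for one response."""

    response_name: str
    family: str
    y: np.ndarray
    y_pred: np.ndarray
    folds: FoldAssignment
    metric: float
    metric_undefined: bool = False
    metric_icv_only: float | None = None
    train_metric: float | None = None
    y_pred_icv_only: np.ndarray | None = None
    fold_maps: list[LCPMap] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class PermutationResult:
    """Null distribution from response-permutation trials.

    Trials whose refit pipeline yields constant predictions have no defined
    correlation; they are counted in ``n_undefined`` and excluded from the
    p-value denominator (a conservative variant keeps them as
    non-exceedances).
    """

    n_trials: int
    null_stats: np.ndarray
    n_undefined: int
    observed: float
    p_value: float


def assign_folds(
    subject_ids,
    k: int,
    seed: int,
    labels: np.ndarray | None = None,
    balance_tolerance: float = 0.25,
    max_attempts: int = 100,
) -> FoldAssignment:
    """Randomly partition subjects into ``k`` folds of near-equal size.

    With binary ``labels`` supplied, the draw is repeated (up to
    ``max_attempts``) until every fold's minority-class count is within
    ``balance_tolerance`` (relative) of its expected count — the "near-even
    class distribution" check that protects infrequent categories from
    ending up concentrated in one fold. Folds hold integer counts, so the
    slack has a floor of one subject.
    """
    n = len(subject_ids) if not np.isscalar(subject_ids) else int(subject_ids)
    if n < k:
        raise ValueError(f"cannot split {n} subjects into {k} folds")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[perm] = np.arange(n) % k
        if labels is None:
            return FoldAssignment(k, fold_of, seed)
        labels = np.asarray(labels)
        minority = np.argmin(np.bincount(labels.astype(int)))
        global_frac = np.mean(labels == minority)
        sizes = np.bincount(fold_of, minlength=k)
        counts = np.array([np.sum(labels[fold_of == f] == minority) for f in range(k)])
        slack = np.maximum(1.0, balance_tolerance * global_frac * sizes)
        if np.all(np.abs(counts - global_frac * sizes) <= slack):
            return FoldAssignment(k, fold_of, seed)
    raise ValueError(
        f"could not balance folds within {balance_tolerance:.0%} after {max_attempts} draws"
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


class _CVEngine:
    """Per-fold design-side state, reusable across permutation trials.

    Everything that depends only on the fingerprints and ICV — fold
    assignment, per-fold SVDs, component scores, and the inner-CV penalty
    selectors with their cached fold splits and Gram matrices — is computed
    once. `run` then evaluates the response-side pipeline for any ``y``
    paired with the same subjects.
    """

    def __init__(self, X, icv, family: str, config: CVConfig,
                 labels: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        icv = np.asarray(icv, dtype=float).ravel()
        if X.shape[0] != len(icv):
            raise ValueError("X and icv row counts differ")
        self.family = family
        self.config = config
        self.n = X.shape[0]
        self.folds = assign_folds(
            self.n, config.k, derive_seed(config.seed, "folds"),
            labels=labels, balance_tolerance=config.balance_tolerance,
        )
        pooled = None
        if config.pooled_decomposition:
            pooled = economical_svd(X, center=config.center_columns)
        self.fold_state = []
        for f in range(config.k):
            tr = self.folds.train_indices(f)
            te = self.folds.test_indices(f)
            if pooled is None:
                d = economical_svd(X[tr], subject_ids=tr, center=config.center_columns)
                Z_tr = d.scores
            else:
                d = pooled
                Z_tr = component_scores(d, X[tr])
            Z_te = component_scores(d, X[te])
            sel_seed = derive_seed(config.seed, "inner", f)
            Z_aug = np.column_stack([Z_tr, icv[tr]])
            selector = PenaltySelector(
                Z_aug, family,
                n_inner_folds=config.n_inner_folds, seed=sel_seed,
                n_lambda=config.n_lambda, lambda_min_ratio=config.lambda_min_ratio,
                stratify_labels=labels[tr] if labels is not None else None,
            )
            icv_selector = None
            if family == "logistic":
                icv_selector = PenaltySelector(
                    icv[tr].reshape(-1, 1), family,
                    n_inner_folds=config.n_inner_folds,
                    seed=derive_seed(config.seed, "inner-icv", f),
                    n_lambda=config.n_lambda, lambda_min_ratio=config.lambda_min_ratio,
                    stratify_labels=labels[tr] if labels is not None else None,
                )
            self.fold_state.append(
                dict(train=tr, test=te, d=d, Z_tr=Z_tr, Z_te=Z_te,
                     icv_tr=icv[tr], icv_te=icv[te],
                     selector=selector, icv_selector=icv_selector)
            )

    def run_continuous(self, y: np.ndarray, keep_maps: bool = False):
        y = np.asarray(y, dtype=float).ravel()
        y_pred = np.empty(self.n)
        maps = []
        for f, st in enumerate(self.fold_state):
            y_tr = y[st["train"]]
            lam = st["selector"].select(y_tr, rule=self.config.rule)
            coef, _ = st["selector"].fit_at(y_tr, lam)
            beta_star = coef[:-1]  # confound truncation: drop the ICV slot
            # x . (V beta*) == z . beta* — score-space evaluation is cheaper
            y_pred[st["test"]] = st["Z_te"] @ beta_star
            if keep_maps:
                maps.append(build_phenotype_map(st["d"], beta_star, fold_id=str(f)))
        return y_pred, maps

    def run_binary(self, y: np.ndarray):
        y = np.asarray(y, dtype=float).ravel()
        pred_full = np.empty(self.n, dtype=int)
        pred_icv = np.empty(self.n, dtype=int)
        for st in self.fold_state:
            y_tr = y[st["train"]]
            lam = st["selector"].select(y_tr, rule=self.config.rule)
            m = fit_sparse_model(st["Z_tr"], st["icv_tr"], y_tr, "logistic", lam,
                                 selection_rule=self.config.rule)
            eta = m.intercept + st["Z_te"] @ m.beta + m.beta_icv * st["icv_te"]
            pred_full[st["test"]] = (eta >= 0).astype(int)
            lam_icv = st["icv_selector"].select(y_tr, rule=self.config.rule)
            m_icv = fit_sparse_model(None, st["icv_tr"], y_tr, "logistic", lam_icv,
                                     selection_rule=self.config.rule)
            eta_icv = m_icv.intercept + m_icv.beta_icv * st["icv_te"]
            pred_icv[st["test"]] = (eta_icv >= 0).astype(int)
        return pred_full, pred_icv


def run_cv_continuous(
    X, icv, y, config: CVConfig | None = None,
    response_name: str = "", keep_maps: bool = False,
    compute_training: bool = True,
) -> CVResult:
    """Cross-validated continuous prediction via the full LASSO-PCR pipeline.

    Per fold: economical SVD of the training fingerprints only, inner-CV
    penalty selection, sparse fit on component scores + ICV, ICV truncation,
    back-projection, and dot-product prediction of the held-out subjects.
    The metric is Pearson r between observed and held-out predicted values;
    if every prediction is constant (all folds intercept-only) the metric is
    flagged undefined rather than raising.
    """
    config = config or CVConfig()
    y = np.asarray(y, dtype=float).ravel()
    engine = _CVEngine(X, icv, "linear", config)
    y_pred, maps = engine.run_continuous(y, keep_maps=keep_maps)
    undefined = bool(np.std(y_pred) == 0)
    metric = float("nan") if undefined else _pearson(y, y_pred)
    train_metric = None
    if compute_training:
        model, d, _ = fit_full_sample(X, icv, y, "linear", config)
        beta_star = truncate_confound(model)
        fitted = d.scores @ beta_star
        train_metric = float("nan") if np.std(fitted) == 0 else _pearson(y, fitted)
    return CVResult(response_name, "linear", y, y_pred, engine.folds, metric,
                    metric_undefined=undefined, train_metric=train_metric,
                    fold_maps=maps)


def run_cv_binary(
    X, icv, y, config: CVConfig | None = None,
    response_name: str = "", compute_training: bool = True,
) -> CVResult:
    """Cross-validated binary prediction: ICV-only vs ICV + components.

    Folds are drawn with the near-even class-balance check. Each fold fits
    two logistic LASSO models on the training split — one with ICV as the
    sole predictor, one adding the fingerprint component scores — and
    classifies the held-out subjects with each. Reported metrics are the
    held-out accuracies of both models (the ICV-only accuracy is the
    benchmark that fingerprint information must beat) plus a full-sample
    training accuracy as a model-fit measure.
    """
    config = config or CVConfig()
    y = np.asarray(y, dtype=float).ravel().astype(int)
    engine = _CVEngine(X, icv, "logistic", config, labels=y)
    pred_full, pred_icv = engine.run_binary(y)
    acc_full = float(np.mean(pred_full == y))
    acc_icv = float(np.mean(pred_icv == y))
    train_metric = None
    if compute_training:
        model, d, _ = fit_full_sample(X, icv, y, "logistic", config)
        eta = model.intercept + d.scores @ model.beta + model.beta_icv * np.asarray(icv, float)
        train_metric = float(np.mean((eta >= 0).astype(int) == y))
    return CVResult(response_name, "logistic", y, pred_full, engine.folds, acc_full,
                    metric_icv_only=acc_icv, train_metric=train_metric,
                    y_pred_icv_only=pred_icv)


def fit_full_sample(
    X, icv, y, family: str = "linear", config: CVConfig | None = None,
    response_name: str = "",
) -> tuple[SparseModel, Decomposition, LCPMap | None]:
    """Fit the pipeline once on the full sample (training metrics and maps).

    Returns the sparse model, the decomposition, and — for linear models —
    the full-sample phenotype map ``V beta_star`` (None for logistic, where
    truncation is invalid).
    """
    config = config or CVConfig()
    X = np.asarray(X, dtype=float)
    icv = np.asarray(icv, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    d = economical_svd(X, center=config.center_columns)
    Z = d.scores
    sel = PenaltySelector(
        np.column_stack([Z, icv]), family,
        n_inner_folds=config.n_inner_folds,
        seed=derive_seed(config.seed, "full-sample"),
        n_lambda=config.n_lambda, lambda_min_ratio=config.lambda_min_ratio,
        stratify_labels=y.astype(int) if family == "logistic" else None,
    )
    lam = sel.select(y, rule=config.rule)
    model = fit_sparse_model(Z, icv, y, family, lam, selection_rule=config.rule)
    lcp = None
    if family == "linear":
        lcp = build_phenotype_map(d, truncate_confound(model),
                                  response_name=response_name)
    return model, d, lcp


_STATISTICS = {
    "accuracy": lambda obs, pred: float(np.mean(np.asarray(obs) == np.asarray(pred))),
    "pearson_r": _pearson,
}


def bootstrap_ci(
    pairs: tuple[np.ndarray, np.ndarray],
    statistic: str = "pearson_r",
    n_boot: int = 10000,
    seed: int = 0,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """95% percentile bootstrap CI over prediction-observation pairs.

    Pairs are resampled with replacement ``n_boot`` times and the 2.5th and
    97.5th percentiles of the recomputed statistic reported. Resamples on
    which the statistic is undefined (a constant vector for Pearson r) are
    redrawn and counted. With ``exhaustive=True`` all ``n^n`` equally likely
    resamples are enumerated instead (tiny n only).
    """
    obs, pred = (np.asarray(a).ravel() for a in pairs)
    if len(obs) != len(pred) or len(obs) < 2:
        raise ValueError("need >= 2 aligned prediction-observation pairs")
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    stat = _STATISTICS[statistic]

    def defined(idx) -> bool:
        if statistic != "pearson_r":
            return True
        return obs[idx].std() > 0 and pred[idx].std() > 0

    if exhaustive:
        n = len(obs)
        if n**n > 200_000:
            raise ValueError(f"exhaustive enumeration infeasible for n={n}")
        vals = [stat(obs[list(idx)], pred[list(idx)])
                for idx in itertools.product(range(n), repeat=n)
                if defined(list(idx))]
        vals = np.asarray(vals)
    else:
        rng = np.random.default_rng(seed)
        vals = np.empty(n_boot)
        n_redrawn = 0
        for b in range(n_boot):
            for _ in range(1000):
                idx = rng.integers(0, len(obs), size=len(obs))
                if defined(idx):
                    break
                n_redrawn += 1
            else:
                raise ValueError("statistic undefined on every bootstrap resample")
            vals[b] = stat(obs[idx], pred[idx])
    return float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))


def permutation_test(
    X, icv, y,
    config: CVConfig | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
    family: str = "linear",
    observed: float | None = None,
    conservative: bool = False,
) -> PermutationResult:
    """Nonparametric significance of a cross-validated prediction.

    Each trial permutes the response values (fingerprint/ICV rows stay
    paired with their subjects), reruns the entire CV pipeline on the
    permuted response, and records the null statistic — |Pearson r| for
    continuous responses, held-out accuracy for binary ones. Null trials in
    which every fitted model is intercept-only yield constant predictions
    with undefined correlation; these are excluded from the p denominator
    (``conservative=True`` instead counts them as non-exceedances).

    The observed statistic is recomputed from the unpermuted response unless
    supplied.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    config = config or CVConfig()
    if seed is None:
        seed = derive_seed(config.seed, "permutation")
    y = np.asarray(y, dtype=float).ravel()
    labels = y.astype(int) if family == "logistic" else None
    engine = _CVEngine(X, icv, family, config, labels=labels)
    binary = family == "logistic"

    def statistic(resp):
        if binary:
            pred_full, _ = engine.run_binary(resp)
            return float(np.mean(pred_full == resp)), False
        pred, _ = engine.run_continuous(resp)
        if np.std(pred) == 0:
            return float("nan"), True
        return abs(_pearson(resp, pred)), False

    if observed is None:
        observed, obs_undefined = statistic(y)
        if obs_undefined:
            # every fold intercept-only: constant predictions carry no
            # evidence, so no p-value can be attached
            return PermutationResult(n_perm, np.empty(0), 0, float("nan"),
                                     float("nan"))
    observed = abs(float(observed)) if not binary else float(observed)
    rng = np.random.default_rng(seed)
    null_stats = []
    n_undefined = 0
    for _ in range(n_perm):
        y_perm = y[rng.permutation(len(y))]
        val, undefined = statistic(y_perm)
        if undefined:
            n_undefined += 1
        else:
            null_stats.append(val)
    null_stats = np.asarray(null_stats)
    denom = n_perm if conservative else n_perm - n_undefined
    exceed = int(np.sum(null_stats >= observed))
    p = float(exceed / denom) if denom > 0 else float("nan")
    return PermutationResult(n_perm, null_stats, n_undefined, observed, p)


def fdr_adjust(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def pairwise_similarity(X) -> tuple[np.ndarray, dict]:
    """Pairwise inter-subject fingerprint correlations and their spread.

    Returns the ``n x n`` Pearson matrix and a summary over the strict upper
    triangle: mean correlation plus the middle-95% interval (2.5th/97.5th
    percentiles). For real cohorts this spread is tight, reflecting a shared
    low-rank structure on which individual variation rides.
    """
    values = getattr(X, "values", X)
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least two subjects")
    if np.any(values.std(axis=1) == 0):
        raise ValueError("constant fingerprint row has no defined correlation")
    C = np.corrcoef(values)
    np.fill_diagonal(C, 1.0)
    iu = np.triu_indices(values.shape[0], k=1)
    upper = C[iu]
    summary = {
        "mean": float(upper.mean()),
        "middle95": (float(np.percentile(upper, 2.5)),
                     float(np.percentile(upper, 97.5))),
        "n_pairs": int(len(upper)),
    }
    return C, summary


def icv_response_association(icv, y, family: str = "linear") -> tuple[bool, float, float]:
    """Does intracranial volume associate with the response?

    Continuous: Pearson correlation test. Binary: Welch two-sample t-test on
    ICV between classes. Returns ``(significant at 0.05, p, statistic)`` —
    the per-response "significant correlation with ICV" flag that motivates
    confound isolation.
    """
    icv = np.asarray(icv, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if np.std(icv) == 0:
        raise ValueError("constant ICV")
    if np.std(y) == 0:
        raise ValueError("constant response")
    if family == "linear":
        if len(icv) < 3:
            raise ValueError("need >= 3 subjects for a correlation test")
        r, p = stats.pearsonr(icv, y)
        return bool(p < 0.05), float(p), float(r)
    groups = [icv[y == c] for c in (0, 1)]
    if min(len(g) for g in groups) < 2:
        raise ValueError("each class needs >= 2 subjects")
    t, p = stats.ttest_ind(groups[0], groups[1], equal_var=False)
    return bool(p < 0.05), float(p), float(t)
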