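"""Candidate sets, AICc model averaging, and model evaluation.

Candidate models all carry a mandatory habitat backbone (distance to
roads, grassland, seasonal pans and permanent water); interaction terms
may involve only one territorial partner family per model — either the
residency family or the neighboring-territory family, never both — and no
model may co-include a collinearity-flagged pair.  Models within 2 AICc of
the minimum are averaged with Akaike weights, with absent coefficients
entering as zero (full averaging).

Evaluation utilities: relative selection strength (log-RSS) between two
covariate configurations, rank-based AUC, k-fold cross-validated RMSE with
a training-mean baseline, and the paired t-test comparing the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import chain, combinations

import numpy as np
import pandas as pd
from scipy import stats

from .inference import FitResult

__all__ = [
    "CandidateSet",
    "AveragedModel",
    "build_candidate_set",
    "aicc",
    "akaike_weights",
    "average_models",
    "log_rss",
    "auc",
    "kfold_cv_rmse",
    "paired_t_test",
    "DegenerateInputError",
]

MANDATORY_TERMS = ("dist_road", "dist_grassland", "dist_pan", "dist_water")

#: substrings identifying a territorial partner family in an interaction term
PARTNER_FAMILIES = {
    "residency": ("residency", "own_core_dist"),
    "neighbor": ("neighbor_boundary_dist", "n_neighbors", "neighbor_ud"),
}


class DegenerateInputError(ValueError):
    """Raised when a statistic is undefined on the given input."""


@dataclass
class CandidateSet:
    """Admissible models (term tuples) plus the null model marker."""

    models: list[tuple[str, ...]]
    constraints: dict = field(default_factory=dict)

    #: the intercept-only null model is represented by an empty tuple
    @property
    def null_model(self) -> tuple:
        return ()

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)


def term_family(term: str) -> str | None:
    """Territorial partner family of an interaction term, if any."""
    if ":" not in term:
        return None
    for fam, keys in PARTNER_FAMILIES.items():
        if any(k in term.split(":") for k in keys):
            return fam
    return None


def _powerset(items):
    items = list(items)
    return chain.from_iterable(
        combinations(items, r) for r in range(len(items) + 1)
    )


def _violates_screen(terms, flagged: set[frozenset]) -> bool:
    linear = {p for t in terms for p in t.split(":")}
    for pair in flagged:
        if pair <= linear:
            return True
    return False


def build_candidate_set(
    linear_terms,
    interaction_terms=(),
    mandatory=MANDATORY_TERMS,
    screen_report: pd.DataFrame | None = None,
    include_null: bool = True,
    require_main_effects: bool = True,
) -> CandidateSet:
    """Enumerate admissible models under the candidate-set rules.

    1. Every (non-null) model includes the mandatory linear terms.
    2. A model's interaction terms involve at most one territorial partner
       family (residency or neighbor terms, never both).
    3. No model co-includes a screen-flagged pair involving an optional
       term (flagged mandatory-mandatory pairs only warn, since mandatory
       terms enter every model).
    4. (Optional, default on) each interaction's components appear as main
       effects.

    The intercept-only null model is appended as the empty term tuple.
    """
    from .covariates import inadmissible_pairs

    linear_terms = list(linear_terms)
    missing = [t for t in mandatory if t not in linear_terms]
    if missing:
        raise ValueError(f"mandatory linear term(s) missing: {missing}")
    optional = [t for t in linear_terms if t not in mandatory]
    flagged = (
        inadmissible_pairs(screen_report) if screen_report is not None else set()
    )
    # Mandatory terms enter every model by design, so a flagged pair made
    # entirely of mandatory terms cannot be resolved by model exclusion;
    # warn and let the screen constrain only pairs touching optional terms.
    mandatory_only = {p for p in flagged if p <= set(mandatory)}
    if mandatory_only:
        warnings.warn(
            "collinearity flagged among mandatory terms (kept in all "
            f"models): {[sorted(p) for p in sorted(mandatory_only, key=sorted)]}",
            UserWarning,
        )
        flagged = flagged - mandatory_only

    models: list[tuple[str, ...]] = []
    seen = set()
    for lin_subset in _powerset(optional):
        lin = tuple(mandatory) + tuple(lin_subset)
        for int_subset in _powerset(interaction_terms):
            fams = {term_family(t) for t in int_subset} - {None}
            if len(fams) > 1:
                continue
            if require_main_effects:
                comps = {p for t in int_subset for p in t.split(":")}
                if not comps <= set(lin):
                    continue
            terms = lin + tuple(int_subset)
            if _violates_screen(terms, flagged):
                continue
            if terms not in seen:
                seen.add(terms)
                models.append(terms)
    if include_null:
        models.append(())
    return CandidateSet(
        models=models,
        constraints={
            "mandatory": list(mandatory),
            "flagged_pairs": [sorted(p) for p in flagged],
            "one_partner_family": True,
            "require_main_effects": require_main_effects,
        },
    )


def aicc(fit: FitResult) -> float:
    """Small-sample corrected AIC: -2 logLik + 2k + 2k(k+1)/(n-k-1)."""
    k, n = fit.k, fit.n
    if n <= k + 1:
        raise ValueError(
            f"AICc undefined: n={n} must exceed k+1={k + 1}"
        )
    return -2.0 * fit.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class AveragedModel:
    """AICc-weighted average of the models within 2 of the minimum."""

    members: list[FitResult]
    aicc_values: list[float]
    delta: list[float]
    weights: list[float]
    beta: dict[str, float]
    term_presence: dict[str, list[bool]]

    @property
    def terms(self) -> list[str]:
        return list(self.beta.keys())

    def coef(self, term: str) -> float:
        return self.beta.get(term, 0.0)

    def mean_intercept(self) -> float:
        """Weighted average of each member's mean intercept (prediction aid)."""
        out = 0.0
        for w, fit in zip(self.weights, self.members):
            vals = list(fit.intercepts.values())
            base = fit.beta.get("(intercept)", 0.0)
            out += w * (base + (float(np.mean(vals)) if vals else 0.0))
        return out


def average_models(
    fits: list[FitResult], delta_max: float = 2.0
) -> AveragedModel:
    """Full model averaging over the fits within ``delta_max`` AICc.

    Akaike weights are renormalized over the retained set; each averaged
    coefficient is the weight-sum of member coefficients with zero
    substituted where a term is absent from a member model.
    """
    if not fits:
        raise ValueError("no fitted models to average")
    a = np.array([aicc(f) for f in fits])
    delta_all = a - a.min()
    keep = delta_all <= delta_max
    members = [f for f, k in zip(fits, keep) if k]
    a_keep = a[keep]
    w = akaike_weights(a_keep)

    all_terms: list[str] = []
    for f in members:
        for t in f.terms:
            if t not in all_terms:
                all_terms.append(t)
    beta = {}
    presence = {}
    for t in all_terms:
        vals = np.array([f.beta.get(t, 0.0) for f in members])
        beta[t] = float((w * vals).sum())
        presence[t] = [t in f.terms for f in members]
    return AveragedModel(
        members=members,
        aicc_values=a_keep.tolist(),
        delta=(a_keep - a_keep.min()).tolist(),
        weights=w.tolist(),
        beta=beta,
        term_presence=presence,
    )


def _expand_vector(x: dict | pd.Series, terms) -> np.ndarray:
    x = dict(x)
    out = []
    for term in terms:
        v = 1.0
        for p in term.split(":"):
            if p not in x:
                raise KeyError(f"covariate {p!r} missing from configuration")
            v *= float(x[p])
        out.append(v)
    return np.asarray(out)


def log_rss(model: AveragedModel | FitResult, x1, x2) -> float:
    """Log relative selection strength between two covariate configurations.

    log-RSS(x1, x2) = beta . (f(x1) - f(x2)) where f expands main effects
    and interaction products.  Zero when x1 == x2; linear in the
    coefficient vector.
    """
    terms = model.terms
    beta = np.array([model.coef(t) if hasattr(model, "coef") else model.beta[t]
                     for t in terms])
    f1 = _expand_vector(x1, terms)
    f2 = _expand_vector(x2, terms)
    return float(beta @ (f1 - f2))


def log_rss_curve(model, sweep_term: str, values, reference: dict) -> pd.DataFrame:
    """log-RSS of varying one covariate against the reference configuration."""
    rows = []
    for v in np.asarray(values, dtype=float):
        x1 = dict(reference)
        x1[sweep_term] = v
        rows.append({sweep_term: v, "log_rss": log_rss(model, x1, reference)})
    return pd.DataFrame(rows)


def auc(predicted, observed) -> float:
    """Rank-based area under the ROC curve.

    The probability that a randomly chosen used point outranks a randomly
    chosen unused one, with ties counting one half (Mann-Whitney form).
    """
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(observed)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def make_folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random fold assignment with fold sizes differing by at most one."""
    if n < k:
        raise ValueError(f"need n >= k (got n={n}, k={k})")
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def kfold_cv_rmse(
    af: pd.DataFrame,
    candidate_terms,
    k: int = 10,
    seed: int | np.random.Generator = 0,
    response_col: str = "log_ratio",
    group_col: str = "pack_id",
) -> pd.DataFrame:
    """k-fold cross-validated RMSE of the averaged trade-off model.

    Per fold the candidate models are re-fitted and re-averaged on the
    training folds; held-out predictions use the averaged fixed effects
    plus the weighted pack intercept prediction (zero for unseen packs).
    The baseline predictor is the training-set mean of the response.
    Returns one row per fold with ``rmse_model`` and ``rmse_baseline``.
    """
    from .inference import expand_terms, fit_logratio

    if isinstance(candidate_terms, CandidateSet):
        model_list = list(candidate_terms.models)
    elif candidate_terms and isinstance(candidate_terms[0], (tuple, list)):
        model_list = [tuple(m) for m in candidate_terms]
    else:
        model_list = [tuple(candidate_terms)]

    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    af = af.reset_index(drop=True)
    folds = make_folds(len(af), k, rng)
    rows = []
    for fold_id, test_idx in enumerate(folds):
        test_mask = np.zeros(len(af), dtype=bool)
        test_mask[test_idx] = True
        train, test = af[~test_mask], af[test_mask]

        fits = []
        for m in model_list:
            try:
                fits.append(fit_logratio(train, m, response_col=response_col,
                                         group_col=group_col))
            except np.linalg.LinAlgError:
                # a model singular on this training fold drops out of the
                # fold's averaged predictor
                continue
        avg = average_models(fits)

        pred = np.zeros(len(test))
        for w, fit in zip(avg.weights, avg.members):
            Xt = expand_terms(test, fit.terms)
            eta = fit.beta["(intercept)"] + (
                Xt @ np.array([fit.beta[t] for t in fit.terms])
                if fit.terms else 0.0
            )
            ranef = test[group_col].map(fit.intercepts).fillna(0.0).to_numpy()
            pred += w * (np.asarray(eta, dtype=float).reshape(-1) + ranef)

        y_test = test[response_col].to_numpy(dtype=float)
        rmse_model = float(np.sqrt(np.mean((y_test - pred) ** 2)))
        base = float(train[response_col].mean())
        rmse_base = float(np.sqrt(np.mean((y_test - base) ** 2)))
        rows.append(
            {"fold": fold_id, "n_test": len(test),
             "rmse_model": rmse_model, "rmse_baseline": rmse_base}
        )
    return pd.DataFrame(rows)


def paired_t_test(a, b) -> tuple[float, float]:
    """Classical paired t-test; returns (t, two-sided p) on n-1 df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D samples with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError(
            "paired differences have zero variance; t is undefined"
        )
    t = d.mean() / (sd / np.sqrt(len(d)))
    p = 2.0 * stats.t.sf(abs(t), df=len(d) - 1)
    return float(t), float(p)
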