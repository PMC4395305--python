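"""OLS with bidirectional stepwise AIC selection and cohort deconstruction.

The candidate set for predicting working-memory d' is every main effect
(task local efficiency, task global efficiency, mean correct RT, volumes
removed, binary age group), every pairwise product, and every squared
continuous covariate, all in raw (uncentered) units.  Search starts from
the full candidate model and repeatedly applies the single add-or-drop
move that most reduces AIC (Gaussian likelihood form,
``AIC = n*ln(RSS/n) + 2*(p+2)`` with p the number of slope terms), with
adjusted R-squared breaking exact AIC ties, then model size, then term
name — making the search deterministic.

A fitted model with the binary group term can be deconstructed into
per-group prediction equations: the group-1 equation adds the group
coefficient to the intercept and each group-interaction coefficient to
its partner's slope.

Numerical note: a fit that reproduces the outcome to ~machine precision
has an unbounded (and numerically noisy) log-likelihood; RSS is therefore
floored at 1e-12 of the outcome's total sum of squares, so all perfect
fits tie on likelihood and compete on the parameter-count penalty alone.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg

__all__ = [
    "ModelFit",
    "DEFAULT_CANDIDATE_COVARIATES",
    "FINAL_MODEL_TERMS",
    "build_design",
    "design_columns",
    "ols_fit",
    "fit_model",
    "stepwise_select",
    "cohort_equations",
]

#: Covariates assessed in the task-efficiency model (age group last so
#: interaction terms read "x:age_group").
DEFAULT_CANDIDATE_COVARIATES = (
    "e_local_task",
    "e_global_task",
    "mean_rt",
    "n_volumes_removed",
    "age_group",
)

#: Terms of the published final model for working-memory d'.
FINAL_MODEL_TERMS = (
    "e_local_task",
    "e_global_task",
    "mean_rt",
    "age_group",
    "e_global_task:age_group",
)

#: Fits with RSS below this fraction of TSS are treated as perfect.
PERFECT_FIT_RSS_FRACTION = 1e-12

INTERCEPT = "intercept"


@dataclass
class ModelFit:
    """One OLS fit: terms, inference, and fit statistics."""

    terms: list[str]
    coefficients: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    aic: float
    r2: float
    adj_r2: float
    f_stat: float
    cohens_f2: float
    n: int
    rss: float
    candidate_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.adj_r2 > self.r2 + 1e-12:
            raise ValueError("adjusted R^2 cannot exceed R^2")
        if len(self.coefficients) != len(self.terms) + 1:
            raise ValueError("coefficient count must be number of terms + 1")

    def summary_table(self) -> pd.DataFrame:
        """Human-readable table: b, SE, t, p, 95% CI per term."""
        return pd.DataFrame(
            {
                "b": self.coefficients,
                "SE": self.se,
                "t": self.tvalues,
                "p": self.pvalues,
                "ci_low": self.conf_int["low"],
                "ci_high": self.conf_int["high"],
            }
        )

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "tvalues": {k: float(v) for k, v in self.tvalues.items()},
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
            "conf_int": {
                k: [float(self.conf_int.loc[k, "low"]), float(self.conf_int.loc[k, "high"])]
                for k in self.conf_int.index
            },
            "aic": float(self.aic),
            "r2": float(self.r2),
            "adj_r2": float(self.adj_r2),
            "f_stat": float(self.f_stat),
            "cohens_f2": float(self.cohens_f2),
            "n": int(self.n),
            "rss": float(self.rss),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _is_binary(col: pd.Series) -> bool:
    return set(np.unique(col.to_numpy())) <= {0, 1}


def build_design(
    records: pd.DataFrame,
    candidates=DEFAULT_CANDIDATE_COVARIATES,
    group_col: str = "age_group",
    interactions: bool = True,
    quadratics: bool = True,
    drop_constant_derived: bool = False,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Candidate design: mains, pairwise products, squared continuous terms.

    Squares of binary columns are skipped (idempotent under 0/1 coding).
    Raises on a missing or constant candidate column, and on fewer than
    two subjects in either age group when ``group_col`` is present.  A
    *derived* column (product/square) that happens to be constant is an
    error by default; with ``drop_constant_derived=True`` it is removed
    with a warning instead (useful for small simulated cohorts).
    """
    candidates = list(candidates)
    missing = [c for c in candidates if c not in records.columns]
    if missing:
        raise ValueError(f"candidate covariates not in records: {missing}")
    if group_col in records.columns:
        counts = records[group_col].value_counts()
        if (counts < 2).any() or len(counts) < 2:
            raise ValueError("need at least 2 subjects in each age group")

    cols: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    for name in candidates:
        cols[name] = records[name].to_numpy(dtype=float)
        kinds[name] = "main"
    if interactions:
        for a, b in itertools.combinations(candidates, 2):
            cols[f"{a}:{b}"] = cols[a] * cols[b]
            kinds[f"{a}:{b}"] = "interaction"
    if quadratics:
        for name in candidates:
            if _is_binary(records[name]):
                continue  # binary^2 == binary
            cols[f"{name}^2"] = cols[name] ** 2
            kinds[f"{name}^2"] = "quadratic"
    X = pd.DataFrame(cols, index=records.index)
    constant = [c for c in X.columns if X[c].std() == 0]
    constant_mains = [c for c in constant if kinds[c] == "main"]
    if constant_mains or (constant and not drop_constant_derived):
        raise ValueError(f"constant design column(s): {constant}")
    if constant:
        warnings.warn(
            f"dropping constant derived design column(s): {constant}",
            RuntimeWarning,
            stacklevel=2,
        )
        X = X.drop(columns=constant)
        for c in constant:
            kinds.pop(c)
    return X, kinds


def design_columns(records: pd.DataFrame, terms) -> pd.DataFrame:
    """Build the design columns for explicit term names.

    Term grammar: ``"x"`` (main effect), ``"a:b"`` (product),
    ``"x^2"`` (square).
    """
    cols: dict[str, np.ndarray] = {}
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            cols[term] = records[a].to_numpy(dtype=float) * records[b].to_numpy(dtype=float)
        elif term.endswith("^2"):
            base = term[:-2]
            cols[term] = records[base].to_numpy(dtype=float) ** 2
        else:
            cols[term] = records[term].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=records.index)


def _gaussian_aic(rss: float, n: int, n_terms: int, floor: float, aicc: bool) -> float:
    """AIC = n ln(RSS/n) + 2k with k = n_terms + 2 (intercept and sigma)."""
    rss = max(rss, floor, 1e-300)
    k = n_terms + 2
    a = n * math.log(rss / n) + 2 * k
    if aicc:
        if n - k - 1 <= 0:
            return math.inf
        a += 2 * k * (k + 1) / (n - k - 1)
    return a


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < tol]
        bad += [names[p] for p in piv[len(diag):]]
        raise ValueError(f"design matrix is singular; collinear term(s): {bad}")


def ols_fit(y, X: pd.DataFrame, aicc: bool = False) -> ModelFit:
    """Ordinary least squares of ``y`` on ``X`` plus an intercept.

    Inference (SEs, t, p, 95% CI) comes from the standard normal-theory
    formulas; AIC uses the Gaussian form stated above; Cohen's
    f^2 = R^2/(1-R^2).
    """
    y = np.asarray(y, dtype=float)
    n, p = len(y), X.shape[1]
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    names = [INTERCEPT] + list(X.columns)
    Xc = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    _check_full_rank(Xc, names)

    res = sm.OLS(y, Xc).fit()
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(res.ssr)
    floor = PERFECT_FIT_RSS_FRACTION * tss
    r2 = float(res.rsquared)
    ci = res.conf_int(alpha=0.05)
    conf = pd.DataFrame(ci, index=names, columns=["low", "high"])
    return ModelFit(
        terms=list(X.columns),
        coefficients=pd.Series(res.params, index=names),
        se=pd.Series(res.bse, index=names),
        tvalues=pd.Series(res.tvalues, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        conf_int=conf,
        aic=_gaussian_aic(rss, n, p, floor, aicc),
        r2=r2,
        adj_r2=float(res.rsquared_adj),
        f_stat=float(res.fvalue) if p > 0 else float("nan"),
        cohens_f2=r2 / (1.0 - r2) if r2 < 1.0 else float("inf"),
        n=n,
        rss=rss,
    )


def fit_model(
    records: pd.DataFrame, terms, outcome: str = "dprime", aicc: bool = False
) -> ModelFit:
    """Least-squares fit of an explicit term list (see ``design_columns``)."""
    X = design_columns(records, terms)
    return ols_fit(records[outcome], X, aicc=aicc)


def _hierarchy_parents(term: str) -> set[str]:
    if ":" in term:
        return set(term.split(":"))
    if term.endswith("^2"):
        return {term[:-2]}
    return set()


def stepwise_select(
    records: pd.DataFrame,
    candidates=DEFAULT_CANDIDATE_COVARIATES,
    outcome: str = "dprime",
    group_col: str = "age_group",
    interactions: bool = True,
    quadratics: bool = True,
    aicc: bool = False,
    hierarchy: bool = False,
    start: str = "full",
    drop_constant_derived: bool = False,
) -> ModelFit:
    """Bidirectional stepwise OLS minimizing AIC, starting from the full model.

    At each iteration every single-term drop and every single-term add is
    scored; the move with the lowest AIC is applied if it strictly
    improves on the current model.  Ties between competing moves are
    broken by higher adjusted R-squared, then fewer terms, then term name.
    With ``hierarchy=True`` an interaction/quadratic may only enter when
    its parent mains are present, and a main may not leave while a child
    term remains.
    """
    X_all, kinds = build_design(
        records, candidates, group_col=group_col,
        interactions=interactions, quadratics=quadratics,
        drop_constant_derived=drop_constant_derived,
    )
    y = records[outcome].to_numpy(dtype=float)
    n = len(y)
    tss = float(np.sum((y - y.mean()) ** 2))
    floor = PERFECT_FIT_RSS_FRACTION * tss
    all_terms = list(X_all.columns)
    col_index = {t: i for i, t in enumerate(all_terms)}
    M = X_all.to_numpy(dtype=float)
    ones = np.ones((n, 1))

    rss_cache: dict[frozenset, float] = {}

    def rss_of(terms: frozenset) -> float:
        if terms in rss_cache:
            return rss_cache[terms]
        if terms:
            cols = sorted(terms, key=col_index.__getitem__)
            Xm = np.hstack([ones, M[:, [col_index[t] for t in cols]]])
        else:
            Xm = ones
        resid = y - Xm @ np.linalg.lstsq(Xm, y, rcond=None)[0]
        rss = float(resid @ resid)
        rss_cache[terms] = rss
        return rss

    def score(terms: frozenset) -> tuple[float, float]:
        rss = rss_of(terms)
        p = len(terms)
        aic = _gaussian_aic(rss, n, p, floor, aicc)
        denom = tss / (n - 1) if tss > 0 else 1.0
        adj_r2 = 1.0 - (rss / max(n - p - 1, 1)) / denom
        return aic, adj_r2

    def allowed_drop(term: str, current: frozenset) -> bool:
        if not hierarchy:
            return True
        return not any(term in _hierarchy_parents(t) for t in current if t != term)

    def allowed_add(term: str, current: frozenset) -> bool:
        if not hierarchy:
            return True
        return _hierarchy_parents(term) <= current

    current = frozenset(all_terms) if start == "full" else frozenset()
    cur_aic, _ = score(current)
    while True:
        moves: list[tuple[float, float, int, str, frozenset]] = []
        for t in sorted(current):
            if allowed_drop(t, current):
                cand = current - {t}
                aic, adj = score(cand)
                moves.append((aic, -adj, len(cand), t, cand))
        for t in sorted(set(all_terms) - current):
            if allowed_add(t, current):
                cand = current | {t}
                aic, adj = score(cand)
                moves.append((aic, -adj, len(cand), t, cand))
        if not moves:
            break
        moves.sort()
        best_aic = moves[0][0]
        tied = [m for m in moves if m[0] <= best_aic + 1e-10]
        tied.sort(key=lambda m: (m[1], m[2], m[3]))
        aic, _, _, _, cand = tied[0]
        if aic < cur_aic - 1e-10:
            current, cur_aic = cand, aic
        else:
            break

    selected = [t for t in all_terms if t in current]
    fit = ols_fit(records[outcome], X_all[selected], aicc=aicc)
    fit.candidate_terms = all_terms
    return fit


def cohort_equations(fit: ModelFit, group_term: str = "age_group") -> dict[int, dict[str, float]]:
    """Deconstruct a fit with a binary group term into per-group equations.

    Group 0 keeps the fitted intercept and main-effect slopes; group 1
    adds the group coefficient to the intercept and each
    group-interaction coefficient to its partner's slope.  Terms not
    involving the group are shared.  Returns
    ``{0: {"intercept": ..., <term>: slope, ...}, 1: {...}}``.
    """
    if group_term not in fit.terms:
        raise ValueError(f"fit does not contain the group term {group_term!r}")
    coefs = fit.coefficients
    young: dict[str, float] = {INTERCEPT: float(coefs[INTERCEPT])}
    older: dict[str, float] = {INTERCEPT: float(coefs[INTERCEPT]) + float(coefs[group_term])}
    for term in fit.terms:
        if term == group_term:
            continue
        c = float(coefs[term])
        if ":" in term:
            parts = term.split(":")
            if group_term in parts:
                if len(parts) != 2:
                    raise ValueError(
                        f"cannot deconstruct higher-order group term {term!r}"
                    )
                partner = parts[0] if parts[1] == group_term else parts[1]
                young.setdefault(partner, 0.0)
                older[partner] = older.get(partner, 0.0) + c
                continue
        young[term] = young.get(term, 0.0) + c
        older[term] = older.get(term, 0.0) + c
    # interaction partners without a main effect: group-0 slope is 0
    for key, val in young.items():
        older.setdefault(key, val)
    return {0: young, 1: older}
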