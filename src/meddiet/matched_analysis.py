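"""Matched-pair inference: McNemar comparisons and conditional logistic regression.

In an individually matched case-control design the matching factors (age
band, sex, centre) are conditioned out rather than estimated: within each
matched set the conditional likelihood of the observed case being the case
given the set's covariates is

    l(beta) = sum_sets [ x_case . beta - log sum_members exp(x_m . beta) ]

which for 1:1 pairs reduces to -sum_i log(1 + exp(-beta . d_i)) with
d_i = x_case - x_control. The fitter maximizes this by Newton-Raphson with
analytic gradient and Hessian and step-halving; the covariance is the
inverse observed information, and odds ratios carry 95 % Wald intervals
(exp(beta +/- 1.96 SE)).

A deliberately independent oracle (`pair_difference_oracle`) refits the
1:1 model as intercept-free binary regression on within-pair differences
by derivative-free maximization; it exists for testing only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

Z95 = 1.96  # Wald multiplier for a 95 % CI

#: Reference level first, then the indicator levels in design order.
CATEGORICAL_LEVELS = {
    "residence": ("urban", "rural"),
    "education": ("illiterate", "primary", "secondary", "higher"),
    "income": ("low", "medium", "high"),
    "smoking": ("never", "ex", "current"),
    "bmi_category": ("normal", "underweight", "overweight", "obese"),
    "activity": ("low", "moderate", "high"),
}

CONTINUOUS_TERMS = {"age": "age", "energy": "energy_kcal_per_day"}
BINARY_TERMS = {"family_history": "family_history", "nsaid": "nsaid"}

#: Full adjustment set used for the adjusted odds ratios.
ADJUSTED_COVARIATES = (
    "age",
    "residence",
    "education",
    "income",
    "family_history",
    "smoking",
    "bmi_category",
    "activity",
    "energy",
)
#: "Crude" model: adjusted for age and total energy intake only.
CRUDE_COVARIATES = ("age", "energy")

EXPOSURE_LEVELS = ("low", "medium", "high")  # reference: low


class AnalysisError(ValueError):
    """Raised for structurally invalid matched data or designs."""


@dataclass(frozen=True)
class ModelSpec:
    """Design specification: exposure categories plus adjustment terms."""

    covariates: tuple[str, ...] = ADJUSTED_COVARIATES
    subsite: str = "all"  # all | colon | rectum
    sex: str = "all"  # all | M | F
    include_exposure: bool = True


@dataclass(frozen=True)
class MatchedSet:
    """One matched set; the case's design row is first."""

    set_id: str
    X: np.ndarray  # (n_members, p); row 0 is the case
    subject_ids: tuple[str, ...]


@dataclass
class FitResult:
    """Conditional-logistic estimates with Wald inference."""

    names: tuple[str, ...]
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    n_sets: int
    converged: bool
    n_iter: int
    flags: tuple[str, ...] = ()

    @property
    def se(self) -> np.ndarray:
        # tiny negative diagonals can occur in near-singular information
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    @property
    def or_(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        half = Z95 * self.se
        with np.errstate(over="ignore"):
            return np.exp(np.column_stack([self.beta - half, self.beta + half]))

    @property
    def wald_p(self) -> np.ndarray:
        z = np.divide(self.beta, self.se, out=np.zeros_like(self.beta),
                      where=self.se > 0)
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "or": self.or_,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.wald_p,
            },
            index=list(self.names),
        )


@dataclass
class McNemarResult:
    """Discordant-pair test for one dichotomy; ``defined`` is False when b + c = 0."""

    b: int
    c: int
    chi2: float
    p: float
    defined: bool


def mcnemar(case_exposed: Sequence[bool], control_exposed: Sequence[bool]) -> McNemarResult:
    """McNemar chi-square from pair-aligned exposure indicators.

    ``case_exposed[i]`` and ``control_exposed[i]`` refer to the same
    matched pair. The statistic is (b - c)^2 / (b + c) on the discordant
    counts, referred to chi-square with 1 df; with no discordant pairs the
    statistic is undefined and flagged rather than NaN-propagated.
    """
    case_exposed = np.asarray(case_exposed, dtype=bool)
    control_exposed = np.asarray(control_exposed, dtype=bool)
    if case_exposed.shape != control_exposed.shape:
        raise AnalysisError("pair-aligned exposure vectors differ in length")
    b = int(np.sum(case_exposed & ~control_exposed))
    c = int(np.sum(~case_exposed & control_exposed))
    if b + c == 0:
        return McNemarResult(b=b, c=c, chi2=float("nan"), p=float("nan"), defined=False)
    chi2 = (b - c) ** 2 / (b + c)
    return McNemarResult(b=b, c=c, chi2=chi2, p=float(stats.chi2.sf(chi2, df=1)), defined=True)


def design_columns(spec: ModelSpec) -> tuple[str, ...]:
    """Deterministic design-column order for a model specification."""
    names: list[str] = []
    if spec.include_exposure:
        names += [f"md_{lvl}" for lvl in EXPOSURE_LEVELS[1:]]
    for term in spec.covariates:
        if term in CONTINUOUS_TERMS or term in BINARY_TERMS:
            names.append(term)
        elif term in CATEGORICAL_LEVELS:
            names += [f"{term}_{lvl}" for lvl in CATEGORICAL_LEVELS[term][1:]]
        else:
            raise AnalysisError(f"unknown covariate term {term!r}")
    return tuple(names)


def _design_row(rec: pd.Series, spec: ModelSpec) -> list[float]:
    row: list[float] = []
    if spec.include_exposure:
        row += [float(rec["category"] == lvl) for lvl in EXPOSURE_LEVELS[1:]]
    for term in spec.covariates:
        if term in CONTINUOUS_TERMS:
            row.append(float(rec[CONTINUOUS_TERMS[term]]))
        elif term in BINARY_TERMS:
            row.append(float(rec[BINARY_TERMS[term]]))
        else:
            levels = CATEGORICAL_LEVELS[term]
            value = rec[term]
            if value not in levels:
                raise AnalysisError(f"{term}={value!r} not in levels {levels}")
            row += [float(value == lvl) for lvl in levels[1:]]
    return row


def build_sets(
    subjects: pd.DataFrame, scores: pd.DataFrame, spec: ModelSpec
) -> tuple[list[MatchedSet], tuple[str, ...], int]:
    """Assemble matched sets for one analysis.

    ``subjects`` (indexed by subject id) carries pair_id, status, sex,
    subsite and the covariate columns; ``scores`` carries the score
    ``category``. Pairs are kept only if both members are scoreable and
    the one-case-one-control structure holds; the subsite filter keeps a
    pair iff its *case's* subsite matches, the sex filter iff both members
    match. Returns (sets, design column names, dropped-pair count).
    """
    frame = subjects.join(scores[["category"]], how="inner")
    names = design_columns(spec)
    sets: list[MatchedSet] = []
    n_dropped = 0
    for pair_id, group in frame.groupby("pair_id", sort=True):
        statuses = group["status"].tolist()
        if len(group) != 2 or sorted(statuses) != ["case", "control"]:
            n_dropped += 1
            continue
        case = group[group["status"] == "case"].iloc[0]
        control = group[group["status"] == "control"].iloc[0]
        if spec.sex != "all" and not (case["sex"] == spec.sex == control["sex"]):
            continue
        if spec.subsite != "all" and case.get("subsite") != spec.subsite:
            continue
        X = np.array([_design_row(case, spec), _design_row(control, spec)])
        sets.append(MatchedSet(set_id=str(pair_id), X=X,
                               subject_ids=(str(case.name), str(control.name))))
    if n_dropped:
        logger.warning("dropped %d pair(s) violating 1 case + 1 control", n_dropped)
    if not sets:
        raise AnalysisError(
            f"no matched sets survive filters (subsite={spec.subsite}, sex={spec.sex})"
        )
    return sets, names, n_dropped


def clogit_loglik(beta: np.ndarray, sets: Sequence[MatchedSet]) -> float:
    """Conditional log-likelihood at ``beta`` (case row first in each set)."""
    beta = np.asarray(beta, dtype=float)
    total = 0.0
    for s in sets:
        if not np.isfinite(s.X).all():
            raise AnalysisError(f"set {s.set_id}: non-finite covariates")
        eta = s.X @ beta
        total += eta[0] - special.logsumexp(eta)
    return float(total)


def _stack(sets: Sequence[MatchedSet]) -> np.ndarray | None:
    """Stack sets into an (n_sets, m, p) array when all have m members."""
    sizes = {s.X.shape[0] for s in sets}
    if len(sizes) != 1:
        return None
    return np.stack([s.X for s in sets])


def _loglik_stacked(beta: np.ndarray, X: np.ndarray) -> float:
    eta = X @ beta
    return float(np.sum(eta[:, 0] - special.logsumexp(eta, axis=1)))


def _score_and_info(beta: np.ndarray, sets: Sequence[MatchedSet],
                    stacked: np.ndarray | None = None):
    p = len(beta)
    if stacked is not None:
        eta = stacked @ beta  # (n, m)
        loglik = float(np.sum(eta[:, 0] - special.logsumexp(eta, axis=1)))
        w = special.softmax(eta, axis=1)
        xbar = np.einsum("nm,nmp->np", w, stacked)
        grad = stacked[:, 0, :].sum(axis=0) - xbar.sum(axis=0)
        info = np.einsum("nm,nmp,nmq->pq", w, stacked, stacked) - xbar.T @ xbar
        return loglik, grad, info
    grad = np.zeros(p)
    info = np.zeros((p, p))
    loglik = 0.0
    for s in sets:
        eta = s.X @ beta
        loglik += eta[0] - special.logsumexp(eta)
        w = special.softmax(eta)
        xbar = w @ s.X
        grad += s.X[0] - xbar
        info += (s.X * w[:, None]).T @ s.X - np.outer(xbar, xbar)
    return loglik, grad, info


def _monotone_columns(sets: Sequence[MatchedSet], names: Sequence[str]) -> list[str]:
    """Columns along which the likelihood increases without bound.

    If in every set the case attains the maximum of a column (strictly in
    at least one set), the likelihood is strictly increasing in that
    coefficient, so no finite MLE exists; symmetrically for minima.
    """
    flagged = []
    for j, name in enumerate(names):
        case_ge = all(s.X[0, j] >= s.X[1:, j].max() for s in sets)
        case_le = all(s.X[0, j] <= s.X[1:, j].min() for s in sets)
        strict_up = any(s.X[0, j] > s.X[1:, j].max() for s in sets)
        strict_dn = any(s.X[0, j] < s.X[1:, j].min() for s in sets)
        if (case_ge and strict_up) or (case_le and strict_dn):
            flagged.append(name)
    return flagged


def _collinear_columns(sets: Sequence[MatchedSet], names: Sequence[str]) -> list[str]:
    from scipy.linalg import qr

    rows = np.vstack([s.X - s.X.mean(axis=0) for s in sets])
    _, rmat, piv = qr(rows, mode="economic", pivoting=True)
    diag = np.abs(np.diag(rmat))
    tol = diag.max() * 1e-10 * max(rows.shape) if diag.size and diag.max() > 0 else 0.0
    rank = int(np.sum(diag > tol))
    return sorted(names[j] for j in piv[rank:])


def fit_clogit(
    sets: Sequence[MatchedSet],
    names: Sequence[str] | None = None,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    loglik_tol: float = 1e-10,
) -> FitResult:
    """Maximize the conditional likelihood by Newton-Raphson with step-halving.

    Convergence when the largest score component falls below ``score_tol``
    or the relative log-likelihood change below ``loglik_tol``. The
    covariance is the inverse observed information at the optimum. A
    column along which the likelihood is monotone (separation) yields
    ``converged = False`` with a ``monotone-likelihood`` flag and no
    finite estimates; a singular information matrix raises, naming the
    collinear columns.
    """
    if not sets:
        raise AnalysisError("no matched sets to fit")
    # canonical set order makes the fit invariant to input permutation
    sets = sorted(sets, key=lambda s: s.set_id)
    p = sets[0].X.shape[1]
    names = tuple(names) if names is not None else tuple(f"x{j}" for j in range(p))
    for s in sets:
        if not np.isfinite(s.X).all():
            raise AnalysisError(f"set {s.set_id}: non-finite covariates")

    mono = _monotone_columns(sets, names)
    if mono:
        nan = np.full(p, np.nan)
        return FitResult(
            names=names, beta=nan, cov=np.full((p, p), np.nan),
            loglik=float("nan"), n_sets=len(sets), converged=False, n_iter=0,
            flags=tuple(f"monotone-likelihood:{c}" for c in mono),
        )

    stacked = _stack(sets)
    beta = np.zeros(p)
    loglik, grad, info = _score_and_info(beta, sets, stacked)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            bad = _collinear_columns(sets, names)
            raise AnalysisError(
                f"singular information matrix; collinear columns: {bad or names}"
            ) from None
        # step-halving keeps the likelihood non-decreasing
        factor = 1.0
        for _ in range(30):
            candidate = beta + factor * step
            new_loglik = (_loglik_stacked(candidate, stacked) if stacked is not None
                          else clogit_loglik(candidate, sets))
            if new_loglik >= loglik - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        prev_loglik = loglik
        loglik, grad, info = _score_and_info(beta, sets, stacked)
        if np.max(np.abs(grad)) < score_tol:
            break
        if abs(loglik - prev_loglik) < loglik_tol * (abs(prev_loglik) + 1e-12):
            break
    converged = np.max(np.abs(grad)) < score_tol or n_iter < max_iter
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        bad = _collinear_columns(sets, names)
        raise AnalysisError(
            f"singular information matrix; collinear columns: {bad or names}"
        ) from None
    return FitResult(
        names=names, beta=beta, cov=cov, loglik=loglik,
        n_sets=len(sets), converged=bool(converged), n_iter=n_iter,
    )


def pair_difference_oracle(sets: Sequence[MatchedSet],
                           names: Sequence[str] | None = None) -> FitResult:
    """Testing oracle: the 1:1 conditional model as a difference regression.

    For strictly 1:1 sets the conditional likelihood equals an
    intercept-free binary regression on within-pair covariate differences,
    l(beta) = sum_i log sigmoid(d_i . beta). Maximized directly — coarse
    grid plus bounded scalar search in one dimension, Nelder-Mead
    otherwise — with no shared code with the Newton fitter. Not for
    production use.
    """
    for s in sets:
        if s.X.shape[0] != 2:
            raise AnalysisError(f"set {s.set_id} is not 1:1; the oracle requires pairs")
    D = np.vstack([(s.X[0] - s.X[1]) for s in sets])
    p = D.shape[1]
    names = tuple(names) if names is not None else tuple(f"x{j}" for j in range(p))

    def negll(beta):
        return -float(np.sum(special.log_expit(D @ np.atleast_1d(beta))))

    if p == 1:
        grid = np.linspace(-10.0, 10.0, 2001)
        best = grid[np.argmin([negll(np.array([g])) for g in grid])]
        res = optimize.minimize_scalar(
            lambda b: negll(np.array([b])),
            bracket=(best - 0.05, best, best + 0.05) if -10 < best < 10 else None,
            bounds=(best - 0.5, best + 0.5), method="bounded",
            options={"xatol": 1e-12},
        )
        beta = np.array([res.x])
    else:
        res = optimize.minimize(negll, np.zeros(p), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000, "maxfev": 20000})
        beta = np.asarray(res.x, dtype=float)
    # numeric observed information for the covariance
    h = 1e-5
    info = np.zeros((p, p))
    for j in range(p):
        for k in range(p):
            ej, ek = np.eye(p)[j] * h, np.eye(p)[k] * h
            info[j, k] = (
                negll(beta + ej + ek) - negll(beta + ej - ek)
                - negll(beta - ej + ek) + negll(beta - ej - ek)
            ) / (4 * h * h)
    cov = np.linalg.pinv(info)
    return FitResult(names=names, beta=beta, cov=cov, loglik=-negll(beta),
                     n_sets=len(sets), converged=True, n_iter=0, flags=("oracle",))


def or_table(
    rows: Sequence[dict],
) -> pd.DataFrame:
    """Assemble a tidy odds-ratio table from per-analysis fit results.

    Each input row is a dict with keys ``subsite``, ``stratum``,
    ``counts`` ({category: (n_cases, n_controls)}), ``crude`` and
    ``adjusted`` (FitResult or None). The reference (low) category is
    emitted with OR exactly 1 and no interval; the medium and high rows
    carry crude and adjusted OR with 95 % CI.
    """
    records = []
    for row in rows:
        counts = row["counts"]
        for category in EXPOSURE_LEVELS:
            n_cases, n_controls = counts.get(category, (0, 0))
            rec = {
                "subsite": row["subsite"], "stratum": row["stratum"],
                "category": category, "n_cases": n_cases, "n_controls": n_controls,
                "or_crude": 1.0 if category == "low" else np.nan,
                "ci_crude_low": np.nan, "ci_crude_high": np.nan,
                "or_adjusted": 1.0 if category == "low" else np.nan,
                "ci_adjusted_low": np.nan, "ci_adjusted_high": np.nan,
            }
            if category != "low":
                term = f"md_{category}"
                for kind in ("crude", "adjusted"):
                    fit = row.get(kind)
                    if fit is None or not fit.converged:
                        continue
                    j = fit.names.index(term)
                    rec[f"or_{kind}"] = fit.or_[j]
                    rec[f"ci_{kind}_low"] = fit.ci95[j, 0]
                    rec[f"ci_{kind}_high"] = fit.ci95[j, 1]
            records.append(rec)
    return pd.DataFrame.from_records(records)
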