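"""Binomial survival estimation and testing for exposure trials.

Each replicate contributes a binomial count (alive out of exposed) at two
assessment times (immediate and 24 h).  Group survival probabilities are
least-squares means from a logistic fit with the experimental group as the
sole factor; groups are compared with a likelihood-ratio (LLR) test against
the intercept-only model, and all pairwise contrasts are screened with a
Scheffé-style simultaneous procedure rendered as compact letter displays.

When a group is invariant (all alive or all dead across its replicates) the
ordinary maximum-likelihood estimate diverges, so a Firth (Jeffreys-prior)
penalty is applied: the penalized log-likelihood ℓ*(β) = ℓ(β) + ½log|I(β)|
keeps every estimate finite.  For an intercept-only binomial fit the Firth
estimate has the closed form (y + ½)/(n + 1), which the implementation is
tested against.  Invariant groups are removed from post hoc comparisons
(they carry no within-group information about contrasts on the logit scale).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from string import ascii_lowercase
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, gammaln

TRIAL_COLUMNS = [
    "life_stage",
    "experiment",
    "group",
    "replicate",
    "n_exposed",
    "n_alive_immediate",
    "n_alive_24h",
]

Endpoint = Literal["immediate", "24h"]
PenalizedMode = Literal["auto", "on", "off"]

_ENDPOINT_COL = {"immediate": "n_alive_immediate", "24h": "n_alive_24h"}


class DataError(ValueError):
    """Malformed or empty trial table."""


def validate_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Check a trial table's schema and count-ordering invariants.

    Requires 0 <= n_alive_24h <= n_alive_immediate <= n_exposed per row and
    rejects rows with no exposed fish.  Returns the table unchanged.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"trial table missing columns: {missing}")
    if len(table) == 0:
        raise DataError("trial table is empty")
    if (table["n_exposed"] <= 0).any():
        raise DataError("rows with n_exposed <= 0 are not allowed")
    bad = ~(
        (0 <= table["n_alive_24h"])
        & (table["n_alive_24h"] <= table["n_alive_immediate"])
        & (table["n_alive_immediate"] <= table["n_exposed"])
    )
    if bad.any():
        raise DataError(
            f"count ordering violated (need 0 <= 24h <= immediate <= exposed) "
            f"in rows {list(table.index[bad])}"
        )
    return table


@dataclass(frozen=True)
class GroupFit:
    """Least-squares-mean survival per group from a binomial logistic fit."""

    groups: tuple[str, ...]
    estimates: tuple[float, ...]  # survival probabilities
    ci_lower: tuple[float, ...]
    ci_upper: tuple[float, ...]
    coef: tuple[float, ...]  # per-group logit (cell-means coding)
    coef_se: tuple[float, ...]
    penalized: bool
    loglik: float  # penalized log-likelihood when penalized
    df_model: int
    endpoint: Endpoint
    group_alive: tuple[int, ...]
    group_exposed: tuple[int, ...]
    invariant_groups: tuple[str, ...]
    overdispersion: float  # replicate-level Pearson chi-square / df (NaN if df=0)
    converged: bool

    def estimate_for(self, group: str) -> float:
        return self.estimates[self.groups.index(group)]


@dataclass(frozen=True)
class LLRResult:
    """Likelihood-ratio test of the group factor against intercept only."""

    statistic: float
    df: int
    p_value: float
    penalized: bool


@dataclass(frozen=True)
class PosthocGrouping:
    """Scheffé-style simultaneous pairwise comparisons as letter groups."""

    letters: Mapping[str, str]  # group -> letter set, e.g. "ab"
    pairwise: pd.DataFrame = field(compare=False)
    excluded_invariant_groups: tuple[str, ...] = ()
    alpha: float = 0.05
    nothing_to_test: bool = False


# ---------------------------------------------------------------------------
# Core penalized/unpenalized binomial logistic Newton fitter
# ---------------------------------------------------------------------------

def _binom_loglik(y: np.ndarray, n: np.ndarray, pi: np.ndarray) -> float:
    """Binomial log-likelihood including combinatorial constants."""
    pi = np.clip(pi, 1e-12, 1 - 1e-12)
    const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    return float(np.sum(const + y * np.log(pi) + (n - y) * np.log(1 - pi)))


def _fit_binomial_logit(
    X: np.ndarray,
    y: np.ndarray,
    n: np.ndarray,
    penalized: bool,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Newton fit of a binomial logit model, optionally Firth-penalized.

    The Firth variant solves the modified score equation
    U*_j = Σ_i (y_i − n_iπ_i + h_i(½ − π_i)) x_ij = 0, with h the diagonal
    of the weighted hat matrix — the half-correction that maximizes
    ℓ(β) + ½log|X'WX| (Jeffreys prior).

    Returns (beta, covariance, log-likelihood [penalized if requested],
    converged flag).
    """
    n_obs, p = X.shape
    beta = np.zeros(p)
    converged = False
    cov = np.full((p, p), np.nan)
    for _ in range(max_iter):
        eta = X @ beta
        pi = expit(eta)
        w = n * pi * (1 - pi)
        xtwx = X.T @ (w[:, None] * X)
        try:
            cov = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError as exc:
            raise DataError("singular information matrix in logistic fit") from exc
        score = X.T @ (y - n * pi)
        if penalized:
            h = np.einsum("ij,jk,ik->i", X, cov, X) * w
            score = score + X.T @ (h * (0.5 - pi))
        delta = cov @ score
        # step-halving keeps the unpenalized fit from overshooting to ±inf
        step = 1.0
        for _half in range(30):
            trial = beta + step * delta
            if np.all(np.isfinite(expit(X @ trial))) and np.max(np.abs(step * delta)) < 50:
                break
            step /= 2.0
        beta = beta + step * delta
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            break
    pi = expit(X @ beta)
    ll = _binom_loglik(y, n, pi)
    if penalized:
        w = n * pi * (1 - pi)
        sign, logdet = np.linalg.slogdet(X.T @ (w[:, None] * X))
        ll += 0.5 * logdet
    return beta, cov, ll, converged


def _aggregate(table: pd.DataFrame, endpoint: Endpoint) -> pd.DataFrame:
    alive_col = _ENDPOINT_COL[endpoint]
    agg = (
        table.groupby("group", sort=False)
        .agg(alive=(alive_col, "sum"), exposed=("n_exposed", "sum"))
        .reset_index()
    )
    return agg


def _invariant_groups(agg: pd.DataFrame) -> list[str]:
    mask = (agg["alive"] == 0) | (agg["alive"] == agg["exposed"])
    return list(agg.loc[mask, "group"])


def fit_group_model(
    table: pd.DataFrame,
    endpoint: Endpoint = "24h",
    penalized: PenalizedMode = "auto",
    alpha: float = 0.05,
) -> GroupFit:
    """Fit survival ~ group (binomial, logit link) and return group means.

    With cell-means coding each coefficient is one group's survival on the
    logit scale; least-squares means are the inverse-logit coefficients and
    their Wald intervals are built on the logit scale and back-transformed,
    so estimates and bounds always lie in [0, 1].

    ``penalized='auto'`` switches the Firth penalty on whenever any group is
    invariant (all alive or all dead), the situation in which ordinary
    maximum likelihood diverges.
    """
    validate_trials(table)
    agg = _aggregate(table, endpoint)
    groups = list(agg["group"])
    invariant = _invariant_groups(agg)
    if penalized == "auto":
        use_penalty = len(invariant) > 0
    else:
        use_penalty = penalized == "on"

    # cell-means design: one indicator column per group, replicate rows kept
    alive_col = _ENDPOINT_COL[endpoint]
    y = table[alive_col].to_numpy(dtype=float)
    n = table["n_exposed"].to_numpy(dtype=float)
    X = pd.get_dummies(table["group"]).reindex(columns=groups).to_numpy(dtype=float)
    beta, cov, ll, converged = _fit_binomial_logit(X, y, n, penalized=use_penalty)
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(1 - alpha / 2)
    est = expit(beta)
    lo = expit(beta - z * se)
    hi = expit(beta + z * se)

    # replicate-level overdispersion: Pearson X²/df vs the fitted group means
    fitted = X @ beta
    pi_row = expit(fitted)
    resid_df = len(table) - len(groups)
    if resid_df > 0:
        pearson = np.sum((y - n * pi_row) ** 2 / (n * pi_row * (1 - pi_row)))
        overdisp = float(pearson / resid_df)
    else:
        overdisp = float("nan")

    return GroupFit(
        groups=tuple(groups),
        estimates=tuple(float(v) for v in est),
        ci_lower=tuple(float(v) for v in lo),
        ci_upper=tuple(float(v) for v in hi),
        coef=tuple(float(v) for v in beta),
        coef_se=tuple(float(v) for v in se),
        penalized=use_penalty,
        loglik=ll,
        df_model=len(groups),
        endpoint=endpoint,
        group_alive=tuple(int(v) for v in agg["alive"]),
        group_exposed=tuple(int(v) for v in agg["exposed"]),
        invariant_groups=tuple(invariant),
        overdispersion=overdisp,
        converged=converged,
    )


def llr_test(
    table: pd.DataFrame,
    endpoint: Endpoint = "24h",
    penalized: PenalizedMode = "auto",
) -> LLRResult:
    """Likelihood-ratio test: group-factor model vs intercept-only.

    Statistic 2(ℓ_full − ℓ_null) on df = (#groups − 1), referred to a
    chi-square distribution.  Under penalization the penalized
    log-likelihoods are differenced (the penalty is applied to the overall
    model test), and the statistic is floored at 0 since the penalties of
    non-nested design matrices need not preserve ordering exactly.
    """
    validate_trials(table)
    agg = _aggregate(table, endpoint)
    if len(agg) < 2:
        raise DataError("llr_test needs at least 2 groups")
    if penalized == "auto":
        use_penalty = len(_invariant_groups(agg)) > 0
    else:
        use_penalty = penalized == "on"

    alive_col = _ENDPOINT_COL[endpoint]
    y = table[alive_col].to_numpy(dtype=float)
    n = table["n_exposed"].to_numpy(dtype=float)
    groups = list(agg["group"])
    X_full = pd.get_dummies(table["group"]).reindex(columns=groups).to_numpy(dtype=float)
    X_null = np.ones((len(table), 1))
    _, _, ll_full, _ = _fit_binomial_logit(X_full, y, n, penalized=use_penalty)
    _, _, ll_null, _ = _fit_binomial_logit(X_null, y, n, penalized=use_penalty)
    statistic = max(0.0, 2.0 * (ll_full - ll_null))
    df = len(groups) - 1
    p = float(stats.chi2.sf(statistic, df))
    return LLRResult(statistic=statistic, df=df, p_value=p, penalized=use_penalty)


# ---------------------------------------------------------------------------
# Scheffé-style post hoc comparisons with compact letter display
# ---------------------------------------------------------------------------

def _maximal_cliques(adjacent: np.ndarray) -> list[frozenset[int]]:
    """All maximal cliques of a small undirected graph (brute force)."""
    k = adjacent.shape[0]
    nodes = range(k)
    cliques: list[frozenset[int]] = []
    for size in range(k, 0, -1):
        for combo in itertools.combinations(nodes, size):
            if all(adjacent[a, b] for a, b in itertools.combinations(combo, 2)):
                s = frozenset(combo)
                if not any(s < c for c in cliques):
                    cliques.append(s)
    return cliques


def scheffe_posthoc(fit: GroupFit, alpha: float = 0.05) -> PosthocGrouping:
    """All pairwise group contrasts with Scheffé simultaneous protection.

    Each contrast (βa − βb)²/(se_a² + se_b²) on the logit scale is compared
    to the chi-square (1−α) quantile on (k − 1) df, k the number of groups
    tested — the large-sample analogue of the classical Scheffé bound
    (k−1)·F, which protects all contrasts simultaneously.  Invariant groups
    are excluded first; groups not significantly different share a letter.
    """
    keep = [g for g in fit.groups if g not in fit.invariant_groups]
    if len(keep) < 2:
        return PosthocGrouping(
            letters={},
            pairwise=pd.DataFrame(
                columns=["group_a", "group_b", "statistic", "critical", "significant"]
            ),
            excluded_invariant_groups=tuple(fit.invariant_groups),
            alpha=alpha,
            nothing_to_test=True,
        )
    idx = [fit.groups.index(g) for g in keep]
    beta = np.array([fit.coef[i] for i in idx])
    se = np.array([fit.coef_se[i] for i in idx])
    k = len(keep)
    critical = float(stats.chi2.ppf(1 - alpha, k - 1))

    rows = []
    not_different = np.eye(k, dtype=bool)
    for a, b in itertools.combinations(range(k), 2):
        statistic = (beta[a] - beta[b]) ** 2 / (se[a] ** 2 + se[b] ** 2)
        significant = statistic > critical
        not_different[a, b] = not_different[b, a] = not significant
        rows.append(
            {
                "group_a": keep[a],
                "group_b": keep[b],
                "statistic": float(statistic),
                "critical": critical,
                "significant": bool(significant),
            }
        )

    # letters: one per maximal clique of the "not significantly different" graph,
    # ordered by the best survival within the clique
    cliques = _maximal_cliques(not_different)
    cliques.sort(key=lambda c: -max(expit(beta[i]) for i in c))
    letters: dict[str, list[str]] = {g: [] for g in keep}
    for letter, clique in zip(ascii_lowercase, cliques):
        for i in sorted(clique):
            letters[keep[i]].append(letter)
    return PosthocGrouping(
        letters={g: "".join(sorted(v)) for g, v in letters.items()},
        pairwise=pd.DataFrame(rows),
        excluded_invariant_groups=tuple(fit.invariant_groups),
        alpha=alpha,
        nothing_to_test=False,
    )


# ---------------------------------------------------------------------------
# Study-level summaries
# ---------------------------------------------------------------------------

def fit_all(
    table: pd.DataFrame,
    endpoint: Endpoint = "24h",
    penalized: PenalizedMode = "auto",
    alpha: float = 0.05,
) -> tuple[
    dict[tuple[str, str], GroupFit],
    dict[tuple[str, str], LLRResult | None],
    dict[tuple[str, str], PosthocGrouping],
]:
    """Fit, test and letter every (life stage × experiment) block of a table.

    Blocks where every group is invariant-alive (a "100% survival all
    round" outcome) get no LLR test: the group factor carries no
    information.
    """
    validate_trials(table)
    fits: dict[tuple[str, str], GroupFit] = {}
    llrs: dict[tuple[str, str], LLRResult | None] = {}
    posthocs: dict[tuple[str, str], PosthocGrouping] = {}
    for (stage, experiment), block in table.groupby(
        ["life_stage", "experiment"], sort=False
    ):
        key = (stage, experiment)
        fit = fit_group_model(block, endpoint=endpoint, penalized=penalized, alpha=alpha)
        fits[key] = fit
        all_alive = all(a == n for a, n in zip(fit.group_alive, fit.group_exposed))
        if all_alive or len(fit.groups) < 2:
            llrs[key] = None
        else:
            llrs[key] = llr_test(block, endpoint=endpoint, penalized=penalized)
        posthocs[key] = scheffe_posthoc(fit, alpha=alpha)
    return fits, llrs, posthocs


def summarize(
    fits: Mapping[tuple[str, str], GroupFit],
    llrs: Mapping[tuple[str, str], LLRResult | None],
    posthocs: Mapping[tuple[str, str], PosthocGrouping] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the study-level test table and the per-group estimate series.

    Returns
    -------
    tests : DataFrame
        One row per (life_stage, experiment): df, LLR, p — or the note
        "100% survival all round" when every fish in every group survived
        and no test is meaningful.
    estimates : DataFrame
        One row per (life_stage, experiment, group): survival estimate with
        95% CI and, where post hoc letters were computed, the letter set.
    """
    if set(fits) != set(llrs):
        raise DataError("fits and llrs must cover the same (life stage, experiment) keys")
    test_rows, est_rows = [], []
    for key, fit in fits.items():
        stage, experiment = key
        llr = llrs[key]
        all_alive = all(a == n for a, n in zip(fit.group_alive, fit.group_exposed))
        test_rows.append(
            {
                "life_stage": stage,
                "experiment": experiment,
                "df": llr.df if llr else np.nan,
                "llr": llr.statistic if llr else np.nan,
                "p_value": llr.p_value if llr else np.nan,
                "penalized": fit.penalized,
                "note": "100% survival all round" if all_alive else "",
            }
        )
        letters = posthocs[key].letters if posthocs and key in posthocs else {}
        for g, est, lo, hi in zip(fit.groups, fit.estimates, fit.ci_lower, fit.ci_upper):
            est_rows.append(
                {
                    "life_stage": stage,
                    "experiment": experiment,
                    "group": g,
                    "estimate": est,
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "letter": letters.get(g, ""),
                }
            )
    return pd.DataFrame(test_rows), pd.DataFrame(est_rows)
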