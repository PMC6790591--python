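"""Logistic genotype-environment scoring engine.

For every (binary genotype indicator, environmental variable) pair the engine
fits two nested logistic regressions — a null model with the intercept and
any population-structure covariates, and a full model adding the
environmental term(s) — and reports the likelihood-ratio statistic
``G = 2 (LL_full - LL_null)`` together with the Wald statistic of the
environmental coefficients.  Under no association both are asymptotically
chi-squared with ``df = number of environmental variables``.

The scan is chunked for parallel execution; the merged output is
byte-identical regardless of chunk count or worker count.
"""

from __future__ import annotations

import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from geascan.env_data import EnvTable
from geascan.genotype_io import MISSING, IndicatorSet

MAX_ITER = 100
LL_TOL = 1e-10
SEPARATION_BETA = 30.0
SEPARATION_SE = 1e3

RESULT_COLUMNS = [
    "indicator", "env", "n", "beta_env", "G", "Wald", "df", "status",
    "loglik_full", "loglik_null",
]


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Which variables enter the full model.

    ``env_vars``: one (univariate) or more environmental variable names.
    ``pop_vars``: population-structure covariates shared by null and full
    models.  Overlap between the two is illegal.
    """

    env_vars: tuple
    pop_vars: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "env_vars", tuple(self.env_vars))
        object.__setattr__(self, "pop_vars", tuple(self.pop_vars))
        if not self.env_vars:
            raise ScanError("env_vars must be nonempty")
        if set(self.env_vars) & set(self.pop_vars):
            raise ScanError("env_vars and pop_vars overlap")

    @property
    def univariate(self) -> bool:
        return len(self.env_vars) == 1 and not self.pop_vars


@dataclass
class FitResult:
    beta: np.ndarray | None
    loglik: float
    cov: np.ndarray | None
    status: str
    n_iter: int = 0


@dataclass
class ModelResult:
    indicator: str
    env_vars: tuple
    n_used: int
    beta: np.ndarray | None
    loglik_full: float
    loglik_null: float
    G: float
    Wald: float
    df: int
    status: str

    def to_row(self) -> dict:
        beta_env = float("nan")
        if self.beta is not None and len(self.env_vars) == 1:
            beta_env = float(self.beta[-1])
        return {
            "indicator": self.indicator,
            "env": "+".join(self.env_vars),
            "n": self.n_used,
            "beta_env": beta_env,
            "G": self.G,
            "Wald": self.Wald,
            "df": self.df,
            "status": self.status,
            "loglik_full": self.loglik_full,
            "loglik_null": self.loglik_null,
        }


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: log(1+exp(eta)) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(y: np.ndarray, X: np.ndarray) -> FitResult:
    """Maximize the Bernoulli log-likelihood with a logit link by IRLS.

    ``X`` must contain the intercept column.  Convergence at
    ``|delta loglik| < 1e-10`` or 100 iterations.  The coefficient
    covariance is the inverse of the final Fisher information.  Quasi-complete
    separation (any ``|beta| > 30`` or standard error ``> 1e3``) is flagged
    ``status="separated"`` but scores are still computable; a rank-deficient
    design gives ``status="degenerate"`` with no estimates.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        return FitResult(None, float("nan"), None, "degenerate")
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        return FitResult(None, float("nan"), None, "degenerate")
    beta = np.zeros(p)
    beta[0] = math.log(ybar / (1.0 - ybar))  # intercept start at logit(mean)
    eta = X @ beta
    ll = _bernoulli_loglik(y, eta)
    xtwx = None
    for it in range(1, MAX_ITER + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        xw = X * w[:, None]
        xtwx = X.T @ xw
        try:
            beta_new = np.linalg.solve(xtwx, xw.T @ z)
        except np.linalg.LinAlgError:
            return FitResult(None, float("nan"), None, "degenerate")
        eta_new = X @ beta_new
        ll_new = _bernoulli_loglik(y, eta_new)
        beta, eta = beta_new, eta_new
        if abs(ll_new - ll) < LL_TOL:
            ll = ll_new
            break
        ll = ll_new
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    xtwx = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        return FitResult(None, float("nan"), None, "degenerate")
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    status = "converged"
    if np.any(np.abs(beta) > SEPARATION_BETA) or np.any(se > SEPARATION_SE):
        status = "separated"
    return FitResult(beta, ll, cov, status, n_iter=it)


def score_model(ind_values: np.ndarray, env: EnvTable | pd.DataFrame,
                spec: ModelSpec, label: str = "indicator") -> ModelResult:
    """Fit the null vs full logistic models for one indicator.

    Complete-case: samples missing the indicator or any modeled variable are
    dropped.  A constant indicator or constant environmental column after
    filtering gives ``status="skipped"``.
    """
    data = env.data if isinstance(env, EnvTable) else env
    cols = list(spec.pop_vars) + list(spec.env_vars)
    mat = data[cols].to_numpy(dtype=float)
    ind_values = np.asarray(ind_values)
    mask = (ind_values != MISSING) & np.isfinite(mat).all(axis=1)
    y = ind_values[mask].astype(float)
    mat = mat[mask]
    n_used = int(mask.sum())
    df = len(spec.env_vars)

    def skipped(reason):
        return ModelResult(label, spec.env_vars, n_used, None, float("nan"),
                           float("nan"), float("nan"), float("nan"), df, reason)

    if n_used < mat.shape[1] + 2:
        return skipped("skipped")
    if y.min() == y.max():
        return skipped("skipped")
    if any(mat[:, j].min() == mat[:, j].max() for j in range(mat.shape[1])):
        return skipped("skipped")

    ones = np.ones((n_used, 1))
    n_pop = len(spec.pop_vars)
    x_null = np.hstack([ones, mat[:, :n_pop]])
    x_full = np.hstack([ones, mat])
    fit_null = fit_logistic(y, x_null)
    fit_full = fit_logistic(y, x_full)
    if fit_null.status == "degenerate" or fit_full.status == "degenerate":
        return ModelResult(label, spec.env_vars, n_used, None, fit_full.loglik,
                           fit_null.loglik, float("nan"), float("nan"), df,
                           "degenerate")
    G = 2.0 * (fit_full.loglik - fit_null.loglik)
    b_env = fit_full.beta[1 + n_pop:]
    v_env = fit_full.cov[1 + n_pop:, 1 + n_pop:]
    try:
        wald = float(b_env @ np.linalg.solve(v_env, b_env))
    except np.linalg.LinAlgError:
        wald = float("nan")
    status = "converged"
    if fit_null.status == "separated" or fit_full.status == "separated":
        status = "separated"
    return ModelResult(label, spec.env_vars, n_used, fit_full.beta,
                       fit_full.loglik, fit_null.loglik, G, wald, df, status)


# ---------------------------------------------------------------------------
# Chunked scan
# ---------------------------------------------------------------------------


def _scan_chunk(args):
    """Score one chunk of indicator columns (module-level for pickling)."""
    values, labels, env_data_records, env_columns, env_vars, pop_vars = args
    data = pd.DataFrame(env_data_records, columns=env_columns)
    rows = []
    for k, label in enumerate(labels):
        for e in env_vars:
            spec = ModelSpec(env_vars=(e,), pop_vars=tuple(pop_vars))
            res = score_model(values[:, k], data, spec, label=label)
            rows.append(res.to_row())
    return rows


def run_scan(ind: IndicatorSet, env: EnvTable, env_vars=None, pop_vars=(),
             chunks: int = 1, workers: int = 1) -> pd.DataFrame:
    """Score every indicator x environmental-variable pair.

    Sample IDs and order must be identical between ``ind`` and ``env``
    (fatal otherwise).  Work is split into ``chunks`` blocks of indicators
    executed by ``workers`` processes; results are merged in (indicator, env)
    order so the output is bitwise independent of the parallelism settings.
    """
    if list(ind.samples) != list(env.samples):
        bad = [
            (a, b) for a, b in zip(ind.samples, env.samples) if a != b
        ][:5] or [("length", f"{len(ind.samples)} vs {len(env.samples)}")]
        raise ScanError(f"sample ID/order mismatch between genotypes and env: {bad}")
    env_vars = list(env_vars) if env_vars is not None else list(env.env_vars)
    pop_vars = list(pop_vars)
    unknown = [v for v in env_vars + pop_vars if v not in env.data.columns]
    if unknown:
        raise ScanError(f"unknown variables: {unknown}")

    labels = list(ind.indicators["label"])
    n_ind = len(labels)
    chunks = max(1, min(chunks, n_ind))
    bounds = np.linspace(0, n_ind, chunks + 1).astype(int)
    env_records = env.data.to_numpy(dtype=float)
    tasks = [
        (
            ind.values[:, lo:hi],
            labels[lo:hi],
            env_records,
            list(env.data.columns),
            env_vars,
            pop_vars,
        )
        for lo, hi in zip(bounds[:-1], bounds[1:])
        if hi > lo
    ]
    if workers > 1 and len(tasks) > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            chunk_rows = list(pool.map(_scan_chunk, tasks))
    else:
        chunk_rows = [_scan_chunk(t) for t in tasks]
    rows = [r for chunk in chunk_rows for r in chunk]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_scores(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
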