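"""Weighted quantile sum (WQS) regression of a symptom mixture on centrality.

Each mixture component is quartile-ranked (0..3). A weighted index
``index_j = sum_i w_i * q_ij`` with non-negative weights summing to one is
estimated in two steps: (1) across bootstrap resamples, the weights that
extremise the covariate-adjusted association between index and outcome in
the configured direction are found exactly by active-set enumeration over
the simplex faces; (2) the bootstrap-aggregated weights define the index on
the full sample, which is tested in a linear model with covariates.

Weight aggregation is the signal-weighted mean: bootstrap fits whose index
t statistic passes a small threshold in the configured direction are
averaged (all fits, with a warning, when none pass); a plain mean is
available via ``aggregation='mean'``. No train/validation split is used.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ecm_core import roi_columns

logger = logging.getLogger(__name__)

DIRECTIONS = ("negative", "positive")
N_QUARTILES = 4
MIN_SUBJECTS = 20


class WQSError(ValueError):
    pass


@dataclass
class WQSFit:
    """Result of a two-step WQS fit for one outcome."""

    beta: float                     # outcome units per index unit
    se: float
    p: float
    weights: pd.Series              # non-negative, sums to 1
    n_boot: int
    n_used: int                     # bootstraps entering the aggregate
    n_dropped: int                  # degenerate bootstrap fits discarded
    direction: str
    n_obs: int
    covariate_coefficients: pd.Series = field(
        default_factory=lambda: pd.Series(dtype=float))

    @property
    def contributions_pct(self) -> pd.Series:
        return self.weights * 100.0


def quartile_rank(x, n_quantiles: int = N_QUARTILES) -> np.ndarray:
    """Integer quantile ranks 0..n_quantiles-1 from sample quantile cuts.

    Values equal to a cut boundary fall in the lower quantile. Columns with
    fewer distinct values than quantiles degrade to the available ranks
    with a warning. Rank invariance: any strictly increasing transform of
    ``x`` yields identical ranks.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise WQSError("quartile_rank expects a single column")
    if np.isnan(x).any():
        raise WQSError("missing values are not allowed in mixture columns")
    if x.size < 2 * n_quantiles:
        raise WQSError(
            f"need at least {2 * n_quantiles} values, got {x.size}"
        )
    cuts = np.quantile(x, np.arange(1, n_quantiles) / n_quantiles)
    ranks = (x[:, None] > cuts[None, :]).sum(axis=1)
    if np.unique(x).size < n_quantiles:
        logger.warning(
            "column has %d distinct values; quartile ranks degrade to %d "
            "levels", np.unique(x).size, np.unique(ranks).size,
        )
    return ranks.astype(int)


def quartile_matrix(scales: pd.DataFrame,
                    n_quantiles: int = N_QUARTILES) -> pd.DataFrame:
    """Column-wise quartile ranks of a subjects x components table."""
    return pd.DataFrame(
        {c: quartile_rank(scales[c].to_numpy(), n_quantiles)
         for c in scales.columns},
        index=scales.index,
    )


def wqs_index(weights, quartiles) -> np.ndarray:
    """Per-subject weighted index sum_i w_i * q_ij, bounded in [0, 3]."""
    w = np.asarray(weights, dtype=float)
    Q = (quartiles.to_numpy(dtype=float)
         if isinstance(quartiles, pd.DataFrame)
         else np.asarray(quartiles, dtype=float))
    if Q.shape[1] != w.size:
        raise WQSError(
            f"weight length {w.size} does not match {Q.shape[1]} components"
        )
    if w.min() < -1e-12:
        raise WQSError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise WQSError(f"weights must sum to 1 (got {w.sum():.12f})")
    return Q @ w


def _optimal_weights(a: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Maximise a'w / sqrt(w'Bw) over the non-negative simplex, exactly.

    Scale invariance reduces the simplex problem to the non-negative cone;
    the KKT solution lies on one of the 2^c - 1 support sets, where the
    unconstrained face solution is w_S = B_S^{-1} a_S. Enumerating supports
    (c is small) gives the global optimum; when no face yields a positive
    value the best vertex is returned.
    """
    c = a.size
    best_w = None
    best_val = -np.inf
    for size in range(1, c + 1):
        for S in itertools.combinations(range(c), size):
            S = list(S)
            try:
                w_S = np.linalg.solve(B[np.ix_(S, S)], a[S])
            except np.linalg.LinAlgError:
                continue
            if size > 1 and w_S.min() <= 0:
                continue
            if size == 1 and w_S[0] <= 0:
                # vertex candidate regardless of sign of a
                w_S = np.array([1.0])
            denom = float(w_S @ B[np.ix_(S, S)] @ w_S)
            if denom <= 0:
                continue
            val = float(a[S] @ w_S) / np.sqrt(denom)
            if val > best_val:
                best_val = val
                w = np.zeros(c)
                w[S] = w_S
                best_w = w
    if best_w is None:  # pathological B; fall back to equal weights
        best_w = np.ones(c)
    total = best_w.sum()
    if total <= 0:
        best_w = np.ones(c)
        total = float(c)
    return best_w / total


def _residualize_columns(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta = np.linalg.lstsq(Z, M, rcond=None)[0]
    return M - Z @ beta


def fit_wqs(
    outcome,
    scales: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_boot: int = 5000,
    direction: str = "negative",
    seed: int | None = None,
    signal_t: float = 1.0,
    aggregation: str = "signal",
    n_quantiles: int = N_QUARTILES,
) -> WQSFit:
    """Two-step WQS regression of ``outcome`` on a component mixture.

    Parameters
    ----------
    outcome : numeric series (e.g. hub EC values, cases only)
    scales : subjects x components table of mixture variables
    covariates : optional nuisance regressors tested alongside the index
    direction : 'negative' or 'positive' association constraint; must be
        chosen explicitly in analysis configs to avoid sign fishing.
    """
    if direction not in DIRECTIONS:
        raise WQSError(f"direction must be one of {DIRECTIONS}")
    if aggregation not in ("signal", "mean"):
        raise WQSError("aggregation must be 'signal' or 'mean'")
    y = np.asarray(outcome, dtype=float)
    n = y.size
    if n < MIN_SUBJECTS:
        raise WQSError(f"need at least {MIN_SUBJECTS} subjects, got {n}")
    if len(scales) != n:
        raise WQSError("outcome and scales disagree on subject count")
    Q = quartile_matrix(scales, n_quantiles).to_numpy(dtype=float)
    c = Q.shape[1]
    component_names = list(scales.columns)

    if covariates is not None:
        C = covariates.to_numpy(dtype=float)
        if C.shape[0] != n:
            raise WQSError("covariates disagree on subject count")
    else:
        C = np.empty((n, 0))
    Z = np.column_stack([np.ones(n), C])
    df = n - Z.shape[1] - 1
    if df < 3:
        raise WQSError("too few degrees of freedom for the index test")
    sign = -1.0 if direction == "negative" else 1.0

    rng = np.random.default_rng(seed)
    boot_w = np.empty((n_boot, c))
    boot_t = np.empty(n_boot)
    n_dropped = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        Qb = Q[idx]
        Zb = Z[idx]
        y_r = _residualize_columns(yb[:, None], Zb)[:, 0]
        Q_r = _residualize_columns(Qb, Zb)
        ss_y = float(y_r @ y_r)
        B = Q_r.T @ Q_r
        if ss_y <= 0 or np.trace(B) <= 0:
            n_dropped += 1
            boot_w[b] = np.nan
            boot_t[b] = np.nan
            continue
        a = sign * (Q_r.T @ y_r)
        w = _optimal_weights(a, B)
        x_r = Q_r @ w
        ss_x = float(x_r @ x_r)
        if ss_x <= 0:
            n_dropped += 1
            boot_w[b] = np.nan
            boot_t[b] = np.nan
            continue
        r = float(x_r @ y_r) / np.sqrt(ss_x * ss_y)
        r = np.clip(r, -0.999999999, 0.999999999)
        boot_w[b] = w
        boot_t[b] = r * np.sqrt(df / (1.0 - r * r))
    if n_dropped > 0.5 * n_boot:
        raise WQSError(
            f"{n_dropped}/{n_boot} bootstrap fits were degenerate"
        )

    ok = ~np.isnan(boot_t)
    if aggregation == "signal":
        selected = ok & (sign * boot_t >= signal_t)
        if not selected.any():
            logger.warning(
                "no bootstrap fit passed the |t| >= %.2f signal threshold; "
                "averaging all fits", signal_t,
            )
            selected = ok
    else:
        selected = ok
    weights = boot_w[selected].mean(axis=0)
    weights = np.maximum(weights, 0.0)
    weights /= weights.sum()

    index = wqs_index(weights, Q)
    Xf = pd.DataFrame({"intercept": np.ones(n), "wqs_index": index})
    for j, name in enumerate(
        covariates.columns if isinstance(covariates, pd.DataFrame)
        else range(C.shape[1])
    ):
        Xf[str(name)] = C[:, j]
    res = sm.OLS(y, Xf).fit()
    cov_terms = [t for t in Xf.columns if t not in ("intercept", "wqs_index")]

    return WQSFit(
        beta=float(res.params["wqs_index"]),
        se=float(res.bse["wqs_index"]),
        p=float(res.pvalues["wqs_index"]),
        weights=pd.Series(weights, index=component_names, name="weight"),
        n_boot=n_boot,
        n_used=int(selected.sum()),
        n_dropped=n_dropped,
        direction=direction,
        n_obs=n,
        covariate_coefficients=res.params[cov_terms],
    )


def average_bilateral(ec: pd.DataFrame, pairs) -> pd.DataFrame:
    """Average left/right ROI column pairs of an EC table into one column.

    ``pairs`` is a list of ``(left_roi, right_roi)`` indices (or ``roi_*``
    column names). The merged column, named ``roi_<l>+<r>``, replaces the
    left column's position; the right column is dropped. An empty pair
    list returns the table unchanged.
    """
    out = ec.copy()
    for left, right in pairs:
        lcol = left if isinstance(left, str) else f"roi_{left}"
        rcol = right if isinstance(right, str) else f"roi_{right}"
        for col in (lcol, rcol):
            if col not in out.columns:
                raise WQSError(f"EC table has no column {col!r}")
        merged = out[[lcol, rcol]].mean(axis=1)
        name = f"roi_{lcol[4:]}+{rcol[4:]}"
        pos = out.columns.get_loc(lcol)
        out = out.drop(columns=[lcol, rcol])
        out.insert(pos, name, merged)
    return out


def wqs_report(fits: dict[str, WQSFit], adjust: bool = True) -> pd.DataFrame:
    """Summary table (one row per outcome) with BH-adjusted p-values."""
    from .exposure_moderation import adjust_pvalues_bh

    rows = [
        {"roi": name, "beta": f.beta, "se": f.se, "p": f.p, "n_obs": f.n_obs}
        for name, f in fits.items()
    ]
    table = pd.DataFrame(rows, columns=["roi", "beta", "se", "p", "n_obs"])
    if adjust and len(table):
        table["p_adjusted"] = adjust_pvalues_bh(table["p"].to_numpy())
    return table


def plot_contributions(fit: WQSFit, path, title: str = "") -> None:
    """Bar plot of component contribution percentages."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    contrib = fit.contributions_pct.sort_values(ascending=False)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    colors = ["#67a9cf" if i == 0 else "#bdbdbd"
              for i in range(len(contrib))]
    ax.bar(contrib.index, contrib.to_numpy(), color=colors)
    ax.set_ylabel("contribution (%)")
    if title:
        ax.set_title(title)
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
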