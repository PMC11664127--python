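"""Sensitivity analysis, trend regressions and the random-intercept model.

Implements a paired-matrix first-order Sobol estimator with bootstrap
standard errors, 1-degree-binned latitudinal OLS trends, record-level
covariate OLS, and a profile-REML random-intercept linear mixed model with
a single grouping factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

MIN_SOBOL_BASE = 64


@dataclass
class SobolResult:
    """First-order Sobol indices with bootstrap SEs and normal 0.05 quantiles."""

    labels: tuple[str, ...]
    s1: np.ndarray
    se: np.ndarray
    q05: np.ndarray
    n_base_samples: int
    n_boot: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variable": self.labels, "s1": self.s1, "se": self.se, "q05": self.q05}
        )


def sobol_first_order(
    model: Callable[[np.ndarray], np.ndarray],
    input_sampler: Callable[[np.random.Generator, int], np.ndarray],
    n_base: int,
    n_boot: int = 100,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> SobolResult:
    """Estimate S1_i = V_i[E(Y|X_i)] / V(Y) with a paired-matrix design.

    ``model`` maps an (n, k) input matrix to n outputs; ``input_sampler``
    draws an (n, k) matrix of independent inputs.  Two base matrices A and B
    are drawn and, for each input i, the model is re-run on A with column i
    taken from B; S1_i = mean(yB * (yAB_i - yA)) / V(Y) on centred outputs.
    SEs come from a bootstrap over base-sample rows.
    """
    if n_base < MIN_SOBOL_BASE:
        raise ValueError(f"n_base must be >= {MIN_SOBOL_BASE}, got {n_base}")
    rng = np.random.default_rng(seed)
    a = np.asarray(input_sampler(rng, n_base), dtype=float)
    b = np.asarray(input_sampler(rng, n_base), dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("input_sampler must return an (n, k) matrix")
    k = a.shape[1]
    if labels is None:
        labels = tuple(f"x{i + 1}" for i in range(k))
    labels = tuple(labels)

    def run(matrix: np.ndarray) -> np.ndarray:
        y = np.asarray(model(matrix), dtype=float).reshape(-1)
        if y.shape[0] != matrix.shape[0]:
            raise ValueError("model must return one output per input row")
        bad = ~np.isfinite(y)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"model returned non-finite output at input row {row}: "
                f"{matrix[row].tolist()}"
            )
        return y

    y_a = run(a)
    y_b = run(b)
    y_ab = np.empty((k, n_base))
    for i in range(k):
        ab = a.copy()
        ab[:, i] = b[:, i]
        y_ab[i] = run(ab)

    # centring makes the estimator exactly invariant to output shifts
    centre = 0.5 * (y_a.mean() + y_b.mean())
    y_a = y_a - centre
    y_b = y_b - centre
    y_ab = y_ab - centre

    def estimate(idx: np.ndarray) -> np.ndarray:
        va = y_a[idx]
        vb = y_b[idx]
        variance = np.concatenate([va, vb]).var(ddof=1)
        return (vb * (y_ab[:, idx] - va)).mean(axis=1) / variance

    full_idx = np.arange(n_base)
    s1 = estimate(full_idx)
    boot = np.empty((n_boot, k))
    for r in range(n_boot):
        boot[r] = estimate(rng.integers(0, n_base, size=n_base))
    se = boot.std(axis=0, ddof=1)
    q05 = s1 - 1.645 * se
    return SobolResult(labels, s1, se, q05, n_base, n_boot, seed)


@dataclass
class TrendFit:
    """Simple OLS fit summary."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    predictor: str
    response: str
    slope_stderr: float = float("nan")

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for the slope."""
        half = sps.t.ppf(0.5 + level / 2.0, self.n - 2) * self.slope_stderr
        return self.slope - half, self.slope + half


def _ols(x: np.ndarray, y: np.ndarray, predictor: str, response: str) -> TrendFit:
    res = sps.linregress(x, y)
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(len(x)),
        predictor=predictor,
        response=response,
        slope_stderr=float(res.stderr),
    )


def latitudinal_trend(
    records: pd.DataFrame,
    ecotone: str | None = None,
    response: str = "ehi",
) -> TrendFit:
    """OLS of 1-degree-band mean response against |band-centre latitude|.

    Records are binned into integer-aligned 1-degree latitude bands; the
    band mean is regressed on the absolute latitude of the band centre.
    """
    table = records if ecotone is None else records[records["ecotone"] == ecotone]
    table = table.dropna(subset=[response, "latitude"])
    if table.empty:
        raise ValueError("no usable records for latitudinal trend")
    band = np.floor(table["latitude"].to_numpy(dtype=float))
    means = (
        pd.DataFrame({"band": band, "y": table[response].to_numpy(dtype=float)})
        .groupby("band")["y"]
        .mean()
    )
    if len(means) < 3:
        raise ValueError(f"need >= 3 latitude bins, got {len(means)}")
    x = np.abs(means.index.to_numpy(dtype=float) + 0.5)
    return _ols(x, means.to_numpy(), predictor="abs_latitude", response=response)


def covariate_trend(
    records: pd.DataFrame, x_label: str, y_label: str
) -> TrendFit:
    """Record-level OLS of one column against another, missing pairs dropped."""
    table = records.dropna(subset=[x_label, y_label])
    if len(table) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(table)}")
    return _ols(
        table[x_label].to_numpy(dtype=float),
        table[y_label].to_numpy(dtype=float),
        predictor=x_label,
        response=y_label,
    )


@dataclass
class MixedModelFit:
    """Random-intercept linear mixed model fitted by profile REML."""

    beta: pd.Series
    random_intercepts: dict[str, float]
    sigma_b: float
    sigma_e: float
    fitted: np.ndarray
    residuals: np.ndarray
    log_reml: float
    groups: tuple[str, ...]


def _check_full_rank(x: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name columns involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.flatnonzero(diag < 1e-10 * diag.max())]
        raise ValueError(f"rank-deficient fixed-effect design; collinear: {bad}")


def fit_random_intercept(
    records: pd.DataFrame,
    fixed_labels: Sequence[str],
    group_label: str = "continent",
    response: str = "ehi",
    add_intercept: bool = True,
) -> MixedModelFit:
    """REML fit of ``response = X beta + b_group + noise``.

    The REML criterion is profiled down to the variance ratio
    lambda = sigma_b^2 / sigma_e^2 and minimized by bounded scalar search.
    With a single group the model degenerates to OLS (with a warning).
    """
    cols = [response, group_label, *fixed_labels]
    table = records.dropna(subset=cols)
    y = table[response].to_numpy(dtype=float)
    names = list(fixed_labels)
    x = table[list(fixed_labels)].to_numpy(dtype=float)
    if x.size == 0:
        x = np.empty((len(y), 0))
    if add_intercept:
        x = np.column_stack([np.ones(len(y)), x])
        names = ["intercept", *names]
    _check_full_rank(x, names)

    group_values = table[group_label].astype(str).to_numpy()
    group_names = tuple(sorted(set(group_values)))
    group_idx = {g: np.flatnonzero(group_values == g) for g in group_names}
    n, p = x.shape

    if len(group_names) < 2:
        warnings.warn(
            "single group: random intercept not identifiable, reducing to OLS",
            stacklevel=2,
        )
        beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        fitted = x @ beta
        resid = y - fitted
        sigma_e = math.sqrt(float(resid @ resid) / max(n - p, 1))
        return MixedModelFit(
            beta=pd.Series(beta, index=names),
            random_intercepts={g: 0.0 for g in group_names},
            sigma_b=0.0,
            sigma_e=sigma_e,
            fitted=fitted,
            residuals=resid,
            log_reml=float("nan"),
            groups=group_names,
        )

    # per-group sufficient statistics
    xtx = x.T @ x
    xty = x.T @ y
    yty = float(y @ y)
    g_sx = {g: x[idx].sum(axis=0) for g, idx in group_idx.items()}
    g_sy = {g: float(y[idx].sum()) for g, idx in group_idx.items()}
    g_n = {g: len(idx) for g, idx in group_idx.items()}

    def profile(lam: float):
        xhx = xtx.copy()
        xhy = xty.copy()
        yhy = yty
        log_det_h = 0.0
        for g in group_names:
            w = lam / (1.0 + lam * g_n[g])
            sx, sy = g_sx[g], g_sy[g]
            xhx -= w * np.outer(sx, sx)
            xhy -= w * sx * sy
            yhy -= w * sy * sy
            log_det_h += math.log1p(lam * g_n[g])
        beta = np.linalg.solve(xhx, xhy)
        rss = yhy - 2.0 * beta @ xhy + beta @ xhx @ beta
        rss = max(rss, 1e-300)
        sigma2 = rss / (n - p)
        sign, log_det_xhx = np.linalg.slogdet(xhx)
        neg2_reml = (n - p) * math.log(sigma2) + log_det_h + log_det_xhx
        return neg2_reml, beta, sigma2

    def objective(u: float) -> float:
        return profile(10.0**u)[0]

    res = optimize.minimize_scalar(
        objective, bounds=(-12.0, 8.0), method="bounded",
        options={"xatol": 1e-10},
    )
    lam = 10.0**res.x
    # accept the lambda -> 0 boundary when it is at least as good
    if profile(0.0)[0] <= res.fun + 1e-12:
        lam = 0.0

    neg2_reml, beta, sigma2 = profile(lam)
    sigma_e = math.sqrt(sigma2)
    sigma_b = math.sqrt(lam * sigma2)

    marginal_resid = y - x @ beta
    intercepts = {}
    fitted = x @ beta
    for g, idx in group_idx.items():
        shrink = lam * g_n[g] / (1.0 + lam * g_n[g])
        b_g = shrink * float(marginal_resid[idx].mean())
        intercepts[g] = b_g
        fitted[idx] += b_g

    return MixedModelFit(
        beta=pd.Series(beta, index=names),
        random_intercepts=intercepts,
        sigma_b=sigma_b,
        sigma_e=sigma_e,
        fitted=fitted,
        residuals=y - fitted,
        log_reml=-0.5 * neg2_reml,
        groups=group_names,
    )
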