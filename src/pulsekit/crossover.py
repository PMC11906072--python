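"""Crossover mixed-model statistics: REML fit, Satterthwaite F-tests,
effect sizes, Tukey HSD post hocs and group comparisons.

The design is a 2-group x 4-condition x 4-timepoint repeated-measures
crossover.  Outcomes are modelled with a linear mixed model: full
factorial fixed effects of condition, timepoint and group (plus optional
covariates) and a random intercept per participant, fitted by restricted
maximum likelihood (REML).  For a single variance-component model the
REML criterion can be profiled over the variance ratio
``lambda = tau^2 / sigma^2``, which keeps each fit to a one-dimensional
optimisation — fast enough for simulation-based calibration checks.

F-tests per term use Wald statistics on sum-to-zero (deviation) coded
coefficients — the type-III hypothesis — with denominator degrees of
freedom by the Satterthwaite approximation (per-eigencontrast df combined
across a multi-df term, the same construction lmerTest uses).  Effect
sizes are omega^2 = df1(F-1)/(df1(F-1)+df1+df2+1) and partial
eta^2 = F df1/(F df1 + df2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "EffectReport",
    "PosthocReport",
    "WelchReport",
    "CrossoverFit",
    "fit_crossover_model",
    "omega_squared",
    "partial_eta_squared",
    "eta_benchmark",
    "tukey_posthoc",
    "welch_compare",
    "noncentral_f_power",
]

FACTORS: Tuple[str, ...] = ("condition", "timepoint", "group")


# ---------------------------------------------------------------------------
# Effect sizes

def omega_squared(F: float, df1: float, df2: float) -> float:
    """omega^2 = df1(F-1) / (df1(F-1) + df1 + df2 + 1).

    Negative values (F < 1) are returned as computed, not truncated.
    """
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("need F >= 0 and positive dfs")
    num = df1 * (F - 1.0)
    return num / (num + df1 + df2 + 1.0)


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """Partial eta^2 = F*df1 / (F*df1 + df2)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("need F >= 0 and positive dfs")
    return (F * df1) / (F * df1 + df2)


def eta_benchmark(eta_p2: float) -> str:
    """Cohen-style label: small (< 0.05), medium (< 0.25), large (>= 0.25)."""
    if eta_p2 < 0.05:
        return "small"
    if eta_p2 < 0.25:
        return "medium"
    return "large"


@dataclass(frozen=True)
class EffectReport:
    term: str
    F: float
    df1: int
    df2: float
    p: float
    omega_sq: float
    partial_eta_sq: float
    benchmark: str


@dataclass(frozen=True)
class PosthocReport:
    contrast: str
    estimate: float
    ci_low: float
    ci_high: float
    se: float
    df: float
    p_tukey: float
    p_raw: float


# ---------------------------------------------------------------------------
# Design matrix (sum-to-zero coding, so per-term Wald tests are type III)

def _effects_columns(values: np.ndarray, levels: Sequence[str]) -> np.ndarray:
    out = np.zeros((values.size, len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        out[values == lev, j] = 1.0
    out[values == levels[-1], :] = -1.0
    return out


def _build_design(
    df: pd.DataFrame,
    levels: Dict[str, List[str]],
    covariates: Sequence[str],
    cov_means: Dict[str, float],
) -> Tuple[np.ndarray, Dict[str, slice]]:
    n = len(df)
    cols: List[np.ndarray] = [np.ones((n, 1))]
    slices: Dict[str, slice] = {"Intercept": slice(0, 1)}
    pos = 1
    main = {
        f: _effects_columns(df[f].to_numpy(), levels[f]) for f in FACTORS
    }
    blocks: List[Tuple[str, np.ndarray]] = [(f, main[f]) for f in FACTORS]
    for r in (2, 3):
        for combo in combinations(FACTORS, r):
            m = main[combo[0]]
            for f in combo[1:]:
                m = (m[:, :, None] * main[f][:, None, :]).reshape(n, -1)
            blocks.append((":".join(combo), m))
    for cv in covariates:
        c = df[cv].to_numpy(dtype=float) - cov_means[cv]
        blocks.append((cv, c.reshape(-1, 1)))
    for name, m in blocks:
        cols.append(m)
        slices[name] = slice(pos, pos + m.shape[1])
        pos += m.shape[1]
    return np.hstack(cols), slices


# ---------------------------------------------------------------------------
# The fit

@dataclass
class CrossoverFit:
    """Fitted random-intercept mixed model (internal state + inference API)."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float  # residual variance
    tau2: float  # random-intercept variance
    term_slices: Dict[str, slice]
    levels: Dict[str, List[str]]
    covariates: Tuple[str, ...]
    cov_means: Dict[str, float]
    n_obs: int
    n_participants: int
    _xtx: np.ndarray = field(repr=False, default=None)
    _xty: np.ndarray = field(repr=False, default=None)
    _yty: float = field(repr=False, default=0.0)
    _s_x: np.ndarray = field(repr=False, default=None)  # per-group X colsums
    _s_y: np.ndarray = field(repr=False, default=None)
    _n_g: np.ndarray = field(repr=False, default=None)

    # -- REML quantities at an arbitrary variance ratio ---------------------
    def _gls(self, lam: float):
        c = lam / (1.0 + self._n_g * lam)
        a = self._xtx - (self._s_x.T * c) @ self._s_x
        b = self._xty - self._s_x.T @ (c * self._s_y)
        yy = self._yty - float(np.sum(c * self._s_y**2))
        return a, b, yy

    def _reml_loglik(self, s2: float, t2: float) -> float:
        lam = t2 / s2
        a, b, yy = self._gls(lam)
        beta = np.linalg.solve(a, b)
        rss = max(yy - float(beta @ b), 1e-300)
        p = a.shape[0]
        _, logdet_a = np.linalg.slogdet(a)
        logdet_v = float(np.sum(np.log1p(self._n_g * lam)))
        return -0.5 * (
            (self.n_obs - p) * np.log(s2) + logdet_v + logdet_a + rss / s2
        )

    def _theta_cov(self) -> np.ndarray:
        """Asymptotic covariance of (sigma^2, tau^2) from the REML
        observed information (central finite differences)."""
        s2, t2 = self.sigma2, max(self.tau2, 1e-8 * self.sigma2)
        h = np.array([1e-4 * s2, 1e-4 * s2])
        th = np.array([s2, t2])

        def ll(v):
            return self._reml_loglik(max(v[0], 1e-12), max(v[1], 1e-12))

        hess = np.empty((2, 2))
        for i in range(2):
            for j in range(i, 2):
                ei = np.zeros(2); ei[i] = h[i]
                ej = np.zeros(2); ej[j] = h[j]
                hess[i, j] = hess[j, i] = (
                    ll(th + ei + ej) - ll(th + ei - ej)
                    - ll(th - ei + ej) + ll(th - ei - ej)
                ) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(-hess)
        return cov

    def _contrast_var(self, ell: np.ndarray, s2: float, t2: float) -> float:
        a, _, _ = self._gls(t2 / s2)
        return s2 * float(ell @ np.linalg.solve(a, ell))

    def _satterthwaite_df(self, ell: np.ndarray, theta_cov: np.ndarray) -> float:
        s2, t2 = self.sigma2, max(self.tau2, 1e-8 * self.sigma2)
        phi = self._contrast_var(ell, s2, t2)
        hs, ht = 1e-4 * s2, 1e-4 * s2
        d_s2 = (
            self._contrast_var(ell, s2 + hs, t2)
            - self._contrast_var(ell, s2 - hs, t2)
        ) / (2 * hs)
        if t2 > ht:
            d_t2 = (
                self._contrast_var(ell, s2, t2 + ht)
                - self._contrast_var(ell, s2, t2 - ht)
            ) / (2 * ht)
        else:  # at the tau^2 ~ 0 boundary use a forward difference
            d_t2 = (
                self._contrast_var(ell, s2, t2 + ht)
                - self._contrast_var(ell, s2, t2)
            ) / ht
        g = np.array([d_s2, d_t2])
        var_phi = float(g @ theta_cov @ g)
        if var_phi <= 0:
            return float(self.n_obs - self.beta.size)
        return float(np.clip(2.0 * phi**2 / var_phi, 1.0, 1e7))

    # -- public inference ---------------------------------------------------
    def term_f_test(self, term: str, theta_cov: Optional[np.ndarray] = None):
        """Wald F with Satterthwaite denominator df for one model term."""
        if term not in self.term_slices or term == "Intercept":
            raise KeyError(f"unknown model term {term!r}")
        sl = self.term_slices[term]
        idx = np.arange(sl.start, sl.stop)
        q = idx.size
        beta_t = self.beta[idx]
        m = self.cov_beta[np.ix_(idx, idx)]
        f_stat = float(beta_t @ np.linalg.solve(m, beta_t)) / q
        if theta_cov is None:
            theta_cov = self._theta_cov()
        # per-eigencontrast Satterthwaite dfs, combined lmerTest-style
        evals, evecs = np.linalg.eigh(m)
        nus = []
        for r in range(q):
            ell = np.zeros(self.beta.size)
            ell[idx] = evecs[:, r]
            nus.append(self._satterthwaite_df(ell, theta_cov))
        e_sum = sum(nu / (nu - 2.0) for nu in nus if nu > 2.0)
        if e_sum > q:
            df2 = 2.0 * e_sum / (e_sum - q)
        else:
            df2 = float(self.n_obs - self.beta.size)
        p = float(stats.f.sf(f_stat, q, df2))
        return f_stat, q, df2, p

    def effect_reports(self) -> List[EffectReport]:
        """One report (F, dfs, p, omega^2, partial eta^2) per fixed term."""
        theta_cov = self._theta_cov()
        out = []
        for term in self.term_slices:
            if term == "Intercept":
                continue
            f_stat, df1, df2, p = self.term_f_test(term, theta_cov)
            eta = partial_eta_squared(f_stat, df1, df2)
            out.append(
                EffectReport(
                    term=term,
                    F=f_stat,
                    df1=df1,
                    df2=df2,
                    p=p,
                    omega_sq=omega_squared(f_stat, df1, df2),
                    partial_eta_sq=eta,
                    benchmark=eta_benchmark(eta),
                )
            )
        return out

    def design_row(self, condition: str, timepoint: str, group: str) -> np.ndarray:
        """Fixed-effects row for one design cell (covariates at their mean)."""
        df = pd.DataFrame(
            {"condition": [condition], "timepoint": [timepoint], "group": [group]}
        )
        for cv in self.covariates:
            df[cv] = self.cov_means[cv]
        x, _ = _build_design(df, self.levels, self.covariates, self.cov_means)
        return x[0]


def fit_crossover_model(
    table: pd.DataFrame,
    covariates: Sequence[str] = (),
    outcome: str = "outcome",
) -> CrossoverFit:
    """REML fit of the crossover mixed model on a long-format trial table.

    ``table`` needs columns participant, group, condition, timepoint and
    the outcome; fixed effects are the full condition x timepoint x group
    factorial plus optional (mean-centered) numeric covariates, with a
    random intercept per participant.  A random-intercept variance
    estimated at (numerically) zero triggers a warning and is equivalent
    to dropping the random effect.
    """
    required = {"participant", *FACTORS, outcome}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns: {sorted(missing)}")
    y = pd.to_numeric(table[outcome], errors="raise").to_numpy(dtype=float)
    cell_counts = table.groupby("participant", observed=True).size()
    if (cell_counts < 2).any():
        raise ValueError("every participant needs at least 2 cells")

    levels = {f: sorted(table[f].astype(str).unique()) for f in FACTORS}
    cov_means = {cv: float(table[cv].mean()) for cv in covariates}
    x, slices = _build_design(table, levels, covariates, cov_means)
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("design matrix is rank deficient (unfillable cells?)")

    # per-participant sufficient statistics
    codes, _ = pd.factorize(table["participant"])
    n_groups = int(codes.max()) + 1
    s_x = np.zeros((n_groups, p))
    s_y = np.zeros(n_groups)
    np.add.at(s_x, codes, x)
    np.add.at(s_y, codes, y)
    n_g = np.bincount(codes).astype(float)

    fit = CrossoverFit(
        beta=np.zeros(p),
        cov_beta=np.eye(p),
        sigma2=1.0,
        tau2=0.0,
        term_slices=slices,
        levels=levels,
        covariates=tuple(covariates),
        cov_means=cov_means,
        n_obs=n,
        n_participants=n_groups,
        _xtx=x.T @ x,
        _xty=x.T @ y,
        _yty=float(y @ y),
        _s_x=s_x,
        _s_y=s_y,
        _n_g=n_g,
    )

    def criterion(log_lam: float) -> float:
        lam = np.exp(log_lam)
        a, b, yy = fit._gls(lam)
        try:
            beta = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            return np.inf
        rss = max(yy - float(beta @ b), 1e-300)
        _, logdet_a = np.linalg.slogdet(a)
        return (
            (n - p) * np.log(rss / (n - p))
            + float(np.sum(np.log1p(n_g * lam)))
            + logdet_a
        )

    res = optimize.minimize_scalar(
        criterion, bounds=(-30.0, 12.0), method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.exp(res.x))
    a, b, yy = fit._gls(lam)
    beta = np.linalg.solve(a, b)
    rss = max(yy - float(beta @ b), 1e-300)
    sigma2 = rss / (n - p)
    fit.beta = beta
    fit.sigma2 = float(sigma2)
    fit.tau2 = float(lam * sigma2)
    fit.cov_beta = sigma2 * np.linalg.inv(a)
    if lam < 1e-7:
        warnings.warn(
            "random-intercept variance estimated at zero (singular fit); "
            "inference falls back to the fixed-effects model",
            stacklevel=2,
        )
    return fit


# ---------------------------------------------------------------------------
# Post hocs and group comparisons

def tukey_posthoc(
    fit: CrossoverFit, term: str, conf_level: float = 0.95
) -> List[PosthocReport]:
    """All pairwise Tukey-HSD contrasts of estimated marginal means.

    ``term`` is a factor or colon-joined interaction of factors; marginal
    means average model predictions over the remaining factors on the full
    balanced grid, covariates held at their means.  The adjusted p uses
    the studentized-range distribution with the family size k = number of
    marginal means and the contrast's Satterthwaite df.
    """
    facs = term.split(":")
    for f in facs:
        if f not in FACTORS:
            raise KeyError(f"{term!r} is not a factor term of the model")
    other = [f for f in FACTORS if f not in facs]

    level_combos: List[Tuple[str, ...]] = [()]
    for f in facs:
        level_combos = [c + (lv,) for c in level_combos for lv in fit.levels[f]]
    other_combos: List[Dict[str, str]] = [{}]
    for f in other:
        other_combos = [
            {**c, f: lv} for c in other_combos for lv in fit.levels[f]
        ]

    rows: Dict[Tuple[str, ...], np.ndarray] = {}
    for combo in level_combos:
        cell = dict(zip(facs, combo))
        xs = []
        for oc in other_combos:
            full = {**cell, **oc}
            xs.append(
                fit.design_row(full["condition"], full["timepoint"], full["group"])
            )
        rows[combo] = np.mean(xs, axis=0)

    k = len(rows)
    theta_cov = fit._theta_cov()
    reports = []
    for (la, xa), (lb, xb) in combinations(rows.items(), 2):
        d = xa - xb
        est = float(d @ fit.beta)
        se = float(np.sqrt(d @ fit.cov_beta @ d))
        df = fit._satterthwaite_df(d, theta_cov)
        q_obs = abs(est) * np.sqrt(2.0) / se
        p_tukey = float(stats.studentized_range.sf(q_obs, k, df))
        p_raw = float(2.0 * stats.t.sf(abs(est) / se, df))
        q_crit = float(stats.studentized_range.ppf(conf_level, k, df))
        half = q_crit / np.sqrt(2.0) * se
        reports.append(
            PosthocReport(
                contrast=f"{' '.join(la)} - {' '.join(lb)}",
                estimate=est,
                ci_low=est - half,
                ci_high=est + half,
                se=se,
                df=df,
                p_tukey=min(p_tukey, 1.0),
                p_raw=min(p_raw, 1.0),
            )
        )
    return reports


@dataclass(frozen=True)
class WelchReport:
    mean_diff: float
    ci_low: float
    ci_high: float
    t: float
    df: float
    p: float
    shapiro_p: Tuple[float, float]
    levene_p: float
    mannwhitney_p: Optional[float] = None


def welch_compare(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
) -> WelchReport:
    """Welch unequal-variance t comparison of two samples.

    Reports the mean difference a - b with a Welch-Satterthwaite-df 95% CI,
    Shapiro-Wilk and Levene checks, and a Mann-Whitney U p-value alongside
    whenever either sample fails the normality check at ``alpha``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    diff = float(np.mean(a) - np.mean(b))
    if np.var(a) == 0 and np.var(b) == 0:
        # degenerate: no variability at all
        p = 1.0 if diff == 0 else 0.0
        return WelchReport(diff, diff, diff, 0.0, float(a.size + b.size - 2),
                           p, (1.0, 1.0), 1.0, None)
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    sh_a = float(stats.shapiro(a).pvalue)
    sh_b = float(stats.shapiro(b).pvalue)
    lev = float(stats.levene(a, b).pvalue)
    mw = None
    if min(sh_a, sh_b) < alpha:
        mw = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return WelchReport(
        mean_diff=diff,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        shapiro_p=(sh_a, sh_b),
        levene_p=lev,
        mannwhitney_p=mw,
    )


def noncentral_f_power(
    effect_f: float, df1: float, df2: float, n_total: int, alpha: float = 0.05
) -> float:
    """Power of an F test with Cohen's f and noncentrality f^2 * N.

    Documented utility for a-priori sample-size reasoning; the mapping
    from a published effect size to a noncentrality parameter depends on
    the software convention, so treat results as indicative.
    """
    lam = effect_f**2 * n_total
    crit = stats.f.isf(alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, lam))
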