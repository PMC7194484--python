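"""Univariate twin variance decomposition by maximum likelihood.

The classical twin design decomposes phenotypic variance v into additive
genetic (a²), shared-environment (c²) and nonshared-environment (e²)
proportions.  Each complete pair is modelled as bivariate normal with a
common mean and variance across twin order and zygosity; the within-pair
correlation is a² + c² for monozygotic (MZ) pairs and 0.5·a² + c² for
dizygotic (DZ) pairs, because MZ twins share all segregating genes and DZ
twins share half on average.  The full ACE model and its nested AE, CE and
E submodels are fitted by maximising the summed bivariate-normal
log-likelihood, with proportions constrained to [0, 1]; estimates on the
zero boundary are reported as exactly 0.

The module follows the statsmodels Model/Results convention:
``UnivariateTwinModel(...).fit()`` returns a :class:`TwinVarianceResults`
carrying estimates, log-likelihood, profile-likelihood confidence
intervals and a ``summary()`` table.  Moment-based Falconer estimates and
the maximum-likelihood intraclass pair correlation are module functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ..exceptions import ConvergenceError, DegenerateDataError, MalformedInputError
from .data import TwinPairTable, double_entry_values

MODELS = ("ACE", "AE", "CE", "E")
#: free parameters per model: mean, total variance, plus free proportions
N_PARAMS = {"ACE": 4, "AE": 3, "CE": 3, "E": 2}
_BOUNDARY_TOL = 1e-6


# ---------------------------------------------------------------------------
# likelihood machinery (sufficient statistics per zygosity group)

@dataclass
class _GroupStats:
    n: int
    sx: float
    sy: float
    sxx: float
    syy: float
    sxy: float

    @classmethod
    def from_pairs(cls, xy: np.ndarray) -> "_GroupStats":
        x, y = xy[:, 0], xy[:, 1]
        return cls(
            n=len(x),
            sx=float(x.sum()),
            sy=float(y.sum()),
            sxx=float((x * x).sum()),
            syy=float((y * y).sum()),
            sxy=float((x * y).sum()),
        )

    def loglik(self, mu: float, v: float, r: float) -> float:
        if self.n == 0:
            return 0.0
        if v <= 0 or not (-1.0 < r < 1.0):
            return -np.inf
        qxx = self.sxx - 2 * mu * self.sx + self.n * mu * mu
        qyy = self.syy - 2 * mu * self.sy + self.n * mu * mu
        qxy = self.sxy - mu * (self.sx + self.sy) + self.n * mu * mu
        det = v * v * (1 - r * r)
        quad = (qxx + qyy - 2 * r * qxy) / (v * (1 - r * r))
        return -self.n * np.log(2 * np.pi) - 0.5 * self.n * np.log(det) - 0.5 * quad


def _total_loglik(
    groups: list[tuple[_GroupStats, float]], mu: float, v: float, a2: float, c2: float
) -> float:
    """``groups`` holds (stats, genetic sharing k); within-pair r = k·a² + c²."""
    ll = 0.0
    for g, k in groups:
        r = k * a2 + c2
        if r >= 1.0 - 1e-12:
            r = 1.0 - 1e-12
        ll += g.loglik(mu, v, r)
    return ll


# ---------------------------------------------------------------------------
# moment estimators

def falconer_estimates(r_mz: float, r_dz: float, clip: bool = False):
    """Moment-based Falconer decomposition from twin–cotwin correlations.

    a² = 2(rMZ − rDZ); c² = rMZ − a²; e² = 1 − rMZ.  Returned unclipped by
    default; ``clip=True`` truncates each component to [0, 1] and
    renormalises to unit sum (labelled variant, never silently applied).
    """
    if not (-1 <= r_mz <= 1 and -1 <= r_dz <= 1):
        raise MalformedInputError("correlations must lie in [-1, 1]")
    a2 = 2.0 * (r_mz - r_dz)
    c2 = r_mz - a2
    e2 = 1.0 - r_mz
    if not clip:
        return a2, c2, e2
    comps = np.clip([a2, c2, e2], 0.0, 1.0)
    total = comps.sum()
    if total > 0:
        comps = comps / total
    return tuple(float(c) for c in comps)


@dataclass
class PairCorrelation:
    """Twin–cotwin similarity for one zygosity group.

    ``r`` is the maximum-likelihood intraclass correlation under a
    bivariate normal with equal means and variances across twin order,
    with a profile-likelihood CI.  The double-entry Pearson and Spearman
    variants are reported alongside, labelled — never substituted.
    """

    r: float
    ci_low: float
    ci_high: float
    n_pairs: int
    pearson_double_entry: float
    spearman_double_entry: float
    method: str = "ml_icc"

    def __iter__(self):
        return iter((self.r, (self.ci_low, self.ci_high)))


def pair_correlation(
    pairs, phenotype: str | None = None, group: str | None = None, level: float = 0.95
) -> PairCorrelation:
    """ML intraclass twin correlation with profile-likelihood CI.

    ``pairs`` is either an (n, 2) array of complete pairs or a
    :class:`TwinPairTable` (then ``phenotype`` and ``group`` select the
    data).
    """
    if isinstance(pairs, TwinPairTable):
        xy = pairs.values(phenotype, group)
    else:
        xy = np.asarray(pairs, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise MalformedInputError("expected an (n, 2) array of pairs")
    xy = xy[~np.isnan(xy).any(axis=1)]
    if len(xy) < 3:
        raise DegenerateDataError("need at least 3 complete pairs")
    allv = xy.ravel()
    if np.ptp(allv) == 0:
        raise DegenerateDataError("zero variance: correlation undefined")

    g = _GroupStats.from_pairs(xy)
    mu0, v0 = float(allv.mean()), float(allv.var())
    if np.allclose(xy[:, 0], xy[:, 1]):
        # degenerate perfect concordance: the ML correlation is exactly 1
        rho_s = stats.spearmanr(xy[:, 0], xy[:, 1]).statistic
        return PairCorrelation(1.0, 1.0, 1.0, len(xy), 1.0, float(rho_s))

    def nll(theta):
        mu, logv, z = theta
        return -g.loglik(mu, np.exp(logv), np.tanh(z))

    x, yv = xy[:, 0], xy[:, 1]
    r0 = float(np.corrcoef(np.r_[x, yv], np.r_[yv, x])[0, 1])
    r0 = np.clip(r0, -0.99, 0.99)
    res = optimize.minimize(
        nll, [mu0, np.log(v0), np.arctanh(r0)], method="L-BFGS-B"
    )
    mu_hat, logv_hat, z_hat = res.x
    r_hat = float(np.tanh(z_hat))
    ll_max = -res.fun

    crit = stats.chi2.ppf(level, 1)

    def profile_dev(r):
        def nll_r(theta):
            mu, logv = theta
            return -g.loglik(mu, np.exp(logv), r)

        pr = optimize.minimize(nll_r, [mu_hat, logv_hat], method="L-BFGS-B")
        return 2.0 * (ll_max + pr.fun) - crit

    def bound(lo, hi):
        flo, fhi = profile_dev(lo), profile_dev(hi)
        if flo * fhi > 0:
            return lo if flo < fhi else hi
        return float(optimize.brentq(lambda r: profile_dev(r), lo, hi, xtol=1e-6))

    eps = 1e-9
    ci_low = bound(-1 + 1e-6, r_hat - eps) if r_hat > -1 + 1e-5 else -1.0
    ci_high = bound(r_hat + eps, 1 - 1e-6) if r_hat < 1 - 1e-5 else 1.0

    rho_s = stats.spearmanr(np.r_[x, yv], np.r_[yv, x]).statistic
    return PairCorrelation(
        r=r_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        n_pairs=len(xy),
        pearson_double_entry=r0,
        spearman_double_entry=float(rho_s),
    )


# ---------------------------------------------------------------------------
# the Model / Results pair

class UnivariateTwinModel:
    """ACE-family twin model for one continuous phenotype.

    Parameters
    ----------
    mz, dz : (n, 2) arrays
        Complete-pair phenotype values per zygosity group.
    model : {"ACE", "AE", "CE", "E"}
        Which variance components are free; absent components are fixed
        at exactly 0.
    """

    def __init__(self, mz, dz, model: str = "AE"):
        if model not in MODELS:
            raise MalformedInputError(f"unknown model {model!r}")
        self.model = model
        self.mz = self._clean(mz)
        self.dz = self._clean(dz)
        if len(self.mz) < 2 or len(self.dz) < 2:
            raise DegenerateDataError("need >= 2 complete pairs per zygosity group")
        self._groups = [
            (_GroupStats.from_pairs(self.mz), 1.0),
            (_GroupStats.from_pairs(self.dz), 0.5),
        ]
        allv = np.r_[self.mz.ravel(), self.dz.ravel()]
        if np.ptp(allv) == 0:
            raise DegenerateDataError("phenotype has zero variance")
        self._mu0 = float(allv.mean())
        self._v0 = float(allv.var())

    @staticmethod
    def _clean(xy) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise MalformedInputError("expected an (n, 2) array of pairs")
        return xy[~np.isnan(xy).any(axis=1)]

    @classmethod
    def from_table(
        cls, table: TwinPairTable, phenotype: str, model: str = "AE"
    ) -> "UnivariateTwinModel":
        return cls(
            table.values(phenotype, "MZ"), table.values(phenotype, "DZ"), model=model
        )

    # -- parameter packing: theta = (mu, log v [, u1 [, u2]]) -------------
    def _unpack(self, theta) -> tuple[float, float, float, float]:
        mu, logv = theta[0], theta[1]
        v = float(np.exp(logv))
        if self.model == "ACE":
            u1, u2 = theta[2], theta[3]
            a2 = u1
            c2 = (1.0 - u1) * u2
        elif self.model == "AE":
            a2, c2 = theta[2], 0.0
        elif self.model == "CE":
            a2, c2 = 0.0, theta[2]
        else:  # E
            a2, c2 = 0.0, 0.0
        return float(mu), v, float(a2), float(c2)

    def loglike(self, theta) -> float:
        mu, v, a2, c2 = self._unpack(theta)
        return _total_loglik(self._groups, mu, v, a2, c2)

    def loglike_components(self, mu: float, v: float, a2: float, c2: float) -> float:
        """Log-likelihood at explicit component values (used by profiling
        and by the brute-force equivalence tests)."""
        return _total_loglik(self._groups, mu, v, a2, c2)

    def _starts(self, restarts: int, seed: int):
        # moment start: Falconer from group Pearson correlations
        def grp_r(xy):
            x, y = xy[:, 0], xy[:, 1]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = np.corrcoef(np.r_[x, y], np.r_[y, x])[0, 1]
            return 0.0 if not np.isfinite(r) else float(np.clip(r, -0.9, 0.9))

        rmz, rdz = grp_r(self.mz), grp_r(self.dz)
        a2_0 = float(np.clip(2 * (rmz - rdz), 0.05, 0.9))
        c2_0 = float(np.clip(rmz - a2_0, 0.05, 0.9))
        base = [self._mu0, np.log(self._v0)]
        if self.model == "ACE":
            u2 = c2_0 / max(1.0 - a2_0, 1e-6)
            base += [a2_0, float(np.clip(u2, 0.05, 0.95))]
        elif self.model == "AE":
            base += [float(np.clip(rmz, 0.05, 0.9))]
        elif self.model == "CE":
            base += [float(np.clip((rmz + rdz) / 2, 0.05, 0.9))]
        starts = [np.array(base)]
        rng = np.random.default_rng(seed)
        for _ in range(restarts - 1):
            jit = np.array(base, dtype=float)
            jit[0] += rng.normal(0, 0.2) * np.sqrt(self._v0)
            jit[1] += rng.normal(0, 0.3)
            for i in range(2, len(jit)):
                jit[i] = rng.uniform(0.02, 0.98)
            starts.append(jit)
        return starts

    def fit(self, restarts: int = 5, restart_seed: int = 1234) -> "TwinVarianceResults":
        """Maximise the likelihood with bounded quasi-Newton and jittered
        restarts (boundary estimates such as a²=0 are common)."""
        bounds = [(None, None), (None, None)] + [(0.0, 1.0)] * (
            N_PARAMS[self.model] - 2
        )
        best = None
        for x0 in self._starts(restarts, restart_seed):
            res = optimize.minimize(
                lambda th: -self.loglike(th),
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError(f"{self.model} fit failed to converge")
        mu, v, a2, c2 = self._unpack(best.x)
        # snap boundary estimates to exact zero
        if a2 < _BOUNDARY_TOL:
            a2 = 0.0
        if c2 < _BOUNDARY_TOL:
            c2 = 0.0
        e2 = 1.0 - a2 - c2
        loglik = self.loglike_components(mu, v, a2, c2)
        return TwinVarianceResults(
            model=self.model,
            a2=a2,
            c2=c2,
            e2=e2,
            total_variance=v,
            mean=mu,
            loglik=float(loglik),
            n_mz=len(self.mz),
            n_dz=len(self.dz),
            converged=bool(best.success),
            n_params=N_PARAMS[self.model],
            _model=self,
        )


@dataclass
class TwinVarianceResults:
    """Fitted variance decomposition; components are proportions of the
    total phenotypic variance and sum to 1."""

    model: str
    a2: float
    c2: float
    e2: float
    total_variance: float
    mean: float
    loglik: float
    n_mz: int
    n_dz: int
    converged: bool
    n_params: int
    _model: UnivariateTwinModel = dc_field(repr=False, default=None)

    @property
    def implied_r_mz(self) -> float:
        return self.a2 + self.c2

    @property
    def implied_r_dz(self) -> float:
        return 0.5 * self.a2 + self.c2

    def profile_ci(self, component: str = "a2", level: float = 0.95):
        """Profile-likelihood interval for one variance proportion.

        Bounds solve 2·Δloglik = χ²(1) quantile, truncated at [0, 1]; the
        lower bound is reported as 0 whenever the boundary lies inside.
        """
        free = {"ACE": ("a2", "c2"), "AE": ("a2",), "CE": ("c2",), "E": ()}[self.model]
        if component not in free:
            raise DegenerateDataError(
                f"{component} is fixed at 0 in the {self.model} model; "
                "its profile interval is undefined"
            )
        model = self._model
        crit = stats.chi2.ppf(level, 1)
        hat = getattr(self, component)

        def prof_loglik(val: float) -> float:
            def nll(theta):
                mu, logv = theta[0], theta[1]
                v = np.exp(logv)
                if component == "a2":
                    a2 = val
                    c2 = theta[2] if self.model == "ACE" else 0.0
                else:
                    c2 = val
                    a2 = theta[2] if self.model == "ACE" else 0.0
                if a2 + c2 > 1 - 1e-9:
                    return np.inf
                return -model.loglike_components(mu, v, a2, c2)

            other0 = []
            if self.model == "ACE":
                other_hat = self.c2 if component == "a2" else self.a2
                other0 = [float(np.clip(other_hat, 0.0, max(1 - val - 1e-6, 0.0)))]
            x0 = [self.mean, np.log(self.total_variance)] + other0
            bounds = [(None, None), (None, None)] + [
                (0.0, max(1 - val - 1e-9, 0.0))
            ] * len(other0)
            res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
            return -float(res.fun)

        def dev(val: float) -> float:
            return 2.0 * (self.loglik - prof_loglik(val)) - crit

        def solve(lo: float, hi: float, fallback: float) -> float:
            flo, fhi = dev(lo), dev(hi)
            if flo * fhi > 0:
                return fallback
            return float(optimize.brentq(dev, lo, hi, xtol=1e-5))

        low = 0.0 if hat < 1e-9 or dev(0.0) <= 0 else solve(0.0, hat, 0.0)
        high = 1.0 if hat > 1 - 1e-9 or dev(1.0 - 1e-9) <= 0 else solve(
            hat, 1.0 - 1e-9, 1.0
        )
        return low, high

    def compare(self, reduced: "TwinVarianceResults", mixture: bool = False):
        return compare_models(self, reduced, mixture=mixture)

    def summary(self) -> str:
        lines = [
            f"Twin variance decomposition ({self.model} model, ML)",
            f"  pairs: {self.n_mz} MZ, {self.n_dz} DZ   loglik: {self.loglik:.3f}",
            f"  mean: {self.mean:.4f}   total variance: {self.total_variance:.4f}",
            f"  a2 = {self.a2:.4f}   c2 = {self.c2:.4f}   e2 = {self.e2:.4f}",
            f"  implied rMZ = {self.implied_r_mz:.4f}   rDZ = {self.implied_r_dz:.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "a2": self.a2,
            "c2": self.c2,
            "e2": self.e2,
            "total_variance": self.total_variance,
            "mean": self.mean,
            "loglik": self.loglik,
            "n_mz": self.n_mz,
            "n_dz": self.n_dz,
        }


def compare_models(
    full: TwinVarianceResults, reduced: TwinVarianceResults, mixture: bool = False
):
    """Likelihood-ratio test of nested twin models fitted to the same data.

    Returns (chi-square, df, p).  With ``mixture=True`` the 50:50
    chi²(0):chi²(1) boundary reference is used (df must be 1); the default
    is the standard chi²(df) upper tail.
    """
    if reduced.n_params >= full.n_params:
        raise MalformedInputError("reduced model must have fewer parameters")
    if (reduced.n_mz, reduced.n_dz) != (full.n_mz, full.n_dz):
        raise MalformedInputError("models must be fitted to identical data")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-6:
        raise ConvergenceError(
            f"reduced model fits better (LRT={stat:.3g}); refit with more restarts"
        )
    stat = max(stat, 0.0)
    df = full.n_params - reduced.n_params
    if mixture:
        if df != 1:
            raise MalformedInputError("mixture reference defined for df=1 only")
        p = 1.0 if stat == 0 else 0.5 * stats.chi2.sf(stat, 1)
    else:
        p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return float(stat), int(df), float(p)


def residualize(df: pd.DataFrame, phenotype: str, covariates: list[str]) -> pd.Series:
    """OLS-residualise a phenotype on covariates (e.g. age, sex) as an
    optional pre-step; returns residuals aligned to ``df``."""
    import statsmodels.api as sm

    sub = df[[phenotype] + covariates].dropna()
    X = sm.add_constant(pd.get_dummies(sub[covariates], drop_first=True, dtype=float))
    fitted = sm.OLS(sub[phenotype].astype(float), X).fit()
    out = pd.Series(np.nan, index=df.index, name=phenotype)
    out.loc[sub.index] = fitted.resid
    return out
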