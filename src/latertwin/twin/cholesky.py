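"""Trivariate Cholesky AE model for twin data.

Three phenotypes per twin (fixed order: EHI, QHP, LI) are modelled with
triangular additive-genetic and nonshared-environment factor structures:
per twin y = μ + L_A·f_A + L_E·f_E with lower-triangular 3×3 path
matrices, within-twin covariance W = L_A·L_Aᵀ + L_E·L_Eᵀ and cross-twin
covariance k·L_A·L_Aᵀ with k = 1 for MZ and 0.5 for DZ pairs.  The model
is fitted by full-information maximum likelihood over the observed blocks
of each pair's 6-vector, so pairs with missing phenotypes still
contribute.  Reported estimates are unsquared standardized paths (each
row of L divided by the trait's implied SD) with standard errors from the
observed information matrix via the delta method.

The triangular parameterisation keeps the implied covariance positive
semi-definite for any parameter value; path signs are normalised after
fitting so the diagonals are non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ..exceptions import ConvergenceError, DegenerateDataError, MalformedInputError
from .data import TwinPairTable

_TRIL = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]
_LOG2PI = np.log(2.0 * np.pi)


def _unpack(theta: np.ndarray):
    mu = theta[:3]
    la = np.zeros((3, 3))
    le = np.zeros((3, 3))
    for i, (r, c) in enumerate(_TRIL):
        la[r, c] = theta[3 + i]
        le[r, c] = theta[9 + i]
    return mu, la, le


def _pack(mu, la, le) -> np.ndarray:
    return np.concatenate(
        [mu, [la[r, c] for r, c in _TRIL], [le[r, c] for r, c in _TRIL]]
    )


def _pattern_loglik(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Summed MVN log-density for rows of x under one missingness pattern."""
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return -np.inf
    dev = x - mean
    sol = np.linalg.solve(chol, dev.T)
    quad = (sol**2).sum()
    n, p = x.shape
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (n * p * _LOG2PI + n * logdet + quad)


class CholeskyAEModel:
    """Trivariate AE Cholesky model; see the module docstring."""

    def __init__(
        self, table: TwinPairTable, phenotypes: tuple[str, str, str] = ("ehi", "qhp", "li")
    ):
        if len(phenotypes) != 3:
            raise MalformedInputError("exactly three phenotypes, ordered")
        self.phenotypes = tuple(phenotypes)
        self._data: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
        cols = [f"{p}_{t}" for t in (1, 2) for p in phenotypes]
        self._n_pairs = {}
        for zyg in ("MZ", "DZ"):
            df = table.pairs.loc[table.pairs["zygosity"] == zyg, cols]
            mat = df.to_numpy(dtype=float)
            mat = mat[~np.isnan(mat).all(axis=1)]
            self._n_pairs[zyg] = len(mat)
            if len(mat) < 30:
                raise DegenerateDataError(
                    f"need >= 30 {zyg} pairs with trivariate data, have {len(mat)}"
                )
            # group rows by missingness pattern for vectorised FIML
            patterns: dict[tuple, list[int]] = {}
            for i, row in enumerate(mat):
                patterns.setdefault(tuple(np.isfinite(row)), []).append(i)
            groups = []
            for pat, idx in patterns.items():
                obs = np.flatnonzero(pat)
                if len(obs) == 0:
                    continue
                groups.append((obs, mat[np.ix_(idx, obs)]))
            self._data[zyg] = groups
        obs_all = np.vstack(
            [
                table.pairs[[f"{p}_1" for p in phenotypes]].to_numpy(dtype=float),
                table.pairs[[f"{p}_2" for p in phenotypes]].to_numpy(dtype=float),
            ]
        )
        self._mu0 = np.nanmean(obs_all, axis=0)
        self._cov0 = np.ma.cov(np.ma.masked_invalid(obs_all), rowvar=False).data

    @property
    def n_params(self) -> int:
        return 15

    def loglike(self, theta: np.ndarray) -> float:
        mu, la, le = _unpack(theta)
        a = la @ la.T
        e = le @ le.T
        w = a + e
        mean6 = np.concatenate([mu, mu])
        ll = 0.0
        for zyg, k in (("MZ", 1.0), ("DZ", 0.5)):
            sigma = np.block([[w, k * a], [k * a, w]])
            sigma = sigma + 1e-10 * np.eye(6)
            for obs, rows in self._data[zyg]:
                ll += _pattern_loglik(rows, mean6[obs], sigma[np.ix_(obs, obs)])
            if not np.isfinite(ll):
                return -np.inf
        return float(ll)

    def fit(self, restarts: int = 3, restart_seed: int = 99) -> "CholeskyAEResults":
        cov0 = self._cov0 + 1e-6 * np.eye(3)
        try:
            la0 = np.linalg.cholesky(0.3 * cov0)
            le0 = np.linalg.cholesky(0.7 * cov0)
        except np.linalg.LinAlgError:
            sd = np.sqrt(np.diag(cov0))
            la0 = np.diag(0.55 * sd)
            le0 = np.diag(0.84 * sd)
        x0 = _pack(self._mu0, la0, le0)
        rng = np.random.default_rng(restart_seed)
        best = None
        for trial in range(restarts):
            start = x0 if trial == 0 else x0 * rng.uniform(0.7, 1.3, size=x0.shape)
            res = optimize.minimize(
                lambda th: -self.loglike(th), start, method="L-BFGS-B",
                options={"maxiter": 2000},
            )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-9):
                best = res
        if best is None:
            raise ConvergenceError("Cholesky AE fit failed to converge")
        theta = best.x.copy()
        mu, la, le = _unpack(theta)
        # sign normalisation: L and L·D imply the same covariance
        for mat in (la, le):
            for j in range(3):
                if mat[j, j] < 0:
                    mat[:, j] *= -1.0
        theta = _pack(mu, la, le)
        return CholeskyAEResults(self, theta, float(-best.fun), bool(best.success))


@dataclass
class CholeskyAEResults:
    model: CholeskyAEModel
    params: np.ndarray
    loglik: float
    converged: bool

    def __post_init__(self) -> None:
        mu, la, le = _unpack(self.params)
        self.means = mu
        self.paths_a = la
        self.paths_e = le
        w = la @ la.T + le @ le.T
        self._sd = np.sqrt(np.diag(w))
        self.paths_a_std = la / self._sd[:, None]
        self.paths_e_std = le / self._sd[:, None]
        self._se_std = None

    @property
    def n_mz(self) -> int:
        return self.model._n_pairs["MZ"]

    @property
    def n_dz(self) -> int:
        return self.model._n_pairs["DZ"]

    def _std_vector(self, theta: np.ndarray) -> np.ndarray:
        mu, la, le = _unpack(theta)
        w = la @ la.T + le @ le.T
        sd = np.sqrt(np.diag(w))
        vals = [la[r, c] / sd[r] for r, c in _TRIL] + [
            le[r, c] / sd[r] for r, c in _TRIL
        ]
        return np.array(vals)

    def standard_errors(self) -> tuple[np.ndarray, np.ndarray]:
        """SEs of the standardized paths (observed information + delta
        method); returned as lower-triangular 3×3 matrices for A and E."""
        if self._se_std is None:
            from statsmodels.tools.numdiff import approx_fprime, approx_hess

            hess = approx_hess(self.params, lambda th: -self.model.loglike(th))
            cov = np.linalg.pinv(hess)
            jac = approx_fprime(self.params, self._std_vector, centered=True)
            var = np.einsum("ij,jk,ik->i", jac, cov, jac)
            se = np.sqrt(np.clip(var, 0, None))
            se_a = np.zeros((3, 3))
            se_e = np.zeros((3, 3))
            for i, (r, c) in enumerate(_TRIL):
                se_a[r, c] = se[i]
                se_e[r, c] = se[6 + i]
            self._se_std = (se_a, se_e)
        return self._se_std

    def summary(self) -> str:
        se_a, se_e = self.standard_errors()
        names = self.model.phenotypes
        lines = [
            "Trivariate Cholesky AE model (FIML)",
            f"  pairs: {self.n_mz} MZ, {self.n_dz} DZ   loglik: {self.loglik:.3f}",
            "  unsquared standardized paths (SE):",
        ]
        for label, paths, se in (("A", self.paths_a_std, se_a), ("E", self.paths_e_std, se_e)):
            for r in range(3):
                cells = "  ".join(
                    f"{paths[r, c]:7.3f} ({se[r, c]:.3f})" for c in range(r + 1)
                )
                lines.append(f"    {label} {names[r]:>4}: {cells}")
        return "\n".join(lines)
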