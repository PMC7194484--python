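"""Twin-pair phenotype generator under known variance components.

The generative model is the ACE decomposition itself: per pair draw an
additive-genetic factor with cross-twin correlation 1 (MZ) or 0.5 (DZ), a
shared-environment factor common to both twins, and independent
nonshared factors; the latent phenotype is

    y = sqrt(a2)·A + sqrt(c2)·C + sqrt(e2)·E,

a standard-normal marginal with within-pair correlation a²+c² (MZ) or
0.5·a²+c² (DZ).  An optional frozen monotone quantile map produces a
J-shaped, bounded, handedness-inventory-like marginal while preserving
the rank-based familial structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ..exceptions import MalformedInputError
from ..twin.data import TwinPairTable

#: frozen J-shape constants (versioned; tests depend on them being stable).
#: score = scale_max * Phi(y)**JSHAPE_EXPONENT piles mass at the right-handed
#: end of a bounded 0..scale_max scale, mimicking preference inventories.
JSHAPE_EXPONENT = 0.25
JSHAPE_SCALE_MAX = 10.0


@dataclass
class TwinSimConfig:
    n_mz: int
    n_dz: int
    a2: float
    c2: float
    e2: float
    marginal: str = "normal"  # "normal" | "jshape"
    mean: float = 0.0
    sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        comps = np.array([self.a2, self.c2, self.e2], dtype=float)
        if (comps < 0).any() or abs(comps.sum() - 1.0) > 1e-8:
            raise MalformedInputError("a2, c2, e2 must be >= 0 and sum to 1")
        if self.marginal not in ("normal", "jshape"):
            raise MalformedInputError(f"unknown marginal {self.marginal!r}")


@dataclass
class TwinSimTruth:
    """Ground-truth record stored alongside every simulated table."""

    a2: float
    c2: float
    e2: float
    marginal: str
    seed: int
    latent: pd.DataFrame = field(repr=False, default=None)


def jshape_map(y: np.ndarray) -> np.ndarray:
    """Frozen monotone map from a standard-normal latent scale to a
    J-shaped bounded 0..10 scale."""
    return JSHAPE_SCALE_MAX * stats.norm.cdf(y) ** JSHAPE_EXPONENT


def simulate_twin_phenotypes(
    cfg: TwinSimConfig, phenotype: str = "pheno"
) -> tuple[TwinPairTable, TwinSimTruth]:
    """Simulate a twin cohort under the configured variance components."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    latent_rows = []
    fam = 0
    for zyg, n, k in (("MZ", cfg.n_mz, 1.0), ("DZ", cfg.n_dz, 0.5)):
        a_shared = rng.standard_normal(n)
        a_extra = rng.standard_normal((n, 2))
        c = rng.standard_normal(n)
        e = rng.standard_normal((n, 2))
        sqk = np.sqrt(k)
        sq1k = np.sqrt(1.0 - k)
        for i in range(n):
            fam += 1
            pair_vals = []
            for t in range(2):
                a_t = sqk * a_shared[i] + sq1k * a_extra[i, t]
                y = (
                    np.sqrt(cfg.a2) * a_t
                    + np.sqrt(cfg.c2) * c[i]
                    + np.sqrt(cfg.e2) * e[i, t]
                )
                pair_vals.append(y)
            latent_rows.append(
                {"family_id": f"F{fam:05d}", "zygosity": zyg,
                 "y1": pair_vals[0], "y2": pair_vals[1]}
            )
            if cfg.marginal == "jshape":
                obs = jshape_map(np.array(pair_vals))
            else:
                obs = cfg.mean + cfg.sd * np.array(pair_vals)
            rows.append(
                {
                    "family_id": f"F{fam:05d}",
                    "zygosity": zyg,
                    "sex_pair": "FF",
                    f"{phenotype}_1": obs[0],
                    f"{phenotype}_2": obs[1],
                }
            )
    table = TwinPairTable(pd.DataFrame(rows), phenotypes=[phenotype])
    truth = TwinSimTruth(
        a2=cfg.a2, c2=cfg.c2, e2=cfg.e2, marginal=cfg.marginal, seed=cfg.seed,
        latent=pd.DataFrame(latent_rows),
    )
    return table, truth


def simulate_trivariate_ae(
    n_mz: int,
    n_dz: int,
    paths_a: np.ndarray,
    paths_e: np.ndarray,
    means: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[TwinPairTable, dict]:
    """Simulate three phenotypes per twin under a triangular (Cholesky) AE
    factor structure with lower-triangular path matrices ``paths_a`` and
    ``paths_e`` (3x3).  Cross-twin genetic covariance is scaled 1 (MZ) or
    0.5 (DZ)."""
    la = np.asarray(paths_a, dtype=float)
    le = np.asarray(paths_e, dtype=float)
    if la.shape != (3, 3) or le.shape != (3, 3):
        raise MalformedInputError("path matrices must be 3x3")
    mu = np.zeros(3) if means is None else np.asarray(means, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    fam = 0
    names = ["ehi", "qhp", "li"]
    for zyg, n, k in (("MZ", n_mz, 1.0), ("DZ", n_dz, 0.5)):
        for _ in range(n):
            fam += 1
            fa_shared = rng.standard_normal(3)
            fa_extra = rng.standard_normal((2, 3))
            row = {"family_id": f"F{fam:05d}", "zygosity": zyg, "sex_pair": "FF"}
            for t in range(2):
                fa = np.sqrt(k) * fa_shared + np.sqrt(1 - k) * fa_extra[t]
                fe = rng.standard_normal(3)
                y = mu + la @ fa + le @ fe
                for j, name in enumerate(names):
                    row[f"{name}_{t + 1}"] = y[j]
            rows.append(row)
    table = TwinPairTable(pd.DataFrame(rows), phenotypes=names)
    truth = {"paths_a": la, "paths_e": le, "means": mu, "seed": seed}
    return table, truth
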