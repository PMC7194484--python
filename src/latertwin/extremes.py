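"""DeFries–Fulker-style extremes analysis.

If extreme scores have a genetic basis, cotwins of extreme-scoring
probands regress toward the population mean, and less so for MZ than for
DZ pairs (MZ cotwins share all segregating genes, DZ cotwins half on
average).  The test implemented here selects probands past a caller-given
cutoff and compares the cotwin scores of MZ versus DZ probands with a
Welch two-sample t-test (Satterthwaite degrees of freedom).

Double-entry convention: every twin past the cutoff is a proband and
contributes their cotwin, so a pair where both qualify enters twice; a
single-entry variant (first qualifying twin only) sits behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateDataError, MalformedInputError
from .twin.data import TwinPairTable


@dataclass
class ExtremesResult:
    phenotype: str
    cutoff: float
    direction: str
    n_probands_mz: int
    n_probands_dz: int
    proband_mean_mz: float
    proband_sd_mz: float
    proband_mean_dz: float
    proband_sd_dz: float
    cotwin_mean_mz: float
    cotwin_sd_mz: float
    cotwin_mean_dz: float
    cotwin_sd_dz: float
    t: float
    df: float
    p: float
    double_entry: bool = True

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def summary(self) -> str:
        return (
            f"Extremes analysis ({self.phenotype}, {self.direction} {self.cutoff:g}, "
            f"{'double' if self.double_entry else 'single'}-entry probands)\n"
            f"  probands: {self.n_probands_mz} MZ, {self.n_probands_dz} DZ\n"
            f"  proband mean (SD): MZ {self.proband_mean_mz:.2f} "
            f"({self.proband_sd_mz:.2f}), DZ {self.proband_mean_dz:.2f} "
            f"({self.proband_sd_dz:.2f})\n"
            f"  cotwin mean (SD):  MZ {self.cotwin_mean_mz:.2f} "
            f"({self.cotwin_sd_mz:.2f}), DZ {self.cotwin_mean_dz:.2f} "
            f"({self.cotwin_sd_dz:.2f})\n"
            f"  Welch t = {self.t:.2f}, df = {self.df:.1f}, p = {self.p:.3f}"
        )


#: documented default cutoffs; callers should state their own
DEFAULT_CUTOFFS = {"ehi": (4.0, "below"), "qhp": (14.0, "below"), "li_mean": (0.0, "below")}


def _select(values: np.ndarray, cutoff: float, direction: str) -> np.ndarray:
    if direction == "below":
        return values < cutoff
    if direction == "above":
        return values > cutoff
    raise MalformedInputError("direction must be 'below' or 'above'")


def extremes_ttest(
    table: TwinPairTable,
    phenotype: str,
    cutoff: float,
    direction: str = "below",
    double_entry: bool = True,
) -> ExtremesResult:
    """Welch t-test comparing MZ vs DZ cotwin scores of extreme probands."""
    probands: dict[str, list[float]] = {"MZ": [], "DZ": []}
    cotwins: dict[str, list[float]] = {"MZ": [], "DZ": []}
    for zyg in ("MZ", "DZ"):
        xy = table.values(phenotype, zyg)
        for x1, x2 in xy:
            hits = []
            if _select(np.array([x1]), cutoff, direction)[0]:
                hits.append((x1, x2))
            if _select(np.array([x2]), cutoff, direction)[0]:
                hits.append((x2, x1))
            if not double_entry and len(hits) == 2:
                hits = hits[:1]
            for pro, co in hits:
                probands[zyg].append(pro)
                cotwins[zyg].append(co)
    n_mz, n_dz = len(probands["MZ"]), len(probands["DZ"])
    if n_mz < 2 or n_dz < 2:
        raise DegenerateDataError(
            f"cutoff yields {n_mz} MZ / {n_dz} DZ probands; need >= 2 per group"
        )
    co_mz = np.asarray(cotwins["MZ"])
    co_dz = np.asarray(cotwins["DZ"])
    welch = stats.ttest_ind(co_mz, co_dz, equal_var=False)
    return ExtremesResult(
        phenotype=phenotype,
        cutoff=cutoff,
        direction=direction,
        n_probands_mz=n_mz,
        n_probands_dz=n_dz,
        proband_mean_mz=float(np.mean(probands["MZ"])),
        proband_sd_mz=float(np.std(probands["MZ"], ddof=1)),
        proband_mean_dz=float(np.mean(probands["DZ"])),
        proband_sd_dz=float(np.std(probands["DZ"], ddof=1)),
        cotwin_mean_mz=float(co_mz.mean()),
        cotwin_sd_mz=float(co_mz.std(ddof=1)),
        cotwin_mean_dz=float(co_dz.mean()),
        cotwin_sd_dz=float(co_dz.std(ddof=1)),
        t=float(welch.statistic),
        df=float(welch.df),
        p=float(welch.pvalue),
        double_entry=double_entry,
    )
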