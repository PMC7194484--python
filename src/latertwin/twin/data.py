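"""Twin-pair phenotype tables and double-entry I/O.

The canonical in-memory container is a *wide* pandas DataFrame with one row
per pair:

    family_id, zygosity ("MZ"/"DZ"), sex_pair ("FF"/"MM"/"MF"),
    <pheno>_1, <pheno>_2  for each phenotype column

The field's interchange format is the *double-entry* (long) table, in which
every pair appears under both twin orderings so that pairwise statistics are
symmetric in twin order.  Converters between the two layouts live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..exceptions import MalformedInputError

ZYGOSITIES = ("MZ", "DZ")

#: columns of the study-shaped double-entry CSV
DOUBLE_ENTRY_COLUMNS = [
    "family_id",
    "zygosity",
    "twin_order",
    "sex",
    "ehi",
    "qhp",
    "li_mean",
    "li_peak",
    "binary_typical",
    "mean_left_flow",
    "mean_right_flow",
]


@dataclass
class TwinPairTable:
    """One row per twin pair, wide layout; phenotype columns come in
    ``<name>_1`` / ``<name>_2`` sibling pairs."""

    pairs: pd.DataFrame
    phenotypes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.pairs
        for col in ("family_id", "zygosity"):
            if col not in df.columns:
                raise MalformedInputError(f"pair table needs column {col!r}")
        bad = set(df["zygosity"]) - set(ZYGOSITIES)
        if bad:
            raise MalformedInputError(f"unknown zygosity values: {sorted(bad)}")
        if not self.phenotypes:
            self.phenotypes = sorted(
                {
                    c[:-2]
                    for c in df.columns
                    if c.endswith("_1") and f"{c[:-2]}_2" in df.columns
                }
            )
        for p in self.phenotypes:
            for suffix in ("_1", "_2"):
                if p + suffix not in df.columns:
                    raise MalformedInputError(f"missing column {p + suffix!r}")

    def complete_pairs(self, phenotype: str) -> pd.DataFrame:
        """Rows where both twins have the phenotype (listwise per phenotype)."""
        df = self.pairs
        mask = df[f"{phenotype}_1"].notna() & df[f"{phenotype}_2"].notna()
        return df.loc[mask]

    def values(self, phenotype: str, zygosity: str) -> np.ndarray:
        """(n, 2) array of complete pairs for one zygosity group."""
        df = self.complete_pairs(phenotype)
        df = df.loc[df["zygosity"] == zygosity]
        return df[[f"{phenotype}_1", f"{phenotype}_2"]].to_numpy(dtype=float)

    def n_pairs(self, phenotype: str, zygosity: str) -> int:
        return len(self.values(phenotype, zygosity))

    def to_double_entry(self) -> pd.DataFrame:
        """Long table with each pair entered under both orderings."""
        rows = []
        for _, r in self.pairs.iterrows():
            for order in (1, 2):
                row = {
                    "family_id": r["family_id"],
                    "zygosity": r["zygosity"],
                    "twin_order": order,
                }
                if "sex_pair" in r.index:
                    sp = str(r["sex_pair"])
                    row["sex"] = sp[order - 1] if len(sp) == 2 else ""
                for p in self.phenotypes:
                    row[p] = r[f"{p}_{order}"]
                rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_double_entry(cls, df: pd.DataFrame) -> "TwinPairTable":
        """Rebuild the wide table from a double-entry (or single-entry long)
        frame with ``family_id``, ``zygosity``, ``twin_order`` columns."""
        for col in ("family_id", "zygosity", "twin_order"):
            if col not in df.columns:
                raise MalformedInputError(f"double-entry table needs {col!r}")
        meta = {"family_id", "zygosity", "twin_order", "sex"}
        phenos = [c for c in df.columns if c not in meta]
        rows = []
        for fam, g in df.groupby("family_id", sort=False):
            g = g.drop_duplicates(subset="twin_order").set_index("twin_order")
            if not {1, 2}.issubset(g.index):
                raise MalformedInputError(f"family {fam!r} lacks both twins")
            row: dict = {"family_id": fam, "zygosity": g.loc[1, "zygosity"]}
            if "sex" in df.columns:
                row["sex_pair"] = f"{g.loc[1, 'sex']}{g.loc[2, 'sex']}"
            for p in phenos:
                row[f"{p}_1"] = g.loc[1, p]
                row[f"{p}_2"] = g.loc[2, p]
            rows.append(row)
        return cls(pd.DataFrame(rows), phenotypes=phenos)

    def to_csv(self, path) -> None:
        self.to_double_entry().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TwinPairTable":
        return cls.from_double_entry(pd.read_csv(path))


def double_entry_values(pairs: pd.DataFrame, phenotype: str) -> tuple[np.ndarray, np.ndarray]:
    """Double-entry vectors (x, y): every complete pair contributes both
    orderings.  Used for the labelled Pearson/Spearman correlation variants."""
    a = pairs[f"{phenotype}_1"].to_numpy(dtype=float)
    b = pairs[f"{phenotype}_2"].to_numpy(dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    return np.concatenate([a, b]), np.concatenate([b, a])
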