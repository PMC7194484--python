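"""End-to-end study runner: simulate/process → phenotype table → fits →
power → extremes, with report tables shaped like a twin-study results
section (univariate heritability table, multivariate path table, extreme
proband table, power curve).

Everything is driven by a :class:`RunConfig` (YAML, versioned schema);
the effective configuration is serialised into every output directory
and a fixed seed makes re-runs byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import DegenerateDataError, LatertwinError, MalformedInputError
from .extremes import DEFAULT_CUTOFFS, extremes_ttest
from .ftcd import (
    ProcessingConfig,
    apply_sample_exclusions,
    process_recording,
    split_half_reliability,
    subjects_frame,
    trial_li_frame,
    write_subject_summaries,
)
from .ftcd.types import PeriodOfInterest
from .power import power_curve
from .simulate import (
    DopplerSimConfig,
    TwinSimConfig,
    simulate_doppler_session,
    simulate_twin_phenotypes,
)
from .twin import (
    CholeskyAEModel,
    TwinPairTable,
    UnivariateTwinModel,
    compare_models,
    pair_correlation,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of a full simulated-study run."""

    seed: int = 7
    n_mz: int = 65
    n_dz: int = 76
    # variance components of the latent laterality trait
    li_a2: float = 0.0
    li_c2: float = 0.0
    # laterality scale: population mean and SD of the true per-subject LI
    li_mean: float = 2.5
    li_sd: float = 1.5
    # handedness traits (J-shaped marginals)
    ehi_a2: float = 0.25
    ehi_c2: float = 0.0
    qhp_a2: float = 0.18
    qhp_c2: float = 0.0
    n_trials: int = 24
    doppler: dict = field(default_factory=dict)  # DopplerSimConfig overrides
    processing: dict = field(default_factory=dict)  # ProcessingConfig overrides
    power_n_grid: tuple = (60, 100, 140, 180, 220)
    power_a2_values: tuple = (0.15, 0.25, 0.35)
    power_alpha: float = 0.05
    extremes_cutoffs: dict = field(default_factory=dict)
    run_cholesky: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        version = raw.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise MalformedInputError(f"unsupported config schema {version}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise MalformedInputError(f"unknown config keys: {sorted(unknown)}")
        for key in ("power_n_grid", "power_a2_values"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = {"schema_version": SCHEMA_VERSION, **asdict(self)}
        d["power_n_grid"] = list(self.power_n_grid)
        d["power_a2_values"] = list(self.power_a2_values)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _processing_config(cfg: RunConfig) -> ProcessingConfig:
    over = dict(cfg.processing)
    poi = over.pop("poi", None)
    pc = ProcessingConfig(**over)
    if poi:
        pc.poi = PeriodOfInterest(**poi)
    return pc


def run_study(cfg: RunConfig, out_dir) -> dict:
    """Run the full chain and write the report bundle under ``out_dir``.

    Returns the JSON-ready summary dict.  Deterministic for a fixed
    config: re-running byte-reproduces all numeric outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    seeds = np.random.SeedSequence(cfg.seed).generate_state(8)
    pc = _processing_config(cfg)

    # -- stage 1: latent laterality trait per twin -------------------------
    stage = "simulate_twins"
    try:
        li_cfg = TwinSimConfig(
            n_mz=cfg.n_mz, n_dz=cfg.n_dz,
            a2=cfg.li_a2, c2=cfg.li_c2, e2=1 - cfg.li_a2 - cfg.li_c2,
            mean=cfg.li_mean, sd=cfg.li_sd, seed=int(seeds[0]),
        )
        li_table, _ = simulate_twin_phenotypes(li_cfg, phenotype="true_li")
        log(f"simulated {cfg.n_mz} MZ + {cfg.n_dz} DZ pairs (latent LI)")

        # -- stage 2: one Doppler session per twin, through the pipeline --
        stage = "ftcd_process"
        epochs_by_subject = {}
        subjects = []
        subj_meta = []
        session_seed = int(seeds[1])
        for _, row in li_table.pairs.iterrows():
            for t in (1, 2):
                sid = f"{row['family_id']}_{t}"
                session_seed += 1
                dcfg = DopplerSimConfig(
                    n_trials=cfg.n_trials,
                    response_delta=float(row[f"true_li_{t}"]),
                    seed=session_seed,
                    **cfg.doppler,
                )
                rec, _ = simulate_doppler_session(dcfg, subject_id=sid)
                epochs, subject = process_recording(rec, pc)
                epochs_by_subject[sid] = epochs
                subjects.append(subject)
                subj_meta.append(
                    {"subject_id": sid, "family_id": row["family_id"],
                     "zygosity": row["zygosity"], "twin_order": t}
                )
        subjects = apply_sample_exclusions(subjects, sd_limit=pc.sd_limit)
        n_excl = sum(s.excluded for s in subjects)
        log(f"processed {len(subjects)} sessions; {n_excl} excluded")
        trial_li_frame(epochs_by_subject).to_csv(
            out / "trial_lis.csv", index=False, float_format="%.6f"
        )
        write_subject_summaries(subjects, out / "subjects.csv", pc)
        try:
            r_half, r_sb = split_half_reliability(subjects)
        except DegenerateDataError:
            r_half = r_sb = float("nan")

        # -- stage 3: handedness phenotypes and the double-entry table ----
        stage = "phenotypes"
        hand = {}
        for name, a2, c2, sseed in (
            ("ehi", cfg.ehi_a2, cfg.ehi_c2, int(seeds[2])),
            ("qhp", cfg.qhp_a2, cfg.qhp_c2, int(seeds[3])),
        ):
            tcfg = TwinSimConfig(
                n_mz=cfg.n_mz, n_dz=cfg.n_dz, a2=a2, c2=c2, e2=1 - a2 - c2,
                marginal="jshape", seed=sseed,
            )
            table, _ = simulate_twin_phenotypes(tcfg, phenotype=name)
            hand[name] = table.pairs.set_index("family_id")
        # QHP lives on a 0..42 scale
        for col in ("qhp_1", "qhp_2"):
            hand["qhp"][col] = hand["qhp"][col] * 4.2

        smap = {m["subject_id"]: m for m in subj_meta}
        rows = {}
        for s, m in zip(subjects, subj_meta):
            fam = m["family_id"]
            row = rows.setdefault(
                fam, {"family_id": fam, "zygosity": m["zygosity"], "sex_pair": "FF"}
            )
            t = m["twin_order"]
            use = not s.excluded
            row[f"li_mean_{t}"] = s.li_mean if use else np.nan
            row[f"li_peak_{t}"] = s.li_peak if use else np.nan
            row[f"binary_typical_{t}"] = (
                float(s.binary_typical == "typical") if use else np.nan
            )
            row[f"mean_left_flow_{t}"] = s.mean_left_flow if use else np.nan
            row[f"mean_right_flow_{t}"] = s.mean_right_flow if use else np.nan
        pair_df = pd.DataFrame(list(rows.values()))
        # pair-level propagation: a pair enters the LI fits only complete
        for t in (1, 2):
            other = 3 - t
            bad = pair_df[f"li_mean_{t}"].isna()
            for col in ("li_mean", "li_peak", "binary_typical",
                        "mean_left_flow", "mean_right_flow"):
                pair_df.loc[bad, f"{col}_{other}"] = np.nan
        for name in ("ehi", "qhp"):
            for t in (1, 2):
                pair_df[f"{name}_{t}"] = pair_df["family_id"].map(
                    hand[name][f"{name}_{t}"]
                )
        table = TwinPairTable(pair_df)
        table.to_csv(out / "double_entry.csv")

        # -- stage 4: univariate fits (heritability table) -----------------
        stage = "twin_fits"
        phenos = ["ehi", "qhp", "li_mean", "li_peak", "binary_typical"]
        t2_rows = []
        fits = {}
        for p in phenos:
            mz = table.values(p, "MZ")
            dz = table.values(p, "DZ")
            ae = UnivariateTwinModel(mz, dz, model="AE").fit()
            e = UnivariateTwinModel(mz, dz, model="E").fit()
            chisq, dof, pval = compare_models(ae, e)
            ci = ae.profile_ci("a2")
            rmz = pair_correlation(mz)
            rdz = pair_correlation(dz)
            fits[p] = ae
            t2_rows.append(
                {
                    "measure": p,
                    "n_mz": ae.n_mz,
                    "n_dz": ae.n_dz,
                    "rMZ": rmz.r, "rMZ_low": rmz.ci_low, "rMZ_high": rmz.ci_high,
                    "rDZ": rdz.r, "rDZ_low": rdz.ci_low, "rDZ_high": rdz.ci_high,
                    "a2": ae.a2, "a2_low": ci[0], "a2_high": ci[1],
                    "chisq": chisq, "p": pval,
                }
            )
            log(f"AE fit {p}: a2={ae.a2:.3f} CI=({ci[0]:.3f},{ci[1]:.3f})")
        table2 = pd.DataFrame(t2_rows)
        table2.to_csv(out / "table2_heritability.csv", index=False,
                      float_format="%.6f")

        # -- stage 5: trivariate Cholesky ---------------------------------
        stage = "cholesky"
        cholesky_summary = None
        if cfg.run_cholesky:
            try:
                cres = CholeskyAEModel(
                    table, phenotypes=("ehi", "qhp", "li_mean")
                ).fit()
                se_a, se_e = cres.standard_errors()
                t3 = []
                for lbl, paths, se in (
                    ("A", cres.paths_a_std, se_a), ("E", cres.paths_e_std, se_e)
                ):
                    for r, name in enumerate(("ehi", "qhp", "li_mean")):
                        row = {"factor": lbl, "trait": name}
                        for c in range(3):
                            row[f"path_{c + 1}"] = paths[r, c] if c <= r else np.nan
                            row[f"se_{c + 1}"] = se[r, c] if c <= r else np.nan
                        t3.append(row)
                pd.DataFrame(t3).to_csv(
                    out / "table3_cholesky.csv", index=False, float_format="%.6f"
                )
                cholesky_summary = {"loglik": cres.loglik, "converged": cres.converged}
                log("Cholesky AE fitted")
            except DegenerateDataError as err:
                log(f"Cholesky AE skipped: {err}")

        # -- stage 6: extremes --------------------------------------------
        stage = "extremes"
        cutoffs = {**DEFAULT_CUTOFFS, **cfg.extremes_cutoffs}
        t4_rows = []
        for p in ("ehi", "qhp", "li_mean"):
            cutoff, direction = cutoffs[p]
            try:
                res = extremes_ttest(table, p, cutoff, direction)
                t4_rows.append(res.to_dict())
            except DegenerateDataError as err:
                log(f"extremes {p} skipped: {err}")
        pd.DataFrame(t4_rows).to_csv(
            out / "table4_extremes.csv", index=False, float_format="%.6f"
        )

        # -- stage 7: power table -----------------------------------------
        stage = "power"
        mz_fraction = cfg.n_mz / (cfg.n_mz + cfg.n_dz)
        power_tab = power_curve(
            cfg.power_n_grid, mz_fraction, cfg.power_a2_values, alpha=cfg.power_alpha
        )
        power_tab.to_csv(out / "power.csv", index=False, float_format="%.6f")
    except LatertwinError as err:
        raise LatertwinError(f"stage {stage!r} failed: {err}") from err

    summary = {
        "schema_version": SCHEMA_VERSION,
        "seed": cfg.seed,
        "n_pairs": {"MZ": cfg.n_mz, "DZ": cfg.n_dz},
        "n_subjects_excluded": int(n_excl),
        "split_half_r": r_half,
        "split_half_spearman_brown": r_sb,
        "heritability": {
            r["measure"]: {"a2": r["a2"], "ci": [r["a2_low"], r["a2_high"]],
                           "chisq": r["chisq"], "p": r["p"]}
            for r in t2_rows
        },
        "cholesky": cholesky_summary,
        "extremes": {r["phenotype"]: {"t": r["t"], "df": r["df"], "p": r["p"]}
                     for r in t4_rows},
    }
    cfg.to_yaml(out / "effective_config.yaml")
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


def output_checksums(out_dir) -> dict[str, str]:
    """SHA-256 of every file in a report bundle (determinism checks)."""
    out = Path(out_dir)
    return {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest()
        for f in sorted(out.iterdir())
        if f.is_file()
    }
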