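"""End-to-end pipeline: simulate -> features -> QC -> fit -> predict -> report.

One YAML-configurable entry point chains the synthetic cohort generator,
spectral feature construction, deuterium QC, the multi-compartment reference
computation, NIR model fitting per age group, comparator predictors and the
method-comparison report. Reruns with an identical configuration produce
byte-identical artifacts; a manifest records the config hash, seeds and
artifact hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .composition import (
    DEFAULT_HYDRATION_TABLE,
    HydrationTable,
    anthropometric_indices,
    fat_mass_from_ffm,
    ffm_4c,
    ffm_dd,
    slaughter_bf_pct,
    tbk_per_kg_ffm,
)
from .deuterium import QCThresholds, apply_qc
from .errors import ConfigurationError
from .nir_model import NirFatMassRegressor, stratified_split
from .simulate import GeneratorConfig, generate_cohort
from .spectra import build_feature_matrix
from .stats import build_comparison_report, format_report

GROUP_FILTERS = {
    "3-24": lambda age: (age >= 3) & (age <= 24),
    "3-6": lambda age: (age >= 3) & (age < 7),
    "7-24": lambda age: (age >= 7) & (age <= 24),
}


@dataclass
class PipelineConfig:
    """Validated run configuration; every non-published default lives here."""

    n_subjects: int = 300
    seed: int | None = None
    out_dir: str = "out"
    generator: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    train_fraction: float = 3 / 5
    split_seed: int | None = None  # defaults to seed + 1
    groups: tuple = ("3-24", "3-6", "7-24")
    model_group: str = "3-24"
    metric: str = "mae"
    include_covariate_in_selection: bool = True
    write_spectra: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in d.items() if k in known})
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is required when simulation is enabled")
        if not (0 < self.train_fraction < 1):
            raise ConfigurationError("train_fraction must be in (0, 1)")
        for g in self.groups:
            if g not in GROUP_FILTERS:
                raise ConfigurationError(f"unknown age group {g!r}")
        if self.model_group not in GROUP_FILTERS:
            raise ConfigurationError(f"unknown model_group {self.model_group!r}")

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(n_subjects=self.n_subjects, seed=self.seed, **self.generator)

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(**self.qc)

    def canonical_json(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["groups"] = list(d["groups"])
        return json.dumps(d, sort_keys=True, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def compute_method_values(
    cohort: pd.DataFrame,
    qc_report: pd.DataFrame,
    hydration_table: HydrationTable = DEFAULT_HYDRATION_TABLE,
) -> pd.DataFrame:
    """Reference and comparator values for every QC-accepted subject.

    Returns a subject-indexed frame with the 4C reference (``fm_4c_g``),
    direct methods in grams (DD, DXA, SFT) and raw index values (MUAC, BMI,
    W/A, L/A, W/L) awaiting regression calibration, plus the W/L and weight
    covariates for the NIR models.
    """
    merged = cohort.merge(qc_report[["subject_id", "tbw_kg", "accepted"]], on="subject_id")
    merged = merged[merged["accepted"]].reset_index(drop=True)
    age = merged["age_months"].to_numpy(dtype=float)
    sexes = merged["sex"].to_numpy()
    weight = merged["weight_g"].to_numpy(dtype=float)
    tbw = merged["tbw_kg"].to_numpy(dtype=float)

    tbk = np.where(
        sexes == "male",
        tbk_per_kg_ffm(age, "male"),
        tbk_per_kg_ffm(age, "female"),
    )
    fm4c = fat_mass_from_ffm(weight, ffm_4c(tbw, merged["bmc_kg"].to_numpy(dtype=float), tbk))
    fm_dd = fat_mass_from_ffm(weight, ffm_dd(tbw, age, sexes, hydration_table))
    bf_sft = np.where(
        sexes == "male",
        slaughter_bf_pct(merged["subscapular_mm"].to_numpy(), merged["triceps_mm"].to_numpy(), "male"),
        slaughter_bf_pct(merged["subscapular_mm"].to_numpy(), merged["triceps_mm"].to_numpy(), "female"),
    )
    indices = anthropometric_indices(merged)

    out = pd.DataFrame(
        {
            "subject_id": merged["subject_id"],
            "age_months": age,
            "sex": sexes,
            "weight_g": weight,
            "fm_4c_g": fm4c,
            "DD": fm_dd,
            "DXA": merged["dxa_adipose_g"].to_numpy(dtype=float),
            "SFT": bf_sft / 100.0 * weight,
            "MUAC": indices["muac_cm"].to_numpy(),
            "BMI": indices["bmi"].to_numpy(),
            "W/A": indices["pct_w_a"].to_numpy(),
            "L/A": indices["pct_l_a"].to_numpy(),
            "W/L": indices["pct_w_l"].to_numpy(),
            "w_over_l": indices["w_over_l"].to_numpy(),
        }
    ).set_index("subject_id")
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | None = None) -> dict:
    """Run every stage and write artifacts; returns the manifest dict."""
    config.validate()
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    split_seed = config.seed + 1 if config.split_seed is None else config.split_seed

    synth = generate_cohort(config.generator_config(), include_spectra=True)
    synth.cohort.to_csv(out / "cohort.csv", index=False)
    synth.truth.to_csv(out / "truth.csv", index=False)
    if config.write_spectra:
        synth.spectra.to_csv(out / "spectra.csv", index=False, float_format="%.6f")

    features = build_feature_matrix(synth.spectra)
    features.to_csv(out / "features.csv", float_format="%.8f")

    qc_report = apply_qc(synth.cohort, config.qc_thresholds())
    qc_report.to_csv(out / "qc_report.csv", index=False)

    methods = compute_method_values(synth.cohort, qc_report)
    feats = features.loc[methods.index]
    feats = feats.assign(
        w_over_l=methods["w_over_l"], weight_g=methods["weight_g"]
    )

    reports = []
    predictions = []
    models_out = {}
    for group in config.groups:
        mask = GROUP_FILTERS[group](methods["age_months"])
        sub = methods[mask]
        if len(sub) < 10:
            continue
        train_ids, test_ids = stratified_split(
            sub.reset_index(), train_fraction=config.train_fraction, seed=split_seed
        )
        Xg = feats.loc[sub.index]
        y = sub["fm_4c_g"]
        nir_cols = {}
        for name, cov in (("NIR", "w_over_l"), ("NIR_noL", "weight_g")):
            est = NirFatMassRegressor(
                covariate=cov,
                metric=config.metric,
                include_covariate_in_selection=config.include_covariate_in_selection,
            )
            est.fit(Xg.loc[train_ids], y.loc[train_ids])
            nir_cols[name] = pd.Series(est.predict(Xg), index=Xg.index)
            if group == config.model_group:
                est.model_.split_seed = split_seed
                fname = "model.json" if name == "NIR" else "model_nol.json"
                est.model_.to_json(out / fname)
                models_out[name] = str(out / fname)
        method_values = sub[["DD", "DXA", "SFT", "MUAC", "BMI", "W/A", "L/A", "W/L"]].copy()
        method_values["NIR"] = nir_cols["NIR"]
        method_values["NIR_noL"] = nir_cols["NIR_noL"]
        reports.append(
            build_comparison_report(method_values, y, train_ids, test_ids, group_label=group)
        )
        pred = method_values.copy()
        pred["fm_4c_g"] = y
        pred["group"] = group
        pred["fold"] = ["train" if i in set(train_ids) else "test" for i in pred.index]
        predictions.append(pred.reset_index())

    report = pd.concat(reports, ignore_index=True)
    report.to_csv(out / "report.csv", index=False, float_format="%.6f")
    (out / "report.txt").write_text(format_report(report))
    pd.concat(predictions, ignore_index=True).to_csv(
        out / "predictions.csv", index=False, float_format="%.6f"
    )

    artifacts = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(config.canonical_json().encode()).hexdigest(),
        "seed": config.seed,
        "split_seed": split_seed,
        "artifacts": {name: _sha256(out / name) for name in artifacts},
        "models": models_out,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
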