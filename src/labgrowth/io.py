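"""Cohort file I/O, pipeline configuration and the end-to-end driver.

Everything on disk is plain CSV (ages as integer days) with a JSON run
manifest recording the seed, a configuration digest and content digests of
every output, so a run is verifiably reproducible: the same inputs, config
and seed regenerate every file bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import growth, synthetic
from .exercise import DEFAULT_ACTIVITIES, DEFAULT_BINS, ExerciseBins, tde_frame
from .units import Measurement, UnitError, store_height_cm

logger = logging.getLogger("labgrowth")

__all__ = ["PipelineConfig", "read_cohort", "run_pipeline"]

MANDATORY_COLUMNS = ("dog_id", "sex", "age_days")


@dataclass
class PipelineConfig:
    """Configuration of a full simulate-fit-correct-summarize run."""

    out_dir: Path = Path("labgrowth_run")
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    priors: growth.PriorSpec = field(default_factory=growth.PriorSpec)
    mcmc: growth.MCMCConfig = field(default_factory=growth.MCMCConfig)
    bins: ExerciseBins = DEFAULT_BINS
    classification_threshold: float = 0.5
    extreme_height_threshold: float = 1.0
    retention_age_days: float = 365.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict[str, Any] = {}
        if "cohort" in raw:
            cohort = dict(raw["cohort"])
            if "growth_params_by_sex" in cohort:
                cohort["growth_params_by_sex"] = {
                    sex: growth.GrowthParams(**p)
                    for sex, p in cohort["growth_params_by_sex"].items()
                }
            if "contamination_probs" in cohort:
                cohort["contamination_probs"] = tuple(cohort["contamination_probs"])
            kwargs["cohort"] = synthetic.CohortConfig(**cohort)
        if "priors" in raw:
            kwargs["priors"] = growth.PriorSpec(**raw["priors"])
        if "mcmc" in raw:
            kwargs["mcmc"] = growth.MCMCConfig(**raw["mcmc"])
        if "bins" in raw:
            kwargs["bins"] = ExerciseBins(
                {k: tuple(v) for k, v in raw["bins"].items()}
            )
        for key in ("out_dir", "classification_threshold",
                    "extreme_height_threshold", "retention_age_days", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        kwargs.update(overrides)
        cfg = cls(**kwargs)
        cfg.out_dir = Path(cfg.out_dir)
        return cfg

    def digest(self) -> str:
        """Stable hash of the configuration (excluding the output location)."""
        payload = asdict(self)
        payload.pop("out_dir")
        payload["bins"] = {k: list(v) for k, v in self.bins.bounds.items()}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV into typed observation records.

    Requires columns ``dog_id, sex, age_days`` plus either a normalized
    ``height_recorded_cm`` column or a ``height``/``height_unit`` pair that
    is pushed through the database storage rule (inches x 2.54).  Rows whose
    height cannot be parsed are skipped with a logged warning; other columns
    (weights, exercise bins, ...) pass through untouched.
    """
    df = pd.read_csv(path)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cohort file {path} is missing mandatory column {col!r}")

    if "height_recorded_cm" not in df.columns:
        if not {"height", "height_unit"} <= set(df.columns):
            raise ValueError(
                f"cohort file {path} is missing mandatory column 'height_recorded_cm' "
                "(or a 'height'/'height_unit' pair)"
            )

        def convert(row) -> float:
            return store_height_cm(
                Measurement(float(row["height"]), str(row["height_unit"]))
            )

        heights = []
        keep = np.ones(len(df), dtype=bool)
        for i, (_, row) in enumerate(df.iterrows()):
            try:
                heights.append(convert(row))
            except (ValueError, UnitError, TypeError) as exc:
                logger.warning("skipping row %d of %s: %s", i, path, exc)
                keep[i] = False
                heights.append(np.nan)
        df = df.loc[keep].copy()
        df["height_recorded_cm"] = np.asarray(heights)[keep]
    else:
        bad = ~np.isfinite(df["height_recorded_cm"].astype(float, errors="ignore"))
        if bad.any():
            logger.warning("skipping %d rows with unparseable heights", int(bad.sum()))
            df = df.loc[~bad].copy()

    df["age_days"] = df["age_days"].astype(int)
    df["height_recorded_cm"] = df["height_recorded_cm"].astype(float)
    return df.reset_index(drop=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def run_pipeline(config: PipelineConfig, seed: int | None = None) -> dict[str, Any]:
    """Simulate, filter, fit per sex, correct, derive TDE and summarize.

    Returns a report bundle (paths, posterior summaries, stats) and writes
    all stage outputs plus ``manifest.json`` under ``config.out_dir``.
    Idempotent given the seed: two runs produce byte-identical files.
    """
    logging.basicConfig(level=config.log_level)
    if seed is not None:
        root = np.random.SeedSequence(seed)
        sim_seed, mcmc_seed, ex_seed = [
            int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3)
        ]
        from dataclasses import replace
        config = PipelineConfig(
            out_dir=config.out_dir,
            cohort=replace(config.cohort, seed=sim_seed),
            priors=config.priors,
            mcmc=replace(config.mcmc, seed=mcmc_seed),
            bins=config.bins,
            classification_threshold=config.classification_threshold,
            extreme_height_threshold=config.extreme_height_threshold,
            retention_age_days=config.retention_age_days,
            log_level=config.log_level,
        )
    else:
        ex_seed = config.cohort.seed + 1

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # 1. simulate ----------------------------------------------------------
    logger.info("simulating cohort of %d dogs", config.cohort.n_dogs)
    observations, truth = synthetic.generate_cohort(config.cohort)
    synthetic.write_cohort(observations, truth, out / "cohort.csv",
                           out / "truth.csv")

    # 2. filter ------------------------------------------------------------
    kept, removed, gone = growth.filter_extreme_heights(
        observations, config.extreme_height_threshold
    )

    # 3-4. fit per sex, classify and correct -------------------------------
    summaries, corrected_parts, posterior_parts, class_parts = {}, [], [], []
    for sex in sorted(kept["sex"].unique()):
        sex_obs = kept[kept["sex"] == sex].reset_index(drop=True)
        logger.info("fitting %s (%d observations)", sex, len(sex_obs))
        result = growth.sample_posterior(sex_obs, config.priors, config.mcmc)
        summary = result.summary()
        summary.insert(0, "sex", sex)
        summaries[sex] = result
        posterior = pd.DataFrame({
            "sex": sex,
            "iteration": np.arange(config.mcmc.n_keep),
            **{k: result.chains[k] for k in ("a", "b", "c", "tau", "sd")},
            **{f"pi_{lab}": result.chains["pi"][:, i]
               for i, lab in enumerate(growth.CLASS_LABELS)},
        })
        posterior_parts.append(posterior)
        corr, report = growth.classify_and_correct(
            sex_obs, result, config.classification_threshold
        )
        corrected_parts.append(corr)
        cp = pd.DataFrame(result.class_post,
                          columns=[f"p_{lab}" for lab in growth.CLASS_LABELS])
        cp.insert(0, "dog_id", sex_obs["dog_id"].to_numpy())
        cp.insert(1, "age_days", sex_obs["age_days"].to_numpy())
        cp["assigned_class"] = corr["class_label"].to_numpy()
        class_parts.append(cp)

    corrected = pd.concat(corrected_parts, ignore_index=True)
    _write_csv(pd.concat(posterior_parts, ignore_index=True),
               out / "posterior.csv")
    _write_csv(pd.concat(class_parts, ignore_index=True),
               out / "class_posteriors.csv")
    _write_csv(corrected, out / "heights_corrected.csv")
    _write_csv(
        pd.concat([summaries[s].summary().assign(sex=s) for s in summaries],
                  ignore_index=True),
        out / "posterior_summary.csv",
    )

    # 5. exercise ----------------------------------------------------------
    reports = synthetic.generate_exercise_reports(
        observations, seed=ex_seed, activities=DEFAULT_ACTIVITIES,
        bins=config.bins,
    )
    with_tde = tde_frame(reports, config.bins, DEFAULT_ACTIVITIES)
    _write_csv(with_tde, out / "exercise_tde.csv")

    # 6. stats -------------------------------------------------------------
    from .stats import retention_rate

    follow = pd.DataFrame({
        "dog_id": [d.dog_id for d in truth.dogs],
        "age_at_last_entry_days": [
            (d.observed_ages[-1] if d.observed_ages else 0) for d in truth.dogs
        ],
        "days_since_last_entry": [
            (config.cohort.max_age_days - (d.observed_ages[-1] if d.observed_ages else 0))
            for d in truth.dogs
        ],
    })
    _write_csv(follow, out / "follow_up.csv")
    retention = retention_rate(follow, config.retention_age_days)

    from .exercise import summarize_tde

    stats_report = {
        "retention_rate": retention,
        "tde_summary": summarize_tde(with_tde["tde_min"]),
        "n_observations": int(len(observations)),
        "n_filtered": int(len(removed)),
        "n_dogs_fully_removed": len(gone),
        "n_misreported": {s: summaries[s].n_misreported for s in summaries},
    }
    (out / "stats.json").write_text(
        json.dumps(stats_report, indent=2, sort_keys=True) + "\n"
    )

    manifest = {
        "seed": seed,
        "config_digest": config.digest(),
        "package": "labgrowth 0.1.0",
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*.csv")) + [out / "stats.json"]
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return {
        "out_dir": out,
        "manifest": manifest,
        "results": summaries,
        "stats": stats_report,
        "corrected": corrected,
    }
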