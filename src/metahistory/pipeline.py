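"""End-to-end orchestration: simulate -> validate -> decode -> sdt -> transfer.

``run_full_analysis`` chains every stage on a pair of simulated
experiments (belief of success, decision to engage attention), writes the
per-stage CSV exports plus a JSON manifest recording the configuration,
seeds, versions, warnings and per-stage wall times, and renders a plain
text summary report.  A fixed seed makes the whole bundle reproducible
byte for byte.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decoding import DEFAULT_LAGS, HistoryDecodingModel, _derive_seed
from .exceptions import ConfigError
from .sdt import DEFAULT_PADDING, M_RATIO_EPSILON, condition_sdt_grid
from .simulate import (
    CalibrationSummary,
    GeneratorConfig,
    attention_config,
    simulate_experiment,
    summarize_calibration,
)
from .transfer import TransferDecodingModel
from .trial_io import TrialTable, validate_subjects, write_trials

logger = logging.getLogger("metahistory")


@dataclass
class DecodingSettings:
    n_splits: int = 100
    test_fraction: float = 0.2
    n_permutations: int = 100
    lags: tuple[int, ...] = DEFAULT_LAGS


@dataclass
class SDTSettings:
    padding: float = DEFAULT_PADDING
    m_ratio_epsilon: float = M_RATIO_EPSILON


@dataclass
class PipelineConfig:
    """Full configuration of the simulated two-experiment analysis."""

    generator_belief: GeneratorConfig = field(default_factory=GeneratorConfig)
    generator_attention: GeneratorConfig = field(default_factory=attention_config)
    decoding: DecodingSettings = field(default_factory=DecodingSettings)
    sdt: SDTSettings = field(default_factory=SDTSettings)
    seed: int = 0
    output_dir: str = "metahistory_output"

    def validate(self) -> None:
        self.generator_belief.validate()
        self.generator_attention.validate()
        if self.seed is None:
            raise ConfigError("seed", "a seed is mandatory (no silent nondeterminism)")
        for name in ("n_splits", "n_permutations"):
            if getattr(self.decoding, name) < 1:
                raise ConfigError(f"decoding.{name}", "must be a positive count")
        if not 0 < self.decoding.test_fraction < 1:
            raise ConfigError("decoding.test_fraction", "must lie in (0, 1)")

    def fast(self) -> "PipelineConfig":
        """Reduced settings (20 splits, 20 permutations) for quick runs."""
        cfg = PipelineConfig(
            generator_belief=self.generator_belief,
            generator_attention=self.generator_attention,
            decoding=DecodingSettings(
                n_splits=20,
                test_fraction=self.decoding.test_fraction,
                n_permutations=20,
                lags=self.decoding.lags,
            ),
            sdt=self.sdt,
            seed=self.seed,
            output_dir=self.output_dir,
        )
        return cfg

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "generator_belief": self.generator_belief.to_dict(),
            "generator_attention": self.generator_attention.to_dict(),
            "decoding": {
                "n_splits": self.decoding.n_splits,
                "test_fraction": self.decoding.test_fraction,
                "n_permutations": self.decoding.n_permutations,
                "lags": list(self.decoding.lags),
            },
            "sdt": {
                "padding": self.sdt.padding,
                "m_ratio_epsilon": self.sdt.m_ratio_epsilon,
            },
            "seed": self.seed,
            "output_dir": str(self.output_dir),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        if "generator_belief" in d:
            kwargs["generator_belief"] = GeneratorConfig.from_dict(d["generator_belief"])
        if "generator_attention" in d:
            kwargs["generator_attention"] = GeneratorConfig.from_dict(
                d["generator_attention"]
            )
        if "decoding" in d:
            dec = dict(d["decoding"])
            if "lags" in dec:
                dec["lags"] = tuple(dec["lags"])
            kwargs["decoding"] = DecodingSettings(**dec)
        if "sdt" in d:
            kwargs["sdt"] = SDTSettings(**d["sdt"])
        for key in ("seed", "output_dir"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _calibration_dict(summary: CalibrationSummary) -> dict:
    return {
        "phi_aw_conf": [summary.phi_aw_conf.mean, summary.phi_aw_conf.sd],
        "phi_corr_aw": [summary.phi_corr_aw.mean, summary.phi_corr_aw.sd],
        "phi_corr_conf": [summary.phi_corr_conf.mean, summary.phi_corr_conf.sd],
        "p_high_prospective": [
            summary.p_high_prospective.mean,
            summary.p_high_prospective.sd,
        ],
        "p_aware": summary.p_aware,
        "n_subjects": summary.n_subjects,
    }


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.output_dir``.

    Returns the manifest dictionary.  Any stage error aborts with the
    stage name attached; outputs of completed stages are preserved.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "versions": {
            "metahistory": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "warnings": [],
    }
    stage = "setup"
    tables: dict[str, TrialTable] = {}
    summaries = {}
    try:
        # -- simulate -----------------------------------------------------
        stage = "simulate"
        t0 = time.perf_counter()
        for label, gen in (
            ("belief", config.generator_belief),
            ("attention", config.generator_attention),
        ):
            table = simulate_experiment(gen)
            tables[label] = table
            write_trials(table, out / f"trials_{label}.csv")
            gen.to_json(out / f"ground_truth_{label}.json")
        manifest["stages"]["simulate"] = {"seconds": time.perf_counter() - t0}

        # -- validate -----------------------------------------------------
        stage = "validate"
        t0 = time.perf_counter()
        for label in tables:
            retained, report = validate_subjects(tables[label])
            report.to_json(out / f"exclusions_{label}.json")
            if report.excluded:
                manifest["warnings"].append(
                    f"{label}: excluded subjects {report.excluded}"
                )
            tables[label] = retained
            summaries[label] = summarize_calibration(retained)
        manifest["stages"]["validate"] = {"seconds": time.perf_counter() - t0}

        # -- decode -------------------------------------------------------
        stage = "decode"
        t0 = time.perf_counter()
        decode_results = {}
        for label in tables:
            model = HistoryDecodingModel(
                tables[label],
                lags=config.decoding.lags,
                n_splits=config.decoding.n_splits,
                test_fraction=config.decoding.test_fraction,
                n_permutations=config.decoding.n_permutations,
            )
            res = model.fit(seed=_derive_seed(config.seed, f"decode-{label}"))
            decode_results[label] = res
            res.decoding_table().to_csv(out / f"decoding_{label}.csv", index=False)
            res.group_table().to_csv(out / f"decoding_group_{label}.csv", index=False)
            res.odds_ratio_table().to_csv(out / f"odds_ratios_{label}.csv", index=False)
            res.conditional_probability_table().to_csv(
                out / f"conditional_probabilities_{label}.csv", index=False
            )
        manifest["stages"]["decode"] = {"seconds": time.perf_counter() - t0}

        # -- sdt ----------------------------------------------------------
        stage = "sdt"
        t0 = time.perf_counter()
        for label in tables:
            grid = condition_sdt_grid(
                tables[label],
                padding=config.sdt.padding,
                m_ratio_epsilon=config.sdt.m_ratio_epsilon,
            )
            grid.to_csv(out / f"sdt_grid_{label}.csv", index=False)
            n_undef = int((~grid["defined"]).sum())
            if n_undef:
                manifest["warnings"].append(
                    f"{label}: {n_undef} SDT cells with undefined M-ratio"
                )
        manifest["stages"]["sdt"] = {"seconds": time.perf_counter() - t0}

        # -- transfer -----------------------------------------------------
        stage = "transfer"
        t0 = time.perf_counter()
        transfer_model = TransferDecodingModel(
            tables["belief"],
            tables["attention"],
            lags=config.decoding.lags,
            n_iterations=config.decoding.n_splits,
        )
        transfer_results = transfer_model.fit(
            seed=_derive_seed(config.seed, "transfer")
        )
        transfer_results.transfer_table().to_csv(out / "transfer.csv", index=False)
        manifest["stages"]["transfer"] = {"seconds": time.perf_counter() - t0}

        # -- report -------------------------------------------------------
        stage = "report"
        t0 = time.perf_counter()
        manifest["calibration"] = {
            label: _calibration_dict(s) for label, s in summaries.items()
        }
        report_lines = []
        for label in tables:
            report_lines.append(decode_results[label].summary())
            report_lines.append("")
        report_lines.append(transfer_results.summary())
        report_text = "\n".join(report_lines)
        (out / "report.txt").write_text(report_text + "\n")
        manifest["stages"]["report"] = {"seconds": time.perf_counter() - t0}
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete; outputs in %s", out)
    return manifest
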