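"""End-to-end analysis runs: scoring, filtering, regression, permutation,
reporting, with a manifest for exact reproduction.

A run consumes either real input tables (choices, thickness, demographics)
or a synthetic study generated on the fly, and writes a results bundle:
profile table, exclusion report, per-parcel results with corrected
p-values, a JSON manifest (config echo, seed, package version, input
checksums) and a log. Any stage failure removes partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .atlas import load_atlas, read_demographics, read_thickness
from .model import ParcelThicknessModel, PermutationInference
from .ring import CONSISTENCY_THRESHOLD, build_ring, read_choices, write_profiles
from .simulate import AnatomySpec, PopulationSpec, simulate_dataset

__all__ = ["RunConfig", "ResultsBundle", "run", "report"]

log = logging.getLogger("svocortex")


@dataclass
class RunConfig:
    """Configuration of one analysis run (YAML-loadable)."""

    choices: str | None = None
    thickness: str | None = None
    demographics: str | None = None
    atlas: str | None = None
    synthetic: bool = False
    synthetic_seed: int | None = None
    synthetic_effect: float | None = None  # override left-parcel-22 slope
    n_subjects: int = 214
    model: str = "angle"
    include_age_in_weights_model: bool = True
    consistency_threshold: float = CONSISTENCY_THRESHOLD
    include_all: bool = False
    impute_demographics: bool = False
    B: int = 5000
    alpha: float = 0.05
    sidedness: str = "upper"
    seed: int | None = None
    outdir: str = "svocortex_run"

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.consistency_threshold < 0:
            raise ValueError("consistency threshold must be >= 0")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass
class ResultsBundle:
    config: RunConfig
    outdir: Path
    profiles: pd.DataFrame
    exclusions: pd.DataFrame
    table: pd.DataFrame
    inference: PermutationInference
    manifest: dict
    files: dict = field(default_factory=dict)


def _checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _load_inputs(config: RunConfig):
    atlas = load_atlas(config.atlas)
    checksums = {}
    if config.synthetic:
        anat = AnatomySpec()
        if config.synthetic_effect is not None:
            anat = AnatomySpec(effect_map={("left", 22): config.synthetic_effect})
        data = simulate_dataset(
            PopulationSpec(n_subjects=config.n_subjects),
            anat,
            build_ring(),
            atlas,
            seed=config.synthetic_seed if config.synthetic_seed is not None else config.seed,
        )
        choices, thickness, demographics = (
            data["choices"],
            data["thickness"],
            data["demographics"],
        )
    else:
        for key in ("choices", "thickness", "demographics"):
            path = getattr(config, key)
            if path is None:
                raise FileNotFoundError(f"config must set '{key}' (or synthetic: true)")
            checksums[key] = _checksum(path)
        choices = read_choices(config.choices)
        demographics = read_demographics(
            config.demographics, impute=config.impute_demographics, seed=config.seed
        )
        thickness = read_thickness(config.thickness, atlas)
    return atlas, choices, thickness, demographics, checksums


def run(config: RunConfig) -> ResultsBundle:
    """Execute scoring -> filtering -> regression -> permutation -> outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "setup"
    try:
        written.append(outdir / "run.log")
        stage = "inputs"
        atlas, choices, thickness, demographics, checksums = _load_inputs(config)
        log.info("inputs loaded: %d choice rows, %d subjects with thickness",
                 len(choices), thickness.n_subjects)

        stage = "scoring"
        model = ParcelThicknessModel.from_choices(
            choices,
            thickness,
            demographics,
            atlas=atlas,
            model=config.model,
            include_age=config.include_age_in_weights_model,
            consistency_threshold=config.consistency_threshold,
            include_all=config.include_all,
        )
        log.info(
            "scored %d participants, excluded %d, analysing %d",
            len(model.all_profiles),
            len(model.exclusions),
            model.nobs,
        )
        prof_path = outdir / "profiles.csv"
        write_profiles(model.all_profiles, prof_path)
        written.append(prof_path)
        excl_path = outdir / "exclusions.csv"
        model.exclusions.to_csv(excl_path, index=False)
        written.append(excl_path)

        stage = "regression+permutation"
        results = model.fit()
        inference = results.permutation_test(
            B=config.B, seed=config.seed, sidedness=config.sidedness
        )
        table = inference.table
        table["seed"] = config.seed
        table["flagged"] = table["p_corrected"] <= config.alpha
        res_path = outdir / "results.csv"
        table.to_csv(res_path, index=False)
        written.append(res_path)
        n_flag = int(table["flagged"].sum())
        log.info("permutation done (B=%d): %d parcel/variable rows flagged at alpha=%g",
                 config.B, n_flag, config.alpha)

        stage = "manifest"
        manifest = {
            "config": dataclasses.asdict(config),
            "seed": config.seed,
            "svocortex_version": __version__,
            "python": sys.version.split()[0],
            "input_checksums": checksums,
            "n_scored": int(len(model.all_profiles)),
            "n_excluded": int(len(model.exclusions)),
            "n_analysed": int(model.nobs),
            "n_flagged_rows": n_flag,
        }
        man_path = outdir / "manifest.json"
        man_path.write_text(json.dumps(manifest, indent=2, default=str))
        written.append(man_path)
    except Exception as exc:
        log.removeHandler(handler)
        handler.close()
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    log.removeHandler(handler)
    handler.close()
    return ResultsBundle(
        config=config,
        outdir=outdir,
        profiles=model.all_profiles,
        exclusions=model.exclusions,
        table=table,
        inference=inference,
        manifest=manifest,
        files={p.name: p for p in written},
    )


def report(bundle: ResultsBundle, write_scatter: bool = True) -> str:
    """Human-readable per-lobe summary; exports adjusted scatter data for
    every flagged parcel (one row per included subject)."""
    text = bundle.inference.summary(alpha=bundle.config.alpha)
    if write_scatter:
        flagged = bundle.inference.flagged(bundle.config.alpha)
        for _, row in flagged.iterrows():
            data = bundle.inference.results.adjusted_scatter(
                row["parcel_column"], row["variable"]
            )
            path = bundle.outdir / f"scatter_{row['parcel_column']}_{row['variable']}.csv"
            data.to_csv(path, index=False)
            bundle.files[path.name] = path
    summary_path = bundle.outdir / "summary.txt"
    summary_path.write_text(text + "\n")
    bundle.files[summary_path.name] = summary_path
    return text
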