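"""End-to-end orchestration: simulate/ingest -> entropy -> reliability screen
-> fingerprint -> cognition prediction -> structure analyses.

Stages run in dependency order; every stochastic step draws its seed from the
single run seed, so identical config + seed reproduces byte-identical JSON
reports.  Each stage writes one JSON report (plus TSVs where tabular) with
the full config serialised into it; timing goes to the stderr log only, never
into the reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import DataError, PROPERTIES
from .entropy import DEFAULT_PARAMS, EntropyParams, entropy_profiles
from .fingerprint import FingerprintIdentification, identify
from .prediction import (
    DEFAULT_LAMBDA_GRID,
    CognitiveAbilityRidge,
    per_network_prediction,
)
from .reliability import (
    flag_unreliable_rois,
    permuted_entropy_null,
    regional_reliability,
)
from .structure import (
    StructureEntropyModel,
    add_connectivity_properties,
    blueprint_correlations,
    regional_individual_correlations,
)
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort, read_cohort

__all__ = ["RunConfig", "PipelineError", "run_full_analysis"]

log = logging.getLogger("entroprint")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """One configuration drives the whole analysis; ``seed`` governs every
    stochastic step (the cohort seed is derived from it)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_dir: str | None = None
    entropy: EntropyParams = field(default_factory=lambda: DEFAULT_PARAMS)
    n_permutations_per_direction: int = 500
    n_bootstrap: int = 1000
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    fdr_q: float = 0.05
    connectivity_threshold: float = 0.001
    outcomes: tuple[str, ...] = ("g", "vis", "cry", "mem", "spd")
    structure_properties: tuple[str, ...] = PROPERTIES
    per_network_prediction: bool = False
    output_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohort" in raw:
            raw["cohort"] = CohortConfig(**raw["cohort"])
        if "entropy" in raw:
            raw["entropy"] = EntropyParams(**raw["entropy"])
        for key in ("lambda_grid", "outcomes", "structure_properties"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays for JSON serialisation."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _write_report(out_dir: Path | None, name: str, payload: dict) -> None:
    if out_dir is None:
        return
    with open(out_dir / f"{name}.json", "w") as fh:
        json.dump(_jsonable(payload), fh, indent=1, sort_keys=True)
        fh.write("\n")


class _Stage:
    """Context manager: stderr timing and failure attribution."""

    def __init__(self, name: str) -> None:
        self.name = name

    def __enter__(self):
        log.info("stage %s: start", self.name)
        self._t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self._t0
        if exc is not None:
            log.error("stage %s: FAILED after %.1fs (%s)", self.name, dt, exc)
            raise PipelineError(f"stage {self.name!r} failed: {exc}") from exc
        log.info("stage %s: done in %.1fs", self.name, dt)


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and return the report bundle (also written to
    ``config.output_dir`` when set)."""
    rng = np.random.default_rng(config.seed)

    def stage_seed() -> int:
        return int(rng.integers(2**31))

    # validation-first: fail on missing inputs before any computation
    if config.input_dir is not None:
        root = Path(config.input_dir)
        for required in ("manifest.json", "parcellation.tsv", "scores.tsv",
                         "structure.tsv"):
            if not (root / required).exists():
                raise DataError(f"missing input file {root / required}")

    out_dir = None
    if config.output_dir is not None:
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    reports: dict[str, dict] = {}

    with _Stage("cohort"):
        cohort_seed = stage_seed()
        if config.input_dir is not None:
            cohort = read_cohort(config.input_dir)
        else:
            cohort = generate_cohort(
                dataclasses.replace(config.cohort, seed=cohort_seed)
            )
    ts, parcellation = cohort.timeseries, cohort.parcellation

    with _Stage("entropy"):
        prof = [
            entropy_profiles(ts, config.entropy, s)
            for s in range(len(ts.session_labels))
        ]
        prof_avg = prof[0].averaged_with(prof[1])
        if out_dir is not None:
            pd.concat(
                [p.to_frame(parcellation) for p in prof], ignore_index=True
            ).to_csv(out_dir / "entropy_profiles.tsv", sep="\t", index=False,
                     float_format="%.17g")
        reports["entropy"] = {
            "config": cfg_dict,
            "params": dataclasses.asdict(config.entropy),
            "group_mean_by_session": {
                p.session: p.values.mean() for p in prof
            },
        }
        _write_report(out_dir, "entropy", reports["entropy"])

    with _Stage("reliability"):
        rel_r = regional_reliability(prof[0], prof[1])
        mean_en = np.mean([p.values.mean(axis=0) for p in prof], axis=0)
        null = permuted_entropy_null(
            ts, config.entropy, session=0, seed=stage_seed()
        )
        profile = flag_unreliable_rois(
            rel_r, mean_en, null, roi_ids=ts.roi_ids
        )
        retained = profile.retained_mask
        if out_dir is not None:
            profile.to_frame(parcellation).to_csv(
                out_dir / "reliability.tsv", sep="\t", index=False,
                float_format="%.17g")
        reports["reliability"] = {
            "config": cfg_dict,
            "th_relia": profile.th_relia,
            "th_en": profile.th_en,
            "n_flagged": int(profile.flagged.sum()),
            "flagged_rois": [r for r, f in zip(profile.roi_ids,
                                               profile.flagged) if f],
            "null_quantile_05": null.quantile_05,
            "null_mean": null.samples.mean(),
        }
        _write_report(out_dir, "reliability", reports["reliability"])

    rel_prof = [p.select_rois(retained) for p in prof]
    rel_avg = prof_avg.select_rois(retained)
    net_of = parcellation.set_index("roi_id")["network"]
    retained_nets = np.asarray([net_of[r] for r in rel_prof[0].roi_ids])

    with _Stage("fingerprint"):
        fp = FingerprintIdentification(rel_prof[0], rel_prof[1]).fit(
            n_permutations_per_direction=config.n_permutations_per_direction,
            n_bootstrap=config.n_bootstrap,
            seed=stage_seed(),
        )
        per_network_acc = {}
        for net in pd.unique(parcellation["network"]):
            mask = retained_nets == net
            if mask.sum() < 3:
                continue
            per_network_acc[net] = identify(
                rel_prof[1].select_rois(mask), rel_prof[0].select_rois(mask)
            ).accuracy
        reports["fingerprint"] = {
            "config": cfg_dict,
            "accuracy": {
                name: res.accuracy for name, res in fp.directions.items()
            },
            "permutation_p": {
                name: res.permutation_p for name, res in fp.directions.items()
            },
            "ci95": {name: res.ci95 for name, res in fp.directions.items()},
            "per_network_accuracy_R1_to_R2": per_network_acc,
            "dp_median": float(np.median(fp.dp.dp)),
        }
        if out_dir is not None:
            pd.DataFrame(
                {"roi_id": fp.dp.roi_ids, "dp": fp.dp.dp}
            ).to_csv(out_dir / "differentiation_power.tsv", sep="\t",
                     index=False, float_format="%.17g")
        _write_report(out_dir, "fingerprint", reports["fingerprint"])

    with _Stage("prediction"):
        pred_report = {"config": cfg_dict, "outcomes": {}}
        for outcome in config.outcomes:
            res = CognitiveAbilityRidge(
                rel_avg, cohort.scores, outcome=outcome,
                lambda_grid=config.lambda_grid,
            ).fit(n_bootstrap=config.n_bootstrap, seed=stage_seed())
            pred_report["outcomes"][outcome] = {
                "accuracy_r": res.accuracy_r,
                "r_raw": res.r_raw,
                "p": res.p_value,
                "ci95": res.ci95,
                "lambda": res.lambda_selected,
            }
        if config.per_network_prediction:
            table, _ = per_network_prediction(
                rel_avg, cohort.scores, parcellation,
                outcomes=config.outcomes, lambda_grid=config.lambda_grid,
                fdr_q=config.fdr_q, seed=stage_seed(),
            )
            pred_report["per_network"] = table.to_dict(orient="records")
        reports["prediction"] = pred_report
        _write_report(out_dir, "prediction", pred_report)

    with _Stage("structure"):
        structure = add_connectivity_properties(
            cohort.morphometry, cohort.connectivity,
            threshold=config.connectivity_threshold,
        ).select_rois(retained)
        en_blueprint = rel_avg.values.mean(axis=0)
        bp_table = blueprint_correlations(
            en_blueprint,
            {p: structure.values[p].mean(axis=0)
             for p in config.structure_properties},
            n_bootstrap=config.n_bootstrap,
            seed=stage_seed(),
            fdr_q=config.fdr_q,
        )
        _, network_means = regional_individual_correlations(
            rel_avg, structure, parcellation
        )
        families = cohort.scores.set_index("subject_id").loc[
            rel_avg.subject_ids, "family_id"
        ].to_numpy()
        specificity = {}
        for prop in config.structure_properties:
            res = StructureEntropyModel(
                rel_avg, structure, prop, families
            ).fit(
                n_permutations=2 * config.n_permutations_per_direction,
                n_bootstrap=config.n_bootstrap,
                seed=stage_seed(),
            )
            specificity[prop] = {
                "similarity_mean": res.similarity_mean,
                "identification_accuracy": res.identification_accuracy,
                "permutation_p": res.permutation_p,
                "ci95": res.ci95,
                "satisfactory": res.satisfactory,
            }
        reports["structure"] = {
            "config": cfg_dict,
            "blueprint": bp_table.to_dict(orient="records"),
            "network_mean_individual_r": (
                network_means.to_dict() if network_means is not None else None
            ),
            "specificity": specificity,
        }
        _write_report(out_dir, "structure", reports["structure"])

    summary = {
        "config": cfg_dict,
        "n_subjects": ts.n_subjects,
        "n_rois": ts.n_rois,
        "n_retained_rois": int(retained.sum()),
        "identification_accuracy": reports["fingerprint"]["accuracy"],
        "prediction_r": {
            k: v["accuracy_r"]
            for k, v in reports["prediction"]["outcomes"].items()
        },
        "blueprint_r": {
            row["property"]: row["r"] for row in reports["structure"]["blueprint"]
        },
        "specificity_accuracy": {
            p: d["identification_accuracy"]
            for p, d in reports["structure"]["specificity"].items()
        },
    }
    reports["summary"] = summary
    _write_report(out_dir, "summary", summary)
    return reports
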