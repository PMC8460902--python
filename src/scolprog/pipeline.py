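"""End-to-end orchestration: cohort -> geometry -> biomechanics ->
features -> two-phase classification -> statistics.

A :class:`RunConfig` fully determines a run; re-executing from the same
config reproduces every output bitwise.  In ``feature_level`` mode the
biomechanics stage is skipped and predictor vectors are sampled directly;
in ``geometry_level`` mode each subject's orientation chain is pushed
through the descriptor computations and the inverse-statics solver.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import FEATURE_COLUMNS
from .cohort import CohortConfig, cohort_to_frame, generate_cohort
from .features import extract_biomech_params
from .geometry import SpineGeometry, detect_curves, geometrical_params
from .msk import RecruitmentConfig, ScalingConfig, build_model, solve_inverse_statics
from .prediction import (
    ALGORITHMS, assemble_predictors, compare_models, preselect,
)
from .stats import kruskal_with_posthoc, reduced_vs_full_tests

__all__ = ["RunConfig", "StageError", "run_pipeline", "features_from_geometry"]

logger = logging.getLogger("scolprog")


class StageError(RuntimeError):
    def __init__(self, stage: str, subject: str, cause: Exception):
        self.stage = stage
        self.subject = subject
        super().__init__(f"stage {stage!r} failed for subject {subject}: {cause}")


@dataclass
class RunConfig:
    seed: int = 0
    cohort: CohortConfig = None
    recruitment: RecruitmentConfig = field(default_factory=RecruitmentConfig)
    preselect_repetitions: int = 10
    preselect_folds: int = 4
    compare_iterations: int = 100
    n_selected: int = 3
    output_dir: str = "results"

    def __post_init__(self):
        if self.cohort is None:
            self.cohort = CohortConfig(seed=self.seed)

    def to_yaml(self, path):
        """Serialize the run configuration (scalar fields; margin tables
        and correlation overrides keep their defaults)."""
        payload = {
            "seed": self.seed,
            "cohort": {
                "n_stable": self.cohort.n_stable,
                "n_progressive": self.cohort.n_progressive,
                "seed": self.cohort.seed,
                "mode": self.cohort.mode,
                "biomech_coupling": self.cohort.biomech_coupling,
            },
            "recruitment": {
                "exponent": self.recruitment.exponent,
                "min_activation": self.recruitment.min_activation,
            },
            "preselect_repetitions": self.preselect_repetitions,
            "preselect_folds": self.preselect_folds,
            "compare_iterations": self.compare_iterations,
            "n_selected": self.n_selected,
            "output_dir": str(self.output_dir),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path):
        payload = yaml.safe_load(Path(path).read_text())
        cohort = CohortConfig(**payload.pop("cohort", {}))
        recruitment = RecruitmentConfig(**payload.pop("recruitment", {}))
        return cls(cohort=cohort, recruitment=recruitment, **payload)


def features_from_geometry(record, geom: SpineGeometry,
                           recruitment: RecruitmentConfig = None) -> dict:
    """Geometrical descriptors plus simulated biomechanical predictors for
    one subject."""
    gp = geometrical_params(geom)
    curves = detect_curves(geom)
    cfg = ScalingConfig(height=record.height, weight=record.weight,
                        age=record.age)
    model = build_model(record, geom, cfg)
    solution = solve_inverse_statics(model, recruitment)
    bp = extract_biomech_params(solution, curves[0])
    row = {"age": record.age, "sex": record.sex, "risser": record.risser}
    row.update(gp.as_dict())
    row.update(bp.as_dict())
    return row


def run_pipeline(config: RunConfig) -> dict:
    """Execute the whole chain and write all artifacts to ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("scolprog %s, seed %d, mode %s", __version__,
                    config.seed, config.cohort.mode)
        config.to_yaml(out / "config.yaml")
        cohort = generate_cohort(config.cohort)
        cohort_df = cohort_to_frame(cohort)
        cohort_df.to_csv(out / "cohort.csv", index=False)

        if config.cohort.mode == "feature_level":
            features = cohort_df[["id", "group"] + FEATURE_COLUMNS].copy()
        else:
            rows = []
            for rec, geom in cohort:
                try:
                    row = features_from_geometry(rec, geom, config.recruitment)
                except Exception as e:      # noqa: BLE001 - annotate and re-raise
                    raise StageError("biomechanics", rec.id, e) from e
                row["id"] = rec.id
                row["group"] = rec.group
                rows.append(row)
            features = pd.DataFrame(rows)[["id", "group"] + FEATURE_COLUMNS]
        features.to_csv(out / "features.csv", index=False)

        reduced = assemble_predictors(features, "reduced")
        full = assemble_predictors(features, "full")

        logger.info("pre-selection: %d x %d-fold CV", config.preselect_repetitions,
                    config.preselect_folds)
        pre = {
            "reduced": preselect(reduced, ALGORITHMS,
                                 n_rep=config.preselect_repetitions,
                                 k=config.preselect_folds, seed=config.seed + 1),
            "full": preselect(full, ALGORITHMS,
                              n_rep=config.preselect_repetitions,
                              k=config.preselect_folds, seed=config.seed + 1),
        }
        acc_rows = []
        for set_name, res in pre.items():
            for alg, vals in res.accuracy.items():
                for i, v in enumerate(vals):
                    acc_rows.append({"set": set_name, "algorithm": alg,
                                     "fold": i, "accuracy": v})
        pd.DataFrame(acc_rows).to_csv(out / "accuracy.csv", index=False)

        medians = {alg: np.median(pre["reduced"].accuracy[alg]) for alg in ALGORITHMS}
        selected = sorted(medians, key=medians.get, reverse=True)[: config.n_selected]
        logger.info("selected algorithms: %s", selected)

        comp = compare_models(reduced, full, algorithms=selected,
                              n_iter=config.compare_iterations,
                              seed=config.seed + 2)
        ss_rows = []
        for (alg, set_name), vals in comp.sensitivity.items():
            for i, v in enumerate(vals):
                ss_rows.append({"algorithm": alg, "set": set_name,
                                "iteration": i, "sensitivity": v,
                                "specificity": comp.specificity[(alg, set_name)][i]})
        pd.DataFrame(ss_rows).to_csv(out / "sensitivity_specificity.csv", index=False)

        kw = {s: kruskal_with_posthoc(pre[s].accuracy) for s in ("reduced", "full")}
        rf = reduced_vs_full_tests(comp)
        rf.to_csv(out / "reduced_vs_full_tests.csv", index=False)

        summary = {
            "version": __version__,
            "seed": config.seed,
            "mode": config.cohort.mode,
            "n_subjects": int(len(features)),
            "selected_algorithms": selected,
            "median_accuracy": {
                s: {alg: float(np.median(pre[s].accuracy[alg])) for alg in ALGORITHMS}
                for s in ("reduced", "full")},
            "median_sensitivity": {
                f"{alg}_{s}": float(np.median(v))
                for (alg, s), v in comp.sensitivity.items()},
            "median_specificity": {
                f"{alg}_{s}": float(np.median(v))
                for (alg, s), v in comp.specificity.items()},
            "kruskal_pvalue": {s: kw[s][0] for s in ("reduced", "full")},
            "reduced_vs_full_pvalues": {
                f"{r.algorithm}_{r.metric}": r.pvalue for r in rf.itertuples()},
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        logger.info("run complete")
        return {"cohort": cohort_df, "features": features, "preselection": pre,
                "comparison": comp, "summary": summary}
    finally:
        logger.removeHandler(handler)
        handler.close()
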