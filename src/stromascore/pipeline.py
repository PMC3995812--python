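"""End-to-end orchestration: slide pairs -> compartment scores -> survival stats.

``run_score_batch`` chains, per sample: unmix the IHC tile, threshold the
DAB map, register IHC onto ISH, transfer the tumor mask, unmix the ISH
tile, threshold the blue chromogen map, build compartments inside the ROI
and score TBS / TBT / TSA. Per-sample failures are isolated (logged, the
batch continues) because batch slide processing routinely hits bad files.

``run_survival`` joins per-sample scores onto the clinical table, assigns
tertiles, runs the Spearman screen, univariate Cox fits per covariate, the
backward-eliminated multivariable model, PH diagnostics and survival
curves, and writes one JSON + CSV bundle. All runs are deterministic given
the configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .compartments import build_compartments, compute_scores
from .registration import register, warp_mask
from .stains import (
    DEFAULT_IHC_STAINS,
    DEFAULT_ISH_STAINS,
    StainMatrix,
    rgb_to_od,
    threshold_stain,
    unmix,
)
from .survival import (
    TIME_COL,
    EVENT_COL,
    assign_tertiles,
    cox_multivariate_backward,
    cox_univariate,
    ph_test,
    spearman_screen,
    survival_curves,
    validate_cohort,
)

__all__ = ["RunConfig", "run_score_batch", "run_survival", "write_bundle"]

log = logging.getLogger("stromascore")

SCORE_COLUMNS = [
    "sample_id",
    "tbs",
    "tbt",
    "tsa",
    "blue_area_stroma",
    "mean_blue_od_stroma",
    "blue_area_tumor",
    "mean_blue_od_tumor",
    "threshold_used",
    "registration_score",
]

CLINICAL_VARIABLES = [
    "age",
    "gender",
    "site",
    "t_status",
    "n_status",
    "grade",
    "perineural",
    "margin",
    "stage",
    "pack_years",
    "treatment",
]


@dataclass
class RunConfig:
    """Configuration shared by the scoring and survival stages."""

    out_dir: str = "."
    ihc_stain_matrix: str | None = None   # JSON path; None -> package default
    ish_stain_matrix: str | None = None
    dab_stain: str = "dab"
    blue_stain: str = "nbt_bcip"
    ihc_counterstain: str = "hematoxylin"
    ish_counterstain: str = "nuclear_fast_red"
    threshold_method: str = "triangle"
    threshold_value: float | None = None
    registration_model: str = "similarity"
    score_column: str = "tbs"
    removal_alpha: float = 0.10
    seed: int = 0

    def ihc_stains(self) -> StainMatrix:
        if self.ihc_stain_matrix:
            return StainMatrix.from_json(self.ihc_stain_matrix)
        return DEFAULT_IHC_STAINS

    def ish_stains(self) -> StainMatrix:
        if self.ish_stain_matrix:
            return StainMatrix.from_json(self.ish_stain_matrix)
        return DEFAULT_ISH_STAINS

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return cls(**payload)


def score_sample(
    ihc: np.ndarray,
    ish: np.ndarray,
    roi: np.ndarray | None,
    config: RunConfig,
) -> dict:
    """Score one slide pair; ROI is in ISH coordinates (None -> whole tile)."""
    maps_ihc = unmix(rgb_to_od(ihc), config.ihc_stains())
    dab_mask = threshold_stain(
        maps_ihc[config.dab_stain], config.threshold_method, config.threshold_value
    )
    reg = register(
        ihc,
        ish,
        model=config.registration_model,
        moving_stains=config.ihc_stains(),
        fixed_stains=config.ish_stains(),
        moving_counterstain=config.ihc_counterstain,
        fixed_counterstain=config.ish_counterstain,
    )
    dab_warped = warp_mask(dab_mask, reg.transform, ish.shape[:2])

    maps_ish = unmix(rgb_to_od(ish), config.ish_stains())
    blue = maps_ish[config.blue_stain]
    blue_mask = threshold_stain(blue, config.threshold_method, config.threshold_value)

    if roi is None:
        roi = np.ones(ish.shape[:2], dtype=bool)
    comp = build_compartments(roi, dab_warped)
    panel = compute_scores(blue, blue_mask, comp)
    row = panel.as_dict()
    row.pop("negative_stroma_area")
    row["threshold_used"] = blue_mask.meta["threshold"]
    row["registration_score"] = reg.similarity_final
    log.info(
        "scored sample: blue threshold %.4f OD, DAB threshold %.4f OD, "
        "registration NCC %.4f (model=%s)",
        blue_mask.meta["threshold"],
        dab_mask.meta["threshold"],
        reg.similarity_final,
        config.registration_model,
    )
    return row


def run_score_batch(
    manifest: pd.DataFrame, config: RunConfig
) -> tuple[pd.DataFrame, list[dict]]:
    """Score every (sample_id, ihc_path, ish_path[, roi_path]) manifest row.

    Returns the score table and a list of per-sample failures. Raises only
    if every sample fails.
    """
    if manifest["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in manifest")
    rows, failures = [], []
    for rec in manifest.to_dict("records"):
        sid = rec["sample_id"]
        try:
            ihc = np.asarray(iio.imread(rec["ihc_path"]))[..., :3]
            ish = np.asarray(iio.imread(rec["ish_path"]))[..., :3]
            roi = None
            if rec.get("roi_path") and not pd.isna(rec["roi_path"]):
                roi = np.asarray(iio.imread(rec["roi_path"])) > 127
            row = score_sample(ihc, ish, roi, config)
            rows.append({"sample_id": sid, **row})
        except Exception as exc:  # noqa: BLE001 - per-sample isolation
            log.error("sample %s failed: %s", sid, exc)
            failures.append({"sample_id": sid, "error": str(exc)})
    if not rows:
        raise RuntimeError(
            f"all {len(failures)} samples failed; first error: {failures[0]['error']}"
        )
    scores = pd.DataFrame(rows)[SCORE_COLUMNS]
    return scores, failures


def run_survival(
    scores: pd.DataFrame | None,
    clinical: pd.DataFrame,
    config: RunConfig,
) -> dict:
    """Join scores onto the clinical table and run the full survival workflow."""
    if scores is not None:
        orphans_s = set(scores["sample_id"]) - set(clinical["patient_id"])
        orphans_c = set(clinical["patient_id"]) - set(scores["sample_id"])
        if orphans_s or orphans_c:
            raise ValueError(
                "scores and clinical tables do not join 1:1; "
                f"unmatched sample_ids={sorted(orphans_s)}, "
                f"unmatched patient_ids={sorted(orphans_c)}"
            )
        cohort = clinical.merge(
            scores.rename(columns={"sample_id": "patient_id"}),
            on="patient_id",
            suffixes=("_clinical", ""),
        )
    else:
        cohort = clinical.copy()
    validate_cohort(cohort)
    if cohort[EVENT_COL].sum() == 0:
        raise ValueError("no events")

    tert = assign_tertiles(
        cohort[config.score_column].to_numpy(), ids=cohort["patient_id"].to_numpy()
    )
    cohort = cohort.copy()
    cohort["tbs_tertile"] = tert.index
    cohort["tbs_tertile_step"] = tert.index.astype(float)

    variables = [v for v in CLINICAL_VARIABLES if v in cohort.columns]
    screen = spearman_screen(cohort, config.score_column, variables)

    uni_rows, uni_fits = [], {}
    for var in variables + ["tbs_tertile"]:
        try:
            fit = cox_univariate(cohort, var)
        except ValueError as exc:
            log.warning("univariate fit for %s skipped: %s", var, exc)
            continue
        uni_fits[var] = fit
        s = fit.summary()
        s.insert(0, "variable", var)
        s["logrank_p"] = np.nan if fit.logrank_p is None else float(fit.logrank_p)
        uni_rows.append(s)
        log.info("univariate Cox %s: ties=%s, n=%d, events=%d", var, fit.ties, fit.n, fit.n_events)
    univariate = pd.concat(uni_rows, ignore_index=True)

    candidates = [
        v for v, f in uni_fits.items() if f.converged and float(f.p.min()) < 0.05
    ]
    # model the tertile effect per step (as the generator defines it) rather
    # than as two indicators when it enters the multivariable model
    candidates = ["tbs_tertile_step" if c == "tbs_tertile" else c for c in candidates]
    multivariate = None
    trace: list[dict] = []
    diagnostics = []
    if candidates:
        multivariate, trace = cox_multivariate_backward(
            cohort, candidates, removal_alpha=config.removal_alpha
        )
        for step in trace:
            log.info("backward elimination removed %s (p=%.3f)", step["removed"], step["p"])
        diagnostics = ph_test(multivariate)

    curves = None
    if (
        pd.Series(tert.index)[cohort[EVENT_COL] == 1].nunique() >= 2
    ):
        curves = survival_curves(cohort, tert)

    return {
        "tertiles": {
            "sizes": list(tert.sizes),
            "cut_ranks": list(tert.cut_ranks),
            "score_column": config.score_column,
        },
        "spearman": screen,
        "univariate": univariate,
        "multivariate": multivariate,
        "elimination_trace": trace,
        "ph_diagnostics": diagnostics,
        "curves": curves,
        "n": len(cohort),
        "n_events": int(cohort[EVENT_COL].sum()),
    }


def write_bundle(bundle: dict, out_dir: str | Path) -> None:
    """Write the survival bundle as one JSON plus per-table CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["spearman"].to_csv(out / "spearman.csv", index=False)
    bundle["univariate"].to_csv(out / "cox_univariate.csv", index=False)
    payload = {
        "tertiles": bundle["tertiles"],
        "n": bundle["n"],
        "n_events": bundle["n_events"],
        "elimination_trace": bundle["elimination_trace"],
    }
    if bundle["multivariate"] is not None:
        fit = bundle["multivariate"]
        fit.summary().to_csv(out / "cox_multivariate.csv", index=False)
        payload["multivariate"] = {
            "ties": fit.ties,
            "converged": fit.converged,
            "terms": fit.terms,
            "hr": [float(x) for x in fit.hr],
            "ci_lower": [float(x) for x in fit.ci_lower],
            "ci_upper": [float(x) for x in fit.ci_upper],
            "p": [float(x) for x in fit.p],
            "flags": fit.flags,
        }
        payload["ph_diagnostics"] = [asdict(d) for d in bundle["ph_diagnostics"]]
    if bundle["curves"] is not None:
        bundle["curves"].cox_curves.to_csv(out / "cox_curves.csv", index=False)
        bundle["curves"].km_curves.to_csv(out / "km_curves.csv", index=False)
        payload["logrank"] = {
            "statistic": bundle["curves"].logrank_stat,
            "p": bundle["curves"].logrank_p,
        }
    (out / "survival_bundle.json").write_text(json.dumps(payload, indent=2))
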