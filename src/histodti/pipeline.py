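"""ROI extraction, cohort assembly, and end-to-end synthetic runs."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cell_density import CellCountParams, count_cells
from .dti import compute_scalar_metrics, EigenvalueTriple
from .model import PREDICTORS, fit_multivariate, loao_cv, loro_cv, univariate_table
from .phantoms import (AstroPhantomSpec, CohortSpec, FiberPhantomSpec,
                       NisslPhantomSpec, REGIONS, generate_astrocytes,
                       generate_cohort, generate_fibers, generate_nissl)
from .skeleton import SkeletonConfig, skeletonize_and_analyze
from .stats import effect_size_table
from .structure_tensor import StConfig, roi_anisotropy

logger = logging.getLogger("histodti")

__all__ = ["RunConfig", "extract_roi_value", "assemble_cohort", "run_all"]

#: the configured region vocabulary
REGION_VOCABULARY = set(REGIONS)


@dataclass
class RoiSet:
    """Region masks for one section/volume, with geometry metadata.

    ``bregma_mm`` is annotation only (the anatomical plane the section was
    taken from); DTI-histology correspondence is by region label, not by
    registration.
    """

    region: str
    masks: dict  # modality name -> boolean mask
    pixel_size: float | None = None  # um / pixel, where applicable
    bregma_mm: float | None = None

    def __post_init__(self) -> None:
        if self.region not in REGION_VOCABULARY:
            raise ValueError(f"unknown region {self.region!r}; "
                             f"vocabulary: {sorted(REGION_VOCABULARY)}")
        for name, mask in self.masks.items():
            if not np.asarray(mask).any():
                raise ValueError(f"empty mask for modality {name!r}")


def extract_roi_value(scalar_map: np.ndarray, roi: np.ndarray) -> float:
    """Missing-aware mean of a scalar map over an ROI mask."""
    scalar_map = np.asarray(scalar_map, float)
    roi = np.asarray(roi).astype(bool)
    if roi.shape != scalar_map.shape:
        raise ValueError("ROI shape must match the map")
    if not roi.any():
        raise ValueError("empty ROI mask")
    vals = scalar_map[roi]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("ROI contains only missing values")
    return float(vals.mean())


def assemble_cohort(dti_values: pd.DataFrame, histo_values: pd.DataFrame,
                    manifest: pd.DataFrame) -> pd.DataFrame:
    """One row per (animal, region), joining DTI and histology values.

    ``manifest`` lists the expected (animal_id, group, region) rows; pairs
    missing from either value table stay as NaN and are logged.  Duplicate
    (animal, region) entries in any input raise.
    """
    keys = ["animal_id", "region"]
    for name, df in (("manifest", manifest), ("dti_values", dti_values),
                     ("histo_values", histo_values)):
        dup = df.duplicated(subset=keys)
        if dup.any():
            raise ValueError(f"duplicate (animal, region) entries in {name}: "
                             f"{df.loc[dup, keys].to_dict('records')}")
    out = manifest.merge(dti_values, on=keys, how="left", validate="1:1")
    out = out.merge(histo_values, on=keys, how="left", validate="1:1")
    n_missing = int(out.drop(columns=["group"], errors="ignore").isna().any(axis=1).sum())
    if n_missing:
        logger.warning("assemble_cohort: %d row(s) with missing values", n_missing)
    payload = out.to_csv(index=False).encode()
    out.attrs["config_hash"] = hashlib.sha256(payload).hexdigest()[:16]
    return out


@dataclass
class RunConfig:
    """Configuration of an end-to-end synthetic run."""

    out_dir: str = "runs/synthetic"
    seed: int = 0
    cohort: dict = field(default_factory=dict)        # CohortSpec overrides
    regions: tuple[str, ...] = REGIONS
    responses_for_model: tuple[str, ...] = ()         # default: all cohort responses
    st: dict = field(default_factory=dict)            # StConfig overrides
    skeleton: dict = field(default_factory=dict)      # SkeletonConfig overrides
    cells: dict = field(default_factory=dict)         # CellCountParams overrides
    n_perm: int = 10_000
    n_boot: int = 2000
    render_images: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.regions) - REGION_VOCABULARY
        if unknown:
            raise ValueError(f"unknown region name(s) {sorted(unknown)}; "
                             f"vocabulary: {sorted(REGION_VOCABULARY)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = set(cls.__dataclass_fields__)
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "regions" in raw:
            raw["regions"] = tuple(raw["regions"])
        if "responses_for_model" in raw:
            raw["responses_for_model"] = tuple(raw["responses_for_model"])
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"stage {name!r} failed: {err}") from err
        return wrapped
    return deco


@_stage("images")
def _image_stage(cfg: RunConfig, out: Path) -> dict:
    """Quantify one phantom of each image modality as a pipeline exercise."""
    from .images import write_micrograph

    report = {}
    img, truth = generate_nissl(NisslPhantomSpec(seed=cfg.seed, noise_sd=10.0))
    res = count_cells(img, np.ones(img.shape, bool), CellCountParams(**cfg.cells))
    report["cell_count"] = {"counted": res.count, "truth": truth.count,
                            "cd_per_mm2": res.cd_per_mm2}
    write_micrograph(out / "images" / "nissl.tif", img)

    img, otruth = generate_fibers(FiberPhantomSpec(seed=cfg.seed))
    ai = roi_anisotropy(img, cfg=StConfig(**cfg.st))
    report["fiber_ai"] = {"AI": ai.AI, "circular_variance": otruth.circular_variance}
    write_micrograph(out / "images" / "fibers.tif", img)

    img, struth = generate_astrocytes(AstroPhantomSpec(seed=cfg.seed))
    skel_cfg = SkeletonConfig(**cfg.skeleton)
    binary = img.pixels <= skel_cfg.threshold_upper
    _, metrics = skeletonize_and_analyze(binary, img.pixel_size,
                                         cutoff=skel_cfg.fragment_cutoff)
    report["skeleton"] = {"measured": metrics.as_dict(),
                          "truth_branches": struth.branches,
                          "truth_junctions": struth.junctions}
    write_micrograph(out / "images" / "astro.tif", img)
    return report


def run_all(config: RunConfig) -> dict:
    """Full synthetic pipeline: simulate, quantify, test, model, validate.

    Emits the effect-size, regression, univariate-correlation, and
    cross-validation tables as CSV under ``config.out_dir`` plus a run log
    with versions, seed, and the full configuration.  Returns a summary
    report dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed}

    spec = CohortSpec(seed=config.seed, **config.cohort)
    cohort = generate_cohort(spec)
    cohort.to_csv(out / "cohort.csv", index=False)
    report["cohort_rows"] = len(cohort)

    if config.render_images:
        report["images"] = _image_stage(config, out)

    dti_params = ["FA", "AD", "RD", "MD", "CL", "CP", "CS"]
    effects = effect_size_table(cohort, dti_params, n_boot=config.n_boot,
                                n_perm=config.n_perm, seed=config.seed)
    effects.to_csv(out / "effect_sizes_dti.csv", index=False)

    responses = list(config.responses_for_model) or list(spec.responses)
    fits, loaos, loros = [], [], []
    for resp in responses:
        fit = fit_multivariate(cohort, resp, n_boot=config.n_boot, seed=config.seed)
        cv = loao_cv(cohort, resp)
        loro = loro_cv(cohort, resp)
        fits.append(dict(response=resp, R2=fit.R2, R2_ci_low=fit.R2_ci[0],
                         R2_ci_high=fit.R2_ci[1], R2_adj=fit.R2_adj, F=fit.F,
                         R_cv=cv.R_cv, Q2=cv.Q2, n=fit.n))
        loaos.append(cv)
        loros.append(dict(response=resp, pooled_R=loro.pooled_R, **loro.per_region))
    fit_table = pd.DataFrame(fits)
    fit_table.to_csv(out / "regression.csv", index=False)
    pd.DataFrame(loros).to_csv(out / "loro.csv", index=False)

    uni = univariate_table(cohort, responses)
    uni.to_csv(out / "univariate.csv", index=False)

    report["regression"] = fit_table.to_dict("records")
    with open(out / "run_log.json", "w") as fh:
        json.dump({"config": asdict(config), "report": _jsonable(report)}, fh, indent=2)
    logger.info("run_all: wrote outputs to %s", out)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
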