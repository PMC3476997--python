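"""File-level orchestration: run configuration and the end-to-end pipeline.

``RunConfig`` gathers every stage parameter (nested YAML sections with flag
overrides at the CLI); :func:`run_pipeline` validates inputs up front, runs
the fitted model and writes all intermediates plus a JSON manifest.  The
run's data-derived thresholds and frequency cutoffs are always logged,
since they are outputs of the data, not constants.
"""

from __future__ import annotations

import logging
import os
from dataclasses import asdict, dataclass

import yaml

from .model import CnGeIntegration
from .segmentation import CbsParams

logger = logging.getLogger("cnage")


@dataclass
class RunConfig:
    cn_path: str = ""
    cn_annotation: str = ""
    ge_path: str = ""
    ge_annotation: str = ""
    sample_classes: str | None = None
    output_dir: str = "cnage_out"
    seed: int = 0
    normalization_enabled: bool = True
    alpha: float = 0.01
    n_perm: int = 10000
    min_width: int = 2
    smooth_region: int = 10
    smooth_sd: float = 3.0
    smooth_cn: bool = True
    smooth_ge: bool = True
    r_threshold: float = 0.60
    outlier_min_fraction: float = 1.0 / 3.0
    outlier_k_mad: float = 3.0
    quantile: float = 0.90
    max_gap_loci: int = 1
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        flat: dict = {}
        section_map = {
            "input": {
                "cn": "cn_path",
                "cn_annotation": "cn_annotation",
                "ge": "ge_path",
                "ge_annotation": "ge_annotation",
                "sample_classes": "sample_classes",
            },
            "normalization": {"enabled": "normalization_enabled"},
            "segmentation": {
                "alpha": "alpha",
                "n_perm": "n_perm",
                "min_width": "min_width",
                "smooth_region": "smooth_region",
                "smooth_sd": "smooth_sd",
                "smooth_cn": "smooth_cn",
                "smooth_ge": "smooth_ge",
            },
            "correlation": {
                "r_threshold": "r_threshold",
                "outlier_min_fraction": "outlier_min_fraction",
                "outlier_k_mad": "outlier_k_mad",
            },
            "frequency": {"quantile": "quantile"},
            "hotspots": {"max_gap_loci": "max_gap_loci"},
        }
        for key, value in raw.items():
            if key in section_map and isinstance(value, dict):
                for sub, dest in section_map[key].items():
                    if sub in value:
                        flat[dest] = value[sub]
            elif key in cls.__dataclass_fields__:
                flat[key] = value
            else:
                raise ValueError(f"unknown configuration key {key!r} in {path}")
        flat.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**flat)

    def cbs_params(self) -> CbsParams:
        return CbsParams(
            alpha=self.alpha,
            n_perm=self.n_perm,
            min_width=self.min_width,
            smooth_region=self.smooth_region,
            smooth_sd=self.smooth_sd,
            seed=self.seed,
        )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow from files and return the run manifest.

    Aborts before any computation when a referenced input path is missing;
    stage errors propagate with the failing stage named.
    """
    for label, path in [
        ("CN matrix", config.cn_path),
        ("CN annotation", config.cn_annotation),
        ("GE matrix", config.ge_path),
        ("GE annotation", config.ge_annotation),
        ("sample classes", config.sample_classes),
    ]:
        if path and not os.path.exists(path):
            raise FileNotFoundError(f"{label} not found: {path}")
    for label in ("cn_path", "cn_annotation", "ge_path", "ge_annotation"):
        if not getattr(config, label):
            raise FileNotFoundError(f"required input {label} not configured")

    logger.info("loading inputs")
    model = CnGeIntegration.from_files(
        config.cn_path,
        config.cn_annotation,
        config.ge_path,
        config.ge_annotation,
        sample_classes=config.sample_classes,
        cbs_params=config.cbs_params(),
        r_threshold=config.r_threshold,
        outlier_min_fraction=config.outlier_min_fraction,
        outlier_k_mad=config.outlier_k_mad,
        quantile=config.quantile,
        max_gap_loci=config.max_gap_loci,
        normalization_enabled=config.normalization_enabled,
        smooth_cn=config.smooth_cn,
        smooth_ge=config.smooth_ge,
    )
    logger.info("fitting model (normalize -> segment -> correlate -> discretize)")
    results = model.fit()
    t = results.thresholds
    logger.info(
        "derived thresholds: gain>%.4f loss<%.4f up>%.4f down<%.4f; "
        "cutoffs U-G>=%d D-L>=%d",
        t.cn_gain,
        t.cn_loss,
        t.ge_up,
        t.ge_down,
        results.cutoffs.ug_cutoff,
        results.cutoffs.dl_cutoff,
    )
    manifest = results.save(config.output_dir, seed=config.seed)
    if config.make_plots:
        plots = {
            "genome_frequency": os.path.join(config.output_dir, "genome_frequency.png"),
            "correlation_density": os.path.join(
                config.output_dir, "correlation_density.png"
            ),
        }
        results.plot_genome_frequency(plots["genome_frequency"])
        results.plot_correlation_density(plots["correlation_density"])
        manifest["outputs"].update(plots)
    manifest["config"] = asdict(config)
    import json

    with open(
        os.path.join(config.output_dir, "manifest.json"), "w", encoding="utf-8"
    ) as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    logger.info(
        "done: %d U-G and %d D-L regions",
        manifest["n_ug_regions"],
        manifest["n_dl_regions"],
    )
    return manifest
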