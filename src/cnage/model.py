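"""Model/Results interface for the paired CN-GE hotspot analysis.

:class:`CnGeIntegration` is built from paired signal matrices (or files) and
``fit()`` runs the whole procedure - normalization, per-sample CBS
segmentation of both tracks, locus correlation with outlier recovery,
k-means discretization, frequency cutoffs and hotspot-region calling -
returning an :class:`IntegrationResults` that carries every intermediate,
the data-derived thresholds, a ``summary()`` table, plotting helpers and a
``save()`` that writes the SEG/TSV/JSON artefact set.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .correlation import (
    LocusCorrelation,
    combine_correlations,
    correlate_loci,
    correlation_frame,
    detect_segment_outlier_loci,
    recover_outlier_correlations,
    segment_values_at_loci,
)
from .discretize import (
    DiscretizationThresholds,
    FrequencyCutoffs,
    assign_states,
    frequency_cutoffs,
    joint_category_counts,
    kmeans3_thresholds,
)
from .hotspots import (
    DL,
    UG,
    HotspotRegion,
    merge_into_regions,
    region_report,
    select_hotspot_loci,
)
from .io import ensure_dir, read_signal_matrix, write_segments
from .normalization import passthrough_log2_ratio, to_log2_ratio
from .segmentation import CbsParams, cbs_segment
from .tracks import RatioMatrix, SegmentedProfile, SignalMatrix


class CnGeIntegration:
    """Paired copy-number / gene-expression hotspot model.

    Parameters
    ----------
    cn, ge : SignalMatrix
        Paired probe-level CN and gene-level GE signals over the same
        samples (tumors plus the normals used as the ratio reference).
    cbs_params : CbsParams, optional
        Segmentation settings (shared by both tracks unless smoothing is
        toggled per track via ``smooth_cn``/``smooth_ge``).
    r_threshold : float
        Correlation significance threshold on Pearson r (default 0.60).
    outlier_min_fraction, outlier_k_mad : float
        Outlier-recovery rule: a locus must deviate by more than
        ``k_mad`` robust SDs from its expression segment in at least
        ``min_fraction`` of samples to be re-tested unsegmented.
    quantile : float
        Upper quantile defining the U-G / D-L frequency cutoffs.
    max_gap_loci : int
        Non-qualifying loci tolerated inside a merged hotspot region.
    normalization_enabled : bool
        When False, tumor columns are taken as pre-computed log2 ratios.
    """

    def __init__(
        self,
        cn: SignalMatrix,
        ge: SignalMatrix,
        cbs_params: CbsParams | None = None,
        r_threshold: float = 0.60,
        outlier_min_fraction: float = 1.0 / 3.0,
        outlier_k_mad: float = 3.0,
        quantile: float = 0.90,
        max_gap_loci: int = 1,
        normalization_enabled: bool = True,
        smooth_cn: bool | None = None,
        smooth_ge: bool | None = None,
    ) -> None:
        if set(cn.tumor_samples) != set(ge.tumor_samples):
            raise ValueError("CN and GE matrices must share the same tumor samples")
        self.cn = cn
        self.ge = ge
        self.cbs_params = cbs_params or CbsParams()
        self.r_threshold = r_threshold
        self.outlier_min_fraction = outlier_min_fraction
        self.outlier_k_mad = outlier_k_mad
        self.quantile = quantile
        self.max_gap_loci = max_gap_loci
        self.normalization_enabled = normalization_enabled
        self.smooth_cn = self.cbs_params.smooth if smooth_cn is None else smooth_cn
        self.smooth_ge = self.cbs_params.smooth if smooth_ge is None else smooth_ge

    @classmethod
    def from_files(
        cls,
        cn_path: str,
        cn_annotation: str,
        ge_path: str,
        ge_annotation: str,
        sample_classes: str | dict | None = None,
        **kwargs,
    ) -> "CnGeIntegration":
        cn = read_signal_matrix(cn_path, cn_annotation, "cn_probe", sample_classes)
        ge = read_signal_matrix(ge_path, ge_annotation, "gene_locus", sample_classes)
        return cls(cn, ge, **kwargs)

    # -- fitting ---------------------------------------------------------

    def fit(self) -> "IntegrationResults":
        cn_ratio = (
            to_log2_ratio(self.cn)
            if self.normalization_enabled
            else passthrough_log2_ratio(self.cn)
        )
        ge_ratio = (
            to_log2_ratio(self.ge)
            if self.normalization_enabled
            else passthrough_log2_ratio(self.ge)
        )
        samples = cn_ratio.samples
        ge_ratio = RatioMatrix(
            ge_ratio.track,
            samples,
            ge_ratio.to_frame()[samples].to_numpy(),
        )

        from dataclasses import replace

        cn_params = replace(self.cbs_params, smooth=self.smooth_cn)
        ge_params = replace(self.cbs_params, smooth=self.smooth_ge)
        cn_profiles = {
            s: cbs_segment(cn_ratio.track, cn_ratio.values[:, k], cn_params, sample=s)
            for k, s in enumerate(samples)
        }
        ge_profiles = {
            s: cbs_segment(ge_ratio.track, ge_ratio.values[:, k], ge_params, sample=s)
            for k, s in enumerate(samples)
        }

        gene_track = ge_ratio.track
        chroms = gene_track.chroms
        mids = gene_track.midpoints
        cn_at_locus = pd.DataFrame(
            {
                s: segment_values_at_loci(cn_profiles[s], chroms, mids)
                for s in samples
            },
            index=gene_track.ids,
        )
        ge_at_locus = pd.DataFrame(
            {s: ge_profiles[s].values for s in samples}, index=gene_track.ids
        )
        ge_raw = ge_ratio.to_frame()

        primary = correlate_loci(cn_at_locus, ge_at_locus, self.r_threshold)
        m_tested = sum(1 for c in primary if not math.isnan(c.r))
        outliers = detect_segment_outlier_loci(
            ge_raw, ge_profiles, self.outlier_min_fraction, self.outlier_k_mad
        )
        recovered = recover_outlier_correlations(
            outliers, ge_raw, cn_at_locus, self.r_threshold, m=max(m_tested, 1)
        )
        correlations = combine_correlations(primary, recovered)

        cn_pool = cn_at_locus.to_numpy().ravel()
        ge_pool = ge_at_locus.to_numpy().ravel()
        cn_loss, cn_gain = kmeans3_thresholds(cn_pool[np.isfinite(cn_pool)])
        ge_down, ge_up = kmeans3_thresholds(ge_pool[np.isfinite(ge_pool)])
        thresholds = DiscretizationThresholds(cn_gain, cn_loss, ge_up, ge_down)

        covered = cn_at_locus.dropna().index
        cn_states = assign_states(
            cn_at_locus.loc[covered].to_numpy(), cn_loss, cn_gain
        )
        ge_states = assign_states(
            ge_at_locus.loc[covered].to_numpy(), ge_down, ge_up
        )
        counts = joint_category_counts(cn_states, ge_states, list(covered))
        cutoffs = frequency_cutoffs(counts, self.quantile)

        regions: dict[str, list[HotspotRegion]] = {}
        for direction in (UG, DL):
            loci = select_hotspot_loci(correlations, counts, cutoffs, direction)
            regions[direction] = merge_into_regions(
                loci,
                gene_track,
                correlations,
                counts,
                direction,
                n_samples=len(samples),
                max_gap_loci=self.max_gap_loci,
            )

        return IntegrationResults(
            model=self,
            samples=samples,
            cn_ratio=cn_ratio,
            ge_ratio=ge_ratio,
            cn_profiles=cn_profiles,
            ge_profiles=ge_profiles,
            cn_at_locus=cn_at_locus,
            ge_at_locus=ge_at_locus,
            correlations=correlations,
            outlier_loci=outliers,
            thresholds=thresholds,
            category_counts=counts,
            cutoffs=cutoffs,
            ug_regions=regions[UG],
            dl_regions=regions[DL],
        )


@dataclass
class IntegrationResults:
    """Everything the fitted pipeline produced, with reporting helpers."""

    model: CnGeIntegration
    samples: list[str]
    cn_ratio: RatioMatrix
    ge_ratio: RatioMatrix
    cn_profiles: dict[str, SegmentedProfile]
    ge_profiles: dict[str, SegmentedProfile]
    cn_at_locus: pd.DataFrame
    ge_at_locus: pd.DataFrame
    correlations: list[LocusCorrelation]
    outlier_loci: list[str]
    thresholds: DiscretizationThresholds
    category_counts: pd.DataFrame
    cutoffs: FrequencyCutoffs
    ug_regions: list[HotspotRegion]
    dl_regions: list[HotspotRegion]
    manifest: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def significant_loci(self) -> list[str]:
        return [c.locus for c in self.correlations if c.significant]

    @property
    def recovered_loci(self) -> list[str]:
        return [
            c.locus
            for c in self.correlations
            if c.significant and c.source == "outlier_recovered"
        ]

    def correlation_table(self) -> pd.DataFrame:
        track = self.ge_ratio.track
        chrom_of = dict(zip(track.ids, track.chroms))
        mid_of = dict(zip(track.ids, (int(m) for m in track.midpoints)))
        return correlation_frame(self.correlations, chrom_of, mid_of)

    def summary(self) -> str:
        t = self.thresholds
        lines = [
            "Paired CN-GE hotspot analysis",
            "=" * 45,
            f"tumor samples:            {self.n_samples}",
            f"gene loci tested:         {len(self.category_counts)}",
            f"CN thresholds (k=3):      gain > {t.cn_gain:+.4f}, loss < {t.cn_loss:+.4f}",
            f"GE thresholds (k=3):      up   > {t.ge_up:+.4f}, down < {t.ge_down:+.4f}",
            f"frequency cutoffs (q={self.cutoffs.quantile:.2f}):"
            f" U-G >= {self.cutoffs.ug_cutoff}, D-L >= {self.cutoffs.dl_cutoff} samples",
            f"significant loci (r >= {self.model.r_threshold:.2f}): "
            f"{len(self.significant_loci)}"
            f" ({len(self.recovered_loci)} via outlier recovery)",
            f"U-G hotspot regions:      {len(self.ug_regions)}",
            f"D-L hotspot regions:      {len(self.dl_regions)}",
        ]
        for name, regions in (("U-G", self.ug_regions), ("D-L", self.dl_regions)):
            for k, region in enumerate(regions, start=1):
                lines.append(
                    f"  {name} {k}: {region.chrom}:{region.start}-{region.end}"
                    f"  genes={region.n_genes}  avg_r={region.avg_r:.3f}"
                    f"  avg_freq={region.avg_freq_pct:.2f}%"
                )
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------

    def save(self, outdir: str, seed: int | None = None) -> dict:
        """Write SEG files, correlation/count/region TSVs and a JSON manifest."""
        ensure_dir(outdir)
        paths = {
            "cn_segments": os.path.join(outdir, "cn_segments.seg"),
            "ge_segments": os.path.join(outdir, "ge_segments.seg"),
            "correlations": os.path.join(outdir, "locus_correlations.tsv"),
            "category_counts": os.path.join(outdir, "category_counts.tsv"),
            "ug_regions": os.path.join(outdir, "hotspots_ug.tsv"),
            "dl_regions": os.path.join(outdir, "hotspots_dl.tsv"),
            "manifest": os.path.join(outdir, "manifest.json"),
        }
        write_segments(
            [s for p in self.cn_profiles.values() for s in p.segments],
            paths["cn_segments"],
        )
        write_segments(
            [s for p in self.ge_profiles.values() for s in p.segments],
            paths["ge_segments"],
        )
        self.correlation_table().to_csv(paths["correlations"], sep="\t", index=False)
        self.category_counts.rename_axis("locus").to_csv(
            paths["category_counts"], sep="\t"
        )
        region_report(self.ug_regions, paths["ug_regions"])
        region_report(self.dl_regions, paths["dl_regions"])
        manifest = {
            "version": __version__,
            "seed": self.model.cbs_params.seed if seed is None else seed,
            "n_samples": self.n_samples,
            "r_threshold": self.model.r_threshold,
            "quantile": self.cutoffs.quantile,
            "thresholds": {
                "cn_gain": self.thresholds.cn_gain,
                "cn_loss": self.thresholds.cn_loss,
                "ge_up": self.thresholds.ge_up,
                "ge_down": self.thresholds.ge_down,
            },
            "cutoffs": {
                "ug": self.cutoffs.ug_cutoff,
                "dl": self.cutoffs.dl_cutoff,
            },
            "n_significant_loci": len(self.significant_loci),
            "n_recovered_loci": len(self.recovered_loci),
            "n_ug_regions": len(self.ug_regions),
            "n_dl_regions": len(self.dl_regions),
            "outputs": {k: v for k, v in paths.items() if k != "manifest"},
        }
        with open(paths["manifest"], "w", encoding="utf-8") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
        self.manifest = manifest
        return manifest

    # -- plots -----------------------------------------------------------

    def plot_genome_frequency(self, path: str, marker_frequency: float = 0.25):
        from .plotting import plot_genome_frequency

        return plot_genome_frequency(
            self.category_counts,
            self.ge_ratio.track,
            self.n_samples,
            path,
            marker_frequency=marker_frequency,
        )

    def plot_chromosome_detail(self, chrom: str, path: str):
        from .plotting import plot_chromosome_detail

        return plot_chromosome_detail(
            self.correlations,
            self.category_counts,
            self.ge_ratio.track,
            chrom,
            self.n_samples,
            path,
            r_threshold=self.model.r_threshold,
        )

    def plot_correlation_density(self, path: str):
        from .plotting import plot_correlation_density

        return plot_correlation_density(
            self.correlations, path, r_threshold=self.model.r_threshold
        )
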