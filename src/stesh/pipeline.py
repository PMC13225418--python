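"""End-to-end orchestration: preprocess -> histology -> graphs -> train -> cluster."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import downstream, histology, io_preprocess
from .graphs import GraphBundle, build_graph_bundle, default_radius
from .io_preprocess import FeatureMatrix, SpatialDataset
from .training import TrainConfig, TrainResult, train

__all__ = ["PipelineResult", "preprocess", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything a run produces, from inputs to domain labels."""

    dataset: SpatialDataset
    features: FeatureMatrix
    morphology: histology.MorphFeatureMatrix | None
    bundle: GraphBundle
    training: TrainResult
    domains: downstream.DomainLabels
    metrics: dict = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        return self.domains.labels


def preprocess(ds: SpatialDataset, cfg: TrainConfig) -> tuple[SpatialDataset, FeatureMatrix]:
    """Tissue filter -> HVG selection -> depth normalization."""
    ds = io_preprocess.filter_spots(ds)
    ds = io_preprocess.select_hvg(ds, n_top=cfg.n_top_genes)
    fm = io_preprocess.normalize_counts(
        ds, norm_mode=cfg.norm_mode, log_transform=cfg.log_transform
    )
    return ds, fm


def run_pipeline(
    ds: SpatialDataset,
    cfg: TrainConfig | None = None,
    n_domains: int | None = None,
    *,
    use_image: bool = True,
    extractor=None,
    patch_crop: int = 50,
    patch_out_size: int = 64,
    morph_dim: int = 50,
) -> PipelineResult:
    """Run the full workflow on one section.

    ``n_domains`` defaults to the number of distinct reference labels if the
    dataset carries them.  When the dataset has no image (or ``use_image``
    is False) the pipeline runs in image-free mode on two graphs.
    """
    cfg = cfg or TrainConfig()
    ds, fm = preprocess(ds, cfg)
    if n_domains is None:
        if ds.labels is None:
            raise ValueError("n_domains not given and the dataset has no labels")
        n_domains = len(np.unique(ds.labels))

    morph = None
    if use_image and ds.image is not None:
        morph = histology.morphological_features(
            ds.image, ds.coords, crop=patch_crop, out_size=patch_out_size,
            d=morph_dim, extractor=extractor,
        )

    bundle = build_graph_bundle(
        fm.X,
        ds.coords,
        morph.M if morph is not None else None,
        r=default_radius(ds.coords, factor=cfg.radius_factor),
        k_expr=cfg.k_expr,
        k_morph=cfg.k_morph,
    )
    result = train(fm.X, bundle, cfg)
    domains = downstream.cluster_embedding(result.E_final, n_domains, seed=cfg.seed)
    metrics = {}
    if ds.labels is not None:
        metrics = downstream.score_all(ds.labels, domains.labels)
    return PipelineResult(
        dataset=ds,
        features=fm,
        morphology=morph,
        bundle=bundle,
        training=result,
        domains=domains,
        metrics=metrics,
    )
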