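"""End-to-end convenience pipeline: QC -> normalize -> train -> project -> label."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from anndata import AnnData

from .annotate import (AnnotationResult, CellTypeAnnotator, ProjectionResult,
                       TrainingConfig)
from .qc import QCReport, QCThresholds, filter_cells, normalize

__all__ = ["PipelineOutput", "annotate_query"]


@dataclass
class PipelineOutput:
    result: AnnotationResult
    projection: ProjectionResult
    qc_reference: QCReport
    qc_query: QCReport

    @property
    def labels(self) -> pd.Series:
        return self.projection.labels


def annotate_query(reference: AnnData, query: AnnData,
                   label_key: str = "cell_type", cluster_key: str = "cluster",
                   thresholds: QCThresholds | None = None,
                   config: TrainingConfig | None = None) -> PipelineOutput:
    """Run the full annotation pipeline on raw count matrices.

    Both datasets are QC-filtered and depth/log normalized; the annotation
    bundle is trained on the labelled reference and projected onto the query,
    whose clusters are then labelled by highest mean probability.
    """
    thresholds = thresholds or QCThresholds()
    ref_f, qc_ref = filter_cells(reference, thresholds)
    qry_f, qc_qry = filter_cells(query, thresholds)
    ref_n = normalize(ref_f, thresholds.scale_target)
    qry_n = normalize(qry_f, thresholds.scale_target)

    result = CellTypeAnnotator(ref_n, labels=label_key, config=config).fit()
    projection = result.annotate(qry_n, qry_n.obs[cluster_key])
    return PipelineOutput(result=result, projection=projection,
                          qc_reference=qc_ref, qc_query=qc_qry)
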