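"""The diversity score: mean distance to the cell-line centroid.

Quantifies intra-cell-line heterogeneity on an embedding (PCA for RNA, LSI
for ATAC): per line, the Euclidean distance of each cell to the line
centroid over the first ``n_components`` components, with single-pass
exclusion of cells whose distance lies outside mean ± ``sd_cut``·SD of the
line's distance distribution.  The centroid is not recomputed after
exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster_core import Embedding

__all__ = ["DiversityResult", "diversity_score", "compare_diversity"]


@dataclass
class DiversityResult:
    per_line: pd.DataFrame  # line_id, score, n_cells_used, n_outliers_removed

    def scores(self) -> pd.Series:
        return self.per_line.set_index("line_id")["score"]


def diversity_score(
    embedding: Embedding,
    line_labels,
    n_components: int = 30,
    sd_cut: float = 3.0,
) -> DiversityResult:
    """Per-line diversity scores with 3-SD outlier exclusion.

    Lines with fewer than 2 cells get a missing (NaN) score.  Cells whose
    distance satisfies |d - mean| <= sd_cut * SD are retained, so a
    degenerate zero-variance distance distribution keeps every cell.
    """
    labels = np.asarray(line_labels)
    coords = embedding.coords[:, : min(n_components, embedding.coords.shape[1])]
    if coords.shape[0] != labels.size:
        raise ValueError("line_labels must align with embedding rows")
    rows = []
    for line in pd.unique(labels):
        sub = coords[labels == line]
        if sub.shape[0] < 2:
            rows.append(
                {"line_id": line, "score": np.nan, "n_cells_used": sub.shape[0],
                 "n_outliers_removed": 0}
            )
            continue
        centroid = sub.mean(axis=0)
        d = np.linalg.norm(sub - centroid, axis=1)
        keep = np.abs(d - d.mean()) <= sd_cut * d.std()
        rows.append(
            {
                "line_id": line,
                "score": float(d[keep].mean()),
                "n_cells_used": int(keep.sum()),
                "n_outliers_removed": int((~keep).sum()),
            }
        )
    return DiversityResult(pd.DataFrame(rows))


def compare_diversity(scores_a, scores_b) -> float:
    """One-sided rank-sum p for group A scores exceeding group B scores.

    Uses the exact null distribution when both groups are small and tie-free.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    return float(stats.mannwhitneyu(a, b, alternative="greater").pvalue)
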