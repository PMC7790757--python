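"""Phenotype calling by PCA with a robust cutoff, and genotype enrichment.

Samples are characterized by their splicing-index profile over the selected
cryptic 3'-splice-site junctions.  PCA on the column-centered SI matrix
(missing SI imputed as 0, i.e. unexpressed aberrant form; no unit-variance
scaling since SI shares a common [0,1] scale) yields a first principal
component dominated by cryptic-acceptor usage; its sign is oriented so that
PC1 correlates positively with per-sample mean SI.  A sample is called
phenotype-positive ("SF3B1-like") when its PC1 score exceeds

    median(PC1) + k * MAD(PC1),   k = 3 by default,

where MAD is the median absolute deviation scaled by the usual 1.4826
normal-consistency factor (the default of R's ``mad()``), so that under an
approximately normal score null the cutoff sits near 3 sigma.  Pass
``mad_scale=1`` for the raw, unscaled MAD.

Genotype-phenotype association uses a one-sided Fisher's exact test
(enrichment direction) with Bonferroni adjustment for the number of genes
screened.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = ["PhenotypeResult", "EnrichmentResult", "pca_phenotype", "fisher_enrichment"]


@dataclass
class PhenotypeResult:
    """Per-sample PC scores and phenotype calls.

    ``calls`` has columns ``sample_id, pc1_score, cutoff, sf3b1_like``;
    ``scores``/``loadings`` hold the first ``k`` components; ``degenerate``
    marks a constant input matrix (no calls made).
    """

    calls: pd.DataFrame
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    cutoff: float
    mad: float
    degenerate: bool = False


MAD_NORMAL_SCALE = 1.4826  # normal-consistency factor, as in R's mad()


def pca_phenotype(
    si: pd.DataFrame,
    mad_k: float = 3.0,
    n_components: int = 5,
    mad_scale: float = MAD_NORMAL_SCALE,
) -> PhenotypeResult:
    """Call the aberrant-splicing phenotype from a samples x junctions SI table."""
    if si.shape[0] < 3 or si.shape[1] < 2:
        raise ValueError("need at least 3 samples and 2 junctions")
    X = si.fillna(0.0).to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0.0):
        warnings.warn("constant SI matrix: PCA is degenerate, no phenotype calls made")
        empty = pd.DataFrame(index=si.index)
        calls = pd.DataFrame(
            {
                "sample_id": si.index,
                "pc1_score": 0.0,
                "cutoff": np.nan,
                "sf3b1_like": False,
            }
        )
        return PhenotypeResult(
            calls=calls,
            scores=empty,
            loadings=pd.DataFrame(index=si.columns),
            explained_variance_ratio=np.array([]),
            cutoff=np.nan,
            mad=0.0,
            degenerate=True,
        )

    k = int(min(n_components, si.shape[0] - 1, si.shape[1]))
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Xc)
    loadings = pca.components_.T.copy()
    # orient PC1 so that high cryptic-site usage maps to high scores
    r = np.corrcoef(scores[:, 0], X.mean(axis=1))[0, 1]
    if np.isfinite(r) and r < 0:
        scores[:, 0] *= -1
        loadings[:, 0] *= -1

    pc1 = scores[:, 0]
    med = float(np.median(pc1))
    mad = mad_scale * float(np.median(np.abs(pc1 - med)))
    cutoff = med + mad_k * mad
    calls = pd.DataFrame(
        {
            "sample_id": si.index,
            "pc1_score": pc1,
            "cutoff": cutoff,
            "sf3b1_like": pc1 > cutoff,
        }
    )
    cols = [f"PC{i + 1}" for i in range(k)]
    return PhenotypeResult(
        calls=calls,
        scores=pd.DataFrame(scores, index=si.index, columns=cols),
        loadings=pd.DataFrame(loadings, index=si.columns, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
        cutoff=cutoff,
        mad=mad,
    )


@dataclass(frozen=True)
class EnrichmentResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    raw_p: float
    n_tests: int
    adjusted_p: float
    odds_ratio: float


def fisher_enrichment(
    n11: int, n12: int, n21: int, n22: int, n_tests: int = 1
) -> EnrichmentResult:
    """One-sided Fisher's exact enrichment test with Bonferroni adjustment.

    The 2x2 table rows are phenotype-positive / negative and columns
    genotype-altered / unaltered; the alternative is enrichment of the
    genotype among phenotype-positive samples (hypergeometric upper tail).
    ``adjusted_p = min(1, raw_p * n_tests)``.
    """
    if min(n11, n12, n21, n22) < 0:
        raise ValueError("contingency counts must be non-negative")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    odds, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative="greater")
    return EnrichmentResult(
        table=((n11, n12), (n21, n22)),
        raw_p=float(p),
        n_tests=int(n_tests),
        adjusted_p=float(min(1.0, p * n_tests)),
        odds_ratio=float(odds),
    )
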