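"""Sample-level community summaries: richness, Canberra distances,
prevalence filtering.

Richness counts families above 1 RPKM (strict) on raw, pre-pseudocount
values; Canberra distances sum |x-y|/(x+y) over the union family universe
with 0/0 terms contributing nothing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from cazprofiler.profiling import CazyProfile


def _rpkm_matrix(profiles: list[CazyProfile]) -> pd.DataFrame:
    """Samples x families RPKM matrix over the union universe (missing = 0)."""
    families = sorted({f for p in profiles for f in p.rpkm})
    data = [[p.rpkm.get(f, 0.0) for f in families] for p in profiles]
    return pd.DataFrame(data, index=[p.sample_id for p in profiles], columns=families)


def cazyme_richness(profile: CazyProfile, min_rpkm: float = 1.0) -> int:
    """Number of (sub)families with RPKM strictly above ``min_rpkm``."""
    return sum(1 for v in profile.rpkm.values() if v > min_rpkm)


def canberra_matrix(profiles: list[CazyProfile]) -> tuple[list[str], np.ndarray]:
    """Pairwise Canberra distance matrix over RPKM profiles.

    d(x, y) = sum_f |x_f - y_f| / (x_f + y_f), with features where both
    samples are zero contributing 0 (scipy's convention).
    """
    mat = _rpkm_matrix(profiles)
    if len(profiles) < 2:
        return list(mat.index), np.zeros((len(profiles), len(profiles)))
    dist = squareform(pdist(mat.values, metric="canberra"))
    return list(mat.index), dist


def prevalence_filter(
    profiles: list[CazyProfile], min_prevalence: float = 0.01
) -> list[str]:
    """Families present (RPKM > 0, pre-pseudocount) in >= ``min_prevalence``
    of the samples (inclusive)."""
    if not profiles:
        raise ValueError("need at least one profile")
    mat = _rpkm_matrix(profiles)
    prevalence = (mat > 0).mean(axis=0)
    return sorted(prevalence.index[prevalence >= min_prevalence])
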