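"""Community statistics: binary Jaccard dissimilarity, cross-sample Shannon
index (CSI), checkerboard C-score, prevalence and dominance summaries.

These are the building blocks consumed by the MAJIC core and by the
descriptive reports. Pairwise dissimilarities are returned as
``skbio.DistanceMatrix`` objects so downstream code can rely on a standard
container.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy as _shannon_entropy
from skbio import DistanceMatrix

from .tables import AbundanceTable, PresenceMatrix


def jaccard(u: Sequence[int] | np.ndarray, v: Sequence[int] | np.ndarray) -> float:
    """Binary Jaccard dissimilarity 1 − |u∩v| / |u∪v| on the supports.

    Raises if both vectors are all-zero: an empty community has no defined
    Jaccard relation (upstream code drops empty samples before calling this).
    """
    u = np.asarray(u, dtype=bool)
    v = np.asarray(v, dtype=bool)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    union = int(np.count_nonzero(u | v))
    if union == 0:
        raise ValueError("Jaccard undefined: both vectors are all-zero")
    inter = int(np.count_nonzero(u & v))
    return 1.0 - inter / union


def pairwise_jaccard(pa: PresenceMatrix) -> DistanceMatrix:
    """All-pairs binary Jaccard dissimilarities between samples."""
    bits = pa.bits.to_numpy(dtype=bool)
    if bits.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    empty = np.where(~bits.any(axis=1))[0]
    if empty.size:
        names = [pa.sample_ids[i] for i in empty]
        raise ValueError(f"all-zero sample row(s): {names}")
    condensed = pdist(bits, metric="jaccard")
    return DistanceMatrix(squareform(condensed), ids=pa.sample_ids)


def mean_pairwise(
    dm: DistanceMatrix, subset: Iterable[str]
) -> tuple[float, pd.Series, np.ndarray]:
    """Mean within-subset pairwise dissimilarity.

    Returns ``(mean, per_sample_means, pair_values)`` where the mean runs over
    the C(k, 2) within-subset pairs, ``per_sample_means[s]`` is the mean
    dissimilarity of sample *s* to the other subset members, and
    ``pair_values`` is the condensed vector of pair dissimilarities.
    """
    ids = list(subset)
    if len(ids) < 2:
        raise ValueError("subset must contain at least 2 samples")
    sub = dm.filter(ids)
    pair_values = sub.condensed_form()
    per_sample = pd.Series(
        sub.data.sum(axis=1) / (len(ids) - 1), index=list(sub.ids)
    )
    return float(pair_values.mean()), per_sample, pair_values


def shannon(p: Sequence[float] | np.ndarray) -> float:
    """Shannon entropy in nats of a nonnegative vector, normalised to sum 1."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("entries must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValueError("Shannon entropy undefined for an all-zero vector")
    return float(_shannon_entropy(p / total))


def csi(table: AbundanceTable, samples: Iterable[str] | None = None) -> pd.DataFrame:
    """Cross-sample Shannon index per species, with percentile ranks.

    CSI is the Shannon entropy (nats) of one species' relative-abundance
    vector across samples, normalised within the species — a measure of how
    evenly the species is spread over the cohort, bounded by ln(N samples).
    ``percentile_rank`` is the fraction of *other* species (with defined CSI)
    whose CSI is strictly smaller; ties share a rank. Species flagged
    ``top5pct_flag`` have rank > 0.95. Species absent everywhere get NaN CSI
    and are excluded from the ranking.
    """
    data = table.data if samples is None else table.subset_samples(samples).data
    if data.shape[0] < 2:
        raise ValueError("CSI needs at least 2 samples")
    values = []
    for sp in data.columns:
        vec = data[sp].to_numpy()
        values.append(shannon(vec) if vec.sum() > 0 else np.nan)
    out = pd.DataFrame({"species_id": data.columns, "csi": values})
    defined = out["csi"].dropna()
    m = len(defined)
    ranks = np.full(len(out), np.nan)
    for i, v in enumerate(out["csi"]):
        if np.isnan(v):
            continue
        smaller = int((defined < v).sum())
        ranks[i] = 1.0 if m == 1 else smaller / (m - 1)
    out["percentile_rank"] = ranks
    out["top5pct_flag"] = out["percentile_rank"] > 0.95
    return out


def c_score(pa: PresenceMatrix) -> tuple[float, pd.DataFrame]:
    """Checkerboard C-score over all species pairs.

    For species *i*, *j* with occupancy counts r_i, r_j and co-occurrence
    count S, the checkerboard unit count is CU = (r_i − S)(r_j − S); the mean
    over all C(k, 2) species pairs quantifies segregation.
    """
    bits = pa.bits.to_numpy(dtype=np.int64).T  # species × samples
    species = pa.species_ids
    k = bits.shape[0]
    if k < 2:
        raise ValueError("C-score needs at least 2 species")
    r = bits.sum(axis=1)
    S = bits @ bits.T
    cu = (r[:, None] - S) * (r[None, :] - S)
    iu, ju = np.triu_indices(k, k=1)
    per_pair = pd.DataFrame(
        {
            "species_i": [species[i] for i in iu],
            "species_j": [species[j] for j in ju],
            "r_i": r[iu],
            "r_j": r[ju],
            "shared": S[iu, ju],
            "cu": cu[iu, ju],
        }
    )
    return float(cu[iu, ju].mean()), per_pair


def prevalence_summary(
    table: AbundanceTable, high_threshold: float = 0.20
) -> pd.DataFrame:
    """Per-species prevalence and high-abundance fractions.

    ``prevalence`` = fraction of samples where the species' abundance is > 0;
    ``high_abundance`` = fraction where it strictly exceeds ``high_threshold``
    (default 20% of the community).
    """
    if table.n_samples < 1:
        raise ValueError("need at least one sample")
    data = table.data
    return pd.DataFrame(
        {
            "species_id": data.columns,
            "prevalence": (data > 0).mean(axis=0).to_numpy(),
            "high_abundance": (data > high_threshold).mean(axis=0).to_numpy(),
        }
    )


#: dominance-pattern labels for the Bifidobacterium / E. coli classification
DOMINANCE_LABELS = (
    "ecoli_with_single_dominant_bifido",
    "ecoli_with_multiple_dominant_bifido",
    "ecoli_no_dominant_bifido",
    "no_ecoli_dominant_bifido",
    "no_ecoli_no_dominant_bifido",
)


def classify_dominance(
    abundances: pd.Series,
    bifido_set: Iterable[str],
    ecoli_id: str,
    high_threshold: float = 0.20,
) -> str:
    """Classify one sample by Bifidobacterium dominance and E. coli presence.

    "Dominant" means relative abundance strictly > ``high_threshold``;
    E. coli status is presence (> 0).
    """
    bifido = list(bifido_set)
    unknown = [b for b in bifido + [ecoli_id] if b not in abundances.index]
    if unknown:
        raise KeyError(f"unknown species id(s): {unknown}")
    n_dominant = int((abundances[bifido] > high_threshold).sum())
    has_ecoli = abundances[ecoli_id] > 0
    if has_ecoli:
        if n_dominant == 0:
            return "ecoli_no_dominant_bifido"
        if n_dominant == 1:
            return "ecoli_with_single_dominant_bifido"
        return "ecoli_with_multiple_dominant_bifido"
    return "no_ecoli_dominant_bifido" if n_dominant else "no_ecoli_no_dominant_bifido"
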