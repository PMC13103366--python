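"""MAJIC core: focal splits, frequency-preserving shuffle nulls, µ⁺/µ⁻/∆µ
and state-association classification.

For a focal species *i* the analysed samples split into σᵢ⁺ (focal present)
and σᵢ⁻ (focal absent). µᵢ⁺ and µᵢ⁻ are the mean pairwise binary Jaccard
dissimilarities within each set, and ∆µᵢ = µᵢ⁺ − µᵢ⁻. A negative ∆µᵢ means
communities containing the focal species are more mutually similar
("restrictive"/constrained); a positive ∆µᵢ means greater variability
("facilitating"). The null keeps the rest of the matrix fixed and permutes
only the focal species' presence labels across samples, preserving its
prevalence exactly (a frequency-preserving shuffle); classification compares
the observed statistic to 10,000 such shuffles by default.

Implementation note: with the non-focal sub-matrix fixed, adding the focal
bit to a sample changes a pair's intersection/union by at most one, so the
within-σ⁺ pair dissimilarity (focal included) is 1 − (I+1)/(U+1) and the
within-σ⁻ value is 1 − I/U, where I and U are intersection and union counts
over the non-focal species. Both n×n matrices are computed once per focal
species; every shuffle then only selects sub-blocks, which makes the 10,000
shuffle default cheap even for large species sets.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .tables import PresenceMatrix

logger = logging.getLogger("majic")

#: maximum number of pooled null pair values kept for the pairwise KS mode
POOLED_CAP = 100_000

#: switch to the asymptotic two-sample KS p-value above this |x|·|y| product
KS_EXACT_MAX_PRODUCT = 10_000


@dataclass(frozen=True)
class FocalSplit:
    """Partition of samples by one focal species' presence bit."""

    focal_species_id: str
    sigma_plus: tuple[str, ...]
    sigma_minus: tuple[str, ...]

    @property
    def n_plus(self) -> int:
        return len(self.sigma_plus)

    @property
    def n_minus(self) -> int:
        return len(self.sigma_minus)


@dataclass
class NullEnsemble:
    """Per-shuffle µ⁺/µ⁻/∆µ vectors from the frequency-preserving null."""

    focal_species_id: str
    n_shuffles: int
    mu_plus_null: np.ndarray
    mu_minus_null: np.ndarray
    delta_mu_null: np.ndarray
    pooled_pair_values_plus: np.ndarray
    pooled_cap: int
    seed: int | None


@dataclass
class MajicResult:
    """Per-focal-species MAJIC outcome."""

    focal_species_id: str
    n_plus: int
    n_minus: int
    mu_plus: float = np.nan
    mu_minus: float = np.nan
    delta_mu: float = np.nan
    observed_pair_values_plus: np.ndarray = field(default_factory=lambda: np.empty(0))
    ks_D: float = np.nan
    ks_p: float = np.nan
    empirical_p: float = np.nan
    p_value: float = np.nan
    p_mode: str = "pairwise"
    classification: str = "not_computable"
    include_focal: bool = True
    n_shuffles: int = 0
    seed: int | None = None
    null: NullEnsemble | None = None
    sigma_plus: tuple[str, ...] = ()
    sigma_minus: tuple[str, ...] = ()
    group: str = "all"


def split_by_focal(pa: PresenceMatrix, focal: str) -> FocalSplit:
    """Partition the samples of a presence matrix by the focal species bit."""
    if focal not in pa.bits.columns:
        raise KeyError(f"focal species {focal!r} not in matrix")
    col = pa.bits[focal].to_numpy()
    ids = np.asarray(pa.sample_ids, dtype=object)
    return FocalSplit(
        focal_species_id=focal,
        sigma_plus=tuple(ids[col == 1]),
        sigma_minus=tuple(ids[col == 0]),
    )


def shuffle_focal(
    pa: PresenceMatrix, focal: str, rng: np.random.Generator
) -> FocalSplit:
    """One frequency-preserving shuffle of the focal species' presence labels.

    The focal vector is permuted uniformly at random across samples, so its
    prevalence is preserved exactly; the rest of the matrix is untouched.
    """
    if focal not in pa.bits.columns:
        raise KeyError(f"focal species {focal!r} not in matrix")
    col = pa.bits[focal].to_numpy()
    permuted = rng.permutation(col)
    ids = np.asarray(pa.sample_ids, dtype=object)
    return FocalSplit(
        focal_species_id=focal,
        sigma_plus=tuple(ids[permuted == 1]),
        sigma_minus=tuple(ids[permuted == 0]),
    )


def ks_two_sample(x, y) -> tuple[float, float, str]:
    """Two-sided two-sample Kolmogorov–Smirnov test.

    Uses the exact null distribution when |x|·|y| ≤ 10⁴ and the asymptotic
    Kolmogorov distribution otherwise; the method used is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test requires non-empty samples")
    method = "exact" if x.size * y.size <= KS_EXACT_MAX_PRODUCT else "asymp"
    res = sps.ks_2samp(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0)), method


def derive_seed(master_seed: int, *labels: str) -> int:
    """Deterministic, order-independent sub-seed from string labels.

    Sub-seeds depend on the label text (CRC-32), not on iteration order, so
    per-focal results are invariant to species ordering in the input table.
    """
    h = zlib.crc32(("\x1f".join(labels)).encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, h])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _pair_value_matrices(
    rest: np.ndarray, include_focal: bool
) -> tuple[np.ndarray, np.ndarray]:
    """n×n matrices of within-σ⁺ and within-σ⁻ pair dissimilarities.

    ``rest`` is the samples × (species minus focal) 0/1 matrix. Returns
    (A, B): A[s, t] is the Jaccard dissimilarity of samples s, t when both
    carry the focal bit, B[s, t] when neither does.
    """
    r = rest.astype(np.int64)
    inter = r @ r.T
    support = r.sum(axis=1)
    union = support[:, None] + support[None, :] - inter
    n_rest_empty = int((support == 0).sum())
    if n_rest_empty >= 2:
        raise ValueError(
            f"{n_rest_empty} samples share no non-focal species; their pairwise "
            "Jaccard is undefined — drop empty samples upstream"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        b = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1), np.nan)
    if include_focal:
        a = 1.0 - (inter + 1.0) / (union + 1.0)
    else:
        a = b
    np.fill_diagonal(a, 0.0)
    np.fill_diagonal(b, 0.0)
    return a, b


def majic_single(
    pa: PresenceMatrix,
    focal: str,
    n_shuffles: int = 10_000,
    alpha: float = 0.05,
    ks_mode: str = "pairwise",
    include_focal: bool = True,
    min_group: int = 2,
    rng: np.random.Generator | int | None = None,
    pooled_cap: int = POOLED_CAP,
    group: str = "all",
) -> MajicResult:
    """Run MAJIC for one focal species.

    Parameters
    ----------
    pa
        Presence/absence matrix (samples × species, no all-zero samples).
    focal
        Focal species id; its presence bit defines σ⁺/σ⁻.
    n_shuffles
        Size of the frequency-preserving null ensemble (0 disables the null:
        only µ⁺/µ⁻/∆µ are computed and classification is ``not_tested``).
    ks_mode
        ``"pairwise"``: KS between observed within-σ⁺ pair dissimilarities
        and the pooled within-σ⁺ pair values across shuffles.
        ``"permutation"``: add-one-corrected two-sided empirical p of the
        observed µ⁺ against the null µ⁺ ensemble.
    include_focal
        Whether the (permuted, for nulls) focal row takes part in the Jaccard
        computation; on by default so observed and null matrices are treated
        identically.
    min_group
        Minimum σ⁺/σ⁻ size; smaller splits yield ``not_computable``.

    Returns a :class:`MajicResult`; degenerate splits never raise.
    """
    if ks_mode not in ("pairwise", "permutation"):
        raise ValueError(f"unknown ks_mode {ks_mode!r}")
    if min_group < 2:
        raise ValueError("min_group must be >= 2 (a mean needs one pair)")
    if pa.n_samples < 2 * min_group:
        raise ValueError(f"need at least {2 * min_group} samples")
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = None if rng is None else int(rng)
        rng = np.random.default_rng(rng)

    split = split_by_focal(pa, focal)
    n_plus, n_minus = split.n_plus, split.n_minus
    result = MajicResult(
        focal_species_id=focal,
        n_plus=n_plus,
        n_minus=n_minus,
        p_mode=ks_mode,
        include_focal=include_focal,
        n_shuffles=n_shuffles,
        seed=seed,
        sigma_plus=split.sigma_plus,
        sigma_minus=split.sigma_minus,
        group=group,
    )
    if n_plus < min_group or n_minus < min_group:
        logger.info(
            "focal %s: degenerate split (%d/%d) — not computable",
            focal, n_plus, n_minus,
        )
        return result

    focal_col = pa.bits[focal].to_numpy().astype(bool)
    rest = pa.bits.drop(columns=[focal]).to_numpy()
    if int((rest.sum(axis=1) == 0).sum()) >= 2:
        # two or more samples hold nothing but the focal species: a shuffle
        # can place both in σ⁻, where their pairwise Jaccard is undefined
        logger.warning(
            "focal %s: >=2 samples contain only the focal species; "
            "result not computable", focal,
        )
        return result
    a_mat, b_mat = _pair_value_matrices(rest, include_focal)
    n = pa.n_samples
    iu, ju = np.triu_indices(n, k=1)
    a_flat = a_mat[iu, ju]
    b_flat = b_mat[iu, ju]

    obs_plus_mask = focal_col[iu] & focal_col[ju]
    obs_minus_mask = (~focal_col)[iu] & (~focal_col)[ju]
    if np.isnan(b_flat[obs_minus_mask]).any():
        raise ValueError("undefined Jaccard pair within σ⁻ (empty communities)")
    observed_plus = a_flat[obs_plus_mask]
    mu_plus = float(observed_plus.mean())
    mu_minus = float(b_flat[obs_minus_mask].mean())
    result.mu_plus = mu_plus
    result.mu_minus = mu_minus
    result.delta_mu = mu_plus - mu_minus
    result.observed_pair_values_plus = observed_plus

    if n_shuffles == 0:
        result.classification = "not_tested"
        return result

    # Frequency-preserving null: every row of S is an independent uniform
    # permutation of the focal presence vector.
    S = rng.permuted(
        np.broadcast_to(focal_col, (n_shuffles, n)).copy(), axis=1
    )
    row_sums = S.sum(axis=1)
    if not (row_sums == n_plus).all():
        raise AssertionError("shuffle violated focal prevalence conservation")

    c_plus = n_plus * (n_plus - 1) // 2
    c_minus = n_minus * (n_minus - 1) // 2
    mask_plus = S[:, iu] & S[:, ju]
    mask_minus = ~S[:, iu] & ~S[:, ju]
    if np.isnan(b_flat).any():
        # a single rest-empty sample: its σ⁻ pairs are defined (union > 0)
        # unless paired with another rest-empty sample, excluded above
        raise ValueError("undefined Jaccard pair encountered in null ensemble")
    mu_plus_null = (mask_plus @ a_flat) / c_plus
    mu_minus_null = (mask_minus @ b_flat) / c_minus

    pooled = a_flat[np.nonzero(mask_plus)[1]]
    if pooled.size > pooled_cap:
        keep = rng.choice(pooled.size, size=pooled_cap, replace=False)
        pooled = pooled[np.sort(keep)]
    result.null = NullEnsemble(
        focal_species_id=focal,
        n_shuffles=n_shuffles,
        mu_plus_null=mu_plus_null,
        mu_minus_null=mu_minus_null,
        delta_mu_null=mu_plus_null - mu_minus_null,
        pooled_pair_values_plus=pooled,
        pooled_cap=pooled_cap,
        seed=seed,
    )

    # empirical two-sided permutation p of µ⁺ against the null ensemble
    med = float(np.median(mu_plus_null))
    exceed = int((np.abs(mu_plus_null - med) >= abs(mu_plus - med)).sum())
    result.empirical_p = (1 + exceed) / (n_shuffles + 1)

    if ks_mode == "pairwise":
        result.ks_D, result.ks_p, _ = ks_two_sample(observed_plus, pooled)
        result.p_value = result.ks_p
    else:
        result.p_value = result.empirical_p
    result.classification = (
        "state_associated" if result.p_value < alpha else "state_dissociated"
    )
    return result
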