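"""Synthetic community generator with known ground truth.

Emulates filtered relative-abundance tables: per-species occupancy
probabilities drawn from a Beta distribution (right-skewed prevalence
spectrum), log-normal abundances for present species, per-sample
renormalisation to a compositional table summing to 1. Three planted
structures are available for validating the pipeline end to end:

* ``neutral`` — a designated focal species whose occupancy is independent of
  the rest of the community (the type-I-error / calibration anchor);
* ``restrictive`` / ``facilitating`` — samples on one side of the focal split
  draw their community from a restricted species pool, so the planted sign of
  ∆µ (µ⁺ − µ⁻) is known;
* a planted multiplicative abundance effect on chosen target species in σ⁺,
  for validating the Wilcoxon stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import AbundanceTable, SampleGroups

#: id of the designated focal species in generated tables
FOCAL_ID = "focal"


@dataclass
class SyntheticTruth:
    """Ground truth fully determining a generated table given its seed."""

    mode: str  # neutral | restrictive | facilitating | abundance_effect
    focal_species_id: str
    planted_delta_sign: int  # -1, 0, +1
    effect_targets: dict[str, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _as_rng(rng) -> tuple[np.random.Generator, int | None]:
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = None if rng is None else int(rng)
        return np.random.default_rng(rng), seed
    return rng, None


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(n)]


def _force_nonempty(presence: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Give empty samples one uniformly chosen (non-focal) species: an empty
    community has no Jaccard relation, so every sample must host something."""
    presence = presence.copy()
    empty = ~presence.any(axis=1)
    if empty.any():
        cols = rng.integers(0, presence.shape[1], size=int(empty.sum()))
        presence[np.where(empty)[0], cols] = True
    return presence


def _abundances(presence: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Log-normal(0, 1) abundances on the occupancy pattern, rows sum to 1."""
    weights = np.where(presence, rng.lognormal(0.0, 1.0, size=presence.shape), 0.0)
    return weights / weights.sum(axis=1, keepdims=True)


def _exact_focal_vector(
    n_samples: int, focal_prevalence: float, rng: np.random.Generator
) -> np.ndarray:
    """Presence vector with exactly round(prevalence·n) occupied samples."""
    k = int(round(focal_prevalence * n_samples))
    if not 0 < k < n_samples:
        raise ValueError(
            f"focal prevalence {focal_prevalence} degenerate for n={n_samples}"
        )
    vec = np.zeros(n_samples, dtype=bool)
    vec[rng.choice(n_samples, size=k, replace=False)] = True
    return vec


def _assemble(
    presence: np.ndarray,
    focal_vec: np.ndarray,
    n_samples: int,
    n_species: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Append the focal column and convert to a compositional DataFrame."""
    full = np.column_stack([_force_nonempty(presence, rng), focal_vec])
    values = _abundances(full, rng)
    cols = _ids("sp", n_species) + [FOCAL_ID]
    return pd.DataFrame(values, index=_ids("s", n_samples), columns=cols)


def simulate_neutral(
    n_samples: int,
    n_species: int,
    occupancy_alpha: float = 1.0,
    occupancy_beta: float = 3.0,
    focal_prevalence: float = 0.5,
    rng=None,
) -> tuple[AbundanceTable, SyntheticTruth]:
    """Neutral community: focal occupancy independent of everything else.

    Per-species occupancy probability ~ Beta(alpha, beta); occupancy is
    independent Bernoulli per sample; present species get log-normal(0, 1)
    abundances, normalised per sample. The focal species occupies an
    independent Bernoulli(``focal_prevalence``) set of samples, so any
    state-association call on it is a false positive by construction.
    """
    if n_samples < 4 or n_species < 2:
        raise ValueError("need n_samples >= 4 and n_species >= 2")
    rng, seed = _as_rng(rng)
    occ_p = rng.beta(occupancy_alpha, occupancy_beta, size=n_species)
    presence = rng.random((n_samples, n_species)) < occ_p
    focal_vec = rng.random(n_samples) < focal_prevalence
    df = _assemble(presence, focal_vec, n_samples, n_species, rng)
    truth = SyntheticTruth(
        mode="neutral",
        focal_species_id=FOCAL_ID,
        planted_delta_sign=0,
        params=dict(
            n_samples=n_samples, n_species=n_species,
            occupancy_alpha=occupancy_alpha, occupancy_beta=occupancy_beta,
            focal_prevalence=focal_prevalence, occupancy_probs=occ_p.tolist(),
        ),
        seed=seed,
    )
    return AbundanceTable(df), truth


def simulate_focal_structure(
    mode: str,
    n_samples: int,
    n_species: int,
    restricted_pool: int,
    focal_prevalence: float = 0.5,
    contrast: float = 0.8,
    occupancy_alpha: float = 1.0,
    occupancy_beta: float = 3.0,
    rng=None,
) -> tuple[AbundanceTable, SyntheticTruth]:
    """Plant a restrictive or facilitating focal species.

    In ``restrictive`` mode, σ⁺ samples (focal present) draw their community
    from the first ``restricted_pool`` species with occupancy pushed towards
    1 by ``contrast`` and suppressed by ``contrast`` outside the pool, while
    σ⁻ samples draw from the full pool at baseline occupancy — so σ⁺
    communities are mutually more similar and the planted ∆µ sign is −1.
    ``facilitating`` mirrors the construction (σ⁻ restricted), planting +1.
    ``contrast`` ∈ [0, 1]; 0 degenerates to the neutral generator.
    """
    if mode not in ("restrictive", "facilitating"):
        raise ValueError(f"unknown mode {mode!r}")
    if not 0 < restricted_pool < n_species:
        raise ValueError("restricted_pool must lie strictly between 0 and n_species")
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must lie in [0, 1]")
    rng, seed = _as_rng(rng)
    occ_p = rng.beta(occupancy_alpha, occupancy_beta, size=n_species)
    in_pool = np.arange(n_species) < restricted_pool
    restricted_p = np.where(
        in_pool, occ_p + contrast * (1.0 - occ_p), occ_p * (1.0 - contrast)
    )
    focal_vec = _exact_focal_vector(n_samples, focal_prevalence, rng)
    restricted_side = focal_vec if mode == "restrictive" else ~focal_vec
    probs = np.where(restricted_side[:, None], restricted_p, occ_p)
    presence = rng.random((n_samples, n_species)) < probs
    df = _assemble(presence, focal_vec, n_samples, n_species, rng)
    truth = SyntheticTruth(
        mode=mode,
        focal_species_id=FOCAL_ID,
        planted_delta_sign=-1 if mode == "restrictive" else 1,
        params=dict(
            n_samples=n_samples, n_species=n_species,
            restricted_pool=restricted_pool, focal_prevalence=focal_prevalence,
            contrast=contrast, occupancy_alpha=occupancy_alpha,
            occupancy_beta=occupancy_beta,
        ),
        seed=seed,
    )
    return AbundanceTable(df), truth


def simulate_abundance_effect(
    n_samples: int,
    n_species: int,
    target_effects: dict[str, float],
    occupancy_alpha: float = 1.0,
    occupancy_beta: float = 3.0,
    focal_prevalence: float = 0.5,
    rng=None,
) -> tuple[AbundanceTable, SyntheticTruth]:
    """Plant multiplicative abundance effects on target species in σ⁺.

    A neutral table is generated (focal with exactly round(prevalence·n)
    occupied samples for stable split sizes), then each target species'
    abundance is multiplied in σ⁺ samples before per-sample renormalisation —
    so the planted effect spills mildly onto other species, as real
    compositions do. Planted targets are made ubiquitous (present in every
    sample): a multiplicative abundance effect only exists where the species
    occurs, so the planted signal is purely an abundance difference rather
    than an occupancy one.
    """
    for mult in target_effects.values():
        if mult <= 0:
            raise ValueError("multipliers must be > 0")
    rng, seed = _as_rng(rng)
    occ_p = rng.beta(occupancy_alpha, occupancy_beta, size=n_species)
    species_ids = _ids("sp", n_species)
    target_cols = [species_ids.index(t) for t in target_effects if t in species_ids]
    occ_p[target_cols] = 1.0
    presence = rng.random((n_samples, n_species)) < occ_p
    focal_vec = _exact_focal_vector(n_samples, focal_prevalence, rng)
    df = _assemble(presence, focal_vec, n_samples, n_species, rng)
    unknown = set(target_effects) - set(df.columns)
    if unknown:
        raise KeyError(f"unknown target id(s): {sorted(unknown)}")
    plus_rows = df.index[focal_vec]
    for target, mult in target_effects.items():
        df.loc[plus_rows, target] *= mult
    df = df.div(df.sum(axis=1), axis=0)
    truth = SyntheticTruth(
        mode="abundance_effect",
        focal_species_id=FOCAL_ID,
        planted_delta_sign=0,
        effect_targets=dict(target_effects),
        params=dict(
            n_samples=n_samples, n_species=n_species,
            occupancy_alpha=occupancy_alpha, occupancy_beta=occupancy_beta,
            focal_prevalence=focal_prevalence,
        ),
        seed=seed,
    )
    return AbundanceTable(df), truth


def groups_for(table: AbundanceTable, label: str = "sim") -> SampleGroups:
    """Single-group metadata for a generated table."""
    return SampleGroups.single_group(table.sample_ids, label=label)
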