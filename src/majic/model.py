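"""Model interface: a :class:`Majic` object built from an abundance table and
sample groupings; ``fit()`` returns :class:`MajicResults` carrying every
per-focal estimate, the null ensembles, a ``summary()`` table and writers.

The pipeline per group is: species filter (group-wise prevalence/abundance
rule) → binarise at the detection threshold → drop samples left empty →
loop every retained species as focal through :func:`majic.core.majic_single`.
Per-focal random seeds are derived from the master seed and the
(group, species) labels, so results do not depend on iteration order.
"""

from __future__ import annotations

import logging
import secrets
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import core
from .tables import (
    AbundanceTable,
    PresenceMatrix,
    SampleGroups,
    filter_species,
    to_presence_absence,
    write_majic_results,
)

logger = logging.getLogger("majic")


class Majic:
    """MAJIC state-association model over a grouped abundance table.

    Parameters
    ----------
    table
        Relative-abundance table (samples × species, fraction scale).
    groups
        Sample → group assignment; ``None`` treats all samples as one group.
    min_prevalence, min_abundance
        Group-wise species filter: keep a species iff it reaches
        ``min_abundance`` relative abundance in at least ``min_prevalence``
        of the group's samples (defaults 10% of samples at 0.1%).
    presence_threshold
        Detection cutoff for binarisation (bit = 1 iff abundance > cutoff).
    n_shuffles, alpha, ks_mode, include_focal, min_group
        Passed to :func:`majic.core.majic_single`.
    apply_filter
        Set False if ``table`` is already filtered.
    renormalize
        Renormalise abundances after filtering (off by default: dominance
        thresholds are defined on the original fractions).
    """

    def __init__(
        self,
        table: AbundanceTable,
        groups: SampleGroups | None = None,
        *,
        min_prevalence: float = 0.10,
        min_abundance: float = 0.001,
        presence_threshold: float = 0.0,
        n_shuffles: int = 10_000,
        alpha: float = 0.05,
        ks_mode: str = "pairwise",
        include_focal: bool = True,
        min_group: int = 2,
        apply_filter: bool = True,
        renormalize: bool = False,
    ) -> None:
        self.table = table
        self.groups = groups or SampleGroups.single_group(table.sample_ids)
        self.min_prevalence = min_prevalence
        self.min_abundance = min_abundance
        self.presence_threshold = presence_threshold
        self.n_shuffles = n_shuffles
        self.alpha = alpha
        self.ks_mode = ks_mode
        self.include_focal = include_focal
        self.min_group = min_group
        self.apply_filter = apply_filter
        self.renormalize = renormalize

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        metadata: pd.DataFrame | None = None,
        group_col: str = "group",
        host_col: str | None = None,
        **kwargs,
    ) -> "Majic":
        """Build the model from plain DataFrames (samples-as-rows table)."""
        table = AbundanceTable(df)
        groups = None
        if metadata is not None:
            meta = metadata.copy()
            if "sample_id" in meta.columns:
                meta = meta.set_index("sample_id")
            host = meta[host_col].astype(str) if host_col else None
            groups = SampleGroups(group=meta[group_col], host=host)
        return cls(table, groups, **kwargs)

    # -- fitting ------------------------------------------------------------

    def _filtered_tables(self) -> dict[str, AbundanceTable]:
        if self.apply_filter:
            return filter_species(
                self.table,
                self.groups,
                min_prevalence=self.min_prevalence,
                min_abundance=self.min_abundance,
                renormalize=self.renormalize,
            )
        self.groups.require_cover(self.table.sample_ids)
        out = {}
        for label in self.groups.group_labels:
            samples = [s for s in self.groups.samples_in(label)
                       if s in set(self.table.sample_ids)]
            if samples:
                out[label] = self.table.subset_samples(samples)
        return out

    def fit(self, seed: int | None = None) -> "MajicResults":
        """Run MAJIC for every retained species in every group.

        ``seed`` is the single master seed; if omitted one is drawn from
        entropy and logged, so every run is reproducible after the fact.
        """
        if seed is None:
            seed = secrets.randbelow(2**31)
            logger.info("no seed supplied; drew master seed %d", seed)
        seed = int(seed)
        per_group = self._filtered_tables()
        results: dict[str, list[core.MajicResult]] = {}
        matrices: dict[str, PresenceMatrix] = {}
        tables: dict[str, AbundanceTable] = {}
        for label in sorted(per_group):
            table = per_group[label]
            pa = to_presence_absence(table, self.presence_threshold)
            occupied = pa.bits.sum(axis=1) > 0
            if not occupied.all():
                dropped = list(pa.bits.index[~occupied])
                logger.warning(
                    "group %s: dropping %d all-zero sample(s) from MAJIC: %s",
                    label, len(dropped), dropped,
                )
                table = table.subset_samples(list(pa.bits.index[occupied]))
                pa = to_presence_absence(table, self.presence_threshold)
            if pa.n_samples < 2 * self.min_group:
                logger.warning(
                    "group %s: only %d samples (< %d) — skipped",
                    label, pa.n_samples, 2 * self.min_group,
                )
                continue
            matrices[label] = pa
            tables[label] = table
            group_results = []
            for focal in pa.species_ids:
                sub_seed = core.derive_seed(seed, label, focal)
                res = core.majic_single(
                    pa,
                    focal,
                    n_shuffles=self.n_shuffles,
                    alpha=self.alpha,
                    ks_mode=self.ks_mode,
                    include_focal=self.include_focal,
                    min_group=self.min_group,
                    rng=sub_seed,
                    group=label,
                )
                group_results.append(res)
            results[label] = group_results
        return MajicResults(
            model=self, seed=seed, groups_results=results,
            presence_matrices=matrices, filtered_tables=tables,
        )


@dataclass
class MajicResults:
    """Fitted MAJIC results: one :class:`majic.core.MajicResult` per
    (group, focal species), plus the filtered tables and presence matrices
    the estimates were computed on."""

    model: Majic
    seed: int
    groups_results: dict[str, list[core.MajicResult]]
    presence_matrices: dict[str, PresenceMatrix]
    filtered_tables: dict[str, AbundanceTable]

    def __iter__(self):
        for label in sorted(self.groups_results):
            yield from self.groups_results[label]

    def result_for(self, group: str, focal: str) -> core.MajicResult:
        for res in self.groups_results[group]:
            if res.focal_species_id == focal:
                return res
        raise KeyError(f"no result for focal {focal!r} in group {group!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for res in self:
            rows.append(
                {
                    "group": res.group,
                    "focal_species": res.focal_species_id,
                    "n_plus": res.n_plus,
                    "n_minus": res.n_minus,
                    "mu_plus": res.mu_plus,
                    "mu_minus": res.mu_minus,
                    "delta_mu": res.delta_mu,
                    "ks_D": res.ks_D,
                    "p_value": res.p_value,
                    "p_mode": res.p_mode,
                    "classification": res.classification,
                    "n_shuffles": res.n_shuffles,
                    "seed": res.seed,
                }
            )
        cols = [
            "group", "focal_species", "n_plus", "n_minus", "mu_plus",
            "mu_minus", "delta_mu", "ks_D", "p_value", "p_mode",
            "classification", "n_shuffles", "seed",
        ]
        df = pd.DataFrame(rows, columns=cols)
        return df.sort_values(["group", "focal_species"]).reset_index(drop=True)

    def summary(self) -> str:
        """Human-readable per-group summary table."""
        df = self.to_frame()
        lines = [
            "MAJIC state-association results",
            f"  master seed: {self.seed}   shuffles: {self.model.n_shuffles}   "
            f"mode: {self.model.ks_mode}   alpha: {self.model.alpha}",
        ]
        for label, sub in df.groupby("group"):
            n_assoc = int((sub["classification"] == "state_associated").sum())
            n_nc = int((sub["classification"] == "not_computable").sum())
            lines.append(
                f"group {label}: {len(sub)} focal species, "
                f"{n_assoc} state-associated, {n_nc} not computable"
            )
            with pd.option_context("display.width", 120):
                lines.append(
                    sub[
                        ["focal_species", "n_plus", "n_minus", "mu_plus",
                         "mu_minus", "delta_mu", "p_value", "classification"]
                    ].to_string(index=False, float_format=lambda v: f"{v:.4f}")
                )
        return "\n".join(lines)

    def abundance_effects(self, **kwargs):
        """Second-stage Wilcoxon abundance effects (see majic.effects)."""
        from .effects import abundance_effects

        return abundance_effects(self.filtered_tables, self, **kwargs)

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "majic_results.tsv"
        write_majic_results(self, path)
        return path

    def dump_nulls(self, out_dir: str | Path) -> list[Path]:
        """Write one TSV per focal species with the null ensemble, one
        shuffle per row."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for res in self:
            if res.null is None:
                continue
            df = pd.DataFrame(
                {
                    "shuffle": np.arange(res.null.n_shuffles),
                    "mu_plus_null": res.null.mu_plus_null,
                    "mu_minus_null": res.null.mu_minus_null,
                    "delta_mu_null": res.null.delta_mu_null,
                }
            )
            safe = res.focal_species_id.replace("/", "_").replace(" ", "_")
            path = out_dir / f"nulls_{res.group}_{safe}.tsv"
            df.to_csv(path, sep="\t", index=False, float_format="%.10g")
            written.append(path)
        return written


def run_majic(
    table: AbundanceTable,
    groups: SampleGroups | None = None,
    seed: int | None = None,
    **config,
) -> MajicResults:
    """Functional entry point: build a :class:`Majic` model and fit it."""
    return Majic(table, groups, **config).fit(seed=seed)
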