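"""Second MAJIC stage: species whose relative abundances differ between the
σᵢ⁺ and σᵢ⁻ sample sets of a focal species, by two-sided Wilcoxon rank-sum
tests with family-wise multiple-testing control.

The family for adjustment is, by default, all targets *j* of one focal
species *i* within one group ("per_focal"); a global family over all
(focal, target) pairs is available. Abundances are tested on the original
fraction scale without renormalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("majic")

#: use the exact rank-sum null when tie-free and n+m is at most this
WILCOXON_EXACT_MAX_N = 20


@dataclass
class EffectRecord:
    """One (focal i, target j) Wilcoxon abundance-effect test."""

    group: str
    focal_species_id: str
    target_species_id: str
    n_plus: int
    n_minus: int
    W: float
    p_raw: float
    p_adj: float
    direction: str  # higher_when_present | lower_when_present
    significant: bool
    adjust_method: str
    focal_classification: str
    method: str = "exact"


def wilcoxon_rank_sum(x, y) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact p when the pooled data are tie-free and n+m ≤ 20; otherwise the
    normal approximation with tie and continuity corrections. Returns
    (U statistic of x, p, method). Completely tied data (all values equal)
    give p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test requires non-empty samples")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return x.size * y.size / 2.0, 1.0, "degenerate"
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and pooled.size <= WILCOXON_EXACT_MAX_N:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0)), "asymptotic"


def _direction(x: np.ndarray, y: np.ndarray, W: float) -> str:
    """Effect orientation: sign of the median difference, falling back on the
    rank-sum orientation (U vs nm/2) under a median tie."""
    diff = float(np.median(x) - np.median(y))
    if diff > 0:
        return "higher_when_present"
    if diff < 0:
        return "lower_when_present"
    return "higher_when_present" if W >= x.size * y.size / 2 else "lower_when_present"


def _adjust(p_raw: np.ndarray, method: str) -> np.ndarray:
    if len(p_raw) == 0:
        return np.asarray(p_raw)
    sm_method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    return multipletests(p_raw, method=sm_method)[1]


def abundance_effects(
    tables: Mapping[str, "AbundanceTable"],
    report,
    adjust: str = "bonferroni",
    alpha: float = 0.05,
    family: str = "per_focal",
    focals: Iterable[str] | None = None,
) -> list[EffectRecord]:
    """Test every target species j ≠ i across σᵢ⁺ vs σᵢ⁻ for every focal i.

    Parameters
    ----------
    tables
        Per-group abundance tables sharing samples/species with ``report``
        (normally ``report.filtered_tables``).
    report
        Fitted :class:`majic.model.MajicResults`.
    adjust
        ``"bonferroni"`` (default, p_adj = min(1, m·p)) or ``"bh"``.
    family
        ``"per_focal"``: adjust within each focal species' target family
        (per group); ``"global"``: one family over all records.
    focals
        Optional subset of focal species ids to test.

    All records are returned, each flagged ``significant`` at ``alpha``;
    filtering to the reported subset is :func:`filter_effects`' job.
    """
    if adjust not in ("bonferroni", "bh"):
        raise ValueError(f"unknown adjust method {adjust!r}")
    if family not in ("per_focal", "global"):
        raise ValueError(f"unknown family {family!r}")
    focal_set = set(focals) if focals is not None else None
    records: list[EffectRecord] = []
    for label in sorted(report.groups_results):
        if label not in tables:
            raise ValueError(f"no abundance table supplied for group {label!r}")
        table = tables[label]
        data = table.data
        for res in report.groups_results[label]:
            if res.classification == "not_computable":
                continue
            if focal_set is not None and res.focal_species_id not in focal_set:
                continue
            plus, minus = list(res.sigma_plus), list(res.sigma_minus)
            missing = (set(plus) | set(minus)) - set(data.index)
            if missing:
                raise ValueError(
                    f"group {label!r}: samples in MAJIC split absent from "
                    f"table: {sorted(missing)}"
                )
            family_records = []
            for target in data.columns:
                if target == res.focal_species_id:
                    continue
                x = data.loc[plus, target].to_numpy()
                y = data.loc[minus, target].to_numpy()
                W, p, method = wilcoxon_rank_sum(x, y)
                family_records.append(
                    EffectRecord(
                        group=label,
                        focal_species_id=res.focal_species_id,
                        target_species_id=target,
                        n_plus=len(plus),
                        n_minus=len(minus),
                        W=W,
                        p_raw=p,
                        p_adj=np.nan,
                        direction=_direction(x, y, W),
                        significant=False,
                        adjust_method=adjust,
                        focal_classification=res.classification,
                        method=method,
                    )
                )
            if family == "per_focal":
                p_adj = _adjust(np.array([r.p_raw for r in family_records]), adjust)
                for rec, pa in zip(family_records, p_adj):
                    rec.p_adj = float(pa)
                    rec.significant = bool(pa < alpha)
            records.extend(family_records)
    if family == "global" and records:
        p_adj = _adjust(np.array([r.p_raw for r in records]), adjust)
        for rec, pa in zip(records, p_adj):
            rec.p_adj = float(pa)
            rec.significant = bool(pa < alpha)
    return records


def filter_effects(
    records: list[EffectRecord],
    require_state_associated: bool = True,
    taxa_of_interest: Iterable[str] = (),
) -> list[EffectRecord]:
    """Keep significant effect records; optionally require a state-associated
    focal species and/or an intersection with an interest set (e.g. dominant
    Bifidobacterium and E. coli)."""
    interest = set(taxa_of_interest)
    out = []
    for rec in records:
        if not rec.significant:
            continue
        if require_state_associated and rec.focal_classification != "state_associated":
            continue
        if interest and not ({rec.focal_species_id, rec.target_species_id} & interest):
            continue
        out.append(rec)
    return out


_EFFECT_COLS = [
    "group", "focal_species", "target_species", "n_plus", "n_minus", "W",
    "p_raw", "p_adj", "adjust_method", "direction", "significant",
    "focal_classification",
]


def effects_to_frame(records: list[EffectRecord]) -> pd.DataFrame:
    rows = [
        {
            "group": r.group,
            "focal_species": r.focal_species_id,
            "target_species": r.target_species_id,
            "n_plus": r.n_plus,
            "n_minus": r.n_minus,
            "W": r.W,
            "p_raw": r.p_raw,
            "p_adj": r.p_adj,
            "adjust_method": r.adjust_method,
            "direction": r.direction,
            "significant": r.significant,
            "focal_classification": r.focal_classification,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=_EFFECT_COLS)
    return df.sort_values(
        ["group", "focal_species", "target_species"]
    ).reset_index(drop=True)
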