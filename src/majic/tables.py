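"""Abundance-table I/O, validation, group-wise filtering and binarisation.

The canonical in-memory layout is samples-as-rows: an :class:`AbundanceTable`
wraps a ``pandas.DataFrame`` whose index holds sample identifiers, whose
columns hold species identifiers, and whose cells hold relative abundances on
the fraction scale (percent inputs are rescaled at read time). Row sums may be
below 1 because low-abundance taxa are removed by upstream profiling or by
:func:`filter_species`; abundances are deliberately *not* renormalised after
filtering so that dominance thresholds (e.g. the 20% high-abundance cutoff)
keep their meaning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("majic")

#: tolerance on per-sample relative-abundance sums (allows float round-off)
SUM_TOLERANCE = 1e-6


class TableFormatError(ValueError):
    """A delimited input file violates the table contract."""


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    # pandas silently mangles duplicate header names, so check the raw header
    _check_unique(header[1:], "column", path)
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str)


def _check_unique(ids: Iterable[str], what: str, path: str | Path) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise TableFormatError(f"{path}: duplicate {what} id(s): {dups}")


@dataclass
class AbundanceTable:
    """Relative abundances per (sample, species), samples as rows.

    Parameters
    ----------
    data
        Samples × species DataFrame of fractions in ``[0, 1]``. Per-sample
        sums must not exceed ``1 + SUM_TOLERANCE``; sub-1 sums are legal.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise TableFormatError("duplicate sample ids in abundance table")
        if df.columns.has_duplicates:
            raise TableFormatError("duplicate species ids in abundance table")
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise TableFormatError("abundance table contains missing values")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise TableFormatError(
                f"negative abundance at sample {df.index[r]!r}, "
                f"species {df.columns[c]!r}"
            )
        sums = values.sum(axis=1)
        if (sums > 1.0 + SUM_TOLERANCE).any():
            bad = df.index[np.argmax(sums)]
            raise TableFormatError(
                f"sample {bad!r} has relative-abundance sum {sums.max():.6g} > 1"
            )
        self.data = df.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_species(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        ids = list(sample_ids)
        missing = set(ids) - set(self.data.index)
        if missing:
            raise KeyError(f"unknown sample id(s): {sorted(missing)}")
        return AbundanceTable(self.data.loc[ids])

    def subset_species(self, species_ids: Iterable[str]) -> "AbundanceTable":
        ids = list(species_ids)
        missing = set(ids) - set(self.data.columns)
        if missing:
            raise KeyError(f"unknown species id(s): {sorted(missing)}")
        return AbundanceTable(self.data[ids])


@dataclass
class SampleGroups:
    """Sample → group assignment, optionally sample → host."""

    group: pd.Series
    host: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.group.index.has_duplicates:
            dup = self.group.index[self.group.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate sample id(s) in metadata: {dup}")
        self.group = self.group.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.group.index)

    @property
    def group_labels(self) -> list[str]:
        return sorted(self.group.unique())

    def samples_in(self, label: str) -> list[str]:
        return list(self.group.index[self.group == label])

    def require_cover(self, sample_ids: Iterable[str]) -> None:
        """Hard error if any analysed sample lacks a group label."""
        missing = set(sample_ids) - set(self.group.index)
        if missing:
            raise TableFormatError(
                f"analysed sample(s) missing from metadata: {sorted(missing)}"
            )

    @classmethod
    def single_group(cls, sample_ids: Iterable[str], label: str = "all") -> "SampleGroups":
        ids = list(sample_ids)
        return cls(group=pd.Series([label] * len(ids), index=ids, name="group"))


@dataclass
class PresenceMatrix:
    """Binary occupancy matrix derived from an AbundanceTable at a threshold."""

    bits: pd.DataFrame  # samples × species, values in {0, 1}
    threshold: float = 0.0

    def __post_init__(self) -> None:
        arr = self.bits.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("presence matrix must contain only 0/1")
        self.bits = self.bits.astype(np.int8)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.bits.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.bits.columns)

    @property
    def n_samples(self) -> int:
        return self.bits.shape[0]


def read_abundance_table(
    path: str | Path,
    orientation: str = "samples-as-rows",
    scale: str = "fraction",
) -> AbundanceTable:
    """Read a delimited abundance table into canonical form.

    Parameters
    ----------
    path
        TSV (default) or CSV file with one header row and one id column.
    orientation
        ``"samples-as-rows"`` or ``"species-as-rows"``; the latter is
        transposed on read.
    scale
        ``"fraction"`` (values already in [0, 1]) or ``"percent"``
        (values divided by 100 on read).
    """
    if orientation not in ("samples-as-rows", "species-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if scale not in ("fraction", "percent"):
        raise ValueError(f"unknown scale {scale!r}")
    raw = _read_delimited(path)
    _check_unique(raw.index, "row", path)
    _check_unique(raw.columns, "column", path)
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad][0]
            raise TableFormatError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}: "
                f"{raw.loc[row, col]!r}"
            )
        numeric[col] = converted
    if orientation == "species-as-rows":
        numeric = numeric.T
    if scale == "percent":
        numeric = numeric / 100.0
    empty_samples = numeric.index[(numeric.sum(axis=1) == 0)].tolist()
    empty_species = numeric.columns[(numeric.sum(axis=0) == 0)].tolist()
    if empty_samples:
        logger.warning("%s: all-zero sample row(s) retained: %s", path, empty_samples)
    if empty_species:
        logger.warning("%s: all-zero species column(s) retained: %s", path, empty_species)
    numeric.index = numeric.index.astype(str).rename("sample_id")
    numeric.columns = numeric.columns.astype(str).rename(None)
    return AbundanceTable(numeric)


def read_metadata(path: str | Path) -> SampleGroups:
    """Read sample metadata with columns ``sample_id``, ``group``, [``host_id``]."""
    raw = _read_delimited(path).reset_index()
    first = raw.columns[0]
    if first != "sample_id":
        raw = raw.rename(columns={first: "sample_id"})
    if "group" not in raw.columns:
        raise TableFormatError(f"{path}: metadata must have a 'group' column")
    dup = raw[raw.duplicated("sample_id", keep=False)]
    if not dup.empty:
        for sid, sub in dup.groupby("sample_id"):
            if sub["group"].nunique() > 1:
                raise TableFormatError(
                    f"{path}: sample {sid!r} has conflicting group labels: "
                    f"{sorted(sub['group'].unique())}"
                )
        raw = raw.drop_duplicates("sample_id")
        logger.warning("%s: dropped duplicated consistent metadata rows", path)
    raw = raw.set_index("sample_id")
    raw.index = raw.index.astype(str)
    host = raw["host_id"].astype(str) if "host_id" in raw.columns else None
    return SampleGroups(group=raw["group"], host=host)


def filter_species(
    table: AbundanceTable,
    groups: SampleGroups,
    min_prevalence: float = 0.10,
    min_abundance: float = 0.001,
    renormalize: bool = False,
) -> dict[str, AbundanceTable]:
    """Apply the group-wise prevalence/abundance filter.

    For each group independently, a species is retained iff the fraction of
    that group's samples in which its relative abundance is at least
    ``min_abundance`` reaches ``min_prevalence`` (inclusive boundary: exactly
    10% of samples retains the species). Returns one filtered table per group;
    abundances are not renormalised unless requested.
    """
    if not (0 <= min_prevalence <= 1 and 0 <= min_abundance <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    groups.require_cover(table.sample_ids)
    in_table = [s for s in groups.sample_ids if s in set(table.sample_ids)]
    dropped_meta = set(groups.sample_ids) - set(in_table)
    if dropped_meta:
        logger.warning(
            "metadata sample(s) absent from table, ignored: %s", sorted(dropped_meta)
        )
    out: dict[str, AbundanceTable] = {}
    labels = sorted(groups.group.loc[in_table].unique())
    for label in labels:
        samples = [s for s in in_table if groups.group[s] == label]
        if len(samples) == 0:
            raise ValueError(f"group {label!r} has zero samples in the table")
        sub = table.data.loc[samples]
        detected = (sub >= min_abundance).mean(axis=0)
        keep = detected[detected >= min_prevalence].index
        if len(keep) == 0:
            raise ValueError(
                f"group {label!r}: every species fails the "
                f"{min_prevalence:.0%}/{min_abundance:.2%} filter "
                f"(max detection fraction {detected.max():.3f})"
            )
        filt = sub[keep]
        if renormalize:
            sums = filt.sum(axis=1)
            filt = filt.div(sums.where(sums > 0, 1.0), axis=0)
        out[label] = AbundanceTable(filt)
        logger.info(
            "group %s: retained %d/%d species over %d samples",
            label, len(keep), table.n_species, len(samples),
        )
    return out


def to_presence_absence(table: AbundanceTable, threshold: float = 0.0) -> PresenceMatrix:
    """Binarise at a detection threshold: bit = 1 iff abundance > threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    bits = (table.data > threshold).astype(np.int8)
    empty = bits.index[bits.sum(axis=1) == 0].tolist()
    if empty:
        logger.warning("all-zero presence row(s) at threshold %g: %s", threshold, empty)
    return PresenceMatrix(bits=bits, threshold=threshold)


# ---------------------------------------------------------------------------
# Result writers. All outputs are TSV with deterministic row order and a
# fixed float format so identical runs produce byte-identical files.

_FLOAT_FMT = "%.10g"


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    try:
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    except OSError as exc:  # surface the path in the error
        raise OSError(f"failed to write {path}: {exc}") from exc


def write_majic_results(results, path: str | Path) -> None:
    """Write per-focal MAJIC rows (group, then focal species id order)."""
    df = results.to_frame()
    cols = [
        "group", "focal_species", "n_plus", "n_minus", "mu_plus", "mu_minus",
        "delta_mu", "ks_D", "p_value", "p_mode", "classification",
        "n_shuffles", "seed",
    ]
    _write_tsv(df[cols].sort_values(["group", "focal_species"]), path)


def write_effects(records, path: str | Path) -> None:
    """Write Wilcoxon abundance-effect rows; header-only file if empty."""
    from .effects import effects_to_frame

    _write_tsv(effects_to_frame(records), path)


def write_csi(csi_table: pd.DataFrame, path: str | Path) -> None:
    cols = ["species_id", "csi", "percentile_rank", "top5pct_flag"]
    _write_tsv(csi_table[cols].sort_values("species_id"), path)


def write_prevalence(summary: pd.DataFrame, path: str | Path) -> None:
    cols = ["species_id", "prevalence", "high_abundance"]
    _write_tsv(summary[cols].sort_values("species_id"), path)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    try:
        table.data.to_csv(path, sep="\t", index_label="sample_id")
    except OSError as exc:
        raise OSError(f"failed to write {path}: {exc}") from exc


def write_metadata(groups: SampleGroups, path: str | Path) -> None:
    df = pd.DataFrame({"sample_id": groups.sample_ids, "group": groups.group.values})
    if groups.host is not None:
        df["host_id"] = groups.host.values
    _write_tsv(df, path)


def write_results(obj, out_dir: str | Path) -> list[Path]:
    """Dispatch writer: MajicResults, effect-record lists, or CSI/summary frames."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from .effects import EffectRecord

    written: list[Path] = []
    if hasattr(obj, "to_frame") and hasattr(obj, "groups_results"):
        p = out_dir / "majic_results.tsv"
        write_majic_results(obj, p)
        written.append(p)
    elif isinstance(obj, list) and (not obj or isinstance(obj[0], EffectRecord)):
        p = out_dir / "effects.tsv"
        write_effects(obj, p)
        written.append(p)
    elif isinstance(obj, pd.DataFrame) and "csi" in obj.columns:
        p = out_dir / "csi.tsv"
        write_csi(obj, p)
        written.append(p)
    elif isinstance(obj, pd.DataFrame) and "prevalence" in obj.columns:
        p = out_dir / "prevalence.tsv"
        write_prevalence(obj, p)
        written.append(p)
    else:
        raise TypeError(f"no writer for object of type {type(obj)!r}")
    return written
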