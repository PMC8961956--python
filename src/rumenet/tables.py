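"""Core in-memory containers for the pipeline.

All downstream analyses operate on these validated domain objects:

* :class:`CountTable` — samples x ASVs matrix of nonnegative integer read
  counts, the root object of every analysis.
* :class:`TaxonomyTable` — ASV -> seven-rank lineage with explicit
  unassigned flags.
* :class:`SampleFrame` — per-sample design metadata (animal, backgrounding
  group, timepoint, study day) driving all stratifications.
* :class:`PhenotypeTable` — per-animal average daily gain (kg/day) per
  study phase.

Validation happens at construction; readers in :mod:`rumenet.io_formats`
only parse and then delegate here, so a constructed object can always be
trusted by the statistics modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("rumenet")

#: canonical rank names, finest last
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: backgrounding systems used in the study design
DEFAULT_GROUPS = ("CC", "DL", "PP")

#: sampling timepoints: weaning, early/late backgrounding, early/late finishing
DEFAULT_TIMEPOINTS = ("T1", "T2", "T3", "T4", "T5")

#: ADG phases
PHASES = ("backgrounding", "finishing", "overall")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_unique(labels: Iterable[str], what: str) -> None:
    labels = list(labels)
    if len(labels) != len(set(labels)):
        seen, dups = set(), []
        for x in labels:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValidationError(f"duplicate {what} identifiers: {sorted(set(dups))[:5]}")


@dataclass
class CountTable:
    """Samples x ASVs nonnegative integer count matrix.

    ``data`` is indexed by sample id with one column per ASV. Use
    :meth:`from_frame` to construct with validation (all-zero samples are
    dropped with a warning by default, mirroring what rarefaction or
    prevalence filters can produce mid-pipeline).
    """

    data: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame, drop_empty: bool = True) -> "CountTable":
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "ASV")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("count table contains non-numeric entries")
        if np.any(~np.isfinite(values)):
            raise ValidationError("count table contains non-finite entries")
        if np.any(values < 0):
            raise ValidationError("count table contains negative entries")
        if np.any(values != np.round(values)):
            raise ValidationError(
                "count table contains non-integer entries; this layer accepts "
                "raw read counts only (normalisation belongs to the CLR layer)"
            )
        df = df.astype(np.int64)
        empty = df.sum(axis=1) == 0
        if empty.any():
            if drop_empty:
                logger.warning(
                    "dropping %d all-zero sample(s): %s",
                    int(empty.sum()),
                    list(df.index[empty])[:5],
                )
                df = df.loc[~empty]
            else:
                raise ValidationError(
                    f"all-zero samples present: {list(df.index[empty])[:5]}"
                )
        if df.shape[0] == 0:
            raise ValidationError("no samples")
        return cls(df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions (rows sum to 1)."""
        return self.data.div(self.data.sum(axis=1), axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        """Restrict to the given samples (order preserved); revalidates."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return CountTable.from_frame(self.data.loc[list(sample_ids)])

    def subset_taxa(self, asv_ids: Sequence[str]) -> "CountTable":
        missing = [a for a in asv_ids if a not in self.data.columns]
        if missing:
            raise KeyError(f"unknown ASV ids: {missing[:5]}")
        return CountTable.from_frame(self.data[list(asv_ids)])


@dataclass
class TaxonomyTable:
    """ASV -> positional seven-rank lineage; missing entries mean unassigned.

    Ranks are positional: rank *k* is meaningful only when every coarser
    rank is assigned. Lineages violating that are truncated at the first
    gap with a logged warning.
    """

    data: pd.DataFrame  # index asv_id, columns RANKS; NaN = unassigned

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TaxonomyTable":
        _check_unique(df.index, "ASV")
        for rank in RANKS:
            if rank not in df.columns:
                df[rank] = np.nan
        df = df[list(RANKS)].copy()
        # blank strings count as unassigned
        df = df.replace({"": np.nan})
        # enforce positional ranks: truncate after first unassigned rank
        arr = df.to_numpy(dtype=object)
        n_truncated = 0
        for i in range(arr.shape[0]):
            gap = None
            for j in range(arr.shape[1]):
                if pd.isna(arr[i, j]):
                    gap = j
                    break
            if gap is not None and any(not pd.isna(x) for x in arr[i, gap:]):
                arr[i, gap:] = np.nan
                n_truncated += 1
        if n_truncated:
            logger.warning(
                "truncated %d lineage(s) at the first unassigned rank", n_truncated
            )
        return cls(pd.DataFrame(arr, index=df.index, columns=list(RANKS)))

    def lineage(self, asv_id: str) -> tuple:
        return tuple(self.data.loc[asv_id])

    def assigned_at(self, asv_id: str, rank: str) -> bool:
        return not pd.isna(self.data.loc[asv_id, rank])

    def covers(self, asv_ids: Iterable[str]) -> bool:
        return all(a in self.data.index for a in asv_ids)


@dataclass
class SampleFrame:
    """Per-sample design metadata.

    ``data`` is indexed by sample id with columns ``animal_id``, ``group``,
    ``timepoint`` and ``day``. ``timepoints`` preserves the declared
    temporal order (days must be monotone along it).
    """

    data: pd.DataFrame
    groups: tuple = DEFAULT_GROUPS
    timepoints: tuple = DEFAULT_TIMEPOINTS

    REQUIRED = ("animal_id", "group", "timepoint", "day")

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        groups: Sequence[str] = DEFAULT_GROUPS,
        timepoints: Sequence[str] = DEFAULT_TIMEPOINTS,
        label_map: Mapping[str, str] | None = None,
    ) -> "SampleFrame":
        missing = [c for c in cls.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"missing required column(s): {missing}")
        if df.shape[0] == 0:
            raise ValidationError("no samples")
        _check_unique(df.index, "sample")
        df = df[list(cls.REQUIRED)].copy()
        if label_map:
            df["group"] = df["group"].map(lambda g: label_map.get(g, g))
            df["timepoint"] = df["timepoint"].map(lambda t: label_map.get(t, t))
        bad_groups = sorted(set(df["group"]) - set(groups))
        if bad_groups:
            raise ValidationError(
                f"unknown group label(s) {bad_groups}; expected one of {list(groups)} "
                "(supply label_map to translate)"
            )
        bad_tp = sorted(set(df["timepoint"]) - set(timepoints))
        if bad_tp:
            raise ValidationError(
                f"unknown timepoint label(s) {bad_tp}; expected one of {list(timepoints)}"
            )
        df["day"] = df["day"].astype(int)
        dup = df.duplicated(subset=["animal_id", "timepoint"])
        if dup.any():
            pairs = df.loc[dup, ["animal_id", "timepoint"]].to_records(index=False)
            raise ValidationError(f"duplicate (animal, timepoint) pairs: {list(pairs)[:5]}")
        # days monotone in timepoint index
        order = {t: i for i, t in enumerate(timepoints)}
        by_tp = df.groupby("timepoint")["day"].agg(["min", "max"])
        prev_max, prev_t = None, None
        for t in sorted(by_tp.index, key=order.get):
            lo, hi = by_tp.loc[t]
            if prev_max is not None and lo < prev_max:
                raise ValidationError(
                    f"study days not monotone across timepoints ({prev_t} -> {t})"
                )
            prev_max, prev_t = hi, t
        return cls(df, tuple(groups), tuple(timepoints))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def samples_at(self, timepoint: str | None = None, group: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.data.index)
        if timepoint is not None:
            mask &= self.data["timepoint"] == timepoint
        if group is not None:
            mask &= self.data["group"] == group
        return list(self.data.index[mask])

    def labels(self, sample_ids: Sequence[str], key: str) -> pd.Series:
        return self.data.loc[list(sample_ids), key]

    def animal_groups(self) -> pd.Series:
        """animal_id -> group (validated to be unique per animal)."""
        ag = self.data.groupby("animal_id")["group"].agg(set)
        multi = ag[ag.map(len) > 1]
        if len(multi):
            raise ValidationError(f"animals assigned to several groups: {list(multi.index)[:5]}")
        return ag.map(lambda s: next(iter(s)))


@dataclass
class PhenotypeTable:
    """animal_id -> average daily gain (kg/day) per phase."""

    data: pd.DataFrame  # index animal_id, columns subset of PHASES

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhenotypeTable":
        _check_unique(df.index, "animal")
        bad = [c for c in df.columns if c not in PHASES]
        if bad:
            raise ValidationError(f"unknown phase column(s) {bad}; expected subset of {PHASES}")
        if df.shape[1] == 0:
            raise ValidationError("phenotype table has no phase columns")
        values = df.to_numpy(dtype=float)
        if np.any(~np.isfinite(values)):
            raise ValidationError("non-finite ADG values")
        return cls(df.astype(float))

    @property
    def phases(self) -> list[str]:
        return list(self.data.columns)

    def adg(self, phase: str) -> pd.Series:
        if phase not in self.data.columns:
            raise KeyError(f"phase {phase!r} not present (have {list(self.data.columns)})")
        return self.data[phase]
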