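"""Core in-memory containers shared across the package.

Expression data live in a pandas DataFrame with genes on the rows and
samples (or cells) on the columns; the :class:`ExpressionMatrix` wrapper
adds a units tag so that stages which require raw counts or normalized
values can check what they were given.  Binary alteration calls live in an
:class:`EventMatrix` keyed by ``"<gene>:<class>"`` event identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_CLASSES = ("mutation", "amplification", "deletion")

COUNTS = "counts"
NORMALIZED = "normalized"
RESIDUALS = "residuals"


class ConfigError(ValueError):
    """A configuration value violates its documented constraint."""


class SchemaError(ValueError):
    """An input table is missing a required column or is malformed."""


def event_id(gene: str, event_class: str) -> str:
    if event_class not in EVENT_CLASSES:
        raise ConfigError(
            f"event_class must be one of {EVENT_CLASSES}, got {event_class!r}"
        )
    return f"{gene}:{event_class}"


def parse_event_id(eid: str) -> tuple[str, str]:
    gene, _, cls = eid.rpartition(":")
    if not gene or cls not in EVENT_CLASSES:
        raise ValueError(f"malformed event id {eid!r}")
    return gene, cls


@dataclass
class ExpressionMatrix:
    """Gene x sample numeric matrix with a units tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier, columns = sample identifiers.
    units
        ``"counts"`` for raw (integer) counts, ``"normalized"`` or
        ``"residuals"`` for transformed values.
    """

    values: pd.DataFrame
    units: str = COUNTS

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise SchemaError(f"duplicate gene identifiers: {list(dupes[:5])}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise SchemaError(f"duplicate sample identifiers: {list(dupes[:5])}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.units)


@dataclass
class EventMatrix:
    """Binary gene-event x sample matrix.

    Rows are event identifiers ``"<gene>:<class>"`` with
    class in {mutation, amplification, deletion}; values are 0/1.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("EventMatrix values must be binary 0/1")
        for eid in self.values.index:
            parse_event_id(eid)
        self.values = self.values.astype(np.int8)

    @property
    def events(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def event_class(self, eid: str) -> str:
        return parse_event_id(eid)[1]

    def frequency(self) -> pd.DataFrame:
        """Per-event carrier count and fraction, consistent with row sums."""
        counts = self.values.sum(axis=1)
        n = max(self.values.shape[1], 1)
        return pd.DataFrame(
            {"carrier_count": counts, "carrier_fraction": counts / n}
        )

    def select(self, event_ids) -> "EventMatrix":
        return EventMatrix(self.values.loc[list(event_ids)])


@dataclass
class Regulon:
    """A transcription factor and its signed target set.

    ``targets`` maps gene identifier -> mode (+1 activated, -1 repressed).
    A regulon must contain at least 10 targets excluding the TF itself.
    """

    tf: str
    targets: dict[str, int] = field(default_factory=dict)
    min_targets: int = 10

    def __post_init__(self) -> None:
        if self.tf in self.targets:
            raise ConfigError(f"regulon {self.tf}: TF listed among its own targets")
        if len(self.targets) < self.min_targets:
            raise ConfigError(
                f"regulon {self.tf}: {len(self.targets)} targets, "
                f"needs at least {self.min_targets} (excluding the TF)"
            )
        bad = {g: m for g, m in self.targets.items() if m not in (+1, -1)}
        if bad:
            raise ConfigError(f"regulon {self.tf}: modes must be +1/-1, got {bad}")

    @property
    def size(self) -> int:
        return len(self.targets)


@dataclass
class GeneCluster:
    """A disjoint coexpression group used as one aggregated variable."""

    cluster_id: str
    members: list[str]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ConfigError(f"cluster {self.cluster_id}: duplicate members")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class CnvSegment:
    """A copy-number segment; log2_ratio = log2(tumor coverage) - median coverage.

    Coordinates are 0-based half-open.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"segment {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                "end must exceed start"
            )


@dataclass(frozen=True)
class GeneInterval:
    """Gene model interval, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")
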