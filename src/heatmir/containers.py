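"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from heatmir.errors import FormatError, MetadataError

#: Detection-call alphabet: present / absent / marginal.
FLAG_ALPHABET = frozenset({"P", "A", "M"})

#: Direction alphabet used for per-timepoint and overall calls.
DIRECTIONS = ("up", "down", "up_down")

#: The experiment's canonical heat time course (0 min is the control).
DEFAULT_TIMEPOINTS = ("0min", "10min", "20min", "60min", "2h")


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of log2 intensities with optional P/A/M flags.

    ``values`` is a probes x samples DataFrame; ``samples`` is indexed by
    sample id with columns ``timepoint`` (ordered categorical) and
    ``replicate`` (positive int); ``flags`` (optional) mirrors ``values``
    with cells in {P, A, M}.  Construction validates shapes and reorders
    columns canonically by (timepoint, replicate) so downstream column
    indexing is deterministic.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate probe id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise MetadataError(
                f"samples present in matrix but missing from sample sheet: {missing}"
            )
        if not isinstance(self.samples["timepoint"].dtype, pd.CategoricalDtype):
            self.samples = self.samples.copy()
            self.samples["timepoint"] = pd.Categorical(
                self.samples["timepoint"],
                categories=list(dict.fromkeys(self.samples["timepoint"])),
                ordered=True,
            )
        if self.samples["timepoint"].isna().any():
            raise MetadataError("sample with timepoint outside the ordered timepoint set")
        if self.flags is not None:
            if self.flags.shape != self.values.shape:
                raise FormatError(
                    f"flag matrix shape {self.flags.shape} != value matrix shape "
                    f"{self.values.shape}"
                )
            bad = set(self.flags.values.ravel()) - FLAG_ALPHABET
            if bad:
                where = (~self.flags.isin(FLAG_ALPHABET)).stack()
                row, col = where[where].index[0]
                raise FormatError(
                    f"unknown flag {sorted(bad)[0]!r} at probe {row!r}, sample {col!r}"
                )
            self.flags = self.flags.loc[self.values.index, self.values.columns]
        # canonical sample order: timepoint, then replicate
        meta = self.samples.loc[list(self.values.columns)]
        order = meta.sort_values(["timepoint", "replicate"]).index
        self.values = self.values.loc[:, order]
        if self.flags is not None:
            self.flags = self.flags.loc[:, order]

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def timepoints(self) -> list[str]:
        """Ordered timepoint labels (first label is the control by convention)."""
        return list(self.samples["timepoint"].cat.categories)

    def samples_at(self, timepoint: str) -> list[str]:
        """Sample ids belonging to one timepoint, in canonical order."""
        meta = self.samples.loc[list(self.values.columns)]
        return list(meta.index[meta["timepoint"] == timepoint])

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[list(probe_ids)],
            samples=self.samples,
            flags=None if self.flags is None else self.flags.loc[list(probe_ids)],
        )

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Same metadata/flags, new value matrix (same shape and labels)."""
        if values.shape != self.values.shape:
            raise FormatError("replacement values have a different shape")
        return ExpressionMatrix(values=values, samples=self.samples, flags=self.flags)


@dataclass(frozen=True)
class TargetSite:
    """One scored miRNA-transcript duplex site.

    ``start``/``end`` are 1-based fully-closed transcript coordinates of the
    site (5'-most base first).  ``alignment`` is one character per duplex
    column, ordered from the miRNA 5' end:

    ``|`` Watson-Crick match, ``o`` G:U wobble, ``x`` mismatch,
    ``-`` bulged miRNA base (gap in target), ``^`` bulged target base
    (gap in miRNA).

    ``expectation`` is the cumulative complementarity penalty (lower is
    better); ``mode`` is ``cleavage`` unless central pairing (miRNA positions
    10-11) is disrupted, then ``translation_inhibition``.
    """

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    alignment: str
    expectation: float
    mode: str


@dataclass
class FamilyProfile:
    """A miRNA family's members and expression-direction summary."""

    family: str
    members: list[str]
    direction_by_timepoint: dict[str, str]  # up | down | none | conflict
    overall_direction: str  # up | down | up_down


@dataclass
class CoregModule:
    """A coregulatory module: a connected set of >=2 families plus their genes."""

    families: list[str]
    genes: list[str]
    hub: str
    edges: list[tuple[str, str, str]] = field(default_factory=list)  # (u, v, kind)

    @property
    def size(self) -> int:
        return len(self.families) + len(self.genes)
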