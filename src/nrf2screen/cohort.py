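"""Sample/cohort data model, delimited-text IO, and the use/validation split.

A cohort is a table of NSCLC tumors: one row per sample with histology
(LUAD or LUSC), KEAP1/NFE2L2 mutation status, normalised log-scale RNA
expression for a small marker panel, and optionally an NQO1 IHC H-score, a
continuous K1N2 pathway score with its published binary call, and (for
synthetic cohorts only) the latent pathway-activation truth.

The use/validation split mirrors the standard train/held-out design:
cutpoints are optimised on the "use" subset and performance is assessed on
the "validation" subset.  The split is either a seeded stratified draw or
an explicit assignment file (two columns: sample_id, group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd


class Histology(str, Enum):
    LUAD = "LUAD"
    LUSC = "LUSC"


class MutationStatus(str, Enum):
    KEAP1mut = "KEAP1mut"
    NFE2L2mut = "NFE2L2mut"
    WT = "WT"


class SplitGroup(str, Enum):
    use = "use"
    validation = "validation"


#: Columns with fixed meaning in a cohort file; everything else is a panel gene.
RESERVED_COLUMNS = (
    "sample_id",
    "histology",
    "mutation_status",
    "h_score",
    "k1n2_score",
    "k1n2_call",
    "pathway_active_truth",
)


class CohortValidationError(ValueError):
    """A cohort file or object violates a field invariant."""


@dataclass(frozen=True)
class Sample:
    """One tumor sample.

    ``expression`` maps gene symbol to normalised log-scale expression.
    ``h_score`` is the NQO1 IHC H-score (integer 0-300) when IHC was done.
    ``k1n2_call`` is the published binary pathway call belonging to
    ``k1n2_score``; ``pathway_active_truth`` exists only in synthetic
    cohorts, where the generator knows the latent truth.
    """

    sample_id: str
    histology: Histology
    mutation_status: MutationStatus
    expression: Mapping[str, float] = field(default_factory=dict)
    h_score: int | None = None
    k1n2_score: float | None = None
    k1n2_call: bool | None = None
    pathway_active_truth: bool | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "histology", Histology(self.histology))
        object.__setattr__(self, "mutation_status", MutationStatus(self.mutation_status))
        if self.h_score is not None:
            h = self.h_score
            if not float(h).is_integer() or not 0 <= h <= 300:
                raise CohortValidationError(
                    f"sample {self.sample_id!r}: h_score must be an integer "
                    f"in [0, 300], got {h!r}"
                )
            object.__setattr__(self, "h_score", int(h))
        expr = {str(g): float(v) for g, v in self.expression.items()}
        bad = [g for g, v in expr.items() if not math.isfinite(v)]
        if bad:
            raise CohortValidationError(
                f"sample {self.sample_id!r}: non-finite expression for {bad}"
            )
        object.__setattr__(self, "expression", expr)

    @property
    def is_mutant(self) -> bool:
        """Binary mutant-vs-wildtype collapse (KEAP1mut and NFE2L2mut pooled)."""
        return self.mutation_status is not MutationStatus.WT


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of samples with panel metadata and optional split."""

    samples: tuple[Sample, ...]
    panel: tuple[str, ...]
    split: Mapping[str, SplitGroup] | None = None

    def __post_init__(self) -> None:
        samples = tuple(self.samples)
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate sample_id(s): {dupes}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "panel", tuple(self.panel))
        if self.split is not None:
            split = {str(k): SplitGroup(v) for k, v in self.split.items()}
            unknown = set(split) - set(ids)
            if unknown:
                raise CohortValidationError(
                    f"split refers to unknown sample_id(s): {sorted(unknown)}"
                )
            object.__setattr__(self, "split", split)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[Sample]:
        return iter(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def histology_counts(self) -> dict[str, int]:
        counts = {h.value: 0 for h in Histology}
        for s in self.samples:
            counts[s.histology.value] += 1
        return counts

    def subset(
        self,
        histology: Histology | str | None = None,
        split_group: SplitGroup | str | None = None,
    ) -> "Cohort":
        """Samples matching all given filters; no filters returns an
        identical cohort (split entries restricted to retained samples)."""
        histology = Histology(histology) if histology is not None else None
        split_group = SplitGroup(split_group) if split_group is not None else None
        kept = []
        for s in self.samples:
            if histology is not None and s.histology is not histology:
                continue
            if split_group is not None:
                if self.split is None or self.split.get(s.sample_id) is not split_group:
                    continue
            kept.append(s)
        split = None
        if self.split is not None:
            ids = {s.sample_id for s in kept}
            split = {k: v for k, v in self.split.items() if k in ids}
        return Cohort(samples=tuple(kept), panel=self.panel, split=split)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row: dict = {
                "sample_id": s.sample_id,
                "histology": s.histology.value,
                "mutation_status": s.mutation_status.value,
                "h_score": s.h_score,
                "k1n2_score": s.k1n2_score,
                "k1n2_call": None if s.k1n2_call is None else int(s.k1n2_call),
                "pathway_active_truth": (
                    None if s.pathway_active_truth is None else int(s.pathway_active_truth)
                ),
            }
            for gene in self.panel:
                row[gene] = s.expression.get(gene)
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(RESERVED_COLUMNS) + list(self.panel))
        df["h_score"] = df["h_score"].astype("Int64")
        df["k1n2_call"] = df["k1n2_call"].astype("Int64")
        df["pathway_active_truth"] = df["pathway_active_truth"].astype("Int64")
        return df


def _parse_optional_bool(value, row_label: str, column: str) -> bool | None:
    if pd.isna(value):
        return None
    if value in (0, 1, "0", "1", True, False):
        return bool(int(value))
    if str(value).strip().lower() in ("true", "false"):
        return str(value).strip().lower() == "true"
    raise CohortValidationError(f"row {row_label}: bad boolean {value!r} in {column}")


def cohort_from_dataframe(df: pd.DataFrame, panel: Sequence[str] | None = None) -> Cohort:
    """Build a validated cohort from a tidy sample table."""
    missing = [c for c in ("sample_id", "histology", "mutation_status") if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required column(s): {missing}")
    if panel is None:
        panel = [c for c in df.columns if c not in RESERVED_COLUMNS]
    samples = []
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        try:
            histology = Histology(str(row["histology"]))
        except ValueError:
            raise CohortValidationError(
                f"row {sid!r}: bad histology {row['histology']!r} "
                f"(expected LUAD or LUSC)"
            ) from None
        try:
            mstatus = MutationStatus(str(row["mutation_status"]))
        except ValueError:
            raise CohortValidationError(
                f"row {sid!r}: bad mutation_status {row['mutation_status']!r}"
            ) from None
        expression = {
            g: float(row[g]) for g in panel if g in row.index and not pd.isna(row[g])
        }
        h = row.get("h_score")
        if h is not None and not pd.isna(h):
            if float(h) != int(float(h)):
                raise CohortValidationError(
                    f"row {sid!r}: h_score must be an integer, got {h!r}"
                )
            h = int(float(h))
        else:
            h = None
        k_score = row.get("k1n2_score")
        k_score = None if k_score is None or pd.isna(k_score) else float(k_score)
        samples.append(
            Sample(
                sample_id=sid,
                histology=histology,
                mutation_status=mstatus,
                expression=expression,
                h_score=h,
                k1n2_score=k_score,
                k1n2_call=_parse_optional_bool(row.get("k1n2_call"), sid, "k1n2_call"),
                pathway_active_truth=_parse_optional_bool(
                    row.get("pathway_active_truth"), sid, "pathway_active_truth"
                ),
            )
        )
    return Cohort(samples=tuple(samples), panel=tuple(panel))


def read_cohort(
    path: str | Path,
    delimiter: str = "\t",
    panel: Sequence[str] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> Cohort:
    """Read a cohort from a delimited text file (TSV by default).

    ``column_map`` renames file columns to the canonical names before
    parsing (e.g. ``{"id": "sample_id"}``).  ``panel`` restricts which
    columns are treated as panel genes; by default every non-reserved column
    is a gene.  Missing optional cells become absent fields, never zero.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={"sample_id": str},
                     float_precision="round_trip")
    if column_map:
        df = df.rename(columns=dict(column_map))
    return cohort_from_dataframe(df, panel=panel)


def write_cohort(cohort: Cohort, path: str | Path, delimiter: str = "\t") -> None:
    """Write a cohort re-readable by :func:`read_cohort`.

    Missing optional fields are written as empty cells (missingness is
    preserved through a round trip)."""
    df = cohort.to_dataframe()
    df.to_csv(path, sep=delimiter, index=False)


def read_split_assignment(path: str | Path, delimiter: str = "\t") -> dict[str, SplitGroup]:
    """Read a two-column sample_id/group assignment file."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise CohortValidationError(
            f"split-assignment file must have columns sample_id, group; "
            f"got {list(df.columns)}"
        )
    out = {}
    for _, row in df.iterrows():
        try:
            out[str(row["sample_id"])] = SplitGroup(row["group"])
        except ValueError:
            raise CohortValidationError(
                f"row {row['sample_id']!r}: bad split group {row['group']!r}"
            ) from None
    return out


def with_split(cohort: Cohort, assignment: Mapping[str, SplitGroup | str]) -> Cohort:
    """Attach an explicit split assignment (validated against sample ids)."""
    return replace(cohort, split={k: SplitGroup(v) for k, v in assignment.items()})


def _stratum_key(sample: Sample, strata: Sequence[str]) -> tuple:
    key = []
    for name in strata:
        if name == "histology":
            key.append(sample.histology.value)
        elif name in ("mutation", "mutation_status"):
            key.append("mutant" if sample.is_mutant else "WT")
        else:
            raise ValueError(f"unknown stratification field {name!r}")
    return tuple(key)


def split_cohort(
    cohort: Cohort,
    validation_fraction: float = 0.31,
    strata: Sequence[str] = ("histology", "mutation"),
    seed: int | None = None,
) -> Cohort:
    """Seeded stratified use/validation split.

    Within each stratum (default histology × mutant-vs-WT),
    ``round(stratum size × validation_fraction)`` samples go to validation
    and the rest to "use".  The default fraction 0.31 reproduces a
    108-of-348 validation share.  Identical seeds give identical splits.
    """
    if not 0 < validation_fraction < 1:
        raise ValueError("validation_fraction must be in (0, 1)")
    groups: dict[tuple, list[str]] = {}
    for s in cohort.samples:
        groups.setdefault(_stratum_key(s, strata), []).append(s.sample_id)
    for key, ids in groups.items():
        if len(ids) < 2:
            raise CohortValidationError(
                f"stratum {key} has {len(ids)} sample(s); at least 2 required"
            )
    rng = np.random.default_rng(seed)
    split: dict[str, SplitGroup] = {}
    for key in sorted(groups):
        ids = groups[key]
        n_val = int(math.floor(len(ids) * validation_fraction + 0.5))
        n_val = min(n_val, len(ids))  # degenerate fractions still partition
        chosen = set(rng.permutation(ids)[:n_val].tolist())
        for sid in ids:
            split[sid] = SplitGroup.validation if sid in chosen else SplitGroup.use
    return replace(cohort, split=split)
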