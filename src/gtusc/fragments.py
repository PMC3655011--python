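"""Physicochemical filtering and summarising of fragment libraries.

A fragment-based screening library is narrowed by Lipinski-style range
filters on vendor-supplied descriptors: molecular weight 200–500 Da,
logP −5 to 2, molar refractivity 40–130 m³·mol⁻¹, total atom count 20–70,
and polar surface area at most 200 Å². All bounds are inclusive.

Descriptors are *inputs* — this module filters property tables (CSV rows
or SDF property tags); it does not predict logP, PSA or solubility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, MissingDescriptorError

__all__ = [
    "FragmentRecord",
    "FilterSpec",
    "FilterResult",
    "FilterReport",
    "PropertySummary",
    "apply_filter",
    "filter_library",
    "property_summary",
    "read_property_csv",
    "write_property_csv",
    "read_sdf",
    "DEFAULT_FILTER",
]

#: descriptor columns of a property table, in canonical order
PROPERTY_FIELDS = ["MW", "logP", "logS", "MR", "n_atoms", "HAC", "nHA",
                   "NR", "HD", "HA", "PSA"]


@dataclass(frozen=True)
class FragmentRecord:
    """Per-compound physicochemical descriptors.

    MW in Da; PSA in Å²; MR in m³·mol⁻¹; n_atoms counts every atom
    including hydrogens while HAC is the heavy-atom count; nHA counts
    hetero-atoms; NR rings; HD/HA hydrogen-bond donors/acceptors.
    """

    compound_id: str
    MW: float
    logP: float
    logS: float
    MR: float
    n_atoms: int
    HAC: int
    nHA: int
    NR: int
    HD: int
    HA: int
    PSA: float

    def __post_init__(self) -> None:
        if self.MW is not None and not math.isnan(self.MW) and self.MW <= 0:
            raise ValueError(f"{self.compound_id}: MW must be positive")
        for name in ("n_atoms", "HAC", "nHA", "NR", "HD", "HA"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{self.compound_id}: {name} must be >= 0")

    def get(self, prop: str) -> float:
        if not hasattr(self, prop):
            raise MissingDescriptorError(f"{self.compound_id}: no descriptor {prop!r}")
        v = getattr(self, prop)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise MissingDescriptorError(
                f"{self.compound_id}: descriptor {prop!r} is missing"
            )
        return v


@dataclass(frozen=True)
class FilterSpec:
    """Inclusive per-property ranges a passing fragment must satisfy."""

    ranges: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for prop, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"{prop}: lower bound {lo} > upper bound {hi}")

    @classmethod
    def default(cls) -> "FilterSpec":
        return cls(ranges={
            "MW": (200.0, 500.0),
            "logP": (-5.0, 2.0),
            "MR": (40.0, 130.0),
            "n_atoms": (20, 70),
            "PSA": (-math.inf, 200.0),
        })

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterSpec":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        ranges = {}
        for prop, bounds in raw.items():
            lo = -math.inf if bounds[0] is None else float(bounds[0])
            hi = math.inf if bounds[1] is None else float(bounds[1])
            ranges[prop] = (lo, hi)
        return cls(ranges=ranges)


DEFAULT_FILTER = FilterSpec.default()


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    violations: tuple[str, ...]


@dataclass
class FilterReport:
    n_input: int
    n_pass: int
    n_fail: int
    violation_counts: dict[str, int]


@dataclass
class PropertySummary:
    means: dict[str, float]
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]  # (counts, bin edges)
    n_records: int
    n_bins: int


def apply_filter(record: FragmentRecord,
                 spec: FilterSpec = DEFAULT_FILTER) -> FilterResult:
    """Check one record against every range; bounds are inclusive.

    Raises :class:`MissingDescriptorError` (naming the property) when the
    record lacks a descriptor the spec references.
    """
    violations = []
    for prop in spec.ranges:
        lo, hi = spec.ranges[prop]
        v = record.get(prop)
        if not (lo <= v <= hi):
            violations.append(prop)
    return FilterResult(passed=not violations, violations=tuple(violations))


def filter_library(
    table: Sequence[FragmentRecord],
    spec: FilterSpec = DEFAULT_FILTER,
) -> tuple[list[FragmentRecord], FilterReport]:
    """Subset of records passing every range, original order preserved."""
    passed: list[FragmentRecord] = []
    violation_counts: dict[str, int] = {p: 0 for p in spec.ranges}
    for rec in table:
        res = apply_filter(rec, spec)
        if res.passed:
            passed.append(rec)
        else:
            for prop in res.violations:
                violation_counts[prop] += 1
    report = FilterReport(
        n_input=len(table), n_pass=len(passed),
        n_fail=len(table) - len(passed),
        violation_counts=violation_counts,
    )
    return passed, report


def property_summary(table: Sequence[FragmentRecord],
                     n_bins: int = 10) -> PropertySummary:
    """Arithmetic means and fixed-width histograms per descriptor.

    Histograms use ``n_bins`` equal-width bins over the observed range of
    each property (a single occupied bin when the property is constant).
    """
    if not table:
        raise EmptyInputError("property table is empty")
    means: dict[str, float] = {}
    hists: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for prop in PROPERTY_FIELDS:
        values = np.array([rec.get(prop) for rec in table], dtype=float)
        means[prop] = float(values.mean())
        lo, hi = float(values.min()), float(values.max())
        if lo == hi:
            hi = lo + 1.0
        counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
        hists[prop] = (counts, edges)
    return PropertySummary(means=means, histograms=hists,
                           n_records=len(table), n_bins=n_bins)


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def _record_from_row(row: Mapping) -> FragmentRecord:
    def num(key, cast=float):
        v = row.get(key)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return math.nan if cast is float else None
        return cast(v)

    return FragmentRecord(
        compound_id=str(row["compound_id"]),
        MW=num("MW"), logP=num("logP"), logS=num("logS"), MR=num("MR"),
        n_atoms=num("n_atoms", int), HAC=num("HAC", int), nHA=num("nHA", int),
        NR=num("NR", int), HD=num("HD", int), HA=num("HA", int),
        PSA=num("PSA"),
    )


def read_property_csv(path: str | Path) -> list[FragmentRecord]:
    """Read a property table: one row per compound, header = descriptor names."""
    df = pd.read_csv(path)
    if "compound_id" not in df.columns:
        raise MissingDescriptorError("property CSV lacks a 'compound_id' column")
    return [_record_from_row(row) for row in df.to_dict(orient="records")]


def to_dataframe(table: Iterable[FragmentRecord]) -> pd.DataFrame:
    cols = [f.name for f in dc_fields(FragmentRecord)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in table],
                        columns=cols)


def write_property_csv(table: Iterable[FragmentRecord], path: str | Path) -> None:
    to_dataframe(table).to_csv(path, index=False)


def read_sdf(path: str | Path) -> list[FragmentRecord]:
    """Read fragments from an SDF whose property tags carry the descriptors.

    Tag names must match the descriptor names (``MW``, ``logP``, ...);
    the molecule title (or a ``compound_id`` tag) identifies the compound.
    """
    from rdkit import Chem

    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        props = mol.GetPropsAsDict()
        cid = props.get("compound_id") or (mol.GetProp("_Name")
                                           if mol.HasProp("_Name") else f"mol{i}")
        props["compound_id"] = cid
        records.append(_record_from_row(props))
    if not records:
        raise EmptyInputError(f"{path}: no molecules found")
    return records
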