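"""Arm-level datasets and the treatment networks they induce.

A subgroup dataset is a collection of randomized studies, each contributing
two or more arms.  Every arm carries the observed mean outcome (a change
score or endpoint on some instrument scale), the arm standard deviation and
the number of randomized participants.  Networks are built by connecting
every pair of treatments that co-occur within a study.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from itertools import combinations
from statistics import median
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ArmRecord",
    "Study",
    "SubgroupDataset",
    "TreatmentNetwork",
    "NetworkSummary",
    "SchemaError",
    "ValidationError",
    "DEFAULT_DIALECT",
    "read_arm_table",
    "write_arm_table",
    "build_network",
    "network_descriptives",
    "common_treatments",
    "flag_nct_studies",
]

#: Default column names for delimited arm-level tables.
DEFAULT_DIALECT: dict[str, str] = {
    "study": "study",
    "subgroup": "subgroup",
    "treatment": "treatment",
    "n": "n",
    "mean": "mean",
    "sd": "sd",
    "year": "year",
    "rob": "rob",
    "scale": "scale",
}

_ROB_LEVELS = {"low", "some", "high"}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row violates an arm- or study-level invariant."""


def _canon(label: str) -> str:
    """Canonical treatment label: trimmed, internal whitespace collapsed."""
    return " ".join(str(label).split())


def _key(label: str) -> str:
    """Case-insensitive matching key for treatment labels."""
    return _canon(label).casefold()


@dataclass(frozen=True)
class ArmRecord:
    """One randomized arm: treatment, size, observed mean and SD."""

    study_id: str
    treatment: str
    n: int
    mean: float
    sd: float
    scale_name: str | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(
                f"study {self.study_id!r}, arm {self.treatment!r}: n must be >= 1, got {self.n}"
            )
        if not (self.sd > 0):
            raise ValidationError(
                f"study {self.study_id!r}, arm {self.treatment!r}: sd must be > 0, got {self.sd}"
            )
        if not math.isfinite(self.mean):
            raise ValidationError(
                f"study {self.study_id!r}, arm {self.treatment!r}: mean must be finite"
            )


@dataclass(frozen=True)
class Study:
    """A multi-arm study; arm ``k = 1`` is the study-specific baseline."""

    study_id: str
    subgroup: str
    arms: tuple[ArmRecord, ...]
    year: int | None = None
    rob: str | None = None

    def __post_init__(self) -> None:
        if len(self.arms) < 2:
            raise ValidationError(
                f"study {self.study_id!r}: needs >= 2 arms, got {len(self.arms)}"
            )
        keys = [_key(a.treatment) for a in self.arms]
        if len(set(keys)) != len(keys):
            raise ValidationError(
                f"study {self.study_id!r}: duplicate treatment within study"
            )
        scales = {a.scale_name for a in self.arms if a.scale_name is not None}
        if len(scales) > 1:
            raise ValidationError(
                f"study {self.study_id!r}: arms use different scales {sorted(scales)}"
            )
        if self.rob is not None and self.rob not in _ROB_LEVELS:
            raise ValidationError(
                f"study {self.study_id!r}: rob must be one of {sorted(_ROB_LEVELS)}, got {self.rob!r}"
            )

    @property
    def n_arms(self) -> int:
        return len(self.arms)

    @property
    def treatments(self) -> tuple[str, ...]:
        return tuple(a.treatment for a in self.arms)

    @property
    def total_n(self) -> int:
        return sum(a.n for a in self.arms)

    def rebaseline(self, treatment: str) -> "Study":
        """Return a copy with ``treatment`` moved to the baseline position."""
        k = _key(treatment)
        idx = next((i for i, a in enumerate(self.arms) if _key(a.treatment) == k), None)
        if idx is None:
            raise ValidationError(
                f"study {self.study_id!r}: cannot re-baseline to absent treatment {treatment!r}"
            )
        arms = (self.arms[idx],) + self.arms[:idx] + self.arms[idx + 1:]
        return replace(self, arms=arms)


@dataclass(frozen=True)
class SubgroupDataset:
    """All studies informing one population subgroup."""

    subgroup: str
    studies: tuple[Study, ...]

    def __post_init__(self) -> None:
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate study ids: {dupes}")
        for s in self.studies:
            if s.subgroup != self.subgroup:
                raise ValidationError(
                    f"study {s.study_id!r} carries subgroup {s.subgroup!r}, "
                    f"dataset is {self.subgroup!r}"
                )

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    def treatments(self) -> list[str]:
        """Distinct treatment labels, sorted, case-insensitive uniqueness."""
        seen: dict[str, str] = {}
        for s in self.studies:
            for a in s.arms:
                seen.setdefault(_key(a.treatment), a.treatment)
        return sorted(seen.values())

    def study(self, study_id: str) -> Study:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(study_id)

    def subset(self, study_ids: Iterable[str]) -> "SubgroupDataset":
        keep = set(study_ids)
        return SubgroupDataset(
            self.subgroup, tuple(s for s in self.studies if s.study_id in keep)
        )


@dataclass(frozen=True)
class TreatmentNetwork:
    """Treatments as nodes; an edge per pair compared within some study."""

    nodes: tuple[str, ...]
    edges: Mapping[frozenset, tuple[str, ...]]  # unordered pair -> study ids
    reference: str

    @property
    def n_direct(self) -> int:
        return sum(1 for v in self.edges.values() if len(v) >= 1)


@dataclass(frozen=True)
class NetworkSummary:
    n_studies: int
    n_treatments: int
    n_direct: int
    n_possible: int
    median_sample_size: float
    studies_per_edge: dict[str, int]
    year_span: tuple[int, int] | None = None
    mean_years_per_study: float | None = None

    def to_json(self) -> str:
        d = dict(self.__dict__)
        if d["year_span"] is not None:
            d["year_span"] = list(d["year_span"])
        return json.dumps(d, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# reading / writing


def _optional(row: Mapping, col: str | None):
    if col is None or col not in row:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return v


def read_arm_table(
    path,
    dialect: Mapping[str, str] | None = None,
    *,
    subgroup: str | None = None,
    sep: str = ",",
    rebaseline_to: str | None = None,
) -> SubgroupDataset:
    """Read a delimited arm-level table into a validated dataset.

    Parameters
    ----------
    path:
        CSV file, one row per arm.  Required columns (under the dialect's
        names): study, treatment, n, mean, sd.  Optional: subgroup, year,
        rob, scale.
    dialect:
        Overrides for the default column names.
    subgroup:
        Subgroup label to use when the table has no subgroup column (or to
        select one subgroup from a mixed table).
    rebaseline_to:
        If given, every study containing this treatment is re-baselined so
        that it occupies arm 1; other studies keep file order.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    required = ["study", "treatment", "n", "mean", "sd"]
    missing = [cols[c] for c in required if cols[c] not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    has_subgroup = cols["subgroup"] in df.columns
    if subgroup is not None and has_subgroup:
        df = df[df[cols["subgroup"]].astype(str).str.strip() == subgroup]

    studies: list[Study] = []
    label_map: dict[str, str] = {}  # casefold key -> first-seen spelling
    for sid, g in df.groupby(cols["study"], sort=False):
        arms = []
        for _, row in g.iterrows():
            label = _canon(row[cols["treatment"]])
            label = label_map.setdefault(_key(label), label)
            arms.append(
                ArmRecord(
                    study_id=str(sid),
                    treatment=label,
                    n=int(row[cols["n"]]),
                    mean=float(row[cols["mean"]]),
                    sd=float(row[cols["sd"]]),
                    scale_name=_optional(row, cols.get("scale")),
                )
            )
        year = _optional(g.iloc[0], cols.get("year"))
        rob = _optional(g.iloc[0], cols.get("rob"))
        sg = subgroup
        if sg is None:
            sg = str(g.iloc[0][cols["subgroup"]]).strip() if has_subgroup else "P1"
        study = Study(
            study_id=str(sid),
            subgroup=sg,
            arms=tuple(arms),
            year=int(year) if year is not None else None,
            rob=str(rob).strip().lower() if rob is not None else None,
        )
        if rebaseline_to is not None and _key(rebaseline_to) in {
            _key(a.treatment) for a in study.arms
        }:
            study = study.rebaseline(rebaseline_to)
        studies.append(study)
    if not studies:
        raise ValidationError(f"no rows read from {path}")
    sg = subgroup if subgroup is not None else studies[0].subgroup
    return SubgroupDataset(subgroup=sg, studies=tuple(studies))


def write_arm_table(ds: SubgroupDataset, path, sep: str = ",") -> None:
    """Write a dataset back to the standard CSV dialect (round-trip safe)."""
    rows = []
    for s in ds.studies:
        for a in s.arms:
            rows.append(
                {
                    "study": s.study_id,
                    "subgroup": s.subgroup,
                    "treatment": a.treatment,
                    "n": a.n,
                    "mean": a.mean,
                    "sd": a.sd,
                    "year": s.year if s.year is not None else "",
                    "rob": s.rob if s.rob is not None else "",
                    "scale": a.scale_name if a.scale_name is not None else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# networks


def build_network(
    ds: SubgroupDataset,
    reference: str,
    *,
    allow_disconnected_reference: bool = False,
) -> TreatmentNetwork:
    """Enumerate the direct-comparison edges induced by a dataset."""
    if ds.n_studies == 0:
        raise ValidationError("cannot build a network from an empty dataset")
    nodes = ds.treatments()
    node_keys = {_key(t): t for t in nodes}
    rk = _key(reference)
    if rk not in node_keys:
        if not allow_disconnected_reference:
            raise ValidationError(
                f"reference {reference!r} appears in no study; pass "
                "allow_disconnected_reference=True to accept"
            )
        nodes = sorted(nodes + [_canon(reference)])
        node_keys[rk] = _canon(reference)
    edges: dict[frozenset, list[str]] = {}
    for s in ds.studies:
        for a, b in combinations(s.treatments, 2):
            pair = frozenset((_key(a), _key(b)))
            edges.setdefault(pair, []).append(s.study_id)
    named = {
        frozenset(node_keys[k] for k in pair): tuple(sids)
        for pair, sids in edges.items()
    }
    return TreatmentNetwork(
        nodes=tuple(nodes), edges=named, reference=node_keys[rk]
    )


def network_descriptives(net: TreatmentNetwork, ds: SubgroupDataset) -> NetworkSummary:
    """Descriptive counts: edges, sample sizes, trial-production pace."""
    t = len(net.nodes)
    n_possible = t * (t - 1) // 2
    med = float(median(s.total_n for s in ds.studies))
    per_edge = {
        " vs ".join(sorted(pair)): len(sids) for pair, sids in net.edges.items()
    }
    years = [s.year for s in ds.studies if s.year is not None]
    span = (min(years), max(years)) if years else None
    mean_years = (
        (span[1] - span[0]) / ds.n_studies if span is not None else None
    )
    return NetworkSummary(
        n_studies=ds.n_studies,
        n_treatments=t,
        n_direct=net.n_direct,
        n_possible=n_possible,
        median_sample_size=med,
        studies_per_edge=per_edge,
        year_span=span,
        mean_years_per_study=mean_years,
    )


def common_treatments(
    net1: TreatmentNetwork, net2: TreatmentNetwork
) -> tuple[list[str], list[str]]:
    """All treatments ``T_a`` and the bridge set ``T_c`` of both networks.

    Returns ``(T_a, T_c)`` as sorted label lists; matching is
    case-insensitive, spellings from the first network win.
    """
    k1 = {_key(t): t for t in net1.nodes}
    k2 = {_key(t): t for t in net2.nodes}
    union = dict(k2)
    union.update(k1)
    t_a = sorted(union.values())
    t_c = sorted(k1[k] for k in k1 if k in k2)
    if not t_c:
        raise ValidationError("no bridge treatments; information sharing impossible")
    return t_a, t_c


def flag_nct_studies(dense: SubgroupDataset, t_c: Sequence[str]) -> set[str]:
    """Studies in the dense subgroup with >= 1 non-common-treatment arm.

    These are the studies downweighted under the NCT scheme: they evaluate
    at least one treatment never studied in the target subgroup.
    """
    ck = {_key(t) for t in t_c}
    return {
        s.study_id
        for s in dense.studies
        if any(_key(a.treatment) not in ck for a in s.arms)
    }


def export_edge_list(net: TreatmentNetwork, path) -> None:
    """Network edge list as CSV (treat1, treat2, n_studies, study_ids)."""
    rows = []
    for pair, sids in sorted(net.edges.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(pair)
        rows.append(
            {"treat1": a, "treat2": b, "n_studies": len(sids), "study_ids": ";".join(sids)}
        )
    pd.DataFrame(rows).to_csv(path, index=False)
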