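"""Single-cell pedigree data model, I/O, validation and kinship extraction.

A lifetime table has one row per tracked cell: its identifier, its
parent's identifier (absent for founders), absolute birth and end times in
hours from experiment start, a fate label, the generation number and any
covariate columns (treatment flags, fluorescence intensities, reporter
status).  ``lost`` and ``end_of_observation`` are both right-censoring
fates.  Division is binary: a cell has at most two children.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sample import CRSample

__all__ = [
    "CENSORING_FATES",
    "CellRecord",
    "PedigreeForest",
    "DialectConfig",
    "KinPairSet",
    "ConversionReport",
    "read_lifetime_table",
    "write_lifetime_table",
    "validate_pedigree",
    "extract_kin_pairs",
    "to_cr_sample",
    "tabulate_fates",
    "data_usage",
]

#: the two fixed right-censoring fate labels; all other labels are events
CENSORING_FATES = frozenset({"lost", "end_of_observation"})

RELATIONS = ("sibling", "mother_daughter", "cousin1", "cousin2")


@dataclass
class CellRecord:
    """One tracked cell.

    ``birth_time`` may be ``None`` for founders already present at the
    start of observation; ``end_time`` is when the fate was recorded.
    Fate labels are an open vocabulary: ``division``, ``death``, the two
    censoring labels, plus user-defined events (e.g. differentiation
    onset).
    """

    cell_id: str
    parent_id: str | None
    pedigree_id: str
    birth_time: float | None
    end_time: float
    fate: str
    generation: int
    covariates: dict = field(default_factory=dict)

    @property
    def is_founder(self) -> bool:
        return self.parent_id is None

    @property
    def is_censored(self) -> bool:
        return self.fate in CENSORING_FATES

    @property
    def lifetime(self) -> float | None:
        if self.birth_time is None:
            return None
        return self.end_time - self.birth_time


class PedigreeForest:
    """A forest of lineage trees, one per founder, indexed by cell id."""

    def __init__(self, records: Iterable[CellRecord],
                 metadata: Mapping[str, Mapping] | None = None):
        self._cells: dict[str, CellRecord] = {}
        for rec in records:
            if rec.cell_id in self._cells:
                raise ValueError(f"duplicate cell_id: {rec.cell_id!r}")
            self._cells[rec.cell_id] = rec
        dangling = [
            r.cell_id for r in self._cells.values()
            if r.parent_id is not None and r.parent_id not in self._cells
        ]
        if dangling:
            raise ValueError(
                "dangling parent_id for cells: " + ", ".join(map(repr, dangling))
            )
        self._children: dict[str, list[str]] = {cid: [] for cid in self._cells}
        for rec in self._cells.values():
            if rec.parent_id is not None:
                self._children[rec.parent_id].append(rec.cell_id)
        #: per-pedigree metadata such as condition / well labels
        self.metadata = dict(metadata or {})

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self._cells)

    def __iter__(self):
        return iter(self._cells.values())

    def __contains__(self, cell_id: str) -> bool:
        return cell_id in self._cells

    def __getitem__(self, cell_id: str) -> CellRecord:
        return self._cells[cell_id]

    @property
    def founders(self) -> list[CellRecord]:
        return [r for r in self._cells.values() if r.is_founder]

    @property
    def n_pedigrees(self) -> int:
        return len({r.pedigree_id for r in self._cells.values()})

    def children(self, cell_id: str) -> list[CellRecord]:
        return [self._cells[c] for c in self._children[cell_id]]

    def ancestor(self, cell_id: str, depth: int) -> CellRecord | None:
        """The ancestor ``depth`` generations up, or None if the lineage
        is shorter."""
        rec = self._cells[cell_id]
        for _ in range(depth):
            if rec.parent_id is None:
                return None
            rec = self._cells[rec.parent_id]
        return rec

    def covariate_names(self) -> list[str]:
        names: list[str] = []
        for rec in self._cells.values():
            for k in rec.covariates:
                if k not in names:
                    names.append(k)
        return names

    def to_frame(self) -> pd.DataFrame:
        cov_names = self.covariate_names()
        rows = []
        for rec in self._cells.values():
            row = {
                "cell_id": rec.cell_id,
                "parent_id": rec.parent_id,
                "pedigree_id": rec.pedigree_id,
                "birth_time": rec.birth_time,
                "end_time": rec.end_time,
                "fate": rec.fate,
                "generation": rec.generation,
            }
            for k in cov_names:
                row[k] = rec.covariates.get(k)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class DialectConfig:
    """Column mapping and parsing conventions for lifetime tables."""

    columns: dict = field(default_factory=dict)  # canonical -> file column
    fate_map: dict = field(default_factory=dict)  # file label -> canonical label
    na_token: str = "NA"
    sep: str | None = None  # None = auto-detect comma/tab
    time_scale: float = 1.0  # multiply file times by this to get hours

    def column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


_CANONICAL = ("cell_id", "parent_id", "pedigree_id", "birth_time",
              "end_time", "fate", "generation")


def read_lifetime_table(
    source, dialect: DialectConfig | None = None
) -> tuple[PedigreeForest, dict]:
    """Read a delimited lifetime table into a :class:`PedigreeForest`.

    Returns ``(forest, report)`` where the report records rows read and
    rejected.  Unknown fate labels pass through as user-defined events.
    Duplicate cell ids, dangling parent pointers and non-numeric times
    are hard errors.
    """
    dialect = dialect or DialectConfig()
    sep = dialect.sep
    if sep is None:
        if hasattr(source, "read"):
            text = source.read()
            source = io.StringIO(text)
            head = text.splitlines()[0] if text else ""
        else:
            with open(source) as fh:
                head = fh.readline()
        sep = "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","
    df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)

    col = dialect.column
    required = ("cell_id", "parent_id", "end_time", "fate")
    missing = [c for c in required if col(c) not in df.columns]
    if missing:
        raise ValueError(f"lifetime table is missing required columns: {missing}")

    def _get(name, default=None):
        c = col(name)
        if c in df.columns:
            return df[c]
        return pd.Series([default] * len(df))

    na = dialect.na_token

    def _num(series, name, allow_missing=False):
        out = []
        for i, v in enumerate(series):
            v = v.strip() if isinstance(v, str) else v
            if v in ("", na, None):
                if allow_missing:
                    out.append(None)
                    continue
                raise ValueError(f"row {i}: missing value in column {name!r}")
            try:
                out.append(float(v) * dialect.time_scale)
            except (TypeError, ValueError):
                raise ValueError(
                    f"row {i}: non-numeric value {v!r} in column {name!r}"
                ) from None
        return out

    cell_ids = _get("cell_id").astype(str)
    parent_ids = [
        None if (isinstance(v, str) and v.strip() in ("", na)) else str(v).strip()
        for v in _get("parent_id")
    ]
    birth = _num(_get("birth_time", ""), "birth_time", allow_missing=True)
    end = _num(_get("end_time"), "end_time")
    fates = [dialect.fate_map.get(str(v).strip(), str(v).strip()) for v in _get("fate")]

    gen_series = _get("generation", None)
    have_gen = col("generation") in df.columns
    ped_series = _get("pedigree_id", None)
    have_ped = col("pedigree_id") in df.columns

    known = {col(c) for c in _CANONICAL}
    cov_cols = [c for c in df.columns if c not in known]

    records = []
    for i in range(len(df)):
        gen = None
        if have_gen:
            g = str(gen_series.iloc[i]).strip()
            if g not in ("", na):
                gen = int(float(g))
        cov = {}
        for c in cov_cols:
            v = str(df[c].iloc[i]).strip()
            if v in ("", na):
                continue
            try:
                cov[c] = float(v)
            except ValueError:
                cov[c] = v
        records.append(
            CellRecord(
                cell_id=str(cell_ids.iloc[i]).strip(),
                parent_id=parent_ids[i],
                pedigree_id=(str(ped_series.iloc[i]).strip()
                             if have_ped else "<unlabelled>"),
                birth_time=birth[i],
                end_time=end[i],
                fate=fates[i],
                generation=gen if gen is not None else -1,
                covariates=cov,
            )
        )

    forest = PedigreeForest(records)
    # fill generations and pedigree ids from topology where absent
    _fill_derived(forest)
    report = {"rows_read": len(df), "rows_rejected": 0, "n_cells": len(forest)}
    return forest, report


def _fill_derived(forest: PedigreeForest) -> None:
    """Derive missing generation numbers (founder = 0) and pedigree ids
    (founder's id) by walking down from the founders."""
    for founder in forest.founders:
        stack = [(founder, 0)]
        ped = (founder.pedigree_id
               if founder.pedigree_id != "<unlabelled>" else founder.cell_id)
        while stack:
            rec, depth = stack.pop()
            if rec.generation < 0:
                rec.generation = depth
            if rec.pedigree_id == "<unlabelled>":
                rec.pedigree_id = ped
            for child in forest.children(rec.cell_id):
                stack.append((child, depth + 1))


def write_lifetime_table(forest: PedigreeForest, path, sep: str = ",",
                         na_token: str = "NA") -> None:
    """Write the canonical column set as delimited text."""
    df = forest.to_frame()
    df.to_csv(path, sep=sep, index=False, na_rep=na_token)


# ----------------------------------------------------------------------
def validate_pedigree(forest: PedigreeForest) -> list[str]:
    """Check structural invariants; returns a list of violations
    (empty iff valid).

    Checked: generation = parent generation + 1; at most two children
    (binary division); children only under cells with fate ``division``;
    ``end_time >= birth_time``; child born when the parent ends.
    Cycles and dangling parents cannot occur in a constructed forest.
    """
    issues: list[str] = []
    for rec in forest:
        kids = forest.children(rec.cell_id)
        if len(kids) > 2:
            issues.append(
                f"cell {rec.cell_id!r} has {len(kids)} children (binary division)"
            )
        if kids and rec.fate != "division":
            issues.append(
                f"cell {rec.cell_id!r} has children but fate {rec.fate!r}"
            )
        if rec.birth_time is not None and rec.end_time < rec.birth_time:
            issues.append(
                f"cell {rec.cell_id!r}: end_time {rec.end_time} < "
                f"birth_time {rec.birth_time}"
            )
        if rec.parent_id is not None:
            parent = forest[rec.parent_id]
            if rec.generation != parent.generation + 1:
                issues.append(
                    f"cell {rec.cell_id!r}: generation {rec.generation} != "
                    f"parent generation {parent.generation} + 1"
                )
            if rec.pedigree_id != parent.pedigree_id:
                issues.append(
                    f"cell {rec.cell_id!r}: pedigree_id differs from parent"
                )
            if (rec.birth_time is not None
                    and abs(rec.birth_time - parent.end_time) > 1e-9):
                issues.append(
                    f"cell {rec.cell_id!r}: birth_time {rec.birth_time} != "
                    f"parent end_time {parent.end_time}"
                )
    return issues


# ----------------------------------------------------------------------
@dataclass
class KinPairSet:
    """Unordered kin pairs of one relation with their cluster ids.

    ``cluster_id`` is the id of the common ancestor defining the cluster
    (the parent for siblings and mother-daughter pairs, the grandparent
    for first cousins, the great-grandparent for second cousins), so a
    four-cell cousin cluster yields cross pairs sharing one cluster id.
    """

    relation: str
    pairs: list[tuple[str, str, str]]

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def extract_kin_pairs(forest: PedigreeForest, relation: str) -> KinPairSet:
    """All cell pairs with exactly the requested kinship relation.

    ``cousin1`` pairs share a grandparent but not a parent; ``cousin2``
    pairs share a great-grandparent but not a grandparent.  Each
    unordered pair appears once; an empty set is allowed.
    """
    if relation not in RELATIONS:
        raise ValueError(f"relation must be one of {RELATIONS}")
    pairs: list[tuple[str, str, str]] = []
    if relation == "mother_daughter":
        for rec in forest:
            for child in forest.children(rec.cell_id):
                pairs.append((rec.cell_id, child.cell_id, rec.cell_id))
        return KinPairSet(relation, pairs)
    if relation == "sibling":
        depth = 1
    elif relation == "cousin1":
        depth = 2
    else:
        depth = 3
    # group cells by their depth-level ancestor, then keep cross pairs
    # whose nearest common ancestor is exactly at that depth
    groups: dict[str, list[str]] = {}
    for rec in forest:
        anc = forest.ancestor(rec.cell_id, depth)
        if anc is not None:
            groups.setdefault(anc.cell_id, []).append(rec.cell_id)
    for anc_id, members in groups.items():
        for a, b in itertools.combinations(sorted(members), 2):
            if depth > 1:
                closer_a = forest.ancestor(a, depth - 1).cell_id
                closer_b = forest.ancestor(b, depth - 1).cell_id
                if closer_a == closer_b:
                    continue  # related more closely than requested
            pairs.append((a, b, anc_id))
    return KinPairSet(relation, pairs)


# ----------------------------------------------------------------------
@dataclass
class ConversionReport:
    n_total: int
    n_included: int
    n_excluded_missing_birth: int
    n_excluded_filtered: int

    @property
    def conserved(self) -> bool:
        return (self.n_included + self.n_excluded_missing_birth
                + self.n_excluded_filtered) == self.n_total


def to_cr_sample(
    forest: PedigreeForest,
    cause_map: Mapping[str, int] | Callable[[CellRecord], int],
    time_origin: str = "cell_birth",
    covariates: Sequence[str] | None = None,
    generation_filter: Callable[[int], bool] | None = None,
) -> tuple[CRSample, ConversionReport]:
    """Flatten a forest into competing-risks observations.

    Parameters
    ----------
    cause_map
        Either a mapping from fate label to cause code (0 = censored;
        every fate present must be mapped — a missing label is a hard
        error), or a callable ``record -> code`` for codings that cross
        fate with a covariate predicate (e.g. reporter-positive vs
        -negative divisions).
    time_origin
        ``"cell_birth"``: time = end_time - birth_time (founders with an
        unknown birth are excluded, counted in the report).
        ``"ancestor_stimulus"``: time = end_time, measured from the start
        of the experiment, i.e. from when the stimulus was received by
        the ancestors; all cells are included.
    generation_filter
        Optional predicate on generation number (e.g. ``lambda g: g == 0``
        or ``lambda g: g > 0``).

    Counts are conserved: included + excluded = total, for every filter.
    """
    if time_origin not in ("cell_birth", "ancestor_stimulus"):
        raise ValueError("time_origin must be 'cell_birth' or 'ancestor_stimulus'")
    if not callable(cause_map):
        mapping = dict(cause_map)

        def code_of(rec: CellRecord) -> int:
            if rec.fate not in mapping:
                raise KeyError(
                    f"fate {rec.fate!r} (cell {rec.cell_id!r}) is absent from cause_map"
                )
            return mapping[rec.fate]
    else:
        code_of = cause_map

    cov_names = list(covariates) if covariates else []
    times, statuses, cov_rows, peds, gens, ids = [], [], [], [], [], []
    kinds = []
    n_missing_birth = n_filtered = 0
    nonpositive: list[str] = []
    for rec in forest:
        if generation_filter is not None and not generation_filter(rec.generation):
            n_filtered += 1
            continue
        if time_origin == "cell_birth":
            if rec.birth_time is None:
                n_missing_birth += 1
                continue
            t = rec.end_time - rec.birth_time
        else:
            t = rec.end_time
        if t <= 0:
            nonpositive.append(rec.cell_id)
            continue
        times.append(t)
        statuses.append(code_of(rec))
        cov_rows.append({k: rec.covariates.get(k) for k in cov_names})
        peds.append(rec.pedigree_id)
        gens.append(rec.generation)
        ids.append(rec.cell_id)
        kinds.append(rec.fate if rec.fate in CENSORING_FATES else "")
    if nonpositive:
        raise ValueError(
            "nonpositive computed time for cells: " + ", ".join(map(repr, nonpositive))
        )
    if not times:
        raise ValueError(
            "no cells remain after filtering "
            f"(total {len(forest)}, filtered out {n_filtered}, "
            f"missing birth {n_missing_birth})"
        )
    cov = pd.DataFrame(cov_rows) if cov_names else None
    sample = CRSample(
        times, statuses, cov,
        pedigree=peds, generation=gens, ids=ids, censor_kind=kinds,
        cause_map=None if callable(cause_map) else mapping,
    )
    report = ConversionReport(len(forest), len(times), n_missing_birth, n_filtered)
    return sample, report


# ----------------------------------------------------------------------
def tabulate_fates(
    data: PedigreeForest | CRSample | pd.DataFrame,
    group_by: str | Sequence[str] | None = None,
) -> pd.DataFrame:
    """Counts and proportions per fate (or status code) per group.

    Source for fate-distribution pie charts.  Empty groups yield zero
    counts without division-by-zero.
    """
    if isinstance(data, PedigreeForest):
        df = data.to_frame()
        fate_col = "fate"
    elif isinstance(data, CRSample):
        df = data.to_frame()
        fate_col = "status"
    else:
        df = data
        fate_col = "fate" if "fate" in df.columns else "status"
    keys = [group_by] if isinstance(group_by, str) else list(group_by or [])
    counts = (
        df.groupby(keys + [fate_col], dropna=False, observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    if keys:
        totals = counts.groupby(keys, observed=True)["count"].transform("sum")
    else:
        totals = counts["count"].sum()
    counts["proportion"] = np.where(
        np.asarray(totals) > 0, counts["count"] / totals, 0.0
    )
    return counts


_USAGE_METHODS = ("mean_time_ttest", "pearson", "icc", "yules_q",
                  "permutation", "binomial", "cr_analysis")


def data_usage(
    sample: CRSample,
    kin_pairs: KinPairSet | None = None,
    method: str = "cr_analysis",
    cause: int = 1,
) -> dict:
    """Fraction of records a statistical method can actually use.

    Complete-case inclusion rules: correlation methods (``pearson``,
    ``icc``, ``permutation``) use only pairs where both members realised
    the concordant fate of interest; the categorical concordance methods
    (``yules_q``, ``binomial``) use pairs where both fates are known
    (censored-containing pairs excluded); ``mean_time_ttest`` uses the
    records with the realised fate of interest; competing-risks analysis
    uses every record.
    """
    if method not in _USAGE_METHODS:
        raise ValueError(f"method must be one of {_USAGE_METHODS}")
    if method == "cr_analysis":
        denom = len(kin_pairs) if kin_pairs is not None else sample.n
        return {"method": method, "n_used": denom, "n_total": denom,
                "fraction": 1.0 if denom else 0.0}
    if method == "mean_time_ttest":
        used = int(np.sum(sample.status == cause))
        return {"method": method, "n_used": used, "n_total": sample.n,
                "fraction": used / sample.n}
    if kin_pairs is None:
        raise ValueError(f"method {method!r} requires kin pairs")
    if sample.ids is None:
        raise ValueError("sample must carry cell ids to join kin pairs")
    status_of = dict(zip(sample.ids, sample.status))
    total = used = 0
    for a, b, _ in kin_pairs:
        if a not in status_of or b not in status_of:
            continue
        total += 1
        sa, sb = status_of[a], status_of[b]
        if method in ("pearson", "icc", "permutation"):
            if sa == cause and sb == cause:
                used += 1
        else:  # yules_q, binomial: both fates known
            if sa != 0 and sb != 0:
                used += 1
    return {"method": method, "n_used": used, "n_total": total,
            "fraction": used / total if total else 0.0}
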