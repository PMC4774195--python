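"""Two-way, two-reporter yeast-2-hybrid (Y2H) interaction tables.

The auxin signalling network of *Arabidopsis thaliana* was screened by
testing every pair of transcriptional regulators (ARF activators and
repressors, Aux/IAA) in both orientations: each protein fused to the Gal4
DNA-binding domain (bait) and to the activation domain (prey).  Two
reporter genes score each ordered pair: a colorimetric X-Gal test on a
7-level ordinal scale and a growth-based HIS3 test reported as an optical
density ratio (histidine-free over histidine-rich medium).

This module parses, validates and filters such tables and maintains the
protein roster.  Records are held in a :class:`pandas.DataFrame` with
columns ``bait``, ``prey``, ``xgal`` (integer mark code) and ``his3``
(float ratio, ``NaN`` when the test is missing).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MARKS",
    "OrdinalScale",
    "Roster",
    "parse_y2h_table",
    "write_y2h_table",
    "filter_regulators",
    "cohort_accounting",
]

#: The ordered X-Gal marks, weakest to strongest.
DEFAULT_MARKS: tuple[str, ...] = ("-", "-?", "?", "+?", "+", "++", "+++")

_ORIENTATION_PREFIX = re.compile(r"^(AD-|BD-)", re.IGNORECASE)
_MISSING_TOKENS = {"", "na", "nan", "none", "null", "."}


@dataclass(frozen=True)
class OrdinalScale:
    """Ordered mark labels mapped to contiguous integer codes 0..K-1."""

    marks: tuple[str, ...] = DEFAULT_MARKS

    def __post_init__(self) -> None:
        if len(self.marks) == 0:
            raise ValueError("scale needs at least one mark")
        if len(set(self.marks)) != len(self.marks):
            raise ValueError("duplicate mark labels in scale")

    @property
    def n_levels(self) -> int:
        return len(self.marks)

    def code(self, mark: str) -> int:
        """Integer code of ``mark``; raises ``KeyError`` for unknown labels."""
        try:
            return self.marks.index(mark)
        except ValueError:
            raise KeyError(f"unknown mark label {mark!r}; expected one of {self.marks}")

    def label(self, code: int) -> str:
        return self.marks[int(code)]


@dataclass
class Roster:
    """Ordered list of unique protein ids with optional family annotation.

    ``families`` maps protein id to one of ``ARF+``, ``ARF-``, ``AuxIAA``
    (or any user label); it may be empty for synthetic data.
    """

    proteins: list[str]
    families: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.proteins)) != len(self.proteins):
            raise ValueError("protein ids must be unique")

    def __len__(self) -> int:
        return len(self.proteins)

    def __contains__(self, protein: str) -> bool:
        return protein in self.proteins

    def __iter__(self):
        return iter(self.proteins)

    def index(self) -> dict[str, int]:
        """Map protein id -> position, following roster order."""
        return {p: i for i, p in enumerate(self.proteins)}


def _normalize_id(raw: str) -> str:
    """Strip an ``AD-``/``BD-`` orientation prefix from a protein id."""
    return _ORIENTATION_PREFIX.sub("", raw.strip())


def _parse_his3(token) -> float:
    """HIS3 OD ratio from a raw token.

    Accepts plain ratios (``0.45``), percent dialects (``119 %`` -> 1.19)
    and empty/NA tokens (missing).  Negative values are rejected.
    """
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return math.nan
    s = str(token).strip()
    if s.lower() in _MISSING_TOKENS:
        return math.nan
    percent = s.endswith("%")
    if percent:
        s = s[:-1].strip()
    value = float(s)
    if percent:
        value /= 100.0
    if value < 0:
        raise ValueError(f"negative HIS3 ratio {token!r}")
    return value


def parse_y2h_table(path, scale: OrdinalScale | None = None) -> tuple[Roster, pd.DataFrame]:
    """Read a delimited Y2H table into a roster and a record frame.

    The file must have columns ``bait``, ``prey``, ``xgal``, ``his3``
    (case-insensitive; tab or comma delimited; ``#`` comment lines are
    skipped).  Orientation prefixes ``AD-``/``BD-`` on protein ids are
    stripped, HIS3 percentages are converted to the ratio scale, and the
    roster is inferred from the union of ids in order of first appearance.

    Raises
    ------
    KeyError
        for an X-Gal label absent from ``scale`` (the offending row is
        named in the message).
    ValueError
        for a duplicated ordered bait-prey pair.
    """
    scale = scale or OrdinalScale()
    raw = pd.read_csv(path, sep=None, engine="python", comment="#", dtype=str,
                      keep_default_na=False, skipinitialspace=True)
    raw.columns = [c.strip().lower() for c in raw.columns]
    required = {"bait", "prey", "xgal", "his3"}
    if not required.issubset(raw.columns):
        raise ValueError(f"missing columns {sorted(required - set(raw.columns))}")

    proteins: list[str] = []
    seen: set[str] = set()
    pairs: set[tuple[str, str]] = set()
    baits, preys, xgals, his3s = [], [], [], []
    for row_no, row in enumerate(raw.itertuples(index=False), start=2):
        bait = _normalize_id(row.bait)
        prey = _normalize_id(row.prey)
        for p in (bait, prey):
            if p not in seen:
                seen.add(p)
                proteins.append(p)
        if (bait, prey) in pairs:
            raise ValueError(f"duplicate ordered pair ({bait}, {prey}) at line {row_no}")
        pairs.add((bait, prey))
        try:
            code = scale.code(row.xgal.strip())
        except KeyError as exc:
            raise KeyError(f"line {row_no}: {exc.args[0]}") from None
        baits.append(bait)
        preys.append(prey)
        xgals.append(code)
        his3s.append(_parse_his3(row.his3))

    records = pd.DataFrame({
        "bait": baits,
        "prey": preys,
        "xgal": np.asarray(xgals, dtype=int),
        "his3": np.asarray(his3s, dtype=float),
    })
    return Roster(proteins), records


def write_y2h_table(path, records: pd.DataFrame, scale: OrdinalScale | None = None) -> None:
    """Write records back to canonical TSV (marks as labels, full-precision ratios)."""
    scale = scale or OrdinalScale()
    out = records.copy()
    out["xgal"] = [scale.label(c) for c in records["xgal"]]
    out["his3"] = ["" if math.isnan(v) else repr(float(v)) for v in records["his3"]]
    out.to_csv(path, sep="\t", index=False)


def filter_regulators(
    roster: Roster,
    records: pd.DataFrame,
    exclusions: list[str] | set[str],
) -> tuple[Roster, pd.DataFrame]:
    """Drop excluded proteins from the roster and every record touching them.

    In the published study ARF3 and ARF17 were removed for lacking the
    dimerisation domain and ARF11 for showing no interaction in the binary
    network, bringing 49 cloned regulators down to 46.  Exclusion ids not
    present in the roster trigger a warning, not a failure; remaining
    protein order is preserved and the operation is idempotent.
    """
    exclusions = set(exclusions)
    unknown = exclusions - set(roster.proteins)
    if unknown:
        warnings.warn(f"exclusions not in roster (ignored): {sorted(unknown)}",
                      stacklevel=2)
    keep = [p for p in roster.proteins if p not in exclusions]
    keep_set = set(keep)
    families = {p: f for p, f in roster.families.items() if p in keep_set}
    mask = records["bait"].isin(keep_set) & records["prey"].isin(keep_set)
    return Roster(keep, families), records.loc[mask].reset_index(drop=True)


def cohort_accounting(n_regulators: int, n_ways: int = 2, n_replicates: int = 2) -> dict:
    """Test-count bookkeeping for an all-against-all two-way screen.

    For ``n`` regulators there are ``n**2`` ordered bait-prey pairs and
    ``n(n+1)/2`` unordered pairs (self-pairs included); each unordered
    pair is assayed in ``n_ways`` orientations with ``n_replicates``
    biological replicates.  For the 49 cloned regulators of the study this
    gives 2401 ordered pairs, 1225 tested interactions and 4900 test
    results.
    """
    if n_regulators < 1:
        raise ValueError("need at least one regulator")
    n = int(n_regulators)
    unordered = n * (n + 1) // 2
    return {
        "ordered_pairs": n * n,
        "unordered_pairs": unordered,
        "total_tests": unordered * int(n_ways) * int(n_replicates),
    }
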