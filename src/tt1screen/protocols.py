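"""Screening protocols: conjunctions of directional threshold criteria.

A screening protocol is a named set of criteria, each a cut-off value (COV)
on one panel biomarker with a direction (at least / at most).  A record is
screen-positive iff *every* criterion holds; comparisons are inclusive
(>= / <=), as the national programme prints its cut-offs.

The catalogue covers the historical Dutch protocols (tyr >= 500 in 2007,
SA >= 1.5 in 2008, SA >= 1.2 from 2009, both on raw NeoBase SA), the current
protocol (SA >= 0.60 on the NeoBase 2 scale) and the three best-performing
published multi-biomarker alternatives (L, N, O).  Historical protocols
threshold ``sa_raw`` — they were applied to the era's own assay scale —
while the current and alternative protocols threshold the effective
(converted) SA ``sa_eff``.

COV derivation for non-SA biomarkers follows the programme's rule: the
cut-off is anchored to the most extreme value observed among confirmed TT1
patients, moved one granularity step further out as a safety margin, so no
known patient is excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import PANEL_BIOMARKERS, DerivedPanel, ScreenResult

__all__ = [
    "Direction",
    "Criterion",
    "Protocol",
    "UndefinedBiomarkerError",
    "classify",
    "classify_frame",
    "builtin_protocols",
    "derive_cov",
    "enumerate_alternatives",
    "default_alternative_protocols",
    "parse_protocols",
    "format_protocols",
    "CURRENT_SA_CRITERION",
    "DEFAULT_SINGLETON_GRID",
    "DEFAULT_COMBINATION_ADDONS",
]


class Direction(str, Enum):
    AT_LEAST = "ge"
    AT_MOST = "le"


class UndefinedBiomarkerError(ValueError):
    """A criterion referenced a ratio that is undefined (zero denominator)
    for a record, and no other criterion already rejects the record."""


@dataclass(frozen=True)
class Criterion:
    """One directional cut-off: ``value >= cov`` (at_least) or ``<= cov``."""

    biomarker: str
    direction: Direction
    cov: float

    def __post_init__(self) -> None:
        if self.biomarker not in PANEL_BIOMARKERS:
            raise ValueError(f"unknown panel biomarker: {self.biomarker!r}")
        object.__setattr__(self, "direction", Direction(self.direction))
        if not self.cov > 0:
            raise ValueError(f"cut-off must be positive, got {self.cov}")

    def holds(self, value: float) -> bool:
        if math.isnan(value):
            raise UndefinedBiomarkerError(
                f"{self.biomarker} undefined for this record"
            )
        if self.direction is Direction.AT_LEAST:
            return value >= self.cov
        return value <= self.cov

    def __str__(self) -> str:
        op = ">=" if self.direction is Direction.AT_LEAST else "<="
        return f"{self.biomarker} {op} {self.cov:g}"


@dataclass(frozen=True)
class Protocol:
    """A named conjunction of criteria."""

    name: str
    criteria: tuple[Criterion, ...]
    provenance: str = "user"

    def __post_init__(self) -> None:
        object.__setattr__(self, "criteria", tuple(self.criteria))
        if not self.criteria:
            raise ValueError(f"protocol {self.name!r} has no criteria")
        seen = set()
        for c in self.criteria:
            key = (c.biomarker, c.direction)
            if key in seen:
                raise ValueError(
                    f"protocol {self.name!r}: duplicate criterion on "
                    f"{c.biomarker} ({c.direction.value})"
                )
            seen.add(key)
        if self.provenance not in {"historical", "current", "alternative", "user"}:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def key(self) -> frozenset:
        """Identity of the rule set, ignoring the name."""
        return frozenset((c.biomarker, c.direction.value, c.cov) for c in self.criteria)


def classify(panel: DerivedPanel, protocol: Protocol) -> ScreenResult:
    """Screen-positive iff every criterion holds (inclusive comparisons).

    A criterion on an undefined (NaN) ratio is only tolerated when another
    criterion already rejects the record; otherwise it is surfaced as
    :class:`UndefinedBiomarkerError` — a record is never silently negative
    because of a zero denominator.
    """
    undefined = False
    for c in protocol.criteria:
        value = getattr(panel, c.biomarker)
        if isinstance(value, float) and math.isnan(value):
            undefined = True
            continue
        if not c.holds(value):
            return ScreenResult.NEGATIVE
    if undefined:
        raise UndefinedBiomarkerError(
            f"record {panel.record_id}: protocol {protocol.name!r} references "
            "an undefined ratio and no other criterion rejects the record"
        )
    return ScreenResult.POSITIVE


def classify_frame(panel: pd.DataFrame, protocol: Protocol) -> pd.Series:
    """Vectorised :func:`classify`: boolean Series (True = screen-positive).

    Same undefined-ratio semantics as the record-level path: rows where an
    undefined ratio would decide the outcome raise, with offending record ids
    in the message.
    """
    n = len(panel)
    fails = np.zeros(n, dtype=bool)
    undefined = np.zeros(n, dtype=bool)
    for c in protocol.criteria:
        values = panel[c.biomarker].to_numpy(dtype=float)
        nan = np.isnan(values)
        undefined |= nan
        if c.direction is Direction.AT_LEAST:
            fails |= ~nan & (values < c.cov)
        else:
            fails |= ~nan & (values > c.cov)
    blocked = undefined & ~fails
    if blocked.any():
        ids = panel.loc[blocked, "record_id"].head(5).tolist()
        raise UndefinedBiomarkerError(
            f"protocol {protocol.name!r}: undefined ratio decides classification "
            f"for {int(blocked.sum())} record(s), e.g. {ids}"
        )
    return pd.Series(~fails, index=panel.index, name=protocol.name)


# ---------------------------------------------------------------------------
# Builtin catalogue

CURRENT_SA_CRITERION = Criterion("sa_eff", Direction.AT_LEAST, 0.60)

_TYR100 = Criterion("tyr", Direction.AT_LEAST, 100)
_PROD100 = Criterion("tyr_times_sa", Direction.AT_LEAST, 100)
_PROD110 = Criterion("tyr_times_sa", Direction.AT_LEAST, 110)
_TYRPHE25 = Criterion("tyr_over_phe", Direction.AT_LEAST, 2.5)
_PHETYR05 = Criterion("phe_over_tyr", Direction.AT_MOST, 0.5)


def builtin_protocols() -> dict[str, Protocol]:
    """Catalogue of the historical, current and best published alternative
    protocols, keyed by name."""
    protos = [
        Protocol("tyr500_2007", (Criterion("tyr", Direction.AT_LEAST, 500),), "historical"),
        Protocol("sa15_2008", (Criterion("sa_raw", Direction.AT_LEAST, 1.5),), "historical"),
        Protocol("sa12_2009", (Criterion("sa_raw", Direction.AT_LEAST, 1.2),), "historical"),
        Protocol("sa060_current", (CURRENT_SA_CRITERION,), "current"),
        Protocol("alt_L", (CURRENT_SA_CRITERION, _TYR100, _PROD100, _TYRPHE25), "alternative"),
        Protocol("alt_N", (CURRENT_SA_CRITERION, _TYR100, _PROD110, _PHETYR05), "alternative"),
        Protocol("alt_O", (CURRENT_SA_CRITERION, _TYR100, _PROD110, _TYRPHE25), "alternative"),
    ]
    return {p.name: p for p in protos}


# ---------------------------------------------------------------------------
# COV derivation

def derive_cov(
    tp_values: Sequence[float],
    direction: Direction,
    granularity: float,
) -> float:
    """Derive a cut-off from confirmed-patient values with a safety margin.

    at_least: the largest multiple of ``granularity`` strictly below
    min(tp_values) (falling back to the minimum itself when that multiple
    would be non-positive).  at_most: the smallest multiple of ``granularity``
    at or above max(tp_values), plus one further step.  Either way the derived
    COV never excludes any supplied patient value under inclusive comparison.
    """
    values = [float(v) for v in tp_values]
    if not values:
        raise ValueError("cannot derive a cut-off from an empty value list")
    if not granularity > 0:
        raise ValueError("granularity must be positive")
    g = float(granularity)
    direction = Direction(direction)
    eps = 1e-9
    if direction is Direction.AT_LEAST:
        vmin = min(values)
        k = math.floor(vmin / g - eps)
        cov = k * g
        if cov <= 0:
            cov = vmin  # inclusive >= retains the value
    else:
        vmax = max(values)
        k = math.ceil(vmax / g - eps)
        cov = (k + 1) * g
    cov = round(cov, 12)
    # contract: never exclude a supplied patient value
    probe = Criterion("tyr", direction, cov) if cov > 0 else None
    assert probe is None or all(probe.holds(v) for v in values)
    return cov


# ---------------------------------------------------------------------------
# Alternative-protocol enumeration

#: Reconstructed candidate grid of 13 single-biomarker protocols (the source
#: reports the count and three winning combinations, not the full grid).
#: COVs anchored to the 13 confirmed patients via `derive_cov`-style margins.
DEFAULT_SINGLETON_GRID: tuple[Criterion, ...] = (
    Criterion("tyr", Direction.AT_LEAST, 100),
    Criterion("tyr", Direction.AT_LEAST, 110),
    Criterion("tyr", Direction.AT_LEAST, 500),
    Criterion("phe", Direction.AT_MOST, 150),
    _PROD100,
    _PROD110,
    Criterion("tyr_over_sa", Direction.AT_LEAST, 20),
    Criterion("sa_over_tyr", Direction.AT_LEAST, 0.001),
    Criterion("sa_over_phe", Direction.AT_LEAST, 0.005),
    _TYRPHE25,
    Criterion("tyr_over_phe", Direction.AT_LEAST, 4.0),
    _PHETYR05,
    Criterion("phe_over_tyr", Direction.AT_MOST, 0.4),
)

#: Reconstructed 17 add-on sets for SA-based combination protocols; the three
#: published winners (L, N, O) appear as sets 14, 15 and 16.
DEFAULT_COMBINATION_ADDONS: tuple[tuple[Criterion, ...], ...] = (
    (_TYR100,),
    (_PROD100,),
    (_PROD110,),
    (_TYRPHE25,),
    (_PHETYR05,),
    (Criterion("phe", Direction.AT_MOST, 150),),
    (_TYR100, _PROD100),
    (_TYR100, _PROD110),
    (_TYR100, _TYRPHE25),
    (_TYR100, _PHETYR05),
    (_PROD100, _TYRPHE25),
    (_PROD110, _TYRPHE25),
    (_PROD110, _PHETYR05),
    (_TYR100, _PROD100, _TYRPHE25),   # alternative L
    (_TYR100, _PROD110, _PHETYR05),   # alternative N
    (_TYR100, _PROD110, _TYRPHE25),   # alternative O
    (_TYR100, _PROD100, _PHETYR05),
)


def _criterion_slug(c: Criterion) -> str:
    op = "ge" if c.direction is Direction.AT_LEAST else "le"
    return f"{c.biomarker}_{op}_{c.cov:g}"


def enumerate_alternatives(
    base: Criterion,
    singletons: Iterable[Criterion] = (),
    addon_sets: Iterable[Sequence[Criterion]] = (),
) -> list[Protocol]:
    """Build alternative protocols from a candidate grid.

    ``singletons`` become one-criterion protocols; each set in ``addon_sets``
    is conjoined with the SA base criterion.  Protocols identical as a
    (biomarker, direction, cov) set are deduplicated, first occurrence wins.
    """
    if base != CURRENT_SA_CRITERION:
        raise ValueError(
            "alternative protocols keep the current SA criterion "
            f"({CURRENT_SA_CRITERION}) as their base"
        )
    singletons = tuple(singletons)
    addon_sets = tuple(tuple(s) for s in addon_sets)
    if not singletons and not addon_sets:
        raise ValueError("empty candidate grid")

    protocols: list[Protocol] = []
    seen: set[frozenset] = set()
    for i, crit in enumerate(singletons, start=1):
        p = Protocol(f"single_{i:02d}_{_criterion_slug(crit)}", (crit,), "alternative")
        if p.key() not in seen:
            seen.add(p.key())
            protocols.append(p)
    for i, addons in enumerate(addon_sets, start=1):
        if not addons:
            raise ValueError("empty add-on set in candidate grid")
        slug = "+".join(_criterion_slug(c) for c in addons)
        p = Protocol(f"combo_{i:02d}_sa060+{slug}", (base, *addons), "alternative")
        if p.key() not in seen:
            seen.add(p.key())
            protocols.append(p)
    return protocols


def default_alternative_protocols() -> list[Protocol]:
    """The reconstructed grid of 30 alternative protocols (13 singleton
    variants + 17 SA-based combinations)."""
    return enumerate_alternatives(
        CURRENT_SA_CRITERION, DEFAULT_SINGLETON_GRID, DEFAULT_COMBINATION_ADDONS
    )


# ---------------------------------------------------------------------------
# Plain-text protocol config round-trip

def format_protocols(protocols: Iterable[Protocol]) -> str:
    """Serialise protocols to the plain config format::

        [name]
        provenance = current
        sa_eff ge 0.60
    """
    blocks = []
    for p in protocols:
        lines = [f"[{p.name}]", f"provenance = {p.provenance}"]
        lines += [f"{c.biomarker} {c.direction.value} {c.cov:g}" for c in p.criteria]
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def parse_protocols(text: str) -> list[Protocol]:
    """Inverse of :func:`format_protocols`; round-trips losslessly."""
    protocols: list[Protocol] = []
    name: str | None = None
    provenance = "user"
    criteria: list[Criterion] = []

    def flush():
        if name is not None:
            protocols.append(Protocol(name, tuple(criteria), provenance))

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            flush()
            name = line[1:-1].strip()
            provenance = "user"
            criteria = []
        elif "=" in line:
            key, _, value = (s.strip() for s in line.partition("="))
            if key != "provenance":
                raise ValueError(f"line {lineno}: unknown setting {key!r}")
            provenance = value
        else:
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(
                    f"line {lineno}: expected '<biomarker> <ge|le> <value>', got {raw!r}"
                )
            if name is None:
                raise ValueError(f"line {lineno}: criterion before any [protocol] header")
            criteria.append(Criterion(parts[0], Direction(parts[1]), float(parts[2])))
    flush()
    if not protocols:
        raise ValueError("no protocols found in config text")
    return protocols
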