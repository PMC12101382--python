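"""Confusion counts and screening-performance indicators.

Definitions are the standard screening ones: sensitivity tp/(tp+fn),
specificity tn/(tn+fp), PPV tp/(tp+fp), NPV tn/(tn+fn), referral rate
(tp+fp)/total, and prevalence expressed as 1:N with N = round(total/(tp+fn)).
Indicators are stored unrounded (percent scale) and rounded only for display,
at the national programme's reporting resolution: sensitivity/PPV/NPV to
integer percent, specificity to three decimals, referral rate to four —
half-up throughout, except the prevalence denominator, which uses ties-to-even
(the convention that reproduces every published prevalence, e.g.
693,821 / 2 -> 1:346,910).

Protocol ranking follows the programme's decision rule: a candidate protocol
may not introduce false negatives relative to the baseline; among the rest,
higher PPV wins, ties broken by lower referral rate, then name.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .harmonization import round_half_up
from .panel import Diagnosis, ScreenResult
from .protocols import Protocol

__all__ = [
    "ConfusionCounts",
    "PerformanceReport",
    "tabulate",
    "metrics",
    "rank_protocols",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fp


def _as_positive_mask(classifications) -> np.ndarray:
    vals = list(classifications)
    out = np.empty(len(vals), dtype=bool)
    for i, v in enumerate(vals):
        if isinstance(v, (bool, np.bool_)):
            out[i] = bool(v)
        elif isinstance(v, ScreenResult):
            out[i] = v is ScreenResult.POSITIVE
        elif isinstance(v, str) and v in ("positive", "negative"):
            out[i] = v == "positive"
        else:
            raise ValueError(f"unrecognised classification value: {v!r}")
    return out


def tabulate(classifications, diagnoses) -> ConfusionCounts:
    """Cross-tabulate aligned screen results against confirmed diagnoses.

    ``classifications`` may be booleans (True = screen-positive),
    :class:`ScreenResult` values or the strings 'positive'/'negative';
    ``diagnoses`` must be 'TT1' or 'not_TT1' (an 'unknown' label is an error —
    callers decide how to handle undiagnosed records before counting).
    """
    pos = _as_positive_mask(classifications)
    diag = [Diagnosis(d) for d in diagnoses]
    if len(diag) != len(pos):
        raise ValueError("classifications and diagnoses must be aligned")
    bad = [d for d in diag if d is Diagnosis.UNKNOWN]
    if bad:
        raise ValueError(
            f"{len(bad)} record(s) have unknown diagnosis; resolve or exclude "
            "them before tabulating"
        )
    tt1 = np.array([d is Diagnosis.TT1 for d in diag], dtype=bool)
    return ConfusionCounts(
        tp=int(np.sum(pos & tt1)),
        fp=int(np.sum(pos & ~tt1)),
        tn=int(np.sum(~pos & ~tt1)),
        fn=int(np.sum(~pos & tt1)),
    )


@dataclass(frozen=True)
class PerformanceReport:
    """Screening indicators on the percent scale, unrounded; ``None`` marks an
    indicator whose denominator is zero (shown as '-' in programme reports).
    ``prevalence`` is the N of '1:N', ``None`` when no affected newborns."""

    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    referral_rate: float
    prevalence: int | None
    provisional_sensitivity: bool = True  # FN may surface years after screening

    def display(self) -> dict:
        """Values at reporting resolution (half-up; '-' for undefined)."""

        def fmt(v, nd):
            if v is None:
                return "-"
            r = round_half_up(v, nd)
            return int(r) if nd == 0 else r

        return {
            "tn": self.counts.tn,
            "fn": self.counts.fn,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "referral_rate_pct": fmt(self.referral_rate, 4),
            "sensitivity_pct": fmt(self.sensitivity, 0),
            "specificity_pct": fmt(self.specificity, 3),
            "ppv_pct": fmt(self.ppv, 0),
            "npv_pct": fmt(self.npv, 0),
            "prevalence": "-" if self.prevalence is None else f"1:{self.prevalence}",
        }


def metrics(counts: ConfusionCounts) -> PerformanceReport:
    """Screening-performance indicators from confusion counts."""
    if counts.total <= 0:
        raise ValueError("cannot compute indicators for an empty cohort")

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else None

    affected = counts.tp + counts.fn
    return PerformanceReport(
        counts=counts,
        sensitivity=ratio(counts.tp, affected),
        specificity=ratio(counts.tn, counts.tn + counts.fp),
        ppv=ratio(counts.tp, counts.tp + counts.fp),
        npv=ratio(counts.tn, counts.tn + counts.fn),
        referral_rate=100.0 * counts.positives / counts.total,
        # ties-to-even reproduces the published 1:N figures
        prevalence=round(counts.total / affected) if affected > 0 else None,
    )


def rank_protocols(
    reports: Sequence[tuple[Protocol, ConfusionCounts]],
    baseline: Protocol | str,
) -> list[tuple[Protocol, ConfusionCounts, PerformanceReport]]:
    """Order candidate protocols under the no-new-false-negatives rule.

    Protocols whose FN count exceeds the baseline's are excluded outright
    (sensitivity may never drop).  The rest — baseline included — are sorted
    by PPV descending, ties by lower referral rate, then by name.  A protocol
    with undefined PPV (no positives at all) sorts last.
    """
    baseline_name = baseline.name if isinstance(baseline, Protocol) else str(baseline)
    by_name = {p.name: (p, c) for p, c in reports}
    if baseline_name not in by_name:
        raise ValueError(f"baseline protocol {baseline_name!r} missing from reports")
    baseline_fn = by_name[baseline_name][1].fn

    admissible = [
        (p, c, metrics(c)) for p, c in reports if c.fn <= baseline_fn
    ]
    admissible.sort(
        key=lambda item: (
            -(item[2].ppv if item[2].ppv is not None else -np.inf),
            item[2].referral_rate,
            item[0].name,
        )
    )
    return admissible
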