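"""Cohort file I/O and the end-to-end evaluation pipeline.

Cohorts travel as UTF-8 comma-separated CSV with '.' decimals — no standard
bioinformatics container fits dried-blood-spot analyte panels.  Required
columns: record_id, assay, sa, tyr, phe, diagnosis, original_result; extra
columns pass through untouched.  Validation is strict and errors are
line-addressed (header is line 1).

`run_evaluation` ties the stages together: read or synthesise a cohort,
compute the derived panel, classify under a protocol set, tabulate against
confirmed diagnoses, rank under the no-new-FN rule, and write a report
bundle whose every file embeds tool version, config hash and seed.  Given
the same config and seed the bundle is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import EnrichedCohort, make_enriched_cohort
from .harmonization import BUILTIN_MODELS, ConversionModel
from .harmonization import round_half_up
from .panel import (
    COHORT_COLUMNS,
    Assay,
    Diagnosis,
    ScreenResult,
    compute_panel_frame,
    DISPLAY_DECIMALS,
)
from .performance import ConfusionCounts, metrics, rank_protocols, tabulate
from .protocols import Protocol, builtin_protocols, classify_frame, parse_protocols

logger = logging.getLogger("tt1screen")

__all__ = [
    "CohortFormatError",
    "RunConfig",
    "ReportBundle",
    "read_cohort",
    "write_cohort",
    "evaluate_protocols",
    "run_evaluation",
    "write_reports",
]


class CohortFormatError(ValueError):
    """A cohort file violates the format contract; message lists offending
    lines (1-based, header = line 1)."""


_VALID_ASSAYS = {a.value for a in Assay}
_VALID_DIAGNOSES = {d.value for d in Diagnosis}
_VALID_RESULTS = {r.value for r in ScreenResult}


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.  Raises :class:`CohortFormatError`
    with row numbers for missing columns, non-numeric or negative biomarkers,
    and unknown enum labels."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"record_id": str})
    except Exception as exc:  # malformed CSV
        raise CohortFormatError(f"{path}: cannot parse CSV: {exc}") from exc

    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing required column(s): {missing}")
    if df.empty:
        raise CohortFormatError(f"{path}: cohort contains no records")

    problems: list[str] = []

    def rownums(mask) -> list[int]:
        return [int(i) + 2 for i in df.index[mask][:10]]  # +2: header + 0-base

    for col in ("sa", "tyr", "phe"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            problems.append(f"non-numeric {col} at row(s) {rownums(bad)}")
        neg = numeric < 0
        if neg.any():
            problems.append(f"negative {col} at row(s) {rownums(neg)}")
        df[col] = numeric

    for col, valid in (
        ("assay", _VALID_ASSAYS),
        ("diagnosis", _VALID_DIAGNOSES),
        ("original_result", _VALID_RESULTS),
    ):
        bad = ~df[col].astype(str).isin(valid)
        if bad.any():
            labels = sorted(df.loc[bad, col].astype(str).unique()[:5])
            problems.append(
                f"unknown {col} label(s) {labels} at row(s) {rownums(bad)}"
            )

    dup = df["record_id"].duplicated()
    if dup.any():
        problems.append(f"duplicate record_id at row(s) {rownums(dup)}")

    if problems:
        raise CohortFormatError(f"{path}: " + "; ".join(problems))
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of one end-to-end evaluation run."""

    cohort_path: str | None = None  # None -> synthesise the enriched cohort
    protocol_names: tuple[str, ...] = ("sa060_current", "alt_L", "alt_N", "alt_O")
    protocol_file: str | None = None
    model_name: str = "neobase_to_neobase2"
    baseline: str = "sa060_current"
    out_dir: str = "reports"
    seed: int = 0
    n_tn: int = 653_396
    verbosity: int = 0

    def config_hash(self) -> str:
        # out_dir and verbosity do not influence the analysis
        payload = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("out_dir", "verbosity")
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def resolve_model(self) -> ConversionModel:
        try:
            return BUILTIN_MODELS[self.model_name.removeprefix("builtin:")]
        except KeyError:
            raise ValueError(f"unknown conversion model {self.model_name!r}") from None

    def resolve_protocols(self) -> list[Protocol]:
        if self.protocol_file is not None:
            return parse_protocols(Path(self.protocol_file).read_text())
        catalogue = builtin_protocols()
        unknown = [n for n in self.protocol_names if n not in catalogue]
        if unknown:
            raise ValueError(f"unknown protocol name(s): {unknown}")
        return [catalogue[n] for n in self.protocol_names]


@dataclass
class ReportBundle:
    performance: pd.DataFrame
    ranking: pd.DataFrame
    patients: pd.DataFrame
    counts: dict[str, ConfusionCounts]
    metadata: dict = field(default_factory=dict)


def evaluate_protocols(
    cohort: pd.DataFrame,
    protocols: list[Protocol],
    model: ConversionModel,
) -> tuple[pd.DataFrame, dict[str, ConfusionCounts]]:
    """Classify a cohort under each protocol and tabulate performance.

    Records with unknown diagnosis cannot enter a confusion matrix; they are
    excluded here with one structured log line each (screening audit
    practice), never silently.
    """
    panel = compute_panel_frame(cohort, model)
    known = cohort["diagnosis"].isin([Diagnosis.TT1.value, Diagnosis.NOT_TT1.value])
    for rid in cohort.loc[~known, "record_id"]:
        logger.info("excluded record_id=%s reason=unknown_diagnosis", rid)
    panel_known = panel.loc[known]
    diagnoses = cohort.loc[known, "diagnosis"].tolist()

    rows, counts = [], {}
    for proto in protocols:
        positive = classify_frame(panel_known, proto)
        cc = tabulate(positive.to_numpy(), diagnoses)
        counts[proto.name] = cc
        report = metrics(cc)
        row = {"protocol": proto.name,
               "criteria": "; ".join(str(c) for c in proto.criteria)}
        row.update(report.display())
        row.update(
            {
                "ppv_pct_unrounded": report.ppv,
                "sensitivity_pct_unrounded": report.sensitivity,
                "specificity_pct_unrounded": report.specificity,
                "npv_pct_unrounded": report.npv,
                "referral_rate_pct_unrounded": report.referral_rate,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows), counts


def run_evaluation(config: RunConfig) -> ReportBundle:
    """Run the full evaluation chain described in the module docstring."""
    model = config.resolve_model()
    protocols = config.resolve_protocols()

    if config.cohort_path is not None:
        cohort = read_cohort(config.cohort_path)
    else:
        enriched: EnrichedCohort = make_enriched_cohort(
            seed=config.seed, n_tn=config.n_tn, model=model
        )
        cohort = enriched.frame
    if cohort.empty:
        raise ValueError("empty cohort; nothing to evaluate")

    performance, counts = evaluate_protocols(cohort, protocols, model)

    ranked = rank_protocols(
        [(p, counts[p.name]) for p in protocols], config.baseline
    )
    ranking = pd.DataFrame(
        {
            "rank": range(1, len(ranked) + 1),
            "protocol": [p.name for p, _, _ in ranked],
            "ppv_pct_unrounded": [r.ppv for _, _, r in ranked],
            "referral_rate_pct_unrounded": [r.referral_rate for _, _, r in ranked],
            "fn": [c.fn for _, c, _ in ranked],
        }
    )

    # patient table analogue: derived panel of every TT1-labelled record
    tt1 = cohort[cohort["diagnosis"] == Diagnosis.TT1.value]
    panel_tt1 = compute_panel_frame(tt1, model)
    patients = panel_tt1.copy()
    for name, nd in DISPLAY_DECIMALS.items():
        patients[name] = round_half_up(patients[name].to_numpy(float), nd)

    metadata = {
        "tool": "tt1screen",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_records": int(len(cohort)),
        "conversion_model": model.to_dict(),
    }
    return ReportBundle(
        performance=performance,
        ranking=ranking,
        patients=patients,
        counts=counts,
        metadata=metadata,
    )


def write_reports(bundle: ReportBundle, out_dir) -> list[Path]:
    """Write the bundle to ``out_dir``; deterministic byte-for-byte for a
    fixed config and seed.  Each CSV carries the provenance header as a
    comment line; metadata also lands in metadata.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = (
        f"# tt1screen {bundle.metadata['version']} "
        f"config={bundle.metadata['config_hash']} seed={bundle.metadata['seed']}\n"
    )
    written = []
    for name, df in (
        ("performance.csv", bundle.performance),
        ("ranking.csv", bundle.ranking),
        ("patients.csv", bundle.patients),
    ):
        p = out / name
        with open(p, "w", newline="") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
        written.append(p)
    meta = out / "metadata.json"
    meta.write_text(json.dumps(bundle.metadata, indent=2, sort_keys=True) + "\n")
    written.append(meta)
    return written
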