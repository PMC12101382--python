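"""Published reference figures from the Dutch TT1 screening evaluation.

These are the nationally reported confusion counts and display-rounded
indicators per screening era, and for the enriched evaluation dataset under
the current protocol and the three best multi-biomarker alternatives.  They
serve as inputs (printed counts are data) and as the expectations the
``reproduce`` CLI subcommand and the test suite check recomputed indicators
against.  Nothing here is computed; see :mod:`tt1screen.performance` for the
arithmetic.
"""

from __future__ import annotations

from .performance import ConfusionCounts

__all__ = ["ERA_COUNTS", "ERA_DISPLAY", "ENRICHED_COUNTS", "ENRICHED_DISPLAY"]

#: Confusion counts per screening era (from the national evaluation).
ERA_COUNTS: dict[str, ConfusionCounts] = {
    # NeoBase 2, SA >= 0.60: 693,821 screened, 23 referrals, 2 TT1
    "neobase2_2018_2021": ConfusionCounts(tp=2, fp=21, tn=693_798, fn=0),
    # NeoBase, SA >= 1.2 (mid-2009 through 2017)
    "neobase_2009_2017": ConfusionCounts(tp=8, fp=14, tn=1_506_912, fn=1),
    # NeoBase, SA >= 1.5 (late 2008 through mid-2009)
    "neobase_2008_2009": ConfusionCounts(tp=1, fp=2, tn=136_641, fn=0),
    # tyr >= 500 (early 2007)
    "neogram_2007": ConfusionCounts(tp=0, fp=12, tn=34_099, fn=0),
    # whole NeoBase era pooled: 1,643,579 screened, 25 referrals, 9 TT1, 1 FN
    "neobase_full_era": ConfusionCounts(tp=9, fp=16, tn=1_643_553, fn=1),
}

#: Display-rounded indicators as nationally reported ('-' where undefined).
ERA_DISPLAY: dict[str, dict] = {
    "neobase2_2018_2021": {
        "referral_rate_pct": 0.0033,
        "sensitivity_pct": 100,
        "specificity_pct": 99.997,
        "ppv_pct": 9,
        "npv_pct": 100,
        "prevalence": "1:346910",
    },
    "neobase_2009_2017": {
        "referral_rate_pct": 0.0015,
        "sensitivity_pct": 89,
        "specificity_pct": 99.999,
        "ppv_pct": 36,
        "prevalence": "1:167437",
    },
    # NOTE: the nationally reported prevalence for this era (1:68,322) counts
    # a footnoted second patient who was never screened; the screened-cohort
    # formula used here gives 1:136,644, so that cell is not compared.
    "neobase_2008_2009": {
        "referral_rate_pct": 0.0022,
        "sensitivity_pct": 100,
        "specificity_pct": 99.999,
        "ppv_pct": 33,
    },
    "neogram_2007": {
        "referral_rate_pct": 0.0352,
        "sensitivity_pct": "-",
        "specificity_pct": 99.965,
        "ppv_pct": 0,
        "prevalence": "-",
    },
    "neobase_full_era": {
        "referral_rate_pct": 0.0015,
        "sensitivity_pct": 90,
        "ppv_pct": 36,
    },
}

#: Enriched evaluation dataset (653,536 records) under the current protocol
#: and alternatives L, N, O.
ENRICHED_COUNTS: dict[str, ConfusionCounts] = {
    "sa060_current": ConfusionCounts(tp=13, fp=127, tn=653_396, fn=0),
    "alt_L": ConfusionCounts(tp=13, fp=8, tn=653_515, fn=0),
    "alt_N": ConfusionCounts(tp=13, fp=7, tn=653_516, fn=0),
    "alt_O": ConfusionCounts(tp=13, fp=5, tn=653_518, fn=0),
}

ENRICHED_DISPLAY: dict[str, dict] = {
    "sa060_current": {
        "referral_rate_pct": 0.0214,
        "sensitivity_pct": 100,
        "specificity_pct": 99.981,
        "ppv_pct": 9,
        "npv_pct": 100,
    },
    "alt_L": {
        "referral_rate_pct": 0.0032,
        "sensitivity_pct": 100,
        "specificity_pct": 99.999,
        "ppv_pct": 62,
        "npv_pct": 100,
    },
    "alt_N": {
        "referral_rate_pct": 0.0031,
        "sensitivity_pct": 100,
        "specificity_pct": 99.999,
        "ppv_pct": 65,
        "npv_pct": 100,
    },
    "alt_O": {
        "referral_rate_pct": 0.0028,
        "sensitivity_pct": 100,
        "specificity_pct": 99.999,
        "ppv_pct": 72,
        "npv_pct": 100,
    },
}

#: Derived patient-table cells as nationally published (record id ->
#: {biomarker: displayed value}); used by the reproduce command.
PUBLISHED_PATIENT_TABLE: dict[str, dict] = {
    "TT1-01": {"sa_eff": 2.84, "tyr_times_sa": 2354, "tyr_over_sa": 292,
               "sa_over_tyr": 0.003, "sa_over_phe": 0.035, "tyr_over_phe": 10.23,
               "phe_over_tyr": 0.10},
    "TT1-02": {"sa_eff": 2.52, "tyr_times_sa": 1106, "tyr_over_sa": 174,
               "sa_over_tyr": 0.006, "sa_over_phe": 0.032, "tyr_over_phe": 5.63,
               "phe_over_tyr": 0.18},
    "TT1-03": {"sa_eff": 0.64, "tyr_times_sa": 184, "tyr_over_sa": 450,
               "sa_over_tyr": 0.002, "sa_over_phe": 0.009, "tyr_over_phe": 4.24,
               "phe_over_tyr": 0.24},
    "TT1-04": {"sa_eff": 3.85, "tyr_times_sa": 3207, "tyr_over_sa": 216,
               "sa_over_tyr": 0.005, "sa_over_phe": 0.028, "tyr_over_phe": 6.08,
               "phe_over_tyr": 0.16},
    "TT1-05": {"sa_eff": 4.57, "tyr_times_sa": 1901, "tyr_over_sa": 91,
               "sa_over_tyr": 0.011, "sa_over_phe": 0.083, "tyr_over_phe": 7.56,
               "phe_over_tyr": 0.13},
    "TT1-06": {"sa_eff": 2.95, "tyr_times_sa": 1454, "tyr_over_sa": 167,
               "sa_over_tyr": 0.006, "sa_over_phe": 0.063, "tyr_over_phe": 10.49,
               "phe_over_tyr": 0.10},
    "TT1-07": {"sa_eff": 3.15, "tyr_times_sa": 1575, "tyr_over_sa": 159,
               "sa_over_tyr": 0.006, "sa_over_phe": 0.053, "tyr_over_phe": 8.33,
               "phe_over_tyr": 0.12},
    "TT1-08": {"sa_eff": 1.11, "tyr_times_sa": 999, "tyr_over_sa": 811,
               "sa_over_tyr": 0.001, "sa_over_phe": 0.017, "tyr_over_phe": 14.06,
               "phe_over_tyr": 0.07},
    "TT1-09": {"sa_eff": 9.70, "tyr_times_sa": 2289, "tyr_over_sa": 24,
               "sa_over_tyr": 0.041, "sa_over_phe": 0.173, "tyr_over_phe": 4.21,
               "phe_over_tyr": 0.24},
    "TT1-10": {"sa_eff": 3.06, "tyr_times_sa": 1741, "tyr_over_sa": 186,
               "sa_over_tyr": 0.005, "sa_over_phe": 0.041, "tyr_over_phe": 7.59,
               "phe_over_tyr": 0.13},
    "TT1-11": {"sa_eff": 0.99, "tyr_times_sa": 111, "tyr_over_sa": 113,
               "sa_over_tyr": 0.009, "sa_over_phe": 0.023, "tyr_over_phe": 2.60,
               "phe_over_tyr": 0.38},
    "TT1-12": {"sa_eff": 2.92, "tyr_times_sa": 1232, "tyr_over_sa": 145,
               "sa_over_tyr": 0.007, "sa_over_phe": 0.097, "tyr_over_phe": 14.07,
               "phe_over_tyr": 0.07},
    "TT1-13": {"sa_eff": 2.03, "tyr_times_sa": 944, "tyr_over_sa": 229,
               "sa_over_tyr": 0.004, "sa_over_phe": 0.023, "tyr_over_phe": 5.34,
               "phe_over_tyr": 0.19},
}
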