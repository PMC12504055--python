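"""Published benchmark summaries used as validation inputs.

Small printed tables from the 1.5T study the pipeline was designed
around: a 12-session phantom benchmarking summary for the seven T1 vials
in the physiological window, and per-patient longitudinal ROI summaries
(baseline means, deltas and within-subject CVs) for uninvolved control
tissues in the brain (NAWM) and head-and-neck (masseter) cohorts. The
statistics modules are validated by recomputing every derived cell
(bias, CV, wCV, percent deltas) from the printed inputs.

The raw maps behind these numbers are not distributed; where a follow-up
mean is needed it is reconstructed from the printed baseline and delta.
T1 deltas are printed with sub-percent relative resolution in ms, so the
ms delta reconstructs T1 means; T2 ms deltas are too coarsely rounded
(values of 20-40 ms), so the percent delta reconstructs T2 means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "phantom_t1_summary",
    "control_tissue_longitudinal",
    "LESION_EFFECTS",
    "reconstruct_timepoint_means",
]


def phantom_t1_summary() -> pd.DataFrame:
    """12-session phantom summary, physiological T1 vials (5 scans/session).

    Columns: printed grand mean, intersession SD, intersession CV,
    intrasession CV range, manufacturer reference, and printed bias.
    """
    rows = [
        # vial, mean, sd, cv%, intra_lo%, intra_hi%, reference, bias_ms, bias_pct
        (1, 2175.6, 12.1, 0.6, 0.1, 0.9, 1741.3, 434.3, 24.9),
        (2, 1700.4, 7.6, 0.4, 0.1, 0.6, 1269.8, 430.6, 33.9),
        (3, 1309.4, 4.5, 0.3, 0.1, 0.5, 962.0, 347.4, 36.1),
        (4, 931.1, 3.4, 0.4, 0.0, 0.5, 684.7, 246.3, 36.0),
        (5, 662.8, 3.6, 0.5, 0.1, 0.8, 487.4, 175.5, 36.0),
        (6, 478.0, 2.1, 0.4, 0.2, 1.0, 346.4, 131.6, 38.0),
        (7, 382.3, 3.3, 0.9, 0.1, 1.0, 245.8, 136.6, 55.6),
    ]
    return pd.DataFrame(rows, columns=[
        "vial", "mean", "intersession_sd", "intersession_cv_pct",
        "intrasession_cv_min_pct", "intrasession_cv_max_pct",
        "reference", "bias_ms", "bias_pct",
    ])


def control_tissue_longitudinal() -> pd.DataFrame:
    """Printed longitudinal summaries of uninvolved control tissue.

    One row per subject, ROI and parameter: baseline mean, the two
    follow-up deltas (ms and percent) and the printed wCV over the three
    timepoints. Brain rows are NAWM (follow-ups at ~3-month intervals
    post-treatment); head-and-neck rows are contralateral masseter
    (mid-treatment and ~3 months post-treatment).
    """
    rows = [
        # cohort, subject, roi, parameter, baseline, d1_ms, d1_pct, d2_ms, d2_pct, wcv
        ("brain", "A", "NAWM", "T1", 678, 9, 1.3, 23, 3.4, 1.7),
        ("brain", "B", "NAWM", "T1", 855, -148, -17.3, -87, -10.2, 9.6),
        ("brain", "C", "NAWM", "T1", 740, 19, 2.6, 36, 4.9, 2.4),
        ("brain", "A", "NAWM", "T2", 39, 1, 1.3, 0, 0.1, 0.7),
        ("brain", "B", "NAWM", "T2", 36, 0, 0.2, 2, 6.1, 3.4),
        ("brain", "C", "NAWM", "T2", 37, 0, -1.2, 1, 1.7, 1.5),
        ("hn", "I", "masseter", "T1", 934, 47, 5.0, 18, 1.9, 2.5),
        ("hn", "II", "masseter", "T1", 931, 22, 2.4, 53, 5.7, 2.8),
        ("hn", "III", "masseter", "T1", 994, -21, -2.1, -69, -7.0, 3.7),
        ("hn", "IV", "masseter", "T1", 1124, -142, -12.6, -118, -10.5, 7.3),
        ("hn", "V", "masseter", "T1", 1115, 10, 0.9, -124, -11.1, 6.9),
        ("hn", "I", "masseter", "T2", 28, -2, -5.6, -2, -5.6, 3.4),
        ("hn", "II", "masseter", "T2", 31, 1, 4.5, 4, 11.8, 5.6),
        ("hn", "III", "masseter", "T2", 22, 0, -0.4, -4, -17.8, 10.8),
        ("hn", "IV", "masseter", "T2", 22, 1, 6.7, 2, 8.0, 4.1),
        ("hn", "V", "masseter", "T2", 23, 3, 11.7, -1, -4.5, 8.2),
    ]
    return pd.DataFrame(rows, columns=[
        "cohort", "subject", "roi", "parameter", "baseline_mean",
        "delta1_ms", "delta1_pct", "delta2_ms", "delta2_pct", "wcv_pct",
    ])


#: Reported lesion effect sizes (percent change of the ROI mean vs.
#: baseline) used as programmable effects in the synthetic subject:
#: an enhancing lesion and a resolving nodal lesion with its residual
#: disease region.
LESION_EFFECTS = {
    "enhancing_gtv": {"dt1_pct": 13.7, "dt2_pct": 17.8},
    "resolving_gtv": {"dt1_pct": -39.5, "dt2_pct": -32.7},
    "resolving_rd": {"dt1_pct": -29.2, "dt2_pct": -35.3},
}


def reconstruct_timepoint_means(baseline: float, deltas_ms, deltas_pct,
                                parameter: str) -> np.ndarray:
    """Per-timepoint means from a printed baseline and printed deltas.

    T1 means are reconstructed from the ms deltas, T2 means from the
    percent deltas (see module docstring for the precision rationale).
    Returns the baseline followed by the follow-up means.
    """
    baseline = float(baseline)
    if parameter == "T1":
        means = [baseline + float(d) for d in deltas_ms]
    elif parameter == "T2":
        means = [baseline * (1.0 + float(p) / 100.0) for p in deltas_pct]
    else:
        raise ValueError(f"unknown parameter {parameter!r}")
    return np.asarray([baseline] + means, dtype=float)
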