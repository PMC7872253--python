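"""Published cadaver-study summary statistics, used as comparison inputs.

These are the group-level means and standard deviations reported for the
five-pair canine cadaver comparison of guide-assisted versus freehand
bipolar coxofemoral osteochondral allograft preparation.  The raw
per-subject data were not deposited, so only arithmetic on these summaries
(group-mean accuracy differences) can be recomputed; they also calibrate
the synthetic study's generating conditions.
"""

from __future__ import annotations

__all__ = ["STUDY_SUMMARY", "accuracy_difference", "N_PAIRS"]

N_PAIRS = 5

# (mean, sd) per group; alignment rows are absolute deviations from the
# virtual surgical plan.
STUDY_SUMMARY = {
    "surgical_time_min": {
        "donor_femur": {"freehand": (3.0, 1.0), "guide": (5.0, 0.5)},
        "donor_acetabulum": {"freehand": (16.0, 6.0), "guide": (15.0, 4.0)},
        "recipient_femur": {"freehand": (5.0, 2.0), "guide": (15.0, 4.0)},
        "total": {"freehand": (24.0, 7.0), "guide": (34.0, 6.0)},
    },
    "gap_mm3": {
        "femoral": {"freehand": (131.0, 119.0), "guide": (114.0, 40.0)},
        "acetabular": {"freehand": (1066.0, 327.0), "guide": (1090.0, 533.0)},
    },
    "alignment_deviation": {
        "neck_length_mm": {"freehand": (3.0, 2.0), "guide": (1.0, 1.5)},
        "version_deg": {"freehand": (7.0, 4.0), "guide": (0.8, 0.8)},
        "inclination_deg": {"freehand": (8.0, 6.0), "guide": (4.0, 7.0)},
    },
}


def accuracy_difference(parameter: str) -> float:
    """Freehand-minus-guide difference of mean absolute plan deviation.

    A positive value means the guide group tracked the virtual plan more
    closely by that many units (degrees or mm) on average.
    """
    row = STUDY_SUMMARY["alignment_deviation"][parameter]
    return row["freehand"][0] - row["guide"][0]
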