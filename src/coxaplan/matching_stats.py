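"""Donor–recipient pairing, mirror plans, plan deviations and group tests.

Donors are paired to recipients on mean acetabular diameter with the donor
acetabulum required to be 1–4 mm smaller than the recipient's.  The
assignment is an explicit, reproducible objective: maximize the number of
matched pairs subject to the window, then among maximal assignments
minimize the total distance of the size differences from the window center
(2.5 mm).

Accuracy is scored as the absolute deviation of each measured alignment
parameter (version, inclination, neck length) from its virtual surgical
plan; the plan for the contralateral side is the mirror image of the
planned side across the sagittal plane.  Groups are compared with a
one-tailed paired t-test at α = 0.05, with Shapiro–Wilk normality computed
on the paired differences (the quantity that enters the t statistic).  No
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .core import LandmarkSet, reflect_points, reflect_vectors
from .geometry import DegenerateInputError, Line, Plane
from .morphometry import MorphometryResult
from .osteotomy_planning import OsteotomyPlan

__all__ = [
    "MatchRow",
    "MatchTable",
    "DeviationRecord",
    "PairedTestResult",
    "pair_donors",
    "mirror_plan",
    "deviation_from_plan",
    "paired_one_tailed_t",
    "simulate_deviation_study",
    "MATCH_WINDOW_MM",
    "ALPHA",
]

MATCH_WINDOW_MM = (1.0, 4.0)   # donor this much smaller than recipient
_WINDOW_CENTER = 2.5
ALPHA = 0.05


@dataclass(frozen=True)
class MatchRow:
    recipient_id: str
    donor_id: str
    recipient_diameter: float
    donor_diameter: float

    @property
    def size_difference(self) -> float:
        return self.recipient_diameter - self.donor_diameter


@dataclass
class MatchTable:
    rows: list[MatchRow]
    unmatched_recipients: list[str] = field(default_factory=list)
    unmatched_donors: list[str] = field(default_factory=list)

    def __post_init__(self):
        lo, hi = MATCH_WINDOW_MM
        for r in self.rows:
            if not lo <= r.size_difference <= hi:
                raise ValueError(
                    f"pair ({r.recipient_id}, {r.donor_id}) violates the "
                    f"{lo}-{hi} mm rule: difference {r.size_difference:.2f} mm"
                )


def pair_donors(recipient_diameters: dict, donor_diameters: dict) -> MatchTable:
    """One-to-one donor→recipient assignment under the 1–4 mm rule.

    Maximizes the number of matched pairs; among maximal assignments,
    minimizes Σ|size_difference − 2.5 mm|.  Subjects that cannot be matched
    are listed, and an empty table is a legal outcome.
    """
    if not recipient_diameters or not donor_diameters:
        raise ValueError("recipient and donor diameter maps must be non-empty")
    rids = sorted(recipient_diameters)
    dids = sorted(donor_diameters)
    lo, hi = MATCH_WINDOW_MM
    BIG = 1e6
    cost = np.full((len(rids), len(dids)), BIG)
    for i, r in enumerate(rids):
        for j, d in enumerate(dids):
            diff = recipient_diameters[r] - donor_diameters[d]
            if lo <= diff <= hi:
                cost[i, j] = abs(diff - _WINDOW_CENTER)
    ri, dj = linear_sum_assignment(cost)
    rows = []
    used_r, used_d = set(), set()
    for i, j in zip(ri, dj):
        if cost[i, j] >= BIG:
            continue
        rows.append(MatchRow(
            recipient_id=rids[i], donor_id=dids[j],
            recipient_diameter=float(recipient_diameters[rids[i]]),
            donor_diameter=float(donor_diameters[dids[j]]),
        ))
        used_r.add(rids[i])
        used_d.add(dids[j])
    return MatchTable(
        rows=rows,
        unmatched_recipients=[r for r in rids if r not in used_r],
        unmatched_donors=[d for d in dids if d not in used_d],
    )


def _flip_side(side: str) -> str:
    return "left" if side == "right" else "right"


def mirror_plan(obj, sagittal_plane: Plane):
    """Mirror a morphometry result or osteotomy plan across the sagittal plane.

    Geometry is reflected (Householder); the side flag flips; the scalar
    targets — version (anteversion-positive on both sides), inclination and
    neck length — are preserved, since reflection is an isometry.
    Mirroring twice is the identity.
    """
    if isinstance(obj, MorphometryResult):
        return MorphometryResult(
            head_center=reflect_points(obj.head_center, sagittal_plane),
            head_radius=obj.head_radius,
            neck_axis=Line(
                reflect_points(obj.neck_axis.point, sagittal_plane),
                reflect_vectors(obj.neck_axis.direction, sagittal_plane),
            ),
            inclination=obj.inclination,
            version=obj.version,
            neck_length=obj.neck_length,
            side=_flip_side(obj.side),
        )
    if isinstance(obj, OsteotomyPlan):
        lm = obj.source_landmarks
        ab = {
            s: {k: reflect_points(p, sagittal_plane) for k, p in d.items()}
            for s, d in lm.acetabular_borders.items()
        }
        lm_m = LandmarkSet(
            craniomedial=reflect_points(lm.craniomedial, sagittal_plane),
            craniolateral=reflect_points(lm.craniolateral, sagittal_plane),
            caudomedial=reflect_points(lm.caudomedial, sagittal_plane),
            caudolateral=reflect_points(lm.caudolateral, sagittal_plane),
            condyle_medial=None if lm.condyle_medial is None
            else reflect_points(lm.condyle_medial, sagittal_plane),
            condyle_lateral=None if lm.condyle_lateral is None
            else reflect_points(lm.condyle_lateral, sagittal_plane),
            acetabular_borders=ab,
            side=_flip_side(lm.side),
        )
        return OsteotomyPlan(
            plane_a=Plane(
                reflect_points(obj.plane_a.point, sagittal_plane),
                reflect_vectors(obj.plane_a.normal, sagittal_plane),
            ),
            plane_b=Plane(
                reflect_points(obj.plane_b.point, sagittal_plane),
                reflect_vectors(obj.plane_b.normal, sagittal_plane),
            ),
            source_landmarks=lm_m,
        )
    raise TypeError(f"cannot mirror object of type {type(obj).__name__}")


@dataclass(frozen=True)
class DeviationRecord:
    """Absolute deviation of one measured hip from its virtual plan."""

    subject_id: str
    group: str  # "guide" or "freehand"
    abs_dev_version: float
    abs_dev_inclination: float
    abs_dev_neck_length: float

    def __post_init__(self):
        for f in ("abs_dev_version", "abs_dev_inclination", "abs_dev_neck_length"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


def deviation_from_plan(measured: MorphometryResult, planned: MorphometryResult,
                        subject_id: str = "", group: str = "") -> DeviationRecord:
    """Per-parameter absolute differences between outcome and plan."""
    if measured.side != planned.side:
        raise ValueError(
            f"side mismatch: measured {measured.side}, planned {planned.side}; "
            "mirror the plan first"
        )
    return DeviationRecord(
        subject_id=subject_id,
        group=group,
        abs_dev_version=abs(measured.version - planned.version),
        abs_dev_inclination=abs(measured.inclination - planned.inclination),
        abs_dev_neck_length=abs(measured.neck_length - planned.neck_length),
    )


@dataclass(frozen=True)
class PairedTestResult:
    n_pairs: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    p_one_tailed: float
    shapiro_p: float
    direction: str
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_one_tailed < self.alpha


def paired_one_tailed_t(group_a, group_b, direction: str) -> PairedTestResult:
    """One-tailed paired t-test on index-paired samples.

    ``direction='a_less'`` tests H1: mean(a) < mean(b); ``'a_greater'`` the
    opposite.  t = mean(d) / (sd(d)/√n) on the paired differences d = a − b,
    with sd the n−1 sample standard deviation.  Shapiro–Wilk normality is
    reported for the paired differences.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("groups must be 1D arrays of equal length")
    n = len(a)
    if n < 3:
        raise ValueError(f"need >= 3 pairs, got {n}")
    if direction not in ("a_less", "a_greater"):
        raise ValueError("direction must be 'a_less' or 'a_greater'")
    d = a - b
    sd = d.std(ddof=1)
    if sd < 1e-12 * max(1.0, np.abs(d).max()):
        raise DegenerateInputError(
            "paired differences have zero variance; t statistic undefined"
        )
    t = d.mean() / (sd / np.sqrt(n))
    if direction == "a_greater":
        p = float(stats.t.sf(t, df=n - 1))
    else:
        p = float(stats.t.cdf(t, df=n - 1))
    sw = float(stats.shapiro(d).pvalue)
    return PairedTestResult(
        n_pairs=n,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        t_statistic=float(t), p_one_tailed=p, shapiro_p=sw,
        direction=direction,
    )


def simulate_deviation_study(n_pairs: int = 5, n_replicates: int = 200,
                             guide_mean: float = 0.8, guide_sd: float = 1.0,
                             freehand_mean: float = 7.0, freehand_sd: float = 4.0,
                             seed: int = 0) -> dict:
    """Monte-Carlo power check of the paired one-tailed design.

    Each replicate draws per-subject version errors, guide arm ~
    N(guide_mean, guide_sd) and freehand arm ~ N(freehand_mean, freehand_sd),
    scores absolute deviations, and tests H1: guide < freehand.  Returns the
    fraction of significant replicates and the recovered group means.
    """
    rng = np.random.default_rng(seed)
    sig = 0
    gm, fm = [], []
    for _ in range(n_replicates):
        g = np.abs(rng.normal(guide_mean, guide_sd, n_pairs))
        f = np.abs(rng.normal(freehand_mean, freehand_sd, n_pairs))
        try:
            res = paired_one_tailed_t(g, f, direction="a_less")
        except DegenerateInputError:
            continue
        sig += res.significant
        gm.append(g.mean())
        fm.append(f.mean())
    return {
        "n_pairs": n_pairs,
        "n_replicates": n_replicates,
        "fraction_significant": sig / n_replicates,
        "guide_mean": float(np.mean(gm)),
        "freehand_mean": float(np.mean(fm)),
    }
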