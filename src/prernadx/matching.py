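"""Confounder matching and prediagnostic time windows.

Cases are frequency-matched to controls on sex and blood-donor group
(exact strata) and age at donation (nearest-age greedy assignment within
a caliper).  Prediagnostic models are trained on case samples whose time
to diagnosis falls inside half-open windows ``[start, start + width)``
that either slide across the horizon or are fixed at the diagnosis end
(0-2, 0-5, 0-8 years); controls, being cancer-free over the whole
horizon, are eligible for every window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cohort import Cohort, CohortError, SampleRecord


@dataclass
class Matching:
    """1:1 case-control pairs plus the leftovers on both sides."""

    pairs: list[tuple[str, str]]  # (case_sample_id, control_sample_id)
    unmatched_cases: list[str] = field(default_factory=list)
    unused_controls: list[str] = field(default_factory=list)

    @property
    def case_ids(self) -> list[str]:
        return [c for c, _ in self.pairs]

    @property
    def control_ids(self) -> list[str]:
        return [c for _, c in self.pairs]


@dataclass(frozen=True)
class WindowSpec:
    """A time-to-diagnosis interval with an optional histology restriction.

    ``kind`` is 'sliding' for moving windows, 'fixed' for windows anchored
    at diagnosis (start 0), and 'full' for the whole horizon.  Intervals
    are half-open: a case at exactly ``start + width`` is excluded.
    """

    start: float
    width: float
    kind: str = "sliding"  # sliding | fixed | full
    histology: str = "all"  # all | NSCLC | SCLC

    def __post_init__(self) -> None:
        if self.start < 0 or self.width <= 0:
            raise CohortError("window start must be >= 0 and width > 0")
        if self.kind not in ("sliding", "fixed", "full"):
            raise CohortError(f"bad window kind {self.kind!r}")
        if self.kind in ("fixed", "full") and self.start != 0:
            raise CohortError(f"{self.kind} windows must start at 0")
        if self.histology not in ("all", "NSCLC", "SCLC"):
            raise CohortError(f"bad window histology {self.histology!r}")

    @property
    def end(self) -> float:
        return self.start + self.width

    def overlaps(self, lo: float, hi: float) -> bool:
        return self.start < hi and lo < self.end

    def label(self) -> str:
        return f"{self.kind}[{self.start:g},{self.end:g})/{self.histology}"


def match_controls(
    cases: list[SampleRecord],
    controls: list[SampleRecord],
    age_caliper: float = 5.0,
) -> Matching:
    """Optimal nearest-age 1:1 matching within exact sex x BDg strata.

    Within each stratum the case-control assignment maximizes the number
    of within-caliper pairs and, among those, minimizes the total age
    distance (a small bipartite min-cost assignment solved exactly).
    Unmatchable cases are reported, never silently dropped.
    Deterministic for a given input: cases and controls are ordered by
    (age, sample_id) before assignment.
    """
    if not cases or not controls:
        raise CohortError("both cases and controls must be non-empty")
    if age_caliper < 0:
        raise CohortError("age_caliper must be >= 0")

    case_strata: dict[tuple[str, str], list[SampleRecord]] = {}
    ctrl_strata: dict[tuple[str, str], list[SampleRecord]] = {}
    for case in cases:
        case_strata.setdefault((case.sex, case.bdg), []).append(case)
    for ctrl in controls:
        ctrl_strata.setdefault((ctrl.sex, ctrl.bdg), []).append(ctrl)

    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    used: set[str] = set()
    for key in sorted(case_strata):
        stratum_cases = sorted(
            case_strata[key], key=lambda r: (r.age_at_donation, r.sample_id)
        )
        pool = sorted(
            ctrl_strata.get(key, []),
            key=lambda r: (r.age_at_donation, r.sample_id),
        )
        if not pool:
            unmatched.extend(c.sample_id for c in stratum_cases)
            continue
        gaps = np.array(
            [
                [abs(c.age_at_donation - k.age_at_donation) for k in pool]
                for c in stratum_cases
            ]
        )
        feasible = gaps <= age_caliper + 1e-12
        # big-M makes the min-cost assignment maximize the number of
        # within-caliper pairs first, then minimize total age distance
        big_m = gaps[feasible].sum() + age_caliper * len(stratum_cases) + 1.0
        cost = np.where(feasible, gaps, big_m)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if feasible[r, c]:
                pairs.append(
                    (stratum_cases[r].sample_id, pool[c].sample_id)
                )
                used.add(pool[c].sample_id)
            else:
                unmatched.append(stratum_cases[r].sample_id)
        assigned = set(rows)
        unmatched.extend(
            stratum_cases[r].sample_id
            for r in range(len(stratum_cases))
            if r not in assigned
        )

    pairs.sort()
    unmatched.sort()
    unused = [c.sample_id for c in controls if c.sample_id not in used]
    return Matching(pairs=pairs, unmatched_cases=unmatched, unused_controls=unused)


def enumerate_windows(
    widths: list[float] = (2, 3, 4),
    horizon: float = 10.0,
    step: float = 1.0,
    histology: str = "all",
) -> list[WindowSpec]:
    """All sliding windows ``[s, s+w)`` for each width, s = 0, step, ..."""
    if step <= 0:
        raise CohortError("step must be positive")
    windows: list[WindowSpec] = []
    for w in widths:
        if w > horizon:
            raise CohortError(f"width {w} exceeds horizon {horizon}")
        s = 0.0
        while s + w <= horizon + 1e-9:
            kind = "full" if (s == 0 and abs(w - horizon) < 1e-9) else "sliding"
            windows.append(WindowSpec(start=s, width=w, kind=kind, histology=histology))
            s += step
    return windows


def fixed_windows(
    widths: list[float] = (2, 5, 8), histology: str = "all"
) -> list[WindowSpec]:
    """The fixed diagnosis-anchored windows 0-2, 0-5, and 0-8 years."""
    return [
        WindowSpec(start=0.0, width=w, kind="fixed", histology=histology)
        for w in widths
    ]


def full_window(horizon: float = 10.0, histology: str = "all") -> WindowSpec:
    """The standard full-time window covering the whole horizon."""
    return WindowSpec(start=0.0, width=horizon, kind="full", histology=histology)


def select_window(cohort: Cohort, window: WindowSpec, horizon: float = 10.0) -> list[str]:
    """Sample ids captured by a window: matching cases plus ALL controls.

    A case is captured when its time to diagnosis lies in
    ``[start, start+width)`` and its histology matches the window's
    (``'all'`` keeps every case).  Order follows the cohort.
    """
    if window.end > horizon + 1e-9:
        raise CohortError(
            f"window {window.label()} extends past the {horizon}-year horizon"
        )
    selected: list[str] = []
    for rec in cohort.samples:
        if rec.group == "control":
            selected.append(rec.sample_id)
            continue
        if rec.time_to_diagnosis is None:
            raise CohortError(f"case {rec.sample_id} lacks time_to_diagnosis")
        if not window.start <= rec.time_to_diagnosis < window.end:
            continue
        if window.histology != "all" and rec.histology != window.histology:
            continue
        selected.append(rec.sample_id)
    return selected
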