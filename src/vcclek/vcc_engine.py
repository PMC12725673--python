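"""Virtual catch change (VCC): cascade, aggregation, trends.

The VCC model turns a fisher's categorical decadal perceptions into a
dimensionless virtual catch trajectory.  Catch is anchored at 1 before the
1980s and updated once per decade:

    V_k = X_{k-1} + X_{k-1} * f_k

where ``X_{k-1}`` is the previous decade's virtual catch and ``f_k`` is the
signed fraction derived from the decade's trend score and the fisher's own
percentage: stable keeps the prior value (f = 0), declines subtract
(f = -pct/100), increases add (f = +pct/100).  The sign comes entirely from
the categorical score; the elicited percentage is a magnitude.

Shifting-baseline correction: a fisher who entered after the 1980s never saw
the early catches, so anchoring them at 1 would mistake an already-depleted
state for the historical norm.  Instead their first ``X`` is the cohort mean
virtual catch of the decade preceding their entry, computed over fishers
whose trajectories already reach that decade.  Baselines only look backward,
so the decade-by-decade construction is well defined.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.polynomial import polynomial as P

from vcclek.survey_model import (
    DECADES,
    PRE_BASELINE,
    InterviewRecord,
    TrendResponse,
    TrendScore,
    active_decades,
)

#: Default category midpoints used only when percentage imputation is
#: explicitly enabled; the survey instrument always elicits percentages, so
#: the default behaviour is a hard error on a missing one.
MIDPOINT_PCT: dict[str, float] = {"MD": 60.0, "D": 25.0, "I": 30.0, "MI": 70.0}


def score_to_signed_fraction(response: TrendResponse,
                             impute_midpoints: Mapping[str, float] | None = None
                             ) -> float:
    """Signed per-decade change fraction in [-1, 1] for one response."""
    if response.score is TrendScore.S:
        return 0.0
    pct = response.perceived_pct
    if pct is None:
        if impute_midpoints is None:
            raise ValueError(
                f"{response.decade}: score {response.score.value} lacks a "
                "perceived percentage (enable midpoint imputation to proceed)"
            )
        pct = impute_midpoints[response.score.value]
    return response.score.sign * pct / 100.0


@dataclass
class VccTrajectory:
    """One fisher's virtual catch values per decade within a stratum."""

    fisher_id: str
    stratum: str
    values: dict[str, float]
    baseline: float

    def value(self, decade: str) -> float:
        return self.values[decade]


def _cascade(fractions: Mapping[str, float], anchor: float) -> dict[str, float]:
    values: dict[str, float] = {}
    x = anchor
    for dec in DECADES:
        if dec not in fractions:
            continue
        x = x + x * fractions[dec]
        values[dec] = x
    return values


def vcc_trajectory(responses: Sequence[TrendResponse],
                   entry_decade: str,
                   cohort_baselines: Mapping[str, float] | None = None,
                   fisher_id: str = "",
                   stratum: str = "overall",
                   impute_midpoints: Mapping[str, float] | None = None
                   ) -> VccTrajectory:
    """Cascade one fisher's responses into a virtual catch trajectory.

    ``entry_decade`` is :data:`~vcclek.survey_model.PRE_BASELINE` or the
    fisher's first active decade.  Entrants at or before the 1980s are
    anchored at 1; later entrants are anchored at
    ``cohort_baselines[previous decade]``, which must then be supplied.
    Responses must be in chronological order and cover contiguous decades
    starting at the entry decade.
    """
    decades = [r.decade for r in responses]
    if not decades:
        raise ValueError("no responses to cascade")
    first = PRE_BASELINE if entry_decade == PRE_BASELINE else entry_decade
    start = "1980s" if first == PRE_BASELINE else first
    idx = DECADES.index(start)
    expected = list(DECADES[idx: idx + len(decades)])
    if decades != expected:
        raise ValueError(
            f"responses cover {decades}, expected contiguous {expected}"
        )
    if entry_decade == PRE_BASELINE or entry_decade == "1980s":
        anchor = 1.0
    else:
        prev = DECADES[DECADES.index(entry_decade) - 1]
        if cohort_baselines is None or prev not in cohort_baselines:
            raise ValueError(
                f"entry in {entry_decade} requires a cohort baseline for {prev}"
            )
        anchor = cohort_baselines[prev]
    fractions = {r.decade: score_to_signed_fraction(r, impute_midpoints)
                 for r in responses}
    return VccTrajectory(fisher_id, stratum, _cascade(fractions, anchor), anchor)


# ---------------------------------------------------------------------------
# Cohort construction with iterative shifting-baseline anchoring

def _overall_fractions(rec: InterviewRecord,
                       impute_midpoints: Mapping[str, float] | None
                       ) -> dict[str, float]:
    """A fisher's per-decade signed fraction for the overall stratum.

    Uses the fisher's general perception when elicited; otherwise the mean
    signed fraction across their per-species responses (derived mode).
    """
    if "overall" in rec.responses:
        return {r.decade: score_to_signed_fraction(r, impute_midpoints)
                for r in rec.responses["overall"]}
    per_decade: dict[str, list[float]] = {}
    for stratum, resps in rec.responses.items():
        for r in resps:
            per_decade.setdefault(r.decade, []).append(
                score_to_signed_fraction(r, impute_midpoints))
    return {d: float(np.mean(v)) for d, v in per_decade.items()}


def _stratum_fractions(rec: InterviewRecord, stratum: str,
                       impute_midpoints: Mapping[str, float] | None
                       ) -> dict[str, float] | None:
    """Fractions for one record under a stratum label, or None if not a member."""
    if stratum == "overall":
        if not rec.responses:
            return None
        return _overall_fractions(rec, impute_midpoints)
    kind, _, label = stratum.partition(":")
    if kind == "gear":
        if label not in rec.gears or not rec.responses:
            return None
        return _overall_fractions(rec, impute_midpoints)
    if kind == "species":
        if label not in rec.responses:
            return None
        return {r.decade: score_to_signed_fraction(r, impute_midpoints)
                for r in rec.responses[label]}
    raise ValueError(f"unknown stratum {stratum!r}")


def build_trajectories(records: Iterable[InterviewRecord],
                       stratum: str = "overall",
                       baseline_weighting: bool = True,
                       impute_midpoints: Mapping[str, float] | None = None
                       ) -> list[VccTrajectory]:
    """Cascade every member of a stratum, anchoring late entrants in turn.

    Strata are ``"overall"``, ``"gear:<label>"`` or ``"species:<label>"``;
    cohort baselines are computed within the stratum being built, decade by
    decade, so per-gear trends use per-gear baselines.  With
    ``baseline_weighting=False`` every fisher is naively anchored at 1
    (useful to quantify the shifting-baseline bias).
    """
    members: list[tuple[InterviewRecord, dict[str, float], str]] = []
    for rec in records:
        fr = _stratum_fractions(rec, stratum, impute_midpoints)
        if fr is None or not fr:
            continue
        entry = active_decades(rec.interview_year, rec.experience).entry_decade
        members.append((rec, fr, entry))

    # Anchor early entrants at 1; late entrants at the running cohort mean of
    # the previous decade (falling back to 1 when weighting is disabled).
    anchors: dict[str, float] = {}
    cascaded: dict[str, dict[str, float]] = {}
    for k, dec in enumerate(DECADES):
        if dec != "1980s" and baseline_weighting:
            prev = DECADES[k - 1]
            prev_vals = [v[prev] for v in cascaded.values() if prev in v]
            baseline = float(np.mean(prev_vals)) if prev_vals else None
        else:
            baseline = None
        for rec, fr, entry in members:
            first = "1980s" if entry == PRE_BASELINE else entry
            if first != dec:
                continue
            if dec == "1980s" or not baseline_weighting:
                anchors[rec.fisher_id] = 1.0
            else:
                if baseline is None:
                    raise ValueError(
                        f"{rec.fisher_id}: no {prev} trajectories available to "
                        f"anchor a {dec} entrant"
                    )
                anchors[rec.fisher_id] = baseline
            cascaded[rec.fisher_id] = _cascade(fr, anchors[rec.fisher_id])

    return [VccTrajectory(rec.fisher_id, stratum, cascaded[rec.fisher_id],
                          anchors[rec.fisher_id])
            for rec, fr, entry in members if rec.fisher_id in cascaded]


# ---------------------------------------------------------------------------
# Aggregation and trends

@dataclass
class DecadalAggregate:
    """Per-decade mean, sample standard deviation and cohort size."""

    stratum: str
    stats: dict[str, tuple[float, float, int]] = field(default_factory=dict)

    def means(self, decades: Sequence[str] = DECADES) -> list[float]:
        return [self.stats[d][0] for d in decades if d in self.stats]


def cohort_aggregate(trajectories: Sequence[VccTrajectory],
                     stratum: str | None = None) -> DecadalAggregate:
    """Mean, sd (n-1 denominator; 0 when n = 1) and n per decade."""
    if not trajectories:
        raise ValueError("no trajectories to aggregate")
    label = stratum if stratum is not None else trajectories[0].stratum
    stats: dict[str, tuple[float, float, int]] = {}
    for dec in DECADES:
        vals = np.array([t.values[dec] for t in trajectories if dec in t.values])
        if vals.size == 0:
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        stats[dec] = (float(vals.mean()), sd, int(vals.size))
    return DecadalAggregate(label, stats)


def relative_change(new_value: float, reference_value: float) -> float:
    """Signed percent change of ``new_value`` relative to ``reference_value``."""
    if reference_value == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (new_value - reference_value) / reference_value


@dataclass(frozen=True)
class TrendFit:
    """Cubic least-squares fit over decade indices.

    ``coefficients`` are ascending (c0 + c1*x + c2*x**2 + c3*x**3); the
    abscissa is the decade index, 0 being the pre-1980s baseline point.
    """

    coefficients: tuple[float, float, float, float]
    domain: tuple[float, ...]

    def predict(self, x: float | np.ndarray) -> np.ndarray:
        return P.polyval(x, np.asarray(self.coefficients))


def fit_decadal_trend(aggregate: DecadalAggregate,
                      include_baseline: bool = True) -> TrendFit:
    """Ordinary least-squares cubic through the decadal means.

    With ``include_baseline`` the anchor point (index 0, value 1) is
    prepended.  At exactly four points the cubic interpolates.
    """
    xs: list[float] = []
    ys: list[float] = []
    if include_baseline:
        xs.append(0.0)
        ys.append(1.0)
    for dec in DECADES:
        if dec in aggregate.stats:
            xs.append(float(DECADES.index(dec) + 1))
            ys.append(aggregate.stats[dec][0])
    if len(xs) < 4:
        raise ValueError(f"cubic fit needs >= 4 points, got {len(xs)}")
    coeffs = P.polyfit(np.array(xs), np.array(ys), 3)
    return TrendFit(tuple(float(c) for c in coeffs), tuple(xs))


def driver_frequency_ranking(records: Iterable[InterviewRecord]
                             ) -> list[tuple[str, int]]:
    """Rank coded decline drivers by how many fishers cite them.

    Each fisher contributes each driver at most once; ties are broken
    alphabetically.
    """
    counts: Counter[str] = Counter()
    for rec in records:
        counts.update(set(rec.drivers))
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
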