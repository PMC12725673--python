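"""Survey sampling design: Yamane sample sizes and coverage accounting.

Sample sizes follow the classical finite-population formula

    n = N / (1 + N * e**2)

with precision ``e`` (default +/-10 %).  Because no single authoritative
count of fishers exists per village, a village's target effort aggregates
several population sources: the per-source (unrounded) sample sizes are
averaged, and the mean together with the smallest and largest per-source
values is rounded half-to-even.  Missing sources are simply skipped, never
imputed as zero.

Two printed values in the study's tables are not reproducible from the
stated definitions; they are recorded in :data:`KNOWN_PRINTED_MISMATCHES`
so downstream checks can assert the discrepancy explicitly instead of
silently passing or failing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class PopulationSource:
    """One source's count of fishers for one village."""

    village: str
    source_label: str
    N: int

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"{self.village}/{self.source_label}: N must be >= 1")


@dataclass(frozen=True)
class SamplingEffort:
    """A village's target sampling effort aggregated over sources."""

    village: str
    mean_n: int
    min_n: int
    max_n: int
    raw_n: tuple[float, ...]


#: Printed table values that the stated computation does not reproduce.
#: Keys are (table, village, column); values are (printed, computed) pairs.
#: - The village-roster table prints a coverage of 164 % for Canaveral while
#:   41 interviewed / target 24 gives 171 % (164 % would require a target of
#:   25, i.e. the unrounded mean before rounding).
#: - The sampling-effort table prints a mean of 24 for Canaveral while the
#:   mean of the four unrounded sample sizes is 24.51 -> 25 under every
#:   defensible rounding; a one-unit typo in the third source (39 vs 38)
#:   would yield the printed value.
KNOWN_PRINTED_MISMATCHES: dict[tuple[str, str, str], tuple[int, int]] = {
    ("sampling_effort", "Cañaveral", "mean_n"): (24, 25),
    ("coverage", "Cañaveral", "coverage_pct"): (164, 171),
}


def _round_half_even(x: float) -> int:
    return int(np.round(x))


def yamane_sample_size(N: int, e: float = 0.10) -> float:
    """Unrounded Yamane sample size n = N / (1 + N * e**2).

    Strictly increasing in ``N`` and bounded above by ``1 / e**2`` for
    ``e > 0``; ``e = 0`` degenerates to a census (n = N).
    """
    if N < 1:
        raise ValueError("population size N must be >= 1")
    if not 0.0 <= e <= 1.0:
        raise ValueError("precision e must lie in [0, 1]")
    return N / (1.0 + N * e * e)


def aggregate_sampling_effort(sources: Sequence[PopulationSource],
                              e: float = 0.10) -> SamplingEffort:
    """Aggregate per-source Yamane sizes into a village target.

    Mean, minimum and maximum are taken over the *unrounded* per-source
    sample sizes and each rounded half-to-even.  All sources must belong to
    the same village.
    """
    if not sources:
        raise ValueError("at least one population source is required")
    villages = {s.village for s in sources}
    if len(villages) > 1:
        raise ValueError(f"sources span several villages: {sorted(villages)}")
    raw = tuple(yamane_sample_size(s.N, e) for s in sources)
    return SamplingEffort(
        village=sources[0].village,
        mean_n=_round_half_even(float(np.mean(raw))),
        min_n=_round_half_even(min(raw)),
        max_n=_round_half_even(max(raw)),
        raw_n=raw,
    )


def coverage_ratio(interviewed: int, target: SamplingEffort | int) -> int:
    """Sample-size coverage: interviewed / target mean, as a rounded percent."""
    mean_n = target.mean_n if isinstance(target, SamplingEffort) else int(target)
    if interviewed < 0:
        raise ValueError("interviewed count must be >= 0")
    if mean_n < 1:
        raise ValueError("target mean sample size must be >= 1")
    return _round_half_even(100.0 * interviewed / mean_n)


# ---------------------------------------------------------------------------
# Table I/O

def load_population_sources(path: str | Path) -> list[PopulationSource]:
    """Read a (village, source_label, N) table; blank or '---' N is skipped."""
    out: list[PopulationSource] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            raw = (row.get("N") or "").strip().replace(",", "")
            if not raw or raw == "---":
                continue
            out.append(PopulationSource(row["village"].strip(),
                                        row["source_label"].strip(), int(raw)))
    return out


def sampling_effort_table(sources: Iterable[PopulationSource],
                          e: float = 0.10) -> "pd.DataFrame":
    """Per-village effort table (village, mean_n, min_n, max_n, n_sources).

    Villages appear in first-seen order, mirroring the layout of a printed
    sampling-effort table.
    """
    import pandas as pd

    by_village: dict[str, list[PopulationSource]] = {}
    for s in sources:
        by_village.setdefault(s.village, []).append(s)
    rows = []
    for village, srcs in by_village.items():
        eff = aggregate_sampling_effort(srcs, e)
        rows.append({"village": village, "mean_n": eff.mean_n,
                     "min_n": eff.min_n, "max_n": eff.max_n,
                     "n_sources": len(srcs)})
    return pd.DataFrame(rows)
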