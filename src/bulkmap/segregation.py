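"""Mendelian segregation analysis of trimodal plant heights.

Continuous heights are classified as tall / semi-dwarf / dwarf by fixed
thresholds and the class counts are tested against candidate Mendelian
ratios with an uncorrected chi-squared goodness-of-fit test.  For a
semi-dominant single-gene trait the F2 segregates 1:2:1 and the two
backcrosses 1:1:0 (to the tall parent) and 0:1:1 (to the dwarf parent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

CLASS_NAMES = ("tall", "semi_dwarf", "dwarf")


@dataclass(frozen=True)
class HeightClassRule:
    """Height thresholds in cm: >= tall_min is tall, <= dwarf_max is dwarf.

    Boundary values belong to the extreme classes (tall wins at the tall
    threshold, dwarf wins at the dwarf threshold), which keeps the three
    classes mutually exclusive.
    """

    dwarf_max_cm: float = 110.0
    tall_min_cm: float = 170.0

    def __post_init__(self):
        if not self.dwarf_max_cm < self.tall_min_cm:
            raise ValueError("dwarf_max_cm must be below tall_min_cm")


@dataclass(frozen=True)
class RatioHypothesis:
    """A Mendelian ratio over (tall, semi-dwarf, dwarf), e.g. 1:2:1."""

    name: str
    expected: tuple[float, ...]

    def __post_init__(self):
        if any(r < 0 for r in self.expected) or sum(self.expected) <= 0:
            raise ValueError("ratio entries must be non-negative, not all zero")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    observed: tuple[int, ...]
    expected: tuple[float, ...]


class RatioViolationError(ValueError):
    """Observed counts in a class the hypothesis declares impossible."""


CANDIDATE_RATIOS: tuple[RatioHypothesis, ...] = tuple(
    RatioHypothesis(":".join(str(int(r)) for r in ratio), ratio)
    for ratio in [
        (1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 2, 1),
        (1, 1, 0), (0, 1, 1), (3, 0, 1), (1, 0, 3),
    ]
)


def classify_heights(heights: Sequence[float],
                     rule: HeightClassRule = HeightClassRule()) -> tuple[int, int, int]:
    """Count (tall, semi-dwarf, dwarf) plants from heights in cm."""
    h = np.asarray(list(heights), dtype=float)
    if h.size == 0:
        raise ValueError("no heights supplied")
    if not np.all(np.isfinite(h)) or np.any(h < 0):
        raise ValueError("heights must be finite and non-negative")
    tall = int(np.sum(h >= rule.tall_min_cm))
    dwarf = int(np.sum(h <= rule.dwarf_max_cm))
    semi = int(h.size - tall - dwarf)
    return tall, semi, dwarf


def chi_square_gof(observed: Sequence[int],
                   hypothesis: RatioHypothesis,
                   total: int | None = None) -> ChiSquareResult:
    """Uncorrected chi-squared goodness-of-fit against a Mendelian ratio.

    Classes with a zero expected ratio are dropped from the statistic and
    the degrees of freedom; observed counts in such a class raise
    :class:`RatioViolationError` (a qualitatively different outcome from a
    large statistic).

    ``total`` sets the population size the expected counts are derived
    from; it defaults to the sum of the observed counts but may be larger
    when some individuals of a scored population could not be assigned to
    a height class.
    """
    obs = np.asarray(list(observed), dtype=float)
    ratio = np.asarray(hypothesis.expected, dtype=float)
    if obs.shape != ratio.shape:
        raise ValueError("observed counts do not align with hypothesis classes")
    if obs.sum() <= 0:
        raise ValueError("total observed count must be positive")
    if total is None:
        total = obs.sum()
    elif total < obs.sum():
        raise ValueError("total cannot be below the sum of observed counts")
    zero = ratio == 0
    if np.any(obs[zero] > 0):
        raise RatioViolationError(
            f"observed counts present in zero-expected class under {hypothesis.name}"
        )
    keep = ~zero
    o = obs[keep]
    e = float(total) * ratio[keep] / ratio.sum()
    df = int(keep.sum()) - 1
    if df == 0:
        stat, p = 0.0, 1.0
    else:
        stat = float(((o - e) ** 2 / e).sum())
        p = float(stats.chi2.sf(stat, df))
    expected_full = np.zeros_like(obs)
    expected_full[keep] = e
    return ChiSquareResult(
        statistic=stat, df=df, p_value=p,
        observed=tuple(int(x) for x in obs),
        expected=tuple(float(x) for x in expected_full),
    )


@dataclass
class PopulationFit:
    population: str
    observed: tuple[int, int, int]
    results: dict[str, ChiSquareResult]  # only ratios not violated
    accepted: list[str]  # names of ratios not rejected at alpha
    best: str | None  # accepted ratio with the largest p-value


def _canonical(name: str) -> str:
    return name.lower().replace("_", "").replace("-", "")


# backcross to the tall parent segregates tall:semi 1:1; to the dwarf
# parent semi:dwarf 1:1
_EXPECTED_BACKCROSS = {"b11": "1:1:0", "b12": "0:1:1"}


def select_inheritance_model(
    populations: Mapping[str, Sequence[int]],
    alpha: float = 0.05,
    candidates: Sequence[RatioHypothesis] = CANDIDATE_RATIOS,
) -> dict:
    """Fit candidate Mendelian ratios per population and give a verdict.

    Returns a dict with per-population :class:`PopulationFit` objects and an
    overall ``verdict``: "single semi-dominant gene" when the F2 is
    consistent with 1:2:1 and every supplied backcross with its 1:1
    expectation; "not segregating" when the F2 is monomorphic;
    otherwise "inconclusive".
    """
    if not populations:
        raise ValueError("at least one population required")
    fits: dict[str, PopulationFit] = {}
    warnings: list[str] = []
    for name, counts in populations.items():
        counts = tuple(int(c) for c in counts)
        if sum(counts) == 0:
            warnings.append(f"population {name} is empty; skipped")
            continue
        results: dict[str, ChiSquareResult] = {}
        accepted: list[str] = []
        for hyp in candidates:
            try:
                res = chi_square_gof(counts, hyp)
            except RatioViolationError:
                continue
            results[hyp.name] = res
            if res.p_value >= alpha:
                accepted.append(hyp.name)
        best = max(accepted, key=lambda n: results[n].p_value) if accepted else None
        fits[name] = PopulationFit(name, counts, results, accepted, best)

    verdict = "inconclusive"
    f2 = next((f for n, f in fits.items() if _canonical(n) == "f2"), None)
    if f2 is not None:
        monomorphic = sum(c > 0 for c in f2.observed) == 1
        if monomorphic:
            verdict = "not segregating"
        elif "1:2:1" in f2.accepted:
            ok = True
            for name, fit in fits.items():
                want = _EXPECTED_BACKCROSS.get(_canonical(name))
                if want is not None and want not in fit.accepted:
                    ok = False
            if ok:
                verdict = "single semi-dominant gene"
    return {"populations": fits, "verdict": verdict, "warnings": warnings}
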