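"""Interval PLS: equal-width spectral intervals, one cross-validated PLS
model per interval, minimum-RMSECV interval selection.

Interval PLS is a variable-selection device for spectra whose informative
chemistry is confined to a sub-band: fitting each block of adjacent
frequency variables separately and ranking blocks by leave-one-out RMSECV
both localises the informative region and usually beats the full-spectrum
model, which must carry every noisy, irrelevant variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .containers import SpectraMatrix
from .pls import PLSModel, fit_pls, loo_cv

__all__ = [
    "IntervalSpec",
    "IntervalResult",
    "IntervalReport",
    "partition",
    "interval_frequencies",
    "run_ipls",
]


@dataclass(frozen=True)
class IntervalSpec:
    """Partition of the variable axis into equal-width blocks.

    ``intervals`` holds 1-based inclusive (start, end) index pairs; any
    remainder when the width does not divide the variable count is merged
    into the final interval.
    """

    n_variables_total: int
    interval_width: int
    intervals: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for s, e in self.intervals:
            if s != prev_end + 1 or e < s:
                raise ValueError("intervals must be ordered, disjoint, covering")
            prev_end = e
        if prev_end != self.n_variables_total:
            raise ValueError("intervals must cover all variables")

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class IntervalResult:
    """Cross-validation outcome of one interval's PLS model."""

    index: int                 # 1-based interval number
    start: int                 # 1-based first variable
    end: int                   # 1-based last variable
    f_lo: float                # THz
    f_hi: float                # THz
    n_components: int
    rmsecv: float
    r: float


@dataclass(frozen=True)
class IntervalReport:
    """Per-interval RMSECV table plus the selected interval and its model."""

    spec: IntervalSpec
    results: Tuple[IntervalResult, ...]
    selected_index: int
    selected_model: PLSModel
    full_spectrum_rmsecv: float
    full_spectrum_r: float

    def __post_init__(self) -> None:
        if len(self.results) != self.spec.n_intervals:
            raise ValueError("one result row per interval required")
        best = min(r.rmsecv for r in self.results)
        sel = self.results[self.selected_index - 1]
        if sel.rmsecv > best + 1e-12:
            raise ValueError("selected interval does not attain minimum RMSECV")

    @property
    def selected(self) -> IntervalResult:
        return self.results[self.selected_index - 1]

    def to_frame(self) -> pd.DataFrame:
        """Flat table (one row per interval) suitable for re-plotting."""
        return pd.DataFrame(
            [
                {
                    "interval": r.index,
                    "start": r.start,
                    "end": r.end,
                    "f_lo_THz": r.f_lo,
                    "f_hi_THz": r.f_hi,
                    "factors": r.n_components,
                    "rmsecv": r.rmsecv,
                    "r": r.r,
                    "selected": r.index == self.selected_index,
                }
                for r in self.results
            ]
        )


def partition(n_variables: int, interval_width: int) -> IntervalSpec:
    """Split ``n_variables`` into consecutive blocks of ``interval_width``.

    A remainder shorter than one width is merged into the last interval,
    so all intervals except possibly the last have exactly
    ``interval_width`` variables.
    """
    if not 1 <= interval_width <= n_variables:
        raise ValueError(
            f"interval_width must be in 1..{n_variables}, got {interval_width}"
        )
    n_full = n_variables // interval_width
    intervals = [
        (i * interval_width + 1, (i + 1) * interval_width) for i in range(n_full)
    ]
    if n_variables % interval_width:
        intervals[-1] = (intervals[-1][0], n_variables)
    return IntervalSpec(n_variables, interval_width, tuple(intervals))


def interval_frequencies(
    spec: IntervalSpec, variable_frequencies: np.ndarray
) -> List[Tuple[float, float]]:
    """Frequency span [f_first, f_last] of each interval, in THz."""
    f = np.asarray(variable_frequencies, float)
    if f.size != spec.n_variables_total:
        raise ValueError(
            f"got {f.size} frequencies for {spec.n_variables_total} variables"
        )
    return [(float(f[s - 1]), float(f[e - 1])) for s, e in spec.intervals]


def run_ipls(
    X: SpectraMatrix,
    interval_width: int,
    n_components: int,
    full_cv: Optional[Tuple[float, float]] = None,
) -> IntervalReport:
    """Fit and LOO-cross-validate one PLS model per interval; select the
    interval with minimum RMSECV (ties broken by lowest interval index).

    Per-interval factor counts are capped at the interval's variable count
    (NIPALS cannot extract more components than variables). The
    full-spectrum RMSECV is computed for comparison unless supplied.
    """
    spec = partition(X.n_variables, interval_width)
    franges = interval_frequencies(spec, X.variable_frequencies)

    if full_cv is None:
        cv = loo_cv(X, min(n_components, X.n_variables, X.n_samples - 2))
        full_rmsecv, full_r = cv.rmsecv, cv.r
    else:
        full_rmsecv, full_r = full_cv

    results: List[IntervalResult] = []
    for i, ((s, e), (flo, fhi)) in enumerate(zip(spec.intervals, franges), 1):
        Xi = X.select_variables(s, e)
        a = min(n_components, Xi.n_variables, Xi.n_samples - 2)
        try:
            cv = loo_cv(Xi, a)
        except ValueError as exc:
            raise ValueError(f"interval {i} ({s}-{e}): {exc}") from exc
        results.append(IntervalResult(i, s, e, flo, fhi, a, cv.rmsecv, cv.r))

    rmsecvs = np.array([r.rmsecv for r in results])
    selected = int(np.argmin(rmsecvs)) + 1  # argmin takes the first minimum
    s, e = spec.intervals[selected - 1]
    Xs = X.select_variables(s, e)
    model = fit_pls(Xs, min(n_components, Xs.n_variables, Xs.n_samples - 1))
    return IntervalReport(
        spec=spec,
        results=tuple(results),
        selected_index=selected,
        selected_model=model,
        full_spectrum_rmsecv=full_rmsecv,
        full_spectrum_r=full_r,
    )
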