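"""Cohort readout statistics: rectangular gating, fold conversion, the
two-tailed Mann-Whitney U (Wilcoxon rank-sum) test, and the per-gene
upregulated-cell-fraction statistic for grouped single-cell counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import ParameterError, SchemaError, UndefinedFoldError

#: combined sample size at or below which the exact (enumeration) null
#: distribution of U is used when there are no ties.
EXACT_ENUMERATION_LIMIT = 12


@dataclass
class GateDefinition:
    """Rectangular gate: an event is positive iff it exceeds every threshold."""

    thresholds: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.thresholds:
            raise ParameterError("gate needs at least one channel threshold")
        for channel, value in self.thresholds.items():
            if not np.isfinite(value) and not np.isinf(value):
                raise ParameterError(f"threshold for {channel!r} must not be NaN")


@dataclass
class ConversionResult:
    fraction_treated: float
    fraction_control: float
    fold: float
    n_treated: int
    n_control: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class UpregulationResult:
    gene: str
    threshold: float | None
    fraction_above: float | None  # percent of query cells strictly above
    n_ref_used: int
    n_ref_excluded: int
    n_query: int = 0
    evaluable: bool = True

    def to_dict(self) -> dict:
        return self.__dict__.copy()


class MannWhitneyResult(NamedTuple):
    u: float
    p: float
    method: str = "exact"


def _event_frame(events) -> pd.DataFrame:
    """Accept a FlowEventTable-like object or a bare DataFrame."""
    frame = getattr(events, "events", events)
    if not isinstance(frame, pd.DataFrame):
        raise ParameterError("events must be a DataFrame or FlowEventTable")
    return frame


def gate_fraction(events, gate: GateDefinition) -> float:
    """Fraction of events strictly exceeding every gate threshold."""
    frame = _event_frame(events)
    if frame.empty:
        raise ParameterError("event table has no events")
    mask = np.ones(len(frame), dtype=bool)
    for channel, threshold in gate.thresholds.items():
        if channel not in frame.columns:
            raise SchemaError(f"gate channel {channel!r} missing from event table")
        mask &= frame[channel].to_numpy() > threshold
    return float(mask.mean())


def fold_conversion(treated, control, gate: GateDefinition) -> ConversionResult:
    """Ratio of gated-positive fractions, treated over control.

    Computed on fractions rather than counts so unequal acquisition depths
    cancel. A zero control fraction raises rather than returning infinity.
    """
    f_treated = gate_fraction(treated, gate)
    f_control = gate_fraction(control, gate)
    if f_control == 0:
        raise UndefinedFoldError("control group has no gated-positive events")
    return ConversionResult(
        fraction_treated=f_treated,
        fraction_control=f_control,
        fold=f_treated / f_control,
        n_treated=len(_event_frame(treated)),
        n_control=len(_event_frame(control)),
    )


def _exact_two_sided_p(u_obs: float, n_x: int, n_y: int) -> float:
    """P(|U - n_x*n_y/2| >= |u_obs - n_x*n_y/2|) by enumerating rank splits.

    Valid only without ties; the null U distribution is then symmetric about
    n_x*n_y/2, so this equals twice the smaller tail.
    """
    n = n_x + n_y
    center = n_x * n_y / 2.0
    dev = abs(u_obs - center) - 1e-9  # tolerate float fuzz at the boundary
    hits = 0
    total = 0
    offset = n_x * (n_x + 1) // 2
    for combo in itertools.combinations(range(1, n + 1), n_x):
        u = sum(combo) - offset
        total += 1
        if abs(u - center) >= dev:
            hits += 1
    return hits / total


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    U is the statistic of the first sample (U_x = R_x - n_x(n_x+1)/2). The
    p-value is exact by enumeration when n_x + n_y <= 12 and no ties are
    present, otherwise a normal approximation with tie and continuity
    corrections is used.
    """
    if alternative != "two-sided":
        raise ParameterError("only the two-sided alternative is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    u_x = float(ranks[:n_x].sum() - n_x * (n_x + 1) / 2.0)

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if not has_ties and n_x + n_y <= EXACT_ENUMERATION_LIMIT:
        p = _exact_two_sided_p(u_x, n_x, n_y)
        return MannWhitneyResult(u=u_x, p=p, method="exact")

    n = n_x + n_y
    mean_u = n_x * n_y / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var_u = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:  # all observations identical
        return MannWhitneyResult(u=u_x, p=1.0, method="normal")
    # continuity correction shrinks |U - mean| by 0.5
    dev = abs(u_x - mean_u)
    z = max(dev - 0.5, 0.0) / np.sqrt(var_u)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return MannWhitneyResult(u=u_x, p=p, method="normal")


def isg_upregulated_fraction(
    counts,
    gene: str,
    query_group: str,
    ref_group: str,
) -> UpregulationResult:
    """Percent of query cells strictly above the reference nonzero mean.

    The threshold is the mean expression of reference-group cells with a
    detectable (count > 0) signal; reference cells with zero counts are
    excluded from the mean. If every reference cell is zero the gene is
    flagged non-evaluable instead of raising.
    """
    vec = counts.gene_vector(gene)
    groups = np.asarray(counts.groups)
    q_mask = groups == query_group
    r_mask = groups == ref_group
    if not q_mask.any():
        raise SchemaError(f"query group {query_group!r} has no cells")
    if not r_mask.any():
        raise SchemaError(f"reference group {ref_group!r} has no cells")

    ref = vec[r_mask]
    ref_nonzero = ref[ref > 0]
    n_excluded = int(ref.size - ref_nonzero.size)
    if ref_nonzero.size == 0:
        return UpregulationResult(
            gene=gene,
            threshold=None,
            fraction_above=None,
            n_ref_used=0,
            n_ref_excluded=n_excluded,
            n_query=int(q_mask.sum()),
            evaluable=False,
        )
    threshold = float(ref_nonzero.mean())
    query = vec[q_mask]
    fraction = 100.0 * float((query > threshold).mean())
    return UpregulationResult(
        gene=gene,
        threshold=threshold,
        fraction_above=fraction,
        n_ref_used=int(ref_nonzero.size),
        n_ref_excluded=n_excluded,
        n_query=int(query.size),
        evaluable=True,
    )
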