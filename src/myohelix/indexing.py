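"""Scoring observed layer-line spacings against candidate helical repeats.

The adjudication between the historical 72 nm repeat and the proposed
172 nm repeat: each observed spacing d is assigned the order
``l = round(c / d)`` for candidate repeat c, and candidates are ranked by
the reciprocal-space least-squares residual ``sum (1/d - l/c)^2``.
Residuals are computed in reciprocal space because spectral bin error is
uniform in frequency, not in spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .helix import ParameterError

__all__ = ["CandidateScore", "IndexingResult", "index_repeats"]

#: Observations assigned orders beyond this are excluded from the residual.
MAX_ORDER = 24


@dataclass(frozen=True)
class CandidateScore:
    repeat: float
    orders: tuple[int, ...]  # assigned order per observation (0 = excluded)
    residual: float  # summed squared reciprocal-space misfit
    n_indexed: int

    @property
    def mean_residual(self) -> float:
        return self.residual / self.n_indexed if self.n_indexed else float("inf")


@dataclass(frozen=True)
class IndexingResult:
    candidates: tuple[CandidateScore, ...]
    best_repeat: float
    margin: float  # best residual / second-best residual (0 when unique fit)

    def score_for(self, repeat: float) -> CandidateScore:
        for cand in self.candidates:
            if cand.repeat == repeat:
                return cand
        raise KeyError(repeat)


def index_repeats(
    observed: Sequence[float],
    candidates: Sequence[float],
    max_order: int = MAX_ORDER,
) -> IndexingResult:
    """Rank candidate repeats by reciprocal-space residual.

    Candidates are ranked by the *mean* squared residual over the
    observations they index, so a candidate cannot win merely by excluding
    most observations (a short spacing assigned an order beyond
    ``max_order`` does not count against the candidate that excluded it).
    Ties break to the candidate indexing more observations, then to the
    smaller repeat.  A candidate that indexes nothing scores infinity.
    """
    if len(observed) == 0 or len(candidates) == 0:
        raise ParameterError("need at least one observation and one candidate")
    if any(d <= 0 for d in observed) or any(c <= 0 for c in candidates):
        raise ParameterError("spacings and repeats must be positive")

    scores: list[CandidateScore] = []
    for c in candidates:
        orders: list[int] = []
        residual = 0.0
        n_indexed = 0
        for d in observed:
            l = max(int(round(c / d)), 1)
            if l > max_order:
                orders.append(0)
                continue
            orders.append(l)
            residual += (1.0 / d - l / c) ** 2
            n_indexed += 1
        scores.append(
            CandidateScore(
                repeat=float(c),
                orders=tuple(orders),
                residual=residual if n_indexed else float("inf"),
                n_indexed=n_indexed,
            )
        )

    ranked = sorted(scores, key=lambda s: (s.mean_residual, -s.n_indexed, s.repeat))
    best = ranked[0]
    if (
        len(ranked) > 1
        and np.isfinite(ranked[1].mean_residual)
        and ranked[1].mean_residual > 0
    ):
        margin = best.mean_residual / ranked[1].mean_residual
    else:
        margin = 0.0
    return IndexingResult(
        candidates=tuple(scores),
        best_repeat=best.repeat,
        margin=margin,
    )
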