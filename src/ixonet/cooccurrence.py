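"""Probabilistic pairwise co-occurrence of tick species over host families.

For two species using ``n_a`` and ``n_b`` of ``N`` host families, the number
of shared families under random, independent placement follows a
hypergeometric law.  Exact tail probabilities classify each pair as
*positive* (sharing more hosts than chance), *negative* (fewer), *random*
(compatible with chance), or *unclassifiable* when even the most extreme
attainable overlap could not reach significance in either tail (low power).
No multiple-testing correction is applied; pairs are screened one at a time.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import hypergeom

from .network import InteractionMatrix

__all__ = [
    "Classification",
    "CooccurrencePair",
    "pair_cooccurrence",
    "cooccurrence_matrix",
    "pairs_to_frame",
]


class Classification(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    RANDOM = "random"
    UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class CooccurrencePair:
    """Exact hypergeometric co-occurrence verdict for one species pair."""

    species_a: str
    species_b: str
    n_hosts_total: int
    n_a: int
    n_b: int
    observed_shared: int
    expected_shared: float
    p_lt: float  # P(J <= observed)
    p_gt: float  # P(J >= observed)
    classification: Classification


def pair_cooccurrence(
    n_a: int,
    n_b: int,
    j_obs: int,
    n_total: int,
    alpha: float = 0.05,
    species_a: str = "a",
    species_b: str = "b",
) -> CooccurrencePair:
    """Classify one species pair from its host-set sizes and observed overlap.

    ``J ~ Hypergeometric(N, n_a, n_b)`` is the null overlap.  Positive means
    ``P(J >= j_obs) < alpha``; negative means ``P(J <= j_obs) < alpha``.  A
    non-significant pair is *unclassifiable* when neither tail could reach
    ``alpha`` even at the most extreme attainable overlap, else *random*.
    """
    j_min = max(0, n_a + n_b - n_total)
    j_max = min(n_a, n_b)
    if not (0 <= n_a <= n_total and 0 <= n_b <= n_total):
        raise ValueError(f"host-set sizes out of range: n_a={n_a}, n_b={n_b}, N={n_total}")
    if not (j_min <= j_obs <= j_max):
        raise ValueError(
            f"observed overlap {j_obs} outside attainable range [{j_min}, {j_max}]"
        )
    dist = hypergeom(n_total, n_a, n_b)
    p_lt = float(dist.cdf(j_obs))
    p_gt = float(dist.sf(j_obs - 1))
    if p_gt < alpha:
        cls = Classification.POSITIVE
    elif p_lt < alpha:
        cls = Classification.NEGATIVE
    else:
        # power check: tails at the most extreme attainable overlaps
        min_p_gt = float(dist.pmf(j_max))
        min_p_lt = float(dist.pmf(j_min))
        powerless = min_p_gt >= alpha and min_p_lt >= alpha
        cls = Classification.UNCLASSIFIABLE if powerless else Classification.RANDOM
    return CooccurrencePair(
        species_a=species_a,
        species_b=species_b,
        n_hosts_total=n_total,
        n_a=n_a,
        n_b=n_b,
        observed_shared=j_obs,
        expected_shared=n_a * n_b / n_total,
        p_lt=p_lt,
        p_gt=p_gt,
        classification=cls,
    )


def cooccurrence_matrix(
    m: InteractionMatrix, alpha: float = 0.05
) -> list[CooccurrencePair]:
    """All unordered species pairs of an interaction matrix, classified.

    Uses the binary view (family-level incidence, stages merged); ``N`` is
    the number of host columns.
    """
    b = m.binary
    n_total = b.shape[1]
    results = []
    for i, j in itertools.combinations(range(b.shape[0]), 2):
        results.append(
            pair_cooccurrence(
                n_a=int(b[i].sum()),
                n_b=int(b[j].sum()),
                j_obs=int((b[i] & b[j]).sum()),
                n_total=n_total,
                alpha=alpha,
                species_a=m.row_labels[i],
                species_b=m.row_labels[j],
            )
        )
    return results


def pairs_to_frame(pairs: Sequence[CooccurrencePair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species_a": [p.species_a for p in pairs],
            "species_b": [p.species_b for p in pairs],
            "n_hosts_total": [p.n_hosts_total for p in pairs],
            "n_a": [p.n_a for p in pairs],
            "n_b": [p.n_b for p in pairs],
            "observed_shared": [p.observed_shared for p in pairs],
            "expected_shared": [p.expected_shared for p in pairs],
            "p_lt": [p.p_lt for p in pairs],
            "p_gt": [p.p_gt for p in pairs],
            "classification": [p.classification.value for p in pairs],
        }
    )
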