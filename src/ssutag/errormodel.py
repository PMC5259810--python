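"""Expected false-positive tag counts from single-base sequencing error.

Assuming a tag of interest is *not* actually present in the community,
reads reporting it can still arise from single sequencing errors in
tags one substitution away.  A 1-nt neighbour observed in ``n`` reads,
differing at tag position ``j`` where the observed per-base error
probability is ``e``, contributes ``E = n * e / 3`` expected reads
(the error is equally likely to produce any of the three alternative
bases).  Summing E over all 1-nt neighbours gives the expected
abundance of the focal tag due to one sequencing error; multiple-error
paths are negligible after per-base quality filtering and are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import BASES
from .scanner import TagObservation, phred_error_prob

__all__ = ["NeighborTerm", "expected_fp", "neighbor_terms",
           "position_error_profile"]


@dataclass(frozen=True)
class NeighborTerm:
    """Contribution of one 1-nt neighbour to a focal tag's expected
    false-positive count."""

    neighbor_tag: str
    n: int            # reads covering the neighbour
    position: int     # tag index where neighbour and focal tag differ
    e: float          # observed per-base error probability there

    @property
    def E(self) -> float:
        return self.n * self.e / 3.0


def position_error_profile(observations: Iterable[TagObservation],
                           tag_length: int = 33,
                           fallback_error: float = 0.001) -> np.ndarray:
    """Mean observed error probability at each tag position.

    Element ``j`` is the mean over observations of the Phred-implied
    error probability of tag base ``j``.  Observations without quality
    data (FASTA input) yield a constant ``fallback_error`` vector; the
    0.001 default corresponds to the Q30 filtering threshold.
    """
    total = np.zeros(tag_length)
    n = 0
    for ob in observations:
        if ob.tag_quals is None:
            continue
        qs = np.frombuffer(ob.tag_quals, dtype=np.uint8).astype(float)
        if len(qs) != tag_length:
            raise ValueError(f"tag quality length {len(qs)} != {tag_length}")
        total += 10.0 ** (-qs / 10.0)
        n += 1
    if n == 0:
        return np.full(tag_length, float(fallback_error))
    return total / n


def neighbor_terms(tag: str, counts: Mapping[str, int],
                   err: Sequence[float]) -> list[NeighborTerm]:
    """Observed 1-nt neighbours of ``tag`` with their contributions."""
    if len(tag) != len(err):
        raise ValueError(f"tag length {len(tag)} != error profile length "
                         f"{len(err)}")
    terms = []
    for j, orig in enumerate(tag):
        for b in BASES:
            if b == orig:
                continue
            nb = tag[:j] + b + tag[j + 1:]
            n = counts.get(nb, 0)
            if n:
                terms.append(NeighborTerm(nb, n, j, float(err[j])))
    return terms


def expected_fp(tag: str, counts: Mapping[str, int],
                err: Sequence[float]) -> float:
    """Expected count of ``tag`` arising from sequencing error alone.

    Enumerates all 3L single-substitution neighbours; neighbours not
    present in ``counts`` contribute nothing.
    """
    return sum(t.E for t in neighbor_terms(tag, counts, err))
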