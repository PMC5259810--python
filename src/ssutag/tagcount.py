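"""Per-sample aggregation of tag observations into ribotag records."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from . import errormodel
from .scanner import TagObservation

__all__ = ["TagRecord", "aggregate"]


@dataclass
class TagRecord:
    """Per-sample aggregate for one ribotag.

    ``n`` counts reads containing the tag; ``npos`` counts distinct RS
    offsets among those reads — a large ``n`` with a small ``npos`` is
    the signature of PCR-duplicated (or amplicon) reads.  ``fp`` is the
    expected number of reads showing this tag through sequencing error
    alone (see :mod:`ssutag.errormodel`).  The three most abundant long
    variants are tracked; a low ``long1_count``/``long_total_count``
    ratio suggests the tag represents a mixture of organisms.
    """

    tag: str
    n: int
    npos: int
    fp: float = 0.0
    long_total_count: int = 0
    long1_count: int = 0
    long2_count: int = 0
    long3_count: int = 0
    long1: str = ""
    long2: str = ""
    long_counts: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not (1 <= self.npos <= self.n):
            raise ValueError(f"require 1 <= npos <= n, got npos={self.npos} "
                             f"n={self.n}")
        if not (self.long1_count >= self.long2_count >= self.long3_count >= 0):
            raise ValueError("long variant counts must be non-increasing")
        if (self.long1_count + self.long2_count + self.long3_count
                > self.long_total_count or self.long_total_count > self.n):
            raise ValueError("inconsistent long variant counts")
        if self.fp < 0:
            raise ValueError("fp must be non-negative")


def aggregate(observations: list[TagObservation],
              sample_id: str | None = None,
              collapse_pairs: bool = False,
              fallback_error: float = 0.001) -> list[TagRecord]:
    """Aggregate one sample's observations into tag records.

    With ``collapse_pairs`` same-tag observations sharing a read name
    (paired-end mates both covering the tag) count once; by default
    mates are independent observations.  ``fp`` is filled from the
    sample-wide per-position error profile.
    """
    if sample_id is not None:
        wrong = {ob.sample_id for ob in observations} - {sample_id}
        if wrong:
            raise ValueError(f"observations from foreign samples: {wrong}")
    if collapse_pairs:
        seen: set[tuple[str, str]] = set()
        kept = []
        for ob in observations:
            key = (ob.read_id, ob.tag)
            if key in seen:
                continue
            seen.add(key)
            kept.append(ob)
        observations = kept
    if not observations:
        return []

    offsets: dict[str, set[int]] = {}
    counts: Counter[str] = Counter()
    longs: dict[str, Counter] = {}
    for ob in observations:
        counts[ob.tag] += 1
        offsets.setdefault(ob.tag, set()).add(ob.rs_offset)
        if ob.long_seq is not None:
            longs.setdefault(ob.tag, Counter())[ob.long_seq] += 1

    tag_length = len(next(iter(counts)))
    err = errormodel.position_error_profile(observations, tag_length,
                                            fallback_error)
    records = []
    for tag in sorted(counts):
        lc = longs.get(tag, Counter())
        # rank long variants by count, ties lexicographic
        ranked = sorted(lc.items(), key=lambda kv: (-kv[1], kv[0]))
        top = ranked[:3] + [("", 0)] * (3 - len(ranked))
        records.append(TagRecord(
            tag=tag,
            n=counts[tag],
            npos=len(offsets[tag]),
            fp=errormodel.expected_fp(tag, counts, err),
            long_total_count=sum(lc.values()),
            long1_count=top[0][1],
            long2_count=top[1][1],
            long3_count=top[2][1],
            long1=top[0][0],
            long2=top[1][0],
            long_counts=dict(lc),
        ))
    return records
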