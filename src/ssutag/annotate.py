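"""Tag -> taxonomy reference index, majority-vote annotation, concordance.

A reference index is built by scanning each (unaligned) reference
sequence exactly like a read — no quality gate — and keying every
detected tag and long sequence to the sequences and lineages that
contain it.  Observed tags are then annotated by walking the seven
ranks kingdom→species and taking the modal label at each rank among
the matching reference sequences; annotation stops at the first rank
where the modal fraction drops below the confidence cutoff (or ties).

*Concordance* of a tag at a rank is the modal-label fraction among its
reference sequences; a fully concordant tag (all sequences agree) has
concordance 1.  Empty labels are treated as missing and excluded from
denominators.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .profiles import RANKS, RecognitionProfile
from .scanner import ScanConfig, scan_reads

__all__ = ["ReferenceIndex", "TaxonAnnotation", "annotate_tag",
           "build_index", "concordance", "concordance_histogram",
           "default_bins", "load_index", "save_index"]

Entry = tuple[str, tuple[str, ...]]  # (seq_id, 7-rank lineage)


@dataclass
class ReferenceIndex:
    """Map from ribotag (and long sequence) to reference sequences."""

    entries: dict[str, list[Entry]] = field(default_factory=dict)
    long_entries: dict[str, list[Entry]] = field(default_factory=dict)
    regions: dict[str, str] = field(default_factory=dict)  # tag -> region
    source_db: str = "unknown"


@dataclass
class TaxonAnnotation:
    """A tag-level taxonomy call.

    ``support`` counts reference sequences containing the tag (or long
    sequence); ``confidence`` is the fraction of those agreeing at the
    emitted ``taxon_level``; ``taxon_data`` is the deepest rank for
    which the reference holds any label for this tag.
    """

    tag: str
    use: str = "tag"               # "tag" | "long"
    taxon_level: str = ""
    taxon_data: str = ""
    support: int = 0
    confidence: float = 0.0
    labels: dict = field(default_factory=lambda: {r: "" for r in RANKS})

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")
        seen_empty = False
        for r in RANKS:
            if self.labels.get(r, ""):
                if seen_empty:
                    raise ValueError("labels must be hierarchical: a deep "
                                     "rank implies all shallower ranks")
                if self.support < 1:
                    raise ValueError("non-empty labels require support >= 1")
            else:
                seen_empty = True


def build_index(ref_seqs: Sequence[tuple[str, str, tuple[str, ...]]],
                profiles: Sequence[RecognitionProfile],
                config: ScanConfig | None = None,
                source_db: str = "unknown") -> ReferenceIndex:
    """Scan reference sequences with the profiles and key every
    detected tag / long sequence to (seq_id, lineage).

    Emits an empty index (no error) when nothing is detectable.
    """
    config = config or ScanConfig()
    index = ReferenceIndex(source_db=source_db)
    lineages = {sid: lin for sid, _, lin in ref_seqs}
    obs, _ = scan_reads(((sid, seq) for sid, seq, _ in ref_seqs),
                        profiles, config, sample_id=source_db)
    for ob in obs:
        entry = (ob.read_id, tuple(lineages[ob.read_id]))
        index.entries.setdefault(ob.tag, []).append(entry)
        index.regions.setdefault(ob.tag, ob.region)
        if ob.long_seq is not None:
            index.long_entries.setdefault(ob.long_seq, []).append(entry)
    return index


def _modal(labels: list[str]) -> tuple[str, int, int, bool]:
    """(modal label, modal count, denominator, unique?) over non-empty
    labels."""
    present = [x for x in labels if x]
    if not present:
        return "", 0, 0, False
    counts = Counter(present)
    top = max(counts.values())
    winners = sorted(k for k, v in counts.items() if v == top)
    return winners[0], top, len(present), len(winners) == 1


def annotate_tag(tag: str,
                 long_seq: str | None,
                 index: ReferenceIndex,
                 min_confidence: float = 0.5) -> TaxonAnnotation:
    """Majority-vote annotation of one tag.

    The long sequence is looked up first (more specific context); when
    absent or unmatched, the short tag is used.  Labels are emitted
    down to the deepest rank where the modal fraction is at least
    ``min_confidence`` and the mode is unique (ties leave the rank
    unannotated).  Unmatched tags return empty labels with support 0.
    """
    matches = None
    use = "tag"
    if long_seq is not None and long_seq in index.long_entries:
        matches = index.long_entries[long_seq]
        use = "long"
    elif tag in index.entries:
        matches = index.entries[tag]
    if not matches:
        return TaxonAnnotation(tag=tag)

    lineages = [lin for _, lin in matches]
    taxon_data = ""
    for ri, rank in enumerate(RANKS):
        if any(lin[ri] for lin in lineages):
            taxon_data = rank

    labels = {r: "" for r in RANKS}
    taxon_level = ""
    confidence = 0.0
    for ri, rank in enumerate(RANKS):
        label, top, denom, unique = _modal([lin[ri] for lin in lineages])
        if denom == 0 or not unique:
            break
        frac = top / denom
        if frac < min_confidence:
            break
        labels[rank] = label
        taxon_level = rank
        confidence = frac
    return TaxonAnnotation(tag=tag, use=use, taxon_level=taxon_level,
                           taxon_data=taxon_data, support=len(matches),
                           confidence=confidence, labels=labels)


def concordance(index: ReferenceIndex, rank: str) -> dict[str, float]:
    """Per-tag modal-label fraction at one rank.

    Sequences with an empty label at the rank are excluded from the
    denominator; tags with an empty denominator are omitted.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
    ri = RANKS.index(rank)
    out = {}
    for tag, entries in index.entries.items():
        _, top, denom, _ = _modal([lin[ri] for _, lin in entries])
        if denom:
            out[tag] = top / denom
    return out


def default_bins() -> list[tuple[float, float]]:
    """Concordance bins: the exact bin {1} first, then [0.95, 1),
    [0.90, 0.95), ... down to [0, 0.05)."""
    bins = [(1.0, 1.0)]
    hi = 1.0
    while hi > 0:
        lo = round(hi - 0.05, 10)
        bins.append((max(lo, 0.0), hi))
        hi = lo
    return bins


def concordance_histogram(values: dict[str, float],
                          bins: list[tuple[float, float]] | None = None
                          ) -> list[tuple[tuple[float, float], float]]:
    """Percentage of tags per concordance bin (sums to 100 up to
    rounding); an empty input yields an all-zero histogram."""
    bins = bins if bins is not None else default_bins()
    n = len(values)
    counts = [0] * len(bins)
    for v in values.values():
        for i, (lo, hi) in enumerate(bins):
            exact = lo == hi
            if (exact and v == lo) or (not exact and lo <= v < hi):
                counts[i] += 1
                break
    return [(b, 100.0 * c / n if n else 0.0) for b, c in zip(bins, counts)]


def save_index(index: ReferenceIndex, path) -> None:
    """Serialize to a versioned TSV (kind, key, region, seq_id, lineage)."""
    with open(path, "w") as fh:
        fh.write(f"#ssutag-index\tv1\t{index.source_db}\n")
        fh.write("kind\tkey\tregion\tseq_id\tlineage\n")
        for kind, entries in (("tag", index.entries),
                              ("long", index.long_entries)):
            for key in sorted(entries):
                region = index.regions.get(key, "") if kind == "tag" else ""
                for sid, lin in entries[key]:
                    fh.write(f"{kind}\t{key}\t{region}\t{sid}\t"
                             f"{';'.join(lin)}\n")


def load_index(path) -> ReferenceIndex:
    index = ReferenceIndex()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header[0].startswith("#ssutag-index"):
            raise ValueError(f"{path}: not an ssutag index file")
        if len(header) > 2:
            index.source_db = header[2]
        fh.readline()  # column header
        for line in fh:
            kind, key, region, sid, lin = line.rstrip("\n").split("\t")
            entry = (sid, tuple(lin.split(";")))
            if kind == "tag":
                index.entries.setdefault(key, []).append(entry)
                if region:
                    index.regions.setdefault(key, region)
            else:
                index.long_entries.setdefault(key, []).append(entry)
    return index
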