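"""Read scanning: probe prefilter + PSSM confirmation + tag extraction.

Every read is examined in both orientations.  Candidate recognition
sites are positions where a profile's degenerate probe pattern matches
with at most ``probe_mismatches`` mismatches; candidates are confirmed
when the 23-nt window scores at least the profile threshold under the
PSSM.  The 33-nt tag immediately following the RS (in anchored
orientation) is extracted when the read is long enough and, for FASTQ
input, when every tag base meets the per-base Phred threshold.

The module exposes a per-read API (`scan_read`), a streaming API that
buckets reads by length for throughput (`scan_reads`), and a batch API
over equal-length code matrices (`scan_batch`) used by the evaluation
harness at large scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np

from . import _seq

if TYPE_CHECKING:  # pragma: no cover
    from .profiles import RecognitionProfile

__all__ = [
    "ScanConfig",
    "ScanStats",
    "TagObservation",
    "phred_error_prob",
    "pssm_score",
    "scan_batch",
    "scan_read",
    "scan_reads",
]


def phred_error_prob(q: float) -> float:
    """Sequencing-error probability for a Phred score: 10^(-q/10).

    Q30 corresponds to an error probability of 0.1%.
    """
    if q < 0:
        raise ValueError(f"Phred score must be >= 0, got {q}")
    return 10.0 ** (-q / 10.0)


def pssm_score(pssm, window: str) -> float:
    """Additive log-odds score of a window under a PSSM.

    ``N`` (or any ambiguity character) contributes the column minimum —
    the conservative worst case.
    """
    m = np.asarray(pssm, dtype=float)
    if len(window) != m.shape[0]:
        raise ValueError(f"window length {len(window)} != PSSM length "
                         f"{m.shape[0]}")
    codes = _seq.encode(window)
    codes = np.where(codes > _seq.N, _seq.N, codes)
    m5 = np.hstack([m, m.min(axis=1, keepdims=True)])
    return float(m5[np.arange(len(codes)), codes].sum())


@dataclass(frozen=True)
class ScanConfig:
    """Scanning policy.

    probe_mismatches
        Mismatch budget of the probe prefilter; ``None`` disables the
        prefilter (every position becomes a PSSM candidate).
    qv_threshold
        Minimum Phred score required of *every* tag base (per-base
        gate, not a mean).
    phred_offset
        ASCII offset of the quality encoding (33 = Sanger/Illumina1.8+).
    """

    probe_mismatches: int | None = 1
    qv_threshold: int = 30
    phred_offset: int = 33
    best_per_region: bool = True


@dataclass(slots=True)
class TagObservation:
    """One detected tag on one read (anchored orientation)."""

    read_id: str
    sample_id: str
    profile_id: str
    region: str
    strand: str                  # '+'/'-' relative to SSU gene sense
    rs_offset: int               # RS start on the read, reported orientation
    tag: str
    long_seq: str | None = None
    tag_quals: bytes | None = None   # per-base Phred scores of the tag
    score: float = 0.0

    @property
    def min_tag_quality(self) -> int | None:
        if self.tag_quals is None:
            return None
        return min(self.tag_quals)


@dataclass
class ScanStats:
    """Read/hit/filter accounting for one scanning pass."""

    reads_in: int = 0
    reads_hit: int = 0
    hits: int = 0
    length_filtered: int = 0
    quality_filtered: int = 0
    observations: int = 0
    bad_reads: int = 0           # malformed records (e.g. qual length mismatch)

    @property
    def reads_no_hit(self) -> int:
        return self.reads_in - self.reads_hit

    def __iadd__(self, other: "ScanStats") -> "ScanStats":
        for f in ("reads_in", "reads_hit", "hits", "length_filtered",
                  "quality_filtered", "observations", "bad_reads"):
            setattr(self, f, getattr(self, f) + getattr(other, f))
        return self


class _Compiled:
    """numpy-ready form of a RecognitionProfile."""

    __slots__ = ("pssm5", "not_allowed", "probe_offset", "probe_len",
                 "threshold", "tag_length", "long_length", "region",
                 "profile_id", "gene_sense_fwd")

    def __init__(self, prof: "RecognitionProfile"):
        m = np.asarray(prof.pssm, dtype=float)
        self.pssm5 = np.ascontiguousarray(
            np.hstack([m, m.min(axis=1, keepdims=True)]))
        na = np.ones((len(prof.probe_pattern), 6), dtype=np.uint8)
        for j, ch in enumerate(prof.probe_pattern):
            for b in _seq.IUPAC_BASES[ch]:
                na[j, _seq.BASES.index(b)] = 0
        self.not_allowed = na            # N/gap in the read never match
        self.probe_offset = prof.probe_offset
        self.probe_len = len(prof.probe_pattern)
        self.threshold = prof.score_threshold
        self.tag_length = prof.tag_length
        self.long_length = prof.long_length
        self.region = prof.target_region
        self.profile_id = prof.profile_id
        # a forward-orientation hit is gene-sense '+' only for an
        # upstream-side RS (anchored orientation == gene sense there)
        self.gene_sense_fwd = prof.side == "upstream"


def _compile(profiles: Sequence["RecognitionProfile"]) -> list[_Compiled]:
    return [_Compiled(p) for p in profiles]


RS = 23


def _confirmed_sites(oriented: np.ndarray, cp: _Compiled,
                     max_mm: int | None
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rows, RS-start positions and scores of confirmed sites in an
    (R, L) oriented code matrix."""
    R, L = oriented.shape
    W = L - RS + 1
    empty = (np.empty(0, int), np.empty(0, int), np.empty(0, float))
    if W <= 0:
        return empty
    if max_mm is None:
        rows = np.repeat(np.arange(R), W)
        ps = np.tile(np.arange(W), R)
    else:
        m = cp.probe_len
        sub = oriented[:, cp.probe_offset:cp.probe_offset + W + m - 1]
        mm = np.zeros((R, W), dtype=np.uint8)
        for j in range(m):
            mm += cp.not_allowed[j][sub[:, j:j + W]]
        rows, ps = np.nonzero(mm <= max_mm)
    if rows.size == 0:
        return empty
    win = oriented[rows[:, None], ps[:, None] + np.arange(RS)[None, :]]
    win = np.minimum(win, _seq.N)
    scores = cp.pssm5[np.arange(RS)[None, :], win].sum(axis=1)
    keep = scores >= cp.threshold
    return rows[keep], ps[keep], scores[keep]


def confirmed_read_mask(seqs: np.ndarray,
                        profiles: Sequence["RecognitionProfile"],
                        config: ScanConfig | None = None) -> np.ndarray:
    """Boolean per-read flag: does any profile confirm an RS on either
    strand?  Used by the false-positive-rate harness (no tag-length or
    quality requirement — the conservative count)."""
    config = config or ScanConfig()
    compiled = _compile(profiles)
    flag = np.zeros(seqs.shape[0], dtype=bool)
    for oriented in (seqs, _seq.COMP[seqs][:, ::-1]):
        for cp in compiled:
            rows, _, _ = _confirmed_sites(oriented, cp,
                                          config.probe_mismatches)
            flag[rows] = True
    return flag


def scan_batch(seqs: np.ndarray,
               quals: np.ndarray | None,
               profiles: Sequence["RecognitionProfile"],
               config: ScanConfig | None = None,
               sample_id: str = "sample",
               read_ids: Sequence[str] | None = None,
               stats: ScanStats | None = None) -> list[TagObservation]:
    """Scan an (R, L) uint8 code matrix (plus optional (R, L) Phred
    matrix) with a set of profiles; returns surviving observations.

    When several profiles target the same region on one read, only the
    highest-scoring site is kept (ties: lexicographic profile id, then
    forward orientation, then leftmost position).
    """
    config = config or ScanConfig()
    compiled = _compile(profiles)
    R, L = seqs.shape
    if stats is not None:
        stats.reads_in += R

    rc_seqs = _seq.COMP[seqs][:, ::-1]
    rc_quals = quals[:, ::-1] if quals is not None else None

    # (score, pid, orient, p, cp) best per (read, region)
    best: dict[tuple[int, str], tuple] = {}
    for orient, oriented in ((0, seqs), (1, rc_seqs)):
        for cp in compiled:
            rows, ps, scores = _confirmed_sites(oriented, cp,
                                                config.probe_mismatches)
            for r, p, s in zip(rows.tolist(), ps.tolist(), scores.tolist()):
                key = (r, cp.region) if config.best_per_region \
                    else (r, cp.region, cp.profile_id, orient, p)
                cand = (-s, cp.profile_id, orient, p, cp)
                if key not in best or cand[:4] < best[key][:4]:
                    best[key] = cand

    obs: list[TagObservation] = []
    hit_reads: set[int] = set()
    n_len = n_qual = 0
    for key in sorted(best, key=lambda k: (k[0], k[1])):
        neg_s, pid, orient, p, cp = best[key]
        r = key[0]
        hit_reads.add(r)
        oriented = seqs if orient == 0 else rc_seqs
        oq = quals if orient == 0 else rc_quals
        t0, t1 = p + RS, p + RS + cp.tag_length
        if t1 > L:
            n_len += 1
            continue
        tag_codes = oriented[r, t0:t1]
        if (tag_codes >= _seq.N).any():
            n_qual += 1
            continue
        tq = None
        if oq is not None:
            tqa = oq[r, t0:t1]
            if int(tqa.min()) < config.qv_threshold:
                n_qual += 1
                continue
            tq = tqa.astype(np.uint8).tobytes()
        long_seq = None
        l1 = p + RS + cp.long_length
        if l1 <= L:
            long_codes = oriented[r, t0:l1]
            ok = not (long_codes >= _seq.N).any()
            if ok and oq is not None:
                ok = int(oq[r, t0:l1].min()) >= config.qv_threshold
            if ok:
                long_seq = _seq.decode(long_codes)
        strand = "+" if (orient == 0) == cp.gene_sense_fwd else "-"
        obs.append(TagObservation(
            read_id=read_ids[r] if read_ids is not None else f"read{r}",
            sample_id=sample_id,
            profile_id=pid,
            region=cp.region,
            strand=strand,
            rs_offset=p,
            tag=_seq.decode(tag_codes),
            long_seq=long_seq,
            tag_quals=tq,
            score=-neg_s,
        ))
    if stats is not None:
        stats.reads_hit += len(hit_reads)
        stats.hits += len(best)
        stats.length_filtered += n_len
        stats.quality_filtered += n_qual
        stats.observations += len(obs)
    return obs


def _decode_quals(qual: str, offset: int) -> np.ndarray:
    return (np.frombuffer(qual.encode("ascii"), dtype=np.uint8)
            .astype(np.int16) - offset)


def scan_read(read: tuple,
              profiles: Sequence["RecognitionProfile"],
              config: ScanConfig | None = None,
              sample_id: str = "sample") -> list[TagObservation]:
    """Scan one read given as ``(id, seq)`` or ``(id, seq, qual)``."""
    obs, _ = scan_reads([read], profiles, config, sample_id)
    return obs


def scan_reads(reads: Iterable[tuple],
               profiles: Sequence["RecognitionProfile"],
               config: ScanConfig | None = None,
               sample_id: str = "sample",
               batch_size: int = 512
               ) -> tuple[list[TagObservation], ScanStats]:
    """Stream reads (variable length), bucketing equal-length reads
    into batches for the vectorized core.  Reads whose quality string
    length mismatches the sequence are rejected per-read (counted in
    ``stats.bad_reads``), never fatal."""
    config = config or ScanConfig()
    stats = ScanStats()
    out: list[TagObservation] = []
    buckets: dict[int, list[tuple[str, str, str | None]]] = {}

    def flush(length: int) -> None:
        group = buckets.pop(length, [])
        if not group:
            return
        ids = [g[0] for g in group]
        seqs = np.vstack([_seq.encode(g[1]) for g in group])
        quals = None
        if group[0][2] is not None:
            quals = np.vstack([_decode_quals(g[2], config.phred_offset)
                               for g in group])
        out.extend(scan_batch(seqs, quals, profiles, config,
                              sample_id, ids, stats))

    for read in reads:
        rid, seq = read[0], read[1]
        qual = read[2] if len(read) > 2 else None
        if not seq:
            stats.bad_reads += 1
            continue
        if qual is not None and len(qual) != len(seq):
            stats.bad_reads += 1
            continue
        buckets.setdefault(len(seq), []).append((rid, seq, qual))
        if len(buckets[len(seq)]) >= batch_size:
            flush(len(seq))
    for length in list(buckets):
        flush(length)
    return out, stats
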