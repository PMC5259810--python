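"""Recognition-profile construction from aligned SSU references.

A recognition profile is a detector for the conserved 23-nt recognition
sequence (RS) flanking one hypervariable region (V-region) of the SSU
rRNA gene.  It combines a short degenerate *probe pattern* (a fast
prefilter) with a 23-column position-specific scoring matrix (PSSM) of
log-odds weights, a score threshold calibrated to a target training
sensitivity, and the geometry of the adjacent 33-nt tag sequence (TS).

Profiles are built from a multiple alignment of full-length reference
sequences together with 7-rank lineages.  A *universal* profile is
trained on every sequence of a domain; supplementary *taxon-specific*
profiles are the same machinery applied to the subset of a phylum that
the universal profile misses.

All profiles are stored in *anchored orientation*: the PSSM reads the
RS such that the tag always lies immediately 3' of the RS in scan
orientation.  For an RS upstream of the V-region this is gene sense;
for a downstream RS it is the reverse complement of gene sense.  The
scanner relies on this so tag extraction is identical for both sides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

from . import _seq

RANKS = ("k", "p", "c", "o", "f", "g", "s")
RS_LENGTH = 23

__all__ = [
    "RANKS",
    "RS_LENGTH",
    "AlignedReference",
    "ProfileConfig",
    "ProfileConstructionError",
    "RecognitionProfile",
    "build_profile",
    "build_pssm",
    "build_taxon_profiles",
    "column_entropy",
    "load_profiles",
    "save_profiles",
]


class ProfileConstructionError(RuntimeError):
    """No acceptable recognition-sequence window could be built."""


@dataclass
class AlignedReference:
    """A multiple alignment of SSU reference sequences with lineages.

    Parameters
    ----------
    records
        ``(seq_id, aligned_seq, lineage)`` triples.  ``lineage`` is a
        7-tuple of rank labels kingdom→species; missing ranks are empty
        strings.
    region_map
        V-region name → ``(start_col, end_col)`` half-open alignment
        column interval.
    """

    records: list[tuple[str, str, tuple[str, ...]]]
    region_map: dict[str, tuple[int, int]]
    alignment_length: int = 0

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain at least one record")
        n = len(self.records[0][1])
        if self.alignment_length == 0:
            self.alignment_length = n
        for sid, seq, lineage in self.records:
            if len(seq) != self.alignment_length:
                raise ValueError(f"sequence {sid!r} length {len(seq)} != "
                                 f"alignment length {self.alignment_length}")
            if len(lineage) != len(RANKS):
                raise ValueError(f"lineage for {sid!r} must have "
                                 f"{len(RANKS)} ranks")
        ivals = sorted(self.region_map.values())
        for (s, e) in ivals:
            if not (0 <= s < e <= self.alignment_length):
                raise ValueError(f"region interval {(s, e)} outside alignment")
        for (_, e0), (s1, _) in zip(ivals, ivals[1:]):
            if s1 < e0:
                raise ValueError("region intervals overlap")
        self._codes: np.ndarray | None = None

    @property
    def codes(self) -> np.ndarray:
        """(n_records, alignment_length) uint8 code matrix (cached)."""
        if self._codes is None:
            self._codes = np.vstack([_seq.encode(seq)
                                     for _, seq, _ in self.records])
        return self._codes

    def domain_indices(self, domain: str | None) -> np.ndarray:
        """Indices of records whose kingdom label matches ``domain``."""
        if domain is None:
            return np.arange(len(self.records))
        want = domain.strip().lower()
        idx = [i for i, (_, _, lin) in enumerate(self.records)
               if lin[0].strip().lower() == want]
        return np.asarray(idx, dtype=int)


@dataclass(frozen=True)
class ProfileConfig:
    """Tunables for profile construction.

    The defaults encode the method's fixed geometry (23-nt RS, 33-nt
    tag, 60-nt long sequence) and the training policy: a pseudocount of
    0.5 against a uniform background, a +/-5 column entropy-minimising
    shift search for the RS window, a probe pattern of at least 8
    columns admitting bases at >= 5% frequency, and a score threshold
    placed by a sensitivity sweep over leave-one-out training scores.
    The sweep's default target of 98% leaves margin so sensitivity on
    unseen sequences stays above the 95% design goal at modest
    training sizes; the specificity budget (false positives on
    non-SSU sequence) has orders of magnitude of headroom, so the
    lower threshold costs little.
    """

    tag_length: int = 33
    long_length: int = 60
    pseudocount: float = 0.5
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    shift_range: int = 5
    min_probe_len: int = 8
    probe_min_freq: float = 0.05
    target_sensitivity: float = 0.98
    max_mean_entropy: float = 1.5
    miss_rate: float = 0.05


@dataclass
class RecognitionProfile:
    """One V-region/domain RS detector (PSSM + probe + geometry)."""

    profile_id: str
    target_region: str
    target_domain: str
    side: str                      # "upstream" | "downstream" of the V-region
    pssm: np.ndarray               # (23, 4) log-odds in bits, anchored
    probe_pattern: str             # IUPAC consensus prefilter
    probe_offset: int              # probe start within the 23-nt RS window
    score_threshold: float         # bits
    tag_length: int = 33
    long_length: int = 60
    scope: str = "universal"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pssm = np.asarray(self.pssm, dtype=float)
        if self.pssm.shape != (RS_LENGTH, 4):
            raise ValueError(f"PSSM must be {RS_LENGTH}x4, "
                             f"got {self.pssm.shape}")
        if not np.isfinite(self.pssm).all():
            raise ValueError("PSSM entries must be finite")
        if self.side not in ("upstream", "downstream"):
            raise ValueError(f"bad side {self.side!r}")
        if not (6 <= len(self.probe_pattern)
                and self.probe_offset >= 0
                and self.probe_offset + len(self.probe_pattern) <= RS_LENGTH):
            raise ValueError("probe pattern must be >= 6 nt and fit inside "
                             "the 23-nt RS window")
        if self.tag_length <= 0 or self.tag_length > self.long_length:
            raise ValueError("require 0 < tag_length <= long_length")
        if self.score_threshold > self.max_score + 1e-9:
            raise ValueError("score threshold exceeds the maximum "
                             "attainable PSSM score")

    @property
    def max_score(self) -> float:
        return float(self.pssm.max(axis=1).sum())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pssm"] = [[float(x) for x in row] for row in self.pssm]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RecognitionProfile":
        return cls(**d)


def _column_counts(codes: np.ndarray, cols) -> np.ndarray:
    """Base counts (len(cols), 4) over A,C,G,T; N and gaps excluded."""
    sub = codes[:, cols]
    counts = np.empty((sub.shape[1], 4), dtype=float)
    for b in range(4):
        counts[:, b] = (sub == b).sum(axis=0)
    return counts


def _entropy_from_counts(counts: np.ndarray) -> np.ndarray:
    """Shannon entropy (bits) per row; all-gap rows score 2 bits."""
    totals = counts.sum(axis=1)
    ent = np.full(counts.shape[0], 2.0)
    ok = totals > 0
    if ok.any():
        p = counts[ok] / totals[ok, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, -p * np.log2(p), 0.0)
        ent[ok] = terms.sum(axis=1)
    return ent


def column_entropy(ref: AlignedReference, col: int) -> float:
    """Shannon entropy (bits) of base frequencies at one alignment column.

    Gaps and ambiguous bases are excluded from the denominator; an
    all-gap column carries no information and returns the maximum of
    2 bits.
    """
    if not (0 <= col < ref.alignment_length):
        raise IndexError(f"column {col} outside [0, {ref.alignment_length})")
    counts = _column_counts(ref.codes, [col])
    return float(_entropy_from_counts(counts)[0])


def build_pssm(ref: AlignedReference,
               window_cols: Sequence[int],
               pseudocount: float = 0.5,
               background: Sequence[float] | None = None,
               records: Sequence[int] | None = None,
               anchored_revcomp: bool = False) -> np.ndarray:
    """Log-odds PSSM over a 23-column alignment window.

    ``entry[i][b] = log2((count[i][b] + pc) / (N_i + 4 pc) / bg[b])``
    with ``N_i`` the non-gap count at window position ``i``; an all-gap
    position yields a zero row.  With ``anchored_revcomp`` the matrix
    is built on the reverse complement of the window (used for
    downstream-side profiles so the tag always follows the RS).
    """
    window_cols = list(window_cols)
    if len(window_cols) != RS_LENGTH:
        raise ValueError(f"RS window must span exactly {RS_LENGTH} columns")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = np.asarray(background if background is not None else [0.25] * 4,
                    dtype=float)
    if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1) > 1e-9:
        raise ValueError("background must be a positive 4-vector summing to 1")
    codes = ref.codes if records is None else ref.codes[np.asarray(records)]
    counts = _column_counts(codes, window_cols)
    if anchored_revcomp:
        counts = counts[::-1, ::-1]  # reverse positions, complement bases
    totals = counts.sum(axis=1)
    with np.errstate(divide="ignore"):
        m = np.log2((counts + pseudocount)
                    / (totals[:, None] + 4 * pseudocount) / bg[None, :])
    m[totals == 0] = 0.0
    return m


def _anchor_counts(counts: np.ndarray, side: str) -> np.ndarray:
    return counts[::-1, ::-1] if side == "downstream" else counts


def _probe_from_counts(counts: np.ndarray, cfg: ProfileConfig
                       ) -> tuple[str, int]:
    """Pick the lowest-entropy run of >= min_probe_len columns and emit
    its IUPAC consensus (bases at frequency >= probe_min_freq)."""
    ent = _entropy_from_counts(counts)
    csum = np.concatenate([[0.0], np.cumsum(ent)])
    best = None  # (mean_entropy, -length, start)
    for length in range(cfg.min_probe_len, RS_LENGTH + 1):
        for start in range(0, RS_LENGTH - length + 1):
            mean = (csum[start + length] - csum[start]) / length
            key = (round(mean, 12), -length, start)
            if best is None or key < best:
                best = key
    _, neg_len, start = best
    length = -neg_len
    letters = []
    for i in range(start, start + length):
        total = counts[i].sum()
        if total == 0:
            letters.append("N")
            continue
        freqs = counts[i] / total
        bases = frozenset(_seq.BASES[b] for b in range(4)
                          if freqs[b] >= cfg.probe_min_freq)
        if not bases:
            bases = frozenset(_seq.BASES[int(np.argmax(freqs))])
        letters.append(_seq.IUPAC[bases] if len(bases) < 4 else "N")
    return "".join(letters), start


def _true_site_scores(codes: np.ndarray, window_cols: Sequence[int],
                      side: str, pssm: np.ndarray) -> np.ndarray:
    """Anchored PSSM score of each training sequence at its own RS site."""
    sub = codes[:, list(window_cols)]
    if side == "downstream":
        sub = _seq.COMP[sub][:, ::-1]
    sub = np.where(sub > _seq.N, _seq.N, sub)  # gaps score as N
    pssm5 = np.hstack([pssm, pssm.min(axis=1, keepdims=True)])
    return pssm5[np.arange(RS_LENGTH)[None, :], sub].sum(axis=1)


def _loo_site_scores(codes: np.ndarray, window_cols: Sequence[int],
                     side: str, cfg: ProfileConfig) -> np.ndarray:
    """Leave-one-out PSSM score of each training sequence at its own
    RS site.

    Scoring a sequence against a matrix whose counts include that very
    sequence is optimistically biased — strongly so at rare bases,
    where a single self-count can move the log-odds by half a bit or
    more.  Removing the sequence's own contribution before scoring
    gives an unbiased estimate of the score an *unseen* sequence would
    obtain, which is what the threshold sweep needs.
    """
    sub = codes[:, list(window_cols)]
    if side == "downstream":
        sub = _seq.COMP[sub][:, ::-1]
    pc = cfg.pseudocount
    bg = np.asarray(cfg.background, dtype=float)
    counts = np.empty((RS_LENGTH, 4), dtype=float)
    anchored = np.minimum(sub, _seq.N)
    for b in range(4):
        counts[:, b] = (anchored == b).sum(axis=0)
    totals = counts.sum(axis=1)
    with np.errstate(divide="ignore"):
        loo = np.log2((counts - 1 + pc).clip(min=pc * 0.5)
                      / (totals[:, None] - 1 + 4 * pc) / bg[None, :])
        full = np.log2((counts + pc)
                       / (totals[:, None] + 4 * pc) / bg[None, :])
    # gaps/N score the worst case of the full matrix
    loo5 = np.hstack([loo, full.min(axis=1, keepdims=True)])
    return loo5[np.arange(RS_LENGTH)[None, :], anchored].sum(axis=1)


def _sensitivity_threshold(scores: np.ndarray, target: float,
                           gap_bits: float = 2.0) -> tuple[float, float]:
    """Sensitivity-sweep threshold with cluster-aware placement.

    True-site scores cluster by the number of diverged positions (each
    costs several bits), so the raw target quantile can land *inside*
    a cluster and cut it in half — making the emitted threshold highly
    sensitive to sampling noise.  After the sweep picks the largest
    threshold keeping >= ``target`` of the training scores, the
    threshold is relaxed downward to the middle of the first score gap
    of at least ``gap_bits`` (well below a single-position penalty),
    so it sits between clusters.  Training sensitivity can only
    increase in this step.
    """
    s = np.sort(scores)[::-1]
    n = len(s)
    k = math.ceil(target * n)          # sequences that must score >= thr
    j = k - 1
    while j + 1 < n and s[j] - s[j + 1] < gap_bits:
        j += 1
    thr = float((s[j] + s[j + 1]) / 2.0) if j + 1 < n else float(s[n - 1])
    sens = float((scores >= thr).mean())
    return thr, sens


def build_profile(ref: AlignedReference,
                  region: str,
                  domain: str = "bacteria",
                  side: str = "upstream",
                  config: ProfileConfig | None = None,
                  records: Sequence[int] | None = None,
                  scope: str = "universal") -> RecognitionProfile:
    """Train one recognition profile for a V-region flank.

    The nominal 23-column RS window sits immediately upstream or
    downstream of the region's alignment interval; a +/-``shift_range``
    column search refines it to the minimum mean column entropy (ties
    prefer the nominal placement).  The PSSM, probe pattern and
    threshold are then derived from the training subset.

    Raises
    ------
    ProfileConstructionError
        If the best window's mean entropy exceeds
        ``config.max_mean_entropy`` (no usable conserved flank).
    KeyError
        If ``region`` is not present in the reference's region map.
    """
    cfg = config or ProfileConfig()
    if region not in ref.region_map:
        raise KeyError(f"region {region!r} not in region map "
                       f"{sorted(ref.region_map)}")
    if side not in ("upstream", "downstream"):
        raise ValueError(f"bad side {side!r}")
    if records is None:
        records = ref.domain_indices(domain)
    records = np.asarray(records, dtype=int)
    if len(records) < 2:
        raise ValueError(f"need >= 2 training sequences for domain "
                         f"{domain!r}, got {len(records)}")
    codes = ref.codes[records]

    start, end = ref.region_map[region]
    nominal = start - RS_LENGTH if side == "upstream" else end
    best = None  # (mean_entropy, |shift|, shift)
    for shift in range(-cfg.shift_range, cfg.shift_range + 1):
        w0 = nominal + shift
        if w0 < 0 or w0 + RS_LENGTH > ref.alignment_length:
            continue
        counts = _column_counts(codes, range(w0, w0 + RS_LENGTH))
        mean_ent = float(_entropy_from_counts(counts).mean())
        key = (round(mean_ent, 12), abs(shift), shift)
        if best is None or key < best:
            best = key
    if best is None:
        raise ProfileConstructionError(
            f"no RS window fits the alignment for {region}/{side}")
    mean_ent, _, shift = best
    if mean_ent > cfg.max_mean_entropy:
        raise ProfileConstructionError(
            f"best RS window for {region}/{side} has mean entropy "
            f"{mean_ent:.3f} bits > {cfg.max_mean_entropy} (flank not "
            f"conserved enough)")
    w0 = nominal + shift
    window_cols = range(w0, w0 + RS_LENGTH)

    pssm = build_pssm(ref, window_cols, cfg.pseudocount, cfg.background,
                      records=records,
                      anchored_revcomp=(side == "downstream"))
    counts = _anchor_counts(_column_counts(codes, window_cols), side)
    probe, probe_off = _probe_from_counts(counts, cfg)
    loo_scores = _loo_site_scores(codes, window_cols, side, cfg)
    # Calibrate on recognizable sites only: a training sequence whose
    # site scores below zero (worse than background odds — e.g. a
    # divergent clade with its own flank) is not a detectable instance
    # of this profile and must not drag the threshold down; such
    # clades are what taxon-specific supplements are for.
    usable = loo_scores[loo_scores > 0.0]
    if len(usable) < 2:
        raise ProfileConstructionError(
            f"fewer than 2 recognizable training sites for "
            f"{region}/{side}")
    threshold, _ = _sensitivity_threshold(usable, cfg.target_sensitivity)
    threshold = min(threshold, float(pssm.max(axis=1).sum()))
    scores = _true_site_scores(codes, window_cols, side, pssm)
    detectable = scores > 0.0
    train_sens = float((scores[detectable] >= threshold).mean())

    dom = (domain or "all")[:3].lower()
    pid = f"{region}_{dom}_{side[:4]}"
    if scope != "universal":
        pid += f"_{scope}"
    return RecognitionProfile(
        profile_id=pid,
        target_region=region,
        target_domain=domain or "all",
        side=side,
        pssm=pssm,
        probe_pattern=probe,
        probe_offset=probe_off,
        score_threshold=threshold,
        tag_length=cfg.tag_length,
        long_length=cfg.long_length,
        scope=scope,
        meta={"window_start": int(w0), "shift": int(shift),
              "mean_entropy": float(mean_ent),
              "training_sensitivity": float(train_sens),
              "detectable_fraction": float(detectable.mean()),
              "n_training": int(len(records))},
    )


def build_taxon_profiles(ref: AlignedReference,
                         region: str,
                         domain: str = "bacteria",
                         side: str = "upstream",
                         config: ProfileConfig | None = None,
                         universal: RecognitionProfile | None = None,
                         records: Sequence[int] | None = None
                         ) -> list[RecognitionProfile]:
    """Supplementary phylum-specific profiles for sequences the
    universal profile misses.

    For every phylum whose members fail the universal threshold at a
    rate above ``config.miss_rate``, a profile is trained on that
    phylum alone (scope set to the phylum label).  Phyla with fewer
    than two members are skipped; the list may be empty.
    """
    cfg = config or ProfileConfig()
    if universal is None:
        universal = build_profile(ref, region, domain, side, cfg,
                                  records=records)
    if records is None:
        records = ref.domain_indices(domain)
    records = np.asarray(records, dtype=int)
    w0 = universal.meta["window_start"]
    window_cols = range(w0, w0 + RS_LENGTH)
    scores = _true_site_scores(ref.codes[records], window_cols, side,
                               universal.pssm)
    detected = scores >= universal.score_threshold

    by_phylum: dict[str, list[int]] = {}
    for pos, rec_idx in enumerate(records):
        phylum = ref.records[rec_idx][2][1]
        if phylum:
            by_phylum.setdefault(phylum, []).append(pos)
    out: list[RecognitionProfile] = []
    for phylum in sorted(by_phylum):
        pos = np.asarray(by_phylum[phylum])
        miss = float(1.0 - detected[pos].mean())
        if miss <= cfg.miss_rate or len(pos) < 2:
            continue
        out.append(build_profile(ref, region, domain, side, cfg,
                                 records=records[pos], scope=phylum))
    return out


_FORMAT = "ssutag-profiles"
_VERSION = 1


def save_profiles(profiles: Sequence[RecognitionProfile], path) -> None:
    """Serialize profiles to a versioned YAML document."""
    doc = {"format": _FORMAT, "version": _VERSION,
           "profiles": [p.to_dict() for p in profiles]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_profiles(path) -> list[RecognitionProfile]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("format") != _FORMAT:
        raise ValueError(f"{path}: not a {_FORMAT} document")
    return [RecognitionProfile.from_dict(d) for d in doc["profiles"]]
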