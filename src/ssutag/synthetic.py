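"""Synthetic SSU-like communities and error-bearing shotgun reads.

The generator emulates the two data classes the method consumes:

* reference sequences laid out as alternating conserved and
  hypervariable blocks (by default 10 conserved and 9 variable blocks,
  mirroring the SSU gene's architecture), with hierarchical 7-rank
  lineages — conserved blocks are drawn once from a master template
  and lightly mutated per taxon, variable blocks evolve down the
  lineage tree so sequence similarity tracks taxonomic relatedness;

* shotgun reads sampled uniformly along the references with abundance
  weighting, i.i.d. substitution errors and Phred strings consistent
  with the error rate actually simulated, plus a "faux read" mode
  emitting fixed-length non-SSU fragments for false-positive-rate
  estimation.

Everything is driven by a single integer seed; a fixed seed yields
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _seq
from .profiles import RANKS, AlignedReference

__all__ = ["CommunitySpec", "default_region_layout", "faux_fragments",
           "make_reference", "reads_to_fastq", "simulate_reads"]


def default_region_layout(conserved_len: int = 30,
                          variable_len: int = 50,
                          n_variable: int = 9
                          ) -> tuple[tuple[str, int], ...]:
    """Alternating conserved/variable block layout, C V1 C V2 ... V9 C."""
    blocks: list[tuple[str, int]] = []
    for i in range(n_variable):
        blocks.append((f"C{i}", conserved_len))
        blocks.append((f"V{i + 1}", variable_len))
    blocks.append((f"C{n_variable}", conserved_len))
    return tuple(blocks)


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic community.

    conserved_mut_rate
        Per-base substitution probability of each taxon's conserved
        blocks relative to the master template.  The 1% default
        matches the near-universal conservation of real recognition
        sites (the windows universal primers target show ~99%
        per-position conservation) while still exercising profile
        thresholds.
    variable_diversity
        Per-base substitution probability applied along *each* edge of
        the lineage tree to the variable blocks, so divergence
        accumulates with taxonomic distance (default 10% per rank
        step).
    per_base_error
        Sequencing substitution error rate; the emitted Phred score is
        ``round(-10 log10 e)`` for every base.
    """

    n_taxa: int = 20
    lineage_tree: tuple[int, ...] = (1, 2, 2, 2, 2, 2)  # k..g branching
    region_layout: tuple[tuple[str, int], ...] = field(
        default_factory=default_region_layout)
    conserved_mut_rate: float = 0.01
    variable_diversity: float = 0.10
    abundances: tuple[float, ...] | None = None
    read_length: int = 100
    n_reads: int = 10_000
    per_base_error: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.conserved_mut_rate, self.variable_diversity,
                  self.per_base_error):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rates must lie in [0, 1], got {r}")
        if self.abundances is not None:
            if len(self.abundances) != self.n_taxa:
                raise ValueError("abundances must have one weight per taxon")
            if abs(sum(self.abundances) - 1.0) > 1e-9:
                raise ValueError("abundances must sum to 1")

    @property
    def weights(self) -> np.ndarray:
        if self.abundances is None:
            return np.full(self.n_taxa, 1.0 / self.n_taxa)
        return np.asarray(self.abundances, dtype=float)


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator
            ) -> np.ndarray:
    """Substitute each base independently with probability ``rate``."""
    out = codes.copy()
    if rate <= 0:
        return out
    mask = rng.random(codes.shape) < rate
    shift = rng.integers(1, 4, size=codes.shape)
    out[mask] = (out[mask] + shift[mask]) % 4
    return out


def _partition_labels(spec: CommunitySpec) -> list[tuple[str, ...]]:
    """Assign a 7-rank lineage to each taxon by recursively splitting
    the taxon index range per the branching factors; species labels
    are unique per taxon."""
    counters = {r: 0 for r in RANKS}
    lineages: list[list[str]] = [[] for _ in range(spec.n_taxa)]
    prefixes = {"k": "Bacteria", "p": "P", "c": "C", "o": "O",
                "f": "F", "g": "G"}

    def split(idx: np.ndarray, depth: int) -> None:
        rank = RANKS[depth]
        if rank == "s":
            for i in idx:
                lineages[i].append(f"T{i:04d}")
            return
        factor = (spec.lineage_tree[depth]
                  if depth < len(spec.lineage_tree) else 1)
        groups = [g for g in np.array_split(idx, max(factor, 1))
                  if len(g)]
        for g in groups:
            counters[rank] += 1
            label = ("Bacteria" if rank == "k" and factor == 1
                     else f"{prefixes[rank]}{counters[rank]:02d}")
            for i in g:
                lineages[i].append(label)
            split(g, depth + 1)

    split(np.arange(spec.n_taxa), 0)
    return [tuple(lin) for lin in lineages]


def make_reference(spec: CommunitySpec,
                   rng: np.random.Generator | None = None
                   ) -> AlignedReference:
    """Generate the reference community.

    Variable blocks evolve along the lineage tree (one mutation round
    per rank step at ``variable_diversity``); conserved blocks are the
    master template mutated once per taxon at ``conserved_mut_rate``.
    Block lengths are equal across taxa, so the 'alignment' is trivial
    (no gaps) and the region map follows directly from the layout.
    """
    rng = rng or np.random.default_rng(spec.seed)
    lineages = _partition_labels(spec)

    layout = spec.region_layout
    total = sum(length for _, length in layout)
    master = {name: rng.integers(0, 4, size=length).astype(np.uint8)
              for name, length in layout}

    # evolve variable blocks down the lineage tree
    var_names = [n for n, _ in layout if n.startswith("V")]
    taxon_blocks: dict[str, dict[int, np.ndarray]] = {n: {} for n in var_names}

    def evolve(idx: list[int], depth: int,
               state: dict[str, np.ndarray]) -> None:
        if depth == len(RANKS):
            for name in var_names:
                for i in idx:
                    taxon_blocks[name][i] = state[name]
            return
        groups: dict[str, list[int]] = {}
        for i in idx:
            groups.setdefault(lineages[i][depth], []).append(i)
        for label in sorted(groups):
            child = {n: _mutate(state[n], spec.variable_diversity, rng)
                     for n in var_names}
            evolve(groups[label], depth + 1, child)

    evolve(list(range(spec.n_taxa)), 0,
           {n: master[n] for n in var_names})

    records = []
    region_map: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, length in layout:
        if name.startswith("V"):
            region_map[name] = (pos, pos + length)
        pos += length
    for i in range(spec.n_taxa):
        parts = []
        for name, length in layout:
            if name.startswith("V"):
                parts.append(taxon_blocks[name][i])
            else:
                parts.append(_mutate(master[name], spec.conserved_mut_rate,
                                     rng))
        seq = _seq.decode(np.concatenate(parts))
        records.append((f"T{i:04d}", seq, lineages[i]))
    return AlignedReference(records=records, region_map=region_map,
                            alignment_length=total)


def error_phred(e: float) -> int:
    """Phred score consistent with a per-base error rate."""
    if e <= 0:
        return 40
    return int(round(-10.0 * math.log10(e)))


def simulate_reads(ref: AlignedReference,
                   spec: CommunitySpec,
                   rng: np.random.Generator | None = None,
                   n_reads: int | None = None,
                   cover: tuple[int, int] | None = None,
                   taxa: Sequence[int] | None = None,
                   rc_fraction: float = 0.5,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate shotgun reads; returns ``(seqs, quals, taxa)`` arrays.

    ``seqs`` is (n, read_length) uint8 codes, ``quals`` the matching
    integer Phred matrix, ``taxa`` the source taxon of each read.
    Start positions are uniform; with ``cover=(lo, hi)`` every read
    fully contains the reference interval [lo, hi).  A ``rc_fraction``
    of reads is emitted reverse-complemented.
    """
    rng = rng or np.random.default_rng(spec.seed)
    n = spec.n_reads if n_reads is None else n_reads
    L = ref.alignment_length
    rlen = spec.read_length
    if rlen > L:
        raise ValueError("read length exceeds reference length")

    if taxa is None:
        taxa = rng.choice(spec.n_taxa, size=n, p=spec.weights)
    else:
        taxa = np.asarray(taxa, dtype=int)
        if len(taxa) != n:
            raise ValueError("taxa must give one source per read")
    if cover is None:
        starts = rng.integers(0, L - rlen + 1, size=n)
    else:
        lo, hi = cover
        if hi - lo > rlen:
            raise ValueError("cover interval longer than a read")
        s0, s1 = max(0, hi - rlen), min(lo, L - rlen)
        if s1 < s0:
            raise ValueError("cover interval cannot fit in a read")
        starts = rng.integers(s0, s1 + 1, size=n)

    ref_codes = ref.codes
    seqs = ref_codes[taxa[:, None], starts[:, None] + np.arange(rlen)[None, :]]
    seqs = np.ascontiguousarray(seqs)
    if spec.per_base_error > 0:
        mask = rng.random(seqs.shape) < spec.per_base_error
        shift = rng.integers(1, 4, size=seqs.shape).astype(np.uint8)
        seqs[mask] = (seqs[mask] + shift[mask]) % 4
    q = error_phred(spec.per_base_error)
    quals = np.full(seqs.shape, q, dtype=np.int16)

    if rc_fraction > 0:
        flip = rng.random(n) < rc_fraction
        seqs[flip] = _seq.COMP[seqs[flip]][:, ::-1]
        # constant quality profile: reversal is a no-op, kept for shape
        quals[flip] = quals[flip][:, ::-1]
    return seqs, quals, taxa


def reads_to_fastq(seqs: np.ndarray, quals: np.ndarray,
                   taxa: np.ndarray | None = None,
                   phred_offset: int = 33) -> list[tuple[str, str, str]]:
    """Render simulated read arrays as FASTQ-ready (id, seq, qual)."""
    out = []
    for i in range(seqs.shape[0]):
        tax = f"_t{int(taxa[i])}" if taxa is not None else ""
        qual = "".join(chr(int(q) + phred_offset) for q in quals[i])
        out.append((f"r{i:07d}{tax}", _seq.decode(seqs[i]), qual))
    return out


def faux_fragments(rng: np.random.Generator,
                   n: int,
                   length: int = 80,
                   source: str | None = None,
                   composition: Sequence[float] | None = None
                   ) -> np.ndarray:
    """Non-SSU fragments for false-positive-rate estimation.

    With ``source`` given, emits its non-overlapping ``length``-nt
    windows (the faux-read protocol applied to a supplied sequence);
    otherwise draws i.i.d. random fragments, uniform over A/C/G/T or
    per ``composition``.
    """
    if source is not None:
        codes = _seq.encode(source)
        k = len(codes) // length
        frags = codes[:k * length].reshape(k, length)
        return frags[:n] if n < k else frags
    if composition is None:
        return rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    p = np.asarray(composition, dtype=float)
    if p.shape != (4,) or abs(p.sum() - 1) > 1e-9 or (p < 0).any():
        raise ValueError("composition must be a 4-vector summing to 1")
    cum = np.cumsum(p)
    u = rng.random((n, length))
    return np.searchsorted(cum, u).astype(np.uint8)
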