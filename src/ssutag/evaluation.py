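"""Validation harnesses: sensitivity, specificity, error-model and
end-to-end recovery experiments, plus the expected-yield estimate.

The experiment functions regenerate their synthetic inputs from a
seed, run the full pipeline and return plain dictionaries of measured
quantities, so the same code backs the test suite, the CLI ``eval``
subcommand and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import profiles as profiles_mod
from . import synthetic, tagcount
from .profiles import RecognitionProfile
from .scanner import ScanConfig, confirmed_read_mask, scan_batch, scan_reads
from .synthetic import faux_fragments

__all__ = ["FPRResult", "error_model_experiment", "expected_tag_yield",
           "false_positive_rate", "holdout_sensitivity",
           "recovery_experiment", "sensitivity", "train_profiles"]


def expected_tag_yield(total_reads: int, genes_per_genome: int,
                       n_regions: int) -> int:
    """Back-of-envelope expected reads per V-region in a shotgun run.

    Assumes one SSU gene among ``genes_per_genome`` equally covered
    genes and ``n_regions`` equally sized segments of the gene (9
    variable + 10 conserved = 19), so the yield is
    ``total_reads // (n_regions * genes_per_genome)``.
    """
    if total_reads < 0:
        raise ValueError("total_reads must be non-negative")
    if genes_per_genome <= 0 or n_regions <= 0:
        raise ValueError("genes_per_genome and n_regions must be positive")
    return total_reads // (n_regions * genes_per_genome)


def sensitivity(profiles: Sequence[RecognitionProfile],
                seqs: Sequence[tuple[str, str]],
                config: ScanConfig | None = None) -> float:
    """Fraction of sequences on which any profile yields an
    observation (tag extracted; no quality gate for FASTA input)."""
    if not seqs:
        raise ValueError("no sequences to evaluate")
    config = config or ScanConfig()
    obs, _ = scan_reads(seqs, profiles, config)
    detected = {ob.read_id for ob in obs}
    return len(detected) / len(seqs)


@dataclass(frozen=True)
class FPRResult:
    n_fragments: int
    positives: int

    @property
    def rate(self) -> float:
        return self.positives / self.n_fragments if self.n_fragments else 0.0


def false_positive_rate(profiles: Sequence[RecognitionProfile],
                        n_fragments: int,
                        length: int = 80,
                        rng: np.random.Generator | None = None,
                        config: ScanConfig | None = None,
                        composition: Sequence[float] | None = None,
                        chunk: int = 200_000) -> FPRResult:
    """Empirical FPR of the profiles on random non-SSU fragments.

    Fragments are scanned in chunks on both strands; a fragment counts
    as a false positive when any profile confirms a recognition
    sequence on it (conservative: no tag-length requirement).
    """
    rng = rng or np.random.default_rng(0)
    config = config or ScanConfig()
    positives = 0
    done = 0
    while done < n_fragments:
        m = min(chunk, n_fragments - done)
        frags = faux_fragments(rng, m, length, composition=composition)
        positives += int(confirmed_read_mask(frags, profiles, config).sum())
        done += m
    return FPRResult(n_fragments=n_fragments, positives=positives)


def train_profiles(ref, region: str = "V4",
                   records: Sequence[int] | None = None,
                   config=None) -> list[RecognitionProfile]:
    """Universal profile plus any taxon-specific supplements for one
    region, trained on ``records`` (default: all)."""
    uni = profiles_mod.build_profile(ref, region, records=records,
                                     config=config)
    sups = profiles_mod.build_taxon_profiles(ref, region, config=config,
                                             universal=uni, records=records)
    return [uni] + sups


def holdout_sensitivity(seed: int, n_train: int = 400, n_test: int = 200,
                        region: str = "V4") -> dict:
    """Train profiles on ``n_train`` synthetic references and measure
    the detection rate on ``n_test`` held-out references from the same
    community generator."""
    spec = synthetic.CommunitySpec(n_taxa=n_train + n_test, seed=seed)
    rng = np.random.default_rng(seed)
    ref = synthetic.make_reference(spec, rng)
    profs = train_profiles(ref, region, records=np.arange(n_train))
    held = [(sid, s) for sid, s, _ in ref.records[n_train:]]
    value = sensitivity(profs, held)
    return {"sensitivity": value, "n_train": n_train, "n_test": n_test,
            "n_profiles": len(profs)}


def specificity_experiment(seed: int, n_fragments: int = 10_000_000,
                           length: int = 80, n_train: int = 400,
                           region: str = "V4") -> dict:
    """Faux-read false-positive rate of profiles trained on a synthetic
    community: scan ``n_fragments`` random non-SSU fragments."""
    spec = synthetic.CommunitySpec(n_taxa=n_train, seed=seed)
    rng = np.random.default_rng(seed)
    ref = synthetic.make_reference(spec, rng)
    profs = train_profiles(ref, region)
    res = false_positive_rate(profs, n_fragments, length=length, rng=rng)
    return {"fpr": res.rate, "positives": res.positives,
            "n_fragments": n_fragments, "n_profiles": len(profs)}


def error_model_experiment(seed: int, n_reads: int = 1_000_000,
                           per_base_error: float = 0.001,
                           read_length: int = 80,
                           region: str = "V4") -> dict:
    """Generative check of the sequencing-error model.

    Simulates ``n_reads`` reads from a single organism, every read
    fully covering the region's RS + tag window, with i.i.d. per-base
    substitution errors.  Among reads that yield an observation, each specific
    1-nt tag variant should be seen ``Binomial(n_detected,
    (e/3)(1-e)^(L-1))`` times — an error at its position, no second
    error elsewhere in the tag (tag errors are independent of whether
    the RS was detected) — and
    ``expected_fp`` applied to the resulting tag table should recover
    each variant's count.  Returns per-variant counts, the binomial
    mean/sigma, and the worst standardized deviations.
    """
    spec = synthetic.CommunitySpec(seed=seed, read_length=read_length,
                                   per_base_error=per_base_error)
    rng = np.random.default_rng(seed)
    ref = synthetic.make_reference(spec, rng)
    profs = train_profiles(ref, region)

    # the true tag of taxon 0, from an error-free scan of its reference
    sid0, seq0, _ = ref.records[0]
    clean = scan_reads([(sid0, seq0)], profs)[0][0]
    true_tag = clean.tag
    L = len(true_tag)
    w0 = clean.rs_offset
    read_spec = synthetic.CommunitySpec(
        n_taxa=spec.n_taxa, seed=seed, read_length=read_length,
        per_base_error=per_base_error)
    seqs, quals, _ = synthetic.simulate_reads(
        ref, read_spec, rng, n_reads=n_reads,
        cover=(w0, w0 + profiles_mod.RS_LENGTH + L),
        taxa=np.zeros(n_reads, dtype=int))
    obs = scan_batch(seqs, quals, profs, sample_id="errormodel")
    records = tagcount.aggregate(obs, "errormodel")
    by_tag = {r.tag: r for r in records}

    # tag errors are independent of RS detection, so among the reads
    # that actually yielded an observation each specific variant is
    # Binomial(n_detected, (e/3)(1-e)^(L-1))
    n_detected = sum(r.n for r in records)
    e = per_base_error
    p = (e / 3.0) * (1.0 - e) ** (L - 1)
    mean = n_detected * p
    sigma = float(np.sqrt(n_detected * p * (1.0 - p)))
    variants = []
    for j, orig in enumerate(true_tag):
        for b in "ACGT":
            if b == orig:
                continue
            v = true_tag[:j] + b + true_tag[j + 1:]
            rec = by_tag.get(v)
            count = rec.n if rec is not None else 0
            fp = rec.fp if rec is not None else 0.0
            variants.append({"count": count, "fp": fp,
                             "z_count": (count - mean) / sigma,
                             "z_fp": (count - fp) / sigma})
    zc = [abs(v["z_count"]) for v in variants]
    zf = [abs(v["z_fp"]) for v in variants]
    return {"n_reads": n_reads, "n_detected": n_detected,
            "true_tag": true_tag,
            "true_count": by_tag[true_tag].n,
            "binomial_mean": mean, "binomial_sigma": sigma,
            "variants": variants,
            "max_abs_z_count": max(zc), "max_abs_z_fp": max(zf),
            "frac_within_3sigma": float(np.mean([z <= 3 for z in zc])),
            "fp_within_3sigma": float(np.mean([z <= 3 for z in zf]))}


def recovery_experiment(seed: int, n_taxa: int = 20,
                        n_reads: int = 30_000,
                        region: str = "V4") -> dict:
    """End-to-end check on an error-free community.

    Trains profiles, simulates error-free reads with geometric
    abundances, runs the scan/aggregate pipeline and compares the
    recovered tag set and relative counts with the truth (tags the
    profiles detect on the error-free references themselves).
    """
    w = 0.85 ** np.arange(n_taxa)
    w /= w.sum()
    spec = synthetic.CommunitySpec(n_taxa=n_taxa, seed=seed,
                                   per_base_error=0.0,
                                   abundances=tuple(w), n_reads=n_reads)
    rng = np.random.default_rng(seed)
    ref = synthetic.make_reference(spec, rng)
    profs = train_profiles(ref, region)

    truth_obs, _ = scan_reads(((sid, s) for sid, s, _ in ref.records),
                              profs)
    truth_weight: dict[str, float] = {}
    for ob in truth_obs:
        idx = int(ob.read_id[1:])       # taxon ids are T%04d
        truth_weight[ob.tag] = truth_weight.get(ob.tag, 0.0) + w[idx]

    seqs, quals, _ = synthetic.simulate_reads(ref, spec, rng)
    obs = scan_batch(seqs, quals, profs, sample_id="recovery")
    records = tagcount.aggregate(obs, "recovery")
    counts = {r.tag: r.n for r in records}

    tags = sorted(truth_weight)
    x = np.array([truth_weight[t] for t in tags])
    y = np.array([counts.get(t, 0) for t in tags], dtype=float)
    r = float(np.corrcoef(x, y)[0, 1]) if len(tags) > 1 else 1.0
    return {"n_true_tags": len(truth_weight),
            "n_observed_tags": len(counts),
            "missing": sorted(set(truth_weight) - set(counts)),
            "extra": sorted(set(counts) - set(truth_weight)),
            "pearson_r": r}
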