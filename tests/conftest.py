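"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive expected results by enumeration or
naive looping, independent of the package's own code paths.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cnasim import (ArmaModel, BafNoiseModel, LrrModel, SampleConfig)


@pytest.fixture
def default_config():
    return SampleConfig()


@pytest.fixture
def zero_noise_config():
    return SampleConfig().zero_noise()


# ---------------------------------------------------------------------------
# genotype coherence oracle


def admissible_region_genotypes(cns, n_snps, germline=False):
    """Enumerate every coherent (x, z) tuple for one region, by brute force.

    Rules enforced directly from first principles:
      * normal clone diploid, z1 in {0,1,2} (germline regions: {0,2});
      * homozygous normal forces the same homozygous allele in each clone;
      * heterozygous normal bounds z by the clone copy number;
      * per clone there must exist one event value m with every
        heterozygous SNP's z in {m, cn - m}.

    Returns a set of flattened ``(z1..zn per clone incl normal)`` tuples,
    keyed by the normal-genotype column.
    """
    z1_values = (0, 2) if germline else (0, 1, 2)
    result = set()
    for z1 in itertools.product(z1_values, repeat=n_snps):
        clone_options = []
        for cn in cns:
            options = set()
            het_idx = [i for i in range(n_snps) if z1[i] == 1]
            base = [0] * n_snps
            for i in range(n_snps):
                if z1[i] == 0:
                    base[i] = 0
                elif z1[i] == 2:
                    base[i] = cn
            if not het_idx:
                options.add(tuple(base))
            else:
                for m in range(cn + 1):
                    for choice in itertools.product((m, cn - m),
                                                    repeat=len(het_idx)):
                        col = list(base)
                        for i, v in zip(het_idx, choice):
                            col[i] = v
                        options.add(tuple(col))
            clone_options.append(options)
        for combo in itertools.product(*clone_options):
            result.add((z1,) + combo)
    return result


# ---------------------------------------------------------------------------
# evaluation oracle: naive all-pairs overlap scoring


def naive_recall(truth_regions, calls, min_overlap=0.5, require_loh=False):
    """(n_recalled, n_truth) by exhaustive per-call checking."""

    def has_loh_t(r):
        return r.loh_status in ("somatic", "germline")

    def has_loh_c(c):
        return c.loh in ("somatic", "germline")

    def major_cn(r):
        fr = list(r.fractions)
        return r.cns[fr.index(max(fr))]

    truth_kept = [r for r in truth_regions
                  if not (r.cns == (2,) and r.loh_status == "none")]
    calls_kept = [c for c in calls
                  if not (c.copy_number == 2 and not has_loh_c(c))]
    n_rec = 0
    for r in truth_kept:
        hit = False
        for c in calls_kept:
            if c.chrom != r.chrom or c.copy_number != major_cn(r):
                continue
            if require_loh and has_loh_c(c) != has_loh_t(r):
                continue
            ov = min(r.end_bp, c.end) - max(r.start_bp, c.start)
            if ov >= min_overlap * (r.end_bp - r.start_bp):
                hit = True
        n_rec += int(hit)
    return n_rec, len(truth_kept)


def naive_fdr(truth_regions, calls):
    """(total_fdr, n_calls) by exhaustive maximal-overlap matching."""

    def has_loh_c(c):
        return c.loh in ("somatic", "germline")

    def major_cn(r):
        fr = list(r.fractions)
        return r.cns[fr.index(max(fr))]

    truth_kept = [r for r in truth_regions
                  if not (r.cns == (2,) and r.loh_status == "none")]
    calls_kept = [c for c in calls
                  if not (c.copy_number == 2 and not has_loh_c(c))]
    wrong = 0
    for c in calls_kept:
        overlaps = []
        for k, r in enumerate(truth_kept):
            if r.chrom != c.chrom:
                continue
            ov = min(r.end_bp, c.end) - max(r.start_bp, c.start)
            if ov > 0:
                overlaps.append((ov, -r.start_bp, k))
        if not overlaps:
            wrong += 1
            continue
        best = max(overlaps)
        if major_cn(truth_kept[best[2]]) != c.copy_number:
            wrong += 1
    n = len(calls_kept)
    return (wrong / n if n else 0.0), n
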