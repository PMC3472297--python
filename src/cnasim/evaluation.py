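"""Benchmarking harness: overlap-based recall and wrong-copy-number FDR.

A truth region counts as recalled when a single call with the same copy
number overlaps at least half of the region's length (bp, half-open
intervals; the threshold is configurable and inclusive).  Heterozygous
diploid fragments are stripped from both truth and calls before scoring.
The FDR approximation assigns every call to the truth region of maximal
overlap and counts calls whose copy number disagrees; because callers with
finer breakpoints accumulate more assignments, these FDRs are not
comparable across callers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CallRecord

__all__ = [
    "region_recalled",
    "recall_table",
    "fdr_matrix",
    "FdrMatrix",
    "ContractionFit",
    "estimate_contraction",
    "LENGTH_BINS",
]

#: length bins in SNP units (lower edges); the menu lengths map one-to-one
LENGTH_BINS = (10, 20, 40, 80, 160)


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _truth_cn(region) -> int:
    """Copy number used for matching: the major subclone's CN."""
    if len(region.cns) == 1:
        return int(region.cns[0])
    k = int(np.argmax(region.fractions))
    return int(region.cns[k])


def _truth_has_loh(region) -> bool:
    return region.loh_status in ("somatic", "germline")


def _call_has_loh(call: CallRecord) -> bool:
    return call.loh in ("somatic", "germline")


def _is_diploid_call(call: CallRecord) -> bool:
    return call.copy_number == 2 and not _call_has_loh(call)


def region_recalled(truth_region, calls, min_overlap: float = 0.5,
                    require_loh: bool = False) -> bool:
    """True iff one single call covers the region well enough.

    Matching requires the same copy number; with ``require_loh`` also the
    same LOH presence/absence (germline vs somatic are interchangeable).
    Multiple partial calls are never pooled.
    """
    if not (0 < min_overlap <= 1):
        raise ValueError("min_overlap must lie in (0, 1]")
    length = truth_region.end_bp - truth_region.start_bp
    cn = _truth_cn(truth_region)
    for call in calls:
        if call.chrom != truth_region.chrom or call.copy_number != cn:
            continue
        if require_loh and _call_has_loh(call) != _truth_has_loh(truth_region):
            continue
        ov = _overlap(truth_region.start_bp, truth_region.end_bp,
                      call.start, call.end)
        if ov >= min_overlap * length:
            return True
    return False


def _length_bin(n_snps: int) -> int:
    edges = [b for b in LENGTH_BINS if b <= n_snps]
    return edges[-1] if edges else 0


def recall_table(truth_sets, call_sets, contaminations=None,
                 min_overlap: float = 0.5, require_loh: bool = False,
                 group_by=("contamination", "copy_number")) -> pd.DataFrame:
    """Aggregate recall over paired samples, grouped per the chosen keys.

    ``truth_sets``/``call_sets`` are parallel lists (one entry per sample);
    ``contaminations`` may override the per-truth contamination label.
    Diploid-heterozygous truth regions and calls are excluded up front.
    Returns a tidy frame with ``n_truth``, ``n_recalled`` and ``recall``;
    cells without truth regions simply do not appear.
    """
    if len(truth_sets) != len(call_sets):
        raise ValueError("truth_sets and call_sets must pair up")
    valid = {"contamination", "copy_number", "length_bin", "loh"}
    if not set(group_by) <= valid:
        raise ValueError(f"group_by keys must be among {sorted(valid)}")
    rows = {}
    for k, (truth, calls) in enumerate(zip(truth_sets, call_sets)):
        regions = getattr(truth, "regions", truth)
        cont = (contaminations[k] if contaminations is not None
                else getattr(truth, "contamination", float("nan")))
        kept_calls = [c for c in calls if not _is_diploid_call(c)]
        for region in regions:
            if region.is_diploid_het:
                continue
            key = []
            for g in group_by:
                if g == "contamination":
                    key.append(cont)
                elif g == "copy_number":
                    key.append(_truth_cn(region))
                elif g == "length_bin":
                    key.append(_length_bin(region.n_snps))
                else:
                    key.append(_truth_has_loh(region))
            key = tuple(key)
            n_rec, n_tot = rows.get(key, (0, 0))
            hit = region_recalled(region, kept_calls, min_overlap=min_overlap,
                                  require_loh=require_loh)
            rows[key] = (n_rec + int(hit), n_tot + 1)
    out = []
    for key, (n_rec, n_tot) in sorted(rows.items(), key=lambda kv: str(kv[0])):
        rec = dict(zip(group_by, key))
        rec.update(n_truth=n_tot, n_recalled=n_rec, recall=n_rec / n_tot)
        out.append(rec)
    return pd.DataFrame(out)


@dataclass
class FdrMatrix:
    """Wrong-call fractions by (called CN, true CN); true CN ``-1`` means
    the call overlapped no truth region."""

    matrix: pd.DataFrame
    total_fdr: float
    n_calls: int


def fdr_matrix(truth, calls) -> FdrMatrix:
    """Wrong-copy-number FDR for one sample.

    Every non-diploid call is matched to the truth region (diploid excluded)
    of maximal bp overlap, ties to the leftmost; a call is wrong iff its CN
    differs from that region's.  Cell values are wrong-call counts divided
    by the total number of calls, so ``total_fdr`` is the off-diagonal mass.
    """
    regions = [r for r in getattr(truth, "regions", truth)
               if not r.is_diploid_het]
    kept = [c for c in calls if not _is_diploid_call(c)]
    if not kept:
        empty = pd.DataFrame(dtype=float)
        return FdrMatrix(matrix=empty, total_fdr=0.0, n_calls=0)
    counts = {}
    for call in kept:
        best, best_ov = None, 0
        # genome-order scan with a strict improvement test: ties stay with
        # the leftmost truth region
        for region in regions:
            if region.chrom != call.chrom:
                continue
            ov = _overlap(region.start_bp, region.end_bp, call.start, call.end)
            if ov > best_ov:
                best, best_ov = region, ov
        true_cn = _truth_cn(best) if best_ov > 0 else -1
        key = (call.copy_number, true_cn)
        counts[key] = counts.get(key, 0) + 1
    called = sorted({k[0] for k in counts})
    trues = sorted({k[1] for k in counts})
    mat = pd.DataFrame(0.0, index=called, columns=trues)
    wrong = 0
    for (ccn, tcn), n in counts.items():
        if ccn != tcn:
            mat.loc[ccn, tcn] = n / len(kept)
            wrong += n
    mat.index.name = "called_cn"
    mat.columns.name = "true_cn"
    return FdrMatrix(matrix=mat, total_fdr=wrong / len(kept),
                     n_calls=len(kept))


@dataclass
class ContractionFit:
    """Per-sample contraction coefficients and their fit against purity."""

    q: np.ndarray            # one coefficient per sample
    purity: np.ndarray       # 1 - contamination per sample
    slope: float
    intercept: float
    r_squared: float


def estimate_contraction(samples, lrr_model) -> ContractionFit:
    """Fit the contraction coefficient q against tumour purity.

    ``samples`` is a list of ``(SampleTruth, SignalTrack, contamination)``.
    Per sample, the observed per-region LRR means (baseline shift removed)
    are regressed on their pure-tumour expectations; the slope is that
    sample's q.  The q values are then regressed on purity.
    """
    if len(samples) < 2:
        raise ValueError("need samples at >= 2 contamination levels")
    qs, purities = [], []
    for truth, track, cont in samples:
        expected, observed = [], []
        for r in truth.regions:
            mu = float(sum(f * lrr_model.mu[c]
                           for f, c in zip(r.fractions, r.cns)))
            obs = float(np.mean(track.lrr[r.snp_start:r.snp_end])) - truth.shift
            expected.append(mu)
            observed.append(obs)
        expected = np.asarray(expected)
        observed = np.asarray(observed)
        if np.ptp(expected) == 0:
            raise ValueError("degenerate regression: all regions share one "
                             "expected LRR (e.g. an all-diploid sample)")
        fit = stats.linregress(expected, observed)
        qs.append(fit.slope)
        purities.append(1.0 - cont)
    qs = np.asarray(qs)
    purities = np.asarray(purities)
    if np.ptp(purities) == 0:
        raise ValueError("need >= 2 distinct contamination levels")
    fit = stats.linregress(purities, qs)
    return ContractionFit(q=qs, purity=purities, slope=float(fit.slope),
                          intercept=float(fit.intercept),
                          r_squared=float(fit.rvalue ** 2))
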