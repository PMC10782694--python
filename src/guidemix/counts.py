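"""From guide x sample read counts to per-guide logFCs.

Pipeline: low-abundance filtering (counts per million), per-sample
normalization factors estimated by a trimmed mean of M-values (TMM) on the
non-targeting control guides — which by design have no fitness effect and
therefore anchor logFC 0 — and a normalized log-ratio depletion estimate
with replicate averaging. The estimator consumes library sizes from full
column sums and normalization factors from the control subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Counts with sample and guide annotations.

    ``counts``: guides x samples (non-negative ints, index = guide_id);
    ``sample_meta``: per-sample (timepoint, replicate, is_input), indexed
    by sample name; ``guide_meta``: per-guide (gene_id, is_nontargeting).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    guide_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("every sample must have positive total counts")
        if not self.sample_meta["is_input"].any():
            raise ValueError("need at least one input sample")
        if not self.guide_meta["is_nontargeting"].any():
            raise ValueError("need non-targeting guides for normalization")
        if not self.counts.index.equals(self.guide_meta.index):
            raise ValueError("counts and guide_meta must share an index")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_guides(self, keep: pd.Index) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.loc[keep],
            sample_meta=self.sample_meta,
            guide_meta=self.guide_meta.loc[keep],
        )


def cpm_filter(
    cm: CountMatrix, min_cpm: float = 1.0, min_samples: int = 4
) -> CountMatrix:
    """Keep guides with >= ``min_cpm`` counts per million in >= ``min_samples``
    samples (inclusive bounds); CPM uses raw column sums."""
    cpm = cm.counts / cm.library_sizes * 1e6
    keep = cm.counts.index[(cpm >= min_cpm).sum(axis=1) >= min_samples]
    if len(keep) == 0:
        raise ValueError("CPM filter removed every guide")
    dropped = len(cm.counts) - len(keep)
    if dropped:
        logger.info("CPM filter dropped %d of %d guides", dropped, len(cm.counts))
    return cm.subset_guides(keep)


def nontargeting_norm_factors(
    cm: CountMatrix,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> pd.Series:
    """TMM normalization factors from the non-targeting subset.

    For each sample against the reference (the first input sample), guide-
    wise log-ratios M and average abundances A are computed on control
    guides with positive counts in both; the upper and lower ``m_trim``
    and ``a_trim`` quantiles are discarded and the factor is the
    precision-weighted mean of the surviving M values (on the log2 scale),
    normalized so the factors' geometric mean is 1. Downstream logFCs are
    invariant to that final rescaling.
    """
    nt = cm.counts[cm.guide_meta["is_nontargeting"]]
    if len(nt) < 5:
        raise ValueError(f"need >= 5 non-targeting guides, got {len(nt)}")
    lib = cm.library_sizes
    ref = cm.sample_meta.index[cm.sample_meta["is_input"]][0]

    log_factors = {}
    for sample in cm.counts.columns:
        if sample == ref:
            log_factors[sample] = 0.0
            continue
        y, r = nt[sample].to_numpy(float), nt[ref].to_numpy(float)
        ok = (y > 0) & (r > 0)
        y, r = y[ok], r[ok]
        if len(y) == 0:
            raise ValueError(f"no usable non-targeting guides for sample {sample}")
        py, pr = y / lib[sample], r / lib[ref]
        M = np.log2(py / pr)
        A = 0.5 * np.log2(py * pr)
        w = (lib[sample] - y) / (lib[sample] * y) + (lib[ref] - r) / (lib[ref] * r)
        keep = np.ones(len(M), dtype=bool)
        if len(M) > 4:
            m_lo, m_hi = np.quantile(M, [m_trim, 1 - m_trim])
            a_lo, a_hi = np.quantile(A, [a_trim, 1 - a_trim])
            keep = (M >= m_lo) & (M <= m_hi) & (A >= a_lo) & (A <= a_hi)
            if not keep.any():
                keep[:] = True
        log_factors[sample] = float(np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))

    f = pd.Series({s: 2.0**lf for s, lf in log_factors.items()})
    f /= np.exp(np.mean(np.log(f)))
    return f


def estimate_logfc(
    cm: CountMatrix,
    factors: pd.Series,
    pseudo: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Replicate-averaged normalized log2 fold-changes per timepoint.

    For each output sample and its replicate-matched input:
    logFC = log2[(y_out + pseudo) / (N_out f_out)] -
            log2[(y_in + pseudo) / (N_in f_in)],
    averaged over replicates. Also returns the non-targeting guides'
    median logFC per timepoint (a calibration statistic; ~0 when
    normalization is adequate).
    """
    meta = cm.sample_meta
    inputs = {
        int(row["replicate"]): s for s, row in meta[meta["is_input"]].iterrows()
    }
    if not inputs:
        raise ValueError("no input samples")
    lib = cm.library_sizes

    def norm_abund(sample: str) -> np.ndarray:
        return (cm.counts[sample].to_numpy(float) + pseudo) / (
            lib[sample] * factors.get(sample, 1.0)
        )

    frames = []
    for tp, grp in meta[~meta["is_input"]].groupby("timepoint"):
        per_rep = []
        for sample, row in grp.iterrows():
            rep = int(row["replicate"])
            if rep not in inputs:
                raise ValueError(f"no input sample for replicate {rep}")
            per_rep.append(np.log2(norm_abund(sample) / norm_abund(inputs[rep])))
        frames.append(
            pd.DataFrame(
                {
                    "guide_id": cm.counts.index,
                    "gene_id": cm.guide_meta["gene_id"].to_numpy(),
                    "timepoint": tp,
                    "logfc": np.mean(per_rep, axis=0),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    nt_ids = set(cm.guide_meta.index[cm.guide_meta["is_nontargeting"]])
    calib = {
        tp: float(grp[grp["guide_id"].isin(nt_ids)]["logfc"].median())
        for tp, grp in out.groupby("timepoint")
    }
    for tp, med in calib.items():
        logger.info("non-targeting median logFC at %s: %.3f", tp, med)
    return out, calib
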