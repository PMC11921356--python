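"""RPKM computation and differential expression between culture conditions.

Expression is quantified as RPKM (reads per kilobase of gene per million
mapped reads)::

    RPKM[g, s] = counts[g, s] / (length_g / 1000 * total_s / 1e6)

Differential expression between coculture and monoculture transcriptomes is
called per gene by a two-tailed pooled t-test on RPKM values, with
Benjamini-Hochberg correction across genes and strict gates
``fold change > fc_threshold`` (default 4) and ``q < alpha`` (default 0.05).
This deliberately tests normalized expression values directly rather than
fitting a count model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interactions import fdr_adjust, student_t_test

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"

COCULTURE = "coculture"
MONOCULTURE = "monoculture"


@dataclass
class CountMatrix:
    """Gene-level read counts with gene lengths and per-sample totals.

    ``totals`` defaults to column sums; an explicit override is allowed
    (and flagged) because library-wide mapped-read totals may exceed the
    sum over annotated genes.
    """

    gene_ids: list
    gene_lengths: np.ndarray  # bp
    sample_ids: list
    condition: dict  # sample_id -> condition label
    counts: np.ndarray  # (genes, samples)
    totals: np.ndarray | None = None
    totals_overridden: bool = field(default=False, init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.gene_lengths = np.asarray(self.gene_lengths, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape must be (n_genes, n_samples)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.gene_lengths <= 0):
            raise ValueError("gene lengths must be positive")
        colsums = self.counts.sum(axis=0)
        if self.totals is None:
            self.totals = colsums.astype(float)
        else:
            self.totals = np.asarray(self.totals, dtype=float)
            if not np.array_equal(self.totals, colsums):
                self.totals_overridden = True
                logger.info("per-sample totals overridden (differ from column sums)")
        missing = [s for s in self.sample_ids if s not in self.condition]
        if missing:
            raise ValueError(f"samples without a condition label: {missing}")

    def samples_in(self, condition: str) -> list:
        return [i for i, s in enumerate(self.sample_ids) if self.condition[s] == condition]

    @classmethod
    def from_tsv(cls, path, condition: dict, totals=None) -> "CountMatrix":
        """Read a counts TSV: columns ``gene_id, length_bp`` then one
        integer column per sample."""
        df = pd.read_csv(path, sep="\t")
        for col in ("gene_id", "length_bp"):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        samples = [c for c in df.columns if c not in ("gene_id", "length_bp")]
        return cls(
            gene_ids=df["gene_id"].astype(str).tolist(),
            gene_lengths=df["length_bp"].to_numpy(),
            sample_ids=samples,
            condition=condition,
            counts=df[samples].to_numpy(),
            totals=totals,
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.counts, columns=self.sample_ids)
        df.insert(0, "length_bp", self.gene_lengths.astype(int))
        df.insert(0, "gene_id", self.gene_ids)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class DifferentialExpressionResult:
    gene_id: str
    mean_rpkm_co: float
    mean_rpkm_mono: float
    fold_change: float
    log2fc: float
    p_raw: float
    q: float
    status: str


def compute_rpkm(counts: CountMatrix) -> np.ndarray:
    """RPKM matrix (genes x samples) by direct evaluation of the formula."""
    if np.any(counts.totals <= 0):
        bad = [s for s, t in zip(counts.sample_ids, counts.totals) if t <= 0]
        raise ValueError(f"zero total reads in sample(s): {bad}")
    denom = (counts.gene_lengths[:, None] / 1_000.0) * (counts.totals[None, :] / 1e6)
    return counts.counts / denom


def differential_expression(counts: CountMatrix, alpha: float = 0.05,
                            fc_threshold: float = 4.0,
                            pseudocount: float = 0.01) -> list:
    """Per-gene DE calls between coculture and monoculture samples.

    Fold change is ``(mean_rpkm_co + c) / (mean_rpkm_mono + c)`` with
    pseudocount ``c`` (RPKM units).  Genes with zero counts in every sample
    are excluded before testing.  Status gates are strict:
    up means ``fold_change > fc_threshold`` and ``q < alpha``; down means
    ``fold_change < 1/fc_threshold`` and ``q < alpha``.
    """
    co_idx = counts.samples_in(COCULTURE)
    mono_idx = counts.samples_in(MONOCULTURE)
    if len(co_idx) < 2 or len(mono_idx) < 2:
        raise ValueError("need >= 2 samples in each of coculture and monoculture")

    rpkm = compute_rpkm(counts)
    expressed = counts.counts.sum(axis=1) > 0

    results = []
    p_raw = []
    kept = np.flatnonzero(expressed)
    for g in kept:
        x = rpkm[g, co_idx]
        y = rpkm[g, mono_idx]
        if np.ptp(x) == 0 and np.ptp(y) == 0 and x.mean() == y.mean():
            t, p = 0.0, 1.0
        else:
            t, p = student_t_test(x, y)
        p_raw.append(p)
        mc, mm = float(x.mean()), float(y.mean())
        fc = (mc + pseudocount) / (mm + pseudocount)
        results.append(DifferentialExpressionResult(
            gene_id=counts.gene_ids[g], mean_rpkm_co=mc, mean_rpkm_mono=mm,
            fold_change=fc, log2fc=float(np.log2(fc)), p_raw=p,
            q=np.nan, status=UNCHANGED,
        ))
    q = fdr_adjust(p_raw)
    for r, qi in zip(results, q):
        r.q = float(qi)
        if r.q < alpha and r.fold_change > fc_threshold:
            r.status = UP
        elif r.q < alpha and r.fold_change < 1.0 / fc_threshold:
            r.status = DOWN
    n_up = sum(r.status == UP for r in results)
    n_down = sum(r.status == DOWN for r in results)
    logger.info("DE: %d genes tested, %d up, %d down", len(results), n_up, n_down)
    return results


def top_n_by_fold_change(results, n: int = 40, direction: str = UP) -> list:
    """The top-n genes of one status ranked by fold change.

    Up-regulated genes sort by descending fold change, down-regulated by
    ascending; ties break by smaller q, then gene_id.
    """
    if direction not in (UP, DOWN):
        raise ValueError(f"direction must be '{UP}' or '{DOWN}'")
    sub = [r for r in results if r.status == direction]
    sign = -1 if direction == UP else 1
    sub.sort(key=lambda r: (sign * r.fold_change, r.q, r.gene_id))
    return sub[:n]


def de_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.mean_rpkm_co, r.mean_rpkm_mono, r.fold_change,
          r.log2fc, r.p_raw, r.q, r.status) for r in results],
        columns=["gene_id", "mean_rpkm_co", "mean_rpkm_mono", "fold_change",
                 "log2fc", "p_raw", "q", "status"],
    )
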