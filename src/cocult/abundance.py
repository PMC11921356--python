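"""Community-abundance statistics for amplicon and metagenome count tables.

Two normalizations live here:

* 16S amplicon read counts are divided by each strain's genomic 16S rRNA
  gene copy number before computing relative abundance (multi-copy genomes
  otherwise inflate their apparent share);
* metagenome read-recruitment counts are rarefied to a fixed depth
  (default 1,000,000 reads) by without-replacement subsampling before
  pairwise Spearman co-occurrence analysis with BH correction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sstats

from .interactions import fdr_adjust

logger = logging.getLogger(__name__)


@dataclass
class AmpliconTable:
    """Per-timepoint amplicon read counts with per-strain 16S copy numbers."""

    timepoints: list  # days
    strain_ids: list
    read_counts: np.ndarray  # (timepoints, strains)
    copy_numbers: np.ndarray  # 16S copies per genome, per strain

    def __post_init__(self):
        self.read_counts = np.asarray(self.read_counts)
        self.copy_numbers = np.asarray(self.copy_numbers)
        if self.read_counts.shape != (len(self.timepoints), len(self.strain_ids)):
            raise ValueError("read_counts shape must be (n_timepoints, n_strains)")
        if np.any(self.read_counts < 0):
            raise ValueError("read counts must be non-negative")
        if np.any(self.copy_numbers <= 0):
            raise ValueError("16S copy numbers must be positive")


@dataclass
class RecruitmentMatrix:
    """Metagenomic read-recruitment counts per (sample, strain).

    ``other_counts`` holds reads per sample not recruited by any of the
    strains; including it keeps the strains a small fraction of each
    rarefied library, as they are in real metagenomes.
    """

    sample_ids: list
    strain_ids: list
    counts: np.ndarray  # (samples, strains)
    other_counts: np.ndarray | None = None
    target_depth: int = 1_000_000
    read_length: int = 101  # bp, metadata

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.strain_ids)):
            raise ValueError("counts shape must be (n_samples, n_strains)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.other_counts is None:
            self.other_counts = np.zeros(len(self.sample_ids), dtype=self.counts.dtype)
        else:
            self.other_counts = np.asarray(self.other_counts)
        if self.target_depth <= 0:
            raise ValueError("target_depth must be positive")

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "RecruitmentMatrix":
        """Read a TSV with columns ``sample``, one per strain, and an
        optional ``other`` column."""
        df = pd.read_csv(path, sep="\t")
        if "sample" not in df.columns:
            raise ValueError("missing required column 'sample'")
        other = df.pop("other").to_numpy() if "other" in df.columns else None
        strains = [c for c in df.columns if c != "sample"]
        return cls(sample_ids=df["sample"].astype(str).tolist(), strain_ids=strains,
                   counts=df[strains].to_numpy(), other_counts=other, **kwargs)


@dataclass
class CorrelationResult:
    pair: tuple  # (strain_id, strain_id)
    rho: float
    p_raw: float
    q: float


def copy_number_normalize(reads, copies) -> np.ndarray:
    """Relative abundances after dividing reads by 16S copy numbers.

    ``a_i = (reads_i / copies_i) / sum_j (reads_j / copies_j)``; sums to 1.
    """
    reads = np.asarray(reads, dtype=float)
    copies = np.asarray(copies, dtype=float)
    if np.any(copies <= 0):
        raise ValueError("copy numbers must be positive")
    if reads.sum() <= 0:
        raise ValueError("relative abundance undefined: no reads")
    w = reads / copies
    return w / w.sum()


def relative_abundance_series(tables) -> pd.DataFrame:
    """Copy-number-normalized abundance time series, averaged over replicates.

    Accepts one :class:`AmpliconTable` or a list of replicate tables that
    share timepoints and strains; normalization is applied per timepoint in
    each replicate, then abundances are averaged across replicates.
    Returns a DataFrame indexed by day with one column per strain.
    """
    if isinstance(tables, AmpliconTable):
        tables = [tables]
    ref = tables[0]
    for t in tables[1:]:
        if t.timepoints != ref.timepoints or t.strain_ids != ref.strain_ids:
            raise ValueError("replicate tables must share timepoints and strains")
    per_rep = []
    for t in tables:
        ab = np.vstack([copy_number_normalize(row, t.copy_numbers)
                        for row in t.read_counts])
        per_rep.append(ab)
    mean_ab = np.mean(per_rep, axis=0)
    return pd.DataFrame(mean_ab, index=pd.Index(ref.timepoints, name="day"),
                        columns=ref.strain_ids)


def subsample_counts(counts, target_total: int, seed=None,
                     with_replacement: bool = False) -> np.ndarray:
    """Rarefy one sample's count vector to a fixed total.

    Without replacement (default) this is a multivariate hypergeometric
    draw; the result sums exactly to ``target_total`` and is deterministic
    given ``seed``.  With replacement draws a multinomial on the observed
    proportions (for samples shallower than the target).
    """
    counts = np.asarray(counts)
    total = int(counts.sum())
    if total == target_total and not with_replacement:
        return counts.copy()
    rng = np.random.default_rng(seed)
    if with_replacement:
        return rng.multinomial(target_total, counts / total)
    if total < target_total:
        raise ValueError(
            f"sample depth {total} < target {target_total}; "
            "use with_replacement=True to upsample"
        )
    return rng.multivariate_hypergeometric(counts, target_total)


def spearman(x, y) -> tuple:
    """Spearman rank correlation ``(rho, p)``.

    rho is the Pearson correlation of midranks; the p-value uses the
    t approximation ``t = rho * sqrt((n-2) / (1-rho^2))`` with n-2 df.
    Returns ``(nan, nan)`` when either argument has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need two equal-length vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("undefined Spearman correlation: constant input")
        return math.nan, math.nan
    rho, p = sstats.spearmanr(x, y)
    return float(rho), float(p)


def spearman_exact(x, y) -> tuple:
    """Exact-permutation Spearman p-value, for very small n (< 10)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho, _ = spearman(x, y)
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    perms = itertools.permutations(range(x.size))
    count = total = 0
    for pm in perms:
        r = np.corrcoef(rx, ry[list(pm)])[0, 1]
        count += abs(r) >= abs(rho) - 1e-12
        total += 1
    return rho, count / total


def pairwise_cooccurrence(matrix: RecruitmentMatrix, seed=None) -> list:
    """Strain co-occurrence across metagenomes.

    Each sample (strains plus the unrecruited remainder) is rarefied to
    ``matrix.target_depth``, Spearman rho is computed for every strain
    pair across samples, and p-values are BH-corrected across pairs.
    """
    n_samples = len(matrix.sample_ids)
    if n_samples < 4:
        raise ValueError("need >= 4 samples for co-occurrence analysis")
    rng = np.random.default_rng(seed)
    rarefied = np.empty_like(matrix.counts, dtype=np.int64)
    for i in range(n_samples):
        full = np.append(matrix.counts[i], matrix.other_counts[i])
        sub = subsample_counts(full, matrix.target_depth,
                               seed=rng.integers(2**31))
        rarefied[i] = sub[: len(matrix.strain_ids)]

    results = []
    p_raw = []
    for i, j in itertools.combinations(range(len(matrix.strain_ids)), 2):
        rho, p = spearman(rarefied[:, i], rarefied[:, j])
        results.append(CorrelationResult(
            pair=(matrix.strain_ids[i], matrix.strain_ids[j]),
            rho=rho, p_raw=p, q=math.nan))
        p_raw.append(p)
    finite = ~np.isnan(p_raw)
    if finite.any():
        q = np.full(len(p_raw), math.nan)
        q[finite] = fdr_adjust(np.asarray(p_raw)[finite])
        for r, qi in zip(results, q):
            r.q = float(qi)
    return results


def cooccurrence_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.pair[0], r.pair[1], r.rho, r.p_raw, r.q) for r in results],
        columns=["strain_a", "strain_b", "rho", "p_raw", "q"],
    )
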