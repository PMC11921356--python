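"""Data model and I/O for plate-reader coculture growth experiments.

The experimental unit is a *culture*: one or two strains grown on a single
carbon source, with OD600 recorded on a handful of sampling days (the
source design reads days 1, 3, 5, 7 and 9).  Each (strain set, carbon,
replicate) combination is one :class:`GrowthCurve`; a full experiment is a
:class:`GrowthDataset`.  The summary biomass used by downstream statistics
is the per-replicate maximum OD600, aggregated by :func:`group_stats`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: CSV columns required by :func:`read_growth_table`.
GROWTH_COLUMNS = ["strain_a", "strain_b", "carbon_source", "replicate", "day", "od600"]


class GrowthSchemaError(ValueError):
    """Raised when a growth table violates the expected schema."""


class InsufficientReplicatesError(ValueError):
    """Raised when a culture group has fewer replicates than required."""


def _canon_strains(strains) -> frozenset:
    s = frozenset(str(x) for x in strains if x is not None and str(x) != "")
    if len(s) not in (1, 2):
        raise ValueError(f"a culture holds 1 or 2 strains, got {sorted(s)}")
    return s


@dataclass(frozen=True)
class GrowthCurve:
    """One replicate OD600 time series for a mono- or coculture.

    Parameters
    ----------
    strains
        Set of one (monoculture) or two (coculture) strain identifiers.
    carbon
        Carbon-source identifier.
    replicate
        Biological replicate index (>= 1).
    times
        Strictly increasing sampling days.
    od
        OD600 readings, one per sampling day, all >= 0.
    """

    strains: frozenset
    carbon: str
    replicate: int
    times: tuple
    od: tuple

    def __post_init__(self):
        object.__setattr__(self, "strains", _canon_strains(self.strains))
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "od", tuple(float(v) for v in self.od))
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")
        if len(self.times) != len(self.od) or len(self.times) < 1:
            raise ValueError("times and od must have equal length >= 1")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError(f"times must be strictly increasing: {self.times}")
        if any(v < 0 for v in self.od):
            raise ValueError(f"OD600 values must be >= 0: {self.od}")

    @property
    def is_coculture(self) -> bool:
        return len(self.strains) == 2

    def key(self) -> tuple:
        return (self.strains, self.carbon, self.replicate)


@dataclass
class GrowthDataset:
    """A collection of growth curves plus experiment-level metadata.

    ``inoculum_od`` is the OD600 of the inoculum at t=0 (metadata only: it
    is not subtracted from readings).  ``noise_floor`` is the biomass level
    below which a mean maximum OD is treated as instrument noise.
    """

    curves: list = field(default_factory=list)
    inoculum_od: float = 0.005
    noise_floor: float = 0.05

    def __post_init__(self):
        if self.inoculum_od <= 0:
            raise ValueError("inoculum_od must be > 0")
        if self.noise_floor <= self.inoculum_od:
            raise ValueError("noise_floor must exceed inoculum_od")
        seen = set()
        for c in self.curves:
            k = c.key()
            if k in seen:
                raise ValueError(f"duplicate culture key {k}")
            seen.add(k)

    @property
    def strains(self) -> list:
        out = set()
        for c in self.curves:
            out |= c.strains
        return sorted(out)

    @property
    def carbons(self) -> list:
        return sorted({c.carbon for c in self.curves})

    @property
    def pairs(self) -> list:
        """All coculture strain pairs present, as sorted tuples."""
        return sorted({tuple(sorted(c.strains)) for c in self.curves if c.is_coculture})

    def group(self, strains, carbon) -> list:
        """All replicate curves for one (strain set, carbon) combination."""
        key = _canon_strains(strains)
        return sorted(
            (c for c in self.curves if c.strains == key and c.carbon == str(carbon)),
            key=lambda c: c.replicate,
        )


@dataclass(frozen=True)
class GroupStats:
    """Per-replicate maximum OD600 of one culture group, with summaries."""

    values: tuple
    mean: float
    sd: float
    n: int

    @classmethod
    def from_values(cls, values) -> "GroupStats":
        v = np.asarray(values, dtype=float)
        if v.size < 1:
            raise ValueError("need at least one value")
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        return cls(values=tuple(v.tolist()), mean=float(v.mean()), sd=sd, n=int(v.size))


def max_od(curve: GrowthCurve) -> float:
    """Maximum OD600 over a curve's recorded timepoints."""
    return max(curve.od)


def group_stats(dataset: GrowthDataset, strains, carbon) -> GroupStats:
    """Per-replicate maxima and summary statistics for one culture group.

    Raises
    ------
    InsufficientReplicatesError
        If fewer than two replicates exist for the key.
    """
    curves = dataset.group(strains, carbon)
    if len(curves) < 2:
        raise InsufficientReplicatesError(
            f"group ({sorted(_canon_strains(strains))}, {carbon}) has "
            f"{len(curves)} replicate(s); need >= 2"
        )
    return GroupStats.from_values([max_od(c) for c in curves])


def read_growth_table(path, inoculum_od: float = 0.005, noise_floor: float = 0.05) -> GrowthDataset:
    """Read a tidy growth CSV into a validated :class:`GrowthDataset`.

    Expected columns: ``strain_a, strain_b, carbon_source, replicate, day,
    od600``; an empty ``strain_b`` denotes a monoculture.  One row per
    (culture, day); duplicated (strain set, carbon, replicate, day) rows are
    rejected.
    """
    df = pd.read_csv(path, dtype={"strain_a": str, "strain_b": str})
    missing = [c for c in GROWTH_COLUMNS if c not in df.columns]
    if missing:
        raise GrowthSchemaError(f"missing required column(s): {', '.join(missing)}")
    bad = pd.to_numeric(df["od600"], errors="coerce").isna() & df["od600"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise GrowthSchemaError(f"non-numeric od600 at file row {row}")
    if df["od600"].isna().any():
        row = int(np.flatnonzero(df["od600"].isna().to_numpy())[0]) + 2
        raise GrowthSchemaError(f"missing od600 at file row {row}")
    df["od600"] = df["od600"].astype(float)
    df["strain_b"] = df["strain_b"].fillna("")

    curves = []
    keycols = ["strain_a", "strain_b", "carbon_source", "replicate"]
    for (sa, sb, carbon, rep), sub in df.groupby(keycols, sort=True):
        strains = {sa} if sb == "" else {sa, sb}
        if sub.duplicated("day").any():
            raise GrowthSchemaError(
                f"duplicated day for culture ({sorted(strains)}, {carbon}, rep {rep})"
            )
        sub = sub.sort_values("day")
        curves.append(
            GrowthCurve(
                strains=strains,
                carbon=str(carbon),
                replicate=int(rep),
                times=sub["day"].tolist(),
                od=sub["od600"].tolist(),
            )
        )
    ds = GrowthDataset(curves=curves, inoculum_od=inoculum_od, noise_floor=noise_floor)
    logger.info("read %d curves (%d strains, %d carbons) from %s",
                len(curves), len(ds.strains), len(ds.carbons), path)
    return ds


def write_growth_table(dataset: GrowthDataset, path) -> None:
    """Write a dataset back to the tidy CSV schema (OD to 4 decimals)."""
    rows = []
    for c in sorted(dataset.curves, key=lambda c: (sorted(c.strains), c.carbon, c.replicate)):
        ss = sorted(c.strains)
        sa, sb = (ss[0], ss[1]) if len(ss) == 2 else (ss[0], "")
        for t, v in zip(c.times, c.od):
            rows.append((sa, sb, c.carbon, c.replicate, t, round(v, 4)))
    pd.DataFrame(rows, columns=GROWTH_COLUMNS).to_csv(path, index=False)
    logger.info("wrote %d rows to %s", len(rows), path)


def validate_design(dataset: GrowthDataset, min_reps: int = 3) -> pd.DataFrame:
    """Report design completeness for every strain pair x carbon source.

    A (pair, carbon) *triad* is complete when both monocultures and the
    coculture are present with at least ``min_reps`` replicates each;
    only complete triads are eligible for interaction classification.

    Returns a DataFrame with one row per (pair, carbon) and columns
    ``strain_a, strain_b, carbon, n_mono_a, n_mono_b, n_co, complete, note``.
    """
    counts: dict = {}
    for c in dataset.curves:
        counts.setdefault((c.strains, c.carbon), 0)
        counts[(c.strains, c.carbon)] += 1

    rows = []
    for a, b in dataset.pairs:
        for carbon in dataset.carbons:
            na = counts.get((frozenset({a}), carbon), 0)
            nb = counts.get((frozenset({b}), carbon), 0)
            nc = counts.get((frozenset({a, b}), carbon), 0)
            complete = min(na, nb, nc) >= min_reps
            if complete:
                note = ""
            elif min(na, nb, nc) == 0:
                missing = [lbl for n, lbl in [(na, f"mono {a}"), (nb, f"mono {b}"),
                                              (nc, "coculture")] if n == 0]
                note = "missing " + "; ".join(missing)
            else:
                note = f"below {min_reps} replicates"
            rows.append((a, b, carbon, na, nb, nc, complete, note))
    return pd.DataFrame(
        rows,
        columns=["strain_a", "strain_b", "carbon", "n_mono_a", "n_mono_b",
                 "n_co", "complete", "note"],
    )
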