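"""Per-bin 3D density features: Distance(n) and Radius(m).

Distance(n) — the mean of the n smallest path-averaged distances from a bin;
large values mean the bin's spatial neighborhood is empty, so the feature is
*inversely* proportional to local density.  Radius(m) — the number of bins
lying within the m-th percentile radius of the chromosome-wide distance
distribution; *positively* proportional to density.  The defaults
(n in {1000, 2500, 5000, 10000}, m in {10, 15, 20, 25, 30}) give nine
features per bin.

Missing-data convention: a bin with no computed distance at all carries the
value 0 together with a ``missing`` flag; flagged bins must be excluded from
correlation analyses — a 0 here is a sentinel, not a measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import PairwiseDistances
from .errors import DegenerateInputError, InputError, ParameterError

__all__ = [
    "DensityFeatureSpec",
    "BinFeatureTable",
    "distance_feature",
    "radius_cutoff",
    "radius_feature",
    "feature_table",
    "read_bin_features",
    "assign_bin",
]

DEFAULT_DISTANCE_CUTOFFS = (1000, 2500, 5000, 10000)
DEFAULT_RADIUS_PERCENTILES = (10, 15, 20, 25, 30)


@dataclass(frozen=True)
class DensityFeatureSpec:
    distance_cutoffs: tuple[int, ...] = DEFAULT_DISTANCE_CUTOFFS
    radius_percentiles: tuple[float, ...] = DEFAULT_RADIUS_PERCENTILES

    def __post_init__(self) -> None:
        object.__setattr__(self, "distance_cutoffs", tuple(self.distance_cutoffs))
        object.__setattr__(self, "radius_percentiles", tuple(self.radius_percentiles))
        if any(n < 1 for n in self.distance_cutoffs):
            raise ParameterError("distance cutoffs must be >= 1")
        if any(not 0 < m < 100 for m in self.radius_percentiles):
            raise ParameterError("radius percentiles must lie in (0, 100)")

    @property
    def feature_names(self) -> list[str]:
        return [f"Distance ({n})" for n in self.distance_cutoffs] + [
            f"Radius ({m:g})" for m in self.radius_percentiles
        ]


@dataclass
class BinFeatureTable:
    """Per-bin density features for one chromosome.

    ``frame`` is indexed by 1-based bin and has one column per feature plus a
    boolean ``missing`` column (no distances computed for that bin — its
    feature values are the 0 sentinel).
    """

    chrom: str
    resolution: int
    frame: pd.DataFrame

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c != "missing"]

    def valid(self) -> pd.DataFrame:
        """Rows usable in statistics (missing-flagged bins dropped)."""
        return self.frame.loc[~self.frame["missing"], self.feature_names]

    def to_tsv(self, path) -> None:
        """0-based bin starts; fully-missing bins omitted, matching the
        convention of publishing only bins with a computed value."""
        out = self.valid().copy()
        out.insert(0, "bin_start", (out.index.to_numpy() - 1) * self.resolution)
        out.insert(0, "chrom", self.chrom)
        out.to_csv(path, sep="\t", index=False)


def distance_feature(pd_: PairwiseDistances, b: int, n: int) -> float:
    """Mean of the n smallest distances from bin ``b`` (1-based).

    Bins with k < n computed distances average the k available; an isolated
    bin returns the 0 sentinel (callers track the missing flag).
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    d = pd_.from_bin(b)
    if len(d) == 0:
        return 0.0
    k = min(n, len(d))
    return float(np.mean(np.partition(d, k - 1)[:k]))


def radius_cutoff(pd_: PairwiseDistances, m: float) -> float:
    """The m-th percentile radius: sorted_all[ceil(N*m/100)], 1-based,
    clamped to [1, N]."""
    n_ = pd_.n_pairs
    if n_ == 0:
        raise DegenerateInputError("no pairwise distances to take a radius from")
    pos = min(max(math.ceil(n_ * m / 100.0), 1), n_)
    return float(pd_.sorted_all[pos - 1])


def radius_feature(pd_: PairwiseDistances, b: int, r: float) -> int:
    """Number of bins whose distance from ``b`` is <= r (ties counted)."""
    if r <= 0:
        raise ParameterError(f"radius must be > 0, got {r}")
    d = pd_.from_bin(b)
    return int((d <= r).sum())


def feature_table(
    pd_: PairwiseDistances, spec: DensityFeatureSpec = DensityFeatureSpec(), resolution: int = 10000
) -> BinFeatureTable:
    """All configured Distance(n)/Radius(m) features for every bin."""
    n_bins = pd_.n_bins
    cols: dict[str, np.ndarray] = {}
    sup = np.array([len(pd_.from_bin(b)) for b in range(1, n_bins + 1)])
    for n in spec.distance_cutoffs:
        cols[f"Distance ({n})"] = np.array(
            [distance_feature(pd_, b, n) for b in range(1, n_bins + 1)]
        )
    radii = {m: radius_cutoff(pd_, m) for m in spec.radius_percentiles}
    for m, r in radii.items():
        cols[f"Radius ({m:g})"] = np.array(
            [radius_feature(pd_, b, r) if sup[b - 1] else 0 for b in range(1, n_bins + 1)]
        )
    frame = pd.DataFrame(cols, index=pd.RangeIndex(1, n_bins + 1, name="bin"))
    frame["missing"] = sup == 0
    return BinFeatureTable(pd_.chrom, resolution, frame)


def read_bin_features(path, resolution: int | None = None) -> BinFeatureTable:
    """Read back a :meth:`BinFeatureTable.to_tsv` file.

    Only non-missing bins are on disk, so every row read is unflagged.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "bin_start"}.issubset(df.columns):
        raise InputError(f"{path}: not a bin feature table (chrom/bin_start missing)")
    chrom = str(df["chrom"].iloc[0]) if len(df) else ""
    if resolution is None:
        starts = np.sort(df["bin_start"].unique())
        diffs = np.diff(starts)
        if len(diffs) == 0:
            raise InputError(f"{path}: cannot infer resolution from a single bin")
        resolution = int(diffs.min())
    frame = df.drop(columns=["chrom"]).set_index(
        (df["bin_start"] // resolution + 1).rename("bin")
    )
    frame = frame.drop(columns=["bin_start"])
    frame["missing"] = False
    return BinFeatureTable(chrom, int(resolution), frame)


def assign_bin(position: int, resolution: int) -> int:
    """1-based bin containing a 0-based bp coordinate: floor(pos/res) + 1."""
    if position < 0:
        raise InputError(f"negative genomic position {position}")
    if resolution < 1:
        raise ParameterError(f"resolution must be >= 1, got {resolution}")
    return int(position // resolution) + 1
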