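"""Hi-C contact matrices: reading, balancing, rebinning.

A :class:`ContactMatrix` holds the normalized interaction frequencies (IF)
between fixed-width genomic bins of a single chromosome, stored as an
upper-triangular triplet list.  File coordinates are 0-based bin start
positions (``start1<TAB>start2<TAB>count``, the usual "dump" layout);
in-memory bin indices are 1-based, so the bin covering ``[0, resolution)``
is bin 1.  Diagonal (self) contacts are dropped on construction: the
downstream distance graph has no self-loops.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, FormatError, ParameterError

__all__ = ["ContactMatrix", "read_contacts", "write_contacts", "balance", "rebin"]


@dataclass
class ContactMatrix:
    """Symmetric sparse map of interaction frequencies for one chromosome.

    ``bins1``/``bins2`` are parallel 1-based index arrays with
    ``bins1 < bins2`` (upper triangle); ``counts`` are the non-negative IF
    values.  Symmetric access and zero-for-absent semantics are provided by
    :meth:`get` and :meth:`to_dense`.
    """

    chrom: str
    resolution: int
    n_bins: int
    bins1: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    bins2: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))

    def __post_init__(self) -> None:
        self.bins1 = np.asarray(self.bins1, dtype=np.int64)
        self.bins2 = np.asarray(self.bins2, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.n_bins < 1:
            raise ParameterError(f"n_bins must be >= 1, got {self.n_bins}")
        if self.resolution < 1:
            raise ParameterError(f"resolution must be >= 1, got {self.resolution}")
        if not (len(self.bins1) == len(self.bins2) == len(self.counts)):
            raise ParameterError("triplet arrays must have equal length")
        if np.any(self.counts < 0):
            raise FormatError("interaction frequencies must be non-negative")
        # canonicalize: i<j, merge duplicates, drop diagonal and zeros
        i = np.minimum(self.bins1, self.bins2)
        j = np.maximum(self.bins1, self.bins2)
        keep = i != j
        i, j, c = i[keep], j[keep], self.counts[keep]
        if len(i) and (i.min() < 1 or j.max() > self.n_bins):
            raise FormatError("bin index outside [1, n_bins]")
        key = (i - 1) * np.int64(self.n_bins) + (j - 1)
        order = np.argsort(key, kind="stable")
        key, i, j, c = key[order], i[order], j[order], c[order]
        uniq, start = np.unique(key, return_index=True)
        csum = np.add.reduceat(c, start) if len(c) else c
        keep = csum > 0
        self.bins1, self.bins2, self.counts = i[start][keep], j[start][keep], csum[keep]

    @property
    def nnz(self) -> int:
        return len(self.counts)

    @property
    def total_mass(self) -> float:
        """Sum of IF over unordered off-diagonal pairs."""
        return float(self.counts.sum())

    def get(self, i: int, j: int) -> float:
        """IF between bins i and j (symmetric; 0 when absent; 0 on diagonal)."""
        if i == j:
            return 0.0
        lo, hi = (i, j) if i < j else (j, i)
        mask = (self.bins1 == lo) & (self.bins2 == hi)
        idx = np.flatnonzero(mask)
        return float(self.counts[idx[0]]) if len(idx) else 0.0

    def to_dense(self) -> np.ndarray:
        """Full symmetric n_bins x n_bins array (0-based axes)."""
        a = np.zeros((self.n_bins, self.n_bins))
        a[self.bins1 - 1, self.bins2 - 1] = self.counts
        a[self.bins2 - 1, self.bins1 - 1] = self.counts
        return a

    def bin_sums(self) -> np.ndarray:
        """Marginal IF sum per bin (length n_bins, 0-based)."""
        s = np.zeros(self.n_bins)
        np.add.at(s, self.bins1 - 1, self.counts)
        np.add.at(s, self.bins2 - 1, self.counts)
        return s


def _looks_like_triplet(rows: list[str], resolution: int) -> bool:
    # triplet coordinates are non-negative multiples of the resolution;
    # a dense 3x3 block essentially never is
    for r in rows:
        f = r.split("\t")
        try:
            s1, s2 = float(f[0]), float(f[1])
        except ValueError:
            return False
        if s1 < 0 or s2 < 0 or s1 % resolution or s2 % resolution:
            return False
    return True


def read_contacts(path, resolution: int, chrom: str, n_bins: int | None = None) -> ContactMatrix:
    """Read a contact matrix from a 3-column triplet TSV or a dense square TSV.

    Triplet lines are ``start1<TAB>start2<TAB>count`` with 0-based starts that
    must be multiples of ``resolution``; duplicates (e.g. both triangles)
    are summed.  A square file whose width differs from 3 — or a 3-column
    square whose leading columns are not bin-start coordinates — is read as
    a dense matrix whose row/column k covers start ``(k-1)*resolution``.
    """
    if isinstance(path, io.TextIOBase):
        rows = [ln.rstrip("\n") for ln in path]
    else:
        with open(path) as fh:
            rows = [ln.rstrip("\n") for ln in fh]
    rows = [r for r in rows if r.strip() and not r.startswith(("#", "track"))]
    if not rows:
        raise FormatError(f"{path}: empty contact file")
    widths = {len(r.split("\t")) for r in rows}
    if widths == {3} and (len(rows) != 3 or _looks_like_triplet(rows, resolution)):
        starts1, starts2, counts = [], [], []
        for ln_no, r in enumerate(rows, 1):
            f = r.split("\t")
            try:
                s1, s2, c = float(f[0]), float(f[1]), float(f[2])
            except ValueError as e:
                raise FormatError(f"{path}:{ln_no}: non-numeric field") from e
            if c < 0:
                raise FormatError(f"{path}:{ln_no}: negative count {c}")
            for s in (s1, s2):
                if s % resolution != 0:
                    raise FormatError(
                        f"{path}:{ln_no}: start {s:.0f} not a multiple of resolution {resolution}"
                    )
            starts1.append(s1)
            starts2.append(s2)
            counts.append(c)
        b1 = (np.asarray(starts1) // resolution).astype(np.int64) + 1
        b2 = (np.asarray(starts2) // resolution).astype(np.int64) + 1
        inferred = int(max(b1.max(), b2.max()))
        n = n_bins if n_bins is not None else inferred
        return ContactMatrix(chrom, resolution, n, b1, b2, np.asarray(counts))
    if len(widths) == 1:
        dense = np.loadtxt(io.StringIO("\n".join(rows)), delimiter="\t")
        if dense.ndim != 2 or dense.shape[0] != dense.shape[1]:
            raise FormatError(f"{path}: dense matrix must be square")
        if np.any(dense < 0):
            raise FormatError(f"{path}: negative count in dense matrix")
        iu, ju = np.triu_indices(dense.shape[0], k=1)
        sym = (dense[iu, ju] + dense[ju, iu]) / 2.0
        return ContactMatrix(chrom, resolution, dense.shape[0], iu + 1, ju + 1, sym)
    raise FormatError(f"{path}: inconsistent column counts {sorted(widths)}")


def write_contacts(m: ContactMatrix, path) -> None:
    """Write upper-triangle triplets as ``start1<TAB>start2<TAB>count``."""
    with open(path, "w") as fh:
        for i, j, c in zip(m.bins1, m.bins2, m.counts):
            fh.write(f"{(i - 1) * m.resolution}\t{(j - 1) * m.resolution}\t{c:.10g}\n")


def balance(m: ContactMatrix, method: str = "ice") -> ContactMatrix:
    """Coverage-correct a contact matrix.

    ``"none"``  identity.
    ``"vc"``    vanilla coverage: IF' = IF / (rowsum_i * rowsum_j), rescaled
                so total mass is unchanged.
    ``"ice"``   iterative proportional fitting until the maximum relative
                change of non-zero bin sums drops below 1e-5 (<= 200 rounds);
                output rescaled to the input's total mass.

    Balancing preserves the zero pattern: absent pairs stay absent.
    """
    if method == "none":
        return ContactMatrix(m.chrom, m.resolution, m.n_bins, m.bins1, m.bins2, m.counts)
    if method not in ("vc", "ice"):
        raise ParameterError(f"unknown balancing method {method!r}")
    if m.nnz == 0 or m.total_mass == 0:
        raise DegenerateInputError("cannot balance an all-zero contact matrix")
    i0, j0 = m.bins1 - 1, m.bins2 - 1
    if method == "vc":
        s = m.bin_sums()
        c = m.counts / (s[i0] * s[j0])
        c *= m.total_mass / c.sum()
        return ContactMatrix(m.chrom, m.resolution, m.n_bins, m.bins1, m.bins2, c)
    c = m.counts.copy()
    covered = np.zeros(m.n_bins, dtype=bool)
    covered[i0] = True
    covered[j0] = True
    prev = None
    for _ in range(200):
        s = np.zeros(m.n_bins)
        np.add.at(s, i0, c)
        np.add.at(s, j0, c)
        active = s[covered]
        if prev is not None:
            rel = np.abs(active - prev) / np.maximum(prev, 1e-300)
            if rel.max() < 1e-5:
                break
        prev = active
        bias = np.where(s > 0, s, 1.0)
        c = c / (bias[i0] * bias[j0])
        c *= 1.0 / c.mean()  # keep magnitudes O(1) between rounds
    c *= m.total_mass / c.sum()
    return ContactMatrix(m.chrom, m.resolution, m.n_bins, m.bins1, m.bins2, c)


def rebin(m: ContactMatrix, new_resolution: int) -> ContactMatrix:
    """Aggregate to a coarser resolution.

    Each fine bin is assigned to the coarse bin containing its start
    coordinate, so non-multiple targets (25 kb from 10 kb) are handled
    deterministically.  Fine pairs landing in the same coarse bin become
    coarse-diagonal mass and are dropped, like any other diagonal.
    """
    if new_resolution < m.resolution:
        raise ParameterError(
            f"new resolution {new_resolution} is finer than current {m.resolution}"
        )
    if new_resolution == m.resolution:
        return ContactMatrix(m.chrom, m.resolution, m.n_bins, m.bins1, m.bins2, m.counts)
    starts1 = (m.bins1 - 1) * m.resolution
    starts2 = (m.bins2 - 1) * m.resolution
    c1 = starts1 // new_resolution + 1
    c2 = starts2 // new_resolution + 1
    n_coarse = ((m.n_bins - 1) * m.resolution) // new_resolution + 1
    return ContactMatrix(m.chrom, new_resolution, int(n_coarse), c1, c2, m.counts)
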