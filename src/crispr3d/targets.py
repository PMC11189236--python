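"""CRISPR target sites and their classic feature set.

A target site is the 20-nt protospacer (positions numbered 1, PAM-distal, to
20, PAM-proximal) plus at least one base of PAM-side context, with a
measured editing efficiency in [0, 1].  The classic predictors comprise 420
sequence features — positional mono- and dinucleotide indicators and overall
(di)nucleotide frequencies — and 5 thermodynamic features: nearest-neighbor
melting temperatures of four sub-regions of the DNA site and the minimum
free energy of the guide RNA.  Optional epigenetic features average a
bedGraph signal around the cut site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from . import folding
from .density import BinFeatureTable, assign_bin
from .errors import FormatError, InputError, ParameterError

__all__ = [
    "TargetSite",
    "read_sites",
    "write_sites",
    "positional_mono",
    "positional_di",
    "composition",
    "thermo",
    "read_bedgraph",
    "epigenetic_signal",
    "assemble",
    "SEQUENCE_FEATURE_COUNT",
    "THERMO_FEATURE_NAMES",
]

_NUCS = "ACGT"
_DINUCS = [a + b for a in _NUCS for b in _NUCS]
SEQUENCE_FEATURE_COUNT = 80 + 320 + 4 + 16
THERMO_FEATURE_NAMES = ["Tm_1_20", "Tm_1_4", "Tm_5_12", "Tm_16_20", "sgRNA_MFE"]

# Tm sub-regions as (1-based start, end) along the protospacer
_TM_REGIONS = [("Tm_1_20", 1, 20), ("Tm_1_4", 1, 4), ("Tm_5_12", 5, 12), ("Tm_16_20", 16, 20)]


@dataclass(frozen=True)
class TargetSite:
    """One CRISPR site: location, strand-resolved sequence, efficiency.

    ``seq`` is the uppercase 20-nt protospacer plus >= 1 nt of PAM-side
    context (23 nt for NGG sites), already on the targeted strand; ``pos``
    is the 0-based cut-site coordinate.
    """

    chrom: str
    pos: int
    strand: str
    seq: str
    efficiency: float

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise InputError(f"negative site coordinate {self.pos}")
        if self.strand not in "+-":
            raise InputError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.seq) < 21:
            raise InputError(
                f"site sequence needs >= 21 nt (20-nt protospacer + context), got {len(self.seq)}"
            )
        if any(b not in _NUCS for b in self.seq):
            raise InputError(f"non-ACGT base in site sequence {self.seq!r}")
        if not 0.0 <= self.efficiency <= 1.0:
            raise InputError(f"efficiency must lie in [0,1], got {self.efficiency}")

    @property
    def protospacer(self) -> str:
        return self.seq[:20]

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.strand}"


def read_sites(path) -> list[TargetSite]:
    """Read sites from a header-bearing TSV (chrom, pos, strand, sequence,
    efficiency)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    required = {"chrom", "pos", "strand", "sequence", "efficiency"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return [
        TargetSite(str(r.chrom), int(r.pos), str(r.strand), str(r.sequence).upper(),
                   float(r.efficiency))
        for r in df.itertuples()
    ]


def write_sites(sites: list[TargetSite], path) -> None:
    pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "strand": [s.strand for s in sites],
            "sequence": [s.seq for s in sites],
            "efficiency": [s.efficiency for s in sites],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def _check_seq(seq: str, min_len: int = 20) -> str:
    seq = seq.upper()
    if len(seq) < min_len:
        raise InputError(f"sequence shorter than {min_len} nt")
    if any(b not in _NUCS for b in seq):
        raise InputError(f"non-ACGT character in {seq!r}")
    return seq


def positional_mono(seq: str) -> dict[str, int]:
    """80 indicators pos{k}_{b}: nucleotide b at protospacer position k."""
    seq = _check_seq(seq, 20)
    out = {f"pos{k}_{b}": 0 for k in range(1, 21) for b in _NUCS}
    for k in range(1, 21):
        out[f"pos{k}_{seq[k - 1]}"] = 1
    return out


def positional_di(seq: str) -> dict[str, int]:
    """320 indicators dipos{k}_{bb'}: dinucleotide starting at position k.

    Position 20's dinucleotide spans the last protospacer base and the first
    PAM-side context base, hence the 21-nt minimum.
    """
    seq = _check_seq(seq, 21)
    out = {f"dipos{k}_{d}": 0 for k in range(1, 21) for d in _DINUCS}
    for k in range(1, 21):
        out[f"dipos{k}_{seq[k - 1:k + 1]}"] = 1
    return out


def composition(seq: str) -> dict[str, float]:
    """Overall nucleotide (4) and dinucleotide (16) frequencies across the
    protospacer; each block sums to 1."""
    seq = _check_seq(seq, 20)
    ps = seq[:20]
    out = {f"freq_{b}": ps.count(b) / 20.0 for b in _NUCS}
    for d in _DINUCS:
        out[f"freq_{d}"] = sum(ps[i:i + 2] == d for i in range(19)) / 19.0
    return out


def thermo(seq: str, folding_backend: str = "simple") -> dict[str, float]:
    """Five thermodynamic features.

    Nearest-neighbor (SantaLucia unified parameters, default salt) melting
    temperatures of protospacer regions 1-20, 1-4, 5-12 and 16-20, plus the
    minimum free energy of the guide RNA (RNA copy of positions 1-20).
    """
    seq = _check_seq(seq, 20)
    out = {}
    for name, a, b in _TM_REGIONS:
        # unified SantaLucia NN parameters, default salt/strand concentrations
        out[name] = float(_mt.Tm_NN(seq[a - 1:b], nn_table=_mt.DNA_NN3))
    rna = seq[:20].replace("T", "U")
    out["sgRNA_MFE"] = folding.mfe(rna, backend=folding_backend)
    return out


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    """Parse a bedGraph track into (chrom, start, end, value) records."""
    recs = []
    with open(path) as fh:
        for ln_no, ln in enumerate(fh, 1):
            if not ln.strip() or ln.startswith(("track", "#", "browser")):
                continue
            f = ln.split()
            if len(f) < 4:
                raise FormatError(f"{path}:{ln_no}: bedGraph needs 4 fields")
            recs.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    return recs


def epigenetic_signal(
    site: TargetSite, track: list[tuple[str, int, int, float]], window: int = 500
) -> float:
    """Coverage-weighted mean signal over [pos-window, pos+window).

    The track must be position-sorted and non-overlapping per chromosome;
    uncovered stretches contribute 0 to the mean (denominator is the full
    window length).
    """
    if window < 1:
        raise ParameterError(f"window must be >= 1, got {window}")
    lo, hi = max(site.pos - window, 0), site.pos + window
    span = 2 * window
    prev_end: dict[str, int] = {}
    total = 0.0
    for chrom, start, end, val in track:
        if end <= start:
            raise FormatError(f"bedGraph interval with end <= start: {chrom}:{start}-{end}")
        if start < prev_end.get(chrom, -1):
            raise FormatError(f"bedGraph intervals unsorted or overlapping at {chrom}:{start}")
        prev_end[chrom] = end
        if chrom != site.chrom:
            continue
        ov = min(end, hi) - max(start, lo)
        if ov > 0:
            total += val * ov
    return total / span


def assemble(
    sites: list[TargetSite],
    bin_features: BinFeatureTable | None = None,
    include_3d: str | None = None,
    tracks: dict[str, list] | None = None,
    window: int = 500,
    folding_backend: str = "simple",
) -> pd.DataFrame:
    """Build the site-by-feature matrix.

    Always the 420 sequence + 5 thermodynamic columns; one epigenetic column
    per named track; and, when ``include_3d`` names a density feature,
    exactly that one column joined through the site's bin — rows whose bin
    is missing-flagged (or absent from the table) are dropped, since their
    0 is a sentinel, not a measurement.  The ``efficiency`` response rides
    along as the last column.
    """
    if include_3d is not None:
        if bin_features is None:
            raise ParameterError("include_3d requires a bin feature table")
        if include_3d not in bin_features.feature_names:
            raise ParameterError(
                f"unknown 3D feature {include_3d!r}; available: {bin_features.feature_names}"
            )
    mono_names = [f"pos{k}_{b}" for k in range(1, 21) for b in _NUCS]
    di_names = [f"dipos{k}_{d}" for k in range(1, 21) for d in _DINUCS]
    comp_names = [f"freq_{b}" for b in _NUCS] + [f"freq_{d}" for d in _DINUCS]
    track_names = sorted(tracks) if tracks else []
    columns = (
        mono_names + di_names + comp_names + THERMO_FEATURE_NAMES
        + [f"epi_{t}" for t in track_names]
        + ([include_3d] if include_3d else [])
        + ["efficiency"]
    )
    rows, index = [], []
    for s in sites:
        feats: dict[str, float] = {}
        feats.update(positional_mono(s.seq))
        feats.update(positional_di(s.seq))
        feats.update(composition(s.seq))
        feats.update(thermo(s.seq, folding_backend=folding_backend))
        for t in track_names:
            feats[f"epi_{t}"] = epigenetic_signal(s, tracks[t], window=window)
        if include_3d is not None:
            b = assign_bin(s.pos, bin_features.resolution)
            frame = bin_features.frame
            if b not in frame.index or bool(frame.loc[b, "missing"]):
                continue  # no usable 3D measurement for this site
            feats[include_3d] = float(frame.loc[b, include_3d])
        feats["efficiency"] = s.efficiency
        rows.append(feats)
        index.append(s.site_id)
    fm = pd.DataFrame(rows, index=pd.Index(index, name="site"), columns=columns)
    if len(fm) and fm.drop(columns=["efficiency"]).isna().any().any():
        raise InputError("assembled feature matrix contains missing values")
    return fm
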