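"""Synthetic Hi-C contacts and CRISPR efficiency tables with planted structure.

The contact generator emulates the gross features of a normalized Hi-C map:
power-law decay of contact frequency with genomic separation
(IF ~ |i-j|^-alpha), TAD-like blocks whose internal contacts are uniformly
enriched, per-bin multiplicative log-normal coverage noise, and sparse
dropout.  The site generator places target sites into bins and draws each
efficiency from a logistic model with a planted coefficient on a chosen
per-bin 3D density feature plus a GC-content effect and Gaussian noise —
so the downstream statistics have a known ground truth to recover (the
planted analogue of denser regions editing less efficiently).

Everything is deterministic given the seeds carried in the parameter
objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .contacts import ContactMatrix
from .density import BinFeatureTable, DensityFeatureSpec, feature_table
from .distances import PathDistanceParams, all_pairs, build_graph
from .errors import InputError, ParameterError
from .targets import TargetSite

__all__ = [
    "SyntheticHiCParams",
    "SyntheticCrisprParams",
    "generate_contacts",
    "generate_sites",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SyntheticHiCParams:
    """Knobs of the synthetic contact map.

    n_bins            bins on the synthetic chromosome
    resolution        bin width in bp (default 10000, the working resolution)
    base_if           IF at separation 1 before enrichment/noise
    decay_exponent    power-law exponent alpha > 0 of contact decay
    tad_boundaries    strictly increasing bin indices in [1, n_bins) that
                      end each block (block k spans (b_{k-1}, b_k])
    tad_enrichment    multiplier >= 1 for contacts within one block
    coverage_noise_sd sd of per-bin log-normal coverage factor (0 = off)
    dropout_rate      fraction in [0,1) of entries zeroed at random
    seed              RNG seed
    """

    n_bins: int
    resolution: int = 10000
    base_if: float = 10.0
    decay_exponent: float = 1.0
    tad_boundaries: tuple[int, ...] = ()
    tad_enrichment: float = 1.0
    coverage_noise_sd: float = 0.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "tad_boundaries", tuple(self.tad_boundaries))
        if self.n_bins < 2:
            raise ParameterError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.decay_exponent <= 0:
            raise ParameterError("decay_exponent must be > 0")
        if self.tad_enrichment < 1:
            raise ParameterError("tad_enrichment must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ParameterError("dropout_rate must lie in [0, 1)")
        if self.coverage_noise_sd < 0:
            raise ParameterError("coverage_noise_sd must be >= 0")
        tb = self.tad_boundaries
        if any(b2 <= b1 for b1, b2 in zip(tb, tb[1:])) or any(
            not 1 <= b < self.n_bins for b in tb
        ):
            raise ParameterError("tad_boundaries must be strictly increasing within [1, n_bins)")


@dataclass(frozen=True)
class SyntheticCrisprParams:
    """Knobs of the planted efficiency model.

    efficiency = logistic(density_effect * z(density)
                          + sequence_effect * z(GC) + eps),  eps ~ N(0, sd)

    density_effect  coefficient beta on the standardized per-bin density
                    feature (negative beta plants the density-suppresses-
                    editing direction when the feature measures density)
    sequence_effect coefficient gamma on standardized protospacer GC
    noise_sd        sd of the additive Gaussian noise on the logit scale
    """

    n_sites: int
    density_effect: float = -1.0
    sequence_effect: float = 0.5
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 10:
            raise ParameterError(f"n_sites must be >= 10, got {self.n_sites}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


def _block_ids(n_bins: int, boundaries: tuple[int, ...]) -> np.ndarray:
    ids = np.zeros(n_bins, dtype=int)
    for b in boundaries:
        ids[b:] += 1
    return ids


def expected_if(params: SyntheticHiCParams, i: int, j: int) -> float:
    """Noise-free expected IF between 1-based bins — the generative formula."""
    if i == j:
        return 0.0
    e = params.base_if * abs(i - j) ** (-params.decay_exponent)
    blocks = _block_ids(params.n_bins, params.tad_boundaries)
    if blocks[i - 1] == blocks[j - 1]:
        e *= params.tad_enrichment
    return e


def generate_contacts(params: SyntheticHiCParams, chrom: str = "chrS") -> ContactMatrix:
    """Draw one synthetic chromosome's contact matrix."""
    rng = np.random.default_rng(params.seed)
    n = params.n_bins
    iu, ju = np.triu_indices(n, k=1)
    sep = ju - iu
    vals = params.base_if * sep.astype(float) ** (-params.decay_exponent)
    blocks = _block_ids(n, params.tad_boundaries)
    vals[blocks[iu] == blocks[ju]] *= params.tad_enrichment
    if params.coverage_noise_sd > 0:
        cov = np.exp(rng.normal(0.0, params.coverage_noise_sd, size=n))
        vals = vals * cov[iu] * cov[ju]
    if params.dropout_rate > 0:
        vals = np.where(rng.random(len(vals)) < params.dropout_rate, 0.0, vals)
    return ContactMatrix(chrom, params.resolution, n, iu + 1, ju + 1, vals)


def generate_sites(
    hic_features: BinFeatureTable,
    params: SyntheticCrisprParams,
    density_feature: str | None = None,
    feature_is_density: bool | None = None,
) -> list[TargetSite]:
    """Plant target sites whose efficiency depends on a bin density feature.

    Each site draws a bin (uniformly over non-missing bins), a coordinate
    inside the bin, and a random 23-nt sequence ending in GG (NGG PAM);
    efficiency follows the logistic planted model, clipped to [0, 1].
    Both the density feature and GC are standardized before the planted
    coefficients apply, so the two effects are on a common scale.

    ``density_effect`` multiplies *density*.  Distance(n) features measure
    the inverse of density, so their standardized values are negated before
    the coefficient applies; Radius(m) features enter as-is.  The
    orientation is inferred from the feature name unless
    ``feature_is_density`` overrides it (True = feature already on the
    density scale).
    """
    frame = hic_features.frame
    usable = frame.index[~frame["missing"]].to_numpy()
    if len(usable) == 0:
        raise InputError("feature table has no usable (non-missing) bins")
    name = density_feature or hic_features.feature_names[0]
    if name not in hic_features.feature_names:
        raise InputError(f"unknown density feature {name!r}")
    rng = np.random.default_rng(params.seed)
    res = hic_features.resolution
    bins = rng.choice(usable, size=params.n_sites, replace=True)
    offsets = rng.integers(0, res, size=params.n_sites)
    dens = frame.loc[bins, name].to_numpy(dtype=float)
    if feature_is_density is None:
        feature_is_density = not name.startswith("Distance")
    if not feature_is_density:
        dens = -dens  # Distance-type features are inverse density

    bases = np.array(list("ACGT"))
    seq_core = rng.integers(0, 4, size=(params.n_sites, 21))
    seqs = ["".join(bases[row]) + "GG" for row in seq_core]
    gc = np.array([(s[:20].count("G") + s[:20].count("C")) / 20.0 for s in seqs])

    def z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    logit = (
        params.density_effect * z(dens)
        + params.sequence_effect * z(gc)
        + rng.normal(0.0, params.noise_sd, size=params.n_sites)
    )
    eff = np.clip(expit(logit), 0.0, 1.0)
    return [
        TargetSite(hic_features.chrom, int((b - 1) * res + o), "+", s, float(e))
        for b, o, s, e in zip(bins, offsets, seqs, eff)
    ]


def simulate_dataset(
    hic_params: SyntheticHiCParams,
    crispr_params: SyntheticCrisprParams,
    density_feature: str | None = None,
    path_params: PathDistanceParams = PathDistanceParams(),
    spec: DensityFeatureSpec | None = None,
    chrom: str = "chrS",
):
    """Full closed loop: contacts -> graph -> distances -> bin features -> sites.

    The planted density feature is, by default, a Distance(n) with small n
    computed on the generated matrix through the real pipeline, so recovery
    tests exercise every downstream stage.  Returns
    (ContactMatrix, PairwiseDistances, BinFeatureTable, sites).
    """
    m = generate_contacts(hic_params, chrom=chrom)
    pd_ = all_pairs(build_graph(m), path_params, chrom=chrom)
    if spec is None:
        small_n = max(2, min(10, hic_params.n_bins // 10))
        spec = DensityFeatureSpec(
            distance_cutoffs=(small_n,), radius_percentiles=DensityFeatureSpec().radius_percentiles
        )
    table = feature_table(pd_, spec, resolution=hic_params.resolution)
    feat = density_feature or table.feature_names[0]
    sites = generate_sites(table, crispr_params, density_feature=feat)
    return m, pd_, table, sites
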