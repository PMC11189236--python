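import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crispr3d import (
    TargetSite,
    assemble,
    composition,
    epigenetic_signal,
    positional_di,
    positional_mono,
    thermo,
)
from crispr3d.folding import rnafold_mfe, simple_mfe
from crispr3d.errors import FormatError, InputError, ParameterError
from crispr3d.targets import read_sites, write_sites

SEQ23 = st.text(alphabet="ACGT", min_size=23, max_size=23)


class TestPositionalFeatures:
    def test_homopolymer_mono_indicators(self):
        f = positional_mono("A" * 20 + "TGG")
        assert f["pos1_A"] == 1 and f["pos1_C"] == 0
        assert sum(f.values()) == 20

    def test_mono_pattern(self):
        f = positional_mono("ACGT" * 5 + "AGG")
        assert f["pos1_A"] == f["pos2_C"] == f["pos3_G"] == f["pos4_T"] == 1

    def test_di_boundary_uses_first_context_base(self):
        f = positional_di("A" * 20 + "TGG")
        assert f["dipos20_AT"] == 1

    def test_di_pattern(self):
        f = positional_di("AC" + "A" * 18 + "GGG")
        assert f["dipos1_AC"] == 1 and f["dipos2_CA"] == 1

    @settings(max_examples=25, deadline=None)
    @given(SEQ23)
    def test_one_hot_blocks_sum_to_twenty(self, seq):
        assert sum(positional_mono(seq).values()) == 20
        assert sum(positional_di(seq).values()) == 20

    def test_non_acgt_rejected(self):
        with pytest.raises(InputError):
            positional_mono("N" * 23)

    def test_short_sequence_rejected_for_dinucleotides(self):
        with pytest.raises(InputError):
            positional_di("A" * 20)


class TestComposition:
    def test_uniform_sequence(self):
        f = composition("ACGT" * 5 + "AGG")
        for b in "ACGT":
            assert f[f"freq_{b}"] == pytest.approx(0.25)

    def test_homopolymer(self):
        f = composition("A" * 20 + "TGG")
        assert f["freq_A"] == 1.0 and f["freq_AA"] == 1.0

    @settings(max_examples=25, deadline=None)
    @given(SEQ23)
    def test_blocks_normalized(self, seq):
        f = composition(seq)
        assert sum(f[f"freq_{b}"] for b in "ACGT") == pytest.approx(1.0)
        dis = [a + b for a in "ACGT" for b in "ACGT"]
        assert sum(f[f"freq_{d}"] for d in dis) == pytest.approx(1.0)

    @settings(max_examples=10, deadline=None)
    @given(SEQ23, st.randoms(use_true_random=False))
    def test_mononucleotide_frequencies_permutation_invariant(self, seq, rnd):
        # overlapping-dinucleotide frequencies legitimately change under a
        # shuffle; only the single-base composition is order-free
        shuffled = list(seq[:20])
        rnd.shuffle(shuffled)
        a, b = composition("".join(shuffled) + seq[20:]), composition(seq)
        for base in "ACGT":
            assert a[f"freq_{base}"] == pytest.approx(b[f"freq_{base}"])


def nn_tm_oracle(seq, Na=0.05, dnac1=25, dnac2=25):
    """Independent Tm from the published unified NN table (duplex DNA,
    terminal initiation terms, entropic salt correction, 12.5 nM duplex)."""
    nn = {
        "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
        "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
        "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
        "GG": (-8.0, -19.9),
    }
    comp = str.maketrans("ACGT", "TGCA")
    dh = ds = 0.0
    for b in (seq[0], seq[-1]):
        h, s = (2.3, 4.1) if b in "AT" else (0.1, -2.8)
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        d = seq[i:i + 2]
        if d not in nn:
            d = d.translate(comp)[::-1]
        h, s = nn[d]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(Na)
    k = (dnac1 - dnac2 / 2.0) * 1e-9
    return dh * 1000.0 / (ds + 1.987 * math.log(k)) - 273.15


class TestThermo:
    def test_gc_rich_region_melts_higher(self):
        flank = "ACGTACGTACGTACGT"  # positions 5-20 shared
        gc = thermo("GCGC" + flank + "TGG")
        at = thermo("ATAT" + flank + "TGG")
        assert gc["Tm_1_4"] > at["Tm_1_4"]

    def test_fixed_twentymer_matches_independent_nn_computation(self):
        seq = "ACGTACGTACGTACGTACGT"
        f = thermo(seq + "AGG")
        # frozen from nn_tm_oracle(seq) = 53.0967
        assert f["Tm_1_20"] == pytest.approx(53.0967, abs=1e-3)
        assert f["Tm_1_20"] == pytest.approx(nn_tm_oracle(seq), abs=1e-6)
        assert f["Tm_1_4"] == pytest.approx(nn_tm_oracle(seq[0:4]), abs=1e-6)
        assert f["Tm_5_12"] == pytest.approx(nn_tm_oracle(seq[4:12]), abs=1e-6)
        assert f["Tm_16_20"] == pytest.approx(nn_tm_oracle(seq[15:20]), abs=1e-6)

    def test_all_five_features_finite(self):
        f = thermo("GGGGCCCCAAAATTTTACGT" + "AGG")
        assert len(f) == 5
        assert all(np.isfinite(v) for v in f.values())


class TestFolding:
    def test_poly_a_is_unstructured(self):
        assert simple_mfe("A" * 20) == 0.0

    def test_hairpin_folds_below_open_chain(self):
        assert simple_mfe("GCGCGCAAAAGCGCGC") < simple_mfe("A" * 20)

    def test_simple_backend_agrees_with_rnafold_qualitatively(self):
        # external Turner-model oracle: same sign on a strong hairpin and
        # both zero on an unpairable chain
        hairpin = "GCGCGCAAAAGCGCGC"
        assert rnafold_mfe("A" * 20) == 0.0
        assert rnafold_mfe(hairpin) < -1.0
        assert simple_mfe(hairpin) < -1.0

    def test_mfe_never_positive(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), 20))
            assert simple_mfe(seq) <= 0.0


class TestEpigeneticSignal:
    def _site(self, pos=5000):
        return TargetSite("chr1", pos, "+", "ACGT" * 5 + "AGG", 0.5)

    def test_constant_track(self):
        track = [("chr1", 0, 100_000, 5.0)]
        assert epigenetic_signal(self._site(), track, window=500) == pytest.approx(5.0)

    def test_empty_track(self):
        assert epigenetic_signal(self._site(), [], window=500) == 0.0

    def test_half_covered_window(self):
        # [4500, 5500): covered half at value 2 -> weighted mean 1.0
        track = [("chr1", 4500, 5000, 2.0)]
        assert epigenetic_signal(self._site(), track, window=500) == pytest.approx(1.0)

    def test_unsorted_track_rejected(self):
        track = [("chr1", 1000, 2000, 1.0), ("chr1", 500, 800, 1.0)]
        with pytest.raises(FormatError):
            epigenetic_signal(self._site(), track)

    def test_other_chromosome_ignored(self):
        track = [("chr2", 0, 100_000, 9.0)]
        assert epigenetic_signal(self._site(), track) == 0.0


class TestAssemble:
    def test_classic_feature_cardinality(self, planted):
        fm = assemble(planted["sites"][:5])
        assert fm.shape[1] == 425 + 1  # efficiency response rides along
        mono = [c for c in fm.columns if c.startswith("pos")]
        di = [c for c in fm.columns if c.startswith("dipos")]
        freq = [c for c in fm.columns if c.startswith("freq_")]
        assert (len(mono), len(di), len(freq)) == (80, 320, 20)

    def test_single_3d_column_joined(self, planted):
        name = planted["planted_feature"]
        fm = assemble(planted["sites"][:5], planted["table"], include_3d=name)
        assert fm.shape[1] == 426 + 1
        assert name in fm.columns

    def test_unknown_3d_feature_rejected(self, planted):
        with pytest.raises(ParameterError):
            assemble(planted["sites"][:5], planted["table"], include_3d="Distance (7777)")

    def test_zero_sites_gives_empty_matrix_with_header(self):
        fm = assemble([])
        assert len(fm) == 0 and fm.shape[1] == 426

    def test_epigenetic_column_appended(self, planted):
        track = [("chrS", 0, 10_000_000, 2.0)]
        fm = assemble(planted["sites"][:4], tracks={"dnase": track})
        assert "epi_dnase" in fm.columns
        assert fm["epi_dnase"].eq(2.0).all()


def test_sites_tsv_roundtrip(tmp_path, planted):
    p = tmp_path / "sites.tsv"
    write_sites(planted["sites"][:10], p)
    back = read_sites(p)
    assert back == planted["sites"][:10]
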