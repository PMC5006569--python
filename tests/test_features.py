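import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import piwe
from piwe.features import (
    PropertyTable,
    _revc_classes,
    default_catalog,
    default_property_table,
    feature_names,
    kmer_list,
    reverse_complement,
)
from piwe.exceptions import (
    ConfigurationError,
    DegenerateInputError,
    ParameterError,
    ValidationError,
)

dna = st.text(alphabet="ACGT", min_size=6, max_size=35)


# --- independent brute-force oracles -------------------------------------

def oracle_spectrum(s: str, k: int) -> dict[str, float]:
    counts: dict[str, float] = {}
    for i in range(len(s) - k + 1):
        counts[s[i : i + k]] = counts.get(s[i : i + k], 0) + 1
    total = sum(counts.values())
    return {w: c / total for w, c in counts.items()}


def oracle_mismatch(s: str, k: int, m: int) -> np.ndarray:
    kmers = kmer_list(k)
    counts = np.zeros(len(kmers))
    for i in range(len(s) - k + 1):
        window = s[i : i + k]
        for j, u in enumerate(kmers):
            if sum(a != b for a, b in zip(window, u)) <= m:
                counts[j] += 1
    return counts


def oracle_subsequence(s: str, k: int, w: float) -> np.ndarray:
    kmers = {u: j for j, u in enumerate(kmer_list(k))}
    weights = np.zeros(len(kmers))
    for idx in itertools.combinations(range(len(s)), k):
        gap = (idx[-1] - idx[0] + 1) - k
        weights[kmers["".join(s[i] for i in idx)]] += w**gap if gap else 1.0
    return weights


# --- spectrum -------------------------------------------------------------

@pytest.mark.parametrize(
    "s, k, expected",
    [
        ("ACGT", 1, {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}),
        ("AAAA", 2, {"AA": 1.0}),
        ("ACGTACGT", 3, {"ACG": 2 / 6, "CGT": 2 / 6, "GTA": 1 / 6, "TAC": 1 / 6}),
    ],
)
def test_spectrum_examples(s, k, expected):
    vec = piwe.spectrum_profile(s, k)
    kmers = kmer_list(k)
    for j, u in enumerate(kmers):
        assert vec[j] == pytest.approx(expected.get(u, 0.0))


def test_spectrum_degenerate_k():
    with pytest.raises(DegenerateInputError):
        piwe.spectrum_profile("ACG", 4)


# --- mismatch -------------------------------------------------------------

def test_mismatch_aaa_hamming_ball():
    vec = piwe.mismatch_profile("AAA", 3, 1)
    nz = vec[vec > 0]
    assert len(nz) == 10 and np.allclose(nz, 0.1)


def test_mismatch_requires_m_below_k():
    with pytest.raises(ParameterError):
        piwe.mismatch_profile("ACGTACGT", 3, 3)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(dna, st.integers(2, 4), st.integers(0, 1))
def test_mismatch_matches_bruteforce_and_total(s, k, m):
    """Encoder equals Hamming-ball enumeration; raw total has a closed form."""
    raw = oracle_mismatch(s, k, m)
    expected_total = (len(s) - k + 1) * sum(
        math.comb(k, j) * 3**j for j in range(m + 1)
    )
    assert raw.sum() == expected_total
    assert np.allclose(piwe.mismatch_profile(s, k, m), raw / raw.sum())


@settings(deadline=None, max_examples=25, derandomize=True)
@given(dna, st.integers(1, 5))
def test_mismatch_zero_equals_spectrum(s, k):
    if k <= len(s):
        assert np.allclose(
            piwe.mismatch_profile(s, k, 0), piwe.spectrum_profile(s, k)
        )


# --- subsequence ----------------------------------------------------------

def test_subsequence_acgt_k2_w1():
    vec = piwe.subsequence_profile("ACGT", 2, 1.0)
    kmers = kmer_list(2)
    present = {kmers[j]: v for j, v in enumerate(vec) if v > 0}
    assert present == pytest.approx(
        {u: 1 / 6 for u in ("AC", "AG", "AT", "CG", "CT", "GT")}
    )


def test_subsequence_aga_gap_weight():
    vec = piwe.subsequence_profile("AGA", 2, 0.5)
    kmers = kmer_list(2)
    vals = {kmers[j]: v for j, v in enumerate(vec) if v > 0}
    assert vals == pytest.approx({"AG": 0.4, "GA": 0.4, "AA": 0.2})


def test_subsequence_rejects_bad_w():
    with pytest.raises(ParameterError):
        piwe.subsequence_profile("ACGT", 2, 1.5)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=3, max_size=12),
       st.integers(2, 3), st.floats(0.0, 1.0))
def test_subsequence_matches_index_tuple_enumeration(s, k, w):
    raw = oracle_subsequence(s, k, w)
    got = piwe.subsequence_profile(s, k, w)
    assert np.allclose(got, raw / raw.sum())


@settings(deadline=None, max_examples=25, derandomize=True)
@given(dna, st.integers(1, 4))
def test_subsequence_w0_equals_spectrum(s, k):
    assert np.allclose(
        piwe.subsequence_profile(s, k, 0.0), piwe.spectrum_profile(s, k)
    )


# --- reverse-complement k-mers -------------------------------------------

def test_revc_dimensions():
    assert [piwe.revc_kmer_dimension(k) for k in range(1, 6)] == [2, 10, 32, 136, 512]


def test_revc_aatt_pools_letters():
    vec = piwe.revc_kmer_profile("AATT", 1)
    _, reps = _revc_classes(1)
    assert reps == ("A", "C")
    assert vec == pytest.approx([1.0, 0.0])


@settings(deadline=None, max_examples=40, derandomize=True)
@given(dna, st.integers(1, 4))
def test_revc_profile_strand_invariant(s, k):
    assert np.allclose(
        piwe.revc_kmer_profile(s, k),
        piwe.revc_kmer_profile(reverse_complement(s), k),
    )


# --- pseudo nucleotide composition ----------------------------------------

@pytest.mark.parametrize("variant, dim", [
    ("pc_dnc", 17), ("pc_tnc", 65), ("sc_dnc", 22), ("sc_tnc", 76),
])
def test_pse_dimensions_at_lambda_1(variant, dim):
    vec = piwe.pse_composition("ACGTACGTACGTACGT", variant, 1, 0.1)
    assert len(vec) == dim
    assert vec.sum() == pytest.approx(1.0, abs=1e-9)


def test_pse_zero_weight_reduces_to_plain_composition():
    s = "ACGTTGCAACGTTGCA"
    for variant, t in (("pc_dnc", 2), ("sc_tnc", 3)):
        vec = piwe.pse_composition(s, variant, 1, 0.0)
        counts = np.zeros(4**t)
        kmers = {u: j for j, u in enumerate(kmer_list(t))}
        for i in range(len(s) - t + 1):
            counts[kmers[s[i : i + t]]] += 1
        assert np.allclose(vec[: 4**t], counts / counts.sum())
        assert np.allclose(vec[4**t :], 0.0)


def test_pse_homopolymer_parallel_correlation_vanishes():
    vec = piwe.pse_composition("AAAAAAAA", "pc_dnc", 1, 0.1)
    assert vec[0] == pytest.approx(1.0)
    assert np.allclose(vec[1:], 0.0)


def test_pse_lambda_too_large_errors():
    with pytest.raises(ParameterError):
        piwe.pse_composition("ACGTA", "pc_dnc", 4, 0.1)


def test_property_tables_are_standardized():
    for t, n_props in ((2, 6), (3, 12)):
        table = default_property_table(t)
        assert len(table.property_names) == n_props
        assert np.allclose(table.values.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(table.values.std(axis=0), 1.0, atol=1e-9)


def test_property_table_shape_checked():
    with pytest.raises(ConfigurationError):
        PropertyTable(2, ("only_one",), np.zeros((4, 1)))


# --- fixed-length encodings -----------------------------------------------

@pytest.mark.parametrize("s, d, expected", [
    ("ACG", 5, "ACGEE"), ("ACGTACGT", 4, "ACGT"), ("ACGT", 4, "ACGT"),
])
def test_fix_length(s, d, expected):
    assert piwe.fix_length(s, d) == expected


def test_sparse_profile_one_hot():
    assert piwe.sparse_profile("A", 1).tolist() == [1, 0, 0, 0, 0]
    vec = piwe.sparse_profile("ACGT", 35)
    assert len(vec) == 5 * 35 and vec.sum() == 35


def test_pssm_uniform_column_scores_zero():
    positives = [piwe.Sequence(f"p{i}", b * 4) for i, b in enumerate("ACGT")]
    model = piwe.build_pssm(positives, 4)
    assert np.allclose(model.scores, 0.0)


def test_pssm_single_training_sequence():
    model = piwe.build_pssm([piwe.Sequence("p", "AAAA")], 4)
    assert np.allclose(model.scores[:, 0], np.log2(2.5))
    assert np.allclose(model.scores[:, 1:], -1.0)
    # scoring the training sequence recovers the columnwise maxima
    assert np.allclose(
        piwe.pssm_profile("AAAA", model), model.scores.max(axis=1)
    )


def test_pssm_null_positions_score_zero():
    model = piwe.build_pssm([piwe.Sequence("p", "ACGTA")], 5)
    vec = piwe.pssm_profile("ACG", model)
    assert len(vec) == 5
    assert vec[3] == 0.0 and vec[4] == 0.0


def test_pssm_requires_positives():
    with pytest.raises(ValidationError):
        piwe.build_pssm([], 4)


# --- catalog / dataset encoding -------------------------------------------

def test_default_catalog_dimensions_realized(random_sequences):
    catalog = default_catalog()
    pssm = piwe.build_pssm(random_sequences[:5], 35)
    mats = piwe.encode_dataset(random_sequences, catalog, pssm)
    assert len(mats) == 22
    for spec in catalog:
        assert mats[spec.name].shape == (len(random_sequences), spec.dimension)
        assert len(feature_names(spec)) == spec.dimension


def test_profile_vectors_nonnegative_sum_one(random_sequences):
    """Occurrence profiles and parallel-correlation pse vectors: simplex."""
    for seq in random_sequences[:10]:
        for vec in (
            piwe.spectrum_profile(seq, 3),
            piwe.mismatch_profile(seq, 4, 1),
            piwe.subsequence_profile(seq, 3, 1.0),
            piwe.revc_kmer_profile(seq, 3),
            piwe.pse_composition(seq, "pc_dnc", 1, 0.1),
            piwe.pse_composition(seq, "pc_tnc", 1, 0.1),
        ):
            assert np.all(vec >= 0)
            assert vec.sum() == pytest.approx(1.0, abs=1e-9)
        for variant in ("sc_dnc", "sc_tnc"):
            # series-correlation entries may be signed but still sum to 1
            vec = piwe.pse_composition(seq, variant, 1, 0.1)
            assert vec.sum() == pytest.approx(1.0, abs=1e-9)


def test_encode_dataset_requires_pssm_when_cataloged(random_sequences):
    with pytest.raises(ConfigurationError):
        piwe.encode_dataset(random_sequences, default_catalog(), pssm=None)


def test_short_sequence_encodes_to_zero_vector():
    spec = default_catalog()[4]  # 5-spectrum
    assert np.allclose(piwe.encode_sequence("ACG", spec), 0.0)


def test_row_order_identical_across_matrices(random_sequences):
    catalog = default_catalog()[:3]
    mats = piwe.encode_dataset(random_sequences, catalog)
    single = {
        spec.name: np.vstack([piwe.encode_sequence(s, spec) for s in random_sequences])
        for spec in catalog
    }
    for spec in catalog:
        assert np.allclose(mats[spec.name], single[spec.name])
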