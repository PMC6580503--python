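import math

import numpy as np
import pytest
from importlib import resources

from kascade.feature_encoding import (
    AAIndexError,
    DEFAULT_PROPERTY_ACCESSIONS,
    PropertyTable,
    PSSMMatrix,
    PSSMParseError,
    StructureAnnotation,
    assemble,
    encode_ac,
    encode_asa,
    encode_pcp,
    encode_pssm,
    encode_rc,
    encode_ss,
    load_aaindex,
    normalize_property,
    parse_column_name,
    read_ascii_pssm,
    read_dssp,
    read_feature_tsv,
    window_asa_values,
    window_ss_letters,
    write_ascii_pssm,
)
from kascade.sequence_io import STANDARD_AA, PeptideWindow, Protein


def _win(residues, pid="p", pos=10, label=None):
    return PeptideWindow(pid, pos, residues, label)


@pytest.fixture(scope="module")
def aaindex_path():
    ref = resources.files("kascade.data").joinpath("aaindex_synthetic.txt")
    with resources.as_file(ref) as p:
        yield p


# --- AAindex / property normalisation --------------------------------------


def test_load_aaindex_selected(aaindex_path):
    tables = load_aaindex(aaindex_path, DEFAULT_PROPERTY_ACCESSIONS[:2])
    assert [t.name for t in tables] == list(DEFAULT_PROPERTY_ACCESSIONS[:2])
    assert all(len(t.values) == 20 for t in tables)


def test_load_aaindex_rejects_na_and_unknown(aaindex_path):
    with pytest.raises(AAIndexError, match="SYNA000105"):
        load_aaindex(aaindex_path, ["SYNA000105"])
    with pytest.raises(KeyError, match="NOPE"):
        load_aaindex(aaindex_path, ["NOPE"])
    # unrequested NA entries are skipped silently
    assert {t.name for t in load_aaindex(aaindex_path)} == set(DEFAULT_PROPERTY_ACCESSIONS)


def test_normalize_property_hand_computed():
    """Values 1..20: z('A') = (1 - 10.5) / population SD of 1..20."""
    vals = {aa: float(i + 1) for i, aa in enumerate(STANDARD_AA)}
    norm = normalize_property(PropertyTable("lin", vals))
    sd = math.sqrt(sum((v - 10.5) ** 2 for v in range(1, 21)) / 20)
    assert norm.z_values["A"] == pytest.approx((1 - 10.5) / sd, abs=1e-12)
    assert norm.x_for_X == pytest.approx((0 - 10.5) / sd, abs=1e-12)


def test_normalize_property_invariants_and_idempotence(norm_props):
    for norm in norm_props:
        z = np.array([norm.z_values[a] for a in STANDARD_AA])
        assert abs(z.mean()) < 1e-9 and abs(z.std(ddof=0) - 1) < 1e-9
        # re-standardising an already standardised table is the identity
        again = normalize_property(PropertyTable(norm.name, dict(zip(STANDARD_AA, z))))
        z2 = np.array([again.z_values[a] for a in STANDARD_AA])
        np.testing.assert_allclose(z2, z, atol=1e-9)


def test_normalize_property_constant_is_degenerate():
    with pytest.raises(AAIndexError, match="constant"):
        normalize_property(PropertyTable("flat", {a: 3.0 for a in STANDARD_AA}))


def test_normalize_x_policy_z_zero():
    vals = {aa: float(i) for i, aa in enumerate(STANDARD_AA)}
    assert normalize_property(PropertyTable("t", vals), x_policy="z-zero").x_for_X == 0.0


# --- per-window encoders ----------------------------------------------------


def test_encode_pcp_dimensions_and_x(norm_props):
    w = _win("XXXXXXXXXKXXXXXXXXX")
    v = encode_pcp(w, norm_props)
    assert v.shape == (72,)  # 4 properties x 18 non-centre positions
    expected = np.concatenate([[p.x_for_X] * 18 for p in norm_props])
    np.testing.assert_allclose(v, expected)
    assert encode_pcp(w, norm_props, include_center=True).shape == (76,)


def test_encode_pcp_property_major_order(norm_props):
    w = _win("ACDEFGHILKMNPQRSTVW")
    v = encode_pcp(w, norm_props)
    p0 = norm_props[0]
    assert v[0] == pytest.approx(p0.z_values["A"])
    assert v[17] == pytest.approx(p0.z_values["W"])  # last non-centre of prop 0
    assert v[18] == pytest.approx(norm_props[1].z_values["A"])


def _ac_bruteforce(window, prop, lag):
    """Independent double-loop auto-covariation oracle."""
    x = [prop.z(c) for c in window.residues]
    n = len(x)
    m = sum(x) / n
    return sum((x[i] - m) * (x[i + lag] - m) for i in range(n - lag)) / (n - lag)


def test_encode_ac_zero_for_constant_window(norm_props):
    v = encode_ac(_win("K" * 19), norm_props)
    assert v.shape == (8,)
    np.testing.assert_allclose(v, 0.0, atol=1e-14)


def test_encode_ac_matches_bruteforce(norm_props, rng):
    letters = list(STANDARD_AA) + ["X"]
    for _ in range(200):
        res = "".join(rng.choice(letters, 19))
        res = res[:9] + "K" + res[10:]
        w = _win(res)
        v = encode_ac(w, norm_props, lags=(1, 2))
        expected = [
            _ac_bruteforce(w, p, lag) for p in norm_props for lag in (1, 2)
        ]
        np.testing.assert_allclose(v, expected, atol=1e-12)


def test_encode_ac_lag_out_of_range(norm_props):
    with pytest.raises(ValueError, match="lag"):
        encode_ac(_win("K" * 19), norm_props, lags=(19,))


def test_encode_rc():
    np.testing.assert_allclose(encode_rc(_win("K" * 19))[STANDARD_AA.index("K")], 1.0)
    v = encode_rc(_win("XXXXXXXXXKAAAAAAAAA"))
    assert v[STANDARD_AA.index("K")] == pytest.approx(1 / 10)
    assert v[STANDARD_AA.index("A")] == pytest.approx(9 / 10)
    assert v.sum() == pytest.approx(1.0, abs=1e-12)
    # with 'X' kept in the denominator the mass drops below 1
    assert encode_rc(_win("XXXXXXXXXKAAAAAAAAA"), count_x=True).sum() == pytest.approx(10 / 19)


def test_encode_ss_mapping():
    v = encode_ss(["H"] * 19)
    assert v.shape == (133,)
    assert v.sum() == 19
    # H is the least-significant printed bit: 0000001
    assert "".join(str(int(b)) for b in v[:7]) == "0000001"
    assert "".join(str(int(b)) for b in encode_ss(["S"])[:7]) == "1000000"
    np.testing.assert_allclose(encode_ss(["-"] * 19), 0.0)
    mixed = encode_ss(list("HBEGITS") + ["-"] * 12).reshape(19, 7)
    assert all(mixed[i].sum() == 1 for i in range(7))
    with pytest.raises(ValueError, match="unknown"):
        encode_ss(["Q"])


def test_encode_asa():
    np.testing.assert_allclose(encode_asa([None] * 19), 0.0)
    np.testing.assert_allclose(encode_asa([100.0] * 19), 100.0)
    np.testing.assert_allclose(encode_asa(list(range(19))), np.arange(19))
    with pytest.raises(ValueError, match="negative"):
        encode_asa([-1.0])


# --- PSSM -------------------------------------------------------------------


def _identity_pssm(protein, scale=1):
    L = len(protein)
    scores = np.tile(np.arange(L, dtype=np.int32)[:, None] % 13, (1, 20)) * scale
    return PSSMMatrix(protein.id, "ARNDCQEGHILKMFPSTWYV", scores, protein.sequence)


def test_pssm_roundtrip(tmp_path):
    prot = Protein("p1", "MKKTAAAKLL")
    pssm = _identity_pssm(prot)
    f = tmp_path / "p1.pssm"
    write_ascii_pssm(pssm, f)
    back = read_ascii_pssm(f, protein=prot)
    assert back.letters == pssm.letters
    assert back.sequence == prot.sequence
    np.testing.assert_array_equal(back.scores, pssm.scores)


def test_pssm_truncated_file(tmp_path):
    f = tmp_path / "bad.pssm"
    f.write_text(
        "\nheader\n"
        "            A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V\n"
        "    1 M    1  2  3\n"
    )
    with pytest.raises(PSSMParseError, match="bad.pssm:4"):
        read_ascii_pssm(f)


def test_pssm_sequence_mismatch_warns(tmp_path, caplog):
    prot = Protein("p1", "MKKTAAAKLL")
    other = Protein("p1", "MKKTAAAKLV")
    f = tmp_path / "p1.pssm"
    write_ascii_pssm(_identity_pssm(prot), f)
    with caplog.at_level("WARNING"):
        read_ascii_pssm(f, protein=other)
    assert "differs" in caplog.text


def test_encode_pssm_padding_and_positions():
    prot = Protein("p1", "KAAAAAAAAAAAAAAAAAAA")  # K at 1, length 20
    pssm = _identity_pssm(prot)
    w = PeptideWindow("p1", 1, "XXXXXXXXX" + prot.sequence[:10], None)
    v = encode_pssm(w, pssm)
    assert v.shape == (380,)
    np.testing.assert_allclose(v[:180], 0.0)  # 9 upstream padding rows
    # window position k >= 9 maps to protein row (1 - 9 + k) - 1 = k - 9
    got = v[180:].reshape(10, 20)
    np.testing.assert_array_equal(got, pssm.scores[:10])


def test_encode_pssm_missing_is_zero():
    w = _win("A" * 9 + "K" + "A" * 9)
    np.testing.assert_allclose(encode_pssm(w, None), 0.0)


# --- structure parsing -------------------------------------------------------


def _dssp_line(i, aa, ss, acc):
    """A DSSP per-residue line with the fixed columns the parser reads."""
    line = [" "] * 40
    line[0:5] = f"{i:5d}"
    line[5:10] = f"{i:5d}"
    line[11] = "A"
    line[13] = aa
    line[16] = ss
    line[34:38] = f"{acc:4d}"
    return "".join(line)


def test_read_dssp_minimal(tmp_path):
    lines = [
        "==== Secondary Structure Definition by the program DSSP ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O",
        _dssp_line(1, "M", "H", 52),
        _dssp_line(2, "K", "E", 101),
        _dssp_line(3, "T", " ", 7),
    ]
    f = tmp_path / "x.dssp"
    f.write_text("\n".join(lines) + "\n")
    ann = read_dssp(f, "p1")
    assert ann.ss == "HE-"
    np.testing.assert_allclose(ann.asa, [52.0, 101.0, 7.0])


def test_structure_annotation_validation():
    with pytest.raises(ValueError, match="invalid SS"):
        StructureAnnotation("p", "HZ", np.array([1.0, 2.0]))
    with pytest.raises(ValueError, match="length"):
        StructureAnnotation("p", "H", np.array([1.0, 2.0]))


def test_window_structure_helpers():
    ann = StructureAnnotation("p", "HHEE", np.array([1.0, 2.0, 3.0, 4.0]))
    w = PeptideWindow("p", 2, "XKH", None)  # flank 1 around position 2
    # position 2 is 'H'? build consistent: letters for positions 1..3
    letters = window_ss_letters(w, ann)
    assert letters == ["H", "H", "E"]
    w0 = PeptideWindow("p", 1, "XKH", None)
    assert window_ss_letters(w0, ann) == ["X", "H", "H"]
    assert window_asa_values(w0, ann) == [None, 1.0, 2.0]


# --- assembly ----------------------------------------------------------------


def test_assemble_default_632(small_feature_matrix):
    fm = small_feature_matrix
    assert fm.n_features == 632
    by_encoder = {}
    for name in fm.columns:
        info = fm.registry[name]
        by_encoder[info.encoder] = by_encoder.get(info.encoder, 0) + 1
    assert by_encoder == {"pcp": 72, "pssm": 380, "ac": 8, "rc": 20, "ss": 133, "asa": 19}
    assert len(fm.registry) == fm.n_features
    assert not np.isnan(fm.X).any()


def test_assemble_partial_configurations(small_bundle, norm_props):
    windows = small_bundle.windows()[:30]
    seq_only = assemble(windows, properties=norm_props, pssms=small_bundle.pssms,
                        encoders=("pcp", "pssm", "ac", "rc"))
    assert seq_only.n_features == 480
    rc_only = assemble(windows, encoders=("rc",))
    assert rc_only.n_features == 20


def test_assemble_missing_resource(small_bundle, norm_props):
    windows = small_bundle.windows()[:5]
    with pytest.raises(ValueError, match="pssm missing"):
        assemble(windows, properties=norm_props, pssms={},
                 structures=small_bundle.structures)
    zeroed = assemble(windows, properties=norm_props, pssms={},
                      structures=small_bundle.structures, missing_pssm="zero")
    block = [i for i, c in enumerate(zeroed.columns) if c.startswith("pssm:")]
    np.testing.assert_allclose(zeroed.X[:, block], 0.0)


def test_feature_tsv_roundtrip(tmp_path, small_feature_matrix):
    fm = small_feature_matrix
    f = tmp_path / "features.tsv"
    fm.to_tsv(f)
    back = read_feature_tsv(f)
    assert back.columns == fm.columns
    assert back.meta == fm.meta
    np.testing.assert_array_equal(back.labels, fm.labels)
    np.testing.assert_allclose(back.X, fm.X, rtol=1e-9)
    for name in fm.columns:
        assert parse_column_name(name) == fm.registry[name]
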