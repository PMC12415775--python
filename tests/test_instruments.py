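import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrlink.instruments import (
    COMPLEMENT,
    LDLookup,
    f_statistic,
    harmonize,
    ld_clump,
    select_instruments,
)
from mrlink.summary_io import VariantAssociation
from mrlink.synthetic_data import ld_block_matrix, snp_id
from tests.conftest import make_table


def row(snp, p=1e-8, beta=0.1, se=0.01, chrom="1", pos=1000, ea="A", oa="G", eaf=0.3):
    return {"SNP": snp, "CHR": chrom, "POS": pos, "EA": ea, "OA": oa,
            "BETA": beta, "SE": se, "P": p, "EAF": eaf, "N": 10000}


# ---------------------------------------------------------------- F statistic

def test_f_statistic_is_squared_z():
    assert f_statistic(0.05, 0.01) == pytest.approx(25.0)
    assert f_statistic(0.0, 0.01) == 0.0
    rec = VariantAssociation("rs1", "A", "G", 0.037, 0.011, 0.001)
    assert f_statistic(rec) == pytest.approx((0.037 / 0.011) ** 2)


# ------------------------------------------------------------------ selection

def test_selection_thresholds():
    t = make_table([
        row("rs1", p=2e-5),                      # fails default p < 1e-5
        row("rs2", p=1e-6),                      # passes both
        row("rs3", p=1e-6, beta=0.01, se=0.01),  # F = 1, weak
    ])
    kept = select_instruments(t)
    assert list(kept.df["SNP"]) == ["rs2"]


def test_selection_equals_brute_force_filter():
    rng = np.random.default_rng(3)
    rows = [row(f"rs{i}", p=float(rng.uniform(0, 1e-4)),
                beta=float(rng.normal(0, 0.05)), se=float(rng.uniform(0.005, 0.05)))
            for i in range(10)]
    t = make_table(rows)
    kept = set(select_instruments(t).df["SNP"])
    expected = {r["SNP"] for r in rows
                if r["P"] < 1e-5 and (r["BETA"] / r["SE"]) ** 2 >= 10}
    assert kept == expected


def test_selection_identity_and_errors():
    t = make_table([row("rs1", p=0.9, beta=0.001, se=0.1)])
    assert list(select_instruments(t, 1.0, 0).df["SNP"]) == ["rs1"]
    with pytest.raises(ValueError):
        select_instruments(t, p_threshold=0.0)


# ------------------------------------------------------------------- clumping

def test_clump_same_position_keeps_lower_p():
    t = make_table([row("rs1", p=1e-8, pos=1000), row("rs2", p=1e-6, pos=1000)])
    ld = LDLookup({("rs1", "rs2"): 0.5})
    assert list(ld_clump(t, ld).df["SNP"]) == ["rs1"]


def test_clump_window_excludes_distant_pairs():
    t = make_table([row("rs1", p=1e-8, pos=1000),
                    row("rs2", p=1e-6, pos=1000 + 20_000_000)])  # 20,000 kb away
    ld = LDLookup({("rs1", "rs2"): 0.5})
    assert list(ld_clump(t, ld).df["SNP"]) == ["rs1", "rs2"]


def _brute_force_clump(rows, ld, r2_threshold, window_kb):
    """Independent greedy oracle over explicit candidate lists."""
    pending = sorted(rows, key=lambda r: (r["P"], str(r["CHR"]), r["POS"], r["SNP"]))
    kept = []
    while pending:
        index = pending.pop(0)
        kept.append(index["SNP"])
        survivors = []
        for r in pending:
            same_chr = str(r["CHR"]) == str(index["CHR"])
            close = abs(r["POS"] - index["POS"]) / 1000.0 < window_kb
            linked = ld.r2(index["SNP"], r["SNP"]) >= r2_threshold
            if not (same_chr and close and linked):
                survivors.append(r)
        pending = survivors
    return kept


def test_clump_matches_brute_force_on_three_block_fixture():
    """12 SNPs in 3 LD blocks of 4, plus boundary r² exactly at threshold."""
    ld = ld_block_matrix(12, block_size=4, rho=0.7)  # r² = 0.49 within blocks
    rng = np.random.default_rng(11)
    rows = []
    for i in range(12):
        block = i // 4
        rows.append(row(snp_id(i), p=float(rng.uniform(1e-10, 1e-5)),
                        chrom=str(block + 1), pos=1000 + (i % 4) * 100_000))
    # boundary case: pair in block 1 at exactly the threshold
    ld.set(snp_id(0), snp_id(1), 0.01)
    t = make_table(rows)
    got = list(ld_clump(t, ld, r2_threshold=0.01, window_kb=10_000).df["SNP"])
    expected = _brute_force_clump(rows, ld, 0.01, 10_000)
    assert got == expected


def test_clump_identity_invariants():
    ld = ld_block_matrix(8, block_size=4, rho=0.9)  # off-diagonal r² = 0.81 < 1
    rows = [row(snp_id(i), p=1e-6 - i * 1e-8, chrom="1", pos=1000 + i * 1000)
            for i in range(8)]
    t = make_table(rows)
    assert len(ld_clump(t, ld, r2_threshold=1.0)) == 8
    assert len(ld_clump(t, ld, window_kb=0.0)) == 8
    assert len(ld_clump(t, ld)) == 2  # one index per block otherwise


def test_clump_rho_one_keeps_one_per_block():
    ld = ld_block_matrix(10, block_size=5, rho=1.0)
    rows = [row(snp_id(i), p=1e-6 - i * 1e-8, chrom=str(i // 5), pos=1000 + (i % 5))
            for i in range(10)]
    assert len(ld_clump(make_table(rows), ld)) == 2


# --------------------------------------------------------------- harmonization

def test_harmonize_identity_kept():
    exp = make_table([row("rs1", beta=0.1, ea="A", oa="G", eaf=0.3)], trait_id="exp")
    out = make_table([row("rs1", beta=0.2, ea="A", oa="G", eaf=0.3)], trait_id="out")
    h = harmonize(exp, out)
    assert h.actions["rs1"] == "kept"
    assert h.beta_out[0] == 0.2


def test_harmonize_swapped_alleles_flip_sign_and_frequency():
    exp = make_table([row("rs1", beta=0.1, ea="A", oa="G", eaf=0.3)])
    out = make_table([row("rs1", beta=0.2, ea="G", oa="A", eaf=0.3)])
    h = harmonize(exp, out)
    assert h.actions["rs1"] == "flipped"
    assert h.beta_out[0] == -0.2
    assert h.eaf_out[0] == pytest.approx(0.7)


def test_harmonize_strand_complement_resolved():
    exp = make_table([row("rs1", beta=0.1, ea="A", oa="G", eaf=0.3)])
    out = make_table([row("rs1", beta=0.2, ea="T", oa="C", eaf=0.3)])
    h = harmonize(exp, out)
    assert h.actions["rs1"] == "kept"
    assert h.beta_out[0] == 0.2


@pytest.mark.parametrize("eaf_exp,eaf_out,expected_action,expected_beta", [
    (0.50, 0.50, "dropped_palindromic", None),   # maximally ambiguous
    (0.42, 0.30, "dropped_palindromic", None),   # band edge is ambiguous
    (0.58, 0.30, "dropped_palindromic", None),
    (None, 0.30, "dropped_palindromic", None),   # missing frequency
    (0.30, 0.30, "kept", 0.2),                   # same side of 0.5
    (0.30, 0.70, "flipped", -0.2),               # opposite sides
    (0.41, 0.30, "kept", 0.2),                   # just outside the band
])
def test_harmonize_palindromic_rules(eaf_exp, eaf_out, expected_action, expected_beta):
    exp = make_table([row("rs1", beta=0.1, ea="A", oa="T", eaf=eaf_exp)])
    out = make_table([row("rs1", beta=0.2, ea="A", oa="T", eaf=eaf_out)])
    if expected_action.startswith("dropped"):
        with pytest.raises(ValueError, match="no shared instruments"):
            harmonize(exp, out)
        # action still recorded when other instruments keep the set non-empty
        exp2 = make_table([row("rs1", beta=0.1, ea="A", oa="T", eaf=eaf_exp),
                           row("rs2", beta=0.1, pos=2000)])
        out2 = make_table([row("rs1", beta=0.2, ea="A", oa="T", eaf=eaf_out),
                           row("rs2", beta=0.2, pos=2000)])
        assert harmonize(exp2, out2).actions["rs1"] == expected_action
    else:
        h = harmonize(exp, out)
        assert h.actions["rs1"] == expected_action
        assert h.beta_out[0] == pytest.approx(expected_beta)


def test_harmonize_incompatible_and_missing():
    exp = make_table([row("rs1", ea="A", oa="G"), row("rs2", pos=2000), row("rs3", pos=3000)])
    out = make_table([row("rs1", ea="A", oa="C"), row("rs2", pos=2000)])
    h = harmonize(exp, out)
    assert h.actions == {"rs1": "dropped_incompatible", "rs2": "kept",
                        "rs3": "dropped_missing"}


def test_harmonize_empty_intersection_raises():
    exp = make_table([row("rs1")])
    out = make_table([row("rs9")])
    with pytest.raises(ValueError, match="no shared instruments"):
        harmonize(exp, out)


def test_harmonize_idempotent_on_aligned_pair():
    """Harmonizing an already-aligned pair keeps every SNP unchanged."""
    rows_e = [row(f"rs{i}", beta=0.1 * i + 0.05, pos=1000 * (i + 1), eaf=0.2 + 0.05 * i)
              for i in range(4)]
    rows_o = [dict(r, BETA=r["BETA"] * 2) for r in rows_e]
    h = harmonize(make_table(rows_e), make_table(rows_o))
    assert all(a == "kept" for a in h.actions.values())
    np.testing.assert_array_equal(h.beta_out, [2 * r["BETA"] for r in rows_e])


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_harmonize_orientation_invariance(seed):
    """Swapping outcome alleles + negating beta yields the identical set."""
    rng = np.random.default_rng(seed)
    pairs = [("A", "G"), ("C", "T"), ("G", "C"), ("A", "T")]
    rows_e, rows_o, rows_o_flipped = [], [], []
    for i in range(6):
        ea, oa = pairs[rng.integers(0, len(pairs))]
        eaf = float(rng.uniform(0.05, 0.35))  # outside the palindrome band
        beta_o = float(rng.normal(0, 0.2))
        rows_e.append(row(f"rs{i}", beta=float(rng.normal(0.1, 0.02)),
                          pos=1000 * (i + 1), ea=ea, oa=oa, eaf=eaf))
        rows_o.append(row(f"rs{i}", beta=beta_o, pos=1000 * (i + 1),
                          ea=ea, oa=oa, eaf=eaf))
        rows_o_flipped.append(row(f"rs{i}", beta=-beta_o, pos=1000 * (i + 1),
                                  ea=oa, oa=ea, eaf=1 - eaf))
    exp = make_table(rows_e)
    h1 = harmonize(exp, make_table(rows_o))
    h2 = harmonize(exp, make_table(rows_o_flipped))
    np.testing.assert_array_equal(h1.beta_out, h2.beta_out)
    np.testing.assert_array_equal(h1.se_out, h2.se_out)
    np.testing.assert_allclose(h1.eaf_out, h2.eaf_out, rtol=0, atol=1e-15)


# ------------------------------------------------------------------- LDLookup

def test_ldlookup_symmetry_and_defaults(tmp_path):
    ld = LDLookup({("a", "b"): 0.3})
    assert ld.r2("b", "a") == 0.3
    assert ld.r2("a", "a") == 1.0
    assert ld.r2("a", "zzz") == 0.0
    path = tmp_path / "ld.tsv"
    ld.to_file(path)
    assert LDLookup.from_file(path).r2("a", "b") == 0.3
    with pytest.raises(ValueError):
        ld.set("a", "c", 1.5)
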