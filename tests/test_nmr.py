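"""Peak-table and shift-table statistics."""

import numpy as np
import pandas as pd
import pytest

from idpkit import synth
from idpkit.nmr import (
    cis_pro_signature,
    isomer_ratio,
    load_random_coil_shifts,
    read_peak_table,
    read_shift_table,
    secondary_shift_differential,
    titration_change,
    validate_peak_table,
)


def _peaks(rows):
    return pd.DataFrame(rows, columns=["residue", "code", "isomer", "height"])


def test_isomer_ratio_exact_at_zero_noise():
    peaks, _ = synth.planted_nmr_tables(49.0, n_residues=6, seed=0)
    res = isomer_ratio(peaks, residues=range(1, 7))
    assert res.cis_percent == pytest.approx(49.0, abs=1e-12)
    assert res.trans_percent == pytest.approx(51.0, abs=1e-12)
    assert res.sd == pytest.approx(0.0, abs=1e-12)


def test_isomer_ratio_invariant_under_common_rescaling():
    peaks, _ = synth.planted_nmr_tables(30.0, n_residues=5,
                                        height_noise=0.1, seed=1)
    r1 = isomer_ratio(peaks, range(1, 6))
    scaled = peaks.assign(height=peaks["height"] * 137.0)
    r2 = isomer_ratio(scaled, range(1, 6))
    assert r1.cis_percent == pytest.approx(r2.cis_percent, rel=1e-12)
    assert r1.sd == pytest.approx(r2.sd, rel=1e-12)


def test_isomer_ratio_skips_incomplete_reporters_with_warning():
    peaks = _peaks([
        (1, "A", "cis", 40.0), (1, "A", "trans", 60.0),
        (2, "D", "trans", 50.0),  # no cis peak
    ])
    with pytest.warns(UserWarning, match="residue 2"):
        res = isomer_ratio(peaks, [1, 2])
    assert res.cis_percent == pytest.approx(40.0)
    with pytest.raises(ValueError):
        isomer_ratio(peaks, [2])


def test_peak_table_validation():
    with pytest.raises(ValueError, match="columns"):
        validate_peak_table(pd.DataFrame({"residue": [1]}))
    with pytest.raises(ValueError, match="isomer"):
        validate_peak_table(_peaks([(1, "A", "maybe", 1.0)]))
    with pytest.raises(ValueError, match="non-negative"):
        validate_peak_table(_peaks([(1, "A", "cis", -1.0)]))
    with pytest.raises(ValueError, match="duplicate"):
        validate_peak_table(_peaks([(1, "A", "cis", 1.0), (1, "A", "cis", 2.0)]))


def test_table_io_round_trip(tmp_path):
    peaks, shifts = synth.planted_nmr_tables(40.0, n_residues=4, seed=2)
    pp, sp = tmp_path / "p.tsv", tmp_path / "s.tsv"
    peaks.to_csv(pp, sep="\t", index=False)
    shifts.to_csv(sp, sep="\t", index=False)
    pd.testing.assert_frame_equal(read_peak_table(pp), peaks)
    pd.testing.assert_frame_equal(read_shift_table(sp), shifts)


def test_zero_pattern_gives_zero_differential():
    _, shifts = synth.planted_nmr_tables(50.0, n_residues=8, seed=3)
    table = secondary_shift_differential(shifts)
    np.testing.assert_allclose(table["delta_delta"], 0.0, atol=1e-12)


def test_planted_pattern_is_recovered_exactly():
    pattern = np.array([2.0, -1.5, 0.0, 3.0, -2.5])
    _, shifts = synth.planted_nmr_tables(50.0, n_residues=5,
                                         pattern=pattern, seed=4)
    table = secondary_shift_differential(shifts)
    np.testing.assert_allclose(table["delta_delta"], pattern, atol=1e-12)


def test_glycine_uses_only_the_ca_term():
    ref = load_random_coil_shifts()
    shifts = pd.DataFrame(
        [(1, "G", "CA", ref.loc["G", "ca"] + 1.3, "none")],
        columns=["residue", "code", "atom", "shift", "isomer"],
    )
    table = secondary_shift_differential(shifts)
    assert table["delta_delta"].iloc[0] == pytest.approx(1.3)


def test_missing_atoms_are_skipped_with_warning():
    ref = load_random_coil_shifts()
    shifts = pd.DataFrame(
        [(1, "A", "CA", ref.loc["A", "ca"], "none")],  # no CB for alanine
        columns=["residue", "code", "atom", "shift", "isomer"],
    )
    with pytest.warns(UserWarning, match="Cb"):
        table = secondary_shift_differential(shifts)
    assert len(table) == 0


def test_cis_proline_upfield_signature():
    _, shifts = synth.planted_nmr_tables(50.0, n_residues=3, seed=5,
                                         cis_pro_offset=0.4)
    offset, call = cis_pro_signature(shifts, proline_residue=4)
    assert offset == pytest.approx(0.4)
    assert call is True
    _, shifts2 = synth.planted_nmr_tables(50.0, n_residues=3, seed=5,
                                          cis_pro_offset=2.5)
    offset2, call2 = cis_pro_signature(shifts2, proline_residue=4)
    assert offset2 == pytest.approx(2.5) and call2 is False


def test_titration_floor_is_exactly_minus_100():
    free = _peaks([(1, "A", "none", 100.0), (2, "D", "none", 80.0),
                   (3, "E", "none", 50.0)])
    bound = _peaks([(1, "A", "none", 0.0), (2, "D", "none", 4.0),
                    (3, "E", "none", 60.0)])
    table = titration_change(free, bound, noise_floor=5.0).set_index("residue")
    assert table.loc[1, "change_percent"] == -100.0
    assert table.loc[2, "change_percent"] == -100.0  # at/below the floor
    assert table.loc[3, "change_percent"] == pytest.approx(20.0)
    assert (table["status"] == "ok").all()


def test_titration_flags_missing_and_degenerate_rows():
    free = _peaks([(1, "A", "none", 2.0), (2, "D", "none", 50.0)])
    bound = _peaks([(1, "A", "none", 3.0), (2, "D", "none", 25.0),
                    (3, "E", "none", 10.0)])
    table = titration_change(free, bound, noise_floor=5.0).set_index("residue")
    assert table.loc[1, "status"] == "free_below_floor"
    assert table.loc[3, "status"] == "missing"
    assert table.loc[2, "change_percent"] == pytest.approx(-50.0)
    with pytest.raises(ValueError):
        titration_change(free, bound, noise_floor=-1.0)
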