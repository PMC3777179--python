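"""Pyrogram simulation, quantification, and quality control."""

import numpy as np
import pytest

from pyrometh import (
    DegenerateSequence,
    DispensationOrder,
    Pyrogram,
    UnidentifiableSiteError,
    generate_dispensation,
    qc_conversion,
    quantify,
    read_peak_table,
    simulate_pyrogram,
    write_peak_table,
)

M_POS = (0.86, 0.71, 0.77)


def test_blank_g_dispensation_gives_zero_height(kit_seq, kit_order):
    # first vendor dispensation is a G absent from the upcoming sequence
    p = simulate_pyrogram(kit_seq, M_POS, kit_order)
    assert p.heights[0] == 0.0


def test_leading_tt_peak_is_double_height(kit_seq, kit_order):
    # on fully methylated template no molecule reads the CpG as T, so the
    # leading TT peak is exactly twice the single-T height
    p = simulate_pyrogram(kit_seq, (1.0, 1.0, 1.0), kit_order)
    t_idx = kit_order.bases.index("T")
    assert p.heights[t_idx] == 2.0


@pytest.mark.parametrize("m_all, sub", [(1.0, "C"), (0.0, "T")])
def test_branch_collapse_equals_substituted_template(kit_seq, kit_order, m_all, sub):
    collapsed = DegenerateSequence(kit_seq.bases.replace("Y", sub))
    p_mix = simulate_pyrogram(kit_seq, (m_all,) * 3, kit_order)
    p_sub = simulate_pyrogram(collapsed, (), kit_order)
    np.testing.assert_allclose(p_mix.heights, p_sub.heights, atol=1e-12)


def test_simulation_input_validation(kit_seq, gen_order):
    with pytest.raises(ValueError):
        simulate_pyrogram(kit_seq, (0.5, 0.5), gen_order)  # dimension mismatch
    with pytest.raises(ValueError):
        simulate_pyrogram(kit_seq, (0.5, 0.5, 1.2), gen_order)  # out of range


def test_noise_deterministic_per_seed_and_nonnegative(kit_seq, gen_order):
    a = simulate_pyrogram(kit_seq, M_POS, gen_order, noise_cv=0.3, seed=7)
    b = simulate_pyrogram(kit_seq, M_POS, gen_order, noise_cv=0.3, seed=7)
    c = simulate_pyrogram(kit_seq, M_POS, gen_order, noise_cv=0.3, seed=8)
    np.testing.assert_array_equal(a.heights, b.heights)
    assert not np.array_equal(a.heights, c.heights)
    assert np.all(a.heights >= 0)


@pytest.mark.parametrize(
    "m, expected",
    [(M_POS, (86.0, 71.0, 77.0)), ((0.02, 0.02, 0.02), (2.0, 2.0, 2.0))],
)
def test_noiseless_round_trip_recovers_control_calls(kit_seq, gen_order, m, expected):
    call = quantify(simulate_pyrogram(kit_seq, m, gen_order), kit_seq)
    np.testing.assert_allclose(call.per_site_percent, expected, atol=1e-9)
    assert call.per_site_quality == ("blue", "blue", "blue")
    assert call.conversion_check == "pass"
    assert call.total_percent == pytest.approx(np.mean(expected), abs=1e-9)


def test_quantify_reduces_to_isolated_peak_ratio_and_is_scale_free(kit_seq, gen_order):
    """Where a site's C and T peaks are isolated, the fit equals
    100 * h_C / (h_C + h_T); heights are arbitrary units, so a common
    rescaling changes nothing."""
    p = simulate_pyrogram(kit_seq, M_POS, gen_order)
    scaled = Pyrogram(order=gen_order, heights=3.7 * p.heights)
    call = quantify(scaled, kit_seq)
    np.testing.assert_allclose(call.per_site_percent, (86.0, 71.0, 77.0), atol=1e-9)
    assert call.fit.scale == pytest.approx(3.7, abs=1e-9)
    dm = call.fit.design
    # site 2 is the template's only fully isolated C/T pair (sites 1 and 3
    # follow a template T, so their T signal rides on an adjacent run);
    # there the peak ratio is exactly the called percentage
    idx = dm.site_dispensations(2)
    assert idx.size == 2
    c_idx = idx[0] if gen_order.bases[idx[0]] == "C" else idx[1]
    t_idx = idx[1] if gen_order.bases[idx[0]] == "C" else idx[0]
    h_c, h_t = scaled.heights[c_idx], scaled.heights[t_idx]
    assert call.per_site_percent[1] == pytest.approx(
        100 * h_c / (h_c + h_t), abs=1e-9
    )


def test_monotonic_in_true_methylation(kit_seq, gen_order):
    others = (0.4, 0.6)
    prev = -1.0
    for m1 in np.linspace(0, 1, 11):
        call = quantify(
            simulate_pyrogram(kit_seq, (m1, *others), gen_order), kit_seq
        )
        assert call.per_site_percent[0] >= prev - 1e-12
        prev = call.per_site_percent[0]


def test_mean_recovery_under_noise(kit_seq, gen_order):
    truth = np.array(M_POS)
    estimates = np.array(
        [
            quantify(
                simulate_pyrogram(kit_seq, truth, gen_order, noise_cv=0.05, seed=s),
                kit_seq,
            ).per_site_percent
            for s in range(200)
        ]
    )
    np.testing.assert_allclose(estimates.mean(axis=0), 100 * truth, atol=1.0)


def test_unidentifiable_order_names_sites(kit_seq):
    # a two-dispensation order reads past site 1 only; sites 2 and 3 never
    # contribute signal and must be reported as unresolvable
    order = DispensationOrder.from_string("TG")
    with pytest.raises(UnidentifiableSiteError) as err:
        quantify(simulate_pyrogram(kit_seq, M_POS, order), kit_seq)
    assert err.value.sites == (2, 3)


def test_conversion_qc_pass_fail_and_not_applicable(kit_seq, gen_order):
    clean = simulate_pyrogram(kit_seq, M_POS, gen_order)
    qc = qc_conversion(clean, kit_seq)
    assert qc.status == "pass" and qc.ratio == 0.0

    # failed conversion: control peak as tall as a reference peak
    heights = clean.heights.copy()
    conv = gen_order.control_positions("conversion_control")[0]
    heights[conv] = 1.0
    qc_bad = qc_conversion(Pyrogram(order=gen_order, heights=heights), kit_seq)
    assert qc_bad.status == "fail" and qc_bad.ratio == pytest.approx(1.0)

    no_controls = simulate_pyrogram(kit_seq, M_POS, "TCTGTGTGCTGTCTGT")
    assert qc_conversion(no_controls, kit_seq).status == "not_applicable"


def test_conversion_qc_under_noise(kit_seq, gen_order):
    passes = sum(
        qc_conversion(
            simulate_pyrogram(kit_seq, M_POS, gen_order, noise_cv=0.05, seed=s),
            kit_seq,
        ).status
        == "pass"
        for s in range(100)
    )
    assert passes >= 95


def test_quality_perturbation_reddens_only_that_site(kit_seq, gen_order):
    # a 20% error on a tall methylated-C peak leaves a relative misfit of
    # about 0.2 * m at that site's dispensations (the fit splits it between
    # the C and T peaks), well past the 15% red threshold at high m
    clean = simulate_pyrogram(kit_seq, (0.5, 0.95, 0.5), gen_order)
    dm = quantify(clean, kit_seq).fit.design
    c_idx = next(
        i for i in dm.site_dispensations(2) if gen_order.bases[i] == "C"
    )
    heights = clean.heights.copy()
    heights[c_idx] *= 1.20
    call = quantify(Pyrogram(order=gen_order, heights=heights), kit_seq)
    assert call.per_site_quality[1] == "red"
    assert call.per_site_quality[0] != "red"
    assert call.per_site_quality[2] != "red"


def test_quality_mostly_blue_at_low_noise(kit_seq, gen_order):
    colors = []
    for s in range(100):
        call = quantify(
            simulate_pyrogram(kit_seq, M_POS, gen_order, noise_cv=0.03, seed=s),
            kit_seq,
        )
        colors.extend(call.per_site_quality)
    assert colors.count("blue") > len(colors) / 2


def test_peak_table_round_trip(tmp_path, kit_seq, gen_order):
    p = simulate_pyrogram(kit_seq, M_POS, gen_order, noise_cv=0.05, seed=11)
    path = tmp_path / "peaks.tsv"
    write_peak_table(p, path)
    back = read_peak_table(path)
    assert back.order.bases == p.order.bases
    assert back.order.control_marks == p.order.control_marks
    np.testing.assert_allclose(back.heights, p.heights)
    call_a = quantify(p, kit_seq)
    call_b = quantify(back, kit_seq)
    np.testing.assert_allclose(call_a.per_site_percent, call_b.per_site_percent)
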