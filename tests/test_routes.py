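import numpy as np
import pytest

import deglypk as d
from deglypk.exceptions import UndefinedSplitError


def test_iv_fractions_reproduce_reported_percentages(ref_params):
    rounded = d.iv_route_fractions(ref_params).rounded()
    assert rounded == {
        "route_a": 2,
        "biliary": 28,
        "route_b": 9,
        "unknown_plasma": 70,
        "unknown_bile": 19,
        "total_ppd": 11,
    }


def test_po_fractions_reproduce_reported_percentages(ref_params):
    rounded = d.po_route_fractions(ref_params).rounded()
    assert rounded == {
        "stomach_to_intestine": 61,
        "route_b": 19,
        "route_c": 1,
        "unknown_total": 80,
        "total_ppd": 20,
    }


def test_iv_breakdown_internal_identities(ref_params):
    b = d.iv_route_fractions(ref_params)
    assert b.route_a + b.route_b + b.unknown_plasma + b.unknown_bile == pytest.approx(100, abs=0.01)
    assert b.biliary == pytest.approx(b.route_b + b.unknown_bile, abs=1e-9)
    assert b.total_ppd == pytest.approx(b.route_a + b.route_b, abs=1e-12)


def test_po_breakdown_internal_identities(ref_params):
    b = d.po_route_fractions(ref_params)
    assert b.route_b + b.route_c + b.unknown_total == pytest.approx(100, abs=0.01)
    assert b.total_ppd == pytest.approx(b.route_b + b.route_c, abs=1e-12)


def test_no_transformation_means_no_ppd(ref_params):
    p = ref_params.replace(k_45=0.0, k_43=0.0)
    assert d.iv_route_fractions(p).total_ppd == 0.0


def test_po_without_stomach_transformation(ref_params):
    p = ref_params.replace(k_12=0.0)
    b = d.po_route_fractions(p)
    assert b.route_c == 0.0
    assert b.stomach_to_intestine == pytest.approx(100.0)


def test_degenerate_denominator_rejected(ref_params):
    with pytest.raises(UndefinedSplitError):
        d.po_route_fractions(ref_params.replace(k_12=0.0, k_13=0.0))
    with pytest.raises(UndefinedSplitError):
        d.iv_route_fractions(ref_params.replace(k_t=0.0, k_60=0.0))


def test_oracle_agrees_with_closed_forms_at_reference(ref_params):
    for mode, closed in (
        ("IV", d.iv_route_fractions(ref_params)),
        ("PO", d.po_route_fractions(ref_params)),
    ):
        oracle = d.route_fraction_oracle(ref_params, mode)
        for key, value in closed.as_dict().items():
            assert oracle.as_dict()[key] == pytest.approx(value, abs=0.1)


def test_oracle_percentages_sum_to_100(ref_params):
    iv = d.route_fraction_oracle(ref_params, "IV")
    po = d.route_fraction_oracle(ref_params, "PO")
    assert iv.route_a + iv.route_b + iv.unknown_plasma + iv.unknown_bile == pytest.approx(
        100, abs=0.1
    )
    assert po.route_b + po.route_c + po.unknown_total == pytest.approx(100, abs=0.1)


def test_asymptotic_split_independent_of_chain_length(ref_params):
    """The eventual fraction of biliary Rh2 absorbed as PPD is
    k_t/(k_t+k_60) no matter how many transit compartments delay it."""
    expected = d.iv_route_fractions(ref_params).route_b
    for n_transit in (1, 3, 5):
        oracle = d.route_fraction_oracle(ref_params, "IV", n_transit=n_transit)
        assert oracle.route_b == pytest.approx(expected, abs=0.1)


def test_total_ppd_monotone_in_kt(ref_params):
    kts = [0.1, 0.3, 0.63, 1.5, 5.0]
    iv = [d.iv_route_fractions(ref_params.replace(k_t=k)).total_ppd for k in kts]
    po = [d.po_route_fractions(ref_params.replace(k_t=k)).total_ppd for k in kts]
    assert all(b >= a for a, b in zip(iv, iv[1:]))
    assert all(b >= a for a, b in zip(po, po[1:]))
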