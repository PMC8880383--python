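"""Cage construction, composition bookkeeping, interconversion, unwrapping."""

import math

import numpy as np
import pytest

import capsid
from capsid.lattice import (
    CapsidArchitecture,
    LatticeCage,
    composition,
    elongate_by_ring,
    enumerate_dimers,
    hemisphere_twist,
    hk_from_T,
    unwrap_net,
)


def brute_force_audit(cage):
    """Independent combinatorial audit of a cage: count subunits from the
    capsomer kinds, check degrees, Euler's formula and facet count."""
    kinds = {s.id: s.kind for s in cage.sites}
    deg = {s.id: 0 for s in cage.sites}
    for e in cage.edges:
        deg[e.site_a] += 1
        deg[e.site_b] += 1
    for sid, k in kinds.items():
        assert deg[sid] == (5 if k == "pentamer" else 6)
    n_pent = sum(1 for k in kinds.values() if k == "pentamer")
    n_hex = len(kinds) - n_pent
    assert n_pent == 12
    n_cp = 5 * n_pent + 6 * n_hex
    assert cage.n_cp == n_cp
    assert len(cage.edges) == n_cp // 2
    assert len(cage.sites) - len(cage.edges) + len(cage.facets) == 2
    # each subunit sits on exactly one edge; both edge slots filled
    subs = {p.id for p in cage.subunit_placements}
    on_edges = [s for e in cage.edges for s in e.subunits]
    assert sorted(on_edges) == sorted(subs)
    return n_cp, n_pent, n_hex


@pytest.mark.parametrize(
    "T,n_cp,n_hex",
    [(1, 60, 0), (3, 180, 20), (4, 240, 30), (7, 420, 60)],
)
def test_icosahedral_compositions(T, n_cp, n_hex):
    cage = capsid.build_icosahedral(T)
    got = brute_force_audit(cage)
    assert got == (n_cp, 12, n_hex)


@pytest.mark.parametrize(
    "T,Q,n_cp,n_hex",
    [(3, 4, 210, 25), (3, 2, 150, 15), (1, 2, 90, 5), (1, 3, 120, 10)],
)
def test_elongated_5fold_compositions(T, Q, n_cp, n_hex):
    cage = capsid.build_elongated_5fold(T, Q)
    got = brute_force_audit(cage)
    assert got == (n_cp, 12, n_hex)
    assert cage.n_cp == 30 * (T + Q)


def test_degenerate_elongation_matches_icosahedral(t3_cage):
    q3 = capsid.build_elongated_5fold(3, 3)
    c_ico, c_q3 = composition(t3_cage), composition(q3)
    assert (c_ico.n_cp, c_ico.n_pentamer, c_ico.n_hexamer) == (
        c_q3.n_cp,
        c_q3.n_pentamer,
        c_q3.n_hexamer,
    )
    assert (c_ico.n_dimer_AB, c_ico.n_dimer_CC) == (c_q3.n_dimer_AB, c_q3.n_dimer_CC)


def test_small_prolate_composition(small_prolate_cage):
    assert brute_force_audit(small_prolate_cage) == (132, 12, 12)


def test_small_prolate_degenerate_is_icosahedral(t1_cage):
    c = capsid.build_elongated_3fold(1, 1, 1)
    assert (c.n_cp, c.n_pentamer, c.n_hexamer) == (60, 12, 0)
    assert composition(c).n_dimer_total == composition(t1_cage).n_dimer_total


def test_small_prolate_intermediate_audits():
    c = capsid.build_elongated_3fold(1, 2, 2)
    n_cp, n_pent, n_hex = brute_force_audit(c)
    assert n_cp == 5 * 12 + 6 * n_hex


def test_small_prolate_caps_contribute_six_pentamers_each(small_prolate_cage):
    north = [s for s in small_prolate_cage.sites if s.kind == "pentamer" and s.position[2] > 0]
    south = [s for s in small_prolate_cage.sites if s.kind == "pentamer" and s.position[2] < 0]
    assert len(north) == 6 and len(south) == 6


@pytest.mark.parametrize("bad_T", [2, 5, 6, 0, 11])
def test_invalid_triangulation_number_rejected(bad_T):
    with pytest.raises(ValueError, match="nearest valid|triangulation"):
        capsid.build_icosahedral(bad_T)


def test_incompatible_Q_rejected():
    # T=4 caps have lattice vector (2,0): Q must differ from T by a
    # multiple of gcd(h,k)=2
    with pytest.raises(ValueError, match="incompatible"):
        capsid.build_elongated_5fold(4, 3)


def test_unclosable_3fold_rejected():
    with pytest.raises(ValueError, match="cannot close"):
        capsid.build_elongated_3fold(1, 1, 2)
    with pytest.raises(ValueError):
        capsid.build_elongated_3fold(3, 4, 5)  # only T=1 caps supported


def test_architecture_invariants():
    with pytest.raises(ValueError):
        CapsidArchitecture("icosahedral", 3, Q=4)
    with pytest.raises(ValueError):
        CapsidArchitecture("elongated_5fold", 3)
    with pytest.raises(ValueError):
        CapsidArchitecture("elongated_3fold", 1, Q1=2)


# ---------------------------------------------------------------------------
# dimer accounting
# ---------------------------------------------------------------------------


def test_t3_dimer_census(t3_cage):
    dimers = enumerate_dimers(t3_cage)
    ab = [d for d in dimers if d.dimer_class == "A/B"]
    cc = [d for d in dimers if d.dimer_class == "C/C"]
    assert (len(ab), len(cc), len(dimers)) == (60, 30, 90)
    kinds = {s.id: s.kind for s in t3_cage.sites}
    for d in ab:
        assert {kinds[d.site_a], kinds[d.site_b]} == {"pentamer", "hexamer"}
    for d in cc:
        assert kinds[d.site_a] == kinds[d.site_b] == "hexamer"


def test_dimer_totals(t4_cage, oblate_cage):
    assert len(enumerate_dimers(t4_cage)) == 120
    assert len(enumerate_dimers(oblate_cage)) == 75


def test_mat_and_internal_dimer_accounting(t3_cage):
    comp = composition(t3_cage, mat_substituted=True)
    assert comp.n_dimer_total == 90
    assert comp.n_dimer_capsid_after_mat == 89
    comp = composition(t3_cage, mat_substituted=True, internal_dimer=True)
    assert comp.n_dimer_with_internal == 90


def test_mat_requires_cc_dimer(t1_cage):
    comp = composition(t1_cage)
    assert (comp.n_dimer_total, comp.n_dimer_AB, comp.n_dimer_CC) == (30, 30, 0)
    with pytest.raises(ValueError, match="C/C"):
        composition(t1_cage, mat_substituted=True)


def test_subunit_quasi_labels(t3_cage):
    # pentamer subunits are A; hexamer subunits alternate B (facing a
    # pentamer) and C (facing a hexamer)
    kinds = {s.id: s.kind for s in t3_cage.sites}
    for p in t3_cage.subunit_placements:
        if kinds[p.site] == "pentamer":
            assert p.label == "A"
        else:
            assert p.label in ("B", "C")
    labels = [p.label for p in t3_cage.subunit_placements]
    assert labels.count("A") == 60 and labels.count("B") == 60 and labels.count("C") == 60


# ---------------------------------------------------------------------------
# elongation / interconversion
# ---------------------------------------------------------------------------


def test_elongate_oblate_to_t3(oblate_cage, t3_cage):
    out = elongate_by_ring(oblate_cage)
    assert out.n_hexamer == oblate_cage.n_hexamer + 5
    assert out.n_pentamer == 12
    co, ct = composition(out), composition(t3_cage)
    assert (co.n_cp, co.n_pentamer, co.n_hexamer, co.n_dimer_total) == (
        ct.n_cp, ct.n_pentamer, ct.n_hexamer, ct.n_dimer_total,
    )


def test_elongate_t3_to_prolate(t3_cage, prolate_cage):
    out = elongate_by_ring(t3_cage)
    assert (out.n_cp, out.n_hexamer) == (prolate_cage.n_cp, prolate_cage.n_hexamer) == (210, 25)


def test_elongate_twice_from_oblate(oblate_cage, prolate_cage):
    out = elongate_by_ring(elongate_by_ring(oblate_cage))
    assert (out.n_cp, out.n_hexamer) == (prolate_cage.n_cp, prolate_cage.n_hexamer)


def test_elongation_rotates_hemispheres_36_degrees(oblate_cage):
    cage = oblate_cage
    for _ in range(3):
        out = elongate_by_ring(cage)
        d = abs(hemisphere_twist(out) - hemisphere_twist(cage))
        assert math.isclose(min(d, 72 - d), 36.0, abs_tol=1e-6)
        cage = out


def test_elongate_requires_5fold_axis(small_prolate_cage):
    with pytest.raises(ValueError, match="5-fold"):
        elongate_by_ring(small_prolate_cage)


# ---------------------------------------------------------------------------
# unwrapping
# ---------------------------------------------------------------------------


def test_unwrap_t3_counts(t3_cage):
    net = unwrap_net(t3_cage)
    assert len(net.edges) == 90  # every dimer edge exactly once
    assert len({e["edge"] for e in net.edges}) == 90
    assert len({n["site"] for n in net.nodes}) == 32


def test_unwrap_is_lossless(t3_cage, small_prolate_cage, oblate_cage):
    for cage in (t3_cage, small_prolate_cage, oblate_cage):
        net = unwrap_net(cage)
        truth = {tuple(sorted((e.site_a, e.site_b))) for e in cage.edges}
        assert net.reconstruct_adjacency() == truth


def test_unwrap_pentamer_labels(t3_cage):
    net = unwrap_net(t3_cage)
    assert len(net.pentamer_labels) == 12
    assert sorted(net.pentamer_labels.values()) == sorted(
        ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII"]
    )


def test_unwrap_anchor_choice(t3_cage):
    pent = [s.id for s in t3_cage.sites if s.kind == "pentamer"][3]
    net = unwrap_net(t3_cage, anchor_pentamer=pent)
    assert net.pentamer_labels[pent] == "I"
    hexs = [s.id for s in t3_cage.sites if s.kind == "hexamer"][0]
    with pytest.raises(ValueError, match="not a pentamer"):
        unwrap_net(t3_cage, anchor_pentamer=hexs)


def test_unwrap_markers(t3_cage):
    markers = [(i, 100 * (i + 1)) for i in range(33)]
    net = unwrap_net(t3_cage, markers=markers)
    assert len(net.markers) == 33
    assert sorted(m["color_index"] for m in net.markers) == list(range(33))
    with pytest.raises(ValueError, match="unknown dimer ids.*9999"):
        unwrap_net(t3_cage, markers=[(9999, 5)])


# ---------------------------------------------------------------------------
# serialization and invariants over a (T, Q) grid
# ---------------------------------------------------------------------------


def test_json_round_trip(prolate_cage, tmp_path):
    p = tmp_path / "cage.json"
    prolate_cage.to_json(p)
    back = LatticeCage.from_json(p)
    assert back.n_cp == prolate_cage.n_cp
    assert {(e.site_a, e.site_b, e.dimer_class) for e in back.edges} == {
        (e.site_a, e.site_b, e.dimer_class) for e in prolate_cage.edges
    }
    np.testing.assert_allclose(
        back.sites[0].position, prolate_cage.sites[0].position, atol=1e-9
    )


@pytest.mark.parametrize("T,Q", [(1, 4), (3, 5), (4, 4), (7, 6), (3, 7)])
def test_invariants_on_tq_grid(T, Q):
    if hk_from_T(T) is None:
        pytest.skip("not a triangulation number")
    cage = capsid.build_elongated_5fold(T, Q)
    n_cp, n_pent, n_hex = brute_force_audit(cage)
    assert n_cp == 30 * (T + Q)
    comp = composition(cage)
    assert comp.n_dimer_AB + comp.n_dimer_CC == comp.n_dimer_total == n_cp // 2
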