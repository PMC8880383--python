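"""Stem-loop inventory, contact census, binding-mode classification."""

import numpy as np
import pytest

from capsid import contacts as ct
from capsid import synthetic_data as syn
from capsid.structio import Atom, Chain, EntityConfig, Residue, StructureModel
from capsid.structio import parse_dotbracket


def stems_from_dbn(db, seq=None):
    pairs, _ = parse_dotbracket(db)
    return ct.detect_stem_loops(pairs, seq or "A" * len(db))


# ---------------------------------------------------------------------------
# stem-loop detection
# ---------------------------------------------------------------------------


def test_single_hairpin():
    stems = stems_from_dbn("((((....))))")
    assert len(stems) == 1
    sl = stems[0]
    assert sl.nt_range == (1, 12)
    assert sl.apical_loop == (5, 8)
    assert len(sl.helix_pairs) == 4


def test_unpaired_sequence_has_no_stems():
    assert stems_from_dbn("....") == []


def test_five_way_junction_reports_five_arms():
    arms = "(((...)))" * 4
    db = "(((" + arms + ")))"
    stems = stems_from_dbn(db)
    assert len(stems) == 5
    apical = [s for s in stems if s.apical_loop is not None]
    assert len(apical) == 4  # the closing helix has no terminal loop


def test_bulge_within_helix_tolerance():
    # 1-nt bulge: one helix with default max_bulge=2; forbidden at 0
    db = "(((.((....)))))"
    pairs, _ = parse_dotbracket(db)
    assert len(ct.detect_stem_loops(pairs, "A" * len(db), min_helix=3)) == 1
    split = ct.detect_stem_loops(pairs, "A" * len(db), min_helix=2, max_bulge=0)
    assert len(split) == 2


def test_min_helix_filters_short_stems():
    db = "((....))..(((((.....)))))"
    pairs, _ = parse_dotbracket(db)
    assert len(ct.detect_stem_loops(pairs, "A" * len(db), min_helix=3)) == 1
    assert len(ct.detect_stem_loops(pairs, "A" * len(db), min_helix=2)) == 2


def test_conflicting_pairs_error():
    with pytest.raises(ValueError, match="conflicting"):
        ct.detect_stem_loops([(1, 8), (1, 9)], "A" * 10)


def test_pseudoknot_flagged_both_stems_kept():
    # [[[ ... ]]] crossing ((( ... )))
    db = "(((...[[[...)))...]]]"
    pairs, _ = parse_dotbracket(db)
    stems = ct.detect_stem_loops(pairs, "A" * len(db))
    assert len(stems) == 2
    assert all(s.pseudoknotted for s in stems)


def test_genome_ordered_ids_and_gene_context():
    seq = "A" * ct.QBETA_GENOME_LENGTH
    pairs = [(i + k, i + 20 - k) for i in (100, 1400, 3000) for k in range(4)]
    stems = ct.detect_stem_loops(pairs, seq)
    assert [s.id for s in stems] == [1, 2, 3]
    assert [s.gene_context for s in stems] == ["mat", "cp", "rep"]


# ---------------------------------------------------------------------------
# contact census
# ---------------------------------------------------------------------------


def _point_structure(rna_z):
    """One protein atom at the origin, a 3-nt RNA 'stem-loop' at height z."""
    st = StructureModel()
    p = Chain("P")
    r = Residue("GLY", 1)
    r.atoms.append(Atom("CA", "C", np.zeros(3)))
    p.residues.append(r)
    q = Chain("Q")
    rq = Residue("GLY", 1)
    rq.atoms.append(Atom("CA", "C", np.array([3.0, 0.0, 0.0])))
    q.residues.append(rq)
    rna = Chain("R")
    for i in range(1, 4):
        rr = Residue("U", i)
        rr.atoms.append(Atom("P", "P", np.array([0.0, float(i - 1), rna_z])))
        rna.residues.append(rr)
    st.chains = [p, q, rna]
    return st


def _cfg():
    return EntityConfig(rna_chains=["R"], cp_dimers={"d1": ["P", "Q"]},
                        dimer_class={"d1": "A/B"})


def test_census_distance_exact():
    st = _point_structure(4.0)
    sl = ct.StemLoop(1, (1, 3), [])
    rec = ct.contact_census([sl], st, _cfg())[0]
    assert rec.partner == "d1"
    assert abs(rec.min_distance - 4.0) < 1e-12


def test_census_beyond_cutoff_is_none():
    st = _point_structure(6.0)
    sl = ct.StemLoop(1, (1, 3), [])
    rec = ct.contact_census([sl], st, _cfg(), cutoff=5.0)[0]
    assert rec.partner is None and rec.mode == "none"
    assert abs(rec.min_distance - 6.0) < 1e-12


def test_census_strictly_below_cutoff():
    st = _point_structure(5.0)
    rec = ct.contact_census([ct.StemLoop(1, (1, 3), [])], st, _cfg(), cutoff=5.0)[0]
    assert rec.partner is None  # "less than 5 Å" is strict


def test_census_unresolved_stemloop_flagged():
    st = _point_structure(4.0)
    recs = ct.contact_census([ct.StemLoop(1, (50, 60), [])], st, _cfg())
    assert recs[0].unresolved


def test_census_monotone_in_cutoff():
    st, _ = syn.make_stemloop_fixture("cp_anchored")
    cfg = EntityConfig(rna_chains=["R"], cp_dimers={"d1": ["P", "Q"]})
    sls = [ct.StemLoop(1, (1, 20), [])]
    contact_sets = []
    for cutoff in (2.0, 3.0, 5.0, 8.0):
        recs = ct.contact_census(sls, st, cfg, cutoff=cutoff)
        contact_sets.append({r.stemloop_id for r in recs if r.partner is not None})
    for small, big in zip(contact_sets, contact_sets[1:]):
        assert small <= big


def test_census_agrees_with_brute_force():
    st, _ = syn.make_stemloop_fixture("operator_like", noise_sigma=0.5, seed=9)
    cfg = EntityConfig(rna_chains=["R"], cp_dimers={"d1": ["P", "Q"]})
    sl = ct.StemLoop(1, (1, 20), [])
    rec = ct.contact_census([sl], st, cfg)[0]
    rna = np.vstack([a.pos for r in st.chain("R").residues for a in r.atoms])
    prot = np.vstack(
        [a.pos for name in ("P", "Q") for r in st.chain(name).residues for a in r.atoms]
    )
    brute = np.min(np.linalg.norm(rna[:, None, :] - prot[None, :, :], axis=2))
    assert abs(rec.min_distance - brute) < 1e-12


# ---------------------------------------------------------------------------
# binding-mode classification
# ---------------------------------------------------------------------------


def _classify(mode, sigma, seed):
    st, truth = syn.make_stemloop_fixture(mode, noise_sigma=sigma, seed=seed)
    cfg = EntityConfig(rna_chains=["R"], cp_dimers={"d1": ["P", "Q"]},
                       dimer_class={"d1": "C/C"})
    sl = ct.StemLoop(1, (1, 20), [], apical_loop=truth["apical_residues"])
    recs = ct.contact_census([sl], st, cfg)
    return ct.classify_records(recs, [sl], st, cfg, syn.canonical_operator_trace())[0]


@pytest.mark.parametrize("mode", ["operator_like", "cp_sandwiched", "cp_anchored"])
def test_planted_mode_recovered_exactly(mode):
    rec = _classify(mode, 0.0, 0)
    assert rec.mode == mode
    if mode == "cp_anchored":
        assert len(rec.monomers_contacted) == 1
    else:
        assert set(rec.monomers_contacted) == {"1", "2"}


def test_mode_round_trip_rate_at_1A_noise():
    ok = tot = 0
    for mode in ("operator_like", "cp_sandwiched", "cp_anchored"):
        for seed in range(20):
            tot += 1
            ok += _classify(mode, 1.0, seed).mode == mode
    assert ok / tot >= 0.95


def test_operator_pose_recognized_in_mirrored_orientation():
    st, truth = syn.make_stemloop_fixture("operator_like")
    # flip the RNA through the dimer dyad (x,y -> -x,-y)
    for r in st.chain("R").residues:
        for a in r.atoms:
            a.pos = a.pos * np.array([-1.0, -1.0, 1.0])
    cfg = EntityConfig(rna_chains=["R"], cp_dimers={"d1": ["P", "Q"]})
    sl = ct.StemLoop(1, (1, 20), [], apical_loop=truth["apical_residues"])
    recs = ct.classify_records(
        ct.contact_census([sl], st, cfg), [sl], st, cfg, syn.canonical_operator_trace()
    )
    assert recs[0].mode == "operator_like"


def test_missing_reference_trace_errors():
    st, truth = syn.make_stemloop_fixture("operator_like")
    cfg = EntityConfig(rna_chains=["R"], cp_dimers={"d1": ["P", "Q"]})
    sl = ct.StemLoop(1, (1, 20), [], apical_loop=truth["apical_residues"])
    recs = ct.contact_census([sl], st, cfg)
    with pytest.raises(ValueError, match="reference operator trace"):
        ct.classify_records(recs, [sl], st, cfg, None)


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------


def test_summary_conserves_counts():
    recs = [_classify(m, 0.0, 0) for m in ("operator_like", "cp_sandwiched", "cp_anchored")]
    for i, r in enumerate(recs):
        r.stemloop_id = i + 1
    out = ct.census_summary(recs)
    assert out["n_total"] == 3 and out["n_in_contact"] == 3
    assert out["by_mode"]["count"].sum() == 3


def test_summary_reproduces_planted_marginals():
    # 24 A/B + 8 C/C + 1 internal operator-like contacts
    recs = []
    classes = ["A/B"] * 24 + ["C/C"] * 8 + ["internal"] * 1
    for i, cls in enumerate(classes, start=1):
        rec = _classify("operator_like", 0.0, i)
        rec.stemloop_id = i
        rec.dimer_class = cls
        recs.append(rec)
    out = ct.census_summary(recs)
    ops = out["by_mode"][out["by_mode"]["mode"] == "operator_like"]
    marg = dict(zip(ops["dimer_class"], ops["count"]))
    assert marg == {"A/B": 24, "C/C": 8, "internal": 1}


def test_per_pentamer_operator_tally():
    recs = [_classify("operator_like", 0.0, s) for s in range(4)]
    for i, r in enumerate(recs):
        r.stemloop_id = i + 1
    membership = {"d1": ["I", "II"]}
    out = ct.census_summary(recs, pentamer_membership=membership)
    assert out["per_pentamer_operator"] == {"I": 4, "II": 4}
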