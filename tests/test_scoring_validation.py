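"""Boosting, CSM/cross-link assembly, FDR estimation, entrapment filtering."""

import random
from dataclasses import dataclass

import pytest
from hypothesis import given, settings, strategies as st

from xlms3.peptide_search import PSM, PeptideCandidate, peptide_mass
from xlms3.scoring_validation import (
    CSM,
    boost_score,
    entrapment_filter,
    estimate_fdr,
    group_crosslinks,
    make_csm,
    pool_and_boost,
    two_step_validate,
    validated_group_fdr,
    Crosslink,
    PooledHit,
)


def _cand(seq="AKCDE", site=2, arm="light", decoy=False, entrapment=False):
    return PeptideCandidate(
        sequence=seq, protein_accessions=frozenset({"P"}), is_decoy=decoy,
        is_entrapment=entrapment, missed_cleavages=0, crosslink_site=site,
        arm=arm, fixed_mods=(), neutral_mass=peptide_mass(seq, {}),
    )


def _psm(cand, scan, score):
    return PSM(cand, scan, 3, score, matched_ions=3, total_ions=10)


def _hit(seq="AKCDE", score=50.0, site=2, decoy=False, entrapment=False, n=1):
    cand = _cand(seq, site, decoy=decoy, entrapment=entrapment)
    scores = tuple([score] * n)
    return PooledHit(cand, scores, tuple(f"s{i}" for i in range(n)), 0.0, score)


class TestBoost:
    def test_single_scan_is_never_boosted(self):
        assert boost_score([50.0], n=1, p=100.0) == 50.0

    def test_p100_doubles_per_additional_scan(self):
        assert boost_score([50.0, 40.0], n=2, p=100.0) == 100.0

    def test_p0_reproduces_unboosted_max(self):
        assert boost_score([50.0, 40.0], n=2, p=0.0) == 50.0

    def test_three_scans_p20(self):
        assert boost_score([50.0, 40.0, 30.0], n=3, p=20.0) == pytest.approx(72.0)

    @given(
        scores=st.lists(st.floats(0.1, 500.0), min_size=1, max_size=6),
        n=st.integers(1, 6),
        p1=st.floats(0.0, 100.0),
        p2=st.floats(0.0, 100.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_p_and_n_and_bounded_below_by_max(self, scores, n, p1, p2):
        lo, hi = sorted((p1, p2))
        assert boost_score(scores, n, hi) >= boost_score(scores, n, lo)
        assert boost_score(scores, n + 1, lo) >= boost_score(scores, n, lo)
        b = boost_score(scores, n, lo)
        assert b >= max(scores) - 1e-9
        if n == 1 or lo == 0:
            assert b == pytest.approx(max(scores))

    def test_pooling_counts_unique_scans(self):
        cand = _cand()
        hit = pool_and_boost(
            [_psm(cand, "ms2", 50.0), _psm(cand, "ms3a", 40.0), _psm(cand, "ms3a", 45.0)],
            p=100.0,
        )
        assert hit.n == 2
        assert hit.boosted_score == pytest.approx(100.0)

    def test_empty_pool_is_an_error(self):
        with pytest.raises(ValueError):
            pool_and_boost([])

    def test_mixed_candidates_rejected(self):
        with pytest.raises(ValueError):
            pool_and_boost([_psm(_cand("AKCDE"), "a", 1.0),
                            _psm(_cand("AKCDF"), "a", 1.0)])


class TestCSM:
    def test_score_is_min_of_peptide_scores(self):
        csm = make_csm("scan1", _hit(score=80.0), _hit("GKLMN", 60.0))
        assert csm.score == 60.0

    def test_decoy_classes(self):
        assert make_csm("s", _hit(), _hit("GKLMN", decoy=True)).decoy_class == "TD"
        assert make_csm("s", _hit(decoy=True), _hit("GKLMN", decoy=True)).decoy_class == "DD"
        assert make_csm("s", _hit(), _hit("GKLMN")).decoy_class == "TT"


class TestGrouping:
    def test_max_score_and_count_by_pair(self):
        csms = [
            make_csm("s1", _hit("AKCDE", 60.0), _hit("GKLMN", 70.0)),
            make_csm("s2", _hit("AKCDE", 75.0), _hit("GKLMN", 90.0)),
        ]
        (xl,) = group_crosslinks(csms)
        assert xl.score == 75.0  # max over CSM scores (each CSM = min of pair)
        assert len(xl.csms) == 2

    def test_swapped_roles_group_together(self):
        csms = [
            make_csm("s1", _hit("AKCDE", 60.0), _hit("GKLMN", 70.0)),
            make_csm("s2", _hit("GKLMN", 50.0), _hit("AKCDE", 80.0)),
        ]
        assert len(group_crosslinks(csms)) == 1

    def test_five_csms_three_pairs(self):
        pairs = [("AKCDE", "GKLMN"), ("AKCDE", "WKYYS"), ("NKQQT", "GKLMN")]
        csms = []
        for i, (a, b) in enumerate(pairs + pairs[:2]):
            csms.append(make_csm(f"s{i}", _hit(a, 10.0 + i), _hit(b, 20.0)))
        assert len(group_crosslinks(csms)) == 3

    def test_score_propagation_invariant(self):
        rng = random.Random(1)
        csms = [
            make_csm(f"s{i}",
                     _hit("AKCDE", rng.uniform(1, 100)),
                     _hit(rng.choice(["GKLMN", "WKYYS"]), rng.uniform(1, 100)))
            for i in range(30)
        ]
        for xl in group_crosslinks(csms):
            assert xl.score == max(c.score for c in xl.csms)
            for c in xl.csms:
                assert c.score == min(c.alpha.boosted_score, c.beta.boosted_score)


@dataclass
class Item:
    score: float
    decoy_class: str


def brute_force_fdr(items, target):
    """Independent oracle: scan every distinct score as threshold."""
    best = None
    for thr in sorted({it.score for it in items}):
        kept = [it for it in items if it.score >= thr]
        tt = sum(it.decoy_class == "TT" for it in kept)
        td = sum(it.decoy_class == "TD" for it in kept)
        dd = sum(it.decoy_class == "DD" for it in kept)
        fdr = 0.0 if tt == 0 else max(0, td - dd) / tt
        if fdr <= target and (best is None or thr < best[0]):
            best = (thr, [it for it in kept if it.decoy_class == "TT"])
    return best


class TestFDR:
    def test_hundred_targets_one_td(self):
        items = [Item(50.0 + i, "TT") for i in range(100)] + [Item(120.0, "TD")]
        res = estimate_fdr(items, 0.01)
        assert len(res.accepted) == 100
        assert res.estimated_fdr == pytest.approx(0.01)

    def test_no_decoys_accepts_everything(self):
        items = [Item(10.0 * i + 1, "TT") for i in range(5)]
        res = estimate_fdr(items, 0.01)
        assert len(res.accepted) == 5 and res.estimated_fdr == 0.0

    def test_td_above_targets_blocks_lower_targets(self):
        items = [Item(90, "TT"), Item(85, "TD"), Item(80, "TT"), Item(70, "TT")]
        res = estimate_fdr(items, 0.01)
        assert [it.score for it in res.accepted] == [90]

    def test_matches_bruteforce_over_many_random_instances(self):
        for seed in range(300):
            rng = random.Random(seed)
            items = [
                Item(rng.randint(1, 40),
                     rng.choices(["TT", "TD", "DD"], weights=[6, 2, 1])[0])
                for _ in range(rng.randint(1, 20))
            ]
            target = rng.choice([0.01, 0.05, 0.2, 0.5])
            res = estimate_fdr(items, target)
            oracle = brute_force_fdr(items, target)
            got = sorted((it.score for it in res.accepted))
            expected = sorted((it.score for it in oracle[1])) if oracle else []
            assert got == expected, (seed, target)


class TestTwoStep:
    def _csms(self, rng, n_true=40, n_decoy=8):
        csms = []
        for i in range(n_true):
            csms.append(make_csm(f"t{i}", _hit("AKCDE", rng.uniform(60, 100)),
                                 _hit(f"GK{'LMN'[i % 3]}MN", rng.uniform(60, 100))))
        for i in range(n_decoy):
            csms.append(make_csm(f"d{i}", _hit("AKCDE", rng.uniform(1, 50), decoy=True),
                                 _hit("GKLMN", rng.uniform(1, 50))))
        return csms

    def test_both_estimates_below_target(self):
        rng = random.Random(11)
        csm_res, xl_res, links = two_step_validate(self._csms(rng))
        assert csm_res.estimated_fdr <= 0.01
        assert xl_res.estimated_fdr <= 0.01
        assert links and all(l.decoy_class == "TT" for l in links)

    def test_empty_input(self):
        csm_res, xl_res, links = two_step_validate([])
        assert links == [] and csm_res.accepted == []

    def test_all_decoys_accept_nothing(self):
        rng = random.Random(2)
        csms = [
            make_csm(f"d{i}", _hit(decoy=True, score=rng.uniform(1, 99)),
                     _hit("GKLMN", rng.uniform(1, 99), decoy=True))
            for i in range(10)
        ]
        _, _, links = two_step_validate(csms)
        assert links == []


def _xl(a, b, score, entrapment=False):
    csm = make_csm("s", _hit(a[0], score, site=a[1], entrapment=entrapment),
                   _hit(b[0], score + 1, site=b[1]))
    (link,) = group_crosslinks([csm])
    link.score = score
    return link


class TestGroupFDR:
    GROUPS = {"AKCDE": "g1", "GKLMN": "g1", "WKYYS": "g2", "NKQQT": "g2"}

    def test_inter_group_fraction(self):
        links = [_xl(("AKCDE", 2), ("GKLMN", 2), 10)] * 96 + [
            _xl(("AKCDE", 2), ("WKYYS", 2), 9)
        ] * 4
        assert validated_group_fdr(links, self.GROUPS) == pytest.approx(0.04)

    def test_all_intra_group_is_zero(self):
        links = [_xl(("AKCDE", 2), ("GKLMN", 2), 10),
                 _xl(("WKYYS", 2), ("NKQQT", 2), 12)]
        assert validated_group_fdr(links, self.GROUPS) == 0.0

    def test_non_library_peptide_counts_as_false(self):
        links = [_xl(("AKCDE", 2), ("GKLMN", 2), 10)] * 49 + [
            _xl(("AKCDE", 2), ("QKFFH", 2), 9)
        ]
        assert validated_group_fdr(links, self.GROUPS) == pytest.approx(1 / 50)

    def test_empty_returns_zero_with_warning(self):
        assert validated_group_fdr([], self.GROUPS) == 0.0


class TestEntrapment:
    def test_removal_stops_once_entrapment_gone(self):
        links = [_xl(("AKCDE", 2), (f"GK{c}MN", 2), 100 - i)
                 for i, c in enumerate("ACDEFGHILMNQSTVWY" * 3)][:49]
        trap = _xl(("WKYYS", 2), ("NKQQT", 2), 30.0, entrapment=True)
        filtered = entrapment_filter(links + [trap], max_fraction=0.01)
        assert all(not x.contains_entrapment for x in filtered)
        # everything above the entrapment hit survives
        assert all(x.score > 30.0 for x in filtered)
        assert len(filtered) == sum(1 for x in links if x.score > 30.0)

    def test_no_entrapment_unchanged(self):
        links = [_xl(("AKCDE", 2), ("GKLMN", 2), s) for s in (10, 20, 30)]
        assert len(entrapment_filter(links)) == 3

    def test_all_entrapment_empties_list(self):
        links = [_xl(("AKCDE", 2), ("GKLMN", 2), s, entrapment=True)
                 for s in (10, 20, 30)]
        assert entrapment_filter(links) == []
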