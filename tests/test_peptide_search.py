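"""Digestion, candidate generation, theoretical fragments, and scoring."""

import random

import pytest

from xlms3.constants import PROTON, RESIDUE_MASS, WATER
from xlms3.peptide_search import (
    PeptideCandidate,
    PeptideIndex,
    TRYPSIN,
    binomial_score,
    crosslink_sites,
    digest,
    generate_candidates,
    linear_prefilter,
    peptide_mass,
    score_psm,
    theoretical_fragments,
)
from xlms3.spectra_io import Peak, PrecursorRef, ProteinEntry, Spectrum


def _cand(seq, site, arm="light", decoy=False, mods=()):
    return PeptideCandidate(
        sequence=seq, protein_accessions=frozenset({"P"}), is_decoy=decoy,
        is_entrapment=False, missed_cleavages=0, crosslink_site=site, arm=arm,
        fixed_mods=tuple(mods), neutral_mass=peptide_mass(seq, dict(mods)),
    )


def _no_filter(**kw):
    kw.setdefault("length_range", (1, 100))
    kw.setdefault("mass_range", (0.0, 1e6))
    return kw


class TestDigest:
    def test_proline_blocks_cleavage(self):
        peps = {d.sequence for d in digest("AKRPLKWE", missed_cleavages_max=0,
                                           **_no_filter())}
        assert peps == {"AK", "RPLK", "WE"}

    def test_one_missed_cleavage_adds_joined_fragments(self):
        peps = {d.sequence for d in digest("AKRPLKWE", missed_cleavages_max=1,
                                           **_no_filter())}
        assert peps == {"AK", "RPLK", "WE", "AKRPLK", "RPLKWE"}

    def test_too_short_protein_gives_nothing(self):
        assert digest("AK", length_range=(5, 30)) == []

    def test_matches_character_walk_reference_on_random_sequences(self):
        """Oracle: independent character-walk digestion, 100 random proteins."""
        rng = random.Random(42)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(100):
            seq = "".join(rng.choice(aas) for _ in range(rng.randint(10, 60)))
            mc_max = rng.randint(0, 2)
            got = {(d.sequence, d.start, d.missed_cleavages)
                   for d in digest(seq, missed_cleavages_max=mc_max, **_no_filter())}
            # reference: walk characters, collect cut points, join adjacent runs
            frags, start = [], 0
            for i, aa in enumerate(seq):
                last = i == len(seq) - 1
                if last or (aa in "KR" and seq[i + 1] != "P"):
                    frags.append((start, i + 1))
                    start = i + 1
            expected = set()
            for a in range(len(frags)):
                for mc in range(mc_max + 1):
                    if a + mc < len(frags):
                        s, e = frags[a][0], frags[a + mc][1]
                        expected.add((seq[s:e], s + 1, mc))
            assert got == expected


class TestCandidates:
    def test_cterminal_k_only_admissible_at_protein_cterm(self):
        assert crosslink_sites("PEPTIDEK", _spec_dsso(), protein_cterm=False) == []
        assert crosslink_sites("PEPTIDEK", _spec_dsso(), protein_cterm=True) == [8]

    def test_internal_k_admissible(self):
        assert crosslink_sites("AKCDEFGR", _spec_dsso()) == [2]

    def test_nterm_reactivity(self):
        assert crosslink_sites("AGDEFGR", _spec_dsso(), protein_nterm=True) == [1]
        assert crosslink_sites("AGDEFGR", _spec_dsso(), protein_nterm=False) == []

    def test_generation_matches_bruteforce_mass_filter(self):
        """Oracle: exhaustive mass comparison over a toy database."""
        rng = random.Random(3)
        proteins = [
            ProteinEntry(f"P{i}", "".join(rng.choice("ADEFGHIKLMNQSTVWYR")
                                          for _ in range(30)))
            for i in range(8)
        ]
        index = PeptideIndex(proteins, missed_cleavages_max=2,
                             length_range=(5, 30), mass_range=(400, 6000))
        spec = _spec_dsso()
        for e in rng.sample(index.all_entries(), 10):
            target = e["mass"]
            got = {(c.sequence, c.crosslink_site)
                   for c in generate_candidates(index, target, 5.0, spec, "light")}
            tol = target * 5e-6
            expected = set()
            for f in index.all_entries():
                if abs(f["mass"] - target) <= tol:
                    for site in crosslink_sites(f["sequence"], spec,
                                                f["protein_nterm"], f["protein_cterm"]):
                        expected.add((f["sequence"], site))
            assert got == expected


def _spec_dsso():
    from xlms3.crosslinker import load_spec

    return load_spec("DSSO")


class TestFragments:
    def test_y1_of_ak_carries_the_arm(self, dsso):
        frags = dict(theoretical_fragments(_cand("AK", 2), dsso, max_frag_charge=1))
        y1 = RESIDUE_MASS["K"] + dsso.short_arm.mono_mass + WATER + PROTON
        assert frags["y1+1"] == pytest.approx(y1, abs=1e-4)
        assert frags["y1+1"] == pytest.approx(201.12337, abs=1e-3)

    def test_b_ions_before_site_unshifted(self, dsso):
        frags = dict(theoretical_fragments(_cand("AK", 2), dsso, max_frag_charge=1))
        assert frags["b1+1"] == pytest.approx(RESIDUE_MASS["A"] + PROTON, abs=1e-4)
        assert frags["b1+1"] == pytest.approx(72.04439, abs=1e-3)

    def test_length_one_peptide_has_no_fragments(self, dsso):
        assert theoretical_fragments(_cand("K", 1), dsso) == []

    def test_all_ions_shift_consistently(self, dsso):
        plain = dict(theoretical_fragments(_cand("AKCDE", 2), None))
        armed = dict(theoretical_fragments(_cand("AKCDE", 2), dsso))
        arm = dsso.short_arm.mono_mass
        for label, mz in plain.items():
            kind, rest = label[0], label[1:]
            idx, z = (int(x) for x in rest.split("+"))
            contains_site = (kind == "b" and idx >= 2) or (kind == "y" and idx >= 4)
            shift = arm / z if contains_site else 0.0
            assert armed[label] == pytest.approx(mz + shift, abs=1e-9)


class TestScore:
    def _spectrum_from(self, mzs, scan="s", level=3):
        prec = PrecursorRef("p", 500.0, None)
        return Spectrum(scan, level, 1.0, [Peak(m, 100.0) for m in mzs], prec)

    def test_zero_matches_scores_zero(self, dsso):
        s = self._spectrum_from([1500.0, 1600.0, 1700.0])
        psm = score_psm(s, _cand("AKCDEFG", 2), dsso)
        assert psm.raw_score == 0.0 and psm.matched_ions == 0

    def test_perfect_spectrum_is_maximal_and_monotone_in_length(self, dsso):
        scores = []
        for seq in ("AKCD", "AKCDEF", "AKCDEFGH"):
            frags = [mz for _, mz in theoretical_fragments(_cand(seq, 2), dsso)]
            s = self._spectrum_from(sorted(set(round(f, 6) for f in frags)))
            psm = score_psm(s, _cand(seq, 2), dsso)
            assert psm.matched_ions == psm.total_ions
            scores.append(psm.raw_score)
        assert scores == sorted(scores)  # more explained ions, higher score

    def test_adding_matched_peak_never_decreases_score(self, dsso):
        cand = _cand("AKCDEFG", 2)
        frags = [mz for _, mz in theoretical_fragments(cand, dsso)]
        partial = self._spectrum_from(frags[:4])
        fuller = self._spectrum_from(frags[:5])
        assert score_psm(fuller, cand, dsso).raw_score >= score_psm(
            partial, cand, dsso
        ).raw_score

    def test_wider_tolerance_never_increases_score(self):
        # binomial tail is monotone in the random-match probability
        for k, n in ((3, 10), (7, 20), (1, 5)):
            tight = binomial_score(k, n, n_peaks=50, span=1000.0, tol_width=0.01)
            loose = binomial_score(k, n, n_peaks=50, span=1000.0, tol_width=0.02)
            assert loose <= tight


class TestLinearPrefilter:
    def test_linear_peptide_spectrum_flagged_crosslink_not(self, dsso):
        rng = random.Random(5)
        proteins = [
            ProteinEntry(f"P{i}", "".join(rng.choice("ADEFGHILMNQSTVWY")
                                          for _ in range(12)) + "K")
            for i in range(6)
        ]
        index = PeptideIndex(proteins, missed_cleavages_max=1)
        target = index.all_entries()[3]
        frags = [
            mz for _, mz in theoretical_fragments(
                _cand(target["sequence"], 1,
                      mods=tuple(sorted(index.fixed_mods.items()))), None)
        ]
        mz2 = target["mass"] / 2 + PROTON
        linear = Spectrum("lin", 2, 5.0, [Peak(m, 100.0) for m in sorted(set(frags))],
                          PrecursorRef("ms1", mz2, 2))
        # a cross-link-like MS2: precursor mass matches no linear peptide
        other = Spectrum("xl", 2, 6.0, [Peak(m + 3.3, 100.0) for m in sorted(set(frags))],
                         PrecursorRef("ms1", mz2 + 500.0, 2))
        flagged = linear_prefilter([linear, other], index, threshold=0.01)
        assert flagged == {"lin"}

    def test_empty_collection(self, dsso):
        index = PeptideIndex([ProteinEntry("P1", "AAAAKAAAR")])
        assert linear_prefilter([], index) == set()
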