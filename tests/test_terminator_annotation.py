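import numpy as np
import pytest

from termtk import _fold
from termtk._fold import STACK, fold_hairpin, stem_energy
from termtk.io_formats import GenomeSeq, ThreePrimeEnd, revcomp
from termtk.terminator_annotation import (
    confirm_terminator,
    count_terminal_weak_pairs,
    detect_atract,
    extend_stem_into_tract,
    find_utract_start,
    predict_hairpin,
    utract_seq9,
    validate_utract,
)

from conftest import make_genome


def _end(x, strand="+"):
    return ThreePrimeEnd(x=x, strand=strand, cv=50.0, end_count=50.0)


def _terminator_genome(
    arm5="GGGCGCC", loop="GAAA", tract="TTTTTTTTT", atract="AAAA", d=9
):
    """Plant one plus-strand terminator; returns (genome, x, stem_end)."""
    pad5 = "CATCATCATCATCATCATCATCATCATCATCATCAT"
    pad3 = "CAGCAGCAGCAGCAGCAGCAG"
    cassette = atract + arm5 + loop + revcomp(arm5) + tract
    seq = pad5 + cassette + pad3
    stem_end = len(pad5) + len(atract) + 2 * len(arm5) + len(loop)  # 1-based
    x = stem_end + d
    return make_genome(seq), x, stem_end


class TestFindUtractStart:
    def test_first_u_of_long_run(self):
        g, x, stem_end = _terminator_genome()
        s = find_utract_start(g, _end(x))
        assert s == x - 8  # 9-U tract, POT at its 9th nt

    def test_no_u_in_window_returns_none(self):
        g = make_genome("C" * 40)
        assert find_utract_start(g, _end(30)) is None

    def test_liah_style_two_u_tract(self):
        # tract UUCCGCACG: the first U is 8 nt upstream of the POT
        g, x, _ = _terminator_genome(tract="TTCCGCACG", d=9)
        s = find_utract_start(g, _end(x))
        assert s == x - 8

    def test_minus_strand_mirrored(self):
        g, x, _ = _terminator_genome()
        flipped = make_genome(revcomp(g.sequence))
        x_minus = g.length + 1 - x
        s = find_utract_start(flipped, _end(x_minus, strand="-"))
        assert s == x_minus + 8


class TestPredictHairpin:
    def test_perfect_gc_stem_found(self):
        g, x, stem_end = _terminator_genome(arm5="GGGCGCC", loop="GAAA")
        s = find_utract_start(g, _end(x))
        hp = predict_hairpin(g, _end(x), s)
        assert hp is not None
        assert hp.stem_bp == 7
        assert hp.loop_len == 4
        assert hp.dg < 0
        assert hp.stem_end3 == stem_end

    def test_agrees_with_external_mfe_folder(self):
        RNA = pytest.importorskip("RNA")
        g, x, _ = _terminator_genome(arm5="GGGCGCC", loop="GAAA")
        s = find_utract_start(g, _end(x))
        window = g.slice(s - 50, s - 1).replace("T", "U")
        structure, _ = RNA.fold(window)
        hp = predict_hairpin(g, _end(x), s)
        # the MFE folder pairs the same outermost stem positions
        i5 = structure.index("(")
        j3 = structure.rindex(")")
        assert hp.stem_start5 == s - 50 + i5
        assert hp.stem_end3 == s - 50 + j3

    def test_poly_a_window_has_no_hairpin(self):
        g = make_genome("A" * 60 + "TTTTTTTTT" + "A" * 20)
        x = 69
        s = find_utract_start(g, _end(x))
        assert predict_hairpin(g, _end(x), s) is None

    def test_weak_bottom_pairs_counted(self):
        # bottom two pairs are U-A, with the U residues on the 5' arm so
        # the first-U tract rule still anchors on the downstream tract
        g, x, _ = _terminator_genome(arm5="TTGCGCC", loop="GAAA")
        s = find_utract_start(g, _end(x))
        hp = predict_hairpin(g, _end(x), s)
        assert hp is not None
        assert count_terminal_weak_pairs(hp) == 2

    def test_minus_strand_same_anatomy(self):
        g, x, _ = _terminator_genome()
        s = find_utract_start(g, _end(x))
        hp_plus = predict_hairpin(g, _end(x), s)
        flipped = make_genome(revcomp(g.sequence))
        xm = g.length + 1 - x
        sm = find_utract_start(flipped, _end(xm, strand="-"))
        hp_minus = predict_hairpin(flipped, _end(xm, strand="-"), sm)
        assert hp_minus is not None
        assert (hp_minus.stem_bp, hp_minus.loop_len, hp_minus.dg) == (
            hp_plus.stem_bp,
            hp_plus.loop_len,
            hp_plus.dg,
        )

    def test_pairs_are_nested_non_crossing(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            window = "".join(rng.choice(list("ACGT"), 50))
            sl = fold_hairpin(window)
            if sl is None:
                continue
            for t in range(sl.n_pairs):
                i, j = sl.i5 + t, sl.j3 - t
                assert i < j
                if t:
                    assert i == sl.i5 + t and j == sl.j3 - t  # contiguous ladder

    def test_gc_substitution_never_raises_energy(self):
        # replacing any A-U pair with G-C (same geometry) can only stabilise
        rng = np.random.default_rng(5)
        pair_pool = ["AU", "UA", "GU", "UG", "GC", "CG"]
        for _ in range(200):
            k = int(rng.integers(4, 9))
            pairs = [pair_pool[i] for i in rng.integers(0, 6, k)]
            loop = int(rng.integers(3, 9))
            base = stem_energy(pairs, loop)
            for t, p in enumerate(pairs):
                if p in ("AU", "UA"):
                    swapped = list(pairs)
                    swapped[t] = "GC" if p == "AU" else "CG"
                    assert stem_energy(swapped, loop) <= base + 1e-12

    def test_stack_table_is_helix_symmetric(self):
        for p in _fold.PAIR_TYPES:
            for q in _fold.PAIR_TYPES:
                assert STACK[(p, q)] == STACK[(q[::-1], p[::-1])]


class TestValidateUtract:
    @pytest.mark.parametrize(
        "seq9, valid, n_us",
        [
            ("UUCCGCACG", True, 2),   # the weakest viable tract: a UU lead
            ("UUUUUUUUU", True, 9),
            ("CUCUCUCUC", False, 0),
            ("UCUUUUUUU", False, 1),  # single leading U is not a tract
        ],
    )
    def test_leading_run_rule(self, seq9, valid, n_us):
        ut = validate_utract(seq9)
        assert (ut.valid, ut.n_us) == (valid, n_us)

    def test_dna_input_accepted(self):
        assert validate_utract("TTCCGCACG").n_us == 2


class TestDetectAtract:
    def test_present_run_of_four(self):
        g, x, _ = _terminator_genome(atract="CCAAAAGC"[2:])  # AAAAGC upstream
        s = find_utract_start(g, _end(x))
        hp = predict_hairpin(g, _end(x), s)
        at = detect_atract(g, hp)
        assert at.present and at.run_len >= 4

    def test_absent_when_max_run_two(self):
        g, x, _ = _terminator_genome(atract="CCGGCCAAGC")
        s = find_utract_start(g, _end(x))
        hp = predict_hairpin(g, _end(x), s)
        assert not detect_atract(g, hp).present


class TestConfirmTerminator:
    def _annotated(self, pt):
        g, x, _ = _terminator_genome()
        end = _end(x)
        s = find_utract_start(g, end)
        hp = predict_hairpin(g, end, s)
        seq9, start = utract_seq9(g, hp)
        ut = validate_utract(seq9, start=start)
        return end, hp, ut, confirm_terminator(end, hp, ut, pt)

    def test_wt_efficiency_boundary(self):
        *_, call = self._annotated(5.0)
        assert call is not None
        *_, call = self._annotated(4.9)
        assert call is None

    def test_missing_hairpin_rejected(self):
        end = _end(100)
        assert confirm_terminator(end, None, validate_utract("UUUUUUUUU"), 90.0) is None

    def test_distance_flagging(self):
        g, x, stem_end = _terminator_genome(d=9)
        end = _end(x)
        s = find_utract_start(g, end)
        hp = predict_hairpin(g, end, s)
        seq9, start = utract_seq9(g, hp)
        call = confirm_terminator(end, hp, validate_utract(seq9, start=start), 80.0)
        assert call.distance == 9 and not call.atypical
        far = _end(x + 3)
        call = confirm_terminator(far, hp, validate_utract(seq9), 80.0)
        assert call.distance == 12 and call.atypical


class TestStemExtension:
    def test_extends_with_au_pairs_into_tract(self):
        # A-tract upstream + U-tract downstream let the stem gain A-U pairs
        g, x, stem_end = _terminator_genome(arm5="GGGCGCC", atract="AAAA", d=9)
        end = _end(x)
        s = find_utract_start(g, end)
        hp = predict_hairpin(g, end, s)
        revised = extend_stem_into_tract(g, hp, x + 2)
        assert revised.stem_bp > hp.stem_bp
        assert revised.terminal_weak_run >= 2
        assert revised.dg <= hp.dg  # A-U stacks stabilise

    def test_no_extension_when_bases_cannot_pair(self):
        g, x, _ = _terminator_genome(atract="CCCC", tract="TTGGGGGGG")
        end = _end(x)
        s = find_utract_start(g, end)
        hp = predict_hairpin(g, end, s)
        revised = extend_stem_into_tract(g, hp, x)
        assert revised.stem_bp == hp.stem_bp

    def test_distance_floor_respected(self):
        g, x, _ = _terminator_genome(atract="AAAA", d=9)
        end = _end(x)
        s = find_utract_start(g, end)
        hp = predict_hairpin(g, end, s)
        revised = extend_stem_into_tract(g, hp, x, min_distance=7)
        d = x - revised.stem_end3
        assert d >= 7


class TestSyntheticCohortAnatomy:
    def test_planted_stem_and_loop_recovered(self, clean_world):
        genome, truth = clean_world["genome"], clean_world["truth"]
        for rec in truth:
            if rec.has_pause_motif:
                continue  # primary prediction stops before the first U at -12/-11
            end = ThreePrimeEnd(
                x=rec.x_true, strand=rec.strand, cv=50.0, end_count=50.0
            )
            s = find_utract_start(genome, end)
            hp = predict_hairpin(genome, end, s)
            assert hp is not None, rec.terminator_id
            assert hp.stem_bp == rec.stem_bp, rec.terminator_id
            assert hp.loop_len == rec.loop_len, rec.terminator_id
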