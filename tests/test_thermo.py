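"""Nearest-neighbor Tm and duplex free-energy screening."""

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt

from orthoprimer import iupac, thermo

WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


def naive_duplex_dG(a, b, model):
    """Independent oracle: explicit loop over all antiparallel offsets and
    all maximal contiguous paired helices at each offset."""

    def cap(base):
        return model.dg37("init_AT" if base in "AT" else "init_GC")

    rb = b[::-1]
    na, nb = len(a), len(rb)
    best = 0.0
    for s in range(-(na - 1), nb):
        lo, hi = max(0, -s), min(na, nb - s)
        run = []  # indices (into a) of the current contiguous paired stretch
        for i in list(range(lo, hi)) + [None]:
            if i is not None and rb[i + s] == WC[a[i]]:
                run.append(i)
                continue
            if len(run) >= 2:
                score = sum(
                    model.dg37(a[j] + a[j + 1]) for j in run[:-1]
                ) + cap(a[run[0]]) + cap(a[run[-1]])
                best = min(best, score)
            run = []
    return best


def random_oligo(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_model_rejects_nonpositive_concentrations():
    with pytest.raises(ValueError):
        thermo.ThermoModel(na_mM=0)


def test_tm_monotone_in_gc(model):
    assert thermo.tm_concrete("GCGCGCGCGCGCGCGC", model) > thermo.tm_concrete(
        "ATATATATATATATAT", model
    )


def test_tm_single_at_to_gc_substitution_raises_tm(model):
    rng = np.random.default_rng(5)
    for _ in range(25):
        seq = random_oligo(rng, 20)
        at_positions = [i for i, b in enumerate(seq) if b in "AT"]
        if not at_positions:
            continue
        i = int(rng.choice(at_positions))
        bumped = seq[:i] + rng.choice(["G", "C"]) + seq[i + 1 :]
        assert thermo.tm_concrete(bumped, model) > thermo.tm_concrete(seq, model)


def test_tm_concrete_matches_independent_nn_implementation(model):
    """Cross-check against Biopython's unified-parameter Tm_NN to ±0.5 °C."""
    rng = np.random.default_rng(7)
    for _ in range(40):
        seq = random_oligo(rng, int(rng.integers(15, 26)))
        ours = thermo.tm_concrete(seq, model)
        # same conditions: 50 mM Na+, 0.8 µM total oligo, entropic salt corr.
        theirs = mt.Tm_NN(
            seq, nn_table=mt.DNA_NN3, Na=50, dnac1=400, dnac2=400, saltcorr=5
        )
        assert ours == pytest.approx(theirs, abs=0.5)


def test_tm_concrete_rejects_degenerate_and_short(model):
    with pytest.raises(ValueError):
        thermo.tm_concrete("ACGTACGTACGTACGTACGY", model)
    with pytest.raises(ValueError):
        thermo.tm_concrete("ACGTA", model)


def test_tm_range_concrete_is_degenerate_point(model):
    lo, hi = thermo.tm_range("GCTATCTTCGACTTCGACAG", model)
    assert lo == hi == pytest.approx(
        thermo.tm_concrete("GCTATCTTCGACTTCGACAG", model)
    )


def test_tm_range_equals_enumeration_for_two_expansions(model):
    seq = "GCYATCTTCGACTTCGACAG"
    lo, hi = thermo.tm_range(seq, model)
    tms = [thermo.tm_concrete(s, model) for s in iupac.expand(seq)]
    assert (lo, hi) == (pytest.approx(min(tms)), pytest.approx(max(tms)))


def test_tm_range_widens_with_added_degeneracy(model, panel_primers):
    for rec in panel_primers.itertuples(index=False):
        for seq in (rec.fwd, rec.rev):
            lo, hi = thermo.tm_range(seq, model)
            assert hi >= lo
            # degenerating one concrete position can only widen the range
            i = next(j for j, s in enumerate(seq) if s in "ACGT")
            code = iupac.consensus_code(iupac.IUPAC_SETS[seq[i]] | {"A", "T"})
            lo2, hi2 = thermo.tm_range(seq[:i] + code + seq[i + 1 :], model)
            assert lo2 <= lo + 1e-9 and hi2 >= hi - 1e-9


def test_tm_range_heuristic_contained_in_enumeration(model):
    """Above the enumeration cap the extreme-expansion bound never leaves
    the true enumerated range (its members are actual expansions), and the
    low end — which drives the Tm window filter — sits close to the truth."""
    rng = np.random.default_rng(13)
    for _ in range(10):
        seq = list(random_oligo(rng, 20))
        for i in rng.choice(20, size=9, replace=False):
            seq[int(i)] = str(rng.choice(list("RYSWKM")))
        s = "".join(seq)  # degeneracy 512 <= 1024
        true_lo, true_hi = thermo.tm_range(s, model, cap=1024)
        heur_lo, heur_hi = thermo.tm_range(s, model, cap=1)
        assert true_lo - 1e-9 <= heur_lo <= heur_hi <= true_hi + 1e-9
        assert heur_lo <= true_lo + 1.5


def test_duplex_poly_a_has_no_favorable_duplex(model):
    assert thermo.duplex_dG("A" * 20, "A" * 20, model) == 0.0


def test_duplex_self_complement_strongly_negative(model):
    seq = "ACGTACGTACGT"  # its own reverse complement
    assert thermo.duplex_dG(seq, seq, model) < -10.0


def test_duplex_matches_bruteforce_offset_scan(model):
    rng = np.random.default_rng(2)
    for _ in range(60):
        a = random_oligo(rng, int(rng.integers(8, 25)))
        b = random_oligo(rng, int(rng.integers(8, 25)))
        assert thermo.duplex_dG(a, b, model) == pytest.approx(
            naive_duplex_dG(a, b, model)
        )


def test_duplex_symmetric(model):
    rng = np.random.default_rng(3)
    for _ in range(30):
        a = random_oligo(rng, 18)
        b = random_oligo(rng, 22)
        assert thermo.duplex_dG(a, b, model) == pytest.approx(
            thermo.duplex_dG(b, a, model)
        )


def test_dimer_screen_clean_pair_passes(model):
    rep = thermo.dimer_screen("AGAGAGAGAGAGAGAGAGAG", "AGGAGGAGGAGGAGGAGGAG", model)
    assert rep.passed


def test_dimer_screen_self_complementary_fails(model):
    fwd = "ACACACACAC" + "GTGTGTGTGT"  # fwd == revcomp(fwd)
    rep = thermo.dimer_screen(fwd, "AGAGAGAGAGAGAGAGAGAG", model)
    assert not rep.passed
    assert rep.worst_kind == "homodimer_fwd"


def test_dimer_screen_monotone_in_threshold(model, panel_primers):
    for rec in panel_primers.itertuples(index=False):
        if thermo.dimer_screen(rec.fwd, rec.rev, model, threshold=-11.0).passed:
            assert thermo.dimer_screen(rec.fwd, rec.rev, model, threshold=-13.0).passed


def test_dimer_screen_equals_exhaustive_for_small_pools(model):
    rng = np.random.default_rng(4)
    for _ in range(10):
        fwd = list(random_oligo(rng, 20))
        rev = list(random_oligo(rng, 20))
        for s, n in ((fwd, 3), (rev, 2)):  # total degeneracy 2^5 = 32 <= 64
            for i in rng.choice(20, size=n, replace=False):
                s[int(i)] = str(rng.choice(list("RYSWKM")))
        fwd, rev = "".join(fwd), "".join(rev)
        screened = thermo.dimer_screen(fwd, rev, model, cap=64)
        combos = [
            (x, y)
            for pool in (
                [(x, y) for x in iupac.expand(fwd) for y in iupac.expand(fwd)],
                [(x, y) for x in iupac.expand(rev) for y in iupac.expand(rev)],
                [(x, y) for x in iupac.expand(fwd) for y in iupac.expand(rev)],
            )
            for x, y in pool
        ]
        worst = min(naive_duplex_dG(x, y, model) for x, y in combos)
        assert screened.passed == (worst >= -11.0)
        assert screened.worst_dG == pytest.approx(worst)
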