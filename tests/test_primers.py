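"""Primer properties, consensus, site matching, and specificity scoring."""

import math

import numpy as np
import pytest

from cladeprimer.primers import (
    Primer,
    consensus_majority,
    coverage_tolerance,
    degenerate_count,
    enumerate_candidates,
    gc_percent,
    map_to_reference,
    match_sites,
    pair_coverage,
    round_half_up,
    self_structure_dg,
    specificity_table,
    tm_nearest_neighbor,
)
from cladeprimer.seq_io import IUPAC_SETS, SequenceRecord, iupac_match, revcomp
from cladeprimer.synthetic import GeneratorConfig, PlantedWindow, simulate_pool

from conftest import make_alignment


THAUM_494 = "GAATAAGGGGTGGGCAAGT"


class TestGcAndDegeneracy:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            (THAUM_494, 52.6),  # phylum-directed 19-mer
            ("CGCGGTAATACCAGCYC", 62.5),  # degenerate position excluded
            ("GYGCASCAGKCGMGAAW", 66.7),
            ("AAAAAAAAAA", 0.0),
            ("GGCCGGCCGG", 100.0),
        ],
    )
    def test_percent_gc_over_concrete_positions(self, seq, expected):
        assert round_half_up(gc_percent(seq)) == expected

    def test_all_degenerate_is_undefined(self):
        with pytest.raises(ValueError):
            gc_percent("NNNNNNNNNN")

    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GYGCASCAGKCGMGAAW", 5),
            ("GGCCCTAYGGGGYGCASCAGGC", 3),
            (THAUM_494, 0),
            ("ACGTACGTAC", 0),
        ],
    )
    def test_degenerate_site_count(self, seq, expected):
        assert degenerate_count(seq) == expected

    def test_primer_validation(self):
        with pytest.raises(ValueError):
            Primer(name="short", residues="ACGTACGT")
        with pytest.raises(Exception):
            Primer(name="gap", residues="ACGT-ACGTACGT")


# frozen copy of the published unified NN table used as an independent oracle
_ORACLE_NN = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}


def _oracle_tm(seq, na_mM=50.0, primer_nM=250.0):
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    dh = ds = 0.0
    for i in range(len(seq) - 1):
        d = seq[i : i + 2]
        if d not in _ORACLE_NN:
            d = comp[d[1]] + comp[d[0]]
        h, s = _ORACLE_NN[d]
        dh += h
        ds += s
    for t in (seq[0], seq[-1]):
        h, s = (0.1, -2.8) if t in "GC" else (2.3, 4.1)
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    return 1000 * dh / (ds + 1.987 * math.log(primer_nM * 1e-9 / 4)) - 273.15


class TestTm:
    def test_hand_summed_twelve_mer(self):
        seq = "ACGTTGCAGGCT"
        assert float(tm_nearest_neighbor(seq)) == pytest.approx(
            _oracle_tm(seq), abs=1e-9
        )

    def test_terminal_gc_swap_raises_tm(self):
        lo = float(tm_nearest_neighbor("ACGTTGCAGGCA"))
        hi = float(tm_nearest_neighbor("ACGTTGCAGGCG"))
        assert hi > lo

    def test_agrees_with_biopython_same_convention(self):
        mt = pytest.importorskip("Bio.SeqUtils.MeltingTemp")
        seq = "GAATAAGGGGTGGGCAAGT"
        ours = float(tm_nearest_neighbor(seq, na_mM=50, primer_nM=250))
        ref = mt.Tm_NN(
            seq, nn_table=mt.DNA_NN3, Na=50, dnac1=62.5, dnac2=0, saltcorr=5
        )
        assert ours == pytest.approx(ref, abs=0.05)

    def test_pure_function(self):
        a = tm_nearest_neighbor(THAUM_494)
        b = tm_nearest_neighbor(THAUM_494)
        assert a.celsius == b.celsius

    def test_degenerate_uses_most_stable_expansion(self):
        degen = float(tm_nearest_neighbor("ACGTTGCAGGCS"))
        expansions = [float(tm_nearest_neighbor("ACGTTGCAGGC" + b)) for b in "GC"]
        assert degen == pytest.approx(max(expansions))

    def test_too_short(self):
        with pytest.raises(ValueError):
            tm_nearest_neighbor("ACGTACG")


class TestSelfStructure:
    def test_homopolymer_has_no_structure(self):
        assert self_structure_dg("AAAAAAAAAAAA") == (0.0, 0.0)

    def test_inverted_repeat_forms_hairpin(self):
        hp, _ = self_structure_dg("GGGGAAATTCCCC" + "ATA")
        assert hp < 0.0

    def test_self_complementary_end_forms_dimer(self):
        _, dim = self_structure_dg("ATATATGGGCCC")
        assert dim < 0.0

    def test_bruteforce_hairpin_enumeration(self):
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}

        def stacks(seq, i, stem):
            dh_ds = 0.0
            for t in range(stem - 1):
                d = seq[i + t : i + t + 2]
                if d not in _ORACLE_NN:
                    d = comp[d[1]] + comp[d[0]]
                h, s = _ORACLE_NN[d]
                dh_ds += h - 310.15 * s / 1000
            return dh_ds

        def brute(seq):
            best = 0.0
            L = len(seq)
            for stem in range(3, L // 2 + 1):
                for i in range(L):
                    for j in range(i + stem + 3, L - stem + 1):
                        if all(
                            comp.get(seq[i + t]) == seq[j + stem - 1 - t]
                            for t in range(stem)
                        ):
                            best = min(best, stacks(seq, i, stem))
            return best

        rng = np.random.default_rng(17)
        for _ in range(15):
            s = "".join(rng.choice(list("ACGT"), size=16))
            assert self_structure_dg(s)[0] == pytest.approx(brute(s))


class TestConsensus:
    def test_column_rules(self):
        aln = make_alignment(
            {
                "a": "GACA-",
                "b": "GCCA-",
                "c": "GCAC-",
                "d": "GCAAA",
            }
        )
        cons = consensus_majority(aln)
        # col0 all G; col1 C majority; col2 C/A tie -> M; col3 A majority;
        # col4 gap fraction 75% -> '-'
        assert cons.residues == "GCMA-"

    def test_no_concrete_bases_gives_n(self):
        aln = make_alignment({"a": "NA", "b": "NA"})
        assert consensus_majority(aln).residues.startswith("N")


class TestMatchSites:
    def test_exact_substring_hit(self):
        hits = match_sites("ACGTACGTAC", "TTACGTACGTACTT")
        assert (3, "+") in hits

    def test_iupac_expansion_matches_both(self):
        for subj in ("AAACCTTTTTTT", "AAACTTTTTTTT"):
            assert match_sites("AACYTTTTTT", subj, max_mismatch=1)

    def test_bruteforce_oracle_both_strands(self):
        rng = np.random.default_rng(23)
        codes = sorted(IUPAC_SETS)

        def brute(primer, subject, max_mm):
            out = []
            for strand, pat in (("+", primer), ("-", revcomp(primer))):
                for i in range(len(subject) - len(pat) + 1):
                    mm = sum(
                        not iupac_match(p, s)
                        for p, s in zip(pat, subject[i : i + len(pat)])
                    )
                    if mm <= max_mm:
                        out.append((i + 1, strand))
            return sorted(out)

        for _ in range(15):
            primer = "".join(rng.choice(codes, size=10))
            subject = "".join(rng.choice(list("ACGT"), size=60))
            for mm in (0, 1, 2):
                assert match_sites(primer, subject, max_mismatch=mm) == brute(
                    primer, subject, mm
                )

    def test_mismatch_relaxation_is_monotone(self):
        rng = np.random.default_rng(29)
        primer = "".join(rng.choice(list("ACGT"), size=12))
        subject = "".join(rng.choice(list("ACGT"), size=300))
        sizes = [len(match_sites(primer, subject, max_mismatch=m)) for m in range(4)]
        assert sizes == sorted(sizes)


def _planted_db():
    cfg = GeneratorConfig(
        clade_sizes={"T1": 12, "T2": 10, "T3": 10},
        target_clade="T1",
        alignment_length=500,
        windows=(
            PlantedWindow(
                start=200,
                length=19,
                clades=("T1",),
                retention={"T1": 1.0},
                motif="GAATAAGGGGTGGGCAAGT",
            ),
        ),
        include_outgroup=False,
        rng_seed=31,
    )
    return simulate_pool(cfg)


class TestCoverageTolerance:
    def test_full_retention_gives_exact_percentages(self):
        pool, truth = _planted_db()
        primer = Primer(name="P1", residues="GAATAAGGGGTGGGCAAGT", target="T1")
        res = coverage_tolerance(primer, list(pool))
        assert res.coverage() == 100.0
        assert res.max_tolerance() == 0.0

    def test_partial_retention_matches_truth_counts(self):
        cfg = GeneratorConfig(
            clade_sizes={"T1": 20, "T2": 10},
            target_clade="T1",
            alignment_length=400,
            windows=(
                PlantedWindow(
                    start=100,
                    length=19,
                    clades=("T1",),
                    retention={"T1": 0.6},
                    motif="GAATAAGGGGTGGGCAAGT",
                ),
            ),
            include_outgroup=False,
            rng_seed=33,
        )
        pool, truth = simulate_pool(cfg)
        primer = Primer(name="P1", residues="GAATAAGGGGTGGGCAAGT", target="T1")
        res = coverage_tolerance(primer, list(pool))
        expected = sum(
            truth.window_retained[0][r.id] for r in pool if r.taxon_label == "T1"
        )
        t1_row = next(r for r in res.rows if r.group == "T1")
        assert t1_row.matched == expected

    def test_no_match_anywhere(self):
        pool, _ = _planted_db()
        primer = Primer(name="none", residues="A" * 19, target="T1")
        res = coverage_tolerance(primer, list(pool))
        assert all(r.matched == 0 for r in res.rows)


class TestPairCoverage:
    def _subject(self, fwd, rev_site, gap_len):
        rng = np.random.default_rng(41)
        spacer = "".join(rng.choice(list("ACGT"), size=gap_len))
        return SequenceRecord(
            id="s", residues=fwd + spacer + rev_site, taxon_label="T"
        )

    def test_amplicon_length_convention(self):
        fwd = Primer(name="F", residues="GAATAAGGGGTGGGCAAGT", target="T")
        rev = Primer(name="R", residues="ACTTGCCCACCCCTTATTC", target="T")
        # reverse-strand site = revcomp(rev) on the forward subject
        site = revcomp(rev.residues)
        # footprints 19 + 19 with 462 between: amplicon 500 > 400 -> matched
        rec = self._subject(fwd.residues, site, 462)
        res = pair_coverage(fwd, rev, [rec], target="T", min_amplicon=400)
        assert res.rows[0].matched == 1
        # amplicon exactly 100 -> not matched at the default threshold
        rec = self._subject(fwd.residues, site, 62)
        res = pair_coverage(fwd, rev, [rec], target="T", min_amplicon=400)
        assert res.rows[0].matched == 0

    def test_pair_never_exceeds_single_primer_coverage(self):
        pool, truth = _planted_db()
        motif = truth.window_motifs[0]
        fwd = Primer(name="F", residues=motif, target="T1")
        rev = Primer(name="R", residues="ACTTGCCCACCCCTTATTC", target="T1")
        singles = [
            coverage_tolerance(p, list(pool)).rows for p in (fwd, rev)
        ]
        paired = pair_coverage(fwd, rev, list(pool), min_amplicon=50).rows
        for i, row in enumerate(paired):
            assert row.matched <= min(singles[0][i].matched, singles[1][i].matched)


class TestEnumerateCandidates:
    def test_window_count_on_clean_consensus(self):
        pool, _ = _planted_db()
        L = 60
        consensus = "".join(
            np.random.default_rng(5).choice(list("ACGT"), size=L)
        )
        cands = enumerate_candidates(
            consensus, list(pool), "T1", length_range=(19, 19)
        )
        assert len(cands) == L - 18

    def test_ambiguity_blocks_spanning_windows(self):
        consensus = "A" * 30 + "Y" + "A" * 30
        pool, _ = _planted_db()
        cands = enumerate_candidates(
            consensus, list(pool), "T1", length_range=(19, 19)
        )
        positions = {c.position for c in cands}
        blocked = {p for p in range(31 - 18, 32)}
        assert positions.isdisjoint(blocked)

    def test_planted_window_wins(self):
        pool, truth = _planted_db()
        aln_target = make_alignment(
            {r.id: r.residues for r in pool if r.taxon_label == "T1"}
        )
        cons = consensus_majority(aln_target)
        cands = enumerate_candidates(
            cons, list(pool), "T1", length_range=(19, 19)
        )
        top = cands[0]
        w_start = 201  # 1-based
        assert top.position < w_start + 19 and top.position + 19 > w_start
        assert top.coverage >= 90.0
        assert top.max_tolerance < 1.0


class TestMapToReference:
    def test_prefix_and_revcomp_suffix(self):
        ref = "GAATAAGGGGTGGGCAAGT" + "C" * 50 + "ATCGGATCCTAGGCAT"
        site = map_to_reference("GAATAAGGGGTGGGCAAGT", ref)
        assert (site.start, site.end, site.strand) == (1, 19, "+")
        rc = revcomp(ref[-16:])
        site = map_to_reference(rc, ref)  # suffix, reverse strand
        assert site.strand == "-"
        assert site.end == len(ref)

    def test_planted_offsets_recovered(self):
        rng = np.random.default_rng(51)
        ref = "".join(rng.choice(list("ACGT"), size=300))
        for start in (0, 57, 240):
            primer = ref[start : start + 20]
            site = map_to_reference(primer, ref)
            assert (site.start, site.mismatches) == (start + 1, 0)

    def test_unmappable_returns_none(self):
        assert map_to_reference("A" * 20, "C" * 100, max_mismatch=2) is None


class TestSpecificityTable:
    def test_cells_match_direct_recomputation(self):
        pool, truth = _planted_db()
        p1 = Primer(name="P1", residues=truth.window_motifs[0], target="T1")
        table = specificity_table([p1], list(pool))
        direct = coverage_tolerance(p1, list(pool))
        for row in direct.rows:
            cell = table.loc[table["group"] == row.group, "P1"].iloc[0]
            assert cell == round_half_up(row.percent)

    def test_half_up_rounding_contract(self):
        assert round_half_up(0.05, 1) == 0.1
        assert round_half_up(92.85, 1) == 92.9
        assert round_half_up(0.04999, 1) == 0.0
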