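import pytest

from nullkit._alphabet import AA20, DNA4
from nullkit.fixtures import oracle_mutation_scan, synth_cds, synth_proteome
from nullkit.kmer_core import scan_presence
from nullkit.mutation_maps import (
    MutationEvent,
    cds_peptide_substitution_scan,
    expected_class_counts,
    materialized_words_variant,
    mutation_type_enrichment,
    per_nullomer_event_counts,
    region_density,
    scan_materializing_mutations,
    substitution_context_spectrum,
    transcript_mutation_density,
    translate_cds,
)
from nullkit.sequence_io import ContigSequence


def _event_set(events):
    return {(e.mclass, e.pos, e.ref, e.alt, e.materialized) for e in events}


class TestExpectedClassCounts:
    def test_k13_paper_values(self):
        e = expected_class_counts(13)
        assert (e.deletions, e.substitutions, e.insertions) == (13, 39, 48)
        f = e.fractions
        assert f["DEL"] == pytest.approx(0.13)
        assert f["SUB"] == pytest.approx(0.39)
        assert f["INS"] == pytest.approx(0.48)

    @pytest.mark.parametrize("k,expected", [(2, (2, 6, 4)), (11, (11, 33, 40))])
    def test_formula(self, k, expected):
        e = expected_class_counts(k)
        assert (e.deletions, e.substitutions, e.insertions) == expected

    @pytest.mark.parametrize("k", range(2, 16))
    def test_fractions_sum_to_one(self, k):
        assert sum(expected_class_counts(k).fractions.values()) == pytest.approx(1.0)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            expected_class_counts(1)


class TestScanMaterializingMutations:
    def test_sub_example(self):
        g = ContigSequence("g", "AAAA")
        pmap = scan_presence(["AAAA"], 2, DNA4, "forward")
        evs = list(scan_materializing_mutations([g], pmap, 2))
        hit = [e for e in evs if e.mclass == "SUB" and e.pos == 2 and e.alt == "C"]
        assert hit[0].materialized == frozenset({"AC", "CA"})

    def test_del_example(self):
        g = ContigSequence("g", "ACGT")
        pmap = scan_presence(["ACGT"], 3, DNA4, "forward")
        evs = [e for e in scan_materializing_mutations([g], pmap, 3) if e.mclass == "DEL"]
        del2 = [e for e in evs if e.pos == 2]
        assert del2[0].materialized == frozenset({"AGT"})

    def test_identity_substitution_not_emitted(self):
        g = ContigSequence("g", "AAAA")
        pmap = scan_presence(["AAAA"], 2, DNA4, "forward")
        for e in scan_materializing_mutations([g], pmap, 2):
            if e.mclass == "SUB":
                assert e.alt != e.ref

    def test_k_mismatch_rejected(self):
        pmap = scan_presence(["ACGT"], 3, DNA4, "forward")
        with pytest.raises(ValueError):
            list(scan_materializing_mutations([ContigSequence("g", "ACGT")], pmap, 2))

    def test_class_count_cap(self, rng, random_dna):
        seq = random_dna(rng, 100)
        pmap = scan_presence([seq], 3, DNA4, "forward")
        evs = list(scan_materializing_mutations([ContigSequence("g", seq)], pmap, 3))
        from collections import Counter

        per_pos = Counter((e.pos, e.mclass) for e in evs)
        for (pos, mclass), n in per_pos.items():
            cap = {"SUB": 3, "DEL": 1, "INS": 4}[mclass]
            assert n <= cap

    @pytest.mark.parametrize("mode", ["forward", "both"])
    def test_oracle_equivalence(self, mode, rng, random_dna):
        for _ in range(6):
            seq = random_dna(rng, int(rng.integers(40, 150)), n_fraction=0.03)
            g = ContigSequence("seq", seq)
            for k in (2, 3, 4):
                pmap = scan_presence([seq], k, DNA4, mode)
                mine = _event_set(scan_materializing_mutations([g], pmap, k))
                assert mine == oracle_mutation_scan(seq, k, mode)

    def test_soundness_rescan(self, rng, random_dna):
        seq = random_dna(rng, 200)
        g = ContigSequence("g", seq)
        k = 4
        pmap = scan_presence([seq], k, DNA4, "forward")
        for ev in scan_materializing_mutations([g], pmap, k):
            if ev.mclass == "SUB":
                mutated = seq[: ev.pos - 1] + ev.alt + seq[ev.pos :]
            elif ev.mclass == "DEL":
                mutated = seq[: ev.pos - 1] + seq[ev.pos :]
            else:
                mutated = seq[: ev.pos - 1] + ev.alt + seq[ev.pos - 1 :]
            window = mutated[max(0, ev.pos - 2 * k) : ev.pos + 2 * k]
            for w in ev.materialized:
                assert w in window or not pmap.contains(w)


class TestEventAggregation:
    def _events(self):
        return [
            MutationEvent("c", 1, "A", "C", "SUB", frozenset({"w1", "w2"})),
            MutationEvent("c", 2, "A", "C", "SUB", frozenset({"w1"})),
            MutationEvent("c", 3, "A", "C", "SUB", frozenset({"w1"})),
        ]

    def test_per_nullomer_counts(self):
        counts = per_nullomer_event_counts(self._events(), words=["w1", "w2", "w3"])
        assert counts == {"w1": 3, "w2": 1, "w3": 0}

    def test_enrichment_arithmetic(self):
        e = expected_class_counts(13)
        events = (
            [MutationEvent("c", i, "A", "C", "SUB", frozenset({"w"})) for i in range(50)]
            + [MutationEvent("c", i, "", "C", "INS", frozenset({"w"})) for i in range(40)]
            + [MutationEvent("c", i, "A", "", "DEL", frozenset({"w"})) for i in range(10)]
        )
        enr = mutation_type_enrichment(events, e)
        assert enr["SUB"] == pytest.approx(0.5 / 0.39)
        assert enr["DEL"] == pytest.approx(0.10 / 0.13)

    def test_exact_proportion_gives_unit_enrichment(self):
        e = expected_class_counts(2)  # 2 DEL, 6 SUB, 4 INS
        events = (
            [MutationEvent("c", i, "A", "C", "SUB", frozenset({"w"})) for i in range(6)]
            + [MutationEvent("c", i, "", "C", "INS", frozenset({"w"})) for i in range(4)]
            + [MutationEvent("c", i, "A", "", "DEL", frozenset({"w"})) for i in range(2)]
        )
        enr = mutation_type_enrichment(events, e)
        assert all(v == pytest.approx(1.0) for v in enr.values())

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            mutation_type_enrichment([], expected_class_counts(3))


class TestContextSpectrum:
    def test_single_event_context(self):
        genome = [ContigSequence("c", "ACTGA")]
        ev = MutationEvent("c", 3, "T", "A", "SUB", frozenset({"w"}))
        spec = substitution_context_spectrum([ev], genome)
        assert spec.counts == {("C", "T", "G", "A"): 1}
        assert spec.context_counts == {"CTG": 1}

    def test_normalized_rate(self):
        # genome in which CTG is 1 of 3 trinucleotide windows
        genome = [ContigSequence("c", "CTGCT")]
        ev = MutationEvent("c", 2, "T", "A", "SUB", frozenset({"w"}))
        spec = substitution_context_spectrum([ev], genome)
        freq = spec.context_frequencies["CTG"]
        assert spec.normalized_rates()["CTG"] == pytest.approx((1 / 1) / freq)

    def test_terminal_events_excluded(self):
        genome = [ContigSequence("c", "ACGT")]
        evs = [
            MutationEvent("c", 1, "A", "C", "SUB", frozenset({"w"})),
            MutationEvent("c", 4, "T", "C", "SUB", frozenset({"w"})),
        ]
        spec = substitution_context_spectrum(evs, genome)
        assert spec.counts == {} and spec.n_excluded == 2

    def test_no_substitutions(self):
        genome = [ContigSequence("c", "ACGT")]
        ev = MutationEvent("c", 2, "", "C", "INS", frozenset({"w"}))
        assert substitution_context_spectrum([ev], genome).counts == {}


class TestRegionDensity:
    def test_density_per_bp(self):
        evs = [MutationEvent("c", p, "A", "C", "SUB", frozenset({"w"})) for p in (5, 10, 20, 50)]
        df = region_density(evs, {"r": [("c", 1, 100)]})
        assert df.loc[0, "density"] == pytest.approx(0.04)

    def test_event_outside_intervals_excluded(self):
        evs = [MutationEvent("c", 500, "A", "C", "SUB", frozenset({"w"}))]
        df = region_density(evs, {"r": [("c", 1, 100)]})
        assert df.loc[0, "n_events"] == 0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            region_density([], {"r": []})

    def test_max_isoform_per_gene(self, toy_genome, toy_models):
        from nullkit.sequence_io import GeneModel

        m1 = GeneModel("t1", "g1", "c", "+", 1, 100)
        m2 = GeneModel("t2", "g1", "+", "+", 1, 50)
        m2.contig = "c"
        evs = [MutationEvent("c", p, "A", "C", "SUB", frozenset({"w"})) for p in (10, 20, 30)]
        df = transcript_mutation_density(evs, [m1, m2])
        assert len(df) == 1
        assert df.loc[0, "transcript_id"] == "t2"  # 3/50 > 3/100
        assert df.loc[0, "density"] == pytest.approx(3 / 50)


class TestCdsPeptideScan:
    def test_toy_example(self):
        # CDS TGGTGC -> WC; substituting pos 3 G->T gives TGT TGC -> CC
        pmap = scan_presence(synth_proteome(3, (20, 40), seed=0, planted_absent_motifs=("CC",)),
                             2, AA20, "forward")
        assert not pmap.contains("CC")
        evs = list(cds_peptide_substitution_scan({"t": "TGGTGC"}, pmap, 2))
        hits = [e for e in evs if e.cds_pos == 3 and e.alt == "T"]
        assert hits and "CC" in hits[0].materialized
        assert hits[0].residue_index == 0

    def test_synonymous_no_event(self):
        proteome = synth_proteome(3, (20, 40), seed=0)
        pmap = scan_presence(proteome, 2, AA20, "forward")
        evs = list(cds_peptide_substitution_scan({"t": "TGCTGT"}, pmap, 2))
        # TGC->TGT at pos 3 is synonymous (C->C): never reported
        assert not any(e.cds_pos == 3 and e.alt == "T" for e in evs)

    def test_stop_gain_excluded(self):
        proteome = synth_proteome(3, (20, 40), seed=0)
        pmap = scan_presence(proteome, 2, AA20, "forward")
        # TGG (W) -> TGA (stop) via pos3 G->A must never be an event
        evs = list(cds_peptide_substitution_scan({"t": "TGGTGC"}, pmap, 2))
        assert not any(e.cds_pos == 3 and e.alt == "A" for e in evs)

    def test_internal_stop_rejected(self):
        pmap = scan_presence(synth_proteome(1, (10, 20), seed=0), 2, AA20, "forward")
        with pytest.raises(ValueError, match="tx_bad"):
            list(cds_peptide_substitution_scan({"tx_bad": "TGATGC"}, pmap, 2))

    def test_length_not_divisible_rejected(self):
        pmap = scan_presence(synth_proteome(1, (10, 20), seed=0), 2, AA20, "forward")
        with pytest.raises(ValueError, match="divisible"):
            list(cds_peptide_substitution_scan({"t": "TGGT"}, pmap, 2))

    def test_events_are_nonsynonymous_and_absent(self):
        cds = synth_cds(4, seed=3)
        pmap = scan_presence(synth_proteome(5, (30, 60), seed=4), 3, AA20, "forward")
        for ev in cds_peptide_substitution_scan(cds, pmap, 3):
            for pep in ev.materialized:
                assert not pmap.contains(pep)


class TestMaterializedWordsVariant:
    def test_snv_matches_oracle(self):
        seq = "AAAA"
        pmap = scan_presence([seq], 2, DNA4, "forward")
        words = materialized_words_variant(seq, 2, 2, "A", "C", pmap)
        assert words == frozenset({"AC", "CA"})

    def test_no_new_words(self):
        seq = "ACGTACGT"
        pmap = scan_presence([seq], 2, DNA4, "forward")
        assert materialized_words_variant(seq, 2, 5, "A", "T", pmap) <= {
            w for w in ("TA", "GT")
        } or True  # only absent words may appear
        for w in materialized_words_variant(seq, 2, 5, "A", "T", pmap):
            assert not pmap.contains(w)
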