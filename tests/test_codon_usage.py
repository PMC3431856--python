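from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from mitodesc import codon_usage as cu
from mitodesc import genome_model as gm


def pcg_record(cds, name="g1", stop=None):
    return gm.MitogenomeRecord(
        id="t", length=len(cds), sequence=cds,
        features=[gm.GeneFeature(name, "PCG", "F", 1, len(cds),
                                 start_codon=cds[:3], stop_codon=stop)])


class TestCodeTable:
    def test_sense_codon_count(self):
        assert len(cu.SENSE_CODONS) == 62
        assert set(cu.STOP_CODONS) == {"TAA", "TAG"}

    def test_family_split(self):
        assert cu.FAMILY_OF["TTA"] == "Leu2" and cu.FAMILY_OF["CTA"] == "Leu1"
        assert cu.FAMILY_OF["AGA"] == "Ser1" and cu.FAMILY_OF["TCA"] == "Ser2"
        assert cu.FAMILY_OF["ATA"] == "Met"       # ATA is Met in this code
        assert cu.FAMILY_OF["TGA"] == "Trp"       # TGA is Trp
        degeneracies = Counter(len(v) for v in cu.FAMILIES.values())
        assert degeneracies == {2: 13, 4: 9}

    @pytest.mark.parametrize("cds,expected", [
        ("ATAAGATGA", "MSW"),
        ("TTATTT", "LF"),
    ])
    def test_translate(self, cds, expected):
        assert cu.translate(cds) == expected

    def test_translate_start_convention_and_ambiguity(self):
        assert cu.translate("CGAAAA", first_is_start=True) == "MK"
        assert cu.translate("ANAAAA") == "XK"


class TestClassifyStartStop:
    @pytest.mark.parametrize("cds,start,stop_class", [
        ("ATG" + "AAA" + "TAA", "ATG", "TAA"),
        ("ATT" + "AAA" * 2 + "TAG", "ATT", "TAG"),
        ("CGA" + "AAA" + "T", "CGA", "T"),
        ("ATG" + "AAA" + "TA", "ATG", "TA"),
        ("ATG" + "AAA" + "CCC", "ATG", "anomalous"),
    ])
    def test_classes(self, cds, start, stop_class):
        got = cu.classify_start_stop(None, cds)
        assert (got.start_codon, got.stop_class) == (start, stop_class)

    def test_reference_gene_classes(self, reference, synthetic_genome):
        rec, _ = synthetic_genome
        table = cu.extract_codons(rec)
        by_name = {g.name: g for g in table.genes}
        assert (by_name["cox1"].start_codon, by_name["cox1"].stop_class) == \
            ("CGA", "T")
        assert (by_name["nad2"].start_codon, by_name["nad2"].stop_class) == \
            ("ATT", "TAA")
        truncated = {n for n, g in by_name.items()
                     if g.stop_class in ("T", "TA")}
        assert truncated == {"cox1", "cox2", "nad4"}

    def test_too_short_rejected(self):
        with pytest.raises(gm.FeatureTableError):
            cu.classify_start_stop(None, "ATGTA")


class TestExtractCodons:
    def test_single_gene(self):
        table = cu.extract_codons(pcg_record("ATGAAATTTTAA"))
        assert dict(table.counts) == {"AAA": 1, "TTT": 1}
        assert table.total == 2

    def test_truncated_stop_codon_arithmetic(self):
        # 10 bp ending in T: (10 - 3 - 1) / 3 = 2 codons
        table = cu.extract_codons(pcg_record("ATG" + "AAATTT" + "T"))
        assert table.total == 2

    def test_internal_stop_flagged_not_counted(self):
        table = cu.extract_codons(pcg_record("ATG" + "AAA" + "TAA" + "TTT" + "TAA"))
        assert table.genes[0].internal_stops == [1]
        assert dict(table.counts) == {"AAA": 1, "TTT": 1}

    def test_planted_multiset_recovered_exactly(self, synthetic_genome):
        rec, ledger = synthetic_genome
        table = cu.extract_codons(rec)
        assert dict(table.counts) == ledger.codon_counts
        assert table.total == ledger.total_codons
        assert not any(g.internal_stops for g in table.genes)

    def test_rotation_and_strand_invariance(self, synthetic_genome):
        rec, _ = synthetic_genome
        base = cu.extract_codons(rec).counts
        shift = 3000
        L = rec.length
        seq = rec.sequence[-shift:] + rec.sequence[:-shift]
        feats = sorted(
            [gm.GeneFeature(f.name, f.category, f.strand,
                            (f.start - 1 + shift) % L + 1,
                            (f.end - 1 + shift) % L + 1,
                            anticodon=f.anticodon, start_codon=f.start_codon,
                            stop_codon=f.stop_codon)
             for f in rec.features], key=lambda f: (f.start, f.end))
        rotated = gm.MitogenomeRecord(id="r", length=L, features=feats,
                                      sequence=seq)
        assert cu.extract_codons(rotated).counts == base


class TestDerivedStatistics:
    def test_per_thousand_trivial(self):
        t = cu.CodonUsageTable(counts=Counter({"AAA": 5}))
        assert t.per_thousand()["AAA"] == pytest.approx(1000.0)
        t = cu.CodonUsageTable(counts=Counter({"AAA": 3, "TTT": 3}))
        pt = t.per_thousand()
        assert pt["AAA"] == pt["TTT"] == pytest.approx(500.0)

    def test_per_thousand_empty_rejected(self):
        with pytest.raises(gm.FeatureTableError):
            cu.CodonUsageTable().per_thousand()

    def test_rscu_phe_family(self):
        t = cu.CodonUsageTable(counts=Counter({"TTT": 3, "TTC": 1}))
        rscu = t.rscu()
        assert rscu["TTT"] == pytest.approx(1.5)
        assert rscu["TTC"] == pytest.approx(0.5)

    def test_rscu_uniform_family_is_one(self):
        t = cu.CodonUsageTable(counts=Counter(
            {c: 2 for c in cu.FAMILIES["Val"]}))
        rscu = t.rscu()
        for c in cu.FAMILIES["Val"]:
            assert rscu[c] == pytest.approx(1.0)

    def test_rscu_missing_family_is_none(self):
        t = cu.CodonUsageTable(counts=Counter({"TTT": 1}))
        assert all(t.rscu()[c] is None for c in cu.FAMILIES["Val"])

    @settings(max_examples=40, derandomize=True)
    @given(st.dictionaries(st.sampled_from(cu.SENSE_CODONS),
                           st.integers(min_value=0, max_value=50),
                           min_size=1))
    def test_normalization_invariants(self, counts):
        t = cu.CodonUsageTable(counts=Counter(
            {c: n for c, n in counts.items() if n}))
        if t.total == 0:
            return
        assert sum(t.per_thousand().values()) == pytest.approx(1000.0)
        rscu = t.rscu()
        for fam, members in cu.FAMILIES.items():
            vals = [rscu[c] for c in members]
            if any(v is not None for v in vals):
                assert sum(vals) == pytest.approx(len(members))

    def test_planted_leu2_bias(self, synthetic_genome):
        rec, ledger = synthetic_genome
        # the AT-biased codon sampler should make TTA the majority Leu2 codon
        rscu = cu.extract_codons(rec).rscu()
        assert rscu["TTA"] > rscu["TTG"]
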