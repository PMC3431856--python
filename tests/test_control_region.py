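import numpy as np
import pytest

from mitodesc import control_region as cr
from mitodesc import genome_model as gm
from oracles import stemloop_oracle, tandem_oracle


def rng_region(seed, n=260, at=0.7):
    rng = np.random.default_rng(seed)
    probs = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list("ACGT"), n, p=probs))


class TestOriginSignature:
    def test_motif_plus_t_run(self):
        region = "GG" + "ATAGA" + "T" * 19 + "CCC"
        hits = cr.find_origin_signature(region)
        assert len(hits) == 1
        assert hits[0].start == 3
        assert hits[0].attributes["t_run"] == 19

    def test_short_run_rejected(self):
        assert cr.find_origin_signature("ATAGA" + "T" * 5 + "G") == []

    def test_no_motif(self):
        assert cr.find_origin_signature("ACGT" * 20) == []

    def test_gap_between_motif_and_run(self):
        region = "ATAGA" + "CA" + "T" * 12 + "G"
        hits = cr.find_origin_signature(region, max_gap=5)
        assert hits and hits[0].attributes["gap"] == 2
        assert cr.find_origin_signature(region, max_gap=1) == []


class TestMicrosatellites:
    def test_at7(self):
        hits = cr.find_microsatellites("G" + "AT" * 7 + "C")
        assert [(h.attributes["unit"], h.attributes["copies"]) for h in hits] \
            == [("AT", 7)]

    def test_below_min_copies(self):
        assert cr.find_microsatellites("G" + "AT" * 4 + "C", min_copies=5) == []

    def test_homopolymer(self):
        hits = cr.find_microsatellites("C" + "A" * 12 + "G")
        assert [(h.attributes["unit"], h.attributes["copies"]) for h in hits] \
            == [("A", 12)]

    def test_subrepeat_units_suppressed(self):
        # an (AT)n stretch must never be reported with unit ATAT
        hits = cr.find_microsatellites("G" + "AT" * 10 + "C")
        assert all(h.attributes["unit"] == "AT" for h in hits)

    def test_unit_canonical_rotation(self):
        hits = cr.find_microsatellites("G" + "TA" * 6 + "G")
        assert hits[0].attributes["unit"] == "AT"


class TestTandemRepeats:
    def test_planted_17bp_duplication_with_variation(self):
        rng = np.random.default_rng(3)
        unit = "".join(rng.choice(list("AT"), 17))
        copy2 = list(unit)
        copy2[9] = "C" if copy2[9] != "C" else "G"
        region = "GCGC" + unit + "".join(copy2) + "CGCG"
        hits = [h for h in cr.find_tandem_repeats(region)
                if h.attributes["period"] == 17]
        assert hits
        h = hits[0]
        assert h.attributes["copies"] >= 1.9
        assert h.attributes["identity"] < 100.0

    def test_planted_decuplicated_8bp(self):
        region = "GCG" + "ATATTAAT" * 10 + "CGC"
        hits = cr.find_tandem_repeats(region)
        by_period = {h.attributes["period"]: h for h in hits}
        assert 8 in by_period or 2 in by_period
        h8 = [h for h in hits
              if h.attributes["period"] == 8 or h.attributes["copies"] >= 9]
        assert h8

    def test_matches_exhaustive_oracle_on_random_sequences(self):
        for seed in range(12):
            region = rng_region(seed, n=200)
            got = [(h.start, h.end, h.attributes["period"],
                    h.attributes["score"])
                   for h in cr.find_tandem_repeats(region)]
            assert sorted(got) == tandem_oracle(region), f"seed {seed}"


class TestStemLoops:
    def planted(self):
        arm = "GATTACAG"
        arm3 = gm.reverse_complement(arm)
        return "CGCG" + "TATA" + arm + "AACAAA" + arm3 + "GAAAAT" + "CGCG"

    def test_planted_hairpin_with_flanks(self):
        hits = cr.find_stem_loops(self.planted())
        flagged = [h for h in hits if h.attributes["stem"] >= 8]
        assert len(flagged) == 1
        h = flagged[0]
        assert h.attributes["tata_5prime"] and h.attributes["gaat_3prime"]
        assert h.attributes["loop"] == 6

    def test_short_stem_rejected(self):
        region = "GGG" + "ATT" + "AAACAA" + "AAT" + "GGG"
        assert all(h.attributes["stem"] >= 5
                   for h in cr.find_stem_loops(region))

    def test_matches_exhaustive_oracle(self):
        for seed in range(12):
            region = rng_region(seed + 100, n=150, at=0.6)
            got = sorted((h.start, h.end, h.attributes["stem"],
                          h.attributes["loop"])
                         for h in cr.find_stem_loops(region))
            assert got == stemloop_oracle(region), f"seed {seed}"


class TestFixedMotifs:
    def test_junction_motifs_on_synthetic_genome(self, synthetic_genome):
        rec, _ = synthetic_genome
        motifs = {a.attributes.get("motif", a.kind): a.attributes
                  for a in cr.find_fixed_motifs(rec)}
        assert motifs["AAGCCTTA"]["present"] is True       # planted at trnW/trnC
        assert motifs["ATACTAA"]["present"] is False       # absent by default
        assert motifs["poly_a"]["present"] is False        # absent by default

    def test_planted_s4_motif_found_with_coordinates(self):
        from mitodesc import synthetic_data as syn
        spec = syn.GenomeSpec(seed=13, plant_s4_motif=True)
        rec, _ = syn.simulate_mitogenome(spec)
        hit = [a for a in cr.find_fixed_motifs(rec)
               if a.attributes.get("motif") == "ATACTAA"][0]
        assert hit.attributes["present"]
        g_start = hit.attributes["window_genome_start"] + hit.start - 1
        assert gm.extract_arc(rec.sequence, g_start, g_start + 6) == "ATACTAA"

    def test_missing_junction_gene_is_error(self):
        rec = gm.MitogenomeRecord(id="t", length=100, sequence="A" * 100)
        with pytest.raises(gm.FeatureTableError, match="junction gene"):
            cr.find_fixed_motifs(rec)


class TestCombinedScan:
    def test_position_covariance(self):
        prefix = "GTCAGCA"
        for seed in range(6):
            region = rng_region(seed + 50, n=200)
            base = cr.scan_control_region(region)
            shifted = cr.scan_control_region(prefix + region)
            shifted_set = {(a.kind, a.start, a.end) for a in shifted}
            for a in base:
                if a.start <= 3:  # the very edge may merge with the prefix
                    continue
                assert (a.kind, a.start + len(prefix), a.end + len(prefix)) \
                    in shifted_set

    def test_microsatellite_never_shadowed_by_stronger_tandem(self):
        for seed in range(8):
            region = rng_region(seed, n=250, at=0.8)
            merged = cr.scan_control_region(region)
            msats = [a for a in merged if a.kind == "microsatellite"]
            tandems = [a for a in merged if a.kind == "tandem_repeat"]
            for ms in msats:
                ms_score = 2 * (ms.attributes["span"] - ms.attributes["period"])
                for td in tandems:
                    if td.attributes["period"] != ms.attributes["period"]:
                        continue
                    overlap = min(ms.end, td.end) - max(ms.start, td.start) + 1
                    if overlap > 0:
                        assert td.attributes["score"] <= ms_score
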