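import numpy as np
import pandas as pd
import pytest

from tantseq.classify import (
    Alignment,
    ClassifiedRead,
    ReadClassifier,
    aggregate_species,
    align_to_tier,
    apply_overrides,
    assign_names,
    classify_read,
    reverse_complement,
    subclassify_tsrna,
)
from tantseq.config import PipelineConfig
from tantseq.references import ReferenceTier, TierSpec, load_tier_registry

from .conftest import random_query
from .oracles import oracle_classify


def tier(name, seqs, both=False, label=None):
    reg = load_tier_registry([TierSpec(name, sequences=seqs, biotype_label=label,
                                       append_cca=False, search_both_strands=both)])
    return reg[0]


class TestAlignToTier:
    def test_exact_substring_hits_with_zero_edits(self):
        t = tier("rRNA", {"r1": "AAAACGTACGTACGTACGTTTTT"})
        aln = align_to_tier("ACGTACGTACGTACGT", t, 2)
        assert aln.edits == 0 and aln.start == 4 and aln.end == 19

    def test_distance_three_is_rejected(self):
        t = tier("rRNA", {"r1": "A" * 50})
        assert align_to_tier("AAAAACCCAAAAAAA", t, 2) is None

    def test_lexicographic_reference_tie_break(self):
        seq = "A" * 10 + "ACGTACGTACGTACGT" + "A" * 10
        t = tier("rRNA", {"r2": seq, "r1": seq})
        assert align_to_tier("ACGTACGTACGTACGT", t, 2).reference_id == "r1"

    def test_leftmost_start_tie_break(self):
        q = "ACGTACGTACGTACG"
        t = tier("rRNA", {"r1": "TT" + q + "TTTT" + q + "TT"})
        assert align_to_tier(q, t, 2).start == 3

    INSERT = "AAACCCGGGTTTACGAT"  # far from its own reverse complement

    def test_minus_strand_hit_on_genome_tier(self):
        ref = "T" * 20 + self.INSERT + "T" * 20
        q = reverse_complement(self.INSERT)
        t = tier("genome", {"g1": ref}, both=True)
        aln = align_to_tier(q, t, 2)
        assert aln.strand == "-" and aln.start == 21 and aln.end == 37

    def test_transcript_tier_ignores_minus_strand(self):
        ref = "T" * 20 + self.INSERT + "T" * 20
        q = reverse_complement(self.INSERT)
        t = tier("rRNA", {"r1": ref})
        assert align_to_tier(q, t, 2) is None

    def test_n_bases_never_match(self):
        t = tier("rRNA", {"r1": "AAAACGTACGTACGTACGTTTTT"})
        aln = align_to_tier("ACGTACGTACGTACGN", t, 2)
        assert aln is not None and aln.edits >= 1


class TestClassifyRead:
    def setup_method(self):
        self.insert = "ACGTTGCAACGTTGCAACGT"
        self.registry = load_tier_registry(
            [
                TierSpec("rRNA", sequences={"r1": "TTTT" + self.insert + "TTTT"}),
                TierSpec("tRNA", sequences={"t1": "GG" + self.insert[:-1] + "A" + "GG"}),
                TierSpec("intron", sequences={"i1": "CC" + self.insert + "CC"}),
                TierSpec("genome", sequences={"g1": "AA" + self.insert + "AA"}),
            ]
        )

    def test_earlier_tier_wins_on_equal_exact_hits(self):
        biotype, aln = classify_read(self.insert, self.registry)
        assert biotype == "srRNA" and aln.round == 1

    def test_round1_exact_beats_round2_inexact_at_higher_tier(self):
        # insert matches tRNA (higher tier) with 1 mismatch but intron
        # exactly: the round-1 exact intron hit wins
        registry = [t for t in self.registry if t.tier_name in ("tRNA", "intron")]
        biotype, aln = classify_read(self.insert, registry)
        assert biotype == "sinRNA" and aln.round == 1 and aln.edits == 0

    def test_unmatchable_read_is_unmapped(self):
        assert classify_read("ACGCAGCATCAGCATACG", self.registry[:1]) is None

    def test_round2_assigns_with_edit_budget(self):
        q = "C" + self.insert[1:]  # 1 mismatch to every copy of the insert
        biotype, aln = classify_read(q, self.registry)
        assert biotype == "srRNA" and aln.round == 2 and aln.edits == 1

    def test_agrees_with_exhaustive_two_round_oracle(self, registry):
        rng = np.random.default_rng(42)
        for _ in range(120):
            q = random_query(rng, registry)
            mine = classify_read(q, registry, 2)
            ref = oracle_classify(q, registry, 2)
            if mine is None:
                assert ref is None
                continue
            biotype, a = mine
            tier_name, (rid, s, e, strand, edits), rnd = ref
            assert (a.tier_name, a.reference_id, a.start, a.end, a.strand, a.edits, a.round) == (
                tier_name, rid, s, e, strand, edits, rnd,
            )

    def test_tier_priority_monotone_under_tier_deletion(self, registry):
        rng = np.random.default_rng(43)
        for _ in range(40):
            q = random_query(rng, registry)
            hit = classify_read(q, registry, 2)
            if hit is None:
                continue
            _, aln = hit
            # deleting tiers *below* the winning tier never changes the call
            win_rank = next(t.priority_rank for t in registry if t.tier_name == aln.tier_name)
            keep = [t for t in registry if t.priority_rank <= win_rank]
            again = classify_read(q, keep, 2)
            assert again is not None and again[1].tier_name == aln.tier_name


class TestSubclassifyTsrna:
    PRECURSOR = "G" * 73 + "CCA"  # 76 nt, CCA appended

    def aln(self, start, end):
        return Alignment("t1", "tRNA", start, end, "+", 0, 1)

    def test_five_prime_fragment(self):
        assert subclassify_tsrna(self.aln(1, 30), "G" * 30, self.PRECURSOR) == "5p"

    def test_cca_three_prime_fragment(self):
        q = "G" * 27 + "CCA"
        assert subclassify_tsrna(self.aln(47, 76), q, self.PRECURSOR) == "cca3p"

    def test_cc_three_prime_fragment(self):
        q = "G" * 28 + "CC"
        assert subclassify_tsrna(self.aln(46, 75), q, self.PRECURSOR) == "cc3p"

    def test_internal_fragment(self):
        assert subclassify_tsrna(self.aln(10, 40), "G" * 31, self.PRECURSOR) == "internal"

    def test_full_length_prefers_five_prime(self):
        q = "G" * 73 + "CCA"
        assert subclassify_tsrna(self.aln(1, 76), q, self.PRECURSOR) == "5p"

    def test_non_tsrna_rejected(self):
        with pytest.raises(ValueError):
            subclassify_tsrna(self.aln(1, 30), "G" * 30, self.PRECURSOR, biotype_label="srRNA")


def make_read(read_id, seq, chem="OH", biotype="snRNA", ref="s1", start=1):
    aln = Alignment(ref, "snRNA", start, start + len(seq) - 1, "+", 0, 1)
    return ClassifiedRead(read_id, seq, chem, biotype, aln)


class TestOverrides:
    def test_empty_table_is_identity(self):
        reads = [make_read("r1", "ACGTACGTACGTACGT")]
        out, audit = apply_overrides(reads, {})
        assert out == reads and audit == []

    def test_sequence_override_changes_biotype_not_alignment(self):
        r = make_read("r1", "ACGTACGTACGTACGT", biotype="srpRNA")
        out, audit = apply_overrides([r], {"ACGTACGTACGTACGT": "snoRNA"})
        assert out[0].biotype_label == "snoRNA"
        assert out[0].alignment == r.alignment
        assert len(audit) == 1 and audit[0]["old_biotype"] == "srpRNA"

    def test_audit_count_matches_brute_force(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(50)]
        reads = [make_read(f"r{i}", s, biotype="srpRNA") for i, s in enumerate(seqs)]
        table = {s: "snoRNA" for s in seqs[::3]}
        _, audit = apply_overrides(reads, table)
        assert len(audit) == sum(1 for s in seqs if s in table)

    def test_unknown_biotype_rejected(self):
        with pytest.raises(ValueError):
            apply_overrides([], {"ACGT": "banana"})


class TestAggregateAndNames:
    def test_identical_reads_collapse_to_one_species(self):
        reads = [make_read(f"r{i}", "ACGTACGTACGTACGT") for i in range(10)]
        df = aggregate_species({"s1": reads})
        assert len(df) == 1 and df.iloc[0]["count_s1"] == 10

    def test_totals_conserved_per_sample(self):
        rng = np.random.default_rng(6)
        samples = {}
        for s in ("a", "b"):
            samples[s] = [
                make_read(f"{s}{i}", "".join(rng.choice(list("ACGT"), 16)))
                for i in range(rng.integers(20, 40))
            ]
        df = aggregate_species(samples)
        for s in samples:
            assert df[f"count_{s}"].sum() == len(samples[s])

    def test_read_order_invariance(self):
        rng = np.random.default_rng(7)
        reads = [make_read(f"r{i}", "".join(rng.choice(list("ACGT"), 16))) for i in range(30)]
        df1 = aggregate_species({"s": reads})
        df2 = aggregate_species({"s": list(reversed(reads))})
        pd.testing.assert_frame_equal(df1, df2)

    def _toy_table(self):
        rows = []
        for i, (mean, chem) in enumerate(
            [(100.0, "cP"), (50.0, "cP"), (10.0, "OH"), (2.0, "cP"), (1.0, "OH")]
        ):
            rows.append(
                {
                    "sequence": f"ACGTACGTACGTACG{chr(65 + i)}".replace("E", "T"),
                    "chemistry": chem, "biotype": "snRNA", "tsrna_subtype": "not_applicable",
                    "reference_id": "s1", "tier": "snRNA", "start": 1, "end": 16,
                    "strand": "+", "length": 16, "count_s1": mean, "mean_reads": mean,
                }
            )
        return pd.DataFrame(rows)

    def test_simple_name_prefix_rank_mod(self, config):
        named = assign_names(self._toy_table(), config)
        by_mean = named.set_index("mean_reads")
        assert by_mean.loc[100.0, "simple_name"] == "snR-1-cP"
        assert by_mean.loc[50.0, "simple_name"] == "snR-2-cP"
        assert by_mean.loc[10.0, "simple_name"] == "snR-1-OH"

    def test_threshold_is_strict(self, config):
        named = assign_names(self._toy_table(), config)
        assert named.set_index("mean_reads").loc[2.0, "simple_name"] is None
        assert named.set_index("mean_reads").loc[1.0, "simple_name"] is None

    def test_full_name_format(self, config):
        named = assign_names(self._toy_table(), config)
        assert named.iloc[0]["full_name"].count("|") == 4

    def test_rank_matches_brute_force_sort(self, config):
        rng = np.random.default_rng(8)
        df = self._toy_table()
        named = assign_names(df, config)
        for chem in ("OH", "cP"):
            grp = df[df["chemistry"] == chem]
            expected = grp.sort_values(["mean_reads", "sequence"], ascending=[False, True])
            for rank, (_, row) in enumerate(expected.iterrows(), 1):
                got = named[named["sequence"] == row["sequence"]]["simple_name"].iloc[0]
                if row["mean_reads"] > 2:
                    assert got == f"snR-{rank}-{chem}"


class TestEndToEndRecovery:
    def test_species_recover_truth_biotype_and_chemistry(self, config, registry, species, panel):
        """With error-free reads, >=95% of well-covered species get the
        ground-truth biotype and chemistry."""
        from tantseq.preprocess import preprocess_reads
        from tantseq.simulate import synthesize_reads

        reads, truth = synthesize_reads(
            species, 30000, error_rate=0.0, config=config, seed=17,
            spikein_panel=panel, bad_read_fraction=0.0,
        )
        oh, cp, _, _ = preprocess_reads(reads, config)
        classifier = ReadClassifier(registry, config)
        cls = classifier.classify_reads(oh, "OH")[0] + classifier.classify_reads(cp, "cP")[0]
        df = aggregate_species({"s": cls})
        truth_by_seq = {
            (sp.sequence, sp.chemistry): (sp.source_tier, sp.chemistry)
            for sp in species + panel.species
        }
        biotype_of_tier = {t.tier_name: t.biotype_label for t in registry}
        checked = hits = 0
        for row in df.itertuples():
            if row.count_s < 10:
                continue
            key = (row.sequence, row.chemistry)
            assert key in truth_by_seq  # error-free reads cannot invent species
            checked += 1
            true_tier, true_chem = truth_by_seq[key]
            if row.biotype == biotype_of_tier[true_tier] and row.chemistry == true_chem:
                hits += 1
        assert checked > 20
        assert hits / checked >= 0.95
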