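"""Promoter extraction, mismatch-tolerant k-mer counting, motif discovery
and IUPAC catalog matching."""

import numpy as np
import pandas as pd
import pytest

from coexmod import io as cio
from coexmod.cisreg import (
    MotifResult,
    _ball_counts,
    _spectrum,
    count_kmer,
    discover_motifs,
    extract_promoters,
    match_catalog,
)
from coexmod.syndata import MotifSpec, reverse_complement, simulate_genome

from conftest import make_config


def gff_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["seqid", "source", "type", "start", "end", "score", "strand",
                 "frame", "attributes"],
    )


class TestExtractPromoters:
    def test_plus_strand_coordinates(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        feats = gff_frame([("c1", "t", "CDS", 3000, 3300, ".", "+", "0",
                            "ID=cds_g1;Parent=g1")])
        promoters, skipped = extract_promoters({"c1": seq}, feats, ["g1"], length=2000)
        assert promoters["g1"] == seq[999:2999]  # genomic 1000..2999, 1-based
        assert skipped == []

    def test_minus_strand_is_revcomp_of_downstream(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        feats = gff_frame([("c1", "t", "CDS", 100, 400, ".", "-", "0",
                            "ID=cds_g1;Parent=g1")])
        promoters, _ = extract_promoters({"c1": seq}, feats, ["g1"], length=2000)
        assert promoters["g1"] == reverse_complement(seq[400:2400])

    def test_truncation_at_contig_start(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        feats = gff_frame([("c1", "t", "CDS", 500, 800, ".", "+", "0",
                            "ID=cds_g1;Parent=g1")])
        with pytest.warns(UserWarning, match="truncated"):
            promoters, _ = extract_promoters({"c1": seq}, feats, ["g1"], length=2000)
        assert promoters["g1"] == seq[:499]
        assert len(promoters["g1"]) == 499

    def test_gene_without_cds_is_skipped(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        feats = gff_frame([("c1", "t", "CDS", 2500, 2800, ".", "+", "0",
                            "ID=cds_g1;Parent=g1")])
        with pytest.warns(UserWarning, match="without CDS"):
            promoters, skipped = extract_promoters({"c1": seq}, feats, ["g1", "g2"])
        assert skipped == ["g2"] and "g1" in promoters

    def test_round_trip_through_fasta_and_gff_files(self, tmp_path):
        cfg = make_config(n_genes=30, n_samples=60, module_sizes=(10,), seed=13,
                          motif=MotifSpec("ACCCCC", 0, insertion_rate=1.0,
                                          mutation_prob=0.0))
        sim = simulate_genome(cfg)
        fasta = tmp_path / "genome.fasta"
        gff = tmp_path / "genes.gff3"
        cio.write_fasta(sim.contigs, fasta)
        cio.write_gff3(sim.features, gff)
        promoters, skipped = extract_promoters(fasta, gff, cfg.gene_ids(),
                                               length=cfg.promoter_len)
        assert skipped == []
        truth = sim.promoters.set_index("gene_id")["promoter"]
        assert all(promoters[g] == truth[g] for g in cfg.gene_ids())


class TestCountKmer:
    def test_single_exact_occurrence(self):
        assert count_kmer({"p": "ACGTACGT"}, "ACGTAC", 0) == (1, 1)

    def test_overlapping_occurrences_all_counted(self):
        assert count_kmer({"p": "AAAAAAAA"}, "AAAAAA", 0) == (3, 1)

    def test_windows_with_n_never_match(self):
        assert count_kmer({"p": "AANAAAAA"}, "AAAAAA", 2) == (0, 0)

    def test_matches_brute_force_hamming_oracle(self, rng):
        seqs = {
            f"p{i}": "".join(rng.choice(list("ACGTN"), size=80, p=[0.24] * 4 + [0.04]))
            for i in range(10)
        }
        motif = "ACGTCA"
        for max_mm in (0, 1, 2):
            total = 0
            with_hit = 0
            for seq in seqs.values():
                hits = 0
                for off in range(len(seq) - 6 + 1):
                    window = seq[off : off + 6]
                    if "N" in window:
                        continue
                    mm = sum(a != b for a, b in zip(window, motif))
                    hits += mm <= max_mm
                total += hits
                with_hit += hits > 0
            assert count_kmer(seqs, motif, max_mm) == (total, with_hit)

    def test_full_mismatch_allowance_matches_every_window(self, rng):
        seqs = {f"p{i}": "".join(rng.choice(list("ACGT"), size=50)) for i in range(4)}
        total, n_seq = count_kmer(seqs, "ACGTAC", 6)
        assert total == 4 * (50 - 6 + 1)
        assert n_seq == 4

    def test_both_strands_adds_revcomp_occurrences(self):
        assert count_kmer({"p": "GTACGTCC"}, "GACGTA", 0) == (0, 0)
        assert count_kmer({"p": "GTACGTCC"}, "GACGTA", 0, both_strands=True) == (1, 1)

    def test_invalid_motifs_rejected(self):
        with pytest.raises(ValueError):
            count_kmer({"p": "ACGT"}, "ACGTNA", 1)
        with pytest.raises(ValueError):
            count_kmer({"p": "ACGTACG"}, "ACGTACG", 1)  # length 7


class TestBallCounts:
    def test_hamming_ball_sums_match_direct_enumeration(self, rng):
        seqs = {f"p{i}": "".join(rng.choice(list("ACGT"), size=60)) for i in range(5)}
        spectrum, _ = _spectrum(seqs, 6)
        balls = _ball_counts(spectrum, 6, 1)
        for code in rng.integers(0, 4**6, size=12):
            motif = "".join("ACGT"[(code // 4**p) % 4] for p in range(5, -1, -1))
            total, _ = count_kmer(seqs, motif, 1)
            assert balls[code] == total
        balls2 = _ball_counts(spectrum, 6, 2)
        for code in rng.integers(0, 4**6, size=6):
            motif = "".join("ACGT"[(code // 4**p) % 4] for p in range(5, -1, -1))
            total, _ = count_kmer(seqs, motif, 2)
            assert balls2[code] == total


class TestDiscoverMotifs:
    def planted_sets(self, seed=17, n_fg=40, n_bg=200, length=400,
                     insertion_rate=0.9, mutation_prob=0.0):
        rng = np.random.default_rng(seed)
        consensus = "ACGTCA"

        def one(plant):
            seq = list(rng.choice(list("ACGT"), size=length))
            if plant and rng.random() < insertion_rate:
                pos = int(rng.integers(0, length - 6))
                seq[pos : pos + 6] = list(consensus)
            return "".join(seq)

        fg = {f"f{i}": one(True) for i in range(n_fg)}
        bg = {f"b{i}": one(False) for i in range(n_bg)}
        return consensus, fg, bg

    def test_planted_motif_or_neighbor_ranks_first(self):
        consensus, fg, bg = self.planted_sets()
        results = discover_motifs(fg, bg, k=6)
        neighborhood = {consensus}
        for p in range(6):
            for b in "ACGT":
                neighborhood.add(consensus[:p] + b + consensus[p + 1 :])
        assert results and results[0].motif in neighborhood

    def test_alpha_zero_returns_nothing(self):
        _, fg, bg = self.planted_sets()
        assert discover_motifs(fg, bg, k=6, alpha=0.0) == []

    def test_invariant_to_promoter_ordering_and_gene_relabeling(self):
        _, fg, bg = self.planted_sets(seed=3, n_fg=15, n_bg=30, length=200)
        base = discover_motifs(fg, bg, k=6)
        fg2 = {f"x{i}": fg[k] for i, k in enumerate(reversed(list(fg)))}
        bg2 = {f"y{i}": bg[k] for i, k in enumerate(reversed(list(bg)))}
        relabeled = discover_motifs(fg2, bg2, k=6)
        assert [r.motif for r in base] == [r.motif for r in relabeled]
        assert [r.p_enrich for r in base] == [r.p_enrich for r in relabeled]

    def test_overlapping_sets_rejected(self):
        _, fg, bg = self.planted_sets(n_fg=5, n_bg=5, length=100)
        with pytest.raises(ValueError):
            discover_motifs(fg, {**bg, **fg}, k=6)
        with pytest.raises(ValueError):
            discover_motifs({}, bg, k=6)


class TestMatchCatalog:
    def catalog(self, rows):
        return pd.DataFrame(rows, columns=["accession", "consensus", "description"])

    def result(self, motif):
        return MotifResult(motif=motif, fg_count=1, fg_seqs_with_hit=1, bg_rate=0.0,
                           log_odds=1.0, p_enrich=0.01)

    def test_exact_consensus_match(self):
        cat = self.catalog([("S000288", "GAGGGG", "SE1 stem element")])
        res = match_catalog([self.result("GAGGGG")], cat,
                            reverse_complement_too=False)
        assert res[0].matches == [("S000288", 0, "SE1 stem element")]

    def test_distant_motif_has_no_match(self):
        cat = self.catalog([("S000001", "TTTATTTA", "far away")])
        res = match_catalog([self.result("CAGGGGGG")], cat)
        assert res[0].matches == []

    def test_iupac_class_membership_is_not_a_mismatch(self):
        cat = self.catalog([("S1", "ASGTAC", "S is C or G")])
        res = match_catalog([self.result("ACGTAC")], cat,
                            reverse_complement_too=False)
        assert res[0].matches[0][1] == 0

    def test_motif_inside_longer_consensus(self):
        cat = self.catalog([("S1", "TTGAGGGGAA", "padded")])
        res = match_catalog([self.result("GAGGGG")], cat,
                            reverse_complement_too=False)
        assert res[0].matches[0][1] == 0

    def test_consensus_inside_longer_motif(self):
        cat = self.catalog([("S1", "AGGGGG", "short element")])
        res = match_catalog([self.result("CAGGGGGG")], cat,
                            reverse_complement_too=False)
        assert res[0].matches[0][1] == 0  # AGGGGG sits inside CAGGGGGG

    def test_reverse_complement_match_found_by_default(self):
        cat = self.catalog([("S1", "CCCCTC", "rc of GAGGGG")])
        res = match_catalog([self.result("GAGGGG")], cat)
        assert res[0].matches[0][1] == 0
        res_fwd = match_catalog([self.result("GAGGGG")], cat,
                                reverse_complement_too=False)
        assert res_fwd[0].matches == []

    def test_mismatch_allowance_depends_on_motif_length(self):
        cat = self.catalog([("S1", "AAAAAA", "A-run"), ("S2", "AAAAAAAA", "A-run 8")])
        six = match_catalog([self.result("AAAATT")], cat,
                            reverse_complement_too=False)[0]
        assert six.matches == []  # 2 mismatches > allowance 1 for 6-mers
        eight = match_catalog([self.result("AAAAAATT")], cat,
                              reverse_complement_too=False)[0]
        assert ("S2", 2, "A-run 8") in eight.matches

    def test_invalid_iupac_code_names_the_entry(self):
        cat = self.catalog([("S9", "ACGJ", "bad code")])
        with pytest.raises(ValueError, match="S9"):
            match_catalog([self.result("ACGTAC")], cat)

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            match_catalog([self.result("ACGTAC")], self.catalog([]))
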