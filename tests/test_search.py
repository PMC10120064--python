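"""Translated search, range culling, profiles and iterative search."""


import numpy as np
import pytest

from evescan.seqio import Contig, GenomeAssembly, revcomp
from evescan.search import (TranslatedHit, build_profile, iterative_search,
                            prefilter_proteins, range_cull,
                            transcriptome_search, translated_search)
from evescan.simulate import random_nt, random_protein, reverse_translate


def _asm(*seqs):
    return GenomeAssembly([Contig(f"c{i+1}", s) for i, s in enumerate(seqs)])


def _planted(rng, aa_len=300, flank=400, gc=0.45):
    prot = random_protein(aa_len, rng)
    cds = reverse_translate(prot, gc, rng)
    left = random_nt(flank, 0.5, rng)
    seq = left + cds + random_nt(flank, 0.5, rng)
    return seq, prot, len(left), len(left) + len(cds)


class TestTranslatedSearch:
    def test_unmutated_gene_single_perfect_hit(self):
        rng = np.random.default_rng(0)
        seq, prot, s, e = _planted(rng)
        hits = translated_search(_asm(seq), {"q": prot})
        assert len(hits) == 1
        h = hits[0]
        assert h.pct_identity == 100.0
        assert h.n_frameshifts == 0
        assert h.strand == "+"
        # spans the gene body (stop codon not aligned)
        assert abs(h.nt_start - s) <= 3 and abs(h.nt_end - e) <= 3

    def test_single_deletion_one_hit_with_one_frameshift(self):
        rng = np.random.default_rng(1)
        seq, prot, s, e = _planted(rng)
        mid = (s + e) // 2
        broken = seq[:mid] + seq[mid + 1:]
        hits = translated_search(_asm(broken), {"q": prot})
        assert len(hits) == 1
        h = hits[0]
        assert h.n_frameshifts == 1
        assert h.nt_start < mid - 50 and h.nt_end > mid + 50

    def test_random_host_zero_hits(self):
        rng = np.random.default_rng(2)
        asm = _asm(random_nt(50_000, 0.5, rng))
        prots = {f"p{i}": random_protein(400, rng) for i in range(3)}
        assert translated_search(asm, prots) == []

    def test_minus_strand_hit_mirrored(self):
        rng = np.random.default_rng(3)
        seq, prot, s, e = _planted(rng)
        hits_fwd = translated_search(_asm(seq), {"q": prot})
        hits_rev = translated_search(_asm(revcomp(seq)), {"q": prot})
        assert len(hits_fwd) == len(hits_rev) == 1
        f, r = hits_fwd[0], hits_rev[0]
        n = len(seq)
        assert r.strand == "-"
        assert (r.nt_start, r.nt_end) == (n - f.nt_end, n - f.nt_start)
        assert r.score == f.score

    def test_seeded_and_exhaustive_agree_on_planted_gene(self):
        """The k-mer seeded mode must reproduce the exhaustive DP result."""
        rng = np.random.default_rng(4)
        seq, prot, s, e = _planted(rng, flank=8000)
        exhaustive = translated_search(_asm(seq), {"q": prot},
                                       exhaustive_max_nt=10**9)
        seeded = translated_search(_asm(seq), {"q": prot}, exhaustive_max_nt=0)
        assert [(h.nt_start, h.nt_end, h.score) for h in exhaustive] == \
            [(h.nt_start, h.nt_end, h.score) for h in seeded]

    def test_empty_protein_set_rejected(self):
        with pytest.raises(ValueError):
            translated_search(_asm("ACGTACGT"), {})

    def test_tiny_contig_skipped(self):
        rng = np.random.default_rng(5)
        hits = translated_search(_asm("AC"), {"q": random_protein(100, rng)})
        assert hits == []

    def test_two_copies_both_found(self):
        rng = np.random.default_rng(6)
        prot = random_protein(250, rng)
        cds = reverse_translate(prot, 0.45, rng)
        seq = (random_nt(300, 0.5, rng) + cds + random_nt(500, 0.5, rng)
               + cds + random_nt(300, 0.5, rng))
        hits = translated_search(_asm(seq), {"q": prot})
        assert len(hits) == 2


class TestRangeCull:
    def _hit(self, start, end, score, query="q", contig="c1", ident=50.0):
        return TranslatedHit(contig, start, end, "+", query, 100, ident, 0,
                             score, 1e-20)

    def test_identical_intervals_best_kept(self):
        hits = [self._hit(0, 300, 50.0, "a"), self._hit(0, 300, 40.0, "b")]
        culled = range_cull(hits)
        assert [h.query_id for h in culled] == ["a"]

    def test_disjoint_intervals_both_kept(self):
        hits = [self._hit(0, 300, 50.0), self._hit(400, 700, 40.0)]
        assert len(range_cull(hits)) == 2

    def test_different_contigs_never_conflict(self):
        hits = [self._hit(0, 300, 50.0, contig="c1"),
                self._hit(0, 300, 40.0, contig="c2")]
        assert len(range_cull(hits)) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_greedy_reference_on_random_inputs(self, seed):
        """Culling equals an independently coded best-first reference."""
        rng = np.random.default_rng(seed)
        hits = []
        for i in range(10):
            s = int(rng.integers(0, 2000))
            e = s + int(rng.integers(100, 1000))
            hits.append(self._hit(s, e, float(rng.integers(20, 90)),
                                  query=f"q{i}"))

        def overlaps(a, b):
            ov = min(a.nt_end, b.nt_end) - max(a.nt_start, b.nt_start)
            return ov > 0.5 * min(a.length, b.length)

        kept_ref = []
        for h in sorted(hits, key=lambda h: (-h.score, -h.pct_identity,
                                             h.query_id)):
            if not any(overlaps(h, k) for k in kept_ref):
                kept_ref.append(h)
        got = {(h.nt_start, h.nt_end) for h in range_cull(hits)}
        assert got == {(h.nt_start, h.nt_end) for h in kept_ref}

    def test_mutually_overlapping_chain_keeps_single_best(self):
        hits = [self._hit(0, 900, 50.0, "a"), self._hit(100, 1000, 60.0, "b"),
                self._hit(200, 1100, 55.0, "c")]
        culled = range_cull(hits)
        assert [h.query_id for h in culled] == ["b"]


class TestPrefilter:
    def test_boundary_inclusive(self):
        prots = {"a": "A" * 100, "b": "A" * 200, "c": "A" * 900, "d": "A" * 901}
        assert set(prefilter_proteins(prots)) == {"b", "c"}

    def test_empty_input(self):
        assert prefilter_proteins({}) == {}

    def test_all_pass_identity(self):
        prots = {"a": "A" * 300, "b": "A" * 500}
        assert prefilter_proteins(prots) == prots


class TestProfiles:
    def test_single_sequence_consensus_is_sequence(self):
        rng = np.random.default_rng(7)
        p = random_protein(60, rng)
        prof = build_profile([p])
        assert prof.consensus == p
        aln = prof.align(p)
        assert aln.a_start == 0 and aln.a_end == len(p)

    def test_duplicate_rows_change_nothing(self):
        rng = np.random.default_rng(8)
        p = random_protein(50, rng)
        one = build_profile([p])
        two = build_profile([p, p])
        assert np.allclose(one.scores, two.scores)

    def test_gap_heavy_columns_dropped(self):
        prof = build_profile(["AC-D", "A--D", "AC-D"])
        assert prof.length == 3  # the all-gap column is gone

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_profile(["--", "--"])

    def test_family_member_outscores_random_decoy(self):
        rng = np.random.default_rng(9)
        anc = random_protein(120, rng)

        def mutate(p, n):
            p = list(p)
            for i in rng.choice(len(p), n, replace=False):
                p[i] = "ARNDCQEGHILKMFPSTWYV"[rng.integers(20)]
            return "".join(p)

        family = [mutate(anc, 25) for _ in range(5)]
        prof = build_profile(family)
        held_out = mutate(anc, 30)
        decoy = random_protein(120, rng)
        assert prof.align(held_out).score > prof.align(decoy).score


class TestIterativeSearch:
    def test_db_of_only_the_seed_converges_round_one(self):
        rng = np.random.default_rng(10)
        seed = random_protein(120, rng)
        res = iterative_search([seed], {"seed": seed})
        assert res.inclusion_round == {"seed": 1}
        assert res.converged
        assert res.n_rounds_run <= 2

    def test_stepping_stone_recovered_in_later_round(self):
        """A remote homolog reachable only through an intermediate sequence
        enters the included set after the profile absorbs the intermediate."""
        rng = np.random.default_rng(11)
        a = random_protein(150, rng)

        def mutate(p, n):
            p = list(p)
            for i in rng.choice(len(p), n, replace=False):
                p[i] = "ARNDCQEGHILKMFPSTWYV"[rng.integers(20)]
            return "".join(p)

        b = mutate(a, 55)      # ~63% to A
        c = mutate(b, 55)      # ~63% to B, ~40% to A
        d = mutate(c, 55)      # one more step out
        db = {"a": a, "b": b, "c": c, "d": d,
              **{f"r{i}": random_protein(150, rng) for i in range(10)}}
        res = iterative_search([a], db, n_rounds=5, inclusion_evalue=1e-7)
        assert res.inclusion_round["a"] == 1
        assert res.inclusion_round["b"] == 1
        assert "d" in res.inclusion_round
        assert res.inclusion_round["d"] > res.inclusion_round["b"]
        assert not any(k.startswith("r") for k in res.inclusion_round)

    def test_zero_inclusion_threshold_no_expansion(self):
        rng = np.random.default_rng(12)
        seed = random_protein(100, rng)
        db = {"x": seed, "y": random_protein(100, rng)}
        res = iterative_search([seed], db, inclusion_evalue=0.0)
        assert res.inclusion_round == {}
        assert res.n_rounds_run == 1
        assert len(res.hits) == 2  # round-1 hits still reported


class TestTranscriptomeSearch:
    def test_length_thresholds_between_modes(self):
        rng = np.random.default_rng(13)
        prot = random_protein(300, rng)
        frag60 = prot[100:160]
        cds = reverse_translate(frag60, 0.45, rng)
        contig = random_nt(150, 0.5, rng) + cds + random_nt(150, 0.5, rng)
        asm = _asm(contig)
        refs = {"q": prot}
        loose = transcriptome_search(asm, refs, evalue_max=1e-3)
        strict = translated_search(asm, refs, evalue_max=1e-3)
        assert len(loose) == 1 and loose[0].aligned_aa_len >= 50
        assert strict == []

    def test_short_fragment_rejected_by_both(self):
        rng = np.random.default_rng(14)
        prot = random_protein(300, rng)
        cds = reverse_translate(prot[100:140], 0.45, rng)
        contig = random_nt(150, 0.5, rng) + cds + random_nt(150, 0.5, rng)
        asm = _asm(contig)
        refs = {"q": prot}
        assert transcriptome_search(asm, refs, evalue_max=1e-3) == []
        assert translated_search(asm, refs, evalue_max=1e-3) == []

    def test_full_length_gene_found_by_both(self):
        rng = np.random.default_rng(15)
        seq, prot, _, _ = _planted(rng)
        asm = _asm(seq)
        assert len(transcriptome_search(asm, {"q": prot})) == 1
        assert len(translated_search(asm, {"q": prot})) == 1
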