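import numpy as np
import pytest

from cofitval.data_io import GeneRecord, GenomeAnnotation, Pwm
from cofitval.genome_context import maximal_runs
from cofitval.propagation import (
    align_and_score,
    choose_source,
    genome_best_scores,
    motif_empirical_pvalue,
    pwm_best_hit,
    reciprocal_best_hits,
    upstream_windows,
)
from cofitval.synthetic import mutate_protein, strong_pwm

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, n=100):
    return "".join(rng.choice(list(AA), size=n))


class TestAlignAndScore:
    def test_identical_sequences(self):
        seq = _random_protein(np.random.default_rng(0))
        bit, ident, cov, ev = align_and_score(seq, seq)
        assert ident == 100.0
        assert cov == 100.0
        assert ev < 1e-30

    def test_unrelated_sequences_fail_evalue(self):
        rng = np.random.default_rng(1)
        fails = 0
        for _ in range(30):
            _, _, _, ev = align_and_score(_random_protein(rng), _random_protein(rng))
            fails += ev > 1e-5
        assert fails == 30

    def test_partial_query_span_lowers_coverage(self):
        rng = np.random.default_rng(2)
        query = _random_protein(rng, 100)
        subject = query[:75] + _random_protein(rng, 30)
        _, _, cov, _ = align_and_score(query, subject)
        assert cov < 80.0

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            align_and_score("ACDEFGHIK1LMNP", "ACDEFGHIKLMNPQ")


class TestReciprocalBestHits:
    def test_identical_proteomes_identity_mapping(self):
        rng = np.random.default_rng(3)
        prots = {f"p{i}": _random_protein(rng, 80) for i in range(8)}
        pairs = reciprocal_best_hits(prots, dict(prots))
        assert {(p.locus_a, p.locus_b) for p in pairs} == {(k, k) for k in prots}

    def test_mutated_orthologs_recovered(self):
        # 60% planted identity; length 200 keeps realized identity clear of
        # the 50% acceptance threshold
        rng = np.random.default_rng(4)
        a = {f"a{i:02d}": _random_protein(rng, 200) for i in range(15)}
        b = {f"b{i:02d}": mutate_protein(a[f"a{i:02d}"], 0.6, rng) for i in range(15)}
        pairs = reciprocal_best_hits(a, b)
        recovered = sum(1 for p in pairs if p.locus_a[1:] == p.locus_b[1:])
        assert recovered >= 0.95 * 15

    def test_duplicate_gene_tie_break_is_deterministic(self, caplog):
        rng = np.random.default_rng(5)
        seq = _random_protein(rng, 90)
        a = {"a1": seq}
        b = {"b2": seq, "b1": seq}  # equal scores; lexicographic winner b1
        pairs = reciprocal_best_hits(a, b)
        assert [(p.locus_a, p.locus_b) for p in pairs] == [("a1", "b1")]


class TestChooseSource:
    def test_single_and_highest_bit_score(self):
        assert choose_source("tf", [("orgA", "t", 200.0, True)]) == "orgA"
        cands = [("orgA", "t", 290.0, True), ("orgB", "t", 310.0, True)]
        assert choose_source("tf", cands) == "orgB"

    def test_ineligible_top_candidate_skipped(self):
        cands = [("orgA", "t", 500.0, False), ("orgB", "t", 300.0, True)]
        assert choose_source("tf", cands) == "orgB"

    def test_no_eligible_candidate(self):
        assert choose_source("tf", [("orgA", "t", 500.0, False)]) is None


def _windows_ann():
    genes = [
        GeneRecord("w1", "sc1", 1000, 1400, "+"),
        GeneRecord("w2", "sc1", 1450, 1900, "+"),
        GeneRecord("w3", "sc1", 1950, 2400, "+"),
        GeneRecord("w4", "sc1", 2450, 2900, "+"),
        GeneRecord("edge", "sc2", 40, 400, "+"),
        GeneRecord("minus", "sc3", 1000, 1500, "-"),
    ]
    return GenomeAnnotation("w", genes)


class TestUpstreamWindows:
    def test_singleton_plus_strand(self):
        ann = GenomeAnnotation("x", [GeneRecord("s", "sc1", 1000, 1500, "+")])
        runs = maximal_runs(ann)
        wins = upstream_windows("s", ann, runs)
        assert wins == [("s", (750, 999), "+")]

    def test_third_gene_of_four_gene_run_has_three_windows(self):
        ann = _windows_ann()
        runs = maximal_runs(ann)
        wins = upstream_windows("w3", ann, runs)
        assert [w[0] for w in wins] == ["w1", "w2", "w3"]

    def test_scaffold_edge_truncated(self):
        ann = _windows_ann()
        runs = maximal_runs(ann)
        wins = upstream_windows("edge", ann, runs)
        assert wins == [("edge", (1, 39), "+")]

    def test_minus_strand_window_downstream_in_coordinates(self):
        ann = _windows_ann()
        runs = maximal_runs(ann)
        wins = upstream_windows("minus", ann, runs, seq_lengths={"sc3": 1600})
        assert wins == [("minus", (1501, 1600), "-")]


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestPwmScan:
    def setup_method(self):
        self.pwm = strong_pwm()
        rng = np.random.default_rng(6)
        self.bg = "".join(rng.choice(list("ACGT"), size=400))

    def test_planted_consensus_found_at_offset(self):
        cons = self.pwm.consensus()
        seq = self.bg[:100] + cons + self.bg[100 + len(cons):]
        ann = GenomeAnnotation("x", [GeneRecord("g", "sc1", 301, 380, "+")])
        runs = maximal_runs(ann)
        wins = upstream_windows("g", ann, runs)  # window (51, 300)
        hit = pwm_best_hit(wins, self.pwm, {"sc1": seq}, ann, "g")
        assert hit.position == 50  # 0-based within window starting at 51
        assert hit.strand == "+"
        expected = self.pwm.log_odds().max(axis=1).sum()
        assert hit.score == pytest.approx(expected)

    def test_reverse_complement_leaves_best_score_unchanged(self):
        cons = self.pwm.consensus()
        seq = self.bg[:100] + cons + self.bg[100 + len(cons):]
        ann_f = GenomeAnnotation("x", [GeneRecord("g", "sc1", 301, 380, "+")])
        n = len(seq)
        # same region on the reverse-complemented scaffold, gene mirrored
        ann_r = GenomeAnnotation(
            "y", [GeneRecord("g", "sc1", n - 380 + 1, n - 301 + 1, "-")]
        )
        hit_f = pwm_best_hit(
            upstream_windows("g", ann_f, maximal_runs(ann_f)),
            self.pwm, {"sc1": seq}, ann_f, "g",
        )
        hit_r = pwm_best_hit(
            upstream_windows("g", ann_r, maximal_runs(ann_r), seq_lengths={"sc1": n}),
            self.pwm, {"sc1": _revcomp(seq)}, ann_r, "g",
        )
        assert hit_f.score == pytest.approx(hit_r.score)

    def test_window_shorter_than_motif_skipped(self):
        ann = GenomeAnnotation("x", [GeneRecord("g", "sc1", 5, 100, "+")])
        runs = maximal_runs(ann)
        wins = upstream_windows("g", ann, runs)  # 4 bp window < motif width
        assert pwm_best_hit(wins, self.pwm, {"sc1": self.bg}, ann, "g") is None


class TestEmpiricalPvalue:
    def _genome(self, n_genes=40, seed=7, plant_in=None):
        rng = np.random.default_rng(seed)
        genes = [
            GeneRecord(f"g{i}", "sc1", 1000 + 2000 * i, 1800 + 2000 * i, "+")
            for i in range(n_genes)
        ]
        ann = GenomeAnnotation("e", genes)
        seq = list(rng.choice(list("ACGT"), size=1000 + 2000 * n_genes))
        pwm = strong_pwm()
        if plant_in is not None:
            cons = pwm.consensus()
            for i in plant_in:
                start = genes[i].begin - 100  # inside the upstream window
                seq[start - 1 : start - 1 + len(cons)] = list(cons)
        return ann, {"sc1": "".join(seq)}, pwm

    def test_unique_best_site_gives_one_over_g(self):
        ann, seqs, pwm = self._genome(plant_in=[3])
        runs = maximal_runs(ann)
        wins = upstream_windows("g3", ann, runs)
        hit = pwm_best_hit(wins, pwm, seqs, ann, "g3")
        p = motif_empirical_pvalue(hit, ann, runs, pwm, seqs)
        assert p == pytest.approx(1 / 40)

    def test_uniform_pwm_scores_everything_equally(self):
        ann, seqs, _ = self._genome()
        runs = maximal_runs(ann)
        uniform = Pwm("u", np.full((6, 4), 0.25))
        wins = upstream_windows("g0", ann, runs)
        hit = pwm_best_hit(wins, uniform, seqs, ann, "g0")
        assert hit.score == pytest.approx(0.0)
        p = motif_empirical_pvalue(hit, ann, runs, uniform, seqs)
        assert p == 1.0

    def test_planted_fraction_reflected_in_p(self):
        ann, seqs, pwm = self._genome(n_genes=40, plant_in=[0, 5, 10, 15])
        runs = maximal_runs(ann)
        wins = upstream_windows("g5", ann, runs)
        hit = pwm_best_hit(wins, pwm, seqs, ann, "g5")
        p = motif_empirical_pvalue(hit, ann, runs, pwm, seqs)
        assert p == pytest.approx(4 / 40)

    def test_invariant_to_monotone_score_rescaling(self):
        ann, seqs, pwm = self._genome(plant_in=[3, 8])
        runs = maximal_runs(ann)
        best = genome_best_scores(ann, runs, pwm, seqs)
        wins = upstream_windows("g3", ann, runs)
        hit = pwm_best_hit(wins, pwm, seqs, ann, "g3")
        p1 = motif_empirical_pvalue(hit, ann, runs, pwm, seqs, best_scores=best)
        scaled = {k: (None if v is None else 3 * v + 7) for k, v in best.items()}
        hit3 = type(hit)(hit.target_locus, hit.operon_upstream_locus,
                         hit.position, hit.strand, 3 * hit.score + 7)
        p2 = motif_empirical_pvalue(hit3, ann, runs, pwm, seqs, best_scores=scaled)
        assert p1 == p2

    def test_p_at_least_one_over_genes_scored(self):
        ann, seqs, pwm = self._genome(plant_in=[3])
        runs = maximal_runs(ann)
        best = genome_best_scores(ann, runs, pwm, seqs)
        wins = upstream_windows("g3", ann, runs)
        hit = pwm_best_hit(wins, pwm, seqs, ann, "g3")
        p = motif_empirical_pvalue(hit, ann, runs, pwm, seqs, best_scores=best)
        assert p >= 1 / len(best)


class TestPropagate:
    def test_perfectly_conserved_genome_propagates_everything(self):
        from cofitval.propagation import propagate
        from cofitval.synthetic import (
            MotifSpec, SimulationConfig, TfSpec, predictions_from_truth, simulate_genome,
        )

        # 10 tying consensus carriers among 1500 genes -> empirical p = 10/1500
        pwm = strong_pwm()
        specs = tuple(TfSpec("activator", 1, 0.8) for _ in range(10))
        cfg = SimulationConfig(
            n_genes=1500, n_experiments=10, tf_specs=specs, mean_operon_len=1.0,
            inter_gap=(600, 1200), motif=MotifSpec(pwm, planting_fraction=1.0), seed=9,
        )
        ann, seqs, _, truth = simulate_genome(cfg)
        preds = predictions_from_truth(truth, motif_id=pwm.motif_id)
        omap = {g.locus_id: g.locus_id for g in ann.genes}
        propagated, details = propagate(preds, ann, seqs, {pwm.motif_id: pwm},
                                        ortholog_map=omap)
        assert len(details) == 10
        assert all(d["pvalue"] <= 0.05 for d in details)
        assert len(propagated) == 10
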