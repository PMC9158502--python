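import numpy as np
import pytest

from tetrasieve.ani_psg import DeltaAlignment, ani, psg
from tetrasieve.errors import InputError, ValidationError
from tetrasieve.fragment_signature import compute_zrf, divide_genome
from tetrasieve.sieve_engine import SieveRecord
from tetrasieve.synthetic_data import (
    SimPairSpec,
    benchmark,
    extract_pair,
    feasible_grid,
    simulate_genome,
)
from tetrasieve.tetra_core import encode, pccd, zvalues_from_codes


def spec(psg_pct, cq, cr=None, L=200_000, label="intraspecific", seed=0):
    return SimPairSpec(genome_length_bp=L, psg_target_pct=psg_pct,
                       completeness_q_pct=cq,
                       completeness_r_pct=cr if cr is not None else cq,
                       label=label, seed=seed)


class TestSimulateGenome:
    def test_deterministic_per_seed(self):
        a = simulate_genome(20_000, n_components=2, seed=4)
        b = simulate_genome(20_000, n_components=2, seed=4)
        assert a.concatenated() == b.concatenated()

    def test_seed_changes_sequence(self):
        a = simulate_genome(20_000, seed=4)
        b = simulate_genome(20_000, seed=5)
        assert a.concatenated() != b.concatenated()

    def test_requested_length_and_metadata(self):
        g = simulate_genome(33_000, seed=1)
        assert g.total_length_bp == 33_000
        assert len(g.concatenated()) == 33_000
        assert g.avg_seq_size_bp == 33_000

    def test_rejects_tiny_or_invalid(self):
        with pytest.raises(InputError):
            simulate_genome(5_000, seed=1)
        with pytest.raises(InputError):
            simulate_genome(20_000, n_components=0, seed=1)

    def test_single_component_fragment_pccds_tightly_clustered(self):
        # homogeneous generator: intragenomic fragment-vs-ZRF PCCDs have
        # small spread (measured over 20 replicate 1-Mb genomes)
        sds = []
        for seed in range(20):
            g = simulate_genome(1_000_000, n_components=1, seed=1000 + seed)
            codes = encode(g.concatenated())
            zs = [zvalues_from_codes(codes, s, e)
                  for s, e in divide_genome(g).windows]
            zrf = compute_zrf(zs)
            pccds = [pccd(z, zrf) for z in zs]
            sds.append(float(np.std(pccds)))
        assert max(sds) < 0.05

    def test_four_separated_components_reach_refragment_path(self, default_table):
        from tetrasieve.fragment_signature import build_signature
        hits = 0
        for seed in range(20):
            g = simulate_genome(400_000, n_components=4, seed=seed,
                                block_len_bp=100_000, concentration=0.2)
            if build_signature(g, default_table).refragmented_10kb:
                hits += 1
        assert hits >= 1


@pytest.fixture(scope="module")
def parent():
    return simulate_genome(200_000, n_components=2, seed=21)


class TestExtractPair:
    def test_full_completeness_full_psg_identity(self, parent):
        gq, gr, realized = extract_pair(parent, spec(100.0, 100.0))
        assert gq.concatenated() == parent.concatenated()
        assert gr.concatenated() == parent.concatenated()
        assert realized == 100.0

    def test_psg70_at_feasibility_bound_overlap(self, parent):
        # completeness 70 is the design's ceiling for PSG 70:
        # union = 0.7 L (2 - 0.7) = 0.91 L fits, and overlap is 0.7
        # of each extract
        gq, gr, realized = extract_pair(parent, spec(70.0, 70.0))
        assert realized == pytest.approx(70.0, abs=0.5)
        assert gq.total_length_bp == gr.total_length_bp == 140_000

    def test_full_completeness_psg_below_100_infeasible(self, parent):
        # two full-length extracts necessarily overlap completely, so
        # PSG < 100 at 100/100 completeness is rejected
        with pytest.raises(ValidationError, match="span"):
            extract_pair(parent, spec(70.0, 100.0))

    def test_low_completeness_high_psg_feasible(self, parent):
        gq, gr, realized = extract_pair(parent, spec(90.0, 10.0))
        assert gq.total_length_bp == 20_000
        assert realized == pytest.approx(90.0, abs=0.5)

    def test_extracts_are_substrings_of_parent(self, parent):
        gq, gr, _ = extract_pair(parent, spec(80.0, 30.0, seed=3))
        assert gq.concatenated() in parent.concatenated()
        assert gr.concatenated() in parent.concatenated()

    def test_infeasible_overlap_bound_named(self, parent):
        with pytest.raises(ValidationError, match="overlap"):
            extract_pair(parent, spec(100.0, 10.0, cr=30.0))

    def test_infeasible_union_bound_named(self, parent):
        with pytest.raises(ValidationError, match="span"):
            extract_pair(parent, spec(0.0, 100.0))

    def test_deterministic_per_seed(self, parent):
        a = extract_pair(parent, spec(80.0, 40.0, seed=9))
        b = extract_pair(parent, spec(80.0, 40.0, seed=9))
        assert a[0].concatenated() == b[0].concatenated()
        assert a[2] == b[2]

    def test_realized_psg_matches_alignment_formula_exactly(self, parent):
        # cross-module consistency: coordinate arithmetic == interval
        # union formula on the corresponding perfect alignment
        for p, c, seed in [(70.0, 50.0, 1), (90.0, 20.0, 2), (100.0, 100.0, 3)]:
            gq, gr, realized = extract_pair(parent, spec(p, c, seed=seed))
            l1, l2 = gq.total_length_bp, gr.total_length_bp
            o = round(realized * (l1 + l2) / 200.0)
            sq, sr = gq.concatenated(), gr.concatenated()
            if sq[l1 - o:] == sr[:o]:
                a = DeltaAlignment("r", "q", l2, l1, 1, o, l1 - o + 1, l1,
                                   0, 0, 0, ())
            else:
                assert sr[l2 - o:] == sq[:o]
                a = DeltaAlignment("r", "q", l2, l1, l2 - o + 1, l2, 1, o,
                                   0, 0, 0, ())
            assert ani([a]) == 100.0
            assert psg([a], l1, l2) == realized


class TestFeasibleGrid:
    def test_paper_design_grid(self):
        comps = [float(c) for c in range(10, 101, 10)]
        by_psg = {p: [c for q, c in feasible_grid([p], comps) if q == p]
                  for p in (70.0, 80.0, 90.0, 100.0)}
        assert by_psg[70.0] == [float(c) for c in range(10, 71, 10)]
        assert by_psg[80.0] == [float(c) for c in range(10, 81, 10)]
        assert by_psg[90.0] == [float(c) for c in range(10, 91, 10)]
        assert by_psg[100.0] == [float(c) for c in range(10, 101, 10)]


def rec(q, r, sieved=True, rescued=False):
    return SieveRecord(query_id=q, ref_id=r, pccd=0.9, gsc_p=0.5,
                       sieved=sieved, rescued=rescued)


class TestBenchmark:
    def test_perfect_sieve(self):
        truth = {("q1", "r1"): "intraspecific", ("q1", "r2"): "interspecific",
                 ("q2", "r2"): "intraspecific", ("q2", "r1"): "interspecific"}
        out = benchmark([rec("q1", "r1"), rec("q2", "r2")], truth)
        assert out["sensitivity_pct"] == 100.0
        assert out["specificity_pct"] == 100.0

    def test_three_of_four_sensitivity(self):
        truth = {(f"q{i}", f"r{i}"): "intraspecific" for i in range(4)}
        out = benchmark([rec(f"q{i}", f"r{i}") for i in range(3)], truth)
        assert out["sensitivity_pct"] == 75.0

    def test_rescued_records_count_as_sieved(self):
        truth = {("q", "r"): "intraspecific"}
        out = benchmark([rec("q", "r", rescued=True)], truth)
        assert out["sensitivity_pct"] == 100.0

    def test_unknown_pair_rejected(self):
        with pytest.raises(ValidationError):
            benchmark([rec("q", "rX")], {("q", "r"): "intraspecific"})

    def test_duplicate_truth_pair_rejected(self):
        with pytest.raises(ValidationError):
            benchmark([], [("q", "r", "intraspecific"), ("q", "r", "interspecific")])

    def test_confusion_matrix_oracle_on_seeded_400_pairs(self):
        rng = np.random.default_rng(33)
        truth = {}
        records = []
        for i in range(400):
            label = "intraspecific" if i < 20 else "interspecific"
            key = (f"q{i:03d}", f"r{i:03d}")
            truth[key] = label
            if rng.random() < (0.95 if label == "intraspecific" else 0.03):
                records.append(rec(*key))
        out = benchmark(records, truth)
        # independent recount
        tp = sum(1 for r in records if truth[(r.query_id, r.ref_id)] == "intraspecific")
        fp = len(records) - tp
        assert out["n_intra"] == 20 and out["n_inter"] == 380
        assert out["sensitivity_pct"] == pytest.approx(100.0 * tp / 20)
        assert out["specificity_pct"] == pytest.approx(100.0 * (380 - fp) / 380)
        assert out["sieved_fraction_pct"] == pytest.approx(100.0 * len(records) / 400)

    def test_permutation_invariant(self):
        truth = {(f"q{i}", f"r{i}"): ("intraspecific" if i % 3 == 0
                                      else "interspecific") for i in range(30)}
        records = [rec(f"q{i}", f"r{i}") for i in range(0, 30, 2)]
        assert benchmark(records, truth) == benchmark(records[::-1], truth)
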