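import numpy as np
import pandas as pd
import pytest

import picocult as pc
from picocult.crispr import Cas1Config, alignment_identity, _make_aligner, curate_cas1
from picocult.synthetic import generate_cas_locus_table


def locus_frame(subtype, genes, n_spacers, genome="g1", locus="g1_l1"):
    return pd.DataFrame(
        {
            "genome_id": genome,
            "locus_id": locus,
            "subtype": subtype,
            "gene_name": list(genes),
            "gene_quality": "high",
            "n_spacers_in_locus": n_spacers,
        }
    )


class TestLocusCompleteness:
    def test_complete_ie_locus(self):
        rows = locus_frame(
            "I-E",
            ["cas1", "cas2", "cas3", "cse1", "cse2", "cas7", "cas5", "cas6e"],
            12,
        )
        assert pc.locus_completeness(rows) == (True, True, False)

    def test_ig_locus_lacking_cas1_keeps_spacers(self):
        rows = locus_frame("I-G", ["cas2", "cas3", "csb", "cas7", "cas5"], 8)
        adapt, interf, cas1less = pc.locus_completeness(rows)
        assert adapt is False
        assert interf is True
        assert cas1less is True

    def test_ig_synonym_cas8u2(self):
        rows = locus_frame("I-G", ["cas1", "cas2", "cas3", "cas8u2", "cas7", "cas5"], 3)
        _, interf, _ = pc.locus_completeness(rows)
        assert interf is True

    def test_empty_rows(self):
        empty = locus_frame("I-E", [], 0)
        assert pc.locus_completeness(empty) == (False, False, False)

    def test_unknown_subtype_lists_known(self):
        rows = locus_frame("IX-Z", ["cas1"], 1)
        with pytest.raises(KeyError, match="I-E"):
            pc.locus_completeness(rows)

    def test_low_quality_genes_still_count(self):
        rows = locus_frame("III-B", ["cas1", "cas2", "cas10", "cmr1", "cmr3",
                                     "cmr4", "cmr5", "cmr6"], 5)
        rows["gene_quality"] = "low"
        assert pc.locus_completeness(rows) == (True, True, False)


class TestPrevalenceByGroup:
    def test_printed_percentages(self):
        loci, groups, _ = generate_cas_locus_table(170, 27, 11, seed=3)
        report = pc.prevalence_by_group(loci, groups).set_index("group")
        row = report.loc["freshwater"]
        assert row["n_genomes"] == 170
        assert row["n_with_system"] == 27
        assert row["percent_with_system"] == 15.9
        assert row["n_lacking_cas1"] == 11
        assert row["percent_lacking_cas1"] == 40.7

    def test_zero_positive_group(self):
        loci, groups, _ = generate_cas_locus_table(10, 5, 0, seed=1)
        groups = dict(groups)
        groups.update({f"m{i}": "marine" for i in range(8)})
        report = pc.prevalence_by_group(loci, groups).set_index("group")
        assert report.loc["marine", "percent_with_system"] == 0.0

    def test_planted_rates_recovered_exactly(self):
        for n, pos, d, seed in [(200, 31, 13, 5), (200, 50, 0, 6)]:
            loci, groups, truth = generate_cas_locus_table(n, pos, d, seed=seed)
            report = pc.prevalence_by_group(loci, groups).iloc[0]
            assert report["n_with_system"] == pos
            assert report["n_lacking_cas1"] == d
            assert report["fraction_with_system"] == pytest.approx(pos / n)

    def test_subtype_breakdown(self):
        loci, groups, truth = generate_cas_locus_table(30, 9, 0, seed=2)
        report = pc.prevalence_by_group(loci, groups).iloc[0]
        expected = pd.Series(
            [t["subtype"] for t in truth.values() if t["positive"]]
        ).value_counts().to_dict()
        assert report["subtype_counts"] == expected

    def test_unassigned_genome_errors(self):
        loci, groups, _ = generate_cas_locus_table(10, 3, 0, seed=1)
        groups = {g: grp for g, grp in groups.items() if g not in set(loci["genome_id"])}
        with pytest.raises(KeyError):
            pc.prevalence_by_group(loci, groups)


class TestCas1FilterHits:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["seq_id", "p_value", "length_aa"])

    def test_retained(self):
        hits = self.frame([("a", 0.005, 120)])
        assert pc.cas1_filter_hits(hits) == ["a"]

    def test_pvalue_boundary_strict(self):
        hits = self.frame([("a", 0.01, 120)])
        assert pc.cas1_filter_hits(hits) == []

    def test_length_boundary_strict(self):
        hits = self.frame([("a", 0.001, 80)])
        assert pc.cas1_filter_hits(hits) == []

    def test_negative_length_errors(self):
        with pytest.raises(ValueError):
            pc.cas1_filter_hits(self.frame([("a", 0.001, -5)]))

    def test_monotone_in_pvalue_threshold(self):
        rng = np.random.default_rng(1)
        hits = self.frame(
            [(f"s{i}", float(rng.uniform(0, 0.05)), int(rng.integers(60, 300)))
             for i in range(50)]
        )
        previous = None
        for cutoff in (0.02, 0.01, 0.005, 0.001):
            kept = set(pc.cas1_filter_hits(hits, Cas1Config(max_p_value=cutoff)))
            if previous is not None:
                assert kept <= previous
            previous = kept


class TestTopkNeighbors:
    def sim(self, rows):
        return pd.DataFrame(rows, columns=["query_id", "target_id", "score"])

    def test_fewer_than_k_returns_all(self):
        out = pc.topk_neighbors(self.sim([("q", "a", 1.0), ("q", "b", 0.5),
                                          ("q", "c", 0.2)]), k=10)
        assert set(out["q"]) == {"a", "b", "c"}

    def test_top_10_of_20(self):
        rows = [("q", f"t{i:02d}", float(i)) for i in range(20)]
        out = pc.topk_neighbors(self.sim(rows), k=10)
        assert out["q"] == [f"t{i:02d}" for i in range(19, 9, -1)]

    def test_tie_at_boundary_lexicographic(self):
        rows = [("q", "b", 1.0), ("q", "a", 1.0)]
        out = pc.topk_neighbors(self.sim(rows), k=1)
        assert out["q"] == ["a"]

    def test_k_below_one(self):
        with pytest.raises(ValueError):
            pc.topk_neighbors(self.sim([("q", "a", 1.0)]), k=0)


def nw_identity_oracle(a, b, gap_open=-11, gap_extend=-1):
    """Independent affine-gap Needleman-Wunsch, returning identity over
    columns between the first and last aligned pair (terminal gaps excluded).

    Pure-DP implementation used only as a test oracle for substitution-only
    pairs, where the optimal alignment is unambiguous and gapless.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 1.0 if a[i - 1] == b[j - 1] else 0.0
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    # traceback from the best terminal state
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    pairs = []
    while i > 0 or j > 0:
        if state == 0:
            prev = int(np.argmax([M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]))
            pairs.append((i - 1, j - 1))
            i, j, state = i - 1, j - 1, prev
        elif state == 1:
            state = 0 if M[i - 1, j] + gap_open >= X[i - 1, j] + gap_extend else 1
            i -= 1
        else:
            state = 0 if M[i, j - 1] + gap_open >= Y[i, j - 1] + gap_extend else 2
            j -= 1
    pairs.reverse()
    if not pairs:
        return 0.0
    matches = sum(1 for x, y in pairs if a[x] == b[y])
    # columns between first and last aligned pair, including internal gaps
    (i0, j0), (i1, j1) = pairs[0], pairs[-1]
    ncols = len(pairs) + ((i1 - i0 + 1) - len(pairs)) + ((j1 - j0 + 1) - len(pairs))
    return matches / ncols


def mutate_protein(seq, n_subs, seed):
    rng = np.random.default_rng(seed)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    out = list(seq)
    for p in rng.choice(len(seq), size=n_subs, replace=False):
        choices = [c for c in alphabet if c != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def random_protein(length, seed):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACDEFGHIKLMNPQRSTVWY"))[
        rng.integers(0, 20, size=length)
    ])


class TestAlignmentIdentity:
    def test_against_dp_oracle_on_substitution_pairs(self):
        aligner = _make_aligner(Cas1Config())
        base = random_protein(120, seed=1)
        for n_subs, seed in [(6, 2), (18, 3), (30, 4)]:
            other = mutate_protein(base, n_subs, seed)
            identity, cov_a, cov_b = alignment_identity(base, other, aligner)
            oracle = nw_identity_oracle(base, other)
            assert identity == pytest.approx(oracle)
            assert identity == pytest.approx(1 - n_subs / 120)
            assert cov_a == cov_b == 1.0

    def test_identical_sequences(self):
        aligner = _make_aligner(Cas1Config())
        seq = random_protein(80, seed=9)
        assert alignment_identity(seq, seq, aligner)[0] == 1.0


class TestGreedyCluster:
    def test_identical_pair_one_cluster(self):
        seq = random_protein(100, seed=1)
        out = pc.greedy_cluster({"a": seq, "b": seq})
        assert out["centroid_id"].nunique() == 1

    def test_85_percent_pair_two_clusters(self):
        base = random_protein(100, seed=2)
        other = mutate_protein(base, 15, seed=3)  # oracle identity 0.85
        assert nw_identity_oracle(base, other) == pytest.approx(0.85)
        out = pc.greedy_cluster({"a": base, "b": other})
        assert out["centroid_id"].nunique() == 2

    def test_95_pair_plus_singleton(self):
        base = random_protein(100, seed=4)
        close = mutate_protein(base, 5, seed=5)  # 0.95 >= 0.90 threshold
        unrelated = random_protein(100, seed=6)
        out = pc.greedy_cluster({"a": base, "b": close, "c": unrelated})
        assert out["centroid_id"].nunique() == 2
        by_id = out.set_index("seq_id")["centroid_id"]
        assert by_id["a"] == by_id["b"]
        assert by_id["c"] != by_id["a"]

    def test_identity_one_separates_distinct(self):
        base = random_protein(60, seed=7)
        other = mutate_protein(base, 1, seed=8)
        cfg = Cas1Config(cluster_identity=1.0)
        out = pc.greedy_cluster({"a": base, "b": other, "c": base}, cfg)
        by_id = out.set_index("seq_id")["centroid_id"]
        assert by_id["a"] == by_id["c"]
        assert by_id["b"] != by_id["a"]

    def test_tiny_identity_single_cluster(self):
        seqs = {f"s{i}": random_protein(100, seed=i) for i in range(4)}
        cfg = Cas1Config(cluster_identity=1e-6, cluster_coverage=0.5)
        out = pc.greedy_cluster(seqs, cfg)
        assert out["centroid_id"].nunique() == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pc.greedy_cluster({"a": ""})


class TestCurateCas1:
    def test_chain(self):
        base = random_protein(150, seed=11)
        near = mutate_protein(base, 3, seed=12)      # clusters with base
        distinct = random_protein(150, seed=13)       # own cluster
        short = random_protein(60, seed=14)           # fails length filter
        hits = pd.DataFrame(
            {
                "seq_id": ["base", "near", "distinct", "short"],
                "p_value": [1e-5, 1e-5, 1e-4, 1e-6],
                "length_aa": [150, 150, 150, 60],
            }
        )
        sims = pd.DataFrame(
            {
                "query_id": ["base"] * 3,
                "target_id": ["near", "distinct", "short"],
                "score": [0.9, 0.5, 0.4],
            }
        )
        seqs = {"base": base, "near": near, "distinct": distinct, "short": short}
        curated = curate_cas1(hits, sims, seqs)
        assert "short" not in curated
        assert set(curated) == {"base", "distinct"}
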