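import math

import numpy as np
import pytest

from tufkit import (
    DiscriminatingResidueReport,
    DomainDefinition,
    EFTU_DOMAINS,
    FamilySimParams,
    LabeledAlignment,
    ProteinSequence,
    SequenceError,
    codon_adaptation_index,
    find_discriminating_residues,
    normalize_divergence,
    pairwise_identity,
    partition_by_domain,
    patristic_distance,
    poisson_distance,
    simulate_homolog_family,
)


class TestPairwiseIdentity:
    def test_identical_sequences_are_100_percent(self):
        s = ProteinSequence("a", "MSKEKFERTKPHVNVGTIGHVDHGKT" * 15)
        pct, _ = pairwise_identity(s, ProteinSequence("b", s.residues))
        assert pct == pytest.approx(100.0)

    def test_single_substitution_in_ten_residues(self):
        a = ProteinSequence("a", "MSKEKFERTK")
        b = ProteinSequence("b", "MSKEKFARTK")
        pct, (ra, rb) = pairwise_identity(a, b)
        assert "-" not in ra and "-" not in rb
        assert pct == pytest.approx(90.0)

    def test_symmetry(self):
        a = ProteinSequence("a", "MSKEKFERTKPHVNVGTIGH")
        b = ProteinSequence("b", "MSKDKFERTKPHVNVGH")
        assert pairwise_identity(a, b)[0] == pytest.approx(pairwise_identity(b, a)[0])

    def test_identity_uses_full_alignment_length(self):
        # 8 identical residues, 4-residue insertion: 8/12 = 66.7%
        a = ProteinSequence("a", "MSKEKFER")
        b = ProteinSequence("b", "MSKEWWWWKFER")
        pct, (ra, rb) = pairwise_identity(a, b)
        assert len(ra) == 12
        assert pct == pytest.approx(100.0 * 8 / 12, abs=0.1)

    def test_empty_sequence_rejected(self):
        with pytest.raises(SequenceError):
            pairwise_identity(ProteinSequence("a", "---"), ProteinSequence("b", "MSK"))


class TestPoissonDistance:
    def test_identical_rows_have_zero_distance(self):
        est = poisson_distance("ACDEF", "ACDEF")
        assert est.p_distance == 0.0 and est.poisson_d == 0.0

    def test_closed_form_at_p_ten_percent(self):
        est = poisson_distance("A" * 10, "C" + "A" * 9)
        assert est.p_distance == pytest.approx(0.1)
        assert est.poisson_d == pytest.approx(0.105361, abs=1e-6)

    def test_gap_columns_eliminated(self):
        est = poisson_distance("AC-EF", "ACD-F")
        assert est.positions_used == 3          # columns 1, 2, 5

    def test_saturated_pair_flagged_infinite(self):
        est = poisson_distance("AAAA", "CCCC")
        assert math.isinf(est.poisson_d)

    def test_all_gap_columns_rejected(self):
        with pytest.raises(SequenceError):
            poisson_distance("--", "AA")

    def test_correction_never_below_p_distance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n, k = 50, int(rng.integers(0, 40))
            b = "A" * (n - k) + "C" * k
            est = poisson_distance("A" * n, b)
            assert est.poisson_d >= est.p_distance
            if est.p_distance > 0:
                assert est.poisson_d > est.p_distance

    def test_monte_carlo_estimates_unbiased(self):
        """-ln(1-p̂) against the generator's Poisson process, 3 true distances."""
        for d_true in (0.05, 0.2, 0.5):
            ests = []
            for seed in range(200):
                fam = simulate_homolog_family(
                    FamilySimParams(n_viable=1, n_nonviable=0, target_distances=[d_true],
                                    n_planted_columns=0, seed=seed)
                )
                ests.append(
                    poisson_distance(fam.ancestor, fam.alignment.sequences[0]).poisson_d
                )
            se = np.std(ests, ddof=1) / math.sqrt(len(ests))
            assert abs(np.mean(ests) - d_true) < 3 * se


class TestPatristic:
    def test_cherry_distance_is_branch_sum(self):
        assert patristic_distance("(A:0.1,B:0.2);", "A", "B") == pytest.approx(0.3)

    def test_leaf_to_itself_is_zero(self):
        assert patristic_distance("(A:0.1,B:0.2);", "A", "A") == 0.0

    def test_missing_leaf_rejected(self):
        with pytest.raises(SequenceError, match="not found"):
            patristic_distance("(A:0.1,B:0.2);", "A", "Z")

    def test_matches_independent_path_sum_on_random_trees(self):
        # random binary trees built by hand; oracle sums root paths minus
        # twice the shared-ancestor prefix, never touching the tested code path
        rng = np.random.default_rng(11)

        def build(leaves):
            if len(leaves) == 1:
                return leaves[0]
            k = int(rng.integers(1, len(leaves)))
            return (build(leaves[:k]), build(leaves[k:]), float(rng.uniform(0.01, 1.0)),
                    float(rng.uniform(0.01, 1.0)))

        def newick(node):
            if isinstance(node, str):
                return node
            l, r, bl, br = node
            return f"({newick(l)}:{bl:.6f},{newick(r)}:{br:.6f})"

        def root_paths(node, acc, out):
            if isinstance(node, str):
                out[node] = acc
                return
            l, r, bl, br = node
            root_paths(l, acc + [bl], out)
            root_paths(r, acc + [br], out)

        for _ in range(5):
            leaves = [f"T{i}" for i in range(12)]
            tree = build(leaves)
            paths: dict[str, list[float]] = {}
            root_paths(tree, [], paths)
            a, b = "T0", "T5"
            pa, pb = paths[a], paths[b]
            shared = 0
            for x, y in zip(pa, pb):
                if x == y:
                    shared += 1
                else:
                    break
            expected = sum(pa[shared:]) + sum(pb[shared:])
            assert patristic_distance(newick(tree) + ";", a, b) == pytest.approx(
                expected, rel=1e-6
            )


class TestNormalize:
    def test_max_maps_to_one_and_order_preserved(self):
        out = normalize_divergence({"a": 0.0, "b": 0.5, "c": 1.0})
        assert out == {"a": 0.0, "b": 0.5, "c": 1.0}
        out2 = normalize_divergence({"a": 0.2, "b": 0.6, "c": 0.3})
        assert max(out2.values()) == pytest.approx(1.0)
        assert sorted(out2, key=out2.get) == ["a", "c", "b"]

    def test_all_zero_rejected(self):
        with pytest.raises(SequenceError):
            normalize_divergence({"a": 0.0})


class TestDiscriminatingResidues:
    def test_planted_toy_column_reported(self, toy_alignment):
        report = find_discriminating_residues(toy_alignment)
        assert report.columns == [3]
        assert report.reference_positions == [3]

    def test_column_varying_within_viable_set_excluded(self, toy_alignment):
        # column 5 differs between v1 (F) and v2 (G)
        assert 5 not in find_discriminating_residues(toy_alignment).columns

    def test_gap_in_viable_disqualifies_gap_in_nonviable_differs(self):
        aln = LabeledAlignment(
            sequences=[ProteinSequence("v1", "A-C"), ProteinSequence("v2", "AAC"),
                       ProteinSequence("n1", "AA-")],
            labels=["viable", "viable", "nonviable"],
        )
        # col 2: viable gap -> disqualified; col 3: nonviable gap counts as differing
        assert find_discriminating_residues(aln).columns == [3]

    def test_invariant_under_row_reordering_and_viable_duplication(self, toy_alignment):
        base = find_discriminating_residues(toy_alignment).columns
        seqs = toy_alignment.sequences
        labs = toy_alignment.labels
        order = [3, 1, 4, 0, 2]
        shuffled = LabeledAlignment([seqs[i] for i in order], [labs[i] for i in order])
        assert find_discriminating_residues(shuffled).columns == base
        dup = LabeledAlignment(
            seqs + [ProteinSequence("v1b", seqs[1].residues)], labs + ["viable"]
        )
        assert find_discriminating_residues(dup).columns == base

    def test_reference_positions_skip_reference_gaps(self):
        aln = LabeledAlignment(
            sequences=[ProteinSequence("ref", "A-CD"), ProteinSequence("v", "A-CD"),
                       ProteinSequence("n", "A-CE")],
            labels=["reference", "viable", "nonviable"],
        )
        report = find_discriminating_residues(aln)
        assert report.columns == [4]
        assert report.reference_positions == [3]   # ungapped reference coordinate

    def test_requires_both_label_groups(self, toy_alignment):
        viable_only = LabeledAlignment(toy_alignment.sequences[:3],
                                       toy_alignment.labels[:3])
        with pytest.raises(SequenceError):
            find_discriminating_residues(viable_only)

    def test_planted_families_recovered_exactly(self):
        """Generator ground truth equals filter output and a brute-force scan."""
        for seed in range(10):
            fam = simulate_homolog_family(
                FamilySimParams(n_viable=5, n_nonviable=12, n_planted_columns=12,
                                target_distances=[0.05] * 5 + [0.3] * 12, seed=seed)
            )
            report = find_discriminating_residues(fam.alignment)
            assert report.columns == fam.planted_columns

            # independent brute-force column scan
            viable = [s.residues for s, lab in zip(fam.alignment.sequences,
                                                   fam.alignment.labels) if lab == "viable"]
            nonviable = [s.residues for s, lab in zip(fam.alignment.sequences,
                                                      fam.alignment.labels) if lab == "nonviable"]
            brute = [
                c + 1
                for c in range(len(viable[0]))
                if len({v[c] for v in viable}) == 1
                and any(n[c] != viable[0][c] for n in nonviable)
            ]
            assert report.columns == brute


class TestDomains:
    def test_one_position_per_domain(self):
        report = DiscriminatingResidueReport(columns=[10, 250, 350],
                                             reference_positions=[10, 250, 350])
        counts = partition_by_domain(report, EFTU_DOMAINS)
        assert counts == {"G-domain": 1, "domain2": 1, "domain3": 1}

    def test_empty_report_gives_zeros(self):
        counts = partition_by_domain(
            DiscriminatingResidueReport(columns=[], reference_positions=[]), EFTU_DOMAINS
        )
        assert counts == {"G-domain": 0, "domain2": 0, "domain3": 0}

    def test_counts_conserved_and_outside_tallied(self):
        positions = [1, 200, 201, 299, 300, 393]
        report = DiscriminatingResidueReport(columns=positions,
                                             reference_positions=positions)
        counts = partition_by_domain(report, EFTU_DOMAINS)
        assert sum(counts.values()) == len(positions)

    def test_overlapping_domains_rejected(self):
        with pytest.raises(SequenceError, match="overlap"):
            partition_by_domain(
                DiscriminatingResidueReport(columns=[], reference_positions=[]),
                [DomainDefinition("a", 1, 100), DomainDefinition("b", 100, 200)],
            )


class TestCai:
    WEIGHTS = {"AAA": 1.0, "AAG": 0.25, "GGT": 1.0, "GGC": 0.5, "TTT": 0.3}

    def test_maximal_codons_give_one(self):
        res = codon_adaptation_index("AAAGGT" * 3, self.WEIGHTS)
        assert res.cai == pytest.approx(1.0)

    def test_constant_weight_is_geometric_mean(self):
        res = codon_adaptation_index("GGC" * 5, self.WEIGHTS)
        assert res.cai == pytest.approx(0.5)

    def test_met_trp_and_stops_excluded(self):
        res = codon_adaptation_index("ATGAAATGGTAA", self.WEIGHTS)
        assert res.codons_used == 1
        assert res.cai == pytest.approx(1.0)

    def test_matches_direct_product_oracle(self):
        rng = np.random.default_rng(5)
        codons = list(self.WEIGHTS)
        gene = "".join(rng.choice(codons) for _ in range(40))
        res = codon_adaptation_index(gene, self.WEIGHTS)
        prod = 1.0
        for i in range(0, len(gene), 3):
            prod *= self.WEIGHTS[gene[i:i+3]]
        assert res.cai == pytest.approx(prod ** (1.0 / res.codons_used), rel=1e-12)

    @pytest.mark.parametrize("cds,err", [
        ("AAAA", "multiple of 3"),
        ("AAANNN", "invalid codon"),
        ("AAACCC", "no weight"),
    ])
    def test_invalid_input_rejected(self, cds, err):
        with pytest.raises(SequenceError, match=err):
            codon_adaptation_index(cds, self.WEIGHTS)

    def test_zero_weight_rejected(self):
        with pytest.raises(SequenceError, match="weight"):
            codon_adaptation_index("AAA", {"AAA": 0.0})
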