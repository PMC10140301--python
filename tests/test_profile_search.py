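import math

import numpy as np
import pytest

from ssnmine.profile_search import (
    ArchitectureRule,
    assign_architecture,
    best_local_score,
    build_profile,
    calibrate_evalue,
    confirm_cluster_members,
    parse_domtblout,
    random_background_sequence,
    retrieve_family,
    search_profile,
    star_align,
)
from ssnmine.sequence_io import AMINO_ACIDS, SequenceRecord

from _oracles import brute_force_profile_score
from conftest import make_record, random_protein


class TestBuildProfile:
    def test_consensus_of_identical_sequences(self):
        profile = build_profile(["MKV"] * 4)
        assert profile.model_length == 3
        assert profile.consensus() == "MKV"

    def test_symmetric_counts_give_equal_scores_under_background_prior(self):
        profile = build_profile(
            ["AAAA", "AAAA", "GGGG", "GGGG"],
            pseudocount_weight=1.0,
            prior="background",
        )
        a, g = AMINO_ACIDS.index("A"), AMINO_ACIDS.index("G")
        assert np.allclose(profile.match_scores[:, a], profile.match_scores[:, g])

    def test_scores_match_hand_computed_log_odds(self):
        # two columns over 3 sequences: column 0 = {M, M, K}, column 1 = {V, V, V}
        profile = build_profile(
            ["MV", "MV", "KV"], pseudocount_weight=1.0, prior="background"
        )
        bg = 1.0 / 20.0

        def expected(count: int, total: int = 3) -> float:
            return 2.0 * (math.log2((count + 1.0 * bg) / (total + 1.0)) - math.log2(bg))

        m, k, v = (AMINO_ACIDS.index(x) for x in "MKV")
        assert profile.match_scores[0, m] == pytest.approx(expected(2))
        assert profile.match_scores[0, k] == pytest.approx(expected(1))
        assert profile.match_scores[1, v] == pytest.approx(expected(3))
        assert profile.match_scores[1, m] == pytest.approx(expected(0))

    def test_majority_gap_columns_are_excluded(self):
        profile = build_profile(["M-V", "M-V", "MKV", "M--"])
        assert profile.model_length == 2  # middle column is 75% gaps; last 25%

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_profile(["MKV"])

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(ValueError):
            build_profile(["--", "--"])


class TestCalibration:
    def test_lambda_positive_and_deterministic(self, small_profile):
        assert small_profile.lam > 0 and math.isfinite(small_profile.lam)
        again = calibrate_evalue(
            build_profile(["MKVLG" * 8] * 3, name="x"),
            decoy_count=120,
            decoy_length=150,
            seed=4,
        )
        twice = calibrate_evalue(
            build_profile(["MKVLG" * 8] * 3, name="x"),
            decoy_count=120,
            decoy_length=150,
            seed=4,
        )
        assert (again.lam, again.log_k) == (twice.lam, twice.log_k)

    def test_too_few_decoys_rejected(self, small_profile):
        with pytest.raises(ValueError):
            calibrate_evalue(small_profile, decoy_count=50)

    def test_mean_decoy_hit_count_near_one(self, small_profile):
        """By the definition of the E-value, a fresh random database should
        yield about one hit with E <= 1 on average."""
        rng = np.random.default_rng(77)
        n, length = 400, 200
        total = n * length
        counts = []
        for _ in range(5):
            hits = 0
            for _ in range(n):
                decoy = random_background_sequence(rng, length)
                bits = best_local_score(small_profile, decoy) / 2.0
                hits += small_profile.e_value(bits, total) <= 1.0
            counts.append(hits)
        assert 1 / 3 <= np.mean(counts) <= 3


class TestSearchProfile:
    def test_consensus_target_gets_full_coverage_and_max_score(self, small_profile):
        target = make_record("cons", small_profile.consensus())
        hits = search_profile(small_profile, target)
        assert hits[0].profile_coverage == 1.0
        # no other target of the same length can score higher
        assert hits[0].bit_score * 2 == pytest.approx(
            float(small_profile.match_scores.max(axis=1).sum()), rel=1e-9
        )

    def test_score_matches_brute_force_on_tiny_instances(self, rng):
        """DP local score equals exhaustive enumeration for model_length <= 4
        and targets <= 8 residues."""
        checked = 0
        while checked < 40:
            width = int(rng.integers(1, 5))
            rows = [random_protein(rng, width, start_met=False) for _ in range(3)]
            try:
                profile = build_profile(rows)
            except ValueError:
                continue
            target = random_protein(rng, int(rng.integers(1, 9)), start_met=False)
            assert best_local_score(profile, target) == pytest.approx(
                brute_force_profile_score(profile, target), abs=1e-6
            )
            checked += 1

    def test_local_score_invariant_under_flanking_residues(self, small_profile, rng):
        core = small_profile.consensus()
        flank_left = random_protein(rng, 30, start_met=False)
        flank_right = random_protein(rng, 25, start_met=False)
        bare = search_profile(small_profile, make_record("a", core))[0]
        flanked = search_profile(
            small_profile, make_record("b", flank_left + core + flank_right)
        )[0]
        assert flanked.bit_score >= bare.bit_score  # flanks can only add
        assert flanked.bit_score == pytest.approx(bare.bit_score, rel=0.05)
        start, end = flanked.target_envelope
        assert start >= len(flank_left) - 5 and end <= len(flank_left) + len(core) + 5

    def test_short_record_yields_no_hits(self, small_profile):
        assert search_profile(small_profile, make_record("s", "MKVLGHP")) == []

    def test_random_background_rarely_significant_at_single_sequence_scale(
        self, small_profile
    ):
        rng = np.random.default_rng(123)
        insignificant = 0
        for i in range(20):
            rec = make_record(f"d{i}", random_background_sequence(rng, 500))
            hits = search_profile(small_profile, rec, db_residues=500)
            if not hits or hits[0].e_value >= 0.01:
                insignificant += 1
        assert insignificant >= 19  # >= 95% of trials


class TestRetrieveFamily:
    def test_planted_family_fully_retrieved_and_decoys_rare(
        self, small_benchmark, small_profile
    ):
        _, records, truth, _ = small_benchmark
        retrieval = retrieve_family(small_profile, records)
        got = {r.id for r in retrieval.records}
        fam0_full = {
            rec.id
            for rec in records
            if truth[rec.id].family == 0
            and not truth[rec.id].is_novel_cluster
            and not truth[rec.id].is_partial
        }
        assert fam0_full <= got
        decoys_in = sum(1 for i in got if i.startswith("decoy"))
        assert decoys_in <= 3  # consistent with a permissive E < 1 cutoff

    def test_zero_threshold_retrieves_nothing(self, small_benchmark, small_profile):
        _, records, _, _ = small_benchmark
        assert retrieve_family(small_profile, records, e_inclusion=0.0).entries == []

    def test_monotone_in_inclusion_threshold_and_counts_consistent(
        self, small_benchmark, small_profile
    ):
        _, records, _, _ = small_benchmark
        loose = retrieve_family(small_profile, records, e_inclusion=1.0)
        strict = retrieve_family(small_profile, records, e_inclusion=1e-3)
        loose_ids = {r.id for r in loose.records}
        strict_ids = {r.id for r in strict.records}
        assert strict_ids <= loose_ids
        # reported count equals a direct recount of the hit table
        assert loose.counts[small_profile.name] == len(loose.entries)


def _hit(profile_name, e=0.5):
    from ssnmine.profile_search import DomainHit

    return DomainHit(
        target_id="x",
        profile_name=profile_name,
        bit_score=30.0,
        e_value=e,
        target_envelope=(0, 50),
        profile_coverage=0.9,
    )


class TestArchitecture:
    LIGASE_RULES = [
        ArchitectureRule("LigB", frozenset({"DNA_ligase_A_M", "DNA_ligase_A_N"})),
        ArchitectureRule(
            "LigD",
            frozenset({"DNA_ligase_A_M", "LigD_N"}),
            optional=frozenset({"PrimaseS"}),
        ),
        ArchitectureRule("LigD", frozenset({"DNA_ligase_A_M", "PrimaseS"})),
        ArchitectureRule("ATP_ligase_core", frozenset({"DNA_ligase_A_M"})),
    ]

    def test_ligase_subclassing(self):
        hits = {
            "r1": [_hit("DNA_ligase_A_M"), _hit("LigD_N")],
            "r2": [_hit("DNA_ligase_A_M")],
            "r3": [],
            "r4": [_hit("DNA_ligase_A_M"), _hit("DNA_ligase_A_N")],
        }
        labels = assign_architecture(hits, self.LIGASE_RULES)
        assert labels == {
            "r1": "LigD",
            "r2": "ATP_ligase_core",
            "r3": "unassigned",
            "r4": "LigB",
        }

    def test_hits_above_threshold_are_ignored(self):
        hits = {"r": [_hit("DNA_ligase_A_M"), _hit("LigD_N", e=5.0)]}
        labels = assign_architecture(hits, self.LIGASE_RULES)
        assert labels["r"] == "ATP_ligase_core"

    def test_forbidden_domain_blocks_match(self):
        rules = [
            ArchitectureRule(
                "pure_core",
                frozenset({"DNA_ligase_A_M"}),
                forbidden=frozenset({"LigD_N"}),
            )
        ]
        hits = {"r": [_hit("DNA_ligase_A_M"), _hit("LigD_N")]}
        assert assign_architecture(hits, rules)["r"] == "unassigned"

    def test_duplicate_rule_sets_rejected(self):
        rules = [
            ArchitectureRule("a", frozenset({"X"})),
            ArchitectureRule("b", frozenset({"X"})),
        ]
        with pytest.raises(ValueError):
            assign_architecture({}, rules)

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError):
            ArchitectureRule("a", frozenset({"X"}), optional=frozenset({"X"}))


class TestConfirmClusterMembers:
    def test_planted_members_kept_and_confounders_named(self, small_benchmark):
        config, records, truth, seed_alignments = small_benchmark
        fam0 = build_profile(seed_alignments[0], name="family0")
        fam1 = build_profile(seed_alignments[1], name="family1")
        library = [fam0, fam1]
        cluster = [
            r
            for r in records
            if truth[r.id].family == 0 and not truth[r.id].is_partial
        ][:6]
        confounders = [
            r
            for r in records
            if truth[r.id].family == 1 and not truth[r.id].is_partial
        ][:4]
        kept, rejected = confirm_cluster_members(cluster + confounders, library, "family0")
        assert {r.id for r in kept} == {r.id for r in cluster}
        assert {r.id for r, _ in rejected} == {r.id for r in confounders}
        assert all(name == "family1" for _, name in rejected)

    def test_empty_cluster(self, small_profile):
        assert confirm_cluster_members([], [small_profile], small_profile.name) == ([], [])


class TestDomtbloutParser:
    TABLE = """\
# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target
#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- -----------------
seq1                 -            300 NucS                 PF01939.2    220   3.2e-40  135.1   0.1   1   1   1.1e-42   4.5e-40  134.2   0.1     5   210    12   230    10   233 0.95 hypothetical
seq2                 -            180 NucS                 PF01939.2    220      0.89   12.4   0.0   1   2      0.01      0.95   11.1   0.0    40   120    30   115    28   118 0.80 hypothetical
"""

    def test_columns_consumed(self, tmp_path):
        path = tmp_path / "t.domtblout"
        path.write_text(self.TABLE)
        hits = parse_domtblout(path)
        assert len(hits) == 2
        first = hits[0]
        assert first.target_id == "seq1" and first.profile_name == "NucS"
        assert first.e_value == pytest.approx(3.2e-40)
        assert first.target_envelope == (9, 233)  # env 10..233, 1-based inclusive
        assert first.profile_coverage == pytest.approx((210 - 5 + 1) / 220)

    def test_domain_evalue_selectable(self, tmp_path):
        path = tmp_path / "t.domtblout"
        path.write_text(self.TABLE)
        hits = parse_domtblout(path, e_value_column="domain_i")
        assert hits[1].e_value == pytest.approx(0.95)

    def test_unknown_column_choice_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            parse_domtblout(tmp_path / "x", e_value_column="bogus")


class TestStarAlign:
    def test_rows_projected_onto_longest(self):
        rows = star_align(["MKVLGHPWE", "KVLGHP", "MKVLGHPW"])
        assert all(len(r) == 9 for r in rows)
        assert rows[0] == "MKVLGHPWE"
        assert "KVLGHP" in rows[1].replace("-", "")

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            star_align(["MKV"])
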