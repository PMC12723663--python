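"""Core propagation engine: scores, blocks, repair, oracle equivalence."""

import copy

import numpy as np
import pytest

from hapweave import (
    consensus_sites,
    mate_pair_repair,
    pair_score,
    phase_scores,
    run_phasing,
    site_weight,
)
from hapweave.phase_engine import H1, H2, PhaseState
from hapweave.variant_io import A_ALLELE, B_ALLELE

from .oracles import (
    blocks_match_truth,
    exhaustive_min_disagreement,
    make_obs,
    make_sites,
    pairwise_disagreement,
    random_conflict_free_instance,
)


def weights_of(sites):
    return [s.weight for s in sites]


class TestSiteWeight:
    @pytest.mark.parametrize(
        "alleles,expected",
        [
            (("C", "T"), 2),  # SNV
            (("A", "AT"), 1),  # short insertion
            (("A" * 51, "A"), 1),  # long deletion: any non-SNV class is weight 1
        ],
    )
    def test_weight_by_site_class(self, alleles, expected):
        (site,) = make_sites([alleles])
        assert site_weight(site) == expected


class TestPairScore:
    def test_weighted_agreement_arithmetic(self):
        """Two agreeing SNVs and one disagreeing indel: 2 + 2 - 1 = 3."""
        sites = make_sites([("C", "T"), ("G", "A"), ("A", "AT")])
        r = make_obs("r", {0: A_ALLELE, 1: B_ALLELE, 2: A_ALLELE})
        k = make_obs("k", {0: A_ALLELE, 1: B_ALLELE, 2: B_ALLELE})
        assert pair_score(r, k, weights_of(sites)) == 3

    def test_identical_observations_score_total_weight(self):
        sites = make_sites([("C", "T"), ("A", "AT"), ("G", "A")])
        r = make_obs("r", {0: 0, 1: 1, 2: 0})
        assert pair_score(r, r, weights_of(sites)) == 2 + 1 + 2

    def test_disjoint_site_sets_score_zero(self):
        sites = make_sites([("C", "T")] * 4)
        r = make_obs("r", {0: 0, 1: 0})
        k = make_obs("k", {2: 0, 3: 0})
        assert pair_score(r, k, weights_of(sites)) == 0


class TestPhaseScores:
    def test_single_h1_neighbour_perfect_agreement(self):
        sites = make_sites([("C", "T")] * 3)
        r = make_obs("r", {0: 0, 1: 0, 2: 0})
        k = make_obs("k", {0: 0, 1: 0, 2: 0})
        state = PhaseState(assignment={"k/1": H1})
        assert phase_scores(r, state, [k], weights_of(sites)) == (6, 0)

    def test_no_assigned_overlaps(self):
        sites = make_sites([("C", "T")])
        r = make_obs("r", {0: 0})
        assert phase_scores(r, PhaseState(), [], weights_of(sites)) == (0, 0)

    def test_label_swap_symmetry(self):
        sites = make_sites([("C", "T")] * 3)
        r = make_obs("r", {0: 0, 1: 0, 2: 1})
        ks = [make_obs(f"k{i}", {i: 0}) for i in range(3)]
        fwd = PhaseState(assignment={"k0/1": H1, "k1/1": H1, "k2/1": H2})
        rev = PhaseState(assignment={"k0/1": H2, "k1/1": H2, "k2/1": H1})
        p1, p2 = phase_scores(r, fwd, ks, weights_of(sites))
        q1, q2 = phase_scores(r, rev, ks, weights_of(sites))
        assert (p1, p2) == (q2, q1)


class TestRunPhasing:
    def test_chained_reads_form_one_block(self):
        """Three error-free reads chained over four SNVs: one consistent block."""
        sites = make_sites([("C", "T")] * 4)
        truth = [0, 1, 0, 1]
        obs = [
            make_obs("r0", {0: truth[0], 1: truth[1]}, start=0),
            make_obs("r1", {1: 1 - truth[1], 2: 1 - truth[2]}, start=1),
            make_obs("r2", {2: truth[2], 3: truth[3]}, start=2),
        ]
        state, blocks = run_phasing(obs, sites)
        assert len(blocks) == 1
        assert blocks[0].n_sites == 4
        assert blocks_match_truth(blocks, truth)
        assert state.assignment["r1/1"] != state.assignment["r0/1"]

    def test_disconnected_read_sets_form_two_blocks(self):
        sites = make_sites([("C", "T")] * 4)
        obs = [
            make_obs("a0", {0: 0, 1: 0}, start=0),
            make_obs("a1", {0: 0, 1: 0}, start=0),
            make_obs("b0", {2: 1, 3: 0}, start=2),
            make_obs("b1", {2: 1, 3: 0}, start=2),
        ]
        state, blocks = run_phasing(obs, sites)
        assert len(blocks) == 2
        assert {b.block_id for b in blocks} == {sites[0].pos, sites[2].pos}

    def test_empty_input(self):
        state, blocks = run_phasing([], [])
        assert blocks == [] and state.assignment == {}

    def test_determinism(self):
        rng = np.random.default_rng(5)
        sites, truth, obs = random_conflict_free_instance(rng)
        s1, b1 = run_phasing(obs, sites)
        s2, b2 = run_phasing(obs, sites)
        assert s1.assignment == s2.assignment and b1 == b2

    def test_noisy_read_outvoted_matches_exhaustive_oracle(self):
        """One noisy read among ten cannot flip the consensus orientation."""
        sites = make_sites([("C", "T")] * 6)
        truth = [0, 1, 1, 0, 0, 1]
        obs = []
        for i in range(9):
            lo = i % 3
            calls = {si: truth[si] if i % 2 == 0 else 1 - truth[si] for si in range(lo, lo + 4)}
            obs.append(make_obs(f"r{i}", calls, start=lo))
        # the noisy read disagrees with truth at exactly one site
        noisy = {si: truth[si] for si in range(6)}
        noisy[3] = 1 - noisy[3]
        obs.append(make_obs("r9", noisy, start=0))
        obs.sort(key=lambda o: (o.start, o.read_key))
        state, blocks = run_phasing(obs, sites)
        w = weights_of(sites)
        labels = [0 if state.assignment[o.read_key] == H1 else 1 for o in obs]
        assert pairwise_disagreement(labels, obs, w) == exhaustive_min_disagreement(obs, w)
        assert blocks_match_truth(blocks, truth)

    @pytest.mark.parametrize("seed", range(6))
    def test_vectorized_oracle_agrees_with_plain_enumeration(self, seed):
        """The matrix form of the exhaustive oracle equals the definitional loop."""
        from itertools import product

        rng = np.random.default_rng(300 + seed)
        sites, _, obs = random_conflict_free_instance(rng)
        obs = obs[:6]  # keep the plain 2^n loop cheap
        # scatter noise so the minimum is not trivially zero
        noisy = []
        for ob in obs:
            calls = dict(ob.obs)
            for si in calls:
                if rng.random() < 0.3:
                    calls[si] = 1 - calls[si]
            noisy.append(make_obs(ob.qname, calls, start=ob.start))
        w = weights_of(sites)
        plain = min(
            pairwise_disagreement(labels, noisy, w)
            for labels in product((0, 1), repeat=len(noisy))
        )
        assert exhaustive_min_disagreement(noisy, w) == plain

    @pytest.mark.parametrize("seed", range(8))
    def test_conflict_free_instances_match_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        sites, truth, obs = random_conflict_free_instance(rng)
        state, blocks = run_phasing(obs, sites)
        w = weights_of(sites)
        labels = [0 if state.assignment[o.read_key] == H1 else 1 for o in obs]
        assert pairwise_disagreement(labels, obs, w) == 0
        assert exhaustive_min_disagreement(obs, w) == 0
        assert blocks_match_truth(blocks, truth)

    def test_label_symmetry_at_seed(self):
        """Flipping every read label yields identical blocks with flipped orientations."""
        rng = np.random.default_rng(77)
        sites, truth, obs = random_conflict_free_instance(rng)
        state, blocks = run_phasing(obs, sites)
        flipped_state = PhaseState(
            assignment={k: (H2 if v == H1 else H1) for k, v in state.assignment.items()},
            comp_of=dict(state.comp_of),
        )
        flipped_blocks = consensus_sites(flipped_state, obs, sites)
        assert [b.block_id for b in flipped_blocks] == [b.block_id for b in blocks]
        for fb, b in zip(flipped_blocks, blocks):
            assert fb.site_orientation == b.flipped().site_orientation

    def test_adding_error_free_read_never_splits_or_flips(self):
        rng = np.random.default_rng(13)
        sites, truth, obs = random_conflict_free_instance(rng)
        _, before = run_phasing(obs, sites)
        extra_calls = {si: int(truth[si]) for si in range(len(sites))}
        extended = sorted(
            obs + [make_obs("zzz_extra", extra_calls, start=0)],
            key=lambda o: (o.start, o.read_key),
        )
        _, after = run_phasing(extended, sites)
        assert len(after) <= len(before)
        before_orient = {si: c for b in before for si, c in b.site_orientation}
        for b in after:
            flips = {before_orient[si] == c for si, c in b.site_orientation if si in before_orient}
            # within any old block the relation to the new orientation is constant
            assert len(flips) <= 1 or all(flips) or not any(flips)

    def test_site_conservation(self, long_read_run):
        """Phased + unphased sites account for every unflagged het site."""
        sites = long_read_run["sites"]
        phased = set()
        for b in long_read_run["blocks"]:
            for si, _ in b.site_orientation:
                assert si not in phased, "site in two blocks"
                phased.add(si)
        unflagged = {s.site_index for s in sites if not s.qual_flagged}
        assert phased <= unflagged


class TestMatePairRepair:
    def test_discordant_pair_flipped_to_larger_margin(self):
        """A pair split by one erroneous overlap is reunited on the better-supported side."""
        sites = make_sites([("C", "T")] * 4)
        # clean haplotype-1 scaffold over sites 0-1
        scaffold = [make_obs(f"s{i}", {0: 0, 1: 0}, start=0) for i in range(2)]
        mate_a = make_obs("pair", {0: 0, 1: 0}, segment=1, paired=True, start=0)
        # erroneous read: truly haplotype 1 (agrees at site 1) but carries
        # sequencing errors at sites 2 and 3, pushing mate b off its pair
        erroneous = make_obs("err", {1: 0, 2: 1, 3: 1}, start=1)
        mate_b = make_obs("pair", {2: 0, 3: 0}, segment=2, paired=True, start=2)
        obs = scaffold + [mate_a, erroneous, mate_b]
        obs.sort(key=lambda o: (o.start, o.read_key))
        state, _ = run_phasing(obs, sites)
        assert state.assignment["pair/1"] != state.assignment["pair/2"]
        mate_pair_repair(state, obs, sites)
        assert state.assignment["pair/1"] == state.assignment["pair/2"]
        # mate a's margin (the scaffold) is larger, so the pair lands there
        assert state.assignment["pair/2"] == state.assignment["s0/1"]

    def test_concordant_pairs_left_untouched(self, paired_run):
        state = copy.deepcopy(paired_run["state"])
        before = dict(state.assignment)
        mate_pair_repair(state, paired_run["observations"], paired_run["sites"])
        repaired_once = dict(state.assignment)
        mate_pair_repair(state, paired_run["observations"], paired_run["sites"])
        assert state.assignment == repaired_once
        # error-free input: nothing to repair in the first place
        assert before == repaired_once

    def test_mates_in_different_blocks_ignored(self):
        sites = make_sites([("C", "T")] * 4)
        obs = [
            make_obs("p", {0: 0, 1: 0}, segment=1, paired=True, start=0),
            make_obs("q", {0: 0, 1: 0}, start=0),
            make_obs("p", {2: 1, 3: 1}, segment=2, paired=True, start=2),
            make_obs("z", {2: 1, 3: 1}, start=2),
        ]
        obs.sort(key=lambda o: (o.start, o.read_key))
        state, blocks = run_phasing(obs, sites)
        assert len(blocks) == 2
        before = dict(state.assignment)
        mate_pair_repair(state, obs, sites)
        assert state.assignment == before


class TestConsensusSites:
    def test_unanimous_vote(self):
        sites = make_sites([("C", "T")] * 2)
        obs = [make_obs(f"r{i}", {0: 0, 1: 1}, start=0) for i in range(5)]
        state, blocks = run_phasing(obs, sites)
        assert blocks[0].site_orientation == ((0, A_ALLELE), (1, B_ALLELE))

    def test_tied_vote_leaves_site_unphased(self):
        sites = make_sites([("C", "T")] * 3)
        # all reads agree on sites 0 and 2; site 1 splits two against two
        obs = [
            make_obs("r0", {0: 0, 1: 0, 2: 0}, start=0),
            make_obs("r1", {0: 0, 1: 0, 2: 0}, start=0),
            make_obs("r2", {0: 0, 1: 1, 2: 0}, start=0),
            make_obs("r3", {0: 0, 1: 1, 2: 0}, start=0),
        ]
        state, blocks = run_phasing(obs, sites)
        assert len(blocks) == 1
        assert [si for si, _ in blocks[0].site_orientation] == [0, 2]

    def test_blocks_below_two_sites_dropped(self):
        sites = make_sites([("C", "T")] * 3)
        obs = [make_obs("r0", {0: 0, 1: 0}, start=0), make_obs("lone", {2: 0}, start=2)]
        state, blocks = run_phasing(obs, sites)
        assert len(blocks) == 1
        assert "lone/1" not in state.block_of
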