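"""Move set, gradient walks, enumeration and Boltzmann sampling."""

import itertools

import numpy as np
import pytest
from scipy import stats

from rnabhg.energy import EnergyParams, energy
from rnabhg.landscape import (
    ENUMERATION_GUARD,
    apply_move,
    can_add_pair,
    candidate_pairs,
    enumerate_ensemble,
    gradient_walk,
    lm_composition,
    neighbor_moves,
    neighbors,
    sample_minima,
    _mcmc_sample,
)
from rnabhg.structures import (
    MIN_HAIRPIN,
    Sequence,
    Structure,
    classify_pk,
    pairs_cross,
)

from conftest import exact_lm_table, one_structure_oracle


class TestCanAddPair:
    def test_non_crossing_add(self, hairpin_seq):
        s = Structure([(1, 10), (2, 9)])
        assert can_add_pair(s, 3, 8, hairpin_seq)

    def test_occupied_position_rejected(self, hairpin_seq):
        s = Structure([(1, 10)])
        assert not can_add_pair(s, 1, 9, hairpin_seq)

    def test_noncanonical_rejected(self, hairpin_seq):
        assert not can_add_pair(Structure(), 4, 8, hairpin_seq)

    def test_l_type_add_allowed_genus_two_add_rejected(self):
        seq = Sequence("G" * 17 + "A" + "C" * 17)
        h = Structure([(1, 22), (5, 26)])
        # a third mutually crossing chord stays genus 1 (L-type)
        assert can_add_pair(h, 9, 30, seq)
        # a fourth fully interleaved chord would make the component genus 2
        l_type = h.add(9, 30)
        from conftest import genus_permutation_oracle

        assert genus_permutation_oracle(list(l_type.pairs) + [(13, 34)]) == 2
        assert not can_add_pair(l_type, 13, 34, seq)

    def test_add_matches_oracle_on_random_states(self, h_type_seq, h_type_ensemble):
        for s in h_type_ensemble.structures[:120]:
            occupied = s.paired_positions()
            for i, j in candidate_pairs(h_type_seq.residues):
                if i in occupied or j in occupied:
                    continue
                assert can_add_pair(s, i, j, h_type_seq) == one_structure_oracle(
                    list(s.pairs) + [(i, j)]
                )

    def test_nested_universe_forbids_crossings(self, h_type_seq):
        s = Structure([(1, 13), (2, 12), (3, 11)])
        assert can_add_pair(s, 6, 18, h_type_seq, allow_pk=True)
        assert not can_add_pair(s, 6, 18, h_type_seq, allow_pk=False)


class TestNeighbors:
    def test_open_chain_neighbors_are_single_pairs(self):
        seq = Sequence("GGCAAAAGCC")
        expected = {
            frozenset({(i, j)})
            for i, j in candidate_pairs(seq.residues)
        }
        got = {s.pair_set for s in neighbors(Structure(), seq)}
        assert got == expected

    def test_not_own_neighbor(self, hairpin_seq):
        s = Structure([(1, 10), (2, 9)])
        assert s.pair_set not in {t.pair_set for t in neighbors(s, hairpin_seq)}

    def test_count_matches_quadratic_scan(self, h_type_seq, h_type_ensemble):
        n = len(h_type_seq)
        for s in h_type_ensemble.structures[:60]:
            brute = len(s.pairs)
            occupied = s.paired_positions()
            for i in range(1, n + 1):
                for j in range(i + MIN_HAIRPIN + 1, n + 1):
                    if i in occupied or j in occupied:
                        continue
                    if not h_type_seq.can_pair(i, j):
                        continue
                    if one_structure_oracle(list(s.pairs) + [(i, j)]):
                        brute += 1
            assert len(neighbors(s, h_type_seq)) == brute

    def test_symmetry(self, two_basin_seq, two_basin_ensemble):
        for s in two_basin_ensemble.structures[:80]:
            for t in neighbors(s, two_basin_seq):
                assert s.pair_set in {u.pair_set for u in neighbors(t, two_basin_seq)}


class TestGradientWalk:
    def test_lm_maps_to_itself(self, hairpin_seq, params):
        lm = Structure([(1, 10), (2, 9), (3, 8)])
        assert gradient_walk(lm, hairpin_seq, params) == lm

    def test_strict_descent_and_termination(self, h_type_seq, params, h_type_ensemble):
        for s in h_type_ensemble.structures[::97]:
            lm = gradient_walk(s, h_type_seq, params)
            assert energy(h_type_seq, lm, params) <= energy(h_type_seq, s, params)
            moves = neighbor_moves(lm, h_type_seq)
            e_lm = energy(h_type_seq, lm, params)
            assert all(
                energy(h_type_seq, apply_move(lm, m), params) >= e_lm for m in moves
            )

    def test_basin_assignment_matches_descent_oracle(
        self, two_basin_seq, two_basin_ensemble, params
    ):
        """Full-enumeration memoized steepest-descent oracle: identical basin
        for every structure of the landscape."""
        ens = two_basin_ensemble
        idx = {s.pairs: k for k, s in enumerate(ens.structures)}
        E = ens.energies

        memo: dict = {}

        def descend(k: int):
            if k in memo:
                return memo[k]
            s = ens.structures[k]
            best = None
            for m in neighbor_moves(s, two_basin_seq):
                t = apply_move(s, m)
                kt = idx[t.pairs]
                key = (E[kt], 0 if m.kind == "remove" else 1, m.pair)
                if best is None or key < best[0]:
                    best = (key, kt)
            if best is None or best[0][0] >= E[k]:
                memo[k] = k
            else:
                memo[k] = descend(best[1])
            return memo[k]

        import sys

        sys.setrecursionlimit(10000)
        cache: dict = {}
        for k, s in enumerate(ens.structures):
            expected = ens.structures[descend(k)]
            assert gradient_walk(s, two_basin_seq, params, _cache=cache) == expected


class TestEnumeration:
    def test_six_nt_only_open_chain(self, params):
        ens = enumerate_ensemble(Sequence("GGGAAA"), params, ceiling=None)
        assert len(ens) == 1
        assert ens.structures[0] == Structure()

    def test_count_matches_recursive_oracle(self, params):
        """Independent recursive enumeration over candidate-pair subsets."""
        seq = Sequence("GGCAAAAGGCC")
        cands = candidate_pairs(seq.residues)

        def count(start, chosen, used):
            total = 1
            for k in range(start, len(cands)):
                i, j = cands[k]
                if i in used or j in used:
                    continue
                if not one_structure_oracle(chosen + [(i, j)]):
                    continue
                total += count(k + 1, chosen + [(i, j)], used | {i, j})
            return total

        ens = enumerate_ensemble(seq, params, ceiling=None)
        assert len(ens) == count(0, [], set())

    def test_nested_subset_matches_classical_enumerator(self, params):
        """Every crossing-free structure in the index is found by an
        independent interval-recursion enumerator for nested structures."""
        seq = Sequence("GGCAAAAGGCC")
        n = len(seq)

        def nested(i, j):
            if j - i < MIN_HAIRPIN + 1:
                yield frozenset()
                return
            # position i unpaired
            for rest in nested(i + 1, j):
                yield rest
            for k in range(i + MIN_HAIRPIN + 1, j + 1):
                if not seq.can_pair(i, k):
                    continue
                for inner in nested(i + 1, k - 1):
                    for outer in nested(k + 1, j):
                        yield frozenset({(i, k)}) | inner | outer

        classical = set(nested(1, n))
        ens = enumerate_ensemble(seq, params, ceiling=None)
        ours = {
            s.pair_set
            for s in ens.structures
            if not any(
                pairs_cross(a, b) for a, b in itertools.combinations(s.pairs, 2)
            )
        }
        assert ours == classical

    def test_ceiling_filters(self, two_basin_seq, params):
        full = enumerate_ensemble(two_basin_seq, params, ceiling=None)
        windowed = enumerate_ensemble(two_basin_seq, params, ceiling=3.0)
        assert len(windowed) < len(full)
        assert windowed.mfe == full.mfe
        assert all(e <= full.mfe + 3.0 + 1e-9 for e in windowed.energies)

    def test_size_guard(self, params):
        with pytest.raises(ValueError):
            enumerate_ensemble(
                Sequence("GC" * 21), params, max_n=ENUMERATION_GUARD
            )


class TestSampling:
    def test_zero_samples_keeps_mfe_lm(self, two_basin_seq, params):
        lms = sample_minima(two_basin_seq, params, 0, seed=5)
        assert len(lms) == 1
        assert lms[0].energy == pytest.approx(-4.6)

    def test_same_seed_same_result(self, two_basin_seq, params):
        a = sample_minima(two_basin_seq, params, 200, seed=42)
        b = sample_minima(two_basin_seq, params, 200, seed=42)
        assert a == b

    def test_large_sample_recovers_exhaustive_window_lms(
        self, two_basin_seq, two_basin_ensemble, params
    ):
        exact = exact_lm_table(two_basin_ensemble, two_basin_seq, params)
        mfe = min(e for e, _ in exact)
        window = {s.pair_set for e, s in exact if e <= mfe + 10 + 1e-9}
        sampled = sample_minima(two_basin_seq, params, 3000, seed=3, ceiling=10.0)
        assert {lm.structure.pair_set for lm in sampled} == window

    def test_mcmc_matches_boltzmann(self, params):
        """Chi-square sanity check of the Metropolis sampler against
        exp(-f/RT)/Z on a fully enumerable landscape, at a fixed seed.

        The landscape is chosen flat and tiny (weak A-U pairs only, no deep
        basins) so the chain decorrelates within the thinning interval; on
        deep-basin landscapes the correlated draws would invalidate the
        chi-square independence assumption.
        """
        seq = Sequence("AAAAUU")
        ens = enumerate_ensemble(seq, params, ceiling=None)
        rng = np.random.default_rng(1234)
        draws = _mcmc_sample(
            seq, params, 3000, rng, allow_pk=True, burn_in=500, thin=40
        )
        counts = np.zeros(len(ens))
        for s in draws:
            counts[ens.index_of(s)] += 1
        probs = ens.boltzmann_probabilities()
        # pool rare states for a valid chi-square
        keep = probs * len(draws) >= 5
        pooled_obs = np.append(counts[keep], counts[~keep].sum())
        pooled_exp = np.append(probs[keep], probs[~keep].sum()) * len(draws)
        chi2 = ((pooled_obs - pooled_exp) ** 2 / pooled_exp).sum()
        dof = len(pooled_obs) - 1
        assert chi2 < stats.chi2.ppf(0.999, dof)


class TestComposition:
    def test_all_n(self, two_basin_seq, params):
        lms = sample_minima(two_basin_seq, params, 100, seed=2)
        table = lm_composition(lms)
        assert table.to_dict() == {"N": 1.0}

    def test_fractions_sum_to_one(self, h_type_seq, params):
        lms = sample_minima(h_type_seq, params, 400, seed=7, ceiling=None)
        assert lm_composition(lms).sum() == pytest.approx(1.0)

    def test_h_designed_sequence_has_h_minima(
        self, h_type_seq, h_type_ensemble, params
    ):
        """Verified against exhaustive enumeration: the designed sequence has
        H-class local minima, and they appear in the composition table."""
        from rnabhg.landscape import LocalMinimum

        exact = exact_lm_table(h_type_ensemble, h_type_seq, params)
        assert any(classify_pk(s) == "H" for _, s in exact)
        table = lm_composition(
            [LocalMinimum(s, e, classify_pk(s)) for e, s in exact]
        )
        assert table.get("H", 0) > 0
        # Boltzmann-weighted discovery is dominated by crossing-free minima:
        # the pseudoknot penalty makes H basins exponentially rare draws
        sampled = lm_composition(
            sample_minima(h_type_seq, params, 500, seed=11, ceiling=None)
        )
        assert sampled.get("N", 0) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lm_composition([])
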