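"""Substrate generation, subsite cleavage rules, and the digestion simulator."""

import numpy as np
import pytest

from pectolyze.composition import CompositionError, enumerate_library
from pectolyze.simulate import (
    CleavageRule,
    ResidueChain,
    SubstrateSpec,
    absorbance_trace,
    bond_rates,
    cleavable_bonds,
    enumerate_terminal_products,
    generate_chains,
    initial_total_rate,
    preset_spec,
    simulate_digest,
    synthesize_peak_table,
)


def full_chain(dp):
    return ResidueChain.from_flags([1] * dp)


class TestGenerateChains:
    def test_dm_extremes(self):
        fully = generate_chains(SubstrateSpec(5, 50, dm=100, dac=0), 1)
        assert all(c.methyl.all() for c in fully)
        pga = generate_chains(SubstrateSpec(5, 50, dm=0, dac=0), 1)
        assert all(not c.methyl.any() for c in pga)

    def test_realized_dm_concentrates_around_target(self):
        spec = SubstrateSpec(n_chains=1000, chain_length=100, dm=69, dac=2)
        chains = generate_chains(spec, 7)
        methyls = sum(int(c.methyl.sum()) for c in chains)
        assert 100 * methyls / 1e5 == pytest.approx(69, abs=0.5)

    def test_blockwise_hits_target_and_forms_runs(self):
        spec = SubstrateSpec(n_chains=50, chain_length=100, dm=50, dac=0,
                             methyl_pattern="blockwise", block_length=10)
        chains = generate_chains(spec, 3)
        for c in chains:
            assert int(c.methyl.sum()) == 50
        # blockwise placement yields fewer methyl/non-methyl boundaries than random
        def boundaries(cs):
            return sum(int(np.sum(c.methyl[1:] != c.methyl[:-1])) for c in cs)
        random_chains = generate_chains(SubstrateSpec(50, 100, dm=50, dac=0), 3)
        assert boundaries(chains) < boundaries(random_chains)

    def test_deterministic_under_seed(self):
        spec = SubstrateSpec(10, 60, dm=56, dac=19)
        a = generate_chains(spec, 11)
        b = generate_chains(spec, 11)
        for x, y in zip(a, b):
            assert np.array_equal(x.methyl, y.methyl)
            assert np.array_equal(x.acetyl_o2, y.acetyl_o2)

    def test_invalid_spec_rejected(self):
        with pytest.raises(CompositionError):
            SubstrateSpec(dm=120)
        with pytest.raises(CompositionError):
            SubstrateSpec(dac=-1)


class TestCleavableBonds:
    def test_fully_methylated_dp10_has_seven_strict_bonds(self):
        bonds = cleavable_bonds(full_chain(10), CleavageRule.strict())
        assert [b for b, _ in bonds] == [1, 2, 3, 4, 5, 6, 7]

    def test_trimers_are_never_substrates(self):
        for rule in (CleavageRule.strict(), CleavageRule(rho=0.25), CleavageRule(rho=1.0)):
            assert cleavable_bonds(full_chain(3), rule) == []

    def test_unmethylated_chain_inert(self):
        chain = ResidueChain.from_flags([0] * 12)
        assert cleavable_bonds(chain, CleavageRule(rho=1.0)) == []

    def test_partial_rate_applies_when_plus3_unmethylated(self):
        # +1 methylated, +3 present but unmethylated -> rho
        chain = ResidueChain.from_flags([0, 1, 0, 0, 0])
        rule = CleavageRule(rho=0.25)
        assert cleavable_bonds(chain, rule) == [(1, 0.25)]
        assert cleavable_bonds(chain, CleavageRule.strict()) == []

    def test_acetyl_penalty_multiplies_per_group_in_window(self):
        chain = full_chain(8)
        base = bond_rates(chain, CleavageRule(acetyl_penalty=0.5))
        chain_ac = ResidueChain.from_flags([1] * 8, acetyl_o2=[0, 0, 0, 1, 0, 0, 0, 0])
        acet = bond_rates(chain_ac, CleavageRule(acetyl_penalty=0.5))
        # residue 4 (index 3) sits in the -4..+4 window of every bond here
        assert np.allclose(acet, base * 0.5)

    def test_plus1_acetyl_hard_block_flag(self):
        chain = ResidueChain.from_flags([1] * 6, acetyl_o2=[0, 1, 0, 0, 0, 0])
        blocked = bond_rates(chain, CleavageRule(block_on_plus1_acetyl=True))
        assert blocked[0] == 0.0
        tolerant = bond_rates(chain, CleavageRule(block_on_plus1_acetyl=False))
        assert tolerant[0] > 0.0


class TestSimulateDigest:
    def test_time_zero_snapshot_equals_input(self):
        chains = generate_chains(SubstrateSpec(5, 30, dm=69, dac=2), 1)
        states = simulate_digest(chains, CleavageRule(), time_points=(0.0, 5.0), seed=2)
        assert states[0].time_min == 0.0 and states[0].cleavage_count == 0
        assert len(states[0].chains) == len(chains)
        for orig, snap in zip(chains, states[0].chains):
            assert np.array_equal(orig.methyl, snap.methyl)

    def test_conservation_and_unsaturated_end_accounting(self):
        chains = generate_chains(SubstrateSpec(20, 80, dm=69, dac=5), 3)
        res0 = sum(len(c) for c in chains)
        met0 = sum(int(c.methyl.sum()) for c in chains)
        ace0 = sum(int(c.acetyl_counts.sum()) for c in chains)
        states = simulate_digest(chains, CleavageRule(), time_points=(0, 1, 10, 100), seed=4)
        for s in states:
            res, met, ace, uns = s.totals()
            assert (res, met, ace) == (res0, met0, ace0)
            assert uns == s.cleavage_count
            assert len(s.chains) == len(chains) + s.cleavage_count

    def test_terminal_state_of_fully_methylated_hexamer(self):
        """Exhaustive enumeration: every terminal product multiset conserves
        the six residues and contains no cleavable chain."""
        rule = CleavageRule.strict()
        terminals = enumerate_terminal_products(full_chain(6), rule)
        assert terminals
        for state in terminals:
            assert sum(comp.dp * mult for comp, mult in state) == 6
            for comp, _ in state:
                assert comp.dp <= 5

    def test_long_time_digest_reaches_terminal_state(self):
        chains = [full_chain(6) for _ in range(20)]
        states = simulate_digest(chains, CleavageRule.strict(), time_points=(0, 1e6), seed=5)
        final = states[-1]
        for c in final.chains:
            assert cleavable_bonds(c, CleavageRule.strict()) == []

    def test_deterministic_under_seed(self):
        chains = generate_chains(SubstrateSpec(10, 50, dm=69, dac=2), 0)
        a = simulate_digest(chains, CleavageRule(), time_points=(0, 5), seed=9)
        b = simulate_digest(chains, CleavageRule(), time_points=(0, 5), seed=9)
        assert a[-1].cleavage_count == b[-1].cleavage_count
        assert a[-1].composition_counts() == b[-1].composition_counts()


class TestRateMonotonicity:
    def test_blockwise_beats_random_at_equal_dm(self):
        rule = CleavageRule(rho=0.25)
        block, rand = [], []
        for seed in range(10):
            spec_b = SubstrateSpec(20, 100, dm=50, dac=0, methyl_pattern="blockwise")
            spec_r = SubstrateSpec(20, 100, dm=50, dac=0)
            block.append(initial_total_rate(generate_chains(spec_b, seed), rule))
            rand.append(initial_total_rate(generate_chains(spec_r, seed), rule))
        assert np.mean(block) >= np.mean(rand)

    def test_rate_non_increasing_in_dac(self):
        rule = CleavageRule(acetyl_penalty=0.5)
        means = []
        for dac in (0, 5, 10, 20, 40):
            rates = [
                initial_total_rate(
                    generate_chains(SubstrateSpec(20, 100, dm=69, dac=dac), seed), rule
                )
                for seed in range(8)
            ]
            means.append(np.mean(rates))
        assert all(a >= b for a, b in zip(means, means[1:]))


class TestObservables:
    def test_absorbance_from_beer_lambert(self):
        from pectolyze.simulate import DigestState

        zero = DigestState([full_chain(4)], 0.0, 0)
        # 10 uM product: 1e4 counts of 1e-12 mol in 1 mL
        ten_um = DigestState([full_chain(4)], 5.0, 10000)
        trace = absorbance_trace([zero, ten_um], extinction=5500, path_cm=1.0,
                                 volume_l=1e-3, mol_per_count=1e-12)
        assert trace["A235"].iloc[0] == 0.0
        assert trace["A235"].iloc[1] == pytest.approx(0.055)

    def test_absorbance_nondecreasing_over_trajectory(self):
        chains = generate_chains(SubstrateSpec(10, 60, dm=69, dac=2), 6)
        states = simulate_digest(chains, CleavageRule(), time_points=(0, 1, 5, 20), seed=7)
        trace = absorbance_trace(states)
        assert (trace["A235"].diff().dropna() >= 0).all()

    def test_zero_noise_intensity_equals_counts(self, enumerated_library):
        chains = generate_chains(SubstrateSpec(20, 60, dm=69, dac=2), 8)
        state = simulate_digest(chains, CleavageRule(), time_points=(0, 200), seed=9)[-1]
        peaks, excluded = synthesize_peak_table(state, enumerated_library, noise_cv=0.0, seed=0)
        for row in peaks.itertuples():
            assert float(row.intensity).is_integer()
        # every product chain lands either in the peak table or the exclusion report
        assert peaks["intensity"].sum() + excluded["count"].sum() == len(state.chains)
        assert set(excluded["reason"]) <= {"saturated", "dp>8", "not-in-library"}

    def test_empty_digest_gives_empty_peak_table(self, enumerated_library):
        from pectolyze.simulate import DigestState

        state = DigestState([ResidueChain.from_flags([0] * 30)], 0.0, 0)
        peaks, excluded = synthesize_peak_table(state, enumerated_library, 0.09, 0)
        assert peaks.empty
        assert excluded["reason"].tolist() == ["saturated"]


def test_presets_load_with_expected_degrees():
    apple = preset_spec("apple")
    beet = preset_spec("sugarbeet")
    assert (apple.dm, apple.dac) == (69.0, 2.0)
    assert (beet.dm, beet.dac) == (56.0, 19.0)
    with pytest.raises(CompositionError):
        preset_spec("mango")
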