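import math

import numpy as np
import pytest

import _oracles as oracles
from adtcount import SimulationConfig, generate_dataset
from adtcount.dedup import (
    DedupPolicy,
    MoleculeAssignment,
    dedup_close,
    dedup_exact,
    duplication_profile,
    exact_vs_close_difference,
)


def mol(order, cell, tag, umi):
    return MoleculeAssignment(order=order, cell_index=cell, tag_index=tag, umi=umi)


def random_molecules(rng, n, n_cells=50, n_umis=8, umi_len=4, n_tags=3):
    umis = [oracles.random_dna(rng, umi_len) for _ in range(n_umis)]
    return [
        mol(i, rng.randrange(n_cells), rng.randrange(n_tags), rng.choice(umis))
        for i in range(n)
    ]


class TestDedupPolicy:
    def test_defaults(self):
        policy = DedupPolicy()
        assert policy.mode == "exact"
        assert policy.max_mismatch == 1
        assert not policy.key_includes_tag

    def test_close_mode_run_validation(self):
        DedupPolicy(mode="close", max_mismatch=0)  # constructible for testing
        with pytest.raises(ValueError):
            DedupPolicy(mode="close", max_mismatch=0).validate_for_run()
        DedupPolicy(mode="close", max_mismatch=1).validate_for_run()

    def test_invalid(self):
        with pytest.raises(ValueError):
            DedupPolicy(mode="fuzzy")
        with pytest.raises(ValueError):
            DedupPolicy(max_mismatch=-1)


class TestDedupExact:
    def test_simple_duplicate(self):
        mols = [mol(0, 0, 1, "AAAA"), mol(1, 0, 1, "AAAA")]
        kept, removed = dedup_exact(mols)
        assert kept == [mols[0]]
        assert removed == 1

    def test_all_distinct(self):
        mols = [mol(i, 0, 0, u) for i, u in enumerate(["AAAA", "CCCC", "GGGG"])]
        kept, removed = dedup_exact(mols)
        assert kept == mols
        assert removed == 0

    def test_key_excludes_tag_by_default(self):
        # same cell + UMI but different tags is still a duplicate
        mols = [mol(0, 0, 0, "AAAA"), mol(1, 0, 1, "AAAA")]
        assert dedup_exact(mols)[1] == 1
        assert dedup_exact(mols, DedupPolicy(key_includes_tag=True))[1] == 0

    def test_against_grouping_oracle(self, rng):
        mols = random_molecules(rng, 10_000)
        for include_tag in (False, True):
            policy = DedupPolicy(key_includes_tag=include_tag)
            kept, removed = dedup_exact(mols, policy)
            okept, oremoved = oracles.dedup_exact_oracle(mols, include_tag)
            assert kept == okept
            assert removed == oremoved


class TestDedupClose:
    def test_near_umi_removed(self):
        mols = [mol(0, 0, 0, "AAAA"), mol(1, 0, 0, "AAAT")]
        kept, removed = dedup_close(mols, DedupPolicy(mode="close", max_mismatch=1))
        assert kept == [mols[0]]
        assert removed == 1

    def test_radius_zero_equals_exact(self, rng):
        mols = random_molecules(rng, 2000)
        policy0 = DedupPolicy(mode="close", max_mismatch=0)
        assert dedup_close(mols, policy0) == dedup_exact(mols)

    def test_ragged_umis_error(self):
        mols = [mol(0, 0, 0, "AAAA"), mol(1, 0, 0, "AAA")]
        with pytest.raises(ValueError, match="ragged"):
            dedup_close(mols, DedupPolicy(mode="close"))

    def test_against_quadratic_oracle(self, rng):
        for _ in range(20):
            mols = random_molecules(rng, 200, n_cells=3, n_umis=12)
            for radius in (1, 2):
                policy = DedupPolicy(mode="close", max_mismatch=radius)
                kept, removed = dedup_close(mols, policy)
                okept, oremoved = oracles.dedup_close_oracle(mols, radius)
                assert kept == okept
                assert removed == oremoved


class TestInvariants:
    @pytest.mark.parametrize("mode", ["exact", "close"])
    def test_idempotence_and_conservation(self, rng, mode):
        mols = random_molecules(rng, 3000)
        policy = DedupPolicy(mode=mode, max_mismatch=1)
        fn = dedup_close if mode == "close" else dedup_exact
        kept, removed = fn(mols, policy)
        assert len(kept) + removed == len(mols)
        kept2, removed2 = fn(kept, policy)
        assert kept2 == kept
        assert removed2 == 0

    def test_ordering_stability(self, rng):
        mols = random_molecules(rng, 3000)
        for fn, policy in (
            (dedup_exact, DedupPolicy()),
            (dedup_close, DedupPolicy(mode="close")),
        ):
            kept, _ = fn(mols, policy)
            orders = [m.order for m in kept]
            assert orders == sorted(orders)

    def test_dominance(self, rng):
        mols = random_molecules(rng, 3000)
        removed_exact = dedup_exact(mols)[1]
        prev = removed_exact
        for radius in (1, 2, 3):
            removed_close = dedup_close(
                mols, DedupPolicy(mode="close", max_mismatch=radius)
            )[1]
            assert removed_close >= prev
            prev = removed_close
        assert prev >= removed_exact


class TestDuplicationProfile:
    def test_singleton_key(self):
        prof = duplication_profile([mol(0, 0, 0, "AAAA")])
        assert prof.fractions.tolist() == [0.0]
        assert prof.zero_duplicate_share == 1.0

    def test_key_seen_four_times(self):
        mols = [mol(i, 0, 0, "AAAA") for i in range(4)]
        prof = duplication_profile(mols)
        assert prof.fractions.tolist() == [0.75]
        assert prof.zero_duplicate_share == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            duplication_profile([])

    def test_tsv_export(self, tmp_path):
        prof = duplication_profile([mol(0, 0, 0, "AAAA"), mol(1, 0, 0, "AAAA")])
        out = tmp_path / "profile.tsv"
        prof.to_tsv(out)
        assert out.read_text() == "duplicate_fraction\n0.5\n"

    def test_zero_duplicate_share_matches_generator_expectation(self, tmp_path):
        # with unique UMIs per cell, a key has a duplicate iff the molecule
        # was re-emitted, so the zero-duplicate share estimates 1 - d
        d = 0.4
        config = SimulationConfig(
            n_cells=60, n_tags=10, mean_molecules=5.0, duplication_rate=d, seed=5
        )
        ds = generate_dataset(config, tmp_path / "sim")
        mols = [
            mol(i, p.cell_index, p.tag_index, p.umi)
            for i, p in enumerate(ds.truth.reads)
        ]
        prof = duplication_profile(mols)
        n_keys = len(prof.fractions)
        se = math.sqrt(d * (1 - d) / n_keys)
        assert abs(prof.zero_duplicate_share - (1 - d)) < 3 * se


class TestExactVsCloseDifference:
    def test_no_near_neighbours_is_zero(self):
        mols = [mol(0, 0, 0, "AAAA"), mol(1, 0, 0, "TTTT")]
        diffs = exact_vs_close_difference(mols, DedupPolicy(mode="close"))
        assert diffs.tolist() == [0.0, 0.0]

    def test_hand_computed_case(self):
        # exact removes 1 of {AAAA, AAAA, AAAT}; close(1) removes 2
        mols = [mol(0, 0, 0, "AAAA"), mol(1, 0, 0, "AAAA"), mol(2, 0, 0, "AAAT")]
        diffs = exact_vs_close_difference(mols, DedupPolicy(mode="close", max_mismatch=1))
        assert diffs.tolist() == [pytest.approx((2 - 1) / 3)]

    def test_never_negative_and_matches_oracles(self, rng):
        for _ in range(20):
            mols = random_molecules(rng, 150, n_cells=4, n_umis=10)
            policy = DedupPolicy(mode="close", max_mismatch=1)
            diffs = exact_vs_close_difference(mols, policy)
            assert (diffs >= 0).all()
            # cluster-level totals recompose the global removal counts
            n = len(mols)
            removed_exact = oracles.dedup_exact_oracle(mols)[1]
            removed_close = oracles.dedup_close_oracle(mols, 1)[1]
            # sum over clusters of (dup_close - dup_exact) = global difference
            totals = _cluster_totals(mols, policy)
            assert sum(d * c for d, c in zip(diffs, totals)) == pytest.approx(
                removed_close - removed_exact
            )
            assert len(mols) == n


def _cluster_totals(mols, policy):
    from adtcount.dedup import _close_scan

    _, cluster_of = _close_scan(mols, policy)
    counts = {}
    order = []
    for rep in cluster_of:
        if rep not in counts:
            counts[rep] = 0
            order.append(rep)
        counts[rep] += 1
    return [counts[r] for r in order]
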