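"""Lattice, sequence space and Rosenbluth growth."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import copolyscan as cps
from copolyscan import _kernels
from copolyscan._rng import sample_state, stream_seed
from copolyscan.lattice_model import BOND_VECTORS, Topology, _Grower  # noqa: F401


class TestBondSet:
    def test_exactly_26_nonzero_unit_cube_vectors(self):
        vs = cps.bond_vectors()
        assert len(vs) == 26
        assert (0, 0, 0) not in vs
        assert (2, 0, 0) not in vs
        assert all(max(abs(c) for c in v) == 1 for v in vs)

    def test_set_closed_under_negation(self):
        vs = cps.bond_vectors()
        assert all((-a, -b, -c) in vs for a, b, c in vs)


class TestSequenceSpace:
    @pytest.mark.parametrize(
        "n,n_tail,expected",
        [(16, 8, 12870), (4, 4, 1), (12, 6, 924), (4, 0, 1)],
    )
    def test_enumeration_count_matches_multinomial(self, n, n_tail, expected):
        seqs, count = cps.enumerate_sequences(n, n_tail)
        seqs = list(seqs)
        assert count == expected == len(seqs)
        assert len({s.to_string() for s in seqs}) == count
        assert all(s.n_tail == n_tail for s in seqs)

    def test_reversal_dedupe_classes_for_4_choose_2(self):
        seqs, count = cps.enumerate_sequences(4, 2, dedupe_reversal=True)
        got = {s.to_string() for s in seqs}
        # brute force: pair each of the 6 orderings with its reversal
        assert count == 4
        assert got == {"HHTT", "HTHT", "THHT", "HTTH"}

    def test_invalid_composition_rejected(self):
        with pytest.raises(ValueError, match="composition"):
            cps.enumerate_sequences(4, 7)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(n=st.integers(1, 8), data=st.data())
    def test_dedupe_count_matches_brute_force_classes(self, n, data):
        n_tail = data.draw(st.integers(0, n))
        seqs, count = cps.enumerate_sequences(n, n_tail, dedupe_reversal=True)
        all_seqs, _ = cps.enumerate_sequences(n, n_tail)
        classes = {cps.canonical_form(s).to_string() for s in all_seqs}
        assert count == len(classes) == len(list(seqs))

    def test_canonical_form_examples(self):
        can = lambda s: cps.canonical_form(cps.Sequence.from_string(s)).to_string()
        assert can("TTHH") == "HHTT"
        assert can("THHT") == "THHT"

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.text(alphabet="TH", min_size=1, max_size=12))
    def test_canonical_form_reversal_symmetric(self, s):
        seq = cps.Sequence.from_string(s)
        assert cps.canonical_form(seq) == cps.canonical_form(seq.reversed())


class TestLinearGrowth:
    def test_single_monomer_has_unit_weight(self):
        conf = cps.grow_linear(cps.Sequence.from_string("T"), seed=1)
        assert conf.weight == 1.0
        assert conf.coords.shape == (1, 3)

    def test_dimer_weight_is_one_in_open_space(self):
        conf = cps.grow_linear(
            cps.Sequence.from_string("TH"), seed=1, start=(10, 10, 0)
        )
        assert conf.weight == 1.0

    def test_trimer_weight_is_25_over_26_in_open_space(self):
        # monomer 1 occupies exactly one of monomer 2's 26 neighbor sites
        for idx in range(5):
            conf = cps.grow_linear(
                cps.Sequence.from_string("THT"), seed=2, sample_index=idx,
                start=(10, 10, 0),
            )
            assert conf.weight == pytest.approx(25 / 26)

    def test_generated_chains_satisfy_excluded_volume_and_bonds(self):
        box = cps.SimulationBox()
        seq = cps.Sequence.from_string("THTHTHTHTHTH")
        for idx in range(200):
            conf = cps.grow_linear(seq, box, seed=3, sample_index=idx)
            conf.validate(box)
            assert 0.0 <= conf.weight <= 1.0

    def test_same_substream_reproduces_bitwise(self):
        seq = cps.Sequence.from_string("TTHH")
        a = cps.grow_linear(seq, seed=5, sample_index=7)
        b = cps.grow_linear(seq, seed=5, sample_index=7)
        assert np.array_equal(a.coords, b.coords) and a.weight == b.weight

    def test_python_and_kernel_growth_share_one_stream(self):
        """The jitted scan kernels and the Python grower must consume the
        identical substream and produce identical chains."""
        box = cps.SimulationBox()
        seq = cps.Sequence.from_string("THTHTH")
        base = stream_seed(13, seq.to_string())
        pos = np.empty((6, 3), np.int64)
        occ = np.zeros((box.Lx, box.Ly, box.Lz), np.uint8)
        free = np.empty(26, np.int64)
        for idx in (0, 1, 17):
            conf = cps.grow_linear(seq, box, seed=13, sample_index=idx)
            s0 = np.uint64(sample_state(base, idx))
            w, placed = _kernels._grow_chain(
                s0, 6, box.Lx, box.Ly, box.Lz, BOND_VECTORS, pos, occ, free
            )
            occ[:] = 0
            expect = pos.copy()
            expect[:, 2] += box.z_min
            assert np.array_equal(conf.coords, expect)
            assert conf.weight == w


class TestBranchedGrowth:
    def test_theta_zero_yields_linear_topology(self):
        for idx in range(20):
            conf = cps.grow_branched(12, theta=0.0, f=2, seed=4, sample_index=idx)
            assert conf.topology.is_linear
            assert conf.topology.branch_points() == ()

    def test_certain_branching_gives_first_branch_point_two_children(self):
        # the third placed monomer is the first eligible; with n >= 5 both
        # of its two branches receive a monomer
        conf = cps.grow_branched(5, theta=1.0, f=2, seed=6)
        kids = conf.topology.children()
        assert 2 in conf.topology.branch_points()
        assert len(kids[2]) == 2

    def test_branched_chains_satisfy_lattice_constraints(self):
        box = cps.SimulationBox()
        for idx in range(100):
            conf = cps.grow_branched(16, theta=0.3, f=3, box=box, seed=8,
                                     sample_index=idx)
            if conf.weight > 0:
                conf.validate(box)

    def test_branch_point_count_matches_bernoulli_expectation(self):
        """Every placement from the third on draws branching with prob theta;
        the mean flagged-branch-point count must match theta * eligible."""
        theta, n, runs = 0.05, 20, 8000
        diffs = []
        for idx in range(runs):
            conf = cps.grow_branched(n, theta=theta, f=2, seed=9, sample_index=idx)
            eligible = max(0, (conf.n_placed or n) - 2)
            diffs.append(len(conf.topology.branch_points()) - theta * eligible)
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / math.sqrt(runs)
        assert abs(diffs.mean()) < 3 * se + 1e-12

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="theta"):
            cps.grow_branched(5, theta=1.5)
        with pytest.raises(ValueError, match="functionality"):
            cps.grow_branched(5, theta=0.5, f=1)


class TestTopology:
    def test_parent_indices_must_precede_children(self):
        with pytest.raises(ValueError):
            Topology((-1, 2, 1))

    def test_linear_factory(self):
        t = Topology.linear(4)
        assert t.is_linear and t.parents == (-1, 0, 1, 2)
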