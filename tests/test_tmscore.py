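"""TM-score engine: Kabsch vs quaternion oracle, rigid invariance,
sequential aligner behavior on constructed structure pairs."""

import os
import stat

import numpy as np
import pytest

from ssesym import (
    FixtureSpec,
    apply_indel,
    circular_permute,
    kabsch,
    make_chain,
    tm_align_sequential,
    tm_score,
)
from ssesym.chain import ProteinChain, Residue
from ssesym.tmscore import d0_scale

from conftest import EQUAL_HALF_ELEMENTS, quaternion_superpose_rmsd


def random_chain(seed: int, n: int) -> ProteinChain:
    """Seeded 3.8 Å random-walk Cα trace (no secondary structure)."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n - 1, 3))
    steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    return ProteinChain(
        f"rw{seed}", [Residue(i + 1, c) for i, c in enumerate(coords)]
    )


def rigid(coords: np.ndarray, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    return coords @ q.T + rng.normal(scale=20.0, size=3)


class TestKabsch:
    def test_identity_on_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        sup = kabsch(pts, pts)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)
        assert sup.rmsd < 1e-9

    def test_recovers_known_rotation(self):
        pts = np.random.default_rng(1).normal(size=(12, 3))
        rot90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        sup = kabsch(pts, pts @ rot90.T)
        assert np.allclose(sup.rotation @ rot90, np.eye(3), atol=1e-6)
        assert sup.rmsd < 1e-9

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        sup = kabsch(a, b)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_matches_quaternion_oracle_on_random_clouds(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(scale=5.0, size=(10, 3))
            b = rng.normal(scale=5.0, size=(10, 3))
            assert kabsch(a, b).rmsd == pytest.approx(
                quaternion_superpose_rmsd(a, b), abs=1e-8
            )

    def test_collinear_input_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch(line, line)


def test_d0_formula_and_floor():
    assert d0_scale(120) == pytest.approx(1.24 * (105.0) ** (1 / 3) - 1.8)
    assert d0_scale(21) == 0.5
    assert d0_scale(8) == 0.5


class TestTMScore:
    def test_self_tm_is_one(self):
        chain = make_chain(
            FixtureSpec(seed=5, elements=[("helix", 10), ("strand", 6)], linker_length=4)
        )
        pairs = [(i, i) for i in range(len(chain))]
        res = tm_score(chain, chain, pairs)
        assert res.tm == pytest.approx(1.0)

    def test_fewer_than_three_pairs_rejected(self):
        chain = make_chain(FixtureSpec(seed=5, elements=[("helix", 10)]))
        with pytest.raises(ValueError):
            tm_score(chain, chain, [(0, 0), (1, 1)])

    def test_rigid_motion_invariance(self):
        chain = make_chain(
            FixtureSpec(seed=6, elements=[("helix", 12), ("strand", 7)], linker_length=4)
        )
        other = make_chain(
            FixtureSpec(seed=7, elements=[("helix", 12), ("strand", 7)], linker_length=4)
        )
        pairs = [(i, i) for i in range(min(len(chain), len(other)))]
        base = tm_score(chain, other, pairs).tm
        for seed in (10, 11):
            moved = ProteinChain(
                other.chain_id,
                [
                    Residue(r.author_number, c)
                    for r, c in zip(other.residues, rigid(other.coords, seed))
                ],
            )
            assert tm_score(chain, moved, pairs).tm == pytest.approx(base, abs=1e-6)

    def test_adding_perfect_pairs_never_decreases_tm(self):
        chain = make_chain(
            FixtureSpec(seed=8, elements=[("helix", 10), ("strand", 8)], linker_length=4)
        )
        lt = len(chain)
        tms = []
        for k in (10, 14, 18, len(chain)):
            pairs = [(i, i) for i in range(k)]
            tms.append(tm_score(chain, chain, pairs, normalize_on="a").tm)
        assert tms == sorted(tms)


class TestSequentialAligner:
    def test_identical_chains_score_one(self):
        chain = make_chain(
            FixtureSpec(seed=9, elements=[("helix", 10), ("strand", 6)], linker_length=4)
        )
        assert tm_align_sequential(chain, chain).tm == pytest.approx(1.0)

    def test_two_residue_deletion_stays_high(self):
        chain = make_chain(FixtureSpec(seed=10, elements=[("helix", 20)]))
        deleted = apply_indel(chain, 9, 2, mode="delete")
        res = tm_align_sequential(chain, deleted, normalize_on="shorter")
        assert res.tm > 0.8

    def test_unrelated_random_walks_score_low(self):
        """Empirical null: unrelated 50-residue random walks rarely reach
        the fold threshold."""
        tms = [
            tm_align_sequential(
                random_chain(2 * s, 50), random_chain(2 * s + 1, 50)
            ).tm
            for s in range(25)
        ]
        assert np.median(tms) < 0.35
        assert max(tms) < 0.5

    def test_equal_half_permutant_half_then_full(self):
        chain = make_chain(
            FixtureSpec(seed=11, elements=EQUAL_HALF_ELEMENTS, linker_length=4)
        )
        perm = circular_permute(chain, len(chain) // 2)
        orig_order = tm_align_sequential(perm, chain)
        assert orig_order.tm == pytest.approx(0.5, abs=0.08)
        back = circular_permute(perm, len(chain) - len(chain) // 2)
        assert tm_align_sequential(back, chain).tm == pytest.approx(1.0, abs=0.02)


class TestExternalAdapter:
    def test_stub_binary_output_is_parsed(self, tmp_path):
        """The external TM-align adapter parses the standard output format
        (stub executable standing in for the real binary)."""
        stub = tmp_path / "tmalign_stub"
        stub.write_text(
            "#!/bin/sh\n"
            'echo "TM-score= 0.97215 (if normalized by length of Chain_1)"\n'
            'echo "TM-score= 0.84321 (if normalized by length of Chain_2)"\n'
        )
        stub.chmod(stub.stat().st_mode | stat.S_IXUSR)
        a = make_chain(FixtureSpec(seed=1, elements=[("helix", 8)]))
        b = make_chain(FixtureSpec(seed=2, elements=[("helix", 8), ("strand", 4)], linker_length=3))
        res = tm_align_sequential(a, b, normalize_on="a", tmalign_bin=str(stub))
        assert res.tm == pytest.approx(0.97215)
        assert res.provenance == "external"
        res_b = tm_align_sequential(a, b, normalize_on="b", tmalign_bin=str(stub))
        assert res_b.tm == pytest.approx(0.84321)
        # "shorter" resolves to the smaller chain's normalization
        res_s = tm_align_sequential(a, b, tmalign_bin=str(stub))
        assert res_s.tm == pytest.approx(0.97215)

    def test_failing_binary_raises_with_stderr(self, tmp_path):
        stub = tmp_path / "broken"
        stub.write_text("#!/bin/sh\necho boom >&2\nexit 3\n")
        stub.chmod(stub.stat().st_mode | stat.S_IXUSR)
        a = make_chain(FixtureSpec(seed=1, elements=[("helix", 8)]))
        with pytest.raises(RuntimeError, match="boom"):
            tm_align_sequential(a, a, tmalign_bin=str(stub))
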