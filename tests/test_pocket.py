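"""Grid pocket-volume pipeline: analytic oracles, filter semantics, and the
group comparison statistics."""

import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from nitromet import (InclusionRegion, PocketConfig, carve,
                      compare_volume_groups, contiguity_filter, generate_grid,
                      hull_filter, parse_structure, pocket_volume)
from nitromet.simulate import generate_pocket_fixture

SPHERE_VOL = 4.0 / 3.0 * np.pi * 5.0 ** 3  # 523.60 A^3


class TestGrid:
    def test_sphere_volume_within_two_percent(self):
        region = InclusionRegion.sphere((0.3, -0.2, 0.1), 5.0)
        pts = generate_grid(region, PocketConfig())
        vol = len(pts) * 0.5 ** 3
        assert abs(vol - SPHERE_VOL) / SPHERE_VOL < 0.02

    def test_subgrid_sphere_may_be_empty(self):
        region = InclusionRegion.sphere((0.13, 0.17, 0.19), 0.12)
        pts = generate_grid(region, PocketConfig())
        assert len(pts) * 0.125 <= 0.125  # zero or one point

    def test_disjoint_spheres_are_additive(self):
        a = InclusionRegion.sphere((0, 0, 0), 3.0)
        b = InclusionRegion.sphere((20, 0, 0), 4.0)
        both = InclusionRegion(a.spheres + b.spheres)
        cfg = PocketConfig()
        assert len(generate_grid(both, cfg)) == \
            len(generate_grid(a, cfg)) + len(generate_grid(b, cfg))

    def test_refinement_converges_to_analytic(self):
        region = InclusionRegion.sphere((0.3, 0.1, -0.4), 5.0)
        err = []
        for spacing in (0.5, 0.25):
            pts = generate_grid(region, PocketConfig(grid_spacing=spacing))
            err.append(abs(len(pts) * spacing ** 3 - SPHERE_VOL))
        assert err[1] < err[0]

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            InclusionRegion(())
        with pytest.raises(ValueError):
            InclusionRegion.sphere((0, 0, 0), -1.0)


ONE_CARBON = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
END
"""


class TestCarve:
    def test_no_receptor_atoms_leave_points(self):
        pts = generate_grid(InclusionRegion.sphere((0, 0, 0), 3.0),
                            PocketConfig())
        empty = parse_structure(ONE_CARBON)
        empty.coords = empty.coords[:0]
        for field in ("serials", "names", "elements", "residue_names",
                      "residue_seqs", "chains", "occupancies", "is_hetero"):
            setattr(empty, field, getattr(empty, field)[:0])
        assert len(carve(pts, empty)) == len(pts)

    def test_single_carbon_carves_vdw_plus_pad(self):
        """A carbon (vdW 1.70) with the 1.09 pad removes everything within
        2.79 A and nothing beyond."""
        s = parse_structure(ONE_CARBON)
        pts = generate_grid(InclusionRegion.sphere((0, 0, 0), 5.0),
                            PocketConfig())
        kept = carve(pts, s)
        d_kept = np.linalg.norm(kept, axis=1)
        assert (d_kept >= 2.79 - 1e-9).all()
        removed = len(pts) - len(kept)
        inside = (np.linalg.norm(pts, axis=1) < 2.79).sum()
        assert removed == inside

    def test_adding_an_atom_never_increases_points(self):
        rng = np.random.default_rng(3)
        pts = generate_grid(InclusionRegion.sphere((0, 0, 0), 5.0),
                            PocketConfig())
        pdb1 = ONE_CARBON
        extra = ("ATOM      2  CB  ALA A   1       2.000   1.000   0.500"
                 "  1.00  0.00           C\nEND\n")
        pdb2 = pdb1.replace("END\n", extra)
        assert len(carve(pts, parse_structure(pdb2))) <= \
            len(carve(pts, parse_structure(pdb1)))
        del rng

    def test_unknown_element_without_fallback_rejected(self):
        s = parse_structure(ONE_CARBON)
        s.elements = np.array(["XX"])  # element outside the vdW table
        pts = generate_grid(InclusionRegion.sphere((0, 0, 0), 4.0),
                            PocketConfig())
        with pytest.raises(KeyError, match="XX"):
            carve(pts, s, PocketConfig(vdw_fallback=None))
        # with the default fallback radius the carve proceeds
        assert len(carve(pts, s)) < len(pts)


def _tetrahedron_pdb():
    verts = [(6, 6, 6), (6, -6, -6), (-6, 6, -6), (-6, -6, 6)]
    lines = []
    for i, (x, y, z) in enumerate(verts):
        lines.append(f"ATOM  {i + 1:>5d}  CA  GLY A{i + 1:>4d}    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
    return "\n".join(lines) + "\nEND\n"


class TestHullFilter:
    def test_inside_points_kept_outside_removed(self):
        s = parse_structure(_tetrahedron_pdb())
        pts = np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
        kept = hull_filter(pts, s)
        assert kept.tolist() == [[0.0, 0.0, 0.0]]

    def test_matches_halfspace_oracle(self, rng):
        """Point-in-hull decisions agree with a direct half-space test built
        from the hull facet equations."""
        from scipy.spatial import ConvexHull
        atoms = rng.normal(scale=5.0, size=(12, 3))
        lines = [f"ATOM  {i + 1:>5d}  CA  GLY A{i + 1:>4d}    "
                 f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
                 for i, (x, y, z) in enumerate(atoms)]
        s = parse_structure("\n".join(lines) + "\nEND\n")
        pts = rng.normal(scale=6.0, size=(300, 3))
        kept = {tuple(p) for p in hull_filter(pts, s)}
        hull = ConvexHull(atoms)
        inside = (pts @ hull.equations[:, :3].T
                  + hull.equations[:, 3]) <= 1e-9
        expected = {tuple(p) for p in pts[inside.all(axis=1)]}
        assert kept == expected

    def test_coplanar_atoms_rejected(self):
        lines = [f"ATOM  {i + 1:>5d}  CA  GLY A{i + 1:>4d}    "
                 f"{float(i):8.3f}{float(i * 2):8.3f}{0.0:8.3f}"
                 f"  1.00  0.00           C" for i in range(5)]
        s = parse_structure("\n".join(lines) + "\nEND\n")
        with pytest.raises(ValueError, match="hull"):
            hull_filter(np.zeros((2, 3)), s)


class TestContiguity:
    @staticmethod
    def _lattice(blocks, spacing=0.5):
        pts = []
        for (ox, oy, oz), n in blocks:
            for i, j, k in itertools.product(range(n), repeat=3):
                pts.append((ox + i * spacing, oy + j * spacing,
                            oz + k * spacing))
        return np.array(pts)

    def test_single_blob_unchanged(self):
        pts = self._lattice([((0, 0, 0), 3)])
        assert len(contiguity_filter(pts, PocketConfig())) == len(pts)

    def test_seeded_component_kept(self):
        pts = self._lattice([((0, 0, 0), 5), ((30, 0, 0), 2)])
        cfg = PocketConfig(contiguity_seed=(0.0, 0.0, 0.0))
        assert len(contiguity_filter(pts, cfg)) == 125
        cfg2 = PocketConfig(contiguity_seed=(30.0, 0.0, 0.0))
        assert len(contiguity_filter(pts, cfg2)) == 8

    def test_largest_component_default(self):
        pts = self._lattice([((0, 0, 0), 5), ((30, 0, 0), 2)])
        assert len(contiguity_filter(pts, PocketConfig())) == 125

    def test_matches_bfs_oracle(self, rng):
        """Component labelling on random lattices agrees with breadth-first
        search over the 26-neighbourhood."""
        from collections import deque
        occupied = {tuple(p) for p in rng.integers(0, 6, size=(60, 3))}
        pts = np.array(sorted(occupied), dtype=float) * 0.5
        kept = contiguity_filter(pts, PocketConfig())
        # BFS oracle on integer cells
        cells = {tuple(map(int, np.rint(p / 0.5))) for p in pts}
        comps = []
        seen = set()
        for start in sorted(cells):
            if start in seen:
                continue
            comp, queue = set(), deque([start])
            seen.add(start)
            while queue:
                c = queue.popleft()
                comp.add(c)
                for d in itertools.product((-1, 0, 1), repeat=3):
                    if d == (0, 0, 0):
                        continue
                    nb = (c[0] + d[0], c[1] + d[1], c[2] + d[2])
                    if nb in cells and nb not in seen:
                        seen.add(nb)
                        queue.append(nb)
            comps.append(comp)
        largest = max(comps, key=len)
        assert {tuple(map(int, np.rint(p / 0.5))) for p in kept} == largest


class TestFullPipeline:
    def test_hollow_shell_matches_analytic_cavity(self):
        pdb, expected = generate_pocket_fixture("sphere-shell",
                                                {"radius": 8.0})
        s = parse_structure(pdb)
        result = pocket_volume(s, InclusionRegion.sphere((0, 0, 0), 8.0))
        assert abs(result.volume - expected) / expected < 0.05

    def test_two_chamber_keeps_one_cavity(self):
        pdb, expected = generate_pocket_fixture(
            "two-chamber", {"radius_large": 8.0, "radius_small": 6.0})
        s = parse_structure(pdb)
        region = InclusionRegion((((0.0, 0.0, 0.0), 8.0),
                                  ((18.0, 0.0, 0.0), 6.0)))
        result = pocket_volume(s, region)
        assert abs(result.volume - expected) / expected < 0.05
        assert result.stage_counts["contiguity"] < \
            result.stage_counts["carve"]

    def test_stage_counts_monotone_on_random_fixtures(self, rng):
        for _ in range(3):
            radius = float(rng.uniform(6.0, 9.0))
            pdb, _ = generate_pocket_fixture("sphere-shell",
                                             {"radius": radius})
            s = parse_structure(pdb)
            result = pocket_volume(s, InclusionRegion.sphere((0, 0, 0),
                                                             radius))
            counts = [result.stage_counts[k]
                      for k in ("grid", "carve", "hull", "contiguity")]
            assert counts == sorted(counts, reverse=True)

    def test_rigid_rotation_invariance_within_surface_slack(self):
        """Rotating the structure and region together changes the measured
        volume by at most one grid cell per surface point."""
        pdb, _ = generate_pocket_fixture("sphere-shell", {"radius": 7.0})
        s = parse_structure(pdb)
        cfg = PocketConfig()
        base = pocket_volume(s, InclusionRegion.sphere((0, 0, 0), 7.0), cfg)
        rng = np.random.default_rng(8)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        s.coords[:] = s.coords @ Q.T
        rotated = pocket_volume(s, InclusionRegion.sphere((0, 0, 0), 7.0),
                                cfg)
        r_cav = 7.0 - 1.70 - 1.09
        surface_points = 4 * np.pi * r_cav ** 2 / cfg.grid_spacing ** 2
        slack = 2 * cfg.grid_spacing ** 3 * surface_points
        assert abs(base.volume - rotated.volume) <= slack

    def test_empty_inclusion_region_gives_zero(self):
        pdb, _ = generate_pocket_fixture("sphere-shell", {"radius": 8.0})
        s = parse_structure(pdb)
        # region entirely inside the carved zone next to the shell wall
        region = InclusionRegion.sphere((7.9, 0, 0), 0.4)
        result = pocket_volume(s, region)
        assert result.volume == 0.0


class TestGroupComparison:
    def test_identical_groups_null_center(self):
        out = compare_volume_groups({"a": [1.0, 2.0, 3.0],
                                     "b": [1.0, 2.0, 3.0]})
        pair = out["pairwise"]["a|b"]
        assert pair["median_difference"] == 0.0
        assert pair["U"] == pytest.approx(4.5)  # n*m/2 null center

    def test_disjoint_groups_maximal_separation(self):
        out = compare_volume_groups({"lo": [1, 2, 3], "hi": [101, 102, 103]})
        assert out["pairwise"]["lo|hi"]["U"] == 0.0
        assert out["groups"]["hi"]["mean"] == 102.0

    def test_statistic_matches_permutation_enumeration(self, rng):
        """Exact two-sided p-value agrees with exhaustive enumeration of all
        C(n+m, n) group relabellings for small samples."""
        x = sorted(rng.normal(size=5).tolist())
        y = sorted(rng.normal(loc=0.8, size=4).tolist())
        out = compare_volume_groups({"x": x, "y": y})["pairwise"]["x|y"]

        def u_stat(a, b):
            return sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)

        pooled = x + y
        obs = u_stat(x, y)
        n = len(x)
        more_extreme = total = 0
        for combo in itertools.combinations(range(len(pooled)), n):
            a = [pooled[i] for i in combo]
            b = [pooled[i] for i in range(len(pooled)) if i not in combo]
            u = u_stat(a, b)
            null_center = n * len(b) / 2
            if abs(u - null_center) >= abs(obs - null_center) - 1e-12:
                more_extreme += 1
            total += 1
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert out["U"] == pytest.approx(float(ref.statistic))
        assert out["p"] == pytest.approx(more_extreme / total, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_volume_groups({"only": [1.0]})
        with pytest.raises(ValueError):
            compare_volume_groups({"a": [1.0], "b": []})
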