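import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from tetherdyn import (
    DistanceMatrix,
    PCoAResult,
    build_schedules,
    eigen_accounting,
    group_dispersion,
    ks_matrix,
    pcoa,
)
from tetherdyn.ordination import pcoa_from_frames, pcoa_to_frames


def dm_from_points(points, labels=None):
    points = np.asarray(points, dtype=float)
    if labels is None:
        labels = [(f"p{i}", "G") for i in range(len(points))]
    return DistanceMatrix(labels=labels, D=squareform(pdist(points)))


def reconstructed_distances(p: PCoAResult) -> np.ndarray:
    """Pairwise distances implied by the embedding, with the signed
    negative-axis correction."""
    n = len(p.labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d2 = np.sum((p.real_coords[i] - p.real_coords[j]) ** 2) - np.sum(
                (p.imag_coords[i] - p.imag_coords[j]) ** 2
            )
            out[i, j] = np.sqrt(max(d2, 0.0))
    return out


class TestPcoa:
    def test_all_zero_matrix(self):
        dm = DistanceMatrix(labels=[("a", "G"), ("b", "G")], D=np.zeros((2, 2)))
        p = pcoa(dm)
        assert np.allclose(p.eigenvalues, 0)
        assert p.real_coords.shape == (2, 0)
        assert p.imag_coords.shape == (2, 0)

    def test_collinear_points_single_axis(self):
        dm = dm_from_points([[0.0], [3.0], [4.0]])
        p = pcoa(dm)
        rep = eigen_accounting(p)
        assert p.real_coords.shape[1] == 1
        assert p.imag_coords.shape[1] == 0
        assert rep.axis_share_of_positive[0] == pytest.approx(100.0)
        assert np.allclose(reconstructed_distances(p), dm.D, atol=1e-8)

    def test_non_euclidean_cycle_flagged(self):
        # four points with unit-cycle distances 0/1/2/1 cannot embed in
        # Euclidean space of any dimension
        D = np.array(
            [[0, 1, 2, 1], [1, 0, 1, 2], [2, 1, 0, 1], [1, 2, 1, 0]], dtype=float
        )
        labels = [(c, "G") for c in "abcd"]
        p = pcoa(DistanceMatrix(labels=labels, D=D))
        assert p.n_negative >= 1
        # independent oracle: eigendecompose the centered matrix directly
        J = np.eye(4) - np.ones((4, 4)) / 4
        ev = np.linalg.eigvalsh(J @ (-0.5 * D * D) @ J)
        assert ev.min() < -1e-8

    def test_random_euclidean_clouds_recovered(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(3, 13))
            dims = int(rng.integers(1, 5))
            pts = rng.normal(size=(n, dims))
            dm = dm_from_points(pts)
            p = pcoa(dm)
            assert p.n_negative == 0
            assert np.allclose(reconstructed_distances(p), dm.D, atol=1e-8)

    def test_trace_identity(self, study):
        dm = ks_matrix(build_schedules(study["risks"]))
        p = pcoa(dm)
        n = dm.D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = J @ (-0.5 * dm.D**2) @ J
        assert p.eigenvalues.sum() == pytest.approx(np.trace(B), abs=1e-8)

    def test_label_permutation_invariance(self, study):
        dm = ks_matrix(build_schedules(study["risks"]))
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(dm.labels))
        dm2 = DistanceMatrix(
            labels=[dm.labels[i] for i in perm], D=dm.D[np.ix_(perm, perm)]
        )
        p1, p2 = pcoa(dm), pcoa(dm2)
        assert np.allclose(p1.eigenvalues, p2.eigenvalues, atol=1e-10)
        d1 = group_dispersion(p1).group_means.set_index("group")["dispersion"]
        d2 = group_dispersion(p2).group_means.set_index("group")["dispersion"]
        pd.testing.assert_series_equal(d1, d2, atol=1e-10)

    def test_asymmetric_rejected(self):
        D = np.array([[0, 1.0], [0.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(DistanceMatrix(labels=[("a", "G"), ("b", "G")], D=D))

    def test_skbio_cross_check(self, study):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        dm = ks_matrix(build_schedules(study["risks"]))
        p = pcoa(dm)
        ref = skbio_ord.pcoa(dm.D, method="eigh")
        # skbio clamps negative eigenvalues to zero; compare the positive spectrum
        ref_pos = np.sort(ref.eigvals.to_numpy()[ref.eigvals.to_numpy() > 1e-10])[::-1]
        ours_pos = np.sort(p.eigenvalues[p.eigenvalues > 1e-10])[::-1]
        assert np.allclose(ours_pos, ref_pos, atol=1e-8)


class TestEigenAccounting:
    def test_no_negative_mass(self):
        p = PCoAResult(
            labels=[("a", "G")] * 3,
            eigenvalues=np.array([3.0, 1.0, 0.0]),
            real_coords=np.zeros((3, 2)),
            imag_coords=np.zeros((3, 0)),
            eig_tol=1e-8,
        )
        rep = eigen_accounting(p)
        assert rep.negative_share == 0.0
        assert rep.axis_share_of_positive[0] == pytest.approx(75.0)

    def test_negative_mass_hand_arithmetic(self):
        p = PCoAResult(
            labels=[("a", "G")] * 3,
            eigenvalues=np.array([3.0, 1.0, -0.5]),
            real_coords=np.zeros((3, 2)),
            imag_coords=np.zeros((3, 1)),
            eig_tol=1e-8,
        )
        rep = eigen_accounting(p)
        assert rep.negative_share == pytest.approx(100 * 0.5 / 4.5)
        assert rep.axis_share_of_positive[0] == pytest.approx(75.0)
        assert rep.axis_share_of_total_abs[0] == pytest.approx(100 * 3 / 4.5)

    def test_all_zero_errors(self):
        p = PCoAResult(
            labels=[("a", "G")] * 2,
            eigenvalues=np.zeros(2),
            real_coords=np.zeros((2, 0)),
            imag_coords=np.zeros((2, 0)),
        )
        with pytest.raises(ValueError, match="zero"):
            eigen_accounting(p)


class TestGroupDispersion:
    def test_identical_points(self):
        dm = DistanceMatrix(labels=[(f"p{i}", "G") for i in range(3)], D=np.zeros((3, 3)))
        disp = group_dispersion(pcoa(dm))
        assert (disp.distances["distance"] == 0).all()
        assert disp.group_means["dispersion"].iloc[0] == 0.0

    def test_unit_square(self):
        dm = dm_from_points([[0, 0], [0, 1], [1, 0], [1, 1]])
        disp = group_dispersion(pcoa(dm))
        assert np.allclose(disp.distances["distance"], np.sqrt(2) / 2, atol=1e-10)
        assert disp.group_means["dispersion"].iloc[0] == pytest.approx(np.sqrt(2) / 2)

    def test_euclidean_oracle_on_random_clouds(self):
        """On Euclidean input, dispersion equals direct distance-to-centroid
        computed from the raw coordinates."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            pts = rng.normal(size=(n, int(rng.integers(1, 4))))
            groups = rng.integers(0, 2, size=n)
            if min((groups == 0).sum(), (groups == 1).sum()) < 2:
                continue
            labels = [(f"p{i}", f"G{groups[i]}") for i in range(n)]
            disp = group_dispersion(pcoa(dm_from_points(pts, labels)))
            for g in (0, 1):
                member = pts[groups == g]
                direct = np.linalg.norm(member - member.mean(axis=0), axis=1).mean()
                got = disp.group_means.set_index("group").loc[f"G{g}", "dispersion"]
                assert got == pytest.approx(direct, abs=1e-8)

    def test_negative_axis_truncation(self):
        # one member's imaginary spread exceeds its real spread -> its
        # corrected squared distance is truncated to zero and counted
        p = PCoAResult(
            labels=[("a", "G"), ("b", "G"), ("c", "G")],
            eigenvalues=np.array([9.0, -4.0]),
            real_coords=np.array([[0.0], [0.0], [3.0]]),
            imag_coords=np.array([[0.0], [2.0], [0.0]]),
            eig_tol=1e-8,
        )
        disp = group_dispersion(p)
        assert disp.n_truncated == 1
        by = disp.distances.set_index("species")["distance"]
        assert by["b"] == 0.0
        assert by["a"] == pytest.approx(np.sqrt(1 - 4 / 9))
        assert by["c"] == pytest.approx(np.sqrt(4 - 4 / 9))

    def test_small_group_missing(self):
        dm = dm_from_points(
            [[0, 0], [0, 1], [1, 0]],
            labels=[("a", "G1"), ("b", "G1"), ("c", "G2")],
        )
        disp = group_dispersion(pcoa(dm))
        means = disp.group_means.set_index("group")["dispersion"]
        assert np.isnan(means["G2"])
        assert not np.isnan(means["G1"])

    def test_unassigned_label_rejected(self):
        dm = dm_from_points([[0.0], [1.0]])
        with pytest.raises(ValueError, match="without a group"):
            group_dispersion(pcoa(dm), groups={dm.labels[0]: "G"})

    def test_vegan_betadisper_cross_check(self, study):
        """vegan's betadisper (the reference implementation of
        distance-to-centroid dispersion) agrees on a KS matrix fixture."""
        dm = ks_matrix(build_schedules(study["risks"]))
        disp = group_dispersion(pcoa(dm))
        n = len(dm.labels)
        dvec = ",".join(f"{x:.17g}" for x in dm.D[np.triu_indices(n, k=1)])
        groups = ",".join(f'"{site}"' for _, site in dm.labels)
        script = f"""
        suppressMessages(library(vegan))
        d <- structure(c({dvec}), Size = {n}L, class = "dist")
        g <- factor(c({groups}))
        b <- betadisper(d, g, type = "centroid")
        cat(paste(levels(g), tapply(b$distances, g, mean), sep=","), sep="\\n")
        """
        try:
            res = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
            )
        except FileNotFoundError:
            pytest.skip("Rscript not available")
        assert res.returncode == 0, res.stderr
        ref = {}
        for line in res.stdout.strip().splitlines():
            site, val = line.split(",")
            ref[site] = float(val)
        ours = disp.group_means.set_index("group")["dispersion"]
        for site, val in ref.items():
            assert ours[site] == pytest.approx(val, abs=1e-6)


def test_pcoa_frame_round_trip(study):
    dm = ks_matrix(build_schedules(study["risks"]))
    p = pcoa(dm)
    eig, coords = pcoa_to_frames(p)
    back = pcoa_from_frames(eig, coords)
    assert back.labels == p.labels
    assert np.allclose(back.eigenvalues, p.eigenvalues)
    assert np.allclose(back.real_coords, p.real_coords)
    assert np.allclose(back.imag_coords, p.imag_coords)
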