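"""Principal coordinates analysis and multivariate group dispersion.

PCoA embeds a distance matrix by eigendecomposition of the Gower
double-centered matrix B = -1/2 J (D o D) J with J = I - 11'/n.  Distances
that are not Euclidean-embeddable (KS distance matrices generally are not)
produce negative eigenvalues; those axes are retained as "imaginary"
coordinates scaled by sqrt(|lambda|).

Group dispersion follows the distance-to-centroid definition used for
multivariate homogeneity-of-dispersion analysis (vegan's betadisper): the
squared distance of a member to its group centroid is the squared Euclidean
distance on the positive axes *minus* the squared distance on the negative
axes; negative corrected squares are truncated to zero and counted.  The
per-site mean distance is the site's "among-species variation" in seasonal
predation schedules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schedules import DistanceMatrix

logger = logging.getLogger(__name__)

EIG_RTOL = 1e-8
TRACE_TOL = 1e-8


@dataclass
class PCoAResult:
    """Signed eigenvalues and real/imaginary principal coordinates.

    ``eigenvalues`` are all n eigenvalues in descending order;
    ``real_coords`` has one column per eigenvalue above +tol and
    ``imag_coords`` one per eigenvalue below -tol, each column scaled by
    sqrt(|lambda|).  ``eig_tol`` is the absolute magnitude threshold used.
    """

    labels: list[tuple[str, str]]
    eigenvalues: np.ndarray
    real_coords: np.ndarray
    imag_coords: np.ndarray
    eig_tol: float = 0.0

    @property
    def n_negative(self) -> int:
        return self.imag_coords.shape[1]


def pcoa(dm: DistanceMatrix, eig_rtol: float = EIG_RTOL) -> PCoAResult:
    """Principal coordinates analysis of a symmetric distance matrix.

    Eigenvalues with |lambda| < eig_rtol * max|lambda| are treated as zero.
    The sum of eigenvalues equals the trace of the centered matrix (checked
    to 1e-8); axis signs are fixed so each column's first nonzero loading is
    positive, for reproducible serialized output.
    """
    D = dm.D
    n = D.shape[0]
    if np.max(np.abs(D - D.T)) > 1e-12:
        raise ValueError("distance matrix must be symmetric")
    A = -0.5 * D * D
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if abs(eigval.sum() - np.trace(B)) > TRACE_TOL * max(1.0, np.abs(eigval).max()):
        raise AssertionError("eigenvalue sum does not match centered-matrix trace")
    tol = eig_rtol * (np.abs(eigval).max() if n and np.abs(eigval).max() > 0 else 0.0)
    pos = eigval > tol
    neg = eigval < -tol
    real = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    for coords in (real, imag):
        for k in range(coords.shape[1]):
            col = coords[:, k]
            nz = np.nonzero(np.abs(col) > 1e-12 * np.abs(col).max())[0]
            if nz.size and col[nz[0]] < 0:
                coords[:, k] = -col
    if neg.any():
        logger.info(
            "distance matrix is non-Euclidean: %d negative eigenvalue(s), "
            "most negative %.3g", int(neg.sum()), float(eigval.min()),
        )
    return PCoAResult(
        labels=list(dm.labels),
        eigenvalues=eigval,
        real_coords=real,
        imag_coords=imag,
        eig_tol=float(tol),
    )


@dataclass(frozen=True)
class EigenReport:
    """Eigenvalue mass accounting under both share conventions.

    ``negative_share`` is the percent of total |eigenvalue| mass on negative
    axes.  Per positive axis, ``axis_share_of_positive`` is its percent of
    the positive-eigenvalue sum (sums to 100) and ``axis_share_of_total_abs``
    its percent of the total absolute mass.
    """

    negative_share: float
    axis_share_of_positive: np.ndarray
    axis_share_of_total_abs: np.ndarray


def eigen_accounting(p: PCoAResult) -> EigenReport:
    ev = p.eigenvalues
    pos = ev[ev > p.eig_tol]
    neg = ev[ev < -p.eig_tol]
    total_abs = np.abs(pos).sum() + np.abs(neg).sum()
    if total_abs == 0:
        raise ValueError("all eigenvalues are zero")
    return EigenReport(
        negative_share=float(100.0 * np.abs(neg).sum() / total_abs),
        axis_share_of_positive=100.0 * pos / pos.sum(),
        axis_share_of_total_abs=100.0 * pos / total_abs,
    )


@dataclass
class DispersionResult:
    """Distance-to-centroid per label and mean dispersion per group."""

    distances: pd.DataFrame  # columns: species, site, group, distance
    group_means: pd.DataFrame  # columns: group, dispersion, n_members
    centroids_real: dict[str, np.ndarray] = field(default_factory=dict)
    centroids_imag: dict[str, np.ndarray] = field(default_factory=dict)
    n_truncated: int = 0


def groups_by_site(labels: list[tuple[str, str]]) -> dict[tuple[str, str], str]:
    return {lab: lab[1] for lab in labels}


def group_dispersion(
    p: PCoAResult, groups: dict[tuple[str, str], str] | None = None
) -> DispersionResult:
    """Mean distance of group members to their multivariate centroid.

    Centroids are per-axis means over all retained axes (positive and
    negative).  Member squared distances apply the signed correction
    real^2 - imaginary^2; a negative corrected square (possible with strongly
    non-Euclidean input) is truncated to zero and counted.  Groups with
    fewer than two members get a missing (NaN) dispersion with a warning.
    """
    if groups is None:
        groups = groups_by_site(p.labels)
    missing = [lab for lab in p.labels if lab not in groups]
    if missing:
        raise ValueError(f"labels without a group assignment: {missing}")
    rows = []
    centroids_real: dict[str, np.ndarray] = {}
    centroids_imag: dict[str, np.ndarray] = {}
    n_trunc = 0
    group_names = sorted(set(groups[lab] for lab in p.labels))
    idx_by_group = {
        g: [i for i, lab in enumerate(p.labels) if groups[lab] == g] for g in group_names
    }
    for g in group_names:
        idx = idx_by_group[g]
        c_real = p.real_coords[idx].mean(axis=0)
        c_imag = p.imag_coords[idx].mean(axis=0)
        centroids_real[g], centroids_imag[g] = c_real, c_imag
        for i in idx:
            d2 = float(
                np.sum((p.real_coords[i] - c_real) ** 2)
                - np.sum((p.imag_coords[i] - c_imag) ** 2)
            )
            if d2 < 0:
                n_trunc += 1
                logger.warning(
                    "negative corrected squared distance %.3g truncated to 0 "
                    "for %s in group %s", d2, p.labels[i], g,
                )
                d2 = 0.0
            sp, site = p.labels[i]
            rows.append(
                {"species": sp, "site": site, "group": g, "distance": float(np.sqrt(d2))}
            )
    distances = pd.DataFrame(rows)
    means = []
    for g in group_names:
        member = distances[distances["group"] == g]["distance"]
        if len(member) < 2:
            logger.warning("group %s has %d member(s); dispersion is missing", g, len(member))
            disp = np.nan
        else:
            disp = float(member.mean())
        means.append({"group": g, "dispersion": disp, "n_members": len(member)})
    return DispersionResult(
        distances=distances,
        group_means=pd.DataFrame(means),
        centroids_real=centroids_real,
        centroids_imag=centroids_imag,
        n_truncated=n_trunc,
    )


def pcoa_to_frames(p: PCoAResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize a PCoAResult to (eigenvalues, coordinates) data frames."""
    eig = pd.DataFrame({"axis": np.arange(1, len(p.eigenvalues) + 1),
                        "eigenvalue": p.eigenvalues})
    names = [f"{sp}@{site}" for sp, site in p.labels]
    cols = {}
    for k in range(p.real_coords.shape[1]):
        cols[f"PCo{k + 1}"] = p.real_coords[:, k]
    for k in range(p.imag_coords.shape[1]):
        cols[f"iPCo{k + 1}"] = p.imag_coords[:, k]
    coords = pd.DataFrame(cols, index=pd.Index(names, name="label")).reset_index()
    return eig, coords


def pcoa_from_frames(eig: pd.DataFrame, coords: pd.DataFrame,
                     eig_rtol: float = EIG_RTOL) -> PCoAResult:
    labels = [tuple(name.split("@", 1)) for name in coords["label"]]
    eigval = eig["eigenvalue"].to_numpy(dtype=float)
    real_cols = [c for c in coords.columns if c.startswith("PCo")]
    imag_cols = [c for c in coords.columns if c.startswith("iPCo")]
    tol = eig_rtol * (np.abs(eigval).max() if len(eigval) else 0.0)
    return PCoAResult(
        labels=labels,
        eigenvalues=eigval,
        real_coords=coords[real_cols].to_numpy(dtype=float)
        if real_cols else np.zeros((len(labels), 0)),
        imag_coords=coords[imag_cols].to_numpy(dtype=float)
        if imag_cols else np.zeros((len(labels), 0)),
        eig_tol=float(tol),
    )
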