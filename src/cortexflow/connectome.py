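"""Core containers for directed, weighted mesoscale connectomes.

A connectome here is a set of anatomical areas (nodes) and directed axonal
projections (links) with non-negative weights.  Two weight conventions are
supported:

``FLNe``
    Fraction of Labelled Neurons extrinsic — each measured target's in-weights
    are normalised to sum to 1, so the weighted in-degree of every connected
    target is exactly 1.
``LNe``
    Labelled Neurons extrinsic — absolute labelled-cell counts; the column sum
    at a target equals its total extrinsic count LNe(t) = Σ_s LNe(s, t).

Throughout the package ``W[s, t]`` holds the weight of the link from source
row ``s`` to target column ``t``; an area is *measured* iff it was a tracer
injection site, i.e. its in-links (column) were observed.  Unmeasured columns
are identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

WeightKind = Literal["FLNe", "LNe"]

__all__ = [
    "NodeMeta",
    "InjectionRecord",
    "Connectome",
    "flne_to_lne",
    "lne_to_flne",
    "compute_distances",
]


@dataclass(frozen=True)
class NodeMeta:
    """Metadata for a single anatomical area.

    Parameters
    ----------
    label : str
        Area acronym, unique within a connectome.
    region : str or None
        Lobe/region tag (free text).
    coord : tuple of 3 floats or None
        Centroid coordinates in mm.
    measured : bool
        True iff the area was a tracer injection site, i.e. its in-links
        were measured.
    """

    label: str
    region: str | None = None
    coord: tuple[float, float, float] | None = None
    measured: bool = False

    def __post_init__(self) -> None:
        if self.coord is not None:
            c = np.asarray(self.coord, dtype=float)
            if c.shape != (3,) or not np.all(np.isfinite(c)):
                raise ValueError(
                    f"node {self.label!r}: coord must be a finite 3-vector"
                )


@dataclass(frozen=True)
class InjectionRecord:
    """One retrograde tracer experiment at a target area.

    ``LNi`` counts labelled neurons intrinsic to the injected volume,
    ``LNe_total`` the extrinsic ones (all source areas) and ``LNtot`` their
    sum; repeated injections at the same target yield multiple records.
    """

    target: str
    injection_volume: float = float("nan")
    LNi: float = float("nan")
    LNe_total: float = float("nan")
    LNtot: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("LNi", "LNe_total", "LNtot"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"injection record {self.target!r}: {name} < 0")
        if (
            np.isfinite(self.LNi)
            and np.isfinite(self.LNe_total)
            and np.isfinite(self.LNtot)
            and not np.isclose(self.LNtot, self.LNi + self.LNe_total, atol=1e-6)
        ):
            raise ValueError(
                f"injection record {self.target!r}: LNtot != LNi + LNe_total"
            )


@dataclass
class Connectome:
    """A directed weighted network of cortical areas.

    Attributes
    ----------
    labels : list of str
        Area acronyms, defining the row/column order of ``W``.
    W : ndarray of shape (n, n)
        Link weights, rows = sources, columns = targets.
    weight_kind : {"FLNe", "LNe"}
        Normalisation convention of ``W``.
    measured : ndarray of bool, shape (n,)
        True for injection sites (columns with observed in-links).
    coords : ndarray of shape (n, 3) or None
        Area centroids in mm.
    regions : list of str or None
        Optional region tags, aligned with ``labels``.
    D : ndarray of shape (n, n) or None
        Pairwise inter-area distances in mm (symmetric, zero diagonal).
    """

    labels: list[str]
    W: np.ndarray
    weight_kind: WeightKind = "LNe"
    measured: np.ndarray | None = None
    coords: np.ndarray | None = None
    regions: list[str | None] | None = None
    D: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate node labels: {dupes}")
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (n, n):
            raise ValueError(f"W has shape {self.W.shape}, expected ({n}, {n})")
        if np.any(self.W < 0):
            raise ValueError("negative link weight")
        if np.any(np.diag(self.W) != 0):
            bad = [self.labels[i] for i in np.nonzero(np.diag(self.W))[0]]
            raise ValueError(f"self-links not allowed: {bad}")
        if self.weight_kind not in ("FLNe", "LNe"):
            raise ValueError(f"unknown weight_kind {self.weight_kind!r}")
        if self.measured is None:
            # fall back: a column with any in-weight must have been injected
            self.measured = self.W.sum(axis=0) > 0
        self.measured = np.asarray(self.measured, dtype=bool)
        if self.measured.shape != (n,):
            raise ValueError("measured flag vector has wrong length")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 3):
                raise ValueError(f"coords has shape {self.coords.shape}, expected ({n}, 3)")
            if not np.all(np.isfinite(self.coords)):
                raise ValueError("non-finite coordinates")
        if self.D is not None:
            self.D = np.asarray(self.D, dtype=float)
            if self.D.shape != (n, n):
                raise ValueError("D has wrong shape")
        if self.weight_kind == "FLNe":
            colsums = self.W.sum(axis=0)
            connected = self.measured & (colsums > 0)
            if connected.any() and not np.allclose(colsums[connected], 1.0, atol=1e-9):
                bad = [
                    self.labels[i]
                    for i in np.nonzero(connected & ~np.isclose(colsums, 1.0, atol=1e-9))[0]
                ]
                raise ValueError(f"FLNe columns must sum to 1; offending targets: {bad}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_links(self) -> int:
        return int(np.count_nonzero(self.W))

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown area label {label!r}") from None

    def node_meta(self) -> list[NodeMeta]:
        out = []
        for i, lab in enumerate(self.labels):
            out.append(
                NodeMeta(
                    label=lab,
                    region=None if self.regions is None else self.regions[i],
                    coord=None if self.coords is None else tuple(self.coords[i]),
                    measured=bool(self.measured[i]),
                )
            )
        return out

    def copy(self) -> "Connectome":
        return replace(
            self,
            labels=list(self.labels),
            W=self.W.copy(),
            measured=self.measured.copy(),
            coords=None if self.coords is None else self.coords.copy(),
            regions=None if self.regions is None else list(self.regions),
            D=None if self.D is None else self.D.copy(),
            meta=dict(self.meta),
        )


def _combined_totals(
    records: Iterable[InjectionRecord], combine: str
) -> dict[str, float]:
    """Pool repeated injections per target into a single LNe total."""
    by_target: dict[str, list[float]] = {}
    for r in records:
        if not np.isfinite(r.LNe_total):
            raise ValueError(f"injection record {r.target!r} has no LNe total")
        by_target.setdefault(r.target, []).append(float(r.LNe_total))
    reducers = {"mean": np.mean, "sum": np.sum, "max": np.max}
    if combine not in reducers:
        raise ValueError(f"combine must be one of {sorted(reducers)}, got {combine!r}")
    return {t: float(reducers[combine](v)) for t, v in by_target.items()}


def flne_to_lne(
    c: Connectome,
    records: Sequence[InjectionRecord],
    combine: str = "mean",
) -> Connectome:
    """Rescale fractional in-weights back to absolute labelled-neuron counts.

    Each measured target column of the FLNe matrix is multiplied by that
    target's pooled total extrinsic count T(t), so that afterwards
    Σ_s W[s, t] = T(t).  Repeated experiments at one target are pooled by
    ``combine`` (``mean`` by default; ``sum``/``max`` selectable).

    Raises
    ------
    ValueError
        If a measured, connected target has no injection record, or its
        pooled total is not positive.
    """
    if c.weight_kind != "FLNe":
        raise ValueError(f"expected an FLNe connectome, got {c.weight_kind}")
    totals = _combined_totals(records, combine)
    out = c.copy()
    colsums = c.W.sum(axis=0)
    for j, lab in enumerate(c.labels):
        if not c.measured[j] or colsums[j] == 0:
            continue
        if lab not in totals:
            raise ValueError(f"measured target {lab!r} has in-links but no injection record")
        T = totals[lab]
        if T <= 0:
            raise ValueError(f"non-positive pooled LNe total for target {lab!r}: {T}")
        out.W[:, j] = c.W[:, j] * T
    out.weight_kind = "LNe"
    return out


def lne_to_flne(c: Connectome) -> Connectome:
    """Column-normalise absolute counts to fractional weights (FLNe).

    Every non-zero column is divided by its sum; zero columns (unmeasured or
    unconnected targets) are left zero, never NaN.
    """
    if c.weight_kind != "LNe":
        raise ValueError(f"expected an LNe connectome, got {c.weight_kind}")
    out = c.copy()
    colsums = c.W.sum(axis=0)
    nz = colsums > 0
    out.W[:, nz] = c.W[:, nz] / colsums[nz]
    out.weight_kind = "FLNe"
    return out


def compute_distances(c: Connectome) -> Connectome:
    """Attach the Euclidean inter-centroid distance matrix D (mm).

    Requires coordinates for every node.  D is symmetric with a zero
    diagonal.
    """
    if c.coords is None:
        raise ValueError("connectome has no coordinates; cannot compute distances")
    out = c.copy()
    out.D = squareform(pdist(c.coords, metric="euclidean"))
    return out
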