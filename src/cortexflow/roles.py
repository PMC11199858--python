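"""Node role cartography: participation coefficients, z-scores, R1-R7 roles.

Given a module partition, each node is placed in the (P, z) plane per link
direction.  The participation coefficient

    P_i = 1 - sum_m (s_im / s_i)^2

measures how evenly node i's (weighted) links spread over modules (0 =
purely local, -> 1 = spread across all modules), and the within-module
z-score standardises its degree to its own module against the module's
mean and population standard deviation.  The plane is divided by the
Guimera-Amaral heuristics into seven roles: non-hubs (z <= 2.5) R1
ultra-peripheral, R2 peripheral, R3 connector, R4 kinless; hubs (z > 2.5)
R5 provincial, R6 connector, R7 kinless.  Nodes with 2 < z <= 2.5 are
flagged marginal hubs.  The boundary constants are configurable — they were
calibrated on metabolic networks and may need revisiting for cortex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .community import Partition
from .connectome import Connectome

__all__ = [
    "RoleBoundaries",
    "RoleAssignment",
    "participation",
    "within_module_z",
    "classify_role",
    "assign_roles",
    "extract_hubs_and_connectors",
    "CartographyClassifier",
]


@dataclass(frozen=True)
class RoleBoundaries:
    """Thresholds dividing the (P, z) plane into roles R1-R7."""

    z_hub: float = 2.5
    z_marginal: float = 2.0
    nonhub_p: tuple[float, float, float] = (0.05, 0.62, 0.80)  # R1|R2|R3|R4
    hub_p: tuple[float, float] = (0.30, 0.75)  # R5|R6|R7


@dataclass
class RoleAssignment:
    """Role of one node for one link direction."""

    label: str
    direction: str
    P: float
    z: float
    role: str
    marginal_hub: bool


def _partition_labels(c: Connectome, partition) -> np.ndarray:
    if isinstance(partition, Partition):
        lut = {lab: int(m) for lab, m in zip(partition.labels, partition.modules)}
        return np.array([lut[lab] for lab in c.labels], dtype=int)
    if isinstance(partition, dict):
        return np.array([int(partition[lab]) for lab in c.labels], dtype=int)
    a = np.asarray(partition, dtype=int)
    if a.shape != (c.n_nodes,):
        raise ValueError("partition array length mismatch")
    return a


def _module_degrees(
    c: Connectome, modules: np.ndarray, direction: str, weighted: bool
) -> np.ndarray:
    """Matrix S[i, m]: (weighted) degree of node i towards module m."""
    if direction not in ("in", "out"):
        raise ValueError("direction must be 'in' or 'out'")
    A = c.W if weighted else (c.W > 0).astype(float)
    # out: links i -> j; in: links j -> i
    M = A if direction == "out" else A.T
    k = int(modules.max()) + 1 if modules.size else 0
    S = np.zeros((c.n_nodes, max(k, 1)))
    for m in range(k):
        S[:, m] = M[:, modules == m].sum(axis=1)
    # links towards orphan nodes (module -1) still count in the totals
    orphan_cols = modules < 0
    extra = M[:, orphan_cols].sum(axis=1)
    return S, extra


def participation(
    c: Connectome, partition, direction: str = "out", weighted: bool = True
) -> np.ndarray:
    """Participation coefficient P_i = 1 - sum_m (s_im / s_i)^2 per node.

    ``s_im`` is node i's (weighted, unless ``weighted=False``) degree to
    module m in the given direction and ``s_i`` its total.  Nodes with no
    links in that direction get P = 0.
    """
    modules = _partition_labels(c, partition)
    S, extra = _module_degrees(c, modules, direction, weighted)
    tot = S.sum(axis=1) + extra
    P = np.zeros(c.n_nodes)
    nz = tot > 0
    frac2 = (S[nz] / tot[nz, None]) ** 2
    P[nz] = 1.0 - frac2.sum(axis=1) - (extra[nz] / tot[nz]) ** 2
    return np.clip(P, 0.0, 1.0)


def within_module_z(
    c: Connectome, partition, direction: str = "out", weighted: bool = True
) -> np.ndarray:
    """Within-module degree z-score per node.

    kappa_i is i's (weighted) degree to its own module; z standardises it
    over the members of that module using the population standard
    deviation.  Modules with zero spread (singletons, uniform kappa) give
    z = 0 rather than an error; orphans get z = 0.
    """
    modules = _partition_labels(c, partition)
    S, _ = _module_degrees(c, modules, direction, weighted)
    z = np.zeros(c.n_nodes)
    for m in np.unique(modules[modules >= 0]):
        members = np.nonzero(modules == m)[0]
        kappa = S[members, m]
        sd = kappa.std(ddof=0)
        if sd > 0:
            z[members] = (kappa - kappa.mean()) / sd
    return z


def classify_role(P: float, z: float, boundaries: RoleBoundaries = RoleBoundaries()) -> str:
    """Map a (P, z) pair to its cartography role R1..R7.

    Hubs require z > ``z_hub`` (2.5 by default): R5 provincial
    (P <= 0.30), R6 connector (0.30 < P <= 0.75), R7 kinless (P > 0.75).
    Non-hubs: R1 (P <= 0.05), R2 (P <= 0.62), R3 (P <= 0.80), R4 above.
    """
    if not (0.0 <= P <= 1.0):
        raise ValueError(f"P must lie in [0, 1], got {P}")
    b = boundaries
    if z > b.z_hub:
        if P <= b.hub_p[0]:
            return "R5"
        if P <= b.hub_p[1]:
            return "R6"
        return "R7"
    p1, p2, p3 = b.nonhub_p
    if P <= p1:
        return "R1"
    if P <= p2:
        return "R2"
    if P <= p3:
        return "R3"
    return "R4"


def assign_roles(
    c: Connectome,
    partition,
    direction: str = "out",
    weighted: bool = True,
    boundaries: RoleBoundaries = RoleBoundaries(),
) -> list[RoleAssignment]:
    """Compute (P, z) and roles for every node, one link direction."""
    P = participation(c, partition, direction, weighted)
    z = within_module_z(c, partition, direction, weighted)
    out = []
    for lab, p_i, z_i in zip(c.labels, P, z):
        role = classify_role(float(p_i), float(z_i), boundaries)
        marginal = boundaries.z_marginal < z_i <= boundaries.z_hub
        out.append(RoleAssignment(lab, direction, float(p_i), float(z_i), role, bool(marginal)))
    return out


def roles_frame(roles: list[RoleAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "direction": r.direction,
                "P": r.P,
                "z": r.z,
                "role": r.role,
                "marginal_hub": r.marginal_hub,
            }
            for r in roles
        ]
    )


def extract_hubs_and_connectors(
    roles_in: list[RoleAssignment],
    roles_out: list[RoleAssignment],
    top_n: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Rank hubs, marginal hubs and non-hub connectors over both directions.

    Hubs are R5/R6/R7 nodes in either direction, ranked by z descending;
    connectors are non-hub R3/R4 nodes ranked by P descending; marginal
    hubs (2 < z <= 2.5) are listed separately.
    """
    df = roles_frame(list(roles_in) + list(roles_out))
    hubs = df[df.role.isin(("R5", "R6", "R7"))].sort_values(
        ["z", "label"], ascending=[False, True]
    )
    connectors = df[df.role.isin(("R3", "R4"))].sort_values(
        ["P", "label"], ascending=[False, True]
    )
    marginal = df[df.marginal_hub & ~df.role.isin(("R5", "R6", "R7"))].sort_values(
        ["z", "label"], ascending=[False, True]
    )
    if top_n is not None:
        hubs, connectors, marginal = (
            hubs.head(top_n),
            connectors.head(top_n),
            marginal.head(top_n),
        )
    return {
        "hubs": hubs.reset_index(drop=True),
        "connectors": connectors.reset_index(drop=True),
        "marginal_hubs": marginal.reset_index(drop=True),
    }


class CartographyClassifier(BaseEstimator):
    """Sklearn-style role classifier over a fitted module partition.

    ``fit(X, y)`` takes the adjacency matrix (rows = sources) and the module
    labels ``y`` (e.g. ``MapEquation(...).fit(X).labels_``) and computes
    participation coefficients, z-scores and roles for the configured link
    direction.
    """

    def __init__(
        self,
        direction: str = "out",
        weighted: bool = True,
        z_hub: float = 2.5,
        z_marginal: float = 2.0,
    ):
        self.direction = direction
        self.weighted = weighted
        self.z_hub = z_hub
        self.z_marginal = z_marginal

    def fit(self, X, y):
        W = np.asarray(X, dtype=float)
        labels = [f"n{i}" for i in range(W.shape[0])]
        c = Connectome(labels=labels, W=W, weight_kind="LNe",
                       measured=np.ones(W.shape[0], dtype=bool))
        b = RoleBoundaries(z_hub=self.z_hub, z_marginal=self.z_marginal)
        modules = np.asarray(y, dtype=int)
        self.participation_ = participation(c, modules, self.direction, self.weighted)
        self.z_ = within_module_z(c, modules, self.direction, self.weighted)
        self.roles_ = np.array(
            [classify_role(float(p), float(z), b) for p, z in zip(self.participation_, self.z_)]
        )
        self.marginal_hub_ = (self.z_ > self.z_marginal) & (self.z_ <= self.z_hub)
        return self

    def fit_predict(self, X, y):
        return self.fit(X, y).roles_
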