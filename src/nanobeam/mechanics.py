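"""Axial spring-network mechanics of DNA origami nanobeams.

Each helix is a chain of bp-resolution axial springs of stiffness
``EA / rise`` (EA ~ 1100 pN for B-form DNA, rise 0.34 nm/bp).  Elements at
Holliday-junction crossovers and at nicks are locally degraded by
dimensionless factors ``alpha`` and ``beta``:

* HJ: a block of ``n_hj`` contiguous elements (default 5) per helix per
  junction participation, stiffness ``alpha * EA / rise``;
* nick: a block of ``n_nick`` elements (default 1), stiffness
  ``beta * EA / rise``.

Crossovers rigidly constrain the neighbouring helices at the junction
position; rigid end plates gather all helices at both termini.  One plate is
fixed, an axial force is applied to the other, and the linear equilibrium is
solved exactly on the merged degrees of freedom (rigid ties are handled by
union-find DOF merging, so the constraints are exact).

Apparent axial stiffness follows the flow-stretching convention:
``K = (dF/d_delta) * L0`` in pN, which for a single intact helix equals EA
for any length.

For periodic designs a homogenized closed form serves as an analytic oracle:
one 21 bp repeat with per-helix densities ``j`` (junction participations) and
``nu`` (nicks) has compliance, in intact-element units,

    C_rep = (21 - n_hj*j - n_nick*nu) + n_hj*j/alpha + n_nick*nu/beta

and the bundle stiffness is ``K = n_helices * EA * 21 / C_rep``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .designs import NanobeamDesign, REPEAT_BP
from .errors import SingularSystemError, ValidationError

#: Element labels.
DS, HJ, NICK = "DS", "HJ", "NICK"

#: Reference force (pN) at which the force-extension slope is evaluated.
#: The model is linear, so any positive value gives the same stiffness; the
#: value is recorded for provenance.
REFERENCE_FORCE_PN = 20.0


@dataclass(frozen=True)
class MaterialParams:
    """Elastic properties of the bp elements.

    ``EA`` is the stretch modulus of intact B-form duplex in pN; ``alpha``
    and ``beta`` are the local degradation factors at HJ and nick elements;
    ``n_hj``/``n_nick`` are the degraded block spans in bp.
    """

    EA: float = 1100.0
    rise_per_bp: float = 0.34
    alpha: float = 1.0
    beta: float = 1.0
    n_hj: int = 5
    n_nick: int = 1

    def __post_init__(self) -> None:
        if self.EA <= 0:
            raise ValidationError("EA must be > 0")
        if self.rise_per_bp <= 0:
            raise ValidationError("rise_per_bp must be > 0")
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must be in (0, 1]")
        if not 0 < self.beta <= 1:
            raise ValidationError("beta must be in (0, 1]")
        if self.n_hj < 1 or self.n_nick < 1:
            raise ValidationError("block spans must be >= 1")

    @property
    def k_intact(self) -> float:
        """Stiffness of one intact bp element, pN/nm."""
        return self.EA / self.rise_per_bp

    def with_factors(self, alpha: float | None = None,
                     beta: float | None = None) -> "MaterialParams":
        return replace(self, alpha=self.alpha if alpha is None else alpha,
                       beta=self.beta if beta is None else beta)


@dataclass
class SpringSystem:
    """Assembled axial spring network.

    Nodes are bp boundaries, one per helix: node id ``h * (bp + 1) + i`` for
    helix ``h`` and boundary ``i`` in ``0..bp``.  ``rigid_ties`` are sets of
    node ids constrained to equal axial displacement (junction ties and the
    two end plates).  The plate containing boundary 0 is fixed; the force is
    applied to the plate containing boundary ``bp``.
    """

    n_helices: int
    bp_per_helix: int
    node_a: np.ndarray          # spring endpoint ids
    node_b: np.ndarray
    stiffness: np.ndarray       # pN/nm per spring
    labels: np.ndarray          # element label per spring (DS/HJ/NICK)
    rigid_ties: list[frozenset[int]]
    fixed_plate: frozenset[int] = field(default_factory=frozenset)
    loaded_plate: frozenset[int] = field(default_factory=frozenset)

    @property
    def n_nodes(self) -> int:
        return self.n_helices * (self.bp_per_helix + 1)


def _element_block(pos: int, span: int, bp: int, what: str) -> range:
    """Element indices of a degraded block centered on element ``pos``."""
    start = pos - span // 2
    stop = start + span
    if start < 0 or stop > bp:
        raise ValidationError(
            f"{what} block at position {pos} (span {span}) extends outside "
            f"the helix (0..{bp - 1})")
    return range(start, stop)


def assemble(design: NanobeamDesign, material: MaterialParams) -> SpringSystem:
    """Assemble the spring network for a design.

    Raises :class:`ValidationError` if any degraded blocks overlap on a
    helix, naming the offending positions.
    """
    bp = design.bp_per_helix
    n = design.n_helices
    labels = np.full((n, bp), DS, dtype=object)
    owner = np.full((n, bp), -1, dtype=int)  # position that claimed an element

    def claim(h: int, elems: range, lab: str, pos: int) -> None:
        for e in elems:
            if labels[h, e] != DS:
                raise ValidationError(
                    f"overlapping degraded blocks on helix {h}: "
                    f"{lab} at {pos} collides with {labels[h, e]} at "
                    f"{owner[h, e]} (element {e})")
            labels[h, e] = lab
            owner[h, e] = pos

    for (a, b), pos in design.junction_sites:
        block = _element_block(pos, material.n_hj, bp, "HJ")
        claim(a, block, HJ, pos)
        claim(b, block, HJ, pos)
    for h, pos in design.nick_sites:
        block = _element_block(pos, material.n_nick, bp, "nick")
        claim(h, block, NICK, pos)

    factor = {DS: 1.0, HJ: material.alpha, NICK: material.beta}
    k = material.k_intact
    node = lambda h, i: h * (bp + 1) + i
    node_a = np.empty(n * bp, dtype=int)
    node_b = np.empty(n * bp, dtype=int)
    stiff = np.empty(n * bp, dtype=float)
    labs = np.empty(n * bp, dtype=object)
    s = 0
    for h in range(n):
        for e in range(bp):
            node_a[s] = node(h, e)
            node_b[s] = node(h, e + 1)
            labs[s] = labels[h, e]
            stiff[s] = factor[labels[h, e]] * k
            s += 1

    ties: list[frozenset[int]] = []
    for (a, b), pos in design.junction_sites:
        ties.append(frozenset((node(a, pos), node(b, pos))))
    fixed = frozenset(node(h, 0) for h in range(n))
    loaded = frozenset(node(h, bp) for h in range(n))
    if n > 1:
        ties.append(fixed)
        ties.append(loaded)

    return SpringSystem(n_helices=n, bp_per_helix=bp, node_a=node_a,
                        node_b=node_b, stiffness=stiff, labels=labs,
                        rigid_ties=ties, fixed_plate=fixed,
                        loaded_plate=loaded)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = np.arange(n)

    def find(self, i: int) -> int:
        p = self.parent
        root = i
        while p[root] != root:
            root = p[root]
        while p[i] != root:
            p[i], i = root, p[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _merged_dofs(system: SpringSystem):
    uf = _UnionFind(system.n_nodes)
    for tie in system.rigid_ties:
        it = iter(tie)
        first = next(it)
        for other in it:
            uf.union(first, other)
    roots = np.array([uf.find(i) for i in range(system.n_nodes)])
    unique, dof_of_node = np.unique(roots, return_inverse=True)
    return dof_of_node, len(unique)


def solve_tension(system: SpringSystem, force: float) -> float:
    """Extension (nm) of the loaded end plate under an axial force (pN).

    Solves the constrained linear equilibrium exactly on merged DOFs.
    Raises :class:`SingularSystemError` if the load path is disconnected.
    """
    if force < 0:
        raise ValidationError("force must be >= 0")
    dof, n_dof = _merged_dofs(system)
    a = dof[system.node_a]
    b = dof[system.node_b]
    k = system.stiffness
    fixed = dof[next(iter(system.fixed_plate))]
    loaded = dof[next(iter(system.loaded_plate))]
    if fixed == loaded:
        raise ValidationError("fixed and loaded plates are tied together")

    adj = sp.coo_matrix((np.ones_like(k), (a, b)), shape=(n_dof, n_dof))
    ncomp, comp = csgraph.connected_components(adj, directed=False)
    if comp[fixed] != comp[loaded]:
        raise SingularSystemError(
            "no connected load path between the end plates")

    rows = np.concatenate([a, b, a, b])
    cols = np.concatenate([a, b, b, a])
    vals = np.concatenate([k, k, -k, -k])
    K = sp.coo_matrix((vals, (rows, cols)), shape=(n_dof, n_dof)).tocsr()

    keep = np.ones(n_dof, dtype=bool)
    keep[fixed] = False
    # Drop DOFs not on the load path (springs there carry no load).
    keep &= comp == comp[fixed]
    idx = np.flatnonzero(keep)
    pos = -np.ones(n_dof, dtype=int)
    pos[idx] = np.arange(len(idx))
    Kr = K[idx][:, idx]
    f = np.zeros(len(idx))
    f[pos[loaded]] = force
    u = spla.spsolve(Kr.tocsc(), f)
    if not np.all(np.isfinite(u)):
        raise SingularSystemError("singular stiffness matrix")
    return float(u[pos[loaded]])


@dataclass(frozen=True)
class ForceExtensionCurve:
    """Force (pN) vs extension (nm) of the loaded end plate."""

    forces: np.ndarray
    extensions: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.forces, dtype=float)
        x = np.asarray(self.extensions, dtype=float)
        if f.shape != x.shape:
            raise ValidationError("forces and extensions must align")
        if np.any(np.diff(f) <= 0) or np.any(np.diff(x) <= 0):
            raise ValidationError("curve must be strictly increasing")
        object.__setattr__(self, "forces", f)
        object.__setattr__(self, "extensions", x)


@dataclass(frozen=True)
class StiffnessResult:
    """Apparent axial stiffness: slope of F vs extension times length."""

    apparent_stiffness: float   # pN
    L0: float                   # nm
    slope: float                # pN/nm


def force_extension(design: NanobeamDesign, material: MaterialParams,
                    forces: np.ndarray | list[float]) -> ForceExtensionCurve:
    """Force-extension curve from repeated network solves."""
    system = assemble(design, material)
    f = np.asarray(forces, dtype=float)
    # Linear model: one solve fixes the whole curve.
    delta_ref = solve_tension(system, REFERENCE_FORCE_PN)
    return ForceExtensionCurve(forces=f,
                               extensions=f * (delta_ref / REFERENCE_FORCE_PN))


def apparent_stiffness(design: NanobeamDesign, material: MaterialParams,
                       reference_force: float = REFERENCE_FORCE_PN
                       ) -> StiffnessResult:
    """Apparent axial stiffness ``K = (F / delta) * L0`` of a design."""
    system = assemble(design, material)
    delta = solve_tension(system, reference_force)
    slope = reference_force / delta
    L0 = design.length_nm
    return StiffnessResult(apparent_stiffness=slope * L0, L0=L0, slope=slope)


def homogenized_stiffness(n_helices: int, junctions_per_21bp: float,
                          nicks_per_21bp: float,
                          material: MaterialParams) -> float:
    """Closed-form stiffness of a periodic bundle (analytic oracle).

    ``junctions_per_21bp`` / ``nicks_per_21bp`` are per-helix densities.
    """
    j, nu = junctions_per_21bp, nicks_per_21bp
    if n_helices < 1 or j < 0 or nu < 0:
        raise ValidationError("invalid homogenization arguments")
    degraded = material.n_hj * j + material.n_nick * nu
    if degraded > REPEAT_BP:
        raise ValidationError(
            f"degraded span {degraded} bp exceeds the {REPEAT_BP} bp repeat")
    c_rep = (REPEAT_BP - degraded
             + material.n_hj * j / material.alpha
             + material.n_nick * nu / material.beta)
    return n_helices * material.EA * REPEAT_BP / c_rep


def bundle_sweep(n_list: list[int], packings: list[str],
                 material: MaterialParams, junctions_per_helix_per_21bp: float,
                 nicks_per_helix_per_21bp: float,
                 length_nm: float = 428.0):
    """Stiffness table over bundle sizes and packings.

    Returns a pandas DataFrame with columns ``n_helices, packing,
    stiffness_pN, normalized`` where ``normalized = K / EA`` is the stiffness
    relative to one intact B-form duplex.
    """
    import pandas as pd

    from .designs import build_bundle

    rows = []
    for packing in packings:
        for n in n_list:
            design = build_bundle(n, packing, length_nm,
                                  junctions_per_helix_per_21bp,
                                  nicks_per_helix_per_21bp,
                                  rise_per_bp=material.rise_per_bp)
            res = apparent_stiffness(design, material)
            rows.append({"n_helices": n, "packing": packing,
                         "stiffness_pN": res.apparent_stiffness,
                         "normalized": res.apparent_stiffness / material.EA})
    return pd.DataFrame(rows)
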